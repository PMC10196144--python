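# Methods

## Scope

`strainpi` implements the quantitative core of a strain-level gut-metagenome
workflow: per-position allele-count pileups from read alignments,
coverage-gated selection of reference genomes, a simple frequency-threshold
variant caller with cross-sample support filters, nucleotide diversity (π)
and the fixation index (F\_ST) estimated directly from pileups, strain trees
from consensus-allele p-distances, community-level diversity statistics
(Shannon, Bray–Curtis, PERMANOVA), a three-class draft-genome quality rule,
and a simplified best-match screen for horizontal gene transfer (HGT) with a
fragment-based average nucleotide identity (ANI) gate and keyword
classification of mobile genetic elements. A synthetic-community generator
with exact ground truth makes every stage testable without external data.

## Diversity estimators

For genome *G* of length |*G*|, sample *S*, base counts *x*<sub>*i,B*</sub>
and coverage *c*<sub>*i*</sub> = Σ<sub>*B*</sub> *x*<sub>*i,B*</sub> at
position *i*:

* **π within a sample** — the probability that two reads drawn *without
  replacement* at a position carry different bases, averaged over all |*G*|
  positions:
  π(S,G) = (1/|G|) Σ<sub>i</sub> Σ<sub>B1</sub> Σ<sub>B2≠B1</sub>
  (x<sub>i,B1</sub>/c<sub>i</sub>) (x<sub>i,B2</sub>/(c<sub>i</sub>−1)).
  The c−1 denominator makes the per-site term an unbiased estimator of the
  population heterozygosity 2p(1−p).
* **π between samples** — one read drawn from each sample:
  π(S1,S2,G) = (1/|G|) Σ<sub>i</sub> Σ<sub>B1</sub> Σ<sub>B2≠B1</sub>
  (x<sub>i,B1,S1</sub>/c<sub>i,S1</sub>) (x<sub>i,B2,S2</sub>/c<sub>i,S2</sub>).
* **F\_ST** = 1 − ((π(S1,G)+π(S2,G))/2) / π(S1,S2,G).

Numerical conventions, chosen where the formulas are silent:

* Sites with c < 2 contribute 0 to π within (no read pair exists) but still
  count in the 1/|G| normalisation; sites uncovered in either sample
  contribute 0 to π between, same normalisation. An optional
  covered-sites-only normalisation is not provided for π within because the
  |G| convention is what makes π comparable across samples with different
  breadth.
* Negative F\_ST (sampling noise when differentiation is ~0) is clamped to 0
  and flagged; π between = 0 with π within = 0 returns 0 with an
  `undefined` flag; π between = 0 with positive within-diversity is treated
  as inconsistent input and raises.
* Because π within uses the c−1 correction while π between does not, F\_ST
  between a sample and itself at finite depth is slightly negative in
  expectation — visible as clamped zeros, not an error.

## Coverage gate and thinning

Breadth is the fraction of genome positions with depth ≥ 1 (the depth floor
is 1 deliberately; a higher floor would conflate breadth with depth). Mean
depth averages over **all** genome positions, so it equals
(aligned bases)/|G|. A genome enters strain-level analysis when breadth
≥ 0.40 in at least one sample (inclusive — "at least 40%") and the sum of
per-sample mean depths is **strictly** greater than 10X ("more than 10X").
"Cumulative depth" is interpreted as that sum over samples; the source
protocol does not define it further.

Depth subsampling multiplies every base count by an independent
Binomial(x, r) with r = target/observed mean depth — exactly the count
distribution of keeping each read with probability r. The saturation
analysis re-calls SNPs at each thinned depth; the plateau is the smallest
grid depth reaching 95% (configurable) of the deepest grid point's count.
The 0.95 fraction is a package choice; the underlying stability criterion
in the source protocol is qualitative.

## Variant calling and filtering

The caller is a frequency-threshold model, stated plainly as a divergence
from likelihood-based callers such as GATK: a non-reference base is a
candidate SNP in a sample when its count ≥ `min_alt_reads` (default 2) and
its fraction of coverage ≥ `min_alt_frac` (default 0.1). Candidates merge
across samples per (genome, position, alt). CIGAR-reported
insertions/deletions are aggregated per anchor position with the same count
threshold (no fraction gate — indel-spanning coverage is not tracked per
base); there is no local reassembly. External VCFs with per-sample AD
fields are accepted as an alternative input; multi-allelic records are
split with AD apportioned per alt.

The retention filter keeps a variant present in ≥ `min_samples` samples
(default 2) and supported by ≥ `min_reads` reads (default 4). The read
threshold's scope is ambiguous in the source protocol; the default
`per_sample` scope requires **every** supporting sample to reach the
threshold (the stricter, more reproducible reading), and
`per_variant_total` sums support across samples. Both are implemented and
fixture-tested.

## p-distance and neighbor joining

Per filtered SNP site, a sample's consensus allele is the alternate when
alt-supporting reads exceed half the site depth; a sample covers a site at
depth ≥ 4 (aligned with the support filter). The p-distance between two
samples is the fraction of jointly covered sites with differing consensus
alleles; pairs sharing no site are missing, never 0. Neighbor joining is
the classic Saitou–Nei agglomeration with two pinned details: ties in the
Q criterion break deterministically on the lexicographically smallest leaf
label pair, and a negative branch length is set to 0 with the deficit moved
to its sibling, preserving the joined pair's path length. On additive
matrices the generating tree's path-length matrix is reproduced exactly
(machine precision). Output is an unrooted tree with a trifurcation at the
final join, serialised to Newick.

## Community statistics and MAG quality

Shannon entropy uses natural log (base 2 via flag). Bray–Curtis is
Σ|a−b|/Σ(a+b) via `scipy`. PERMANOVA computes Anderson's pseudo-F from
sums of squared distances on the distance matrix and permutes sample labels
freely (no strata), p = (1 + #{F\* ≥ F}) / (1 + permutations), seeded; the
statistic is verified against scikit-bio's implementation in the test
suite. Draft-genome bins classify as **low** when completeness ≤ 50% or
contamination ≥ 5%, **high** when completeness > 90% and contamination
< 5%, **medium** otherwise. The boundary conventions (50 → low, 90 →
medium, 5 → low) make the three rules exhaustive and mutually exclusive;
contamination above 100% is accepted as CheckM can report it.

## HGT screen

Only the best-match branch of HGT detection is implemented; the
phylogenetic-incongruency validation used by reconciliation-based tools is
out of scope and the screen is correspondingly more permissive on real
data. A gene is called transferred when its best hit in another genome
(shared-k-mer seeding, k = 16, full-query infix alignment by edit distance
via `edlib`) reaches ≥ 99% identity over ≥ 500 aligned bases at 100% query
coverage, the genomes carry different taxon labels at the grouping rank
(genus-like; supplied as labels, not inferred), and the genome pair's ANI
is below the 97% within-species ceiling. The 99% identity default mirrors
the observation that detected transfers concentrate above 99% identity.

ANI cuts the query genome into consecutive 1 kb fragments, aligns each to
its best seeded placement in the subject, and averages identity over
fragments with ≥ 70% identity; the symmetrised mean of both directions is
also reported. Inside the HGT gate, an ANI estimate built from fewer than
10% of the genome's fragments is treated as undefined: an isolated
high-identity region — typically the transferred gene itself — must not
masquerade as genome-wide relatedness. This mirrors the
minimum-mapped-fragment behaviour of whole-genome ANI tools.

Donor/recipient direction uses a copy-count majority over taxa: the taxon
holding more near-identical copies of the gene is the donor side; ties
leave the event undirected. This is a stated heuristic, not a phylogenetic
inference. Transfer frequency is 100 × (species pairs with ≥ 1 event) /
C(n, 2). Mobile-element classification applies keyword rules in fixed
order (Transposons → Phage → Plasmid → Other MGE → Unclassified);
`transpos*` is a prefix wildcard, short tokens (`TN`, `IS element`) match
standalone only, and the gene symbols `Tra[A-Z]`, `Mob[A-Z]`,
`Vir[A-Z][0-9]` are case-sensitive.

## Synthetic communities

The generator emulates a longitudinal multi-individual study design:
i.i.d. uniform reference genomes; per-position coverage ~ Poisson(mean
depth), independent across positions (the simplest model producing breadth
< 1 at low depth); biallelic variant sites with per-sample alternate
frequencies (multi-allelic sites are excluded from the generator — the π
estimator handles four alleles and is tested on hand-built pileups);
uniform base-call errors substituting to the other three bases; ungapped
fixed-length reads with full-match CIGARs (indel truth goes directly into
variant-table fixtures, since the caller's indel branch is
threshold-based, not realignment-based); and gene implants between genomes
with per-base point mutations, placed in non-overlapping windows so each
transferred gene is shared by exactly its donor/recipient pair. Sample
grouping (individual × time point) is emitted as metadata to drive
within/between-individual contrasts and PERMANOVA.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: alignment artefacts and mapping bias,
non-uniform coverage (GC, edge effects), correlated and quality-dependent
errors, true indel reads, linked variation along haplotypes,
within-species recombination, and barcoded long-fragment library
structure. Every stochastic draw derives from a single integer seed; a
fixed configuration reproduces byte-identical FASTA/SAM/TSV output.

Analytic truth recorded alongside: per-site expected heterozygosity
2p(1−p); per-pair expected π between p₁(1−p₂)+p₂(1−p₁); expected F\_ST from
the two. These closed forms are the oracles for the estimator-recovery
tests.

## Problem sizes in the validation suite

The benchmark scenarios (tests and `scripts/acceptance.py`) run at desk
scale, chosen to keep Monte-Carlo error well inside the asserted
tolerances: 1,000 random sites for the brute-force π checks; 20 replicate
communities of 10⁵ bp / 1,000 sites for π recovery; depth 10³ for the
F\_ST extremes; 50 random additive matrices (≤ 16 taxa) for neighbor
joining; 500 null datasets × 999 permutations for the PERMANOVA type-I
rate; a 20 kb / 200-site community at 120X for the saturation curve; a
10 × 50 kb community with 8 implanted transfers for the HGT screen; and
10 kb genome pairs at mutation rates 1–5% for ANI recovery.

## Known limitations

* The variant caller has no genotype likelihoods, base-quality model, or
  realignment; its false-negative profile at low frequency × depth is
  exactly the binomial tail, which the saturation oracle exploits.
* p-distance collapses each sample to a consensus haplotype; mixed strains
  within a sample are invisible to the tree (though π captures them).
* The HGT screen's direction heuristic cannot resolve two-taxon exchanges
  with equal copy numbers, and detection is blind to transfers between
  genomes sharing the grouping-rank label.
* Fragment ANI is a simplification of alignment-free ANI estimators; its
  identity floor (70%) makes it undefined for very distant pairs, which
  the HGT gate interprets as "not the same species".
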