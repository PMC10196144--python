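"""Synthetic multi-genome communities with known ground truth.

The generator emulates the design of a longitudinal gut-microbiome strain
study: several reference genomes (labelled at a genus-like rank), several
samples grouped by individual and time point, biallelic strain variation at
configurable per-sample allele frequencies, Poisson sequencing depth with
uniform base-call error, and optional gene copies implanted from a donor
genome into a recipient of a different taxon to mimic horizontal transfer.

Every stochastic quantity derives from ``SimConfig.seed``: the same config
produces byte-identical FASTA/SAM/TSV output.  The accompanying
``TruthTable`` records what was implanted together with the analytic
diversity values an infinite-depth estimator would recover — the oracle the
pileup-based estimators are tested against.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from strainpi.pileup_coverage import PileupMatrix

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class HGTSpec:
    """One gene copied from ``donor`` into ``recipient`` with point mutations."""

    donor: str
    recipient: str
    gene_length: int = 1000
    mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.gene_length < 1:
            raise ValueError("gene_length must be positive")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must be in [0, 1)")
        if self.donor == self.recipient:
            raise ValueError("donor and recipient must differ")


@dataclass
class SimConfig:
    n_genomes: int = 3
    genome_length: int = 50_000
    taxon_labels: Sequence[str] | None = None
    n_samples: int = 4
    sample_groups: Sequence[tuple[str, str]] | None = None  # (individual, time point)
    variant_sites_per_genome: int = 100
    allele_freq_spec: float | np.ndarray = 0.3
    mean_depth: float = 30.0
    read_length: int = 100
    error_rate: float = 0.0
    hgt_spec: Sequence[HGTSpec] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1 or self.n_samples < 1:
            raise ValueError("need at least one genome and one sample")
        if self.genome_length < self.read_length:
            raise ValueError("genome_length must be >= read_length")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")
        freqs = np.asarray(self.allele_freq_spec, dtype=float)
        if ((freqs < 0) | (freqs > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")
        for spec in self.hgt_spec:
            if spec.gene_length > self.genome_length:
                raise ValueError("HGT gene longer than genome")
        if self.taxon_labels is None:
            self.taxon_labels = [f"genus{i}" for i in range(self.n_genomes)]
        if len(self.taxon_labels) != self.n_genomes:
            raise ValueError("one taxon label per genome required")
        if self.sample_groups is None:
            # two time points per individual by default
            self.sample_groups = [
                (f"P{i // 2 + 1}", f"T{i % 2 + 1}") for i in range(self.n_samples)
            ]
        if len(self.sample_groups) != self.n_samples:
            raise ValueError("one (individual, time point) pair per sample required")

    @property
    def genome_ids(self) -> list[str]:
        return [f"g{i}" for i in range(self.n_genomes)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"s{i}" for i in range(self.n_samples)]

    def allele_freqs(self) -> np.ndarray:
        """Per-sample, per-site alternate allele frequencies, shape (n_samples, n_sites)."""
        freqs = np.asarray(self.allele_freq_spec, dtype=float)
        target = (self.n_samples, self.variant_sites_per_genome)
        return np.broadcast_to(freqs, target).copy()


@dataclass(frozen=True)
class ImplantedGene:
    gene_id: str
    donor: str
    recipient: str
    donor_start: int  # 1-based inclusive
    recipient_start: int
    length: int
    n_mutations: int
    sequence: str


@dataclass
class TruthTable:
    """Ground truth for one generated community.

    ``variant_positions[g]`` holds the 1-based implanted variant positions of
    genome g; ``alt_alleles[g]`` the alternate base at each; ``allele_freqs[g]``
    the (n_samples, n_sites) alternate frequencies.  Analytic expectations are
    those an infinite-depth, error-free estimator would recover.
    """

    config: SimConfig
    variant_positions: dict[str, np.ndarray]
    alt_alleles: dict[str, np.ndarray]
    allele_freqs: dict[str, np.ndarray]
    hgt_genes: list[ImplantedGene]

    def expected_site_diversity(self, genome: str) -> np.ndarray:
        """Per-site within-sample heterozygosity 2p(1-p), shape (n_samples, n_sites)."""
        p = self.allele_freqs[genome]
        return 2.0 * p * (1.0 - p)

    def expected_pi_within(self, genome: str) -> np.ndarray:
        """Analytic genome-wide pi per sample at infinite depth."""
        return self.expected_site_diversity(genome).sum(axis=1) / self.config.genome_length

    def expected_pi_between(self, genome: str, s1: int, s2: int) -> float:
        p1 = self.allele_freqs[genome][s1]
        p2 = self.allele_freqs[genome][s2]
        site = p1 * (1 - p2) + p2 * (1 - p1)
        return float(site.sum() / self.config.genome_length)

    def expected_fst(self, genome: str, s1: int, s2: int) -> float:
        pw = self.expected_pi_within(genome)
        pb = self.expected_pi_between(genome, s1, s2)
        if pb == 0:
            return 0.0
        return 1.0 - ((pw[s1] + pw[s2]) / 2.0) / pb


def _seq_to_str(arr: np.ndarray) -> str:
    return _BASE_ARR[arr].tobytes().decode("ascii")


def generate_references(config: SimConfig) -> tuple[dict[str, str], TruthTable]:
    """Generate reference genomes and the matching truth table.

    Returns (genome id -> sequence, TruthTable).  HGT genes are copied from
    the donor into the recipient (overwriting the recipient at a random
    location) with point mutations applied to the recipient copy at the
    specified per-base rate.  Variant sites are chosen after implantation so
    reference sequences and truth agree.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    genomes = {g: rng.integers(0, 4, size=L, dtype=np.int8) for g in config.genome_ids}

    hgt_genes: list[ImplantedGene] = []
    # keep implant windows disjoint per genome so each transferred gene is
    # shared by exactly its donor/recipient pair and truth stays exact
    occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in config.genome_ids}

    def _draw_start(genome: str, glen: int) -> int:
        for _ in range(200):
            start = int(rng.integers(0, L - glen + 1))
            if all(start + glen <= a or start >= b for a, b in occupied[genome]):
                return start
        raise ValueError(f"cannot place non-overlapping HGT gene in {genome}")

    for k, spec in enumerate(config.hgt_spec):
        glen = spec.gene_length
        donor_start = _draw_start(spec.donor, glen)
        recip_start = _draw_start(spec.recipient, glen)
        occupied[spec.donor].append((donor_start, donor_start + glen))
        occupied[spec.recipient].append((recip_start, recip_start + glen))
        gene = genomes[spec.donor][donor_start : donor_start + glen].copy()
        n_mut = int(rng.binomial(glen, spec.mutation_rate)) if spec.mutation_rate else 0
        if n_mut:
            sites = rng.choice(glen, size=n_mut, replace=False)
            shift = rng.integers(1, 4, size=n_mut)
            gene[sites] = (gene[sites] + shift) % 4
        genomes[spec.recipient][recip_start : recip_start + glen] = gene
        hgt_genes.append(
            ImplantedGene(
                gene_id=f"hgt{k}",
                donor=spec.donor,
                recipient=spec.recipient,
                donor_start=donor_start + 1,
                recipient_start=recip_start + 1,
                length=glen,
                n_mutations=n_mut,
                sequence=_seq_to_str(gene),
            )
        )

    variant_positions: dict[str, np.ndarray] = {}
    alt_alleles: dict[str, np.ndarray] = {}
    allele_freqs: dict[str, np.ndarray] = {}
    base_freqs = config.allele_freqs()
    for g in config.genome_ids:
        n_sites = config.variant_sites_per_genome
        pos = np.sort(rng.choice(L, size=n_sites, replace=False)) if n_sites else np.empty(0, dtype=int)
        ref = genomes[g][pos]
        alt = (ref + rng.integers(1, 4, size=len(pos))) % 4
        variant_positions[g] = pos + 1
        alt_alleles[g] = alt.astype(np.int8)
        allele_freqs[g] = base_freqs.copy()

    refs = {g: _seq_to_str(arr.astype(np.uint8)) for g, arr in genomes.items()}
    truth = TruthTable(
        config=config,
        variant_positions=variant_positions,
        alt_alleles=alt_alleles,
        allele_freqs=allele_freqs,
        hgt_genes=hgt_genes,
    )
    return refs, truth


def _apply_errors(counts: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each counted base with prob error_rate, uniformly to the other 3."""
    if error_rate == 0:
        return counts
    counts = counts.copy()
    for b in range(4):
        errs = rng.binomial(counts[:, b], error_rate)
        if errs.sum() == 0:
            continue
        counts[:, b] -= errs
        others = [j for j in range(4) if j != b]
        split = rng.multinomial(errs, [1 / 3] * 3)
        for j, col in enumerate(others):
            counts[:, col] += split[:, j]
    return counts


def simulate_pileups(
    config: SimConfig, refs: Mapping[str, str], truth: TruthTable
) -> dict[str, dict[str, PileupMatrix]]:
    """Simulate per-sample pileups directly (no reads).

    Coverage at each position is Poisson(mean_depth), independent across
    positions.  At implanted variant sites the alternate-allele count is
    Binomial(coverage, sample allele frequency); elsewhere all reads carry
    the reference base.  Base-call errors then substitute each counted base
    uniformly among the other three with probability ``error_rate``.

    Returns {sample id: {genome id: PileupMatrix}}.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    L = config.genome_length
    out: dict[str, dict[str, PileupMatrix]] = {}
    for si, sample in enumerate(config.sample_ids):
        per_genome: dict[str, PileupMatrix] = {}
        for g in config.genome_ids:
            seq = np.frombuffer(refs[g].encode(), dtype=np.uint8)
            ref_idx = np.searchsorted(_BASE_ARR, seq)  # ACGT are sorted bytes
            cov = rng.poisson(config.mean_depth, size=L)
            counts = np.zeros((L, 4), dtype=np.int64)
            np.add.at(counts, (np.arange(L), ref_idx), cov)
            pos0 = truth.variant_positions[g] - 1
            if len(pos0):
                p = truth.allele_freqs[g][si]
                alt_n = rng.binomial(cov[pos0], p)
                alt_b = truth.alt_alleles[g]
                counts[pos0, ref_idx[pos0]] -= alt_n
                np.add.at(counts, (pos0, alt_b), alt_n)
            counts = _apply_errors(counts, config.error_rate, rng)
            per_genome[g] = PileupMatrix(g, counts, ref=refs[g])
        out[sample] = per_genome
    return out


@dataclass(frozen=True)
class SimRead:
    """One simulated ungapped read (full-length match CIGAR)."""

    name: str
    genome: str
    pos: int  # 1-based leftmost mapped position
    sequence: str


def simulate_reads(
    config: SimConfig, refs: Mapping[str, str], truth: TruthTable
) -> dict[str, list[SimRead]]:
    """Simulate per-sample reads consistent with the pileup model.

    Per genome and sample, round(mean_depth * genome_length / read_length)
    reads of ``read_length`` are placed uniformly.  Each read carries either
    the reference or the alternate haplotype base at implanted variant sites
    (alternate with the sample's allele frequency, independently per site),
    then per-base errors at ``error_rate``.  All reads map forward with a
    full-length match CIGAR.
    """
    if config.read_length > config.genome_length:
        raise ValueError("read_length exceeds genome_length")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rl = config.read_length
    L = config.genome_length
    n_reads = int(round(config.mean_depth * L / rl))
    out: dict[str, list[SimRead]] = {}
    for si, sample in enumerate(config.sample_ids):
        reads: list[SimRead] = []
        for g in config.genome_ids:
            seq = np.frombuffer(refs[g].encode(), dtype=np.uint8)
            base_idx = np.searchsorted(_BASE_ARR, seq)
            vpos = truth.variant_positions[g] - 1
            valt = truth.alt_alleles[g]
            pfreq = truth.allele_freqs[g][si] if len(vpos) else None
            starts = rng.integers(0, L - rl + 1, size=n_reads)
            for r, start in enumerate(starts):
                read = base_idx[start : start + rl].copy()
                if len(vpos):
                    inside = (vpos >= start) & (vpos < start + rl)
                    if inside.any():
                        idx = np.nonzero(inside)[0]
                        take_alt = rng.random(len(idx)) < pfreq[idx]
                        read[vpos[idx[take_alt]] - start] = valt[idx[take_alt]]
                if config.error_rate:
                    errs = np.nonzero(rng.random(rl) < config.error_rate)[0]
                    if len(errs):
                        read[errs] = (read[errs] + rng.integers(1, 4, size=len(errs))) % 4
                reads.append(
                    SimRead(
                        name=f"{sample}:{g}:r{r}",
                        genome=g,
                        pos=int(start) + 1,
                        sequence=_seq_to_str(read.astype(np.uint8)),
                    )
                )
        out[sample] = reads
    return out


# ---------------------------------------------------------------------------
# serialization


def write_fasta(refs: Mapping[str, str], path, taxa: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, seq in refs.items():
            header = name if taxa is None else f"{name} taxon={taxa[name]}"
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_sam(reads: Sequence[SimRead], reference_lengths: Mapping[str, int], path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": g, "LN": length} for g, length in reference_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {g: i for i, g in enumerate(reference_lengths)}
        for read in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.name
            a.query_sequence = read.sequence
            a.flag = 0
            a.reference_id = tid[read.genome]
            a.reference_start = read.pos - 1
            a.mapping_quality = 60
            a.cigarstring = f"{len(read.sequence)}M"
            out.write(a)


def write_sample_metadata(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tindividual\ttime_point\n")
        for sample, (ind, tp) in zip(config.sample_ids, config.sample_groups):
            fh.write(f"{sample}\t{ind}\t{tp}\n")


def write_truth(truth: TruthTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\tpos\talt\t" + "\t".join(f"freq_{s}" for s in truth.config.sample_ids) + "\n")
        for g in truth.config.genome_ids:
            for j, pos in enumerate(truth.variant_positions[g]):
                freqs = "\t".join(f"{truth.allele_freqs[g][si, j]:.6g}" for si in range(truth.config.n_samples))
                fh.write(f"{g}\t{pos}\t{BASES[truth.alt_alleles[g][j]]}\t{freqs}\n")


def write_community(config: SimConfig, outdir) -> tuple[dict[str, str], TruthTable]:
    """Generate a community and write FASTA, SAM, pileup TSVs, truth and metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs, truth = generate_references(config)
    taxa = dict(zip(config.genome_ids, config.taxon_labels))
    write_fasta(refs, outdir / "references.fa", taxa=taxa)
    write_truth(truth, outdir / "truth_variants.tsv")
    write_sample_metadata(config, outdir / "samples.tsv")
    lengths = {g: len(s) for g, s in refs.items()}
    reads = simulate_reads(config, refs, truth)
    for sample, rlist in reads.items():
        write_sam(rlist, lengths, outdir / f"{sample}.sam")
    pileups = simulate_pileups(config, refs, truth)
    for sample, per_genome in pileups.items():
        frames = [p.to_frame() for p in per_genome.values()]
        import pandas as pd

        pd.concat(frames).to_csv(outdir / f"{sample}.pileup.tsv", sep="\t", index=False)
    return refs, truth
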