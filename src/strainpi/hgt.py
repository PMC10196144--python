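"""Horizontal gene transfer screening between genomes of distinct taxa.

The screen looks for genes present in two genomes at anomalously high
nucleotide identity relative to the genomic background.  Genome-wide
relatedness is measured by a fragment-based average nucleotide identity
(ANI): the query genome is cut into consecutive fixed-length windows, each
window is aligned to its best hit in the subject (k-mer seeded, edit
distance via edlib) and ANI is the mean identity over windows reaching a
minimum identity.  A gene is called horizontally transferred when its best
hit in another genome has identity >= ``min_identity`` over >= ``min_len``
aligned bases at full query coverage, the two genomes carry different
taxon labels at the grouping rank (genus in the source protocol), and the
genome pair's ANI is below the within-species ceiling (``ani_max``, 97%).

Transfer prevalence is summarised as the number of species pairs with at
least one event per 100 species pairs, and transferred genes are sorted
into mobile-element categories by keyword rules applied to their
functional description text (transposon, phage, plasmid machinery, other
recombinase/integrase, unclassified).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import edlib
import numpy as np


@dataclass(frozen=True)
class ANIResult:
    genome_a: str
    genome_b: str
    ani: float | None  # percent, None when no fragment passes
    n_fragments: int  # fragments passing the identity floor
    ani_symmetric: float | None = None
    fragment_fraction: float = 0.0  # passing fragments / total query fragments


@dataclass(frozen=True)
class HGTEvent:
    gene_id: str
    donor: str  # empty string when direction is undecided
    recipient: str
    genome_pair: tuple[str, str]  # sorted
    identity: float  # percent
    aligned_length: int
    donor_taxon: str
    recipient_taxon: str


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def _best_hit(query: str, target: str, index: dict[str, list[int]], k: int) -> tuple[float, int] | None:
    """Best local placement of the full query within the target.

    Seeds with shared k-mers, then computes the edit distance of the whole
    query against a window of the target around each seed cluster (infix
    alignment).  Returns (identity fraction, aligned length = len(query))
    or None when no seed is found.
    """
    hits: set[int] = set()
    step = max(1, k // 2)
    for qpos in range(0, len(query) - k + 1, step):
        for tpos in index.get(query[qpos : qpos + k], ()):
            hits.add(tpos - qpos)  # implied target start of the query
    if not hits:
        return None
    # cluster implied starts within one query length
    starts = sorted(hits)
    best_dist = None
    margin = max(16, len(query) // 10)
    merged: list[int] = []
    for s in starts:
        if not merged or s - merged[-1] > len(query) // 2:
            merged.append(s)
    for s in merged:
        lo = max(0, s - margin)
        hi = min(len(target), s + len(query) + margin)
        res = edlib.align(query, target[lo:hi], mode="HW", task="distance")
        dist = res["editDistance"]
        if dist >= 0 and (best_dist is None or dist < best_dist):
            best_dist = dist
    if best_dist is None:
        return None
    identity = 1.0 - best_dist / len(query)
    return identity, len(query)


def ani(
    genome_a: str,
    genome_b: str,
    frag_len: int = 1000,
    min_frag_identity: float = 70.0,
    k: int = 16,
    ids: tuple[str, str] = ("a", "b"),
) -> ANIResult:
    """Fragment-based one-directional ANI of ``genome_a`` against ``genome_b``.

    ``genome_a`` is cut into consecutive ``frag_len`` windows; each is
    placed at its best position in ``genome_b``; fragments with identity
    >= ``min_frag_identity`` percent enter the mean.  The symmetrized mean
    of both directions is also reported.
    """
    fwd = _ani_one_way(genome_a, genome_b, frag_len, min_frag_identity, k)
    rev = _ani_one_way(genome_b, genome_a, frag_len, min_frag_identity, k)
    sym = None
    vals = [v for v in (fwd[0], rev[0]) if v is not None]
    if vals:
        sym = float(np.mean(vals))
    frac = 0.5 * (fwd[1] / max(fwd[2], 1) + rev[1] / max(rev[2], 1))
    return ANIResult(
        genome_a=ids[0],
        genome_b=ids[1],
        ani=fwd[0],
        n_fragments=fwd[1],
        ani_symmetric=sym,
        fragment_fraction=frac,
    )


def _ani_one_way(qseq: str, tseq: str, frag_len: int, min_identity: float, k: int):
    if len(qseq) < frag_len or len(tseq) < frag_len:
        raise ValueError("sequence shorter than fragment length")
    index = _kmer_index(tseq, k)
    identities = []
    n_total = 0
    for start in range(0, len(qseq) - frag_len + 1, frag_len):
        n_total += 1
        frag = qseq[start : start + frag_len]
        hit = _best_hit(frag, tseq, index, k)
        if hit is None:
            continue
        ident_pct = 100.0 * hit[0]
        if ident_pct >= min_identity:
            identities.append(ident_pct)
    if not identities:
        return None, 0, n_total
    return float(np.mean(identities)), len(identities), n_total


@dataclass(frozen=True)
class Gene:
    gene_id: str
    genome: str
    taxon: str
    sequence: str


def detect_hgt_best_match(
    genes: Sequence[Gene],
    genomes: Mapping[str, str],
    taxa: Mapping[str, str],
    min_len: int = 500,
    min_identity: float = 99.0,
    require_full_cov: bool = True,
    ani_max: float = 97.0,
    k: int = 16,
    ani_frag_len: int = 1000,
    min_ani_fragment_fraction: float = 0.1,
) -> list[HGTEvent]:
    """Best-match HGT screen over a gene set and a genome set.

    For each gene, the best hit in every genome other than its source is
    located by k-mer seeding plus infix alignment.  An event is emitted
    when the hit passes the identity/length/coverage thresholds, the two
    genomes carry different taxon labels, and the genome pair's
    symmetrized ANI is below ``ani_max`` percent (or undefined — more
    distant than the ANI floor).  The ANI gate only trusts an ANI estimate
    built from at least ``min_ani_fragment_fraction`` of the genome's
    fragments: an isolated high-identity region (for instance the
    transferred gene itself) cannot masquerade as genome-wide relatedness,
    mirroring the minimum-mapped-fragment behaviour of whole-genome ANI
    tools.  Donor/recipient direction: the gene's
    source taxon, counted over near-identical copies across the gene set,
    is taken as the donor side when one taxon of the pair contributes
    strictly more copies; ties leave the event undirected (empty donor).
    """
    indexes = {g: _kmer_index(seq, k) for g, seq in genomes.items()}
    ani_cache: dict[tuple[str, str], float | None] = {}

    def pair_ani(a: str, b: str) -> float | None:
        key = tuple(sorted((a, b)))
        if key not in ani_cache:
            res = ani(
                genomes[key[0]], genomes[key[1]], frag_len=ani_frag_len, k=k, ids=key
            )
            trusted = res.fragment_fraction >= min_ani_fragment_fraction
            ani_cache[key] = res.ani_symmetric if trusted else None
        return ani_cache[key]

    # copies of each gene sequence per taxon, for the direction heuristic
    copy_count: dict[str, dict[str, int]] = {}
    for gene in genes:
        copy_count.setdefault(gene.gene_id, {})
        t = copy_count[gene.gene_id]
        t[gene.taxon] = t.get(gene.taxon, 0) + 1

    events: list[HGTEvent] = []
    for gene in genes:
        if len(gene.sequence) < min_len:
            continue
        for target, seq in genomes.items():
            if target == gene.genome:
                continue
            if len(gene.sequence) > len(seq):
                continue
            if taxa[target] == gene.taxon:
                continue
            hit = _best_hit(gene.sequence, seq, indexes[target], k)
            if hit is None:
                continue
            identity, aligned = 100.0 * hit[0], hit[1]
            if identity < min_identity:
                continue
            if aligned < min_len:
                continue
            if require_full_cov and aligned < len(gene.sequence):
                continue
            a = pair_ani(gene.genome, target)
            if a is not None and a >= ani_max:
                continue
            counts = copy_count[gene.gene_id]
            src_n = counts.get(gene.taxon, 0)
            tgt_n = counts.get(taxa[target], 0)
            if src_n > tgt_n:
                donor, recipient = gene.genome, target
                d_tax, r_tax = gene.taxon, taxa[target]
            elif tgt_n > src_n:
                donor, recipient = target, gene.genome
                d_tax, r_tax = taxa[target], gene.taxon
            else:
                donor, recipient = "", target
                d_tax, r_tax = gene.taxon, taxa[target]
            events.append(
                HGTEvent(
                    gene_id=gene.gene_id,
                    donor=donor,
                    recipient=recipient if donor else target,
                    genome_pair=tuple(sorted((gene.genome, target))),
                    identity=identity,
                    aligned_length=aligned,
                    donor_taxon=d_tax,
                    recipient_taxon=r_tax,
                )
            )
    return events


def hgt_frequency(events: Sequence[HGTEvent], n_species: int) -> float:
    """Species pairs with >= 1 transfer, per 100 species pairs."""
    if n_species < 2:
        raise ValueError("need at least two species")
    pairs = {e.genome_pair for e in events}
    return 100.0 * len(pairs) / comb(n_species, 2)


# ---------------------------------------------------------------------------
# mobile-element keyword classification

_TRANSPOSON = [
    re.compile(r"transpos", re.I),  # transpos* prefix wildcard
    re.compile(r"(?<![A-Za-z0-9])TN(?![A-Za-z])", re.I),  # standalone token, TN5 etc.
    re.compile(r"insertion element", re.I),
    re.compile(r"(?<![A-Za-z0-9])IS element", re.I),
]
_PHAGE = [
    re.compile(r"phage", re.I),
    re.compile(r"tail protein", re.I),
    re.compile(r"tegument", re.I),
    re.compile(r"capsid", re.I),
]
_PLASMID = [
    re.compile(r"relaxase", re.I),
    re.compile(r"conjugal transfer", re.I),
    re.compile(r"(?<![A-Za-z0-9])Trb", re.I),
    re.compile(r"relaxosome", re.I),
    re.compile(r"type IV secretion", re.I),
    re.compile(r"conjugation", re.I),
    re.compile(r"(?<![A-Za-z0-9])Tra[A-Z](?![a-z])"),  # case-sensitive gene symbols
    re.compile(r"(?<![A-Za-z0-9])Mob[A-Z](?![a-z])"),
    re.compile(r"(?<![A-Za-z0-9])Vir[A-Z][0-9]"),
    re.compile(r"t4ss", re.I),
    re.compile(r"resolvase", re.I),
    re.compile(r"antirestriction", re.I),
]
_OTHER_MGE = [
    re.compile(r"recombinase", re.I),
    re.compile(r"integrase", re.I),
]

_CATEGORIES = [
    ("Transposons", _TRANSPOSON),
    ("Phage", _PHAGE),
    ("Plasmid", _PLASMID),
    ("Other MGE", _OTHER_MGE),
]


def classify_mge(description: str) -> str:
    """Mobile-element category of a gene from its description text.

    Categories are tried in order Transposons, Phage, Plasmid, Other MGE;
    the first matching keyword wins; otherwise Unclassified.  Most keywords
    match case-insensitively; the gene-symbol patterns Tra[A-Z], Mob[A-Z]
    and Vir[A-Z][0-9] are case-sensitive, and short tokens (TN, IS
    element) must be standalone to avoid substring hits.
    """
    for name, patterns in _CATEGORIES:
        if any(p.search(description) for p in patterns):
            return name
    return "Unclassified"


def mge_category_proportions(descriptions: Sequence[str]) -> dict[str, float]:
    cats = [classify_mge(d) for d in descriptions]
    total = len(cats)
    out: dict[str, float] = {}
    for name in [c for c, _ in _CATEGORIES] + ["Unclassified"]:
        n = cats.count(name)
        if n:
            out[name] = n / total
    return out


# ---------------------------------------------------------------------------
# FASTA helpers (gene headers carry genome=<id> taxon=<label> tags)


def read_gene_fasta(path) -> list[Gene]:
    from Bio import SeqIO

    genes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tags = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        genes.append(
            Gene(
                gene_id=rec.id,
                genome=tags.get("genome", ""),
                taxon=tags.get("taxon", ""),
                sequence=str(rec.seq).upper(),
            )
        )
    return genes
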