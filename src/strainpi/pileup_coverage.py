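"""Per-position allele-count pileups, coverage summaries and the reference gate.

A pileup stores, for one genome in one sample, the number of aligned A/C/G/T
bases at every reference position.  Coverage breadth (fraction of positions
with depth >= 1) and mean depth (total aligned bases / genome length,
averaged over *all* positions, covered or not) drive the reference-selection
gate used before strain-level SNP analysis: a genome is analysed when its
breadth reaches ``breadth_min`` in at least one sample and the sum of its
per-sample mean depths exceeds ``cum_depth_min``.

Binomial thinning of a pileup to a lower target depth supports the
depth-saturation analysis (how many SNPs are still discoverable at reduced
coverage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

if TYPE_CHECKING:  # pragma: no cover
    from strainpi.variants import VariantRecord

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PileupMatrix:
    """Dense per-position base counts for one genome (one sample).

    ``counts`` has shape (genome_length, 4), columns ordered A, C, G, T;
    row i holds the counts for 1-based position i+1.  ``indels`` maps a
    1-based position to ``{(ref, alt): read_count}`` for insertions and
    deletions reported by alignment CIGARs.
    """

    genome: str
    counts: np.ndarray
    ref: str | None = None
    indels: dict[int, dict[tuple[str, str], int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must have shape (length, 4)")
        if (self.counts < 0).any():
            raise ValueError("negative base counts")
        if self.ref is not None and len(self.ref) != len(self.counts):
            raise ValueError("reference length does not match count matrix")

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def coverage(self) -> np.ndarray:
        """Per-position depth c_i = sum over bases of x_{i,B}."""
        return self.counts.sum(axis=1)

    def to_frame(self, *, covered_only: bool = True) -> pd.DataFrame:
        cov = self.coverage
        idx = np.nonzero(cov)[0] if covered_only else np.arange(len(self))
        refcol = (
            [self.ref[i] for i in idx] if self.ref is not None else ["N"] * len(idx)
        )
        return pd.DataFrame(
            {
                "genome": self.genome,
                "pos": idx + 1,
                "ref": refcol,
                "nA": self.counts[idx, 0],
                "nC": self.counts[idx, 1],
                "nG": self.counts[idx, 2],
                "nT": self.counts[idx, 3],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, genome_length: int | None = None) -> dict[str, "PileupMatrix"]:
        """Read a pileup TSV (columns genome, pos, ref, nA..nT) into matrices."""
        df = pd.read_csv(path, sep="\t")
        out: dict[str, PileupMatrix] = {}
        for genome, sub in df.groupby("genome", sort=False):
            length = genome_length or int(sub["pos"].max())
            counts = np.zeros((length, 4), dtype=np.int64)
            pos = sub["pos"].to_numpy() - 1
            for j, col in enumerate(["nA", "nC", "nG", "nT"]):
                counts[pos, j] = sub[col].to_numpy()
            ref = None
            if not (sub["ref"] == "N").all():
                refarr = np.full(length, "N", dtype="<U1")
                refarr[pos] = sub["ref"].to_numpy()
                ref = "".join(refarr)
            out[str(genome)] = cls(str(genome), counts, ref=ref)
        return out


@dataclass(frozen=True)
class CoverageProfile:
    """Breadth and mean depth of one genome in one sample."""

    sample: str
    genome: str
    breadth: float
    mean_depth: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.breadth <= 1.0:
            raise ValueError("breadth outside [0, 1]")
        if self.mean_depth < 0:
            raise ValueError("negative mean depth")
        if (self.breadth == 0) != (self.mean_depth == 0):
            raise ValueError("breadth and mean depth must vanish together")


@dataclass(frozen=True)
class ReferenceSelection:
    genome: str
    selected: bool
    max_breadth: float
    cumulative_depth: float


def pileup_from_alignments(
    alignments: str | Iterable[pysam.AlignedSegment],
    reference_lengths: Mapping[str, int],
    references: Mapping[str, str] | None = None,
) -> dict[str, PileupMatrix]:
    """Accumulate per-position base counts from SAM/BAM alignments.

    Only aligned bases (CIGAR M/X/=) are counted; soft-clipped bases,
    insertions and unmapped reads contribute nothing to the base counts.
    Deletions leave the deleted positions untouched.  Insertion and deletion
    events are tallied separately into ``PileupMatrix.indels`` keyed by the
    1-based position of the anchor base, VCF style.

    Parameters
    ----------
    alignments : path to a SAM/BAM file, or an iterable of aligned segments
    reference_lengths : genome id -> genome length in bases
    references : optional genome id -> sequence, stored on the pileups
    """
    counts = {
        g: np.zeros((length, 4), dtype=np.int64)
        for g, length in reference_lengths.items()
    }
    indels: dict[str, dict[int, dict[tuple[str, str], int]]] = {
        g: {} for g in reference_lengths
    }

    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        handle = pysam.AlignmentFile(str(alignments), check_sq=False)
        records: Iterable[pysam.AlignedSegment] = handle
    else:
        handle = None
        records = alignments

    try:
        for read in records:
            if read.is_unmapped:
                continue
            genome = read.reference_name
            if genome not in counts:
                raise ValueError(f"alignment to unknown genome id {genome!r}")
            mat = counts[genome]
            seq = read.query_sequence
            if seq is None:
                continue
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                base = _BASE_INDEX.get(seq[qpos])
                if base is not None and 0 <= rpos < len(mat):
                    mat[rpos, base] += 1
            _collect_cigar_indels(read, seq, references, indels[genome])
    finally:
        if handle is not None:
            handle.close()

    return {
        g: PileupMatrix(
            g,
            counts[g],
            ref=references.get(g) if references else None,
            indels=indels[g],
        )
        for g in reference_lengths
    }


def _collect_cigar_indels(read, seq, references, sink) -> None:
    """Tally I/D CIGAR operations as VCF-style (ref, alt) events."""
    rpos = read.reference_start  # 0-based
    qpos = 0
    genome_seq = references.get(read.reference_name) if references else None
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            rpos += length
            qpos += length
        elif op == 1:  # insertion: anchored at the preceding reference base
            if rpos > 0:
                anchor = genome_seq[rpos - 1] if genome_seq else "N"
                key = (anchor, anchor + seq[qpos : qpos + length])
                sink.setdefault(rpos, {})
                sink[rpos][key] = sink[rpos].get(key, 0) + 1
            qpos += length
        elif op == 2:  # deletion
            if rpos > 0:
                anchor = genome_seq[rpos - 1] if genome_seq else "N"
                deleted = (
                    genome_seq[rpos : rpos + length] if genome_seq else "N" * length
                )
                key = (anchor + deleted, anchor)
                sink.setdefault(rpos, {})
                sink[rpos][key] = sink[rpos].get(key, 0) + 1
            rpos += length
        elif op == 4:  # soft clip
            qpos += length
        elif op == 3:  # N: skip region
            rpos += length
        # H/P consume nothing we track


def coverage_profile(
    pileup: PileupMatrix, genome_length: int, sample: str = ""
) -> CoverageProfile:
    """Breadth (fraction of positions with depth >= 1) and mean depth.

    Mean depth averages over all ``genome_length`` positions, covered or
    not, so that a genome hit only in one small region reports a depth
    proportional to the aligned base total.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    cov = pileup.coverage
    if len(cov) > genome_length:
        raise ValueError("pileup longer than stated genome length")
    breadth = float(np.count_nonzero(cov)) / genome_length
    mean_depth = float(cov.sum()) / genome_length
    return CoverageProfile(sample=sample, genome=pileup.genome, breadth=breadth, mean_depth=mean_depth)


def select_references(
    profiles: Sequence[CoverageProfile],
    breadth_min: float = 0.40,
    cum_depth_min: float = 10.0,
) -> list[ReferenceSelection]:
    """Apply the reference-selection gate over per-sample coverage profiles.

    A genome passes when its breadth is at least ``breadth_min`` in at least
    one sample (inclusive) and the cumulative depth — the sum over samples of
    per-sample mean depth — is strictly greater than ``cum_depth_min``.
    """
    if not profiles:
        raise ValueError("no coverage profiles supplied")
    by_genome: dict[str, list[CoverageProfile]] = {}
    for p in profiles:
        by_genome.setdefault(p.genome, []).append(p)
    out = []
    for genome in by_genome:
        ps = by_genome[genome]
        max_breadth = max(p.breadth for p in ps)
        cum_depth = sum(p.mean_depth for p in ps)
        out.append(
            ReferenceSelection(
                genome=genome,
                selected=(max_breadth >= breadth_min and cum_depth > cum_depth_min),
                max_breadth=max_breadth,
                cumulative_depth=cum_depth,
            )
        )
    return out


def thin_pileup(pileup: PileupMatrix, target_depth: float, seed: int) -> PileupMatrix:
    """Binomially thin a pileup down to ``target_depth`` mean coverage.

    Each base count x is replaced by Binomial(x, target_depth / mean_depth)
    independently, which is exactly the count distribution obtained by
    keeping each original read with that probability.
    """
    mean_depth = pileup.coverage.sum() / len(pileup)
    if target_depth < 0:
        raise ValueError("target_depth must be non-negative")
    if mean_depth == 0:
        if target_depth > 0:
            raise ValueError("cannot thin an empty pileup to positive depth")
        return PileupMatrix(pileup.genome, np.zeros_like(pileup.counts), ref=pileup.ref)
    ratio = target_depth / mean_depth
    if ratio > 1.0 + 1e-12:
        raise ValueError(
            f"target depth {target_depth} exceeds observed mean depth {mean_depth:.3f}"
        )
    ratio = min(ratio, 1.0)
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(pileup.counts, ratio)
    return PileupMatrix(pileup.genome, thinned, ref=pileup.ref)


def saturation_curve(
    pileups: Mapping[str, PileupMatrix],
    references: Mapping[str, str],
    depth_grid: Sequence[float],
    seed: int,
    plateau_fraction: float = 0.95,
    caller_kwargs: Mapping | None = None,
    filter_policy=None,
) -> tuple[list[tuple[float, int]], float]:
    """SNP counts after thinning each sample's pileup to each grid depth.

    ``pileups`` maps sample id -> PileupMatrix for a single genome.  At each
    depth the pileups are thinned, SNPs are called with fixed parameters,
    the cross-sample support filter is applied when ``filter_policy`` is
    given, and the retained SNP records are counted.  The plateau depth is
    the smallest grid depth whose count reaches ``plateau_fraction`` of the
    count at the deepest grid point.
    """
    from strainpi.variants import call_variants, filter_variants

    grid = list(depth_grid)
    if not grid:
        raise ValueError("empty depth grid")
    if sorted(grid) != grid:
        raise ValueError("depth grid must be sorted ascending")
    caller_kwargs = dict(caller_kwargs or {})
    rng = np.random.default_rng(seed)
    curve: list[tuple[float, int]] = []
    for depth in grid:
        thinned = {
            s: thin_pileup(p, depth, int(rng.integers(2**31)))
            for s, p in pileups.items()
        }
        records = call_variants(thinned, references, **caller_kwargs)
        if filter_policy is not None:
            records = filter_variants(records, filter_policy)
        curve.append((depth, sum(1 for r in records if r.variant_class == "SNP")))
    top = curve[-1][1]
    plateau = grid[0]
    for depth, count in curve:
        if top == 0 or count >= plateau_fraction * top:
            plateau = depth
            break
    return curve, plateau


def profiles_to_frame(profiles: Sequence[CoverageProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": p.sample,
                "genome": p.genome,
                "breadth": p.breadth,
                "mean_depth": p.mean_depth,
            }
            for p in profiles
        ]
    )


def selection_to_frame(selections: Sequence[ReferenceSelection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome": s.genome,
                "selected": s.selected,
                "max_breadth": s.max_breadth,
                "cumulative_depth": s.cumulative_depth,
            }
            for s in selections
        ]
    )
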