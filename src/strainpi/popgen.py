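"""Nucleotide diversity, fixation index and strain trees from pileups.

Within-sample nucleotide diversity of genome G in sample S is estimated
from the read pileup as

    pi(S, G) = (1/|G|) * sum_i sum_{B1} sum_{B2 != B1}
               (x_{i,B1} / c_i) * (x_{i,B2} / (c_i - 1))

i.e. the probability that two reads drawn without replacement at position i
carry different bases, averaged over the genome.  The c_i - 1 denominator
makes the site term an unbiased estimator of the population heterozygosity
2p(1-p).  Between two samples the analogous quantity draws one read from
each sample:

    pi(S1, S2, G) = (1/|G|) * sum_i sum_{B1} sum_{B2 != B1}
                    (x_{i,B1,S1} / c_{i,S1}) * (x_{i,B2,S2} / c_{i,S2})

and the fixation index is

    FST(S1, S2, G) = 1 - ((pi(S1,G) + pi(S2,G)) / 2) / pi(S1, S2, G),

clamped to 0 when sampling noise drives it negative.  Both sums are
normalised by the full genome length |G|; uncovered sites (and, within a
sample, sites with coverage < 2, where the without-replacement draw is
undefined) contribute zero to the sum but still count in |G|.

Strain relatedness between samples is summarised by a consensus-allele
p-distance matrix over filtered variant sites and a Saitou–Nei
neighbor-joining tree built from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from strainpi.pileup_coverage import PileupMatrix


# ---------------------------------------------------------------------------
# pi and FST


def pi_site_within(counts: Sequence[int] | np.ndarray) -> float:
    """Per-site diversity: fraction of unordered read pairs that differ.

    ``counts`` are the four base counts at one position.  Sites with
    coverage < 2 return 0 (no read pair exists).
    """
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("negative base counts")
    c = x.sum()
    if c < 2:
        return 0.0
    return float((c * c - (x * x).sum()) / (c * (c - 1.0)))


def pi_site_between(counts1, counts2) -> float:
    """Probability that one read from each sample differs at this site."""
    x1 = np.asarray(counts1, dtype=float)
    x2 = np.asarray(counts2, dtype=float)
    c1, c2 = x1.sum(), x2.sum()
    if c1 == 0 or c2 == 0:
        return 0.0
    return float(1.0 - (x1 / c1) @ (x2 / c2))


def pi_within(pileup: PileupMatrix, genome_size: int) -> float:
    """Genome-wide pi(S, G); positions absent from the pileup contribute 0."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    x = pileup.counts.astype(float)
    c = x.sum(axis=1)
    mask = c >= 2
    if not mask.any():
        return 0.0
    cm = c[mask]
    site = (cm * cm - (x[mask] ** 2).sum(axis=1)) / (cm * (cm - 1.0))
    return float(site.sum() / genome_size)


def pi_between(pileup1: PileupMatrix, pileup2: PileupMatrix, genome_size: int) -> float:
    """Genome-wide pi(S1, S2, G); sites uncovered in either sample contribute 0."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    n = min(len(pileup1), len(pileup2))
    x1 = pileup1.counts[:n].astype(float)
    x2 = pileup2.counts[:n].astype(float)
    c1 = x1.sum(axis=1)
    c2 = x2.sum(axis=1)
    mask = (c1 > 0) & (c2 > 0)
    if not mask.any():
        return 0.0
    f1 = x1[mask] / c1[mask, None]
    f2 = x2[mask] / c2[mask, None]
    site = 1.0 - (f1 * f2).sum(axis=1)
    return float(site.sum() / genome_size)


@dataclass(frozen=True)
class FstResult:
    value: float  # clamped to [0, 1]
    raw: float
    clamped: bool = False
    undefined: bool = False

    def __float__(self) -> float:
        return self.value


def fst(pi_s1: float, pi_s2: float, pi_b: float) -> FstResult:
    """FST = 1 - mean within-sample pi / between-sample pi.

    Negative raw values (within exceeding between, common at low true
    differentiation) are clamped to 0 and flagged.  pi_between == 0 with
    zero within-diversity yields 0 with the ``undefined`` flag; nonzero
    within-diversity with zero between-diversity is inconsistent (the
    between-sample mismatch probability dominates the within-sample one in
    expectation) and raises.
    """
    if min(pi_s1, pi_s2, pi_b) < 0:
        raise ValueError("pi values must be non-negative")
    if pi_b == 0:
        if pi_s1 == 0 and pi_s2 == 0:
            return FstResult(value=0.0, raw=0.0, undefined=True)
        raise ValueError("pi_between is 0 but within-sample pi is positive")
    raw = 1.0 - ((pi_s1 + pi_s2) / 2.0) / pi_b
    if raw < 0:
        return FstResult(value=0.0, raw=raw, clamped=True)
    return FstResult(value=min(raw, 1.0), raw=raw)


@dataclass
class DiversityResult:
    """pi within per sample and pi between / FST per sample pair for one genome."""

    genome: str
    genome_size: int
    pi_within: dict[str, float]
    pi_between: dict[tuple[str, str], float]
    fst: dict[tuple[str, str], FstResult]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        within = pd.DataFrame(
            [
                {"genome": self.genome, "sample": s, "pi_within": v}
                for s, v in self.pi_within.items()
            ]
        )
        pairs = pd.DataFrame(
            [
                {
                    "genome": self.genome,
                    "sample1": s1,
                    "sample2": s2,
                    "pi_between": self.pi_between[(s1, s2)],
                    "fst_raw": self.fst[(s1, s2)].raw,
                    "fst": self.fst[(s1, s2)].value,
                    "fst_clamped": self.fst[(s1, s2)].clamped,
                }
                for (s1, s2) in self.pi_between
            ]
        )
        return within, pairs


def diversity(
    pileups: Mapping[str, PileupMatrix], genome_size: int, genome: str | None = None
) -> DiversityResult:
    """Compute pi within, pi between and FST for one genome across samples."""
    samples = list(pileups)
    if genome is None:
        genome = next(iter(pileups.values())).genome
    pw = {s: pi_within(pileups[s], genome_size) for s in samples}
    pb: dict[tuple[str, str], float] = {}
    fst_map: dict[tuple[str, str], FstResult] = {}
    for i, s1 in enumerate(samples):
        for s2 in samples[i + 1 :]:
            b = pi_between(pileups[s1], pileups[s2], genome_size)
            pb[(s1, s2)] = b
            try:
                fst_map[(s1, s2)] = fst(pw[s1], pw[s2], b)
            except ValueError:
                fst_map[(s1, s2)] = FstResult(value=0.0, raw=0.0, undefined=True)
    return DiversityResult(genome, genome_size, pw, pb, fst_map)


# ---------------------------------------------------------------------------
# p-distance


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over sample ids.

    ``missing`` marks pairs with no shared covered site; their entries are
    NaN and excluded from downstream tree building.
    """

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(np.nan_to_num(self.data), np.nan_to_num(self.data.T)):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.data), 0):
            raise ValueError("diagonal must be zero")

    def __getitem__(self, pair) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.data[i, j])

    @property
    def missing_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(self.data[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{v:.6f}" for v in np.nan_to_num(self.data[i]))
                fh.write(f"{name:<10s} {row}\n")


def p_distance_matrix(
    records: Sequence, samples: Sequence[str], min_depth: int = 4
) -> DistanceMatrix:
    """Consensus-allele p-distance between samples over variant sites.

    For each filtered variant site, a sample's consensus allele is the
    alternate if the alternate supporting reads exceed half the site depth,
    else the reference; the sample covers the site when its depth there is
    at least ``min_depth``.  The distance between two samples is the
    fraction of jointly covered sites whose consensus alleles differ.
    Pairs sharing no covered site get a NaN (missing) entry.
    """
    samples = list(samples)
    n = len(samples)
    if n < 2:
        raise ValueError("need at least two samples")
    sidx = {s: i for i, s in enumerate(samples)}
    n_sites = len(records)
    if n_sites == 0:
        raise ValueError("no variant sites supplied")
    covered = np.zeros((n, n_sites), dtype=bool)
    is_alt = np.zeros((n, n_sites), dtype=bool)
    for j, rec in enumerate(records):
        for s, depth in rec.depth.items():
            if s in sidx and depth >= min_depth:
                i = sidx[s]
                covered[i, j] = True
                is_alt[i, j] = rec.support.get(s, 0) > depth / 2
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = covered[i] & covered[j]
            if not both.any():
                mat[i, j] = mat[j, i] = np.nan
            else:
                diff = (is_alt[i, both] != is_alt[j, both]).mean()
                mat[i, j] = mat[j, i] = diff
    dm = DistanceMatrix(samples, mat)
    if len(dm.missing_pairs) == n * (n - 1) // 2:
        raise ValueError("no sample pair shares a covered site")
    return dm


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    At each step the pair (i, j) minimising the Q criterion is joined; ties
    are broken by the lexicographically smallest pair of leaf labels.
    Negative branch lengths are set to 0 with the difference moved onto the
    sibling branch, preserving the path length between the joined pair.
    Returns an unrooted tree (trifurcation at the final join) as a scikit-bio
    ``TreeNode``.
    """
    missing = matrix.missing_pairs
    if missing:
        raise ValueError(f"incomplete distance matrix; missing pairs: {missing}")
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    d = matrix.data.astype(float).copy()
    nodes = [TreeNode(name=name) for name in matrix.ids]
    # minimal leaf label under each working node, for tie-breaking
    labels = [name for name in matrix.ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] <= qmin + 1e-12:
                    key = tuple(sorted((labels[i], labels[j])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = d[i, j] - vi
        vi, vj = _fix_negative(vi, vj)
        parent = TreeNode()
        nodes[i].length = vi
        nodes[j].length = vj
        parent.extend([nodes[i], nodes[j]])
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        new_label = min(labels[i], labels[j])
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [new_label]

    # final trifurcation: three-point formulas
    root = TreeNode()
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    a.length = max(la, 0.0)
    b.length = max(lb, 0.0)
    c.length = max(lc, 0.0)
    root.extend([a, b, c])
    return root


def _fix_negative(vi: float, vj: float) -> tuple[float, float]:
    """Zero a negative branch, transferring the deficit to its sibling."""
    if vi < 0:
        vj += vi
        vi = 0.0
    if vj < 0:
        vi += vj
        vj = 0.0
    return vi, max(vj, 0.0)


def tree_to_newick(tree: TreeNode, path=None) -> str:
    import io

    buf = io.StringIO()
    tree.write(buf, format="newick")
    s = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def tree_path_lengths(tree: TreeNode, ids: Sequence[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix in the order of ``ids``."""
    tip_dm = tree.tip_tip_distances(endpoints=list(ids))
    order = [list(tip_dm.ids).index(i) for i in ids]
    return np.asarray(tip_dm.data)[np.ix_(order, order)]
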