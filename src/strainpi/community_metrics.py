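"""Community-level diversity statistics and MAG quality classification.

Alpha diversity is the Shannon index in nats by default; beta diversity is
Bray–Curtis dissimilarity; group structure is tested with PERMANOVA
(Anderson's pseudo-F on the distance matrix, free permutation of sample
labels, p = (1 + #{F* >= F}) / (1 + n_perm)).  Draft-genome bins are
classified into low/medium/high quality from CheckM-style completeness and
contamination percentages: low when completeness <= 50% or contamination
>= 5%; high when completeness > 90% and contamination < 5%; medium
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis, pdist, squareform


def load_abundance_table(path) -> pd.DataFrame:
    """Samples x taxa relative abundances; rows renormalised to sum to 1."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return normalize_abundances(df)


def normalize_abundances(df: pd.DataFrame) -> pd.DataFrame:
    if (df.to_numpy() < 0).any():
        raise ValueError("negative abundances")
    sums = df.sum(axis=1)
    if (sums == 0).any():
        raise ValueError("sample with all-zero abundances")
    return df.div(sums, axis=0)


def shannon(abundances, base: float | None = None) -> float:
    """Shannon entropy -sum p log p over p > 0 (natural log by default)."""
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundances")
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def bray_curtis(row1, row2) -> float:
    a = np.asarray(row1, dtype=float)
    b = np.asarray(row2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rows must cover the same taxa")
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero rows")
    return float(braycurtis(a, b))


def bray_curtis_matrix(table: pd.DataFrame) -> np.ndarray:
    return squareform(pdist(table.to_numpy(), metric="braycurtis"))


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_perm: int
    n_samples: int
    n_groups: int


def permanova(dist: np.ndarray, groups, n_perm: int = 9999, seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA on a square distance matrix.

    pseudo-F = (SS_among / (a - 1)) / (SS_within / (n - a)) with sums of
    squared distances computed directly from the matrix; the null
    distribution permutes sample labels freely.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    labels = pd.Categorical(list(groups))
    if len(labels) != n:
        raise ValueError("one group label per sample required")
    codes = np.asarray(labels.codes)
    a = len(labels.categories)
    if a < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes, minlength=a)
    if (sizes < 2).any():
        raise ValueError("every group needs at least two samples")

    d2 = d**2
    ss_total = d2.sum() / (2 * n)

    def ss_within(perm_codes: np.ndarray) -> float:
        ss = 0.0
        for g in range(a):
            idx = np.nonzero(perm_codes == g)[0]
            ss += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
        return ss

    def pseudo_f(perm_codes: np.ndarray) -> float:
        ssw = ss_within(perm_codes)
        ssa = ss_total - ssw
        if ssw == 0:  # perfect separation
            return np.inf
        return (ssa / (a - 1)) / (ssw / (n - a))

    f_obs = pseudo_f(codes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(codes)) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(pseudo_f=float(f_obs), p_value=float(p), n_perm=n_perm, n_samples=n, n_groups=a)


@dataclass(frozen=True)
class MAGQualityRecord:
    bin_id: str
    completeness: float
    contamination: float

    @property
    def quality(self) -> str:
        return quality_class(self.completeness, self.contamination)


def quality_class(completeness: float, contamination: float) -> str:
    """Three-class MAG quality rule from completeness/contamination percent.

    low: completeness <= 50 or contamination >= 5
    high: completeness > 90 and contamination < 5
    medium: otherwise (50 < completeness <= 90, contamination < 5)
    Contamination may exceed 100 (CheckM reports it unbounded).
    """
    if completeness < 0 or contamination < 0:
        raise ValueError("completeness and contamination must be non-negative")
    if completeness <= 50 or contamination >= 5:
        return "low"
    if completeness > 90:
        return "high"
    return "medium"
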