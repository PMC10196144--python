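"""Validation benchmarks: estimator recovery on synthetic communities.

Each function sets up a synthetic scenario with known ground truth, runs
the corresponding analysis code, and returns the measured quantities
together with the independent expectation (brute-force enumeration, closed
form, or a binomial/Poisson tail computation).  They power the acceptance
checks and the numbered analysis scripts; everything is deterministic
under the ``seed`` argument.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson

from strainpi import community_metrics as cm
from strainpi import hgt as hgt_mod
from strainpi import popgen
from strainpi.pileup_coverage import PileupMatrix, saturation_curve
from strainpi.simdata import HGTSpec, SimConfig, generate_references, simulate_pileups


# ---------------------------------------------------------------------------
# per-site estimator vs brute-force pair enumeration


def brute_force_site_within(counts) -> float:
    reads = [b for b, n in enumerate(counts) for _ in range(int(n))]
    pairs = list(itertools.combinations(reads, 2))
    if not pairs:
        return 0.0
    return sum(a != b for a, b in pairs) / len(pairs)


def brute_force_site_between(c1, c2) -> float:
    r1 = [b for b, n in enumerate(c1) for _ in range(int(n))]
    r2 = [b for b, n in enumerate(c2) for _ in range(int(n))]
    if not r1 or not r2:
        return 0.0
    return sum(a != b for a in r1 for b in r2) / (len(r1) * len(r2))


def pi_site_oracle_errors(seed: int, n_sites: int = 1000) -> tuple[float, float]:
    """Max |estimator - brute force| over random sites, within and between."""
    rng = np.random.default_rng(seed)
    err_w = err_b = 0.0
    for _ in range(n_sites):
        c1 = rng.integers(0, 8, size=4)
        c2 = rng.integers(0, 8, size=4)
        err_w = max(err_w, abs(popgen.pi_site_within(c1) - brute_force_site_within(c1)))
        err_b = max(
            err_b, abs(popgen.pi_site_between(c1, c2) - brute_force_site_between(c1, c2))
        )
    return err_w, err_b


# ---------------------------------------------------------------------------
# genome-wide pi recovery


def pi_recovery(
    seed: int,
    n_seeds: int = 20,
    n_sites: int = 1000,
    freq: float = 0.3,
    depth: float = 50.0,
    genome_length: int = 100_000,
) -> dict:
    """Mean pi_within over replicate communities vs the analytic value."""
    vals = []
    for i in range(n_seeds):
        cfg = SimConfig(
            n_genomes=1,
            n_samples=1,
            genome_length=genome_length,
            variant_sites_per_genome=n_sites,
            allele_freq_spec=freq,
            mean_depth=depth,
            error_rate=0.0,
            seed=seed + i,
        )
        refs, truth = generate_references(cfg)
        pile = simulate_pileups(cfg, refs, truth)["s0"]["g0"]
        vals.append(popgen.pi_within(pile, genome_length))
    analytic = n_sites * 2 * freq * (1 - freq) / genome_length
    return {
        "mean_pi": float(np.mean(vals)),
        "analytic": analytic,
        "rel_error": float(abs(np.mean(vals) - analytic) / analytic),
    }


def fst_extremes(seed: int, depth: float = 1000.0) -> dict:
    """FST for a fixed difference (expected 1) and for identical populations."""

    def community(freqs):
        cfg = SimConfig(
            n_genomes=1,
            n_samples=2,
            genome_length=1000,
            variant_sites_per_genome=100,
            allele_freq_spec=np.array(freqs)[:, None],
            mean_depth=depth,
            error_rate=0.0,
            seed=seed,
        )
        refs, truth = generate_references(cfg)
        piles = simulate_pileups(cfg, refs, truth)
        pw1 = popgen.pi_within(piles["s0"]["g0"], 1000)
        pw2 = popgen.pi_within(piles["s1"]["g0"], 1000)
        pb = popgen.pi_between(piles["s0"]["g0"], piles["s1"]["g0"], 1000)
        return popgen.fst(pw1, pw2, pb)

    fixed = community([1.0, 0.0])
    identical = community([0.5, 0.5])
    return {"fst_fixed": fixed.value, "fst_identical": identical.value}


# ---------------------------------------------------------------------------
# neighbor joining on additive matrices


def random_additive_matrix(n: int, rng: np.random.Generator):
    from skbio import TreeNode

    nodes = [TreeNode(name=f"t{i}") for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = TreeNode()
        a.length = float(rng.uniform(0.05, 1.0))
        b.length = float(rng.uniform(0.05, 1.0))
        parent.extend([b, a])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    ids = [f"t{i}" for i in range(n)]
    dm = nodes[0].tip_tip_distances(endpoints=ids)
    order = [list(dm.ids).index(x) for x in ids]
    return ids, np.asarray(dm.data)[np.ix_(order, order)]


def nj_additive_recovery(seed: int, n_matrices: int = 50, max_taxa: int = 16) -> dict:
    """Max path-length deviation of NJ trees over random additive matrices."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        n = int(rng.integers(4, max_taxa + 1))
        ids, mat = random_additive_matrix(n, rng)
        tree = popgen.neighbor_joining(popgen.DistanceMatrix(ids, mat))
        recovered = popgen.tree_path_lengths(tree, ids)
        worst = max(worst, float(np.abs(recovered - mat).max()))
    return {"n_matrices": n_matrices, "max_path_error": worst}


# ---------------------------------------------------------------------------
# PERMANOVA type-I error


def permanova_type1(
    seed: int,
    n_datasets: int = 500,
    n_samples: int = 12,
    n_taxa: int = 5,
    n_perm: int = 999,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of PERMANOVA on null (exchangeable) communities."""
    rng = np.random.default_rng(seed)
    groups = ["a"] * (n_samples // 2) + ["b"] * (n_samples - n_samples // 2)
    rejections = 0
    for i in range(n_datasets):
        X = rng.dirichlet(np.ones(n_taxa), size=n_samples)
        d = cm.bray_curtis_matrix(pd.DataFrame(X))
        res = cm.permanova(d, groups, n_perm=n_perm, seed=int(rng.integers(2**31)))
        if res.p_value <= alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_datasets, "n_datasets": n_datasets}


# ---------------------------------------------------------------------------
# depth saturation


def detectability_oracle(
    depth: float,
    freq: float,
    min_alt_reads: int,
    min_alt_frac: float,
    max_n: int = 400,
) -> float:
    """P(a variant site is called) at the given thinned depth.

    After binomial thinning of Poisson coverage, the alternate and
    reference read counts are independent Poissons with means
    freq*depth and (1-freq)*depth.  The site is called when
    alt >= min_alt_reads and alt >= min_alt_frac * (alt + ref);
    the probability is computed by direct enumeration.
    """
    a = np.arange(max_n)
    pa = poisson.pmf(a, freq * depth)
    total = 0.0
    for alt, p_alt in zip(a, pa):
        if alt < min_alt_reads or p_alt < 1e-15:
            continue
        # fraction condition: ref <= alt * (1 - f) / f
        ref_max = np.floor(alt * (1 - min_alt_frac) / min_alt_frac)
        total += p_alt * poisson.cdf(ref_max, (1 - freq) * depth)
    return float(total)


def saturation_benchmark(
    seed: int,
    depth_grid=(10, 30, 60, 100),
    true_depth: float = 120.0,
    freq: float = 0.1,
    n_sites: int = 200,
    genome_length: int = 20_000,
    n_seeds: int = 20,
    min_alt_reads: int = 4,
    min_alt_frac: float = 0.05,
) -> dict:
    """Thinning saturation curve vs the Poisson/binomial detectability oracle."""
    cfg = SimConfig(
        n_genomes=1,
        n_samples=1,
        genome_length=genome_length,
        variant_sites_per_genome=n_sites,
        allele_freq_spec=freq,
        mean_depth=true_depth,
        error_rate=0.0,
        seed=seed,
    )
    refs, truth = generate_references(cfg)
    pile = simulate_pileups(cfg, refs, truth)["s0"]["g0"]
    grid = list(depth_grid)
    mean_counts = np.zeros(len(grid))
    plateaus = []
    caller = {"min_alt_reads": min_alt_reads, "min_alt_frac": min_alt_frac}
    for i in range(n_seeds):
        curve, plateau = saturation_curve(
            {"s0": pile}, refs, grid, seed=seed + i, caller_kwargs=caller
        )
        mean_counts += [c for _, c in curve]
        plateaus.append(plateau)
    mean_counts /= n_seeds
    oracle_p = [
        detectability_oracle(d, freq, min_alt_reads, min_alt_frac) for d in grid
    ]
    oracle_counts = [n_sites * p for p in oracle_p]
    oracle_plateau = grid[-1]
    for d, c in zip(grid, oracle_counts):
        if c >= 0.95 * oracle_counts[-1]:
            oracle_plateau = d
            break
    modal_plateau = max(set(plateaus), key=plateaus.count)
    return {
        "grid": grid,
        "mean_counts": mean_counts.tolist(),
        "oracle_counts": oracle_counts,
        "plateau": modal_plateau,
        "oracle_plateau": oracle_plateau,
        "nondecreasing": bool(np.all(np.diff(mean_counts) >= -1e-9)),
    }


# ---------------------------------------------------------------------------
# HGT screen recovery


def hgt_screen_benchmark(
    seed: int,
    n_genomes: int = 10,
    genome_length: int = 50_000,
    n_transfers: int = 8,
    gene_length: int = 1000,
    mutation_rate: float = 0.002,
    n_decoys: int = 8,
) -> dict:
    """Precision/recall of the best-match screen on implanted transfers.

    Transfers go between consecutive genome pairs (distinct genera); decoy
    genes are random single-copy segments that must yield no events.  A
    separate two-genome community with ~1% genome-wide divergence (same
    species, ANI ~ 99%) carries an identical implanted gene that the ANI
    gate must veto.
    """
    pairs = [(f"g{i}", f"g{(i + 1) % n_genomes}") for i in range(n_transfers)]
    cfg = SimConfig(
        n_genomes=n_genomes,
        genome_length=genome_length,
        n_samples=1,
        variant_sites_per_genome=0,
        mean_depth=0,
        hgt_spec=[HGTSpec(d, r, gene_length, mutation_rate) for d, r in pairs],
        seed=seed,
    )
    refs, truth = generate_references(cfg)
    taxa = dict(zip(cfg.genome_ids, cfg.taxon_labels))
    genes = [
        hgt_mod.Gene(g.gene_id, g.donor, taxa[g.donor], g.sequence)
        for g in truth.hgt_genes
    ]
    rng = np.random.default_rng(seed + 1)
    for i in range(n_decoys):
        g = cfg.genome_ids[int(rng.integers(n_genomes))]
        start = int(rng.integers(0, genome_length - gene_length))
        genes.append(
            hgt_mod.Gene(f"decoy{i}", g, taxa[g], refs[g][start : start + gene_length])
        )
    events = hgt_mod.detect_hgt_best_match(genes, refs, taxa)
    true_set = {(g.gene_id, tuple(sorted((g.donor, g.recipient)))) for g in truth.hgt_genes}
    found = {(e.gene_id, e.genome_pair) for e in events}
    tp = len(found & true_set)
    precision = tp / len(found) if found else 1.0
    recall = tp / len(true_set)

    # same-species control: identical gene shared by two ~99%-ANI genomes
    rng2 = np.random.default_rng(seed + 2)
    base = "".join("ACGT"[i] for i in rng2.integers(0, 4, genome_length))
    twin = np.frombuffer(base.encode(), dtype=np.uint8).copy()
    muts = np.nonzero(rng2.random(genome_length) < 0.01)[0]
    shift = rng2.integers(1, 4, size=len(muts))
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    idx = np.searchsorted(alphabet, twin[muts])
    twin[muts] = alphabet[(idx + shift) % 4]
    twin = twin.tobytes().decode()
    start = int(rng2.integers(0, genome_length - gene_length))
    pos = int(rng2.integers(0, genome_length - gene_length))
    twin = twin[:pos] + base[start : start + gene_length] + twin[pos + gene_length :]
    control_genomes = {"a": base, "b": twin}
    control_taxa = {"a": "genusA", "b": "genusB"}
    control_genes = [
        hgt_mod.Gene("ctrl", "a", "genusA", base[start : start + gene_length])
    ]
    control_events = hgt_mod.detect_hgt_best_match(control_genes, control_genomes, control_taxa)
    return {
        "precision": precision,
        "recall": recall,
        "n_events": len(events),
        "same_species_events": len(control_events),
    }


def ani_recovery(seed: int, rates=(0.01, 0.03, 0.05), n_seeds: int = 10, length: int = 10_000) -> dict:
    """Mean ANI error versus the expected identity 100(1-m) per mutation rate."""
    out = {}
    for m in rates:
        vals = []
        for i in range(n_seeds):
            rng = np.random.default_rng(seed + 1000 * int(m * 1000) + i)
            g = "".join("ACGT"[j] for j in rng.integers(0, 4, length))
            arr = np.frombuffer(g.encode(), dtype=np.uint8).copy()
            muts = np.nonzero(rng.random(length) < m)[0]
            alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
            idx = np.searchsorted(alphabet, arr[muts])
            arr[muts] = alphabet[(idx + rng.integers(1, 4, size=len(muts))) % 4]
            res = hgt_mod.ani(g, arr.tobytes().decode())
            vals.append(res.ani)
        out[m] = {
            "mean_ani": float(np.mean(vals)),
            "expected": 100.0 * (1 - m),
            "abs_error": float(abs(np.mean(vals) - 100.0 * (1 - m))),
        }
    return out


def quality_rule_grid() -> dict:
    """Exhaustive boundary grid for the MAG quality rule."""
    grid_c = [0, 25, 50, 50.1, 75, 90, 90.1, 95, 100]
    grid_x = [0, 2, 4.9, 5, 5.1, 60, 120]
    classes = {}
    for c in grid_c:
        for x in grid_x:
            classes[(c, x)] = cm.quality_class(c, x)
    n_low = sum(1 for v in classes.values() if v == "low")
    n_med = sum(1 for v in classes.values() if v == "medium")
    n_high = sum(1 for v in classes.values() if v == "high")
    return {
        "n_points": len(classes),
        "n_low": n_low,
        "n_medium": n_med,
        "n_high": n_high,
        "total_classified": n_low + n_med + n_high,
        "classes": classes,
    }
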