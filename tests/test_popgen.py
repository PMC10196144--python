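"""Nucleotide diversity estimators, FST, p-distance and neighbor joining."""

import itertools

import numpy as np
import pytest

from strainpi.pileup_coverage import PileupMatrix
from strainpi.popgen import (
    DistanceMatrix,
    fst,
    neighbor_joining,
    p_distance_matrix,
    pi_between,
    pi_site_between,
    pi_site_within,
    pi_within,
    tree_path_lengths,
)
from strainpi.variants import VariantRecord


def brute_force_within(counts):
    """Mismatch fraction over all unordered read pairs at one site."""
    reads = [b for b, n in enumerate(counts) for _ in range(n)]
    pairs = list(itertools.combinations(reads, 2))
    if not pairs:
        return 0.0
    return sum(a != b for a, b in pairs) / len(pairs)


def brute_force_between(c1, c2):
    """Mismatch fraction over all cross-sample read pairs at one site."""
    r1 = [b for b, n in enumerate(c1) for _ in range(n)]
    r2 = [b for b, n in enumerate(c2) for _ in range(n)]
    if not r1 or not r2:
        return 0.0
    return sum(a != b for a in r1 for b in r2) / (len(r1) * len(r2))


class TestPiSite:
    def test_two_alleles_even_split(self):
        assert pi_site_within([5, 5, 0, 0]) == pytest.approx(5 / 9, abs=1e-15)

    def test_monomorphic(self):
        assert pi_site_within([10, 0, 0, 0]) == 0.0

    def test_three_alleles(self):
        assert pi_site_within([3, 2, 1, 0]) == pytest.approx(11 / 15, abs=1e-15)

    def test_coverage_below_two_contributes_zero(self):
        assert pi_site_within([1, 0, 0, 0]) == 0.0
        assert pi_site_within([0, 0, 0, 0]) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            pi_site_within([-1, 2, 0, 0])

    def test_matches_brute_force_pair_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            counts = rng.integers(0, 8, size=4)
            assert pi_site_within(counts) == pytest.approx(
                brute_force_within(list(counts)), abs=1e-12
            )

    def test_between_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            c1 = rng.integers(0, 6, size=4)
            c2 = rng.integers(0, 6, size=4)
            assert pi_site_between(c1, c2) == pytest.approx(
                brute_force_between(list(c1), list(c2)), abs=1e-12
            )


class TestPiGenomeWide:
    def test_single_polymorphic_site_normalised_by_genome(self):
        counts = np.zeros((100, 4), dtype=int)
        counts[:, 0] = 10
        counts[41] = [5, 5, 0, 0]
        pile = PileupMatrix("g0", counts)
        assert pi_within(pile, 100) == pytest.approx((5 / 9) / 100)

    def test_all_monomorphic_is_zero(self):
        counts = np.zeros((50, 4), dtype=int)
        counts[:, 2] = 30
        assert pi_within(PileupMatrix("g0", counts), 50) == 0.0

    def test_uncovered_positions_count_in_normalisation(self):
        counts = np.zeros((10, 4), dtype=int)
        counts[0] = [5, 5, 0, 0]
        v10 = pi_within(PileupMatrix("g0", counts), 10)
        v100 = pi_within(PileupMatrix("g0", counts), 100)
        assert v10 == pytest.approx(10 * v100)

    def test_estimator_unbiased_at_moderate_depth(self):
        """Mean over seeds approaches sum 2p(1-p)/|G| (c-1 correction)."""
        from strainpi.simdata import SimConfig, generate_references, simulate_pileups

        vals = []
        for seed in range(10):
            cfg = SimConfig(
                n_genomes=1, n_samples=1, genome_length=10_000,
                variant_sites_per_genome=100, allele_freq_spec=0.3,
                mean_depth=50, error_rate=0.0, seed=seed,
            )
            refs, truth = generate_references(cfg)
            pile = simulate_pileups(cfg, refs, truth)["s0"]["g0"]
            vals.append(pi_within(pile, 10_000))
        expected = 100 * 2 * 0.3 * 0.7 / 10_000
        assert np.mean(vals) == pytest.approx(expected, rel=0.05)


class TestPiBetween:
    def test_identical_monomorphic_pileups(self):
        counts = np.zeros((10, 4), dtype=int)
        counts[:, 0] = 5
        p = PileupMatrix("g0", counts)
        assert pi_between(p, p, 10) == 0.0

    def test_fixed_difference_single_site(self):
        a = PileupMatrix("g0", np.array([[9, 0, 0, 0]]))
        b = PileupMatrix("g0", np.array([[0, 7, 0, 0]]))
        assert pi_between(a, b, 1) == pytest.approx(1.0)

    def test_even_split_both_samples(self):
        a = PileupMatrix("g0", np.array([[5, 5, 0, 0]]))
        b = PileupMatrix("g0", np.array([[5, 5, 0, 0]]))
        assert pi_between(a, b, 1) == pytest.approx(0.5)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = PileupMatrix("g0", rng.integers(0, 10, size=(50, 4)))
        b = PileupMatrix("g0", rng.integers(0, 10, size=(50, 4)))
        assert pi_between(a, b, 50) == pytest.approx(pi_between(b, a, 50), abs=1e-15)

    def test_zero_coverage_site_contributes_nothing(self):
        a = PileupMatrix("g0", np.array([[5, 5, 0, 0], [3, 0, 0, 0]]))
        b = PileupMatrix("g0", np.array([[5, 5, 0, 0], [0, 0, 0, 0]]))
        assert pi_between(a, b, 2) == pytest.approx(0.25)


class TestFst:
    def test_half_differentiated(self):
        assert fst(0.2, 0.2, 0.4).value == pytest.approx(0.5)

    def test_within_equals_between_is_zero(self):
        assert fst(0.3, 0.3, 0.3).value == 0.0

    def test_negative_clamped_and_flagged(self):
        res = fst(0.3, 0.3, 0.2)
        assert res.value == 0.0
        assert res.raw == pytest.approx(-0.5)
        assert res.clamped

    def test_all_zero_is_undefined_zero(self):
        res = fst(0.0, 0.0, 0.0)
        assert res.value == 0.0
        assert res.undefined

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError):
            fst(0.1, 0.1, 0.0)

    def test_negative_pi_rejected(self):
        with pytest.raises(ValueError):
            fst(-0.1, 0.1, 0.2)

    def test_parameter_recovery_from_simulated_frequencies(self):
        """FST at high depth matches the closed form from truth frequencies."""
        from strainpi.simdata import SimConfig, generate_references, simulate_pileups

        p1, p2 = 0.8, 0.2
        vals = []
        for seed in range(5):
            cfg = SimConfig(
                n_genomes=1, n_samples=2, genome_length=2000,
                variant_sites_per_genome=200,
                allele_freq_spec=np.array([[p1], [p2]]),
                mean_depth=500, error_rate=0.0, seed=seed,
            )
            refs, truth = generate_references(cfg)
            piles = simulate_pileups(cfg, refs, truth)
            pw1 = pi_within(piles["s0"]["g0"], 2000)
            pw2 = pi_within(piles["s1"]["g0"], 2000)
            pb = pi_between(piles["s0"]["g0"], piles["s1"]["g0"], 2000)
            vals.append(fst(pw1, pw2, pb).value)
        closed = 1 - (p1 * (1 - p1) + p2 * (1 - p2)) / (p1 * (1 - p2) + p2 * (1 - p1))
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - closed) < 3 * se + 1e-3


def make_records(major_alleles, depths=None):
    """Build SNP records from a samples x sites matrix of 0(ref)/1(alt)."""
    n_samples, n_sites = major_alleles.shape
    samples = [f"s{i}" for i in range(n_samples)]
    records = []
    for j in range(n_sites):
        support = {}
        depth = {}
        for i, s in enumerate(samples):
            d = 10 if depths is None else depths[i, j]
            if d == 0:
                continue
            depth[s] = d
            support[s] = d if major_alleles[i, j] else 0
        records.append(
            VariantRecord("g0", j + 1, "A", "C", "SNP", support, depth)
        )
    return records, samples


class TestPDistance:
    def test_identical_vectors_zero(self):
        alleles = np.zeros((2, 50), dtype=int)
        records, samples = make_records(alleles)
        dm = p_distance_matrix(records, samples)
        assert dm[("s0", "s1")] == 0.0

    def test_one_of_ten_sites_differs(self):
        alleles = np.zeros((2, 10), dtype=int)
        alleles[1, 0] = 1
        records, samples = make_records(alleles)
        dm = p_distance_matrix(records, samples)
        assert dm[("s0", "s1")] == pytest.approx(0.1)

    def test_no_shared_sites_is_missing_not_zero(self):
        alleles = np.zeros((3, 4), dtype=int)
        depths = np.full((3, 4), 10)
        depths[0, 2:] = 0  # s0 covers sites 1-2 only
        depths[1, :2] = 0  # s1 covers sites 3-4 only
        records, samples = make_records(alleles, depths)
        dm = p_distance_matrix(records, samples)
        assert ("s0", "s1") in dm.missing_pairs
        assert dm[("s0", "s2")] == 0.0

    def test_min_depth_excludes_shallow_sites(self):
        alleles = np.array([[0, 1], [0, 0]])
        depths = np.array([[10, 3], [10, 10]])  # site 2 shallow in s0
        records, samples = make_records(alleles, depths)
        dm = p_distance_matrix(records, samples, min_depth=4)
        assert dm[("s0", "s1")] == 0.0

    def test_all_pairs_missing_rejected(self):
        alleles = np.zeros((2, 1), dtype=int)
        depths = np.array([[10], [0]])
        records, samples = make_records(alleles, depths)
        with pytest.raises(ValueError):
            p_distance_matrix(records, samples)


def random_additive_matrix(n, rng):
    """Distance matrix of a random binary tree with random positive branches."""
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
    tree = nodes[0]
    ids = [f"t{i}" for i in range(n)]
    dm = tree.tip_tip_distances(endpoints=ids)
    order = [list(dm.ids).index(x) for x in ids]
    return ids, np.asarray(dm.data)[np.ix_(order, order)]


class TestNeighborJoining:
    def test_three_taxa_pendant_lengths(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]))
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(0.05)
        assert lengths["B"] == pytest.approx(0.15)
        assert lengths["C"] == pytest.approx(0.25)

    def test_additive_matrix_recovered_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(4, 10))
            ids, mat = random_additive_matrix(n, rng)
            tree = neighbor_joining(DistanceMatrix(ids, mat))
            recovered = tree_path_lengths(tree, ids)
            np.testing.assert_allclose(recovered, mat, atol=1e-9)

    def test_equidistant_taxa_star_with_equal_pendants(self):
        n = 5
        mat = np.full((n, n), 0.4)
        np.fill_diagonal(mat, 0.0)
        ids = [f"t{i}" for i in range(n)]
        tree = neighbor_joining(DistanceMatrix(ids, mat))
        lengths = {t.name: t.length for t in tree.tips()}
        assert all(v == pytest.approx(0.2) for v in lengths.values())

    def test_incomplete_matrix_rejected_with_pairs_listed(self):
        mat = np.zeros((3, 3))
        mat[0, 1] = mat[1, 0] = np.nan
        mat[0, 2] = mat[2, 0] = 0.5
        mat[1, 2] = mat[2, 1] = 0.5
        dm = DistanceMatrix(["A", "B", "C"], mat)
        with pytest.raises(ValueError, match="A"):
            neighbor_joining(dm)

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 0.1], [0.1, 0]]))
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_branch_lengths_nonnegative(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = 6
            # noisy (non-additive) matrices can produce negative NJ branches
            ids, mat = random_additive_matrix(n, rng)
            noise = rng.normal(0, 0.05, size=mat.shape)
            noisy = np.abs(mat + noise + noise.T)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0.0)
            tree = neighbor_joining(DistanceMatrix(ids, noisy))
            for node in tree.traverse():
                if node.length is not None:
                    assert node.length >= 0
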