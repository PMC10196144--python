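"""Variant calling thresholds, support filters, VCF round-trips and density."""

import numpy as np
import pytest

from strainpi.pileup_coverage import PileupMatrix
from strainpi.variants import (
    FilterPolicy,
    VariantRecord,
    call_variants,
    filter_variants,
    read_vcf,
    snp_density,
    write_vcf,
)


def pileup_from_counts(rows, ref, genome="g0"):
    return PileupMatrix(genome, np.array(rows, dtype=int), ref=ref)


class TestCallVariants:
    def test_low_count_alt_not_called(self):
        # C has fraction 0.1 but only 1 read < min_alt_reads=2
        pile = pileup_from_counts([[9, 1, 0, 0]], "A")
        assert call_variants({"s0": pile}, {"g0": "A"}) == []

    def test_supported_alt_called_with_counts(self):
        pile = pileup_from_counts([[6, 4, 0, 0]], "A")
        recs = call_variants({"s0": pile}, {"g0": "A"})
        assert len(recs) == 1
        rec = recs[0]
        assert (rec.ref, rec.alt, rec.variant_class) == ("A", "C", "SNP")
        assert rec.support == {"s0": 4}
        assert rec.depth == {"s0": 10}

    def test_all_reference_pileup_yields_nothing(self):
        pile = pileup_from_counts([[10, 0, 0, 0], [0, 12, 0, 0]], "AC")
        assert call_variants({"s0": pile}, {"g0": "AC"}) == []

    def test_fraction_gate(self):
        # 3 alt reads out of 100: count passes, fraction 0.03 < 0.1 fails
        pile = pileup_from_counts([[97, 3, 0, 0]], "A")
        assert call_variants({"s0": pile}, {"g0": "A"}) == []
        assert len(call_variants({"s0": pile}, {"g0": "A"}, min_alt_frac=0.01)) == 1

    def test_merging_across_samples(self):
        p1 = pileup_from_counts([[5, 5, 0, 0]], "A")
        p2 = pileup_from_counts([[2, 8, 0, 0]], "A")
        recs = call_variants({"s0": p1, "s1": p2}, {"g0": "A"})
        assert len(recs) == 1
        assert recs[0].support == {"s0": 5, "s1": 8}

    def test_non_acgt_reference_site_skipped(self):
        pile = pileup_from_counts([[5, 5, 0, 0]], "N")
        assert call_variants({"s0": pile}, {"g0": "N"}) == []

    def test_recovery_on_simulated_community(self):
        """At freq 0.3 and depth 50 the caller recovers implanted sites."""
        from strainpi.simdata import SimConfig, generate_references, simulate_pileups

        cfg = SimConfig(
            n_genomes=1, n_samples=1, genome_length=20_000, variant_sites_per_genome=200,
            allele_freq_spec=0.3, mean_depth=50, error_rate=0.0, seed=13,
        )
        refs, truth = generate_references(cfg)
        piles = simulate_pileups(cfg, refs, truth)
        recs = call_variants({"s0": piles["s0"]["g0"]}, refs)
        called = {r.pos for r in recs}
        true_pos = set(truth.variant_positions["g0"].tolist())
        recall = len(called & true_pos) / len(true_pos)
        assert recall >= 0.99
        assert called <= true_pos  # no error model, no false calls

    def test_false_calls_bounded_by_binomial_error_model(self):
        """With base-call errors, false calls stay within the binomial-tail bound.

        A wrong base needs >= max(min_alt_reads, 0.1c) error reads to be
        called; the expected number of such sites follows from the Poisson
        tail of the per-base error count, computed by brute force below.
        """
        from scipy.stats import poisson
        from strainpi.simdata import SimConfig, generate_references, simulate_pileups

        depth, err, L = 50, 0.005, 20_000
        cfg = SimConfig(
            n_genomes=1, n_samples=1, genome_length=L, variant_sites_per_genome=0,
            mean_depth=depth, error_rate=err, seed=17,
        )
        refs, truth = generate_references(cfg)
        piles = simulate_pileups(cfg, refs, truth)
        recs = call_variants({"s0": piles["s0"]["g0"]}, refs)
        n_false = len(recs)
        # per wrong base, error count ~ Poisson(depth * err / 3); a call
        # needs count >= 2 AND fraction >= 0.1 (i.e. >= ~0.1*depth reads)
        threshold = max(2, int(np.ceil(0.1 * depth * 0.5)))  # generous lower bound
        lam = depth * err / 3
        p_site = 3 * poisson.sf(threshold - 1, lam)
        upper = poisson.ppf(0.9999, max(L * p_site, 1e-12)) + 1
        assert n_false <= upper


class TestFilterVariants:
    def test_single_sample_removed(self, filter_fixture):
        records, _, _ = filter_fixture
        kept = filter_variants(
            [r for r in records if r.pos == 1], FilterPolicy()
        )
        assert kept == []

    def test_per_sample_policy(self, filter_fixture):
        records, expected, _ = filter_fixture
        kept = filter_variants(records, FilterPolicy(reads_scope="per_sample"))
        assert {r.pos for r in kept} == expected

    def test_per_variant_total_policy(self, filter_fixture):
        records, _, expected = filter_fixture
        kept = filter_variants(records, FilterPolicy(reads_scope="per_variant_total"))
        assert {r.pos for r in kept} == expected

    def test_idempotent(self, filter_fixture):
        records, _, _ = filter_fixture
        policy = FilterPolicy()
        once = filter_variants(records, policy)
        twice = filter_variants(once, policy)
        assert once == twice

    def test_monotone_in_thresholds(self, filter_fixture):
        records, _, _ = filter_fixture
        base = {r.pos for r in filter_variants(records, FilterPolicy())}
        for ms, mr in [(3, 4), (2, 6), (4, 10)]:
            tighter = {
                r.pos
                for r in filter_variants(records, FilterPolicy(min_samples=ms, min_reads=mr))
            }
            assert tighter <= base

    def test_order_preserved(self, filter_fixture):
        records, _, _ = filter_fixture
        kept = filter_variants(records, FilterPolicy(reads_scope="per_variant_total"))
        positions = [r.pos for r in kept]
        assert positions == sorted(positions)


class TestVcfRoundTrip:
    def test_write_then_read_identity(self, tmp_path, filter_fixture):
        records, _, _ = filter_fixture
        records = [r for r in records if r.support]  # pos 9 has no sample data
        path = tmp_path / "x.vcf"
        write_vcf(records, path, {"g0": 1000})
        back = read_vcf(path)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert a.key == b.key
            assert a.support == b.support
            assert a.depth == b.depth

    def test_multiallelic_split_apportions_ad(self, tmp_path):
        vcf_text = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=g0,length=1000>\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\n"
            "g0\t7\t.\tA\tC,T\t.\t.\t.\tAD\t5,3,2\n"
        )
        path = tmp_path / "m.vcf"
        path.write_text(vcf_text)
        recs = read_vcf(path)
        assert len(recs) == 2
        by_alt = {r.alt: r for r in recs}
        assert by_alt["C"].support == {"s0": 3}
        assert by_alt["T"].support == {"s0": 2}
        assert by_alt["C"].depth == {"s0": 10}

    def test_missing_ad_excluded_from_support(self, tmp_path):
        vcf_text = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=g0,length=1000>\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\n"
            "g0\t7\t.\tA\tC\t.\t.\t.\tAD\t.\n"
        )
        path = tmp_path / "m.vcf"
        path.write_text(vcf_text)
        recs = read_vcf(path)
        assert len(recs) == 1
        assert recs[0].support == {}
        assert recs[0].depth == {}

    def test_empty_vcf_body(self, tmp_path):
        vcf_text = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=g0,length=1000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        path = tmp_path / "e.vcf"
        path.write_text(vcf_text)
        assert read_vcf(path) == []


class TestSnpDensity:
    @pytest.mark.parametrize(
        "n_snps,length,expected",
        [(5, 1000, 5.0), (0, 1000, 0.0), (150, 3_000_000, 0.05)],
    )
    def test_density(self, n_snps, length, expected):
        recs = [
            VariantRecord("g0", i + 1, "A", "C", "SNP", {"s0": 5}, {"s0": 10})
            for i in range(n_snps)
        ]
        assert snp_density(recs, length) == pytest.approx(expected)

    def test_indels_not_counted(self):
        recs = [VariantRecord("g0", 1, "AT", "A", "INDEL", {"s0": 5}, {"s0": 10})]
        assert snp_density(recs, 1000) == 0.0


class TestVariantRecordInvariants:
    def test_alt_equals_ref_rejected(self):
        with pytest.raises(ValueError):
            VariantRecord("g0", 1, "A", "A", "SNP")

    def test_support_above_depth_rejected(self):
        with pytest.raises(ValueError):
            VariantRecord("g0", 1, "A", "C", "SNP", {"s0": 11}, {"s0": 10})

    def test_indel_alleles_must_differ_in_length(self):
        with pytest.raises(ValueError):
            VariantRecord("g0", 1, "AT", "AC", "INDEL")
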