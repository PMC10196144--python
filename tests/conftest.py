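import numpy as np
import pysam
import pytest

from strainpi.variants import VariantRecord


@pytest.fixture
def sam_header():
    def make(lengths):
        return pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6"},
                "SQ": [{"SN": g, "LN": ln} for g, ln in lengths.items()],
            }
        )

    return make


@pytest.fixture
def make_read(sam_header):
    """Build an aligned segment: make_read(header, genome, pos(1-based), seq, cigar)."""

    def _make(header, genome, pos, seq, cigar=None):
        a = pysam.AlignedSegment(header)
        a.query_name = f"read_{genome}_{pos}"
        a.query_sequence = seq
        a.flag = 0
        a.reference_id = list(header.references).index(genome)
        a.reference_start = pos - 1
        a.mapping_quality = 60
        a.cigarstring = cigar or f"{len(seq)}M"
        return a

    return _make


def _rec(genome, pos, ref, alt, support, depth, vclass="SNP"):
    return VariantRecord(
        genome=genome,
        pos=pos,
        ref=ref,
        alt=alt,
        variant_class=vclass,
        support=dict(support),
        depth=dict(depth),
    )


@pytest.fixture
def filter_fixture():
    """Twelve variant records with hand-computed filter outcomes.

    Returns (records, expected_kept_per_sample, expected_kept_total) where
    the expectation sets hold record positions.  Policy: min_samples=2,
    min_reads=4.  Worked by hand:

      pos  support per sample          per_sample(all >=4)   total(sum >=4)
      1    {a:10}                      1 sample -> drop       drop
      2    {a:4, b:4}                  keep                   keep (8)
      3    {a:3, b:3, c:3}             3<4 -> drop            keep (9)
      4    {a:5, b:2}                  2<4 -> drop            keep (7)
      5    {a:4}                       1 sample -> drop       drop
      6    {a:6, b:9}                  keep                   keep
      7    {a:1, b:1}                  drop                   drop (2<4)
      8    {a:4, b:4, c:1}             1<4 -> drop            keep (9)
      9    {}                          drop                   drop
      10   {a:2, b:2}                  drop                   keep (4)
      11   {a:100, b:4}                keep                   keep
      12   {a:3, b:1}                  drop                   keep (4)
    """
    g = "g0"
    rows = [
        (1, {"a": 10}),
        (2, {"a": 4, "b": 4}),
        (3, {"a": 3, "b": 3, "c": 3}),
        (4, {"a": 5, "b": 2}),
        (5, {"a": 4}),
        (6, {"a": 6, "b": 9}),
        (7, {"a": 1, "b": 1}),
        (8, {"a": 4, "b": 4, "c": 1}),
        (9, {}),
        (10, {"a": 2, "b": 2}),
        (11, {"a": 100, "b": 4}),
        (12, {"a": 3, "b": 1}),
    ]
    records = [
        _rec(g, pos, "A", "C", sup, {s: n + 10 for s, n in sup.items()})
        for pos, sup in rows
    ]
    expected_per_sample = {2, 6, 11}
    expected_total = {2, 3, 4, 6, 8, 10, 11, 12}
    return records, expected_per_sample, expected_total
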