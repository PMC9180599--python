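"""Interval engine: BED I/O, merge semantics, overlap fractions,
co-binding partitioning and TSS windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from myorra.intervals import (
    GenomicInterval,
    PeakSet,
    classify_cobinding,
    merge_intervals,
    multiway_union_overlap,
    overlap_fraction,
    read_bed,
    tss_windows,
    write_bed,
)

from conftest import random_peakset


def peaks(*ivs, name="p"):
    return PeakSet.from_records([("chr1", s, e) for s, e in ivs], name=name)


class TestGenomicInterval:
    def test_rejects_inverted_and_empty(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)


class TestBedIO:
    def test_round_trip(self, tmp_path, rng):
        ps = random_peakset(rng, 50, {"chr1": 100000, "chr2": 50000})
        path = tmp_path / "x.bed"
        write_bed(ps, path)
        back = read_bed(path)
        pd.testing.assert_frame_equal(
            ps.df[["chrom", "start", "end"]], back.df[["chrom", "start", "end"]]
        )

    def test_nonstandard_chromosome_dropped(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text("chr1\t10\t20\nchrUn_rand1\t5\t15\n")
        ps = read_bed(path, chrom_sizes={"chr1": 1000})
        assert len(ps) == 1
        assert ps.df["chrom"].tolist() == ["chr1"]

    def test_malformed_row_errors_with_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t10\t20\nchr1\t200\t100\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(path)

    def test_non_integer_coords_error(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\tten\t20\n")
        with pytest.raises(ValueError, match="non-integer"):
            read_bed(path)


class TestMerge:
    @pytest.mark.parametrize(
        "inp, expected",
        [
            ([(0, 10), (5, 15)], [(0, 15)]),
            ([(0, 10), (10, 20)], [(0, 20)]),  # bookended intervals merge
            ([(0, 10), (20, 30)], [(0, 10), (20, 30)]),
        ],
    )
    def test_merge_cases(self, inp, expected):
        merged = merge_intervals(peaks(*inp))
        assert [(s, e) for _, s, e in merged.df[["chrom", "start", "end"]].itertuples(index=False)] == expected

    def test_idempotent_and_base_preserving(self, rng):
        ps = random_peakset(rng, 200, {"chr1": 20000})
        m1 = merge_intervals(ps)
        m2 = merge_intervals(m1)
        pd.testing.assert_frame_equal(m1.df, m2.df)
        covered = set()
        for _, s, e in ps.df[["chrom", "start", "end"]].itertuples(index=False):
            covered.update(range(s, e))
        merged_cov = set()
        for _, s, e in m1.df[["chrom", "start", "end"]].itertuples(index=False):
            merged_cov.update(range(s, e))
        assert covered == merged_cov
        # disjoint and non-touching
        starts = m1.df["start"].to_numpy()
        ends = m1.df["end"].to_numpy()
        assert (starts[1:] > ends[:-1]).all()


def brute_force_overlap_mask(a: PeakSet, b: PeakSet, min_bp=1):
    mask = []
    for ra in a.df.itertuples(index=False):
        hit = False
        for rb in b.df.itertuples(index=False):
            if ra.chrom == rb.chrom:
                ov = min(ra.end, rb.end) - max(ra.start, rb.start)
                if ov >= min_bp:
                    hit = True
                    break
        mask.append(hit)
    return np.array(mask)


class TestOverlapFraction:
    def test_identity(self, rng):
        ps = random_peakset(rng, 30, {"chr1": 10000})
        frac, over, non = overlap_fraction(ps, ps)
        assert frac == 1.0 and len(non) == 0

    def test_manual_half(self):
        a = peaks((100, 200), (300, 400))
        b = peaks((150, 160))
        frac, over, non = overlap_fraction(a, b)
        assert frac == 0.5
        assert over.df["start"].tolist() == [100]
        assert non.df["start"].tolist() == [300]

    def test_disjoint_chromosomes(self):
        a = peaks((0, 100))
        b = PeakSet.from_records([("chr2", 0, 100)])
        frac, _, _ = overlap_fraction(a, b)
        assert frac == 0.0

    def test_empty_query_errors(self):
        empty = PeakSet.from_records([], name="empty")
        with pytest.raises(ValueError, match="empty"):
            overlap_fraction(empty, peaks((0, 10)))

    def test_partition_exhaustive(self, rng):
        a = random_peakset(rng, 100, {"chr1": 50000}, name="a")
        b = random_peakset(rng, 80, {"chr1": 50000}, name="b")
        frac, over, non = overlap_fraction(a, b)
        assert len(over) + len(non) == len(a)
        assert frac == len(over) / len(a)

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            a = random_peakset(rng, 60, {"chr1": 20000, "chr2": 15000}, name="a")
            b = random_peakset(rng, 60, {"chr1": 20000, "chr2": 15000}, name="b")
            frac, _, _ = overlap_fraction(a, b)
            assert frac == brute_force_overlap_mask(a, b).mean()

    def test_min_bp(self):
        a = peaks((100, 200))
        b = peaks((190, 300))
        assert overlap_fraction(a, b, min_bp=10)[0] == 1.0
        assert overlap_fraction(a, b, min_bp=11)[0] == 0.0


class TestClassifyCobinding:
    def test_manual(self):
        a = peaks((0, 10), (20, 30), name="a")
        b = peaks((5, 8), (40, 50), name="b")
        out = classify_cobinding(a, b)
        assert out["A+B+"].df["start"].tolist() == [0]
        assert out["A+B-"].df["start"].tolist() == [20]
        assert out["A-B+"].df["start"].tolist() == [40]

    def test_empty_b(self):
        a = peaks((0, 10))
        b = PeakSet.from_records([], name="b")
        out = classify_cobinding(a, b)
        assert len(out["A+B+"]) == 0
        assert len(out["A+B-"]) == len(a)
        assert len(out["A-B+"]) == 0

    def test_identical_sets(self, rng):
        a = random_peakset(rng, 40, {"chr1": 30000})
        out = classify_cobinding(a, a)
        assert len(out["A+B-"]) == 0 and len(out["A-B+"]) == 0

    def test_count_conservation(self, rng):
        for _ in range(5):
            a = random_peakset(rng, 120, {"chr1": 40000}, name="a")
            b = random_peakset(rng, 90, {"chr1": 40000}, name="b")
            out = classify_cobinding(a, b)
            assert len(out["A+B+"]) + len(out["A+B-"]) == len(a)


class TestMultiwayUnion:
    def test_subset_gives_one(self):
        q = peaks((10, 20), (30, 40))
        assert multiway_union_overlap(q, [q, q])[0] == 1.0

    def test_manual_half(self):
        q = peaks((0, 10), (100, 110), name="q")
        union = [peaks((0, 5), name="x")]
        assert multiway_union_overlap(q, union)[0] == 0.5

    def test_single_other_reduces_to_pairwise(self, rng):
        q = random_peakset(rng, 50, {"chr1": 20000}, name="q")
        x = random_peakset(rng, 50, {"chr1": 20000}, name="x")
        assert multiway_union_overlap(q, [x])[0] == overlap_fraction(q, x)[0]

    def test_empty_others_errors(self):
        with pytest.raises(ValueError):
            multiway_union_overlap(peaks((0, 10)), [])


class TestTssWindows:
    def gene_df(self, tss, strand, chrom="chr1"):
        return pd.DataFrame(
            {"gene": ["g"], "chrom": [chrom], "tss": [tss], "strand": [strand]}
        )

    def test_plus_strand_window(self):
        ps = tss_windows(self.gene_df(10000, "+"), upstream=5000, downstream=1000)
        assert (ps.df["start"][0], ps.df["end"][0]) == (5000, 11000)

    def test_minus_strand_mirror(self):
        ps = tss_windows(self.gene_df(10000, "-"), upstream=5000, downstream=1000)
        assert (ps.df["start"][0], ps.df["end"][0]) == (9000, 15000)

    def test_clipping(self):
        ps = tss_windows(self.gene_df(100, "+"), upstream=5000, downstream=1000)
        assert (ps.df["start"][0], ps.df["end"][0]) == (0, 1100)

    def test_unknown_strand_treated_as_plus(self, caplog):
        ps = tss_windows(self.gene_df(10000, "."), upstream=5000, downstream=1000)
        assert (ps.df["start"][0], ps.df["end"][0]) == (5000, 11000)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 5000), st.integers(1, 400)).map(
            lambda t: (t[0], t[0] + t[1])
        ),
        min_size=1,
        max_size=40,
    )
)
def test_merge_properties(ivs):
    """Merged output is sorted, disjoint, non-touching, and covers the union."""
    ps = peaks(*ivs)
    merged = merge_intervals(ps)
    starts = merged.df["start"].to_numpy()
    ends = merged.df["end"].to_numpy()
    assert (starts < ends).all()
    assert (starts[1:] > ends[:-1]).all()
    assert merged.total_width() == len(
        set().union(*(range(s, e) for s, e in ivs))
    )
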