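"""Synthetic-data generator: construction-level guarantees (planted-truth
recovery is exercised in the downstream-module and acceptance tests)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from myorra.intervals import overlap_fraction
from myorra.motifs import build_pwm, revcomp, scan_pwm
from myorra.simdata import (
    SimConfig,
    simulate_count_datasets,
    simulate_coverage,
    simulate_genome,
    simulate_peaksets,
    simulate_sequences,
)
from myorra.signal_profile import CoverageTrack, anchor_matrix


def sharp_pwm(consensus="ACGTACGTACGT"):
    counts = np.full((4, len(consensus)), 0.5)
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 50.0
    return build_pwm(counts, name="sharp")


class TestSimulateGenome:
    def test_seed_determinism(self):
        cfg = SimConfig(seed=42, n_genes=100, n_true_up=10, n_true_down=10)
        _, g1 = simulate_genome(cfg)
        _, g2 = simulate_genome(cfg)
        pd.testing.assert_frame_equal(g1, g2)

    def test_single_gene_bounds(self):
        cfg = SimConfig(n_genes=1, n_true_up=0, n_true_down=0,
                        chrom_lengths={"chr1": 1000})
        sizes, genes = simulate_genome(cfg)
        assert len(genes) == 1
        assert 0 <= genes["tss"].iloc[0] < 1000
        assert genes["strand"].iloc[0] in "+-"

    def test_length_proportional_placement(self):
        cfg = SimConfig(seed=3, n_genes=1000,
                        chrom_lengths={"chr1": 3_000_000, "chr2": 1_000_000})
        _, genes = simulate_genome(cfg)
        n1 = (genes["chrom"] == "chr1").sum()
        lo, hi = stats.binom.interval(0.99, 1000, 0.75)
        assert lo <= n1 <= hi

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            SimConfig(chrom_lengths={"chr1": 0})


class TestSimulateCounts:
    def test_null_case_centered(self):
        cfg = SimConfig(seed=1, n_genes=2000, n_true_up=0, n_true_down=0,
                        effect_log2fc=0.0, batch_sd=0.0, n_datasets=1,
                        replicates_per_group=4)
        _, genes = simulate_genome(cfg)
        datasets, _ = simulate_count_datasets(genes, cfg)
        counts, groups = datasets[0]
        groups = np.array(groups)
        lr = np.log2(counts.loc[:, groups == "MT"].mean(axis=1) + 0.5) - np.log2(
            counts.loc[:, groups == "MB"].mean(axis=1) + 0.5
        )
        assert abs(lr.mean()) < 0.1

    def test_planted_effect_recovered(self):
        cfg = SimConfig(seed=2, n_genes=500, n_true_up=50, n_true_down=0,
                        effect_log2fc=2.0, dispersion=0.1, batch_sd=0.0,
                        n_datasets=1, replicates_per_group=5)
        _, genes = simulate_genome(cfg)
        datasets, truth = simulate_count_datasets(genes, cfg)
        counts, groups = datasets[0]
        groups = np.array(groups)
        up = counts.index.isin(truth.true_up)
        lr = np.log2(counts.loc[up, groups == "MT"].mean(axis=1) + 0.5) - np.log2(
            counts.loc[up, groups == "MB"].mean(axis=1) + 0.5
        )
        assert 1.5 <= lr.mean() <= 2.5

    def test_seed_contract(self):
        cfg_a = SimConfig(seed=10, n_genes=100, n_datasets=2, n_true_up=10, n_true_down=10)
        cfg_b = SimConfig(seed=11, n_genes=100, n_datasets=2, n_true_up=10, n_true_down=10)
        _, genes = simulate_genome(cfg_a)
        d1, _ = simulate_count_datasets(genes, cfg_a)
        d2, _ = simulate_count_datasets(genes, cfg_a)
        d3, _ = simulate_count_datasets(genes, cfg_b)
        pd.testing.assert_frame_equal(d1[0][0], d2[0][0])
        assert not d1[0][0].equals(d3[0][0])

    def test_counts_are_nonnegative_integers(self):
        cfg = SimConfig(seed=4, n_genes=200, n_datasets=2)
        _, genes = simulate_genome(cfg)
        datasets, _ = simulate_count_datasets(genes, cfg)
        for counts, _ in datasets:
            assert (counts.to_numpy() >= 0).all()
            assert np.issubdtype(counts.to_numpy().dtype, np.integer)

    def test_truth_sets_disjoint(self):
        cfg = SimConfig(seed=5, n_genes=300, n_true_up=80, n_true_down=80)
        _, genes = simulate_genome(cfg)
        _, truth = simulate_count_datasets(genes, cfg)
        assert not (truth.true_up & truth.true_down)
        assert len(truth.true_up) == 80 and len(truth.true_down) == 80

    def test_bad_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            SimConfig(dispersion=0.0)


class TestSimulatePeaksets:
    def test_full_overlap_design(self):
        cfg = SimConfig(seed=6)
        sets, _ = simulate_peaksets(cfg.chrom_lengths, {("B", "A"): 1.0}, cfg,
                                    n_peaks=200)
        frac, _, _ = overlap_fraction(sets["B"], sets["A"])
        assert frac == 1.0

    def test_designed_fraction_realized(self):
        cfg = SimConfig(seed=7)
        sets, _ = simulate_peaksets(cfg.chrom_lengths, {("B", "A"): 0.8}, cfg,
                                    n_peaks=1000)
        frac, _, _ = overlap_fraction(sets["B"], sets["A"])
        assert 0.75 <= frac <= 0.85

    def test_intervals_within_bounds(self):
        cfg = SimConfig(seed=8)
        sets, _ = simulate_peaksets(cfg.chrom_lengths, {("B", "A"): 0.5}, cfg,
                                    n_peaks=300)
        for ps in sets.values():
            for row in ps.df.itertuples(index=False):
                assert 0 <= row.start < row.end <= cfg.chrom_lengths[row.chrom]

    def test_bad_design_fraction(self):
        cfg = SimConfig()
        with pytest.raises(ValueError):
            simulate_peaksets(cfg.chrom_lengths, {("B", "A"): 1.5}, cfg)


class TestSimulateSequences:
    def test_embed_rate_one_all_contain_consensus(self):
        cfg = SimConfig(seed=9)
        sets, _ = simulate_peaksets(cfg.chrom_lengths, {}, cfg, n_peaks=50)
        pwm = sharp_pwm()
        seqs, embedded = simulate_sequences(sets["peaks"], pwm, 1.0, cfg)
        assert len(embedded) == 50
        cons = pwm.consensus
        for seq in seqs.values():
            assert cons in seq or revcomp(cons) in seq

    def test_embed_rate_zero_low_hit_fraction(self):
        cfg = SimConfig(seed=10)
        sets, _ = simulate_peaksets(cfg.chrom_lengths, {}, cfg, n_peaks=100)
        pwm = sharp_pwm()
        seqs, embedded = simulate_sequences(sets["peaks"], pwm, 0.0, cfg)
        assert not embedded
        hit = sum(len(scan_pwm(s, pwm, 0.9)) > 0 for s in seqs.values())
        assert hit / len(seqs) < 0.05

    def test_fixed_seed_identical_output(self):
        cfg = SimConfig(seed=11)
        sets, _ = simulate_peaksets(cfg.chrom_lengths, {}, cfg, n_peaks=20)
        pwm = sharp_pwm()
        s1, e1 = simulate_sequences(sets["peaks"], pwm, 0.5, cfg)
        s2, e2 = simulate_sequences(sets["peaks"], pwm, 0.5, cfg)
        assert s1 == s2 and e1 == e2

    def test_bad_embed_rate(self):
        cfg = SimConfig()
        sets, _ = simulate_peaksets(cfg.chrom_lengths, {}, cfg, n_peaks=5)
        with pytest.raises(ValueError):
            simulate_sequences(sets["peaks"], sharp_pwm(), 1.2, cfg)


class TestSimulateCoverage:
    def anchors(self, rng, n, chrom="chr1", lo=100_000, hi=900_000):
        return [(chrom, int(p)) for p in rng.integers(lo, hi, size=n)]

    def test_null_factor_profiles_close(self):
        cfg = SimConfig(seed=12, chrom_lengths={"chr1": 20_000_000})
        rng = np.random.default_rng(0)
        high = self.anchors(rng, 500, hi=19_000_000)
        low = self.anchors(rng, 500, hi=19_000_000)
        df = simulate_coverage(high, low, cfg, factor=1.0)
        track = CoverageTrack.from_dataframe(df)
        _, p_hi = anchor_matrix(track, pd.DataFrame(high, columns=["chrom", "pos"]),
                                flank=2000, n_bins=20)
        _, p_lo = anchor_matrix(track, pd.DataFrame(low, columns=["chrom", "pos"]),
                                flank=2000, n_bins=20)
        center = len(p_hi) // 2
        assert abs(p_hi[center] - p_lo[center]) / p_lo[center] < 0.10

    def test_factor_three_center_ratio(self):
        cfg = SimConfig(seed=13, chrom_lengths={"chr1": 20_000_000})
        rng = np.random.default_rng(1)
        high = self.anchors(rng, 300, hi=19_000_000)
        low = self.anchors(rng, 300, hi=19_000_000)
        df = simulate_coverage(high, low, cfg, factor=3.0)
        track = CoverageTrack.from_dataframe(df)
        _, p_hi = anchor_matrix(track, pd.DataFrame(high, columns=["chrom", "pos"]),
                                flank=2000, n_bins=20)
        _, p_lo = anchor_matrix(track, pd.DataFrame(low, columns=["chrom", "pos"]),
                                flank=2000, n_bins=20)
        center = len(p_hi) // 2
        assert 2.0 <= p_hi[center] / p_lo[center] <= 4.0

    def test_bedgraph_format_contract(self):
        cfg = SimConfig(seed=14)
        df = simulate_coverage([("chr1", 50_000)], [("chr2", 60_000)], cfg)
        assert list(df.columns) == ["chrom", "start", "end", "value"]
        for chrom, sub in df.groupby("chrom"):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all()  # sorted, non-overlapping
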