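"""Binning, GC correction, reference normalization, segmentation, calls."""

import numpy as np
import pandas as pd
import pytest

from decent import simgen
from decent.cnvrecon import (
    call_and_classify,
    count_in_bins,
    gc_correct,
    make_bins,
    normalize_to_reference,
    segment,
    shrink_for_plot,
)
from decent.readio import MethylRead, ReadSet


@pytest.fixture(scope="module")
def genome():
    cfg = simgen.SimConfig(
        chrom_lengths={"chr1": 10_000_000, "chr2": 5_000_000}, cpg_density=0.01, seed=31
    )
    return simgen.generate_genome(cfg)


def _flat_profile(grid, count=100.0, noise=None, rng=None):
    prof = grid.copy()
    c = np.full(len(grid), count)
    if noise is not None:
        c = c + rng.normal(0, noise, size=len(grid))
    prof["count"] = c
    return prof


class TestMakeBins:
    def test_fixed_width_tiling(self, genome):
        grid = make_bins(genome, width=500_000)
        chr1 = grid[grid["chrom"] == "chr1"]
        assert len(chr1) == 20
        assert (chr1["end"] - chr1["start"] == 500_000).all()

    def test_blacklist_flagging(self, genome):
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [1_000_000], "end": [1_100_000]})
        grid = make_bins(genome, width=500_000, blacklist=bl)
        assert grid.loc[(grid["chrom"] == "chr1") & (grid["start"] == 1_000_000), "blacklist"].all()
        assert grid["blacklist"].sum() == 1

    def test_custom_bins_loaded_verbatim(self, genome):
        custom = pd.DataFrame({
            "chrom": ["chr2", "chr1"],
            "start": [0, 100],
            "end": [400_000, 777_000],
        })
        grid = make_bins(genome, custom_bins=custom)
        assert grid["chrom"].tolist() == ["chr2", "chr1"]
        assert grid["end"].tolist() == [400_000, 777_000]

    def test_bad_width_rejected(self, genome):
        with pytest.raises(ValueError):
            make_bins(genome, width=0)


class TestCountInBins:
    def test_uniform_reads_within_poisson_band(self, genome):
        prof_reads = simgen.generate_reads(
            genome, simgen.make_class_profiles(genome, seed=1)[0], 50_000, seed=2
        )
        grid = make_bins(genome, width=500_000)
        prof = count_in_bins(prof_reads, grid)
        lam = len(prof_reads) / len(grid)
        assert (np.abs(prof["count"] - lam) < 3 * np.sqrt(lam) + 3).mean() > 0.99

    def test_boundary_read_goes_right(self, genome):
        grid = make_bins(genome, width=500_000)
        rs = ReadSet([MethylRead("chr1", 500_000, "+", "ACGT", "....")])
        prof = count_in_bins(rs, grid)
        assert prof.loc[(prof["chrom"] == "chr1") & (prof["start"] == 500_000), "count"].item() == 1

    def test_empty_readset(self, genome):
        grid = make_bins(genome, width=500_000)
        prof = count_in_bins(ReadSet([]), grid)
        assert (prof["count"] == 0).all()

    def test_conservation(self, genome):
        rs = simgen.generate_reads(
            genome, simgen.make_class_profiles(genome, seed=3)[0], 5000, seed=4
        )
        grid = make_bins(genome, width=500_000)
        prof = count_in_bins(rs, grid)
        assert prof["count"].sum() + prof.attrs["n_unassigned"] == len(rs)


class TestGcCorrect:
    def test_gc_independent_counts_nearly_unchanged(self, genome):
        rng = np.random.default_rng(5)
        grid = make_bins(genome, width=250_000)
        prof = _flat_profile(grid, 1000.0, noise=1.0, rng=rng)
        out = gc_correct(prof)
        rel = np.abs(out["corrected"] - out["count"]) / out["count"]
        assert rel.max() < 0.02

    def test_linear_gc_trend_removed(self, genome):
        rng = np.random.default_rng(6)
        grid = make_bins(genome, width=100_000)
        prof = grid.copy()
        prof["count"] = 500 + 900 * (prof["gc"] - prof["gc"].mean()) + rng.normal(0, 5, len(grid))
        out = gc_correct(prof)
        rho = np.corrcoef(out["corrected"], out["gc"])[0, 1]
        assert abs(rho) < 0.05

    def test_mean_preserved(self, genome):
        rng = np.random.default_rng(7)
        grid = make_bins(genome, width=250_000)
        prof = _flat_profile(grid, 300.0, noise=30.0, rng=rng)
        out = gc_correct(prof)
        assert out["corrected"].mean() == pytest.approx(prof["count"].mean(), rel=1e-6)

    def test_too_few_bins_rejected(self, genome):
        grid = make_bins(genome, width=500_000).head(5)
        with pytest.raises(ValueError):
            gc_correct(_flat_profile(grid))


class TestNormalizeToReference:
    def test_identity_gives_cn2(self, genome):
        grid = make_bins(genome, width=500_000)
        prof = _flat_profile(grid, 200.0)
        out = normalize_to_reference(prof, prof.copy(), reference_sex="XX")
        auto = out["chrom"].isin(["chr1", "chr2"])
        np.testing.assert_allclose(out.loc[auto, "ratio"], 1.0)
        np.testing.assert_allclose(out.loc[auto, "copy_number"], 2.0)

    def test_reference_zero_bins_masked(self, genome):
        grid = make_bins(genome, width=500_000)
        prof = _flat_profile(grid, 200.0)
        ref = _flat_profile(grid, 200.0)
        ref.loc[0, "count"] = 0.0
        out = normalize_to_reference(prof, ref)
        assert np.isnan(out.loc[0, "ratio"])
        assert np.isfinite(out["ratio"][1:]).all()

    def test_grid_mismatch_rejected(self, genome):
        grid = make_bins(genome, width=500_000)
        other = grid.copy()
        other.loc[0, "start"] = 123
        with pytest.raises(ValueError):
            normalize_to_reference(_flat_profile(grid), _flat_profile(other))

    def test_synthetic_monosomy_recovers_cn1(self, genome):
        emb, _ = simgen.make_class_profiles(genome, seed=8)
        sample = simgen.generate_reads(
            genome, emb, 100_000, cnv_events=[("chr2", "whole", None, 1)], seed=9
        )
        ref = simgen.generate_reads(genome, emb, 100_000, seed=10)
        grid = make_bins(genome, width=500_000)
        prof = normalize_to_reference(
            gc_correct(count_in_bins(sample, grid)),
            gc_correct(count_in_bins(ref, grid)),
            reference_sex="XX",
        )
        med = prof.loc[prof["chrom"] == "chr2", "copy_number"].median()
        assert med == pytest.approx(1.0, abs=0.2)


class TestSegment:
    def _profile(self, cn_by_chrom):
        rows = []
        for chrom, cns in cn_by_chrom.items():
            for i, cn in enumerate(cns):
                rows.append((chrom, i * 100, (i + 1) * 100, 0.4, False, cn))
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "gc", "blacklist", "copy_number"]
        )

    def test_flat_profile_single_segment_per_chrom(self):
        prof = self._profile({"chr1": [2.0] * 30, "chr2": [2.0] * 20})
        segs = segment(prof)
        assert len(segs) == 2
        assert all(s.mean_cn == pytest.approx(2.0) for s in segs)

    def test_noiseless_step_localized_within_one_bin(self):
        prof = self._profile({"chr1": [2.0] * 17 + [1.0] * 13})
        segs = segment(prof)
        assert len(segs) == 2
        boundary = segs[0].end_bin
        assert abs(boundary - 17) <= 1

    def test_noise_only_profile_stays_neutral(self):
        rng = np.random.default_rng(11)
        prof = self._profile({"chr1": list(2.0 + rng.normal(0, 0.1, 40))})
        segs = segment(prof)
        calls = call_and_classify(segs, prof)
        assert all(s.state == 2 for s in segs if s.state is not None)
        assert calls["event_labels"] == []

    def test_all_masked_chromosome_yields_missing_segment(self):
        prof = self._profile({"chr1": [np.nan] * 10})
        segs = segment(prof)
        assert len(segs) == 1
        assert np.isnan(segs[0].mean_cn)


class TestCallAndClassify:
    def _profile_with(self, chrom_cns):
        rows = []
        for chrom, cns in chrom_cns.items():
            for i, cn in enumerate(cns):
                rows.append((chrom, i * 100, (i + 1) * 100, 0.4, False, cn))
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "gc", "blacklist", "copy_number"]
        )

    def test_whole_chromosome_loss_labeled_aneuploidy(self):
        prof = self._profile_with({
            "chr16": [1.0] * 10, "chr18": [3.0] * 10, "chr1": [2.0] * 10,
            "chrX": [1.0] * 10, "chrY": [1.0] * 5,
        })
        calls = call_and_classify(segment(prof), prof)
        assert "-16" in calls["event_labels"]
        assert "+18" in calls["event_labels"]
        ev = {s.label: s.event_class for s in calls["events"]}
        assert ev["-16"] == "aneuploidy"

    def test_sex_calls_from_dosage(self):
        xx = self._profile_with({"chr1": [2.0] * 10, "chrX": [2.0] * 10, "chrY": [0.05] * 5})
        xy = self._profile_with({"chr1": [2.0] * 10, "chrX": [1.0] * 10, "chrY": [1.0] * 5})
        assert call_and_classify(segment(xx), xx)["sex"] == "XX"
        assert call_and_classify(segment(xy), xy)["sex"] == "XY"

    def test_partial_loss_with_cytoband_label(self):
        prof = self._profile_with({"chr1": [2.0] * 10 + [1.0] * 10})
        bands = pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "start": [0, 1000],
            "end": [1000, 2000],
            "band": ["p11", "q22"],
        })
        calls = call_and_classify(segment(prof), prof, cytobands=bands)
        (ev,) = calls["events"]
        assert ev.event_class == "sub-chromosomal"
        assert ev.label == "-1q22"

    def test_karyotype_summary_string(self):
        prof = self._profile_with({
            **{f"chr{i}": [2.0] * 8 for i in range(1, 23) if i != 19},
            "chr19": [3.0] * 8,
            "chrX": [1.0] * 8,
            "chrY": [1.0] * 4,
        })
        calls = call_and_classify(segment(prof), prof)
        assert calls["karyotype"] == "47,XY,+19"


class TestDownsampling:
    def test_event_detection_degrades_at_low_depth(self):
        """Spiked whole-chromosome events are recovered cleanly at ample
        depth; at very low depth the per-bin noise produces a corrupted
        call set (spurious events), the desk-scale signature of the
        read-budget floor."""
        from decent import benchmark

        g = benchmark.benchmark_genome(seed=5, n_autosomes=22)
        emb, _ = benchmark.benchmark_profiles(g, separable=False, seed=6)
        grid = make_bins(g, width=100_000)
        ref = gc_correct(count_in_bins(
            simgen.generate_reads(g, emb, 120_000, cnv_events=benchmark.XY_EVENTS, seed=7),
            grid,
        ))
        events = [("chr16", "whole", None, 1), ("chr18", "whole", None, 3)]

        def call_with(n):
            rs = simgen.generate_reads(
                g, emb, n, cnv_events=events + benchmark.XY_EVENTS, seed=8
            )
            prof = normalize_to_reference(gc_correct(count_in_bins(rs, grid)), ref)
            return call_and_classify(segment(prof), prof)

        for n in (50_000, 20_000):
            calls = call_with(n)
            assert set(calls["event_labels"]) == {"-16", "+18"}
            assert calls["sex"] == "XY"
        degraded = call_with(1_000)
        assert set(degraded["event_labels"]) != {"-16", "+18"}


class TestShrinkForPlot:
    def test_two_point_closed_form(self):
        out = shrink_for_plot(np.array([1.0, 3.0]))
        np.testing.assert_allclose(out, [2 - 1 / np.sqrt(2), 2 + 1 / np.sqrt(2)])

    def test_constant_group_unchanged(self):
        np.testing.assert_allclose(shrink_for_plot(np.full(5, 2.5)), np.full(5, 2.5))

    def test_mean_preserved_variance_halved_exactly(self):
        rng = np.random.default_rng(12)
        x = rng.normal(2, 0.7, size=500)
        groups = rng.integers(0, 5, size=500)
        out = shrink_for_plot(x, groups)
        for g in range(5):
            sel = groups == g
            assert out[sel].mean() == pytest.approx(x[sel].mean())
            assert out[sel].var() == pytest.approx(x[sel].var() / 2)
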