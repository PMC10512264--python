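"""Windowed depth, repeat masking, the 30% aneuploidy rule, and the
instability statistics, checked against per-base and hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest

from hybridscan import karyotype, simulate
from hybridscan.karyotype import (
    EUPLOID,
    GAIN,
    LOSS,
    AneuploidyReport,
    ChromosomeDepthSummary,
    call_aneuploidy,
    chromosome_summary,
    contribution_balance,
    cross_heatmap,
    genome_metrics,
    mask_repetitive_windows,
    size_regression,
    window_depth,
    windows_from_track,
)


def perbase_oracle(placements, length):
    """Independent per-base accumulation: python loop per read."""
    depth = [0.0] * length
    for _i, row in placements.iterrows():
        for pos in range(max(0, row["start"]), min(length, row["end"])):
            depth[pos] += 1
    return depth


def make_windows(species, chrom, depths, width=10_000):
    return pd.DataFrame({
        "species": species, "chromosome": chrom,
        "start": np.arange(len(depths)) * width,
        "end": (np.arange(len(depths)) + 1) * width,
        "mean_depth": depths, "masked": False,
    })


class TestWindowDepth:
    def test_ten_reads_in_one_window(self):
        placements = pd.DataFrame({
            "species": ["s"] * 10, "chromosome": ["c"] * 10,
            "start": np.arange(10) * 500, "end": np.arange(10) * 500 + 100})
        win = window_depth(placements, {"s": {"c": 10_000}})
        assert len(win) == 1
        assert win.iloc[0]["mean_depth"] == pytest.approx(0.1)

    def test_matches_perbase_oracle(self):
        rng = np.random.default_rng(7)
        L = 50_000
        starts = rng.integers(0, L - 100, 500)
        placements = pd.DataFrame({
            "species": ["s"] * 500, "chromosome": ["c"] * 500,
            "start": starts, "end": starts + 100})
        win = window_depth(placements, {"s": {"c": L}})
        oracle = perbase_oracle(placements, L)
        for _i, row in win.iterrows():
            expect = np.mean(oracle[row["start"]: row["end"]])
            assert row["mean_depth"] == pytest.approx(expect, abs=1e-9)

    def test_empty_chromosome_zero_depth(self):
        win = window_depth(pd.DataFrame(columns=["species", "chromosome", "start", "end"]),
                           {"s": {"c": 25_000}})
        assert (win["mean_depth"] == 0).all()
        assert len(win) == 3  # last window short

    def test_degenerate_window_size_rejected(self):
        with pytest.raises(ValueError):
            window_depth(pd.DataFrame(columns=["species", "chromosome", "start", "end"]),
                         {"s": {"c": 10_000}}, window_size=500)

    def test_bedgraph_track_windows(self, tmp_path):
        path = tmp_path / "t.bedgraph"
        path.write_text("c\t0\t10000\t4\nc\t10000\t15000\t8\n")
        track = karyotype.read_bedgraph(path)
        win = windows_from_track(track, "s", {"c": 20_000})
        assert win["mean_depth"].tolist() == [4.0, 4.0]  # second window half 8, half 0


class TestMasking:
    def test_one_pass_hand_example(self):
        win = make_windows("s", "c", [10, 10, 10, 50, 10])
        out = mask_repetitive_windows(win)
        assert out["masked"].tolist() == [False, False, False, True, False]
        unmasked = out[~out["masked"]]
        assert unmasked["mean_depth"].mean() == pytest.approx(10.0)

    def test_uniform_depths_unmasked(self):
        out = mask_repetitive_windows(make_windows("s", "c", [10, 10, 10, 10]))
        assert not out["masked"].any()

    def test_exactly_twice_mean_not_masked(self):
        # mean of [10, 10, 20] is 40/3; use [5, 5, 5, 5, 10]: mean 6, 2x = 12
        out = mask_repetitive_windows(make_windows("s", "c", [6, 6, 6, 6, 12]))
        assert not out["masked"].any()  # 12 == 2 * mean(6): strict rule

    def test_zero_mean_masks_nothing(self):
        out = mask_repetitive_windows(make_windows("s", "c", [0, 0, 0]))
        assert not out["masked"].any()

    def test_iterative_mode_reaches_fixpoint(self):
        depths = [10, 10, 10, 10, 10, 10, 10, 10, 30, 300]
        one = mask_repetitive_windows(make_windows("s", "c", depths))
        it = mask_repetitive_windows(make_windows("s", "c", depths), iterative=True)
        assert one["masked"].sum() <= it["masked"].sum()
        assert it[~it["masked"]]["mean_depth"].max() == 10


class TestSummaryAndCalls:
    def test_total_is_sum_of_species(self):
        win = pd.concat([make_windows("sp1", "c", [6.0, 6.0]),
                         make_windows("sp2", "c", [4.0, 4.0])], ignore_index=True)
        s = chromosome_summary(win, {"sp1": {"c": 20_000}, "sp2": {"c": 20_000}})
        assert s.totals.iloc[0]["total_depth"] == pytest.approx(10.0)
        assert s.genome_mean == pytest.approx(10.0)  # single chromosome: D_G = D_c

    def test_matches_perbase_totals_on_toy_genome(self):
        rng = np.random.default_rng(8)
        lengths = {"c1": 30_000, "c2": 20_000, "c3": 12_000}
        rows = []
        for sp in ("sp1", "sp2"):
            for chrom, L in lengths.items():
                starts = rng.integers(0, L - 100, 200)
                for s in starts:
                    rows.append((sp, chrom, s, s + 100))
        placements = pd.DataFrame(rows, columns=["species", "chromosome", "start", "end"])
        win = window_depth(placements, {"sp1": lengths, "sp2": lengths})
        s = chromosome_summary(win, {"sp1": lengths, "sp2": lengths})
        for chrom, L in lengths.items():
            expect = 0.0
            for sp in ("sp1", "sp2"):
                sub = placements[(placements.species == sp) & (placements.chromosome == chrom)]
                expect += np.mean(perbase_oracle(sub, L))
            got = float(s.totals.set_index("chromosome").loc[chrom, "total_depth"])
            assert got == pytest.approx(expect, abs=1e-9)

    def test_thirty_percent_rule_with_boundary(self):
        totals = pd.DataFrame({"chromosome": ["c1", "c2", "c3", "c4"],
                               "total_depth": [10.0, 13.1, 6.9, 13.0],
                               "length": [10_000] * 4})
        s = ChromosomeDepthSummary(pd.DataFrame(), totals, genome_mean=10.0)
        calls = call_aneuploidy(s)
        assert calls == {"c1": EUPLOID, "c2": GAIN, "c3": LOSS, "c4": EUPLOID}

    def test_simulated_trisomy_called(self, parent_pair):
        truth = simulate.generate_hybrid(
            parent_pair, 0.5, aneuploidies=[("sp2", "chr04", +1)], sample_id="t", seed=55)
        reads = simulate.simulate_reads(truth, parent_pair, 20.0, seed=56)
        placements = karyotype.placements_from_truth(reads)
        lengths = {p.species_id: p.chrom_lengths for p in parent_pair}
        rep = karyotype.analyze_sample(placements, lengths, "t")
        assert rep.calls["chr04"] == GAIN
        assert rep.n_gain == 1 and rep.n_loss == 0


class TestMetrics:
    def _summary(self, depths, lengths=None):
        n = len(depths)
        lengths = lengths or [10_000] * n
        totals = pd.DataFrame({"chromosome": [f"c{i}" for i in range(n)],
                               "total_depth": depths, "length": lengths})
        dg = float(np.average(depths, weights=lengths))
        return ChromosomeDepthSummary(pd.DataFrame({"species": [], "chromosome": [], "depth": []}),
                                      totals, genome_mean=dg)

    def test_variance_and_delta_hand_example(self):
        s = self._summary([8.0, 10.0, 12.0])
        rep = genome_metrics(s, call_aneuploidy(s), "x")
        assert rep.variance == pytest.approx(4.0)
        assert [rep.delta[c] for c in ("c0", "c1", "c2")] == pytest.approx([2.0, 0.0, 2.0])

    def test_equal_depths_degenerate(self):
        s = self._summary([10.0, 10.0, 10.0], lengths=[8_000, 10_000, 12_000])
        rep = genome_metrics(s, call_aneuploidy(s), "x")
        assert rep.variance == 0.0
        assert all(d == 0 for d in rep.delta.values())
        assert rep.slope == 0.0 and rep.r == 0.0

    def test_gain_and_loss_flagged(self):
        s = self._summary([10.0, 14.0, 6.0])
        rep = genome_metrics(s, call_aneuploidy(s), "x")
        assert rep.both_gain_and_loss

    def test_scale_invariance(self):
        base = self._summary([8.0, 10.0, 12.0, 9.0])
        scaled = self._summary([c * 7 for c in [8.0, 10.0, 12.0, 9.0]])
        rep_b = genome_metrics(base, call_aneuploidy(base), "b")
        rep_s = genome_metrics(scaled, call_aneuploidy(scaled), "s")
        assert rep_b.calls == rep_s.calls
        assert rep_s.variance == pytest.approx(49 * rep_b.variance)
        assert rep_s.r == pytest.approx(rep_b.r)


class TestSizeRegression:
    def _report(self, points, sample="s"):
        delta = {f"c{i}": y for i, (_x, y) in enumerate(points)}
        lengths = {f"c{i}": x for i, (x, _y) in enumerate(points)}
        return AneuploidyReport(
            sample_id=sample, calls={}, n_gain=0, n_loss=0, variance=0.0,
            delta=delta, slope=None, r=None, genome_mean=1.0,
            per_species_mean={}, lengths=lengths)

    def test_hand_least_squares(self):
        reg = size_regression([self._report([(100, 3.0), (200, 2.0), (300, 1.0)])])
        assert reg.pooled_slope == pytest.approx(-0.01)
        assert reg.pooled_r == pytest.approx(-1.0)

    def test_zero_length_variance_rejected(self):
        with pytest.raises(ValueError):
            size_regression([self._report([(100, 1.0), (100, 2.0), (100, 3.0)])])


class TestCrossLevel:
    def test_heatmap_endpoints_and_midpoint(self):
        reps = {
            "A": [TestSizeRegression()._report([(100, 2.0)], "a")],
            "B": [TestSizeRegression()._report([(100, 6.0)], "b")],
        }
        means, norm = cross_heatmap(reps)
        assert means.loc["A", "c0"] == 2.0 and means.loc["B", "c0"] == 6.0
        assert norm.loc["A", "c0"] == 0.0 and norm.loc["B", "c0"] == 1.0

    def test_identical_means_map_to_midpoint(self):
        reps = {
            "A": [TestSizeRegression()._report([(100, 3.0)], "a")],
            "B": [TestSizeRegression()._report([(100, 3.0)], "b")],
        }
        _means, norm = cross_heatmap(reps)
        assert (norm["c0"] == 0.5).all()

    def test_three_cross_hand_scaling(self):
        reps = {c: [TestSizeRegression()._report([(100, v)], c)]
                for c, v in [("A", 1.0), ("B", 4.0), ("C", 7.0)]}
        _means, norm = cross_heatmap(reps)
        # overall mean 4: A at min -> 0, B at mean -> 0.5, C at max -> 1
        assert norm["c0"].tolist() == [0.0, 0.5, 1.0]

    def test_contribution_balance_record(self):
        from hybridscan.ancestry import ContributionProfile

        prof = ContributionProfile("s", {"sp1": 0.7, "sp2": 0.3}, {}, 0.0, 0.0,
                                   "sp1", None, None, None)
        rep = TestSizeRegression()._report([(100, 1.0)], "s")
        rec = contribution_balance(prof, rep)
        assert rec["balance"] == pytest.approx(0.4)
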