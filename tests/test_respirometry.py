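import numpy as np
import pytest

import gillscale as g
from gillscale.respirometry import (
    CycleConfig,
    Mo2Estimate,
    analyze_rmr_trace,
    estimate_pcrit_llo,
    o2_solubility_mg_per_l,
)

from conftest import make_linear_trace


def make_trace(time_s, o2, volume_l=0.657, mass_g=2.62, temp=15.0):
    return g.OxygenTrace(
        fish_id="t",
        temperature_c=temp,
        time_s=np.asarray(time_s, float),
        o2_percent_sat=np.asarray(o2, float),
        system_volume_l=volume_l,
        fish_mass_g=mass_g,
    )


class TestSolubility:
    @pytest.mark.parametrize(
        "temp,expected",
        [(15.0, 10.08), (20.0, 9.09), (0.0, 14.62), (25.0, 8.26)],
    )
    def test_published_freshwater_values(self, temp, expected):
        """Air-saturation concentrations match published solubility tables."""
        assert o2_solubility_mg_per_l(temp) == pytest.approx(expected, abs=0.005)

    def test_percent_scaling(self):
        assert g.percent_sat_to_mg_per_l(0.0, 17.0) == 0.0
        assert g.percent_sat_to_mg_per_l(50.0, 17.0) == pytest.approx(
            0.5 * o2_solubility_mg_per_l(17.0)
        )

    def test_rejects_out_of_range_temperature(self):
        with pytest.raises(ValueError):
            o2_solubility_mg_per_l(45.0)


class TestSegmentCycles:
    CYCLE = CycleConfig(flush_s=240.0, wait_s=60.0, measure_s=300.0)

    def test_exact_tiling(self):
        t = np.arange(6000.0)
        trace = make_trace(t, np.full(6000, 95.0))
        segs = g.segment_cycles(trace, self.CYCLE)
        assert len(segs) == 10
        assert all(ts.size == 300 for ts, _ in segs)
        # first segment spans [300, 600)
        assert segs[0][0][0] == 300.0 and segs[0][0][-1] == 599.0

    def test_trailing_partial_cycle_dropped(self):
        t = np.arange(6100.0)
        trace = make_trace(t, np.full(6100, 95.0))
        assert len(g.segment_cycles(trace, self.CYCLE)) == 10

    def test_short_trace_warns_and_returns_empty(self):
        trace = make_trace(np.arange(100.0), np.full(100, 95.0))
        with pytest.warns(UserWarning, match="shorter than"):
            assert g.segment_cycles(trace, self.CYCLE) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_index_scan(self, seed):
        rng = np.random.default_rng(seed)
        cyc = CycleConfig(
            flush_s=float(rng.integers(30, 120)),
            wait_s=float(rng.integers(10, 60)),
            measure_s=float(rng.integers(60, 240)),
        )
        n = int(rng.integers(2, 6) * cyc.cycle_s + rng.integers(0, cyc.cycle_s))
        t = np.arange(float(n))
        trace = make_trace(t, 100 - 0.001 * t)
        segs = g.segment_cycles(trace, cyc)
        # brute force: classify every sample by its within-cycle offset
        expected = {}
        for i, ti in enumerate(t):
            if ti >= (n // cyc.cycle_s) * cyc.cycle_s:
                continue
            k = int(ti // cyc.cycle_s)
            off = ti - k * cyc.cycle_s
            if off >= cyc.flush_s + cyc.wait_s:
                expected.setdefault(k, []).append(ti)
        assert len(segs) == len(expected)
        for k, (ts, _) in enumerate(segs):
            assert ts.tolist() == expected[k]


class TestFitSegmentSlope:
    def test_exact_line(self):
        t = np.arange(300.0)
        slope, r2 = g.fit_segment_slope(t, 100.0 - 0.01 * t)
        assert slope == pytest.approx(-0.01, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_o2_degenerate(self):
        slope, r2 = g.fit_segment_slope(np.arange(10.0), np.full(10, 95.0))
        assert slope == 0.0
        assert np.isnan(r2)

    def test_zero_time_variance_rejected(self):
        with pytest.raises(ValueError, match="time variance"):
            g.fit_segment_slope(np.zeros(5), np.arange(5.0))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_normal_equation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 600, 200))
        y = 100 - 0.005 * t + rng.normal(0, 0.3, t.size)
        slope, r2 = g.fit_segment_slope(t, y)
        # independent closed-form normal equations
        n = t.size
        b = (n * np.sum(t * y) - t.sum() * y.sum()) / (
            n * np.sum(t * t) - t.sum() ** 2
        )
        r = np.corrcoef(t, y)[0, 1]
        assert slope == pytest.approx(b, abs=1e-12)
        assert r2 == pytest.approx(r**2, abs=1e-12)


class TestComputeMo2:
    def test_hand_arithmetic(self):
        # slope of -0.001 mg/L/s, V_sys 0.657 L, fish 2.62 g
        # -> 0.001 * 0.65438 * 3600 = 2.3558 mg O2/h
        sol = o2_solubility_mg_per_l(15.0)
        slope_pct = -0.001 / sol * 100.0
        assert g.compute_mo2(slope_pct, 0.657, 2.62, 15.0) == pytest.approx(
            0.001 * 0.65438 * 3600.0, rel=1e-6
        )

    def test_zero_slope(self):
        assert g.compute_mo2(0.0, 0.657, 2.62, 15.0) == 0.0

    def test_linearity_in_effective_volume(self):
        m1 = g.compute_mo2(-0.01, 1.0 + 0.005, 5.0, 15.0)
        m2 = g.compute_mo2(-0.01, 2.0 + 0.005, 5.0, 15.0)
        assert m2 == pytest.approx(2.0 * m1)

    def test_rejects_fish_bigger_than_chamber(self):
        with pytest.raises(ValueError, match="effective volume"):
            g.compute_mo2(-0.01, 0.5, 600.0, 15.0)


def _estimates(values, accepted=None):
    accepted = accepted or [True] * len(values)
    return [
        Mo2Estimate(
            window_start_s=i * 100.0,
            window_end_s=i * 100.0 + 60.0,
            slope_percent_sat_per_s=-0.01,
            r_squared=0.99,
            mo2_mg_o2_per_h=v,
            accepted=a,
        )
        for i, (v, a) in enumerate(zip(values, accepted))
    ]


class TestEstimateRmr:
    def test_lowest_quartile_mean(self):
        assert g.estimate_rmr(_estimates([1, 2, 3, 4, 5, 6, 7, 8])) == 1.5

    def test_constant(self):
        assert g.estimate_rmr(_estimates([5.0] * 6)) == 5.0

    def test_ceiling_rule_n5(self):
        # k = ceil(1.25) = 2 -> mean of two smallest
        assert g.estimate_rmr(_estimates([3.0, 1.0, 5.0, 2.0, 4.0])) == 1.5

    def test_permutation_invariance_and_below_median(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(1, 10, 17)
        a = g.estimate_rmr(_estimates(list(vals)))
        b = g.estimate_rmr(_estimates(list(rng.permutation(vals))))
        assert a == pytest.approx(b)
        assert a <= np.median(vals)

    def test_rejected_segments_excluded(self):
        ests = _estimates([1.0, 9.0, 9.0, 9.0], accepted=[False, True, True, True])
        assert g.estimate_rmr(ests) == 9.0

    def test_zero_accepted_raises_with_r2_diagnostics(self):
        ests = _estimates([1.0, 2.0], accepted=[False, False])
        with pytest.raises(ValueError, match="R2"):
            g.estimate_rmr(ests)


class TestEstimateMmr:
    def test_planted_steepest_slope(self):
        t = np.arange(300.0)
        o2 = np.where(t < 120, 100 - 0.02 * t, 100 - 0.02 * 120 - 0.005 * (t - 120))
        trace = make_trace(t, o2)
        mmr, est = g.estimate_mmr(trace, window_s=60.0)
        assert est.window_end_s <= 120.0
        assert est.slope_percent_sat_per_s == pytest.approx(-0.02, abs=1e-12)

    def test_globally_linear_trace(self):
        trace = make_linear_trace(-0.01)
        mmr, est = g.estimate_mmr(trace)
        assert mmr == pytest.approx(
            g.compute_mo2(-0.01, 0.657, 2.62, 15.0), rel=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_window_search(self, seed):
        rng = np.random.default_rng(seed)
        n = 240
        t = np.arange(float(n))
        o2 = 100 - 0.01 * t + rng.normal(0, 0.2, n)
        trace = make_trace(t, o2)
        mmr, est = g.estimate_mmr(trace, window_s=60.0)
        slopes = [
            g.fit_segment_slope(t[i : i + 60], o2[i : i + 60])[0]
            for i in range(n - 59)
        ]
        assert est.slope_percent_sat_per_s == pytest.approx(min(slopes), abs=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            g.estimate_mmr(make_linear_trace(-0.01, n=30), window_s=60.0)


class TestSubtractBackground:
    def test_midpoint_interpolation(self):
        est = _estimates([1.0])[0]
        est = Mo2Estimate(
            window_start_s=12.5 * 3600,
            window_end_s=13.5 * 3600,
            slope_percent_sat_per_s=-0.01,
            r_squared=0.99,
            mo2_mg_o2_per_h=1.0,
            accepted=True,
        )
        out = g.subtract_background([est], 0.02, 0.06, 0.0, 26.0 * 3600)
        assert out[0].mo2_mg_o2_per_h == pytest.approx(1.0 - 0.04)
        assert out[0].background_subtracted

    def test_zero_background_identity(self):
        ests = _estimates([1.0, 2.0])
        out = g.subtract_background(ests, 0.0, 0.0, 0.0, 100.0)
        assert [e.mo2_mg_o2_per_h for e in out] == [1.0, 2.0]

    def test_clamps_to_zero_with_warning(self):
        ests = _estimates([0.03])
        with pytest.warns(UserWarning, match="clamped"):
            out = g.subtract_background(ests, 0.05, 0.05, 0.0, 200.0)
        assert out[0].mo2_mg_o2_per_h == 0.0

    def test_negative_background_clamped(self):
        ests = _estimates([1.0])
        with pytest.warns(UserWarning, match="negative background"):
            out = g.subtract_background(ests, -0.5, -0.5, 0.0, 200.0)
        assert out[0].mo2_mg_o2_per_h == 1.0

    def test_corrected_never_exceeds_uncorrected(self):
        rng = np.random.default_rng(3)
        ests = _estimates(list(rng.uniform(0.1, 3.0, 10)))
        out = g.subtract_background(ests, 0.01, 0.2, 0.0, 1000.0)
        for before, after in zip(ests, out):
            assert after.mo2_mg_o2_per_h <= before.mo2_mg_o2_per_h


def conformer_drawdown(rmr, pcrit, quadratic=True, floor=4.0):
    """Closed-chamber drawdown with MO2 = RMR above P_crit and either a
    quadratic conformer or a hard shutoff below it."""
    fish = {
        "fish_id": "pc",
        "temperature_c": 15.0,
        "mass_g": 2.62,
        "latent_rmr_mg_o2_per_h": rmr,
        "latent_pcrit_percent_sat": pcrit,
    }
    cfg = g.TraceConfig(drawdown_floor_percent_sat=floor)
    return g.generate_trace(fish, cfg, "pcrit_drawdown")


class TestPcritLlo:
    def test_quadratic_conformer_analytic_crossing(self):
        # MO2 = RMR*(P/30)^2 below 30% crosses the line RMR*P/100 at
        # P = 30^2/100 = 9.0% saturation
        trace = conformer_drawdown(2.0, 30.0)
        res = estimate_pcrit_llo(trace, 2.0)
        assert res.defined
        assert res.pcrit_percent_sat == pytest.approx(9.0, abs=2.0)

    def test_step_conformer(self):
        # near-hard shutoff at P_c: binned MO2 drops far below the line there
        sol = o2_solubility_mg_per_l(15.0)
        v_eff = 0.657 - 0.00262
        rate = 2.0 / (sol * v_eff * 3600.0) * 100.0  # % sat/s at RMR
        pc = 40.0
        o2 = [100.0]
        while o2[-1] > 30.0:
            p = o2[-1]
            mo2 = 2.0 if p >= pc else 0.2
            o2.append(p - rate * mo2 / 2.0)
        trace = make_trace(np.arange(len(o2), dtype=float), o2)
        res = estimate_pcrit_llo(trace, 2.0)
        assert res.defined
        assert res.pcrit_percent_sat == pytest.approx(pc, abs=2.5)

    def test_exact_conformer_undefined(self):
        # MO2 = RMR*P/100 rides the reference line; never strictly below
        sol = o2_solubility_mg_per_l(15.0)
        v_eff = 0.657 - 0.00262
        k = 2.0 / (sol * v_eff * 3600.0) * 100.0 / 100.0  # per second
        t = np.arange(40000.0)
        o2 = 100.0 * np.exp(-k * t)
        o2 = o2[o2 > 5.0]
        trace = make_trace(np.arange(float(o2.size)), o2)
        res = estimate_pcrit_llo(trace, 2.0)
        assert not res.defined
        assert np.isnan(res.pcrit_percent_sat)
        assert res.lowest_po2_percent_sat == pytest.approx(float(o2.min()))

    def test_rejects_nonpositive_rmr(self):
        with pytest.raises(ValueError):
            estimate_pcrit_llo(make_linear_trace(-0.01), 0.0)


class TestTraceLevelInvariants:
    def test_mmr_at_least_rmr_on_same_fish(self, small_cohort):
        row = small_cohort[small_cohort["is_sampled"]].iloc[0]
        cfg = g.TraceConfig(n_cycles=6, diel_period_s=3600.0)
        cyc = CycleConfig(flush_s=cfg.flush_s, wait_s=cfg.wait_s, measure_s=cfg.measure_s)
        rmr = g.estimate_rmr(analyze_rmr_trace(g.generate_trace(row, cfg, "rmr"), cyc))
        mmr, _ = g.estimate_mmr(g.generate_trace(row, cfg, "mmr_chase"))
        assert mmr >= rmr

    def test_unknown_trace_kind_rejected(self, small_cohort):
        row = small_cohort[small_cohort["is_sampled"]].iloc[0]
        with pytest.raises(ValueError, match="unknown trace kind"):
            g.generate_trace(row, g.TraceConfig(), "sprint")
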