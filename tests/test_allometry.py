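import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import gillscale as g
from gillscale.allometry import fit_traits_by_temperature, fits_to_frame


class TestFitPowerLaw:
    def test_exact_power_law(self):
        fit = g.fit_power_law(np.array([1.0, 10.0, 100.0]), np.array([2.0, 20.0, 200.0]))
        assert fit.b == pytest.approx(1.0, abs=1e-12)
        assert fit.a == pytest.approx(np.log10(2.0), abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noise_free_recovery(self):
        m = np.array([2.0, 5.0, 11.0, 30.0, 80.0, 200.0])
        fit = g.fit_power_law(m, 3.0 * m**0.8)
        assert fit.b == pytest.approx(0.8, abs=1e-12)
        assert fit.a == pytest.approx(np.log10(3.0), abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_linregress_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.uniform(2, 200, 40)
        y = 2.5 * m**0.9 * 10 ** rng.normal(0, 0.05, 40)
        fit = g.fit_power_law(m, y)
        lr = stats.linregress(np.log10(m), np.log10(y))
        assert fit.b == pytest.approx(lr.slope, abs=1e-12)
        assert fit.a == pytest.approx(lr.intercept, abs=1e-12)
        assert fit.se_b == pytest.approx(lr.stderr, abs=1e-12)
        assert fit.r_squared == pytest.approx(lr.rvalue**2, abs=1e-12)

    def test_ci_contains_slope_and_t_width(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(2, 200, 20)
        fit = g.fit_power_law(m, m**0.9 * 10 ** rng.normal(0, 0.05, 20))
        lo, hi = fit.ci95_b
        assert lo < fit.b < hi
        half = stats.t.ppf(0.975, fit.n - 2) * fit.se_b
        assert hi - fit.b == pytest.approx(half, abs=1e-12)

    def test_rejects_nonpositive_naming_rows(self):
        with pytest.raises(ValueError, match=r"rows \[1\]"):
            g.fit_power_law(np.array([1.0, -2.0, 3.0]), np.array([1.0, 2.0, 3.0]))

    def test_rejects_tiny_n(self):
        with pytest.raises(ValueError, match="at least 3"):
            g.fit_power_law(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestTemperatureInteraction:
    def test_identical_generating_line(self):
        m = np.array([1.0, 3.0, 10.0, 30.0, 100.0])
        y = 2.0 * m**0.9
        res = g.test_temperature_interaction(m, y, m, y)
        assert res["interaction_coef"] == pytest.approx(0.0, abs=1e-10)

    def test_equals_difference_of_group_slopes(self):
        rng = np.random.default_rng(2)
        m1, m2 = rng.uniform(2, 100, 25), rng.uniform(2, 100, 25)
        y1 = m1**0.97 * 10 ** rng.normal(0, 0.05, 25)
        y2 = m2**0.83 * 10 ** rng.normal(0, 0.05, 25)
        res = g.test_temperature_interaction(m1, y1, m2, y2)
        b1 = g.fit_power_law(m1, y1).b
        b2 = g.fit_power_law(m2, y2).b
        assert res["interaction_coef"] == pytest.approx(b2 - b1, abs=1e-10)

    def test_singular_design_rejected(self):
        m = np.full(5, 10.0)
        y = np.linspace(1, 2, 5)
        with pytest.raises(ValueError, match="singular"):
            g.test_temperature_interaction(m, y, m, y)

    def test_detects_slope_difference_with_power(self):
        """Slopes 0.97 vs 0.83 at n=40/group, noise sd 0.05: detected in
        >= 90 of 100 seeded replicates at alpha = 0.05."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m1, m2 = rng.uniform(2, 200, 40), rng.uniform(2, 200, 40)
            y1 = m1**0.97 * 10 ** rng.normal(0, 0.05, 40)
            y2 = m2**0.83 * 10 ** rng.normal(0, 0.05, 40)
            res = g.test_temperature_interaction(m1, y1, m2, y2)
            hits += res["p_value"] < 0.05
        assert hits >= 90


class TestScalingDifference:
    @pytest.mark.parametrize(
        "b_gsa,b_mr,metric,expected",
        [
            (0.969, 0.872, "RMR", 0.097),
            (0.969, 0.943, "MMR", 0.026),
        ],
    )
    def test_reported_slope_pairs(self, b_gsa, b_mr, metric, expected):
        comp = g.scaling_difference(b_gsa, b_mr, metric)
        assert comp.b_s == pytest.approx(expected, abs=1e-12)
        assert not comp.consistent_with_gol_scenario2

    def test_equal_slopes_boundary(self):
        comp = g.scaling_difference(0.9, 0.9)
        assert comp.b_s == 0.0
        assert not comp.consistent_with_gol_scenario2

    @given(st.floats(-2, 2), st.floats(-2, 2))
    def test_antisymmetry(self, x, y):
        assert g.scaling_difference(x, y).b_s == pytest.approx(
            -g.scaling_difference(y, x).b_s, abs=1e-12
        )


class TestDecomposition:
    def _fit(self, trait, b, n=30):
        return g.AllometricFit(trait, 15.0, 0.0, b, 0.01, (b - 0.02, b + 0.02), 0.99, n)

    def test_component_sums(self):
        d = g.decompose_gsa_slope(
            self._fit("lfil", 0.454), self._fit("nlam", -0.036), self._fit("alam", 0.551)
        )
        assert d["b_sum"] == pytest.approx(0.969, abs=1e-12)
        d = g.decompose_gsa_slope(
            self._fit("lfil", 0.33), self._fit("nlam", -0.33), self._fit("alam", 0.67)
        )
        assert d["b_sum"] == pytest.approx(0.67, abs=1e-12)

    def test_mismatched_fish_sets_rejected(self):
        with pytest.raises(ValueError, match="same fish"):
            g.decompose_gsa_slope(
                self._fit("lfil", 0.4), self._fit("nlam", -0.1, n=29), self._fit("alam", 0.5)
            )

    def test_fitted_additivity_on_synthetic_fish(self, small_cohort):
        """On any per-fish dataset, fitted b_GSA equals the sum of fitted
        component slopes (log-additivity + OLS linearity)."""
        sub = small_cohort[small_cohort["temperature_c"] == 15.0]
        m = sub["mass_g"].to_numpy()
        f_l = g.fit_power_law(m, sub["latent_lfil_mm"].to_numpy())
        f_n = g.fit_power_law(m, sub["latent_nlam_per_mm"].to_numpy())
        f_a = g.fit_power_law(m, sub["latent_alam_mm2"].to_numpy())
        f_g = g.fit_power_law(m, sub["latent_gsa_mm2"].to_numpy())
        d = g.decompose_gsa_slope(f_l, f_n, f_a, fit_gsa=f_g)
        assert d["b_sum"] == pytest.approx(f_g.b, abs=1e-10)
        assert d["a_sum"] == pytest.approx(f_g.a, abs=1e-10)


class TestMassCorrection:
    def test_identity_at_reference_mass(self):
        assert g.mass_correct(3.0, 24.0, 0.872) == pytest.approx(3.0)

    def test_hand_arithmetic(self):
        # 3.0 * (24/48)^0.872 = 3.0 * 2^-0.872 = 1.639
        assert g.mass_correct(3.0, 48.0, 0.872) == pytest.approx(1.639, abs=5e-4)

    def test_zero_slope_identity(self):
        assert g.mass_correct(3.0, 480.0, 0.0) == pytest.approx(3.0)

    def test_correction_removes_mass_dependence(self):
        """Mass-correcting with the true slope leaves no residual slope."""
        rng = np.random.default_rng(7)
        m = rng.uniform(2, 200, 60)
        y = 0.15 * m**0.87 * 10 ** rng.normal(0, 0.05, 60)
        b = g.fit_power_law(m, y).b
        corrected = g.mass_correct(y, m, b)
        resid_fit = g.fit_power_law(m, corrected)
        lo, hi = resid_fit.ci95_b
        assert lo < 0.0 < hi

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            g.mass_correct(-1.0, 24.0, 0.9)


class TestQ10AndFas:
    def test_equal_rates(self):
        assert g.q10(2.0, 2.0, 15.0, 20.0) == 1.0

    def test_doubling_over_ten_degrees(self):
        assert g.q10(1.0, 2.0, 15.0, 25.0) == pytest.approx(2.0)

    def test_hand_arithmetic(self):
        assert g.q10(1.0, 1.32, 15.0, 20.0) == pytest.approx(1.7424, abs=1e-4)

    def test_equal_temperatures_rejected(self):
        with pytest.raises(ValueError):
            g.q10(1.0, 2.0, 15.0, 15.0)

    def test_fas(self):
        assert g.factorial_aerobic_scope(6.0, 2.0) == pytest.approx(3.0)
        assert g.factorial_aerobic_scope(2.0, 2.0) == 1.0

    def test_fas_below_one_warns(self):
        with pytest.warns(UserWarning, match="FAS"):
            g.factorial_aerobic_scope(1.0, 2.0)

    def test_fas_invariant_to_reference_when_b_shared(self):
        """With a common slope b, FAS is independent of the correction
        reference mass."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            mmr, rmr = rng.uniform(2, 8), rng.uniform(0.5, 2)
            mass, b = rng.uniform(2, 200), rng.uniform(0.7, 1.1)
            f24 = g.factorial_aerobic_scope(
                g.mass_correct(mmr, mass, b), g.mass_correct(rmr, mass, b)
            )
            cfg = g.MassCorrectionConfig(reference_mass_g=100.0)
            f100 = g.factorial_aerobic_scope(
                g.mass_correct(mmr, mass, b, cfg), g.mass_correct(rmr, mass, b, cfg)
            )
            assert f24 == pytest.approx(f100, rel=1e-12)


class TestFitTables:
    def test_fit_traits_by_temperature(self, small_cohort):
        fits = fit_traits_by_temperature(
            small_cohort, ["latent_gsa_mm2", "latent_rmr_mg_o2_per_h"]
        )
        assert len(fits) == 4  # 2 traits x 2 temperatures
        frame = fits_to_frame(fits)
        assert set(frame["trait"]) == {"latent_gsa_mm2", "latent_rmr_mg_o2_per_h"}
        assert ((frame["ci_low"] < frame["b"]) & (frame["b"] < frame["ci_high"])).all()
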