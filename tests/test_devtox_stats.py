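"""Outlier filtering, Hill fitting, Welch ANOVA / Dunnett T3 and CV."""

import numpy as np
import pytest
from scipy import stats

from wormseg import devtox_stats as ds


class TestTukeyFilter:
    def test_flags_gross_outlier(self):
        kept, removed = ds.tukey_filter([1, 2, 3, 4, 100])
        # oracle: Q1=2, Q3=4 (linear interpolation), fences [-1, 7]
        np.testing.assert_array_equal(kept, [1, 2, 3, 4])
        np.testing.assert_array_equal(removed, [100])

    def test_all_equal_removes_nothing(self):
        kept, removed = ds.tukey_filter([5.0] * 10)
        assert len(kept) == 10 and len(removed) == 0

    def test_clean_normal_sample_rarely_trimmed(self):
        x = np.random.default_rng(0).normal(0, 1, 1000)
        kept, removed = ds.tukey_filter(x)
        assert len(removed) / 1000 < 0.02  # expected Tukey exceedance ~0.7%

    def test_small_sample_passthrough_with_warning(self):
        with pytest.warns(UserWarning):
            kept, removed = ds.tukey_filter([1, 2, 3])
        assert len(kept) == 3 and len(removed) == 0

    def test_idempotent_on_own_output(self):
        x = np.random.default_rng(1).normal(0, 1, 200)
        x[:5] += 10
        kept, _ = ds.tukey_filter(x)
        kept2, removed2 = ds.tukey_filter(kept)
        # second pass may tighten slightly but the bulk is stable
        assert len(removed2) <= 0.01 * len(kept)


class TestSummarizeWell:
    def test_constant_values(self):
        s = ds.summarize_well({"length_um": np.array([10.0, 10, 10, 10])})
        st = s.stats["length_um"]
        assert st["mean"] == 10 and st["sd"] == 0 and st["cv"] == 0

    def test_two_value_closed_form(self):
        s = ds.summarize_well({"length_um": np.array([8.0, 12.0])})
        st = s.stats["length_um"]
        assert st["mean"] == 10
        assert st["sd"] == pytest.approx(np.sqrt(8))
        assert st["cv"] == pytest.approx(np.sqrt(8) / 10)
        assert st["sem"] == pytest.approx(st["sd"] / np.sqrt(2))

    def test_joint_removal_across_endpoints(self):
        """A worm outside the fences of either filter endpoint is removed
        from every endpoint."""
        n = 12
        length = np.full(n, 1000.0)
        af = np.full(n, 1.0)
        length[0] = 5000.0   # length outlier
        af[1] = 50.0         # autofluorescence outlier
        s = ds.summarize_well({"length_um": length, "af_per_length": af,
                               "area_um2": np.full(n, 10.0)})
        assert s.n_worms_kept == n - 2


class TestControlCv:
    def test_identical_means_zero(self):
        assert ds.control_cv(np.array([100.0, 100, 100])) == 0.0

    def test_closed_form(self):
        assert ds.control_cv(np.array([95.0, 100.0, 105.0])) == \
            pytest.approx(5.0 / 100.0)

    def test_requires_two_wells(self):
        with pytest.raises(ValueError):
            ds.control_cv(np.array([1.0]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_simulated_device_control_cv_in_assay_range(self, seed):
        """With a 4% well-level biological CV the control-well-mean CV
        lands in the assay's observed 2-8% band."""
        from wormseg import synthetic_data as sd

        plan = sd.DosePlan(biological_cv=0.04)
        df = sd.simulate_dose_response(plan, np.random.default_rng(seed),
                                       n_replicates=8, n_worms_per_well=25)
        ctrl = df[df.dose_um == 0].groupby("well")["length_um"].mean()
        cv = ds.control_cv(ctrl.to_numpy())
        assert 0.02 <= cv <= 0.08


class TestHillFit:
    def test_ec50_is_ec_fifty_for_any_slope(self):
        for h in (-3.1, -0.7, 1.0, 2.5):
            assert ds.ec_anything(2.0, h, f=50.0) == pytest.approx(2.0)

    def test_noiseless_recovery_matches_analytic_inversion(self):
        """On exact Hill data the fitted EC10 equals the analytic
        concentration of a 10% decline to machine tolerance."""
        doses = np.concatenate([[0.0], np.geomspace(0.1, 10, 11)])
        xs = ds._substitute_control_dose(doses)
        y = ds.hill_curve(xs, 0.0, 1000.0, 1.0, 2.0)
        fit = ds.hill_fit(doses, y, "body")
        # analytic: Y = 0.9*Top at (1/9)^(1/2) * EC50
        expected = (10 / 90) ** (1 / 2.0) * 1.0
        assert fit.ec10 == pytest.approx(expected, rel=1e-6)
        assert fit.bottom == 0.0

    def test_af_mode_recovers_rising_curve(self):
        doses = np.concatenate([[0.0], np.geomspace(0.2, 9, 9)])
        xs = ds._substitute_control_dose(doses)
        y = ds.hill_curve(xs, 2.5, 1.0, 2.0, 3.0)  # rises 1.0 -> 2.5
        fit = ds.hill_fit(doses, y, "af")
        assert fit.ec50 == pytest.approx(2.0, rel=1e-3)
        assert fit.ec10 == pytest.approx((1 / 9) ** (1 / 3.0) * 2.0,
                                         rel=1e-3)

    def test_dose_scale_equivariance(self):
        rng = np.random.default_rng(0)
        doses = np.repeat(np.concatenate([[0.0], np.geomspace(0.1, 10, 9)]),
                          3)
        xs = ds._substitute_control_dose(doses)
        y = ds.hill_curve(xs, 0.0, 100.0, 1.5, 2.0) * \
            (1 + rng.normal(0, 0.02, len(xs)))
        f1 = ds.hill_fit(doses, y, "body")
        f2 = ds.hill_fit(doses * 7.0, y, "body")
        assert f2.ec50 == pytest.approx(7 * f1.ec50, rel=1e-3)
        assert f2.ec10 == pytest.approx(7 * f1.ec10, rel=1e-3)

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            ds.hill_fit([0, 1, 2], [3.0, 2.0, 1.0], "body")

    def test_bootstrap_ci_brackets_noiseless_truth(self):
        rng = np.random.default_rng(1)
        doses = np.repeat(np.concatenate([[0.0], np.geomspace(0.1, 10, 11)]),
                          5)
        xs = ds._substitute_control_dose(doses)
        y = ds.hill_curve(xs, 0.0, 1000.0, 1.0, 2.0) * \
            (1 + rng.normal(0, 0.05, len(xs)))
        fit = ds.hill_fit(doses, y, "body", ci_method="bootstrap",
                          n_boot=100, rng=np.random.default_rng(2))
        lo, hi = fit.ec10_ci
        assert lo < fit.ec10 < hi


class TestWelchAnova:
    def test_matches_published_formula_reference(self):
        """Cross-check against an independent implementation (pingouin)."""
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(0)
        groups = [rng.normal(0, 1, 10), rng.normal(0.5, 2, 12),
                  rng.normal(1, 0.5, 8)]
        f, df1, df2, p = ds.welch_anova(groups)
        frame = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat(np.arange(3), [len(g) for g in groups]),
        })
        ref = pg.welch_anova(frame, dv="y", between="g")
        assert f == pytest.approx(float(ref["F"].iloc[0]))
        assert df2 == pytest.approx(float(ref["ddof2"].iloc[0]))
        assert p == pytest.approx(float(ref["p_unc"].iloc[0]))

    def test_two_groups_equals_squared_welch_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 9), rng.normal(1, 2, 14)
        f, _, _, p = ds.welch_anova([a, b])
        t = stats.ttest_ind(a, b, equal_var=False)
        assert f == pytest.approx(t.statistic**2)
        assert p == pytest.approx(t.pvalue)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            ds.welch_anova([np.array([1.0]), np.array([1.0, 2.0])])


class TestDunnettT3:
    def test_per_comparison_t_matches_scipy_welch(self):
        rng = np.random.default_rng(2)
        g = {0.0: rng.normal(0, 1, 10), 1.0: rng.normal(1, 2, 12)}
        res = ds.dunnett_t3(g)
        ref = stats.ttest_ind(g[1.0], g[0.0], equal_var=False)
        assert res[1.0]["t"] == pytest.approx(float(ref.statistic))
        p_unadj = 2 * stats.t.sf(abs(res[1.0]["t"]), res[1.0]["df"])
        assert p_unadj == pytest.approx(float(ref.pvalue))

    def test_monte_carlo_agrees_with_smm_form(self):
        rng = np.random.default_rng(3)
        g = {d: rng.normal(0, 1, 10) for d in (0.0, 1.0, 2.0)}
        analytic = ds.dunnett_t3(g)
        mc = ds.dunnett_t3(g, n_mc=20000, rng=np.random.default_rng(4))
        for d in (1.0, 2.0):
            assert mc[d]["p_adj"] == pytest.approx(analytic[d]["p_adj"],
                                                   abs=0.05)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="T3"):
            ds.dunnett_t3({0.0: np.ones(2), 1.0: np.ones(5)})


class TestLoael:
    def test_overwhelming_shift_flags_first_treated_dose(self):
        rng = np.random.default_rng(5)
        sigma = 1.0
        vals = {
            0.0: rng.normal(100, sigma, 10),
            1.0: rng.normal(100 - 10 * sigma, sigma, 10),
            2.0: rng.normal(100 - 10 * sigma, sigma, 10),
        }
        res = ds.loael(vals)
        assert res.loael_dose_um == 1.0
        assert all(0 <= p <= 1 for p in res.p_values.values())
        assert set(res.normality_p) == {0.0, 1.0, 2.0}

    def test_requires_control(self):
        with pytest.raises(ValueError, match="control"):
            ds.loael({1.0: np.ones(5), 2.0: np.ones(5)})

    def test_monotone_in_effect_size(self):
        """Increasing every treated group's shift never raises the LOAEL."""
        rng = np.random.default_rng(6)
        base = {d: rng.normal(100, 3, 12) for d in (0.0, 1.0, 2.0, 4.0)}
        loaels = []
        for shift in (0.5, 2.0, 8.0):
            vals = {d: (v - shift * np.log1p(d) if d > 0 else v)
                    for d, v in base.items()}
            res = ds.loael(vals)
            loaels.append(res.loael_dose_um
                          if res.loael_dose_um is not None else np.inf)
        assert loaels[0] >= loaels[1] >= loaels[2]
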