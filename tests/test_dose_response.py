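"""Logistic fitting, extra-sum-of-squares F tests and Holm-Šídák adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from synaptoquant import dose_response as dr
from synaptoquant.simulate import four_param_logistic, simulate_dose_response_study


class TestFit4pl:
    def test_noiseless_recovery_exact(self, dose_ladder):
        y = four_param_logistic(dose_ladder, 0.0, 100.0, 50.0, 1.0)
        fit = dr.fit_4pl(dose_ladder, y, "4pl")
        assert fit.converged
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)
        assert fit.top == pytest.approx(100.0, abs=1e-6)
        assert fit.ec50 == pytest.approx(50.0, abs=1e-6)
        assert fit.hill == pytest.approx(1.0, abs=1e-6)

    def test_noiseless_three_parameter_variant(self, dose_ladder):
        y = four_param_logistic(dose_ladder, 0.0, 80.0, 120.0, 1.6)
        fit = dr.fit_4pl(dose_ladder, y, "3pl")
        assert fit.ec50 == pytest.approx(120.0, abs=1e-5)
        assert fit.hill == pytest.approx(1.6, abs=1e-6)

    def test_constant_responses_flagged_degenerate(self, dose_ladder):
        fit = dr.fit_4pl(dose_ladder, np.full_like(dose_ladder, 5.0), "4pl")
        assert fit.degenerate

    def test_auto_prefers_3pl_when_bottom_is_zero(self, dose_ladder):
        rng = np.random.default_rng(4)
        y = four_param_logistic(dose_ladder, 0.0, 100.0, 50.0, 1.0)
        y = np.repeat(y, 6) + 3 * rng.standard_normal(dose_ladder.size * 6)
        fit = dr.fit_4pl(np.repeat(dose_ladder, 6), y, "auto")
        assert fit.parameterization == "3pl"

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            dr.fit_4pl([0.0, 1.0, 10.0], [0.0, 5.0, 10.0], "4pl")

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(st.floats(0.1, 100.0))
    def test_dose_rescaling_rescales_ec50_only(self, factor):
        """Uniform dose rescaling moves EC50 by the same factor, nothing else."""
        doses = np.array([0.0] + [1000.0 / 2 ** k for k in reversed(range(8))])
        rng = np.random.default_rng(17)
        y = four_param_logistic(doses, 0.0, 100.0, 50.0, 1.2) + rng.normal(0, 3, doses.size)
        a = dr.fit_4pl(doses, y, "3pl")
        b = dr.fit_4pl(doses * factor, y, "3pl")
        assert b.ec50 == pytest.approx(a.ec50 * factor, rel=1e-4)
        assert b.top == pytest.approx(a.top, rel=1e-6)
        assert b.hill == pytest.approx(a.hill, rel=1e-4)

    def test_median_ec50_error_under_noise(self):
        """Recovery study at the default donor design: median |EC50 error| < 10%."""
        errs = []
        for r in range(120):
            d, y = simulate_dose_response_study(seed=5000 + r)
            fit = dr.fit_4pl(d, y, "3pl")
            errs.append(abs(fit.ec50 - 50.0) / 50.0)
        assert np.median(errs) < 0.10


class TestCompareCurves:
    def test_identical_datasets_give_null_result(self, dose_ladder):
        y = four_param_logistic(dose_ladder, 0.0, 100.0, 50.0, 1.0)
        c = dr.compare_curves([(dose_ladder, y), (dose_ladder, y)], "all")
        assert c.f_statistic == pytest.approx(0.0, abs=1e-6)
        assert c.p_value == pytest.approx(1.0, abs=1e-6)

    def test_f_statistic_matches_brute_force_assembly(self):
        """F equals the hand-assembled RSS computation on a 2-group toy."""
        d, y1 = simulate_dose_response_study(ec50=40.0, n_donors=2, seed=31)
        _, y2 = simulate_dose_response_study(ec50=90.0, n_donors=2, seed=32)
        c = dr.compare_curves([(d, y1), (d, y2)], "all", "3pl")

        # independent oracle: brute-force curve_fit per group and pooled
        def f3(x, top, ec50, hill):
            return four_param_logistic(x, 0.0, top, ec50, hill)

        rss = []
        for y in (y1, y2, None):
            xd = d if y is not None else np.concatenate([d, d])
            yd = y if y is not None else np.concatenate([y1, y2])
            best = np.inf
            for e0 in (20.0, 50.0, 150.0, 400.0):
                try:
                    popt, _ = optimize.curve_fit(f3, xd, yd, p0=[100.0, e0, 1.0],
                                                 maxfev=20000)
                    best = min(best, float(np.sum((f3(xd, *popt) - yd) ** 2)))
                except RuntimeError:
                    continue
            rss.append(best)
        rss_alt = rss[0] + rss[1]
        rss_null = rss[2]
        n = 2 * d.size
        df_alt, df_null = n - 6, n - 3
        f_expected = ((rss_null - rss_alt) / (df_null - df_alt)) / (rss_alt / df_alt)
        assert c.f_statistic == pytest.approx(f_expected, rel=1e-3)
        assert c.p_value == pytest.approx(
            float(stats.f.sf(f_expected, df_null - df_alt, df_alt)), rel=1e-3)

    def test_shared_ec50_only_null(self):
        d, y1 = simulate_dose_response_study(ec50=50.0, top=100.0, n_donors=4, seed=41)
        _, y2 = simulate_dose_response_study(ec50=50.0, top=60.0, n_donors=4, seed=42)
        same_ec50 = dr.compare_curves([(d, y1), (d, y2)], "ec50", "3pl")
        different_all = dr.compare_curves([(d, y1), (d, y2)], "all", "3pl")
        # tops differ 100 vs 60: sharing everything must be much worse than
        # sharing only EC50
        assert different_all.f_statistic > same_ec50.f_statistic
        assert same_ec50.p_value > 0.001

    def test_type_one_error_calibrated(self):
        """Shared-curve null: rejection rate compatible with alpha = 0.05."""
        rej = 0
        n_reps = 150
        for r in range(n_reps):
            d, y1 = simulate_dose_response_study(seed=6000 + 2 * r)
            _, y2 = simulate_dose_response_study(seed=6001 + 2 * r)
            rej += dr.compare_curves([(d, y1), (d, y2)], "all", "3pl").p_value < 0.05
        assert 0.05 - 0.04 <= rej / n_reps <= 0.05 + 0.04

    def test_power_against_fourfold_ec50_shift(self):
        rej = 0
        for r in range(40):
            d, y1 = simulate_dose_response_study(ec50=50.0, seed=7000 + 2 * r)
            _, y2 = simulate_dose_response_study(ec50=200.0, seed=7001 + 2 * r)
            rej += dr.compare_curves([(d, y1), (d, y2)], "all", "3pl").p_value < 0.05
        assert rej / 40 > 0.9

    def test_single_group_rejected(self, dose_ladder):
        y = four_param_logistic(dose_ladder, 0, 100, 50, 1)
        with pytest.raises(ValueError, match="two groups"):
            dr.compare_curves([(dose_ladder, y)], "all")


class TestHolmSidak:
    def test_closed_form_worked_example(self):
        """Adjusted p for raw {0.01, 0.04, 0.3}: step-down 1-(1-p)^(m-k+1)."""
        adj = dr.holm_sidak_adjust([0.01, 0.04, 0.3])
        np.testing.assert_allclose(adj, [0.029701, 0.0784, 0.3], atol=1e-6)

    def test_single_comparison_unchanged(self):
        assert dr.holm_sidak_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_ones(self):
        out = dr.holm_sidak_multiple_t(
            [(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))] * 2)
        assert (out.p_adjusted == 1.0).all() and not out.reject.any()

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8))
    def test_adjusted_monotone_and_at_least_raw(self, pvals):
        adj = dr.holm_sidak_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        # step-down closed form on the sorted sequence
        m = len(pvals)
        expected, prev = [], 0.0
        for k, p in enumerate(sorted(pvals), start=1):
            prev = max(prev, 1 - (1 - p) ** (m - k + 1))
            expected.append(prev)
        np.testing.assert_allclose(np.sort(adj), expected, atol=1e-10)

    def test_zero_variance_tie_handling(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = dr.holm_sidak_multiple_t(
                [(np.array([1.0, 1.0]), np.array([1.0, 1.0])),
                 (np.array([2.0, 2.0]), np.array([3.0, 3.0]))])
        assert out.p_raw.tolist() == [1.0, 0.0]

    def test_t_pvalues_match_scipy(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        out = dr.holm_sidak_multiple_t([(a, b)], paired=True)
        assert out.p_raw[0] == pytest.approx(stats.ttest_rel(a, b).pvalue)
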