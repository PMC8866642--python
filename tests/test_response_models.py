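"""Hierarchical smooths, CIs, threshold tests, compensation irradiance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from photoacclim.exceptions import ConfigError, InsufficientDataError, ParameterError
from photoacclim.response_models import (DESIGN_PAR_LEVELS, MQREstimate,
                                         PredictionResult, SmoothSpec,
                                         ci_overlap_regions, convert_par_to_daily,
                                         estimate_mqr, fit_hgam, fit_npp_model,
                                         predict_with_ci, threshold_ttest)

LEVELS = np.array(DESIGN_PAR_LEVELS)


def line_table(slope=0.04, intercept=20.0, reps=9, noise=None, rng=None):
    par = np.repeat(LEVELS, reps)
    y = intercept + slope * par
    if noise and rng is not None:
        y = y + rng.normal(0, noise, par.size)
    return pd.DataFrame({"treatment_par": par, "value": y})


class TestSmoothFitting:
    @pytest.mark.parametrize("lam", [0.0, 1.0, 1e6])
    def test_straight_line_reproduced_at_any_penalty(self, lam):
        """Linear signals live in the penalty null space: exact at every lambda."""
        table = line_table()
        spec = SmoothSpec(criterion="fixed", lambda_smooth=lam)
        fit = fit_hgam(table, spec)
        assert np.max(np.abs(fit.fitted - table["value"])) < 1e-8

    def test_infinite_smoothing_converges_to_ols_line(self, rng):
        table = line_table(noise=2.0, rng=rng)
        # scale the response to order 1 so the comparison is well conditioned
        table["value"] = table["value"] / table["value"].abs().max()
        spec = SmoothSpec(criterion="fixed", lambda_smooth=1e12)
        fit = fit_hgam(table, spec)
        b, a = np.polyfit(table["treatment_par"], table["value"], 1)
        ols_line = a + b * table["treatment_par"]
        assert np.max(np.abs(fit.fitted - ols_line)) < 1e-6

    def test_zero_noise_interpolation_as_penalty_vanishes(self):
        """With k knots = k levels and lambda -> 0, design-level values are exact."""
        truth = lambda p: 30 * (1 - np.exp(-p / 150.0))
        table = pd.DataFrame({"treatment_par": np.repeat(LEVELS, 3),
                              "value": truth(np.repeat(LEVELS, 3))})
        spec = SmoothSpec(criterion="fixed", lambda_smooth=1e-12)
        fit = fit_hgam(table, spec)
        pred = fit.predict(LEVELS)
        assert np.max(np.abs(pred.fit - truth(LEVELS))) < 1e-6

    def test_balanced_random_intercepts_shrink_like_blup(self):
        """Crossed balanced layout: ridge offsets shrink by n/(n + lambda_r)."""
        c = 1.5
        rows = []
        for container, offset in zip("ABC", (c, 0.0, -c)):
            for par in LEVELS:
                rows.append({"treatment_par": par, "container_id": container,
                             "value": 20.0 + 0.04 * par + offset})
        table = pd.DataFrame(rows)
        lam_r = 3.0
        spec = SmoothSpec(criterion="fixed", lambda_smooth=0.0,
                          lambda_random=lam_r, random_terms=("container_id",))
        fit = fit_hgam(table, spec)
        b = fit.coef[fit.term_cols["re(container_id)"]]
        n = LEVELS.size
        expected = np.array([c, 0.0, -c]) * n / (n + lam_r)
        assert np.allclose(b, expected, atol=1e-6)

    def test_grouped_smooths_fit_each_group(self):
        rows = []
        for day, slope in ((5, 0.04), (25, 0.02)):
            for par in np.repeat(LEVELS, 3):
                rows.append({"treatment_par": par, "day": day,
                             "value": 10 + slope * par})
        table = pd.DataFrame(rows)
        spec = SmoothSpec(group_factor="day", criterion="fixed", lambda_smooth=1.0)
        fit = fit_hgam(table, spec)
        p5 = fit.predict(np.array([100.0]), group=5).fit[0]
        p25 = fit.predict(np.array([100.0]), group=25).fit[0]
        assert p5 == pytest.approx(14.0, abs=1e-6)
        assert p25 == pytest.approx(12.0, abs=1e-6)

    def test_group_without_data_errors(self):
        table = line_table()
        table["day"] = 5
        table.loc[table.index[:1], "day"] = 25  # one stray row, one PAR level
        spec = SmoothSpec(group_factor="day")
        with pytest.raises(InsufficientDataError):
            fit_hgam(table, spec)

    def test_basis_reduced_when_few_levels(self):
        table = pd.DataFrame({"treatment_par": np.repeat([10.0, 50.0, 200.0, 600.0], 5),
                              "value": np.tile([1.0, 2.0, 2.5, 2.6], 5)})
        fit = fit_hgam(table, SmoothSpec(basis_dim=7))
        assert fit.knots.size == 4


class TestPrediction:
    def test_prediction_at_design_level_matches_fitted(self):
        table = line_table()
        fit = fit_hgam(table, SmoothSpec(criterion="fixed", lambda_smooth=1.0))
        pred = fit.predict(LEVELS)
        fitted_at_levels = fit.fitted[:LEVELS.size * 9:9]  # first rep of each level
        # ungrouped model without random terms: population prediction == fit
        assert np.allclose(np.repeat(pred.fit, 9), fit.fitted, atol=1e-8)

    def test_ci_width_shrinks_with_noise(self):
        widths = []
        for noise in (2.0, 0.2):
            rng = np.random.default_rng(7)
            table = line_table(noise=noise, rng=rng)
            fit = fit_hgam(table, SmoothSpec())
            pred = fit.predict(np.array([200.0]))
            widths.append(float(pred.upper[0] - pred.lower[0]))
        assert widths[1] < widths[0]

    def test_interval_uses_normal_quantile(self, rng):
        table = line_table(noise=1.0, rng=rng)
        fit = fit_hgam(table, SmoothSpec())
        grid = np.array([100.0, 400.0])
        p95 = fit.predict(grid, level=0.95)
        p68 = fit.predict(grid, level=0.6827)
        ratio = (p95.upper - p95.fit) / (p68.upper - p68.fit)
        assert np.allclose(ratio, stats.norm.ppf(0.975) / stats.norm.ppf(0.84135),
                           rtol=1e-3)

    def test_extrapolation_flagged_not_refused(self):
        fit = fit_hgam(line_table(), SmoothSpec())
        pred = fit.predict(np.array([3.0, 500.0, 1000.0]))
        assert list(pred.extrapolated) == [True, False, True]

    def test_grouped_model_requires_group(self):
        table = line_table()
        table["day"] = 5
        table2 = table.copy()
        table2["day"] = 25
        fit = fit_hgam(pd.concat([table, table2]), SmoothSpec(group_factor="day"))
        with pytest.raises(ConfigError):
            fit.predict(np.array([100.0]))


class TestCIOverlap:
    @staticmethod
    def const_pred(grid, center, halfwidth):
        fit = np.full(grid.size, float(center))
        return PredictionResult(grid, fit, fit - halfwidth, fit + halfwidth,
                                np.zeros(grid.size, bool))

    def test_identical_fits_never_separate(self):
        grid = np.linspace(0, 860, 100)
        a = self.const_pred(grid, 5.0, 1.0)
        assert ci_overlap_regions(a, a) == []

    def test_fully_separated_constants(self):
        grid = np.linspace(0, 860, 100)
        a = self.const_pred(grid, 0.0, 1.0)
        b = self.const_pred(grid, 10.0, 1.0)
        assert ci_overlap_regions(a, b) == [(0.0, 860.0)]

    def test_divergence_onset_located_within_one_grid_step(self):
        grid = np.linspace(0.0, 860.0, 431)  # 2-unit steps
        onset = 355.0
        fit_a = np.zeros(grid.size)
        fit_b = np.where(grid > onset, 0.02 * (grid - onset), 0.0)
        a = PredictionResult(grid, fit_a, fit_a - 1, fit_a + 1,
                             np.zeros(grid.size, bool))
        b = PredictionResult(grid, fit_b, fit_b - 1, fit_b + 1,
                             np.zeros(grid.size, bool))
        regions = ci_overlap_regions(a, b)
        assert len(regions) == 1
        true_onset = onset + 2.0 / 0.02  # where the gap first exceeds both CIs
        assert abs(regions[0][0] - true_onset) <= 2.0 + 1e-9


class TestThresholdTTest:
    def test_equal_samples(self):
        result = threshold_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.t == pytest.approx(0.0, abs=1e-12)
        assert result.p == pytest.approx(1.0)

    def test_matches_scipy_welch(self, rng):
        a, b = rng.normal(0, 1, 9), rng.normal(1, 2, 9)
        result = threshold_ttest(a, b)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
        assert result.t == pytest.approx(float(t_ref))
        assert result.p == pytest.approx(float(p_ref))
        assert 0 <= result.fligner_p <= 1

    def test_requires_three_per_group(self):
        with pytest.raises(InsufficientDataError):
            threshold_ttest([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ParameterError):
            threshold_ttest([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_power_simulation_matches_noncentral_t_oracle(self, rng):
        """Rejection rate at p<0.001 under a 3-SD shift (n=9) matches the
        analytic noncentral-t power (~0.975)."""
        ncp = 3.0 / np.sqrt(2.0 / 9.0)
        crit = stats.t.ppf(1 - 0.0005, 16)
        analytic = float(stats.nct.sf(crit, 16, ncp))
        hits = 0
        n_rep = 600
        for _ in range(n_rep):
            res = threshold_ttest(rng.normal(0, 1, 9), rng.normal(3, 1, 9))
            hits += res.p < 0.001
        assert hits / n_rep == pytest.approx(analytic, abs=0.03)


class TestMQR:
    def test_linear_npp_closed_form_root(self):
        """Fitted NPP = -0.35 + 0.0255 PAR crosses zero at 13.73."""
        par = np.repeat(LEVELS, 6)
        table = pd.DataFrame({"treatment_par": par, "npp": -0.35 + 0.0255 * par})
        fit = fit_npp_model(table, 0.35, spec=SmoothSpec(criterion="fixed",
                                                         lambda_smooth=1.0))
        est = estimate_mqr(fit, 0.35)
        assert est.flag is None
        assert est.mqr == pytest.approx(0.35 / 0.0255, abs=0.02)

    def test_everywhere_positive_flagged(self):
        par = np.repeat(LEVELS, 3)
        table = pd.DataFrame({"treatment_par": par, "npp": 1.0 + 0.001 * par})
        fit = fit_npp_model(table, 0.0, spec=SmoothSpec(criterion="fixed",
                                                        lambda_smooth=1.0))
        # zero anchor keeps the curve non-negative at 0: no crossing
        est = estimate_mqr(fit, 0.0)
        assert est.flag == "no_compensation_point"
        assert np.isnan(est.mqr)

    def test_noiseless_pipeline_round_trip(self, noiseless_experiment):
        """Noiseless generated rates + the truth anchor recover the true
        compensation irradiance of 13.7 to solver tolerance."""
        from photoacclim.metabolism import rates_table
        data, truth = noiseless_experiment
        rates = rates_table(data["incubations"])
        meta = data["rlc_steps"][["shoot_id", "container_id",
                                  "treatment_par"]].drop_duplicates()
        rates = rates.merge(meta, on="shoot_id")
        spec = SmoothSpec(basis_dim=8, random_terms=("container_id",))
        fit = fit_npp_model(rates, 0.35, spec=spec)
        est = estimate_mqr(fit, 0.35)
        assert est.mqr == pytest.approx(13.7, abs=0.02)


class TestDailyDose:
    def test_zero(self):
        assert convert_par_to_daily(0.0) == 0.0

    @pytest.mark.parametrize("par, printed", [(13.7, 0.69), (74.0, 3.7), (200.0, 10.1)])
    def test_printed_conversions(self, par, printed):
        dose = convert_par_to_daily(par, 14.0)
        assert round(dose, 2 if printed < 1 else 1) == printed

    def test_linearity(self):
        assert convert_par_to_daily(100.0, 14.0) == pytest.approx(
            2 * convert_par_to_daily(50.0, 14.0), rel=1e-12)
        assert convert_par_to_daily(100.0, 7.0) == pytest.approx(
            convert_par_to_daily(50.0, 14.0), rel=1e-12)

    def test_validation(self):
        with pytest.raises(ParameterError):
            convert_par_to_daily(-1.0)
        with pytest.raises(ParameterError):
            convert_par_to_daily(10.0, photoperiod_h=30.0)
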