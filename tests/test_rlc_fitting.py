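"""Light-curve construction, photoinhibition-model fitting, and saturation QC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photoacclim.exceptions import InsufficientDataError, ParameterError
from photoacclim.fluorescence import ACTINIC_STEPS, FluorRead
from photoacclim.rlc_fitting import (ETRCurve, RLCTrace, apply_qc, build_etr_curve,
                                     fit_platt, platt_derived, platt_model,
                                     qc_saturation)


def make_trace(pars, yiis, fm=700.0):
    steps = tuple(FluorRead(actinic_par=p, f=fm * (1 - y), fm_prime=fm)
                  for p, y in zip(pars, yiis))
    return RLCTrace("s1", "c1", 74.0, 5, steps)


def noiseless_curve(ps, alpha, beta, pars=ACTINIC_STEPS):
    pars = np.asarray(pars, float)
    return ETRCurve(pars, platt_model(pars, ps, alpha, beta), af_used=0.44)


class TestBuildCurve:
    def test_zero_yield_gives_zero_etr(self):
        trace = make_trace(ACTINIC_STEPS, [0.0] * 10)
        curve = build_etr_curve(trace)
        assert np.all(curve.etr == 0.0)

    def test_constant_yield_arithmetic(self):
        pars = (38.0, 68.0, 100.0, 137.0, 190.0)
        curve = build_etr_curve(make_trace(pars, [0.5] * 5), af=0.44)
        # ETR = 0.5 x E x 0.44 x 0.5; at E = 100 that is 11.0
        assert curve.etr[2] == pytest.approx(11.0, abs=1e-12)

    def test_too_few_valid_steps(self):
        with pytest.raises(InsufficientDataError):
            build_etr_curve(make_trace(ACTINIC_STEPS[:3], [0.5] * 3))

    def test_invalid_steps_dropped(self):
        yiis = [0.6, 0.55, -0.1, 0.5, 0.45, 0.4, 0.35, 0.3, 0.25, 0.2]
        curve = build_etr_curve(make_trace(ACTINIC_STEPS, yiis))
        assert curve.n_dropped == 1
        assert curve.par.size == 9

    def test_unsorted_trace_rejected(self):
        with pytest.raises(ValueError):
            make_trace((100.0, 50.0, 200.0, 300.0, 400.0), [0.5] * 5)


class TestPlattModel:
    def test_zero_irradiance(self):
        assert platt_model(0.0, 50.0, 0.2, 0.05) == 0.0

    def test_saturation_limit_without_photoinhibition(self):
        assert platt_model(1e9, 80.0, 0.2, 0.0) == pytest.approx(80.0, rel=1e-9)

    def test_closed_form_value(self):
        # independent evaluation with math.* scalars
        ps, alpha, beta, e = 80.0, 0.2, 0.01, 400.0
        expected = ps * (1 - math.exp(-alpha * e / ps)) * math.exp(-beta * e / ps)
        assert platt_model(e, ps, alpha, beta) == pytest.approx(expected, abs=1e-12)

    def test_initial_slope(self):
        h = 1e-7
        slope = platt_model(h, 60.0, 0.15, 0.02) / h
        assert slope == pytest.approx(0.15, rel=1e-6)

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            platt_model(10.0, -1.0, 0.2)
        with pytest.raises(ParameterError):
            platt_model(10.0, 50.0, 0.2, -0.01)


class TestPlattDerived:
    def test_beta_zero(self):
        assert platt_derived(60.0, 0.15, 0.0) == pytest.approx((60.0, 400.0))

    def test_continuity_at_beta_zero(self):
        em0, _ = platt_derived(80.0, 0.2, 0.0)
        em1, _ = platt_derived(80.0, 0.2, 1e-9)
        assert em1 == pytest.approx(em0, rel=1e-6)

    def test_against_grid_maximization(self):
        """Closed-form ETRmax matches a dense brute-force maximum to <0.1%."""
        for ps, alpha, beta in [(80.0, 0.2, 0.01), (40.0, 0.1, 0.03), (60.0, 0.3, 0.0)]:
            etr_max, ek = platt_derived(ps, alpha, beta)
            grid = np.linspace(0.0, 20000.0, 400001)
            brute = float(np.max(platt_model(grid, ps, alpha, beta)))
            assert etr_max == pytest.approx(brute, rel=1e-3)
            assert ek * alpha == pytest.approx(etr_max, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(ps=st.floats(1.0, 200.0), alpha=st.floats(0.01, 1.0),
           beta_frac=st.floats(0.0, 1.0))
    def test_ek_identity(self, ps, alpha, beta_frac):
        etr_max, ek = platt_derived(ps, alpha, beta_frac * alpha)
        assert ek * alpha == pytest.approx(etr_max, rel=1e-12)


def grid_best_sse(curve, n_ps=20, n_alpha=20, n_beta=10):
    """Coarse log-spaced grid-search oracle for the least SSE."""
    y_max = curve.etr.max()
    secant = np.max(curve.etr / curve.par)
    best = np.inf
    for ps in np.geomspace(0.1 * y_max, 10 * y_max, n_ps):
        for alpha in np.geomspace(0.01 * secant, 10 * secant, n_alpha):
            for beta in np.concatenate(([0.0], np.geomspace(1e-4, 1, n_beta - 1))) * alpha:
                sse = float(np.sum((platt_model(curve.par, ps, alpha, beta)
                                    - curve.etr) ** 2))
                best = min(best, sse)
    return best


class TestFitPlatt:
    @pytest.mark.parametrize("ps, alpha, beta", [(60.0, 0.15, 0.0), (80.0, 0.2, 0.01)])
    def test_noiseless_recovery(self, ps, alpha, beta):
        fit = fit_platt(noiseless_curve(ps, alpha, beta))
        assert fit.converged
        assert fit.ps == pytest.approx(ps, rel=1e-6)
        assert fit.alpha == pytest.approx(alpha, rel=1e-6)
        assert fit.beta == pytest.approx(beta, rel=1e-4, abs=1e-8)

    def test_sse_beats_grid_oracle(self, rng):
        curves = [noiseless_curve(60.0, 0.15, 0.0)]
        noisy = platt_model(np.array(ACTINIC_STEPS), 50.0, 0.2, 0.02)
        noisy = noisy * (1 + rng.normal(0, 0.05, noisy.size))
        curves.append(ETRCurve(np.array(ACTINIC_STEPS), noisy, af_used=0.44))
        for curve in curves:
            fit = fit_platt(curve)
            assert fit.sse <= grid_best_sse(curve) + 1e-9

    def test_af_rescaling_covariance(self):
        """Scaling ETR by c scales Ps, alpha, ETRmax by c; Ek is unchanged."""
        base = noiseless_curve(60.0, 0.15, 0.01)
        c = 0.4091
        scaled = ETRCurve(base.par, base.etr * c, af_used=0.18)
        f0, f1 = fit_platt(base), fit_platt(scaled)
        assert f1.ps == pytest.approx(c * f0.ps, rel=1e-6)
        assert f1.alpha == pytest.approx(c * f0.alpha, rel=1e-6)
        assert f1.etr_max == pytest.approx(c * f0.etr_max, rel=1e-6)
        assert f1.ek == pytest.approx(f0.ek, rel=1e-6)

    def test_all_zero_curve_not_converged(self):
        curve = ETRCurve(np.array(ACTINIC_STEPS), np.zeros(10), af_used=0.44)
        fit = fit_platt(curve)
        assert not fit.converged

    def test_parameter_recovery_under_noise(self, rng):
        """5% multiplicative noise: ETRmax and alpha recovered within 10% RMSE.

        True ETRmax values span the day-5 range (24.6 to 62.7) of the
        study design the generator emulates.
        """
        rel_err_em, rel_err_a = [], []
        for _ in range(200):
            ps = rng.uniform(24.6, 62.7)
            alpha = rng.uniform(0.1, 0.175)
            truth = platt_model(np.array(ACTINIC_STEPS), ps, alpha, 0.0)
            noisy = truth * (1 + rng.normal(0, 0.05, truth.size))
            fit = fit_platt(ETRCurve(np.array(ACTINIC_STEPS), noisy, af_used=0.44))
            rel_err_em.append(fit.etr_max / ps - 1)
            rel_err_a.append(fit.alpha / alpha - 1)
        assert np.sqrt(np.mean(np.square(rel_err_em))) < 0.10
        assert np.sqrt(np.mean(np.square(rel_err_a))) < 0.10


class TestSaturationQC:
    def test_linear_curve_rejected(self):
        pars = np.array(ACTINIC_STEPS)
        curve = ETRCurve(pars, 0.1 * pars, af_used=0.44)
        fit = fit_platt(curve)
        accepted, reasons = qc_saturation(curve, fit)
        assert not accepted
        assert reasons

    def test_saturating_curve_accepted(self):
        curve = noiseless_curve(50.0, 0.3, 0.0)
        fit = fit_platt(curve)
        assert fit.ek == pytest.approx(50.0 / 0.3, rel=1e-6)
        accepted, reasons = qc_saturation(curve, fit, max_actinic=1246.0)
        assert accepted and not reasons

    def test_ek_threshold_case(self):
        curve = noiseless_curve(50.0, 0.3, 0.0)
        fit = fit_platt(curve)
        doctored = type(fit)(**{**fit.__dict__, "ek": 1300.0})
        accepted, reasons = qc_saturation(curve, doctored, max_actinic=1246.0)
        assert not accepted
        assert "ek_above_max_actinic" in reasons

    def test_apply_qc_records_reason(self):
        pars = np.array(ACTINIC_STEPS)
        curve = ETRCurve(pars, 0.1 * pars, af_used=0.44)
        fit = apply_qc(fit_platt(curve), curve)
        assert fit.rejected
        assert fit.reject_reason
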