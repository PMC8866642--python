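"""Rapid-light-curve construction and photosynthesis-irradiance model fitting.

ETR-versus-irradiance curves built from the fluorescence staircase are fitted
to the double-exponential photoinhibition model of Platt / Ralph & Gademann:

    P(E) = Ps * (1 - exp(-alpha E / Ps)) * exp(-beta E / Ps)

with Ps a scale parameter, alpha the initial slope (photosynthetic
efficiency) and beta >= 0 the photoinhibition parameter.  Derived quantities:

    ETRmax = Ps * [alpha/(alpha+beta)] * [beta/(alpha+beta)]^(beta/alpha)
    Ek     = ETRmax / alpha              (onset of light saturation)

with ETRmax = Ps in the beta -> 0 limit.  Fitting is bounded trust-region
nonlinear least squares with a multi-start initialization; curves that never
saturate within the actinic range are rejected by QC, mirroring the field
practice of discarding rapid light curves with no ETR plateau.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import InsufficientDataError, ParameterError
from .fluorescence import AF_DEFAULT, PSII_FRACTION, FluorRead, quantum_yield

__all__ = [
    "MIN_VALID_STEPS",
    "RLCTrace",
    "ETRCurve",
    "PlattFit",
    "build_etr_curve",
    "platt_model",
    "platt_derived",
    "fit_platt",
    "qc_saturation",
    "apply_qc",
    "fit_rlc_table",
]

logger = logging.getLogger(__name__)

#: Minimum number of valid staircase steps required for a fit.
MIN_VALID_STEPS = 5


@dataclass(frozen=True)
class RLCTrace:
    """One shoot's rapid-light-curve staircase plus design metadata."""

    shoot_id: str
    container_id: str
    treatment_par: float
    day: int
    steps: tuple[FluorRead, ...]

    def __post_init__(self) -> None:
        pars = [s.actinic_par for s in self.steps]
        if any(b <= a for a, b in zip(pars, pars[1:])):
            raise ValueError("RLC steps must have strictly increasing actinic PAR")


@dataclass(frozen=True)
class ETRCurve:
    """ETR-vs-irradiance points derived from one trace."""

    par: np.ndarray
    etr: np.ndarray
    af_used: float
    af_kind: str = "default_044"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "par", np.asarray(self.par, dtype=float))
        object.__setattr__(self, "etr", np.asarray(self.etr, dtype=float))
        if np.any(np.diff(self.par) <= 0):
            raise ValueError("ETR curve irradiances must be strictly increasing")


@dataclass(frozen=True)
class PlattFit:
    """Fitted photoinhibition-model parameters and QC state."""

    ps: float
    alpha: float
    beta: float
    etr_max: float
    ek: float
    sse: float
    converged: bool
    af_kind: str = "default_044"
    n_points: int = 0
    rejected: bool = False
    reject_reason: Optional[str] = None


def build_etr_curve(
    trace: RLCTrace, af: float = AF_DEFAULT, kind: str = "default_044"
) -> ETRCurve:
    """Apply the ETR equation step-by-step to a trace.

    Steps with invalid reads (non-positive Fm') or negative yields are
    dropped and logged; fewer than :data:`MIN_VALID_STEPS` survivors raises
    :class:`InsufficientDataError`.
    """
    if not 0.0 < af <= 1.0:
        raise ParameterError(f"absorption factor must lie in (0, 1], got {af}")
    pars, etrs, dropped = [], [], 0
    for step in trace.steps:
        if not step.is_valid:
            dropped += 1
            continue
        yii = quantum_yield(step.f, step.fm_prime)
        if yii < 0:
            dropped += 1
            continue
        pars.append(step.actinic_par)
        etrs.append(yii * step.actinic_par * af * PSII_FRACTION)
    if dropped:
        logger.info(
            "shoot %s day %s: dropped %d invalid RLC step(s)",
            trace.shoot_id, trace.day, dropped,
        )
    if len(pars) < MIN_VALID_STEPS:
        raise InsufficientDataError(
            f"shoot {trace.shoot_id}: only {len(pars)} valid steps "
            f"(need >= {MIN_VALID_STEPS})"
        )
    return ETRCurve(np.array(pars), np.array(etrs), af_used=af, af_kind=kind,
                    n_dropped=dropped)


def platt_model(e, ps: float, alpha: float, beta: float = 0.0):
    """Evaluate P(E) = Ps (1 - exp(-alpha E/Ps)) exp(-beta E/Ps)."""
    if ps <= 0 or alpha <= 0:
        raise ParameterError("Ps and alpha must be > 0")
    if beta < 0:
        raise ParameterError("beta must be >= 0")
    e = np.asarray(e, dtype=float)
    out = ps * (-np.expm1(-alpha * e / ps)) * np.exp(-beta * e / ps)
    return float(out) if out.ndim == 0 else out


def platt_derived(ps: float, alpha: float, beta: float = 0.0) -> tuple[float, float]:
    """Closed-form (ETRmax, Ek); continuous at beta -> 0 where ETRmax = Ps."""
    if ps <= 0 or alpha <= 0:
        raise ParameterError("Ps and alpha must be > 0")
    if beta < 0:
        raise ParameterError("beta must be >= 0")
    if beta == 0:
        etr_max = ps
    else:
        ab = alpha + beta
        etr_max = ps * (alpha / ab) * (beta / ab) ** (beta / alpha)
    return etr_max, etr_max / alpha


def _initial_alpha(par: np.ndarray, etr: np.ndarray) -> float:
    """OLS slope through the origin of the three lowest-irradiance points."""
    e, y = par[:3], etr[:3]
    denom = float(np.dot(e, e))
    slope = float(np.dot(e, y)) / denom if denom > 0 else 0.0
    return slope


def fit_platt(curve: ETRCurve, relative_weights: bool = False) -> PlattFit:
    """Fit the photoinhibition model to an ETR curve.

    Bounded trust-region least squares on (Ps, alpha, f) with beta = f*alpha
    and f in [0, 1], so the photoinhibition parameter can never exceed the
    initial slope.  Two starts (f0 = 0 and f0 = 0.01) guard against the flat
    beta = 0 boundary.  Optimizer failure from all starts yields a
    non-converged fit, not an exception.
    """
    par, y = curve.par, curve.etr
    if par.size < MIN_VALID_STEPS:
        raise InsufficientDataError(f"need >= {MIN_VALID_STEPS} points, got {par.size}")
    if not (np.all(np.isfinite(par)) and np.all(np.isfinite(y))):
        raise InsufficientDataError("non-finite values in ETR curve")
    y_max = float(np.max(y))
    if y_max <= 0:
        return PlattFit(np.nan, np.nan, 0.0, np.nan, np.nan, float(np.sum(y**2)),
                        converged=False, af_kind=curve.af_kind, n_points=par.size)
    max_secant = float(np.max(y / np.where(par > 0, par, np.inf)))
    alpha0 = min(max(_initial_alpha(par, y), 1e-6), 10.0 * max_secant)
    ps0 = y_max
    weights = 1.0 / np.maximum(np.abs(y), 0.05 * y_max) if relative_weights else None

    def residuals(theta):
        ps, alpha, f = theta
        model = ps * (-np.expm1(-alpha * par / ps)) * np.exp(-f * alpha * par / ps)
        r = model - y
        return r * weights if weights is not None else r

    lower = np.array([1e-8, 1e-8, 0.0])
    upper = np.array([10.0 * y_max, 10.0 * max_secant, 1.0])
    best, best_cost = None, np.inf
    for f0 in (0.0, 0.01):
        x0 = np.clip([ps0, alpha0, f0], lower, upper)
        try:
            res = least_squares(residuals, x0, bounds=(lower, upper), method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if res.cost < best_cost:
            best, best_cost = res, res.cost
    if best is None:
        return PlattFit(np.nan, np.nan, 0.0, np.nan, np.nan, np.nan,
                        converged=False, af_kind=curve.af_kind, n_points=par.size)
    ps, alpha, f = best.x
    beta = f * alpha
    # fits landing on the boundary report no photoinhibition
    if beta < 1e-10 * alpha:
        beta = 0.0
    etr_max, ek = platt_derived(ps, alpha, beta)
    model = platt_model(par, ps, alpha, beta)
    sse = float(np.sum((model - y) ** 2))
    return PlattFit(float(ps), float(alpha), float(beta), float(etr_max), float(ek),
                    sse, converged=bool(best.success), af_kind=curve.af_kind,
                    n_points=par.size)


def qc_saturation(
    curve: ETRCurve, fit: PlattFit, max_actinic: Optional[float] = None
) -> tuple[bool, list[str]]:
    """Decide whether the curve shows saturation of electron transport.

    A curve is rejected (no plateau within the actinic range) when the fitted
    Ek exceeds the highest actinic irradiance, or when the secant slope of
    the last two steps still exceeds 50% of the fitted initial slope.  Both
    sub-rules are reported separately; rejection is data, not an exception.
    """
    if max_actinic is None:
        max_actinic = float(curve.par[-1])
    reasons: list[str] = []
    if not np.isfinite(fit.ek) or fit.ek > max_actinic:
        reasons.append("ek_above_max_actinic")
    tail_slope = (curve.etr[-1] - curve.etr[-2]) / (curve.par[-1] - curve.par[-2])
    if np.isfinite(fit.alpha) and tail_slope > 0.5 * fit.alpha:
        reasons.append("tail_slope_above_half_alpha")
    return (len(reasons) == 0, reasons)


def apply_qc(
    fit: PlattFit, curve: ETRCurve, max_actinic: Optional[float] = None
) -> PlattFit:
    """Return a copy of ``fit`` with the saturation QC verdict recorded."""
    if not fit.converged:
        return replace(fit, rejected=True, reject_reason="not_converged")
    accepted, reasons = qc_saturation(curve, fit, max_actinic)
    if accepted:
        return replace(fit, rejected=False, reject_reason=None)
    return replace(fit, rejected=True, reject_reason="+".join(reasons))


_META_COLS = ["shoot_id", "container_id", "treatment_par", "day"]


def trace_from_rows(rows: pd.DataFrame) -> RLCTrace:
    """Assemble an :class:`RLCTrace` from step-table rows of one shoot-date."""
    rows = rows.sort_values("actinic_par")
    steps = []
    for _, r in rows.iterrows():
        def _opt(col):
            v = r.get(col)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)
        steps.append(FluorRead(
            actinic_par=float(r["actinic_par"]), f=float(r["F"]),
            fm_prime=float(r["Fm_prime"]), fo_prime=_opt("Fo_prime"),
            fm_dark=_opt("Fm_dark"), fo_dark=_opt("Fo_dark"),
        ))
    first = rows.iloc[0]
    return RLCTrace(str(first["shoot_id"]), str(first["container_id"]),
                    float(first["treatment_par"]), int(first["day"]), tuple(steps))


def fit_rlc_table(
    steps: pd.DataFrame, af: float = AF_DEFAULT, kind: str = "default_044",
    qc: bool = True,
) -> pd.DataFrame:
    """Fit every (shoot, day) staircase in a step table.

    Returns one row per trace with the fitted parameters, diagnostics and QC
    verdict; traces with too few valid steps are recorded as rejected with
    reason ``insufficient_data``.
    """
    records = []
    for (shoot, day), rows in steps.groupby(["shoot_id", "day"], sort=True):
        meta = rows.iloc[0]
        base = {
            "shoot_id": str(shoot), "container_id": str(meta["container_id"]),
            "treatment_par": float(meta["treatment_par"]), "day": int(day),
            "af_kind": kind,
        }
        try:
            trace = trace_from_rows(rows)
            curve = build_etr_curve(trace, af=af, kind=kind)
        except InsufficientDataError:
            records.append({**base, "ps": np.nan, "alpha": np.nan, "beta": np.nan,
                            "etr_max": np.nan, "ek": np.nan, "sse": np.nan,
                            "converged": False, "rejected": True,
                            "reject_reason": "insufficient_data"})
            continue
        fit = fit_platt(curve)
        if qc:
            fit = apply_qc(fit, curve)
        records.append({**base, "ps": fit.ps, "alpha": fit.alpha, "beta": fit.beta,
                        "etr_max": fit.etr_max, "ek": fit.ek, "sse": fit.sse,
                        "converged": fit.converged, "rejected": fit.rejected,
                        "reject_reason": fit.reject_reason})
    return pd.DataFrame.from_records(records)
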