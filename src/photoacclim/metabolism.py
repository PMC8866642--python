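"""O2-flux incubation metabolism: NPP, GPP and respiration rates.

Oxygen concentration is regressed on time (OLS with intercept) separately for
the dark and light phases of a sealed-bottle incubation; the slopes
(umol O2 L-1 h-1) convert to surface-standardized rates:

    NPP = slope_light x vol / photosynthetic surface
    GPP = (slope_light - slope_dark) x vol / photosynthetic surface
    R   = slope_dark x vol / total surface

NPP and GPP are standardized to the one-sided green (photosynthetic) leaf
area, respiration to the one-sided total leaf area.  Slopes and R keep their
measured sign (respiration is negative); downstream compensation-irradiance
work uses the magnitude of the mean respiration as its dark anchor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, ParameterError

__all__ = [
    "IncubationSeries",
    "SlopeResult",
    "MetabolicRates",
    "RespirationSummary",
    "o2_slope",
    "rates",
    "mean_respiration",
    "rates_table",
]


@dataclass(frozen=True)
class IncubationSeries:
    """One incubation phase: O2 readings over time in a sealed bottle.

    The protocol takes four readings 20 min apart in a 0.3-L bottle; times
    are hours, O2 in umol L-1, surfaces one-sided cm2.
    """

    shoot_id: str
    phase: str  # "dark" | "light"
    times_h: np.ndarray
    o2_umol_l: np.ndarray
    volume_l: float = 0.3
    ps_surface_cm2: float = 1.0
    total_surface_cm2: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        o2 = np.asarray(self.o2_umol_l, dtype=float)
        if t.shape != o2.shape or t.ndim != 1:
            raise ValueError("times and O2 must be aligned 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.phase not in ("dark", "light"):
            raise ValueError(f"phase must be 'dark' or 'light', got {self.phase!r}")
        if self.volume_l <= 0:
            raise ParameterError("bottle volume must be > 0")
        if not 0 < self.ps_surface_cm2 <= self.total_surface_cm2:
            raise ParameterError(
                "need 0 < photosynthetic surface <= total surface"
            )
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "o2_umol_l", o2)


class SlopeResult(NamedTuple):
    slope: float  # umol O2 L-1 h-1
    se: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class MetabolicRates:
    """Surface-standardized metabolic rates (umol O2 cm-2 h-1, signed)."""

    shoot_id: str
    npp: float
    gpp: float
    r: float
    slope_light: float
    slope_dark: float
    se_light: float
    se_dark: float


class RespirationSummary(NamedTuple):
    mean: float  # signed mean respiration
    se: float
    n: int

    @property
    def magnitude(self) -> float:
        """|mean respiration|, the PAR = 0 anchor for compensation analysis."""
        return abs(self.mean)


def o2_slope(series: IncubationSeries) -> SlopeResult:
    """OLS slope (with intercept) of O2 concentration on time."""
    t, o2 = series.times_h, series.o2_umol_l
    if t.size < 2:
        raise InsufficientDataError("need >= 2 O2 readings for a slope")
    if np.ptp(t) == 0:
        raise ParameterError("zero time variance")
    if t.size == 2:
        slope = (o2[1] - o2[0]) / (t[1] - t[0])
        return SlopeResult(float(slope), float("nan"), 1.0, 2)
    res = stats.linregress(t, o2)
    return SlopeResult(float(res.slope), float(res.stderr),
                       float(res.rvalue**2), int(t.size))


def rates(light: IncubationSeries, dark: IncubationSeries) -> MetabolicRates:
    """Combine the light and dark phases of one shoot into metabolic rates."""
    if light.shoot_id != dark.shoot_id:
        raise ParameterError(
            f"phase shoot ids differ: {light.shoot_id!r} vs {dark.shoot_id!r}"
        )
    if light.phase != "light" or dark.phase != "dark":
        raise ParameterError("series passed in the wrong phase slots")
    if (light.volume_l != dark.volume_l
            or light.ps_surface_cm2 != dark.ps_surface_cm2
            or light.total_surface_cm2 != dark.total_surface_cm2):
        raise ParameterError("light and dark phases must share volume and surfaces")
    s_light = o2_slope(light)
    s_dark = o2_slope(dark)
    vol, ps, total = light.volume_l, light.ps_surface_cm2, light.total_surface_cm2
    npp = s_light.slope * vol / ps
    gpp = (s_light.slope - s_dark.slope) * vol / ps
    r = s_dark.slope * vol / total
    return MetabolicRates(light.shoot_id, npp, gpp, r, s_light.slope, s_dark.slope,
                          s_light.se, s_dark.se)


def mean_respiration(values: Iterable[float]) -> RespirationSummary:
    """Arithmetic mean of signed respiration rates with its standard error.

    The single-rate case reports SE as NaN (undefined) rather than 0.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("no respiration rates supplied")
    mean = float(np.mean(arr))
    se = float(np.std(arr, ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else float("nan")
    return RespirationSummary(mean, se, int(arr.size))


def _series_from_rows(rows: pd.DataFrame, shoot: str, phase: str) -> IncubationSeries:
    rows = rows.sort_values("time_h")
    first = rows.iloc[0]
    return IncubationSeries(
        shoot_id=str(shoot), phase=phase,
        times_h=rows["time_h"].to_numpy(float),
        o2_umol_l=rows["o2_umol_l"].to_numpy(float),
        volume_l=float(first["volume_l"]),
        ps_surface_cm2=float(first["ps_surface_cm2"]),
        total_surface_cm2=float(first["total_surface_cm2"]),
    )


def rates_table(incubations: pd.DataFrame) -> pd.DataFrame:
    """Per-shoot metabolic rates from a long incubation table.

    Expects columns shoot_id, phase, time_h, o2_umol_l, volume_l,
    ps_surface_cm2, total_surface_cm2 with both phases present per shoot.
    """
    records = []
    for shoot, rows in incubations.groupby("shoot_id", sort=True):
        phases = set(rows["phase"])
        if phases != {"dark", "light"}:
            raise InsufficientDataError(
                f"shoot {shoot}: need both phases, got {sorted(phases)}"
            )
        light = _series_from_rows(rows[rows["phase"] == "light"], shoot, "light")
        dark = _series_from_rows(rows[rows["phase"] == "dark"], shoot, "dark")
        m = rates(light, dark)
        records.append({"shoot_id": m.shoot_id, "npp": m.npp, "gpp": m.gpp, "r": m.r,
                        "slope_light": m.slope_light, "slope_dark": m.slope_dark,
                        "se_light": m.se_light, "se_dark": m.se_dark})
    return pd.DataFrame.from_records(records)
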