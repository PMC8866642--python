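"""PAM fluorescence primitives: quantum yields, quenching coefficients, ETR.

The electron transport rate through PSII is estimated from saturation-pulse
fluorometry as

    ETR = YII x PAR x AF x 0.5

where YII = (Fm' - F)/Fm' is the effective quantum yield of PSII under actinic
light (Genty ratio), PAR is the actinic irradiance in umol photons m-2 s-1,
AF is the fraction of incident light absorbed by the leaf (the instrument
default for eelgrass is 0.44), and 0.5 assumes an even split of absorbed
photons between the two photosystems.

Quenching coefficients follow the conventions the Diving-PAM reports:
Stern-Volmer non-photochemical quenching NPQ = (Fm - Fm')/Fm' and the
puddle-model photochemical coefficient qP = (Fm' - F)/(Fm' - Fo').  When Fo'
was not measured it is estimated with the Oxborough-Baker approximation
Fo' = Fo / (Fv/Fm + Fo/Fm') and the result is flagged as estimated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .exceptions import ConfigError, DegenerateReadError, InvalidReadError

__all__ = [
    "AF_DEFAULT",
    "PSII_FRACTION",
    "PAR_BAND_NM",
    "ACTINIC_STEPS",
    "PhotoConstants",
    "FluorRead",
    "FlaggedValue",
    "quantum_yield",
    "etr",
    "npq",
    "qp",
    "estimate_fo_prime",
]

#: Instrument-default leaf absorption factor for eelgrass.
AF_DEFAULT = 0.44
#: Assumed fraction of absorbed photons routed to PSII.
PSII_FRACTION = 0.5
#: Photosynthetically active waveband (nm).
PAR_BAND_NM = (400.0, 700.0)
#: Actinic irradiance staircase of the rapid light curve protocol
#: (umol photons m-2 s-1, 10 steps of 10 s each).
ACTINIC_STEPS = (38.0, 68.0, 98.0, 137.0, 190.0, 288.0, 432.0, 637.0, 954.0, 1246.0)


@dataclass(frozen=True)
class PhotoConstants:
    """Bundle of the fixed photophysical constants used by the ETR equation."""

    af_default: float = AF_DEFAULT
    psii_fraction: float = PSII_FRACTION
    par_range: tuple[float, float] = PAR_BAND_NM
    actinic_steps: tuple[float, ...] = ACTINIC_STEPS

    def __post_init__(self) -> None:
        if not 0.0 < self.af_default < 1.0:
            raise ConfigError(f"af_default must lie in (0, 1), got {self.af_default}")
        if self.psii_fraction != 0.5:
            raise ConfigError("psii_fraction is fixed at 0.5 by the ETR convention")


@dataclass(frozen=True)
class FluorRead:
    """One saturation-pulse fluorescence reading at a given actinic irradiance.

    Parameters
    ----------
    actinic_par : float
        Actinic irradiance during the reading (umol photons m-2 s-1, >= 0).
    f : float
        Steady-state fluorescence under actinic light (instrument units, >= 0).
    fm_prime : float
        Maximal fluorescence during the saturating pulse (> 0).
    fo_prime, fm_dark, fo_dark : float, optional
        Minimal fluorescence under actinic light and the dark-adapted
        maximal/minimal levels, when recorded.
    """

    actinic_par: float
    f: float
    fm_prime: float
    fo_prime: Optional[float] = None
    fm_dark: Optional[float] = None
    fo_dark: Optional[float] = None

    def __post_init__(self) -> None:
        if self.actinic_par < 0:
            raise InvalidReadError(f"actinic_par must be >= 0, got {self.actinic_par}")
        for name in ("f", "fo_prime", "fm_dark", "fo_dark"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise InvalidReadError(f"{name} must be non-negative, got {value}")

    @property
    def is_valid(self) -> bool:
        """True when the reading supports a quantum-yield computation."""
        return np.isfinite(self.f) and np.isfinite(self.fm_prime) and self.fm_prime > 0


class FlaggedValue(NamedTuple):
    """A scalar result carrying a QC flag instead of being silently altered."""

    value: float
    flag: Optional[str] = None


def quantum_yield(f, fm_prime):
    """Effective quantum yield of PSII, YII = (Fm' - F)/Fm'.

    Accepts scalars or arrays.  Negative values (noise with F > Fm') are
    returned as-is so downstream QC can flag or drop them.

    Raises
    ------
    InvalidReadError
        If any Fm' is non-positive.
    """
    f = np.asarray(f, dtype=float)
    fm_prime = np.asarray(fm_prime, dtype=float)
    if np.any(fm_prime <= 0):
        raise InvalidReadError("Fm' must be > 0 to compute a quantum yield")
    out = (fm_prime - f) / fm_prime
    return float(out) if out.ndim == 0 else out


def etr(yii, par, af: float = AF_DEFAULT):
    """Electron transport rate, ETR = YII x PAR x AF x 0.5.

    Units: umol electrons m-2 s-1 for PAR in umol photons m-2 s-1.
    Linear in each argument.
    """
    if not 0.0 < af <= 1.0:
        raise ConfigError(f"absorption factor must lie in (0, 1], got {af}")
    yii = np.asarray(yii, dtype=float)
    par = np.asarray(par, dtype=float)
    if np.any(par < 0):
        raise InvalidReadError("PAR must be non-negative")
    out = yii * par * af * PSII_FRACTION
    return float(out) if out.ndim == 0 else out


def npq(fm_dark: float, fm_prime: float) -> FlaggedValue:
    """Stern-Volmer non-photochemical quenching, NPQ = (Fm - Fm')/Fm'.

    Negative values (Fm' > Fm, measurement noise) are flagged, not clipped.
    """
    if fm_prime <= 0:
        raise InvalidReadError("Fm' must be > 0 to compute NPQ")
    value = (fm_dark - fm_prime) / fm_prime
    return FlaggedValue(value, "negative" if value < 0 else None)


def estimate_fo_prime(fo_dark: float, fm_dark: float, fm_prime: float) -> float:
    """Oxborough-Baker estimate Fo' = Fo / (Fv/Fm + Fo/Fm')."""
    if fm_dark <= 0 or fm_prime <= 0:
        raise InvalidReadError("dark Fm and Fm' must be > 0 to estimate Fo'")
    fv_fm = (fm_dark - fo_dark) / fm_dark
    denom = fv_fm + fo_dark / fm_prime
    if denom <= 0:
        raise DegenerateReadError("Fo' estimate undefined (Fv/Fm + Fo/Fm' <= 0)")
    return fo_dark / denom


def qp(read: FluorRead) -> FlaggedValue:
    """Photochemical quenching coefficient qP = (Fm' - F)/(Fm' - Fo').

    If Fo' is missing it is estimated from the dark-adapted levels
    (Oxborough-Baker) and the result flagged ``fo_prime_estimated``; if the
    dark levels are missing too, the coefficient is reported as missing
    (NaN with flag ``missing_fo_prime``), never guessed.
    """
    if read.fm_prime <= 0:
        raise InvalidReadError("Fm' must be > 0 to compute qP")
    fo_prime = read.fo_prime
    flag = None
    if fo_prime is None:
        if read.fo_dark is None or read.fm_dark is None:
            return FlaggedValue(float("nan"), "missing_fo_prime")
        fo_prime = estimate_fo_prime(read.fo_dark, read.fm_dark, read.fm_prime)
        flag = "fo_prime_estimated"
    if read.fm_prime <= fo_prime:
        raise DegenerateReadError(
            f"qP undefined: Fm' ({read.fm_prime}) must exceed Fo' ({fo_prime})"
        )
    return FlaggedValue((read.fm_prime - read.f) / (read.fm_prime - fo_prime), flag)
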