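"""Seeded synthetic photoacclimation experiments with known ground truth.

The generator emulates the study design this package analyzes: 7 irradiance
treatments (6-860 umol photons m-2 s-1), 3 containers per treatment, 3
shoots per container, rapid light curves on days 5 and 25, and end-of-
experiment pigment extracts, leaf spectra and O2 incubations.  Truth
surfaces interpolate the reported response anchors with monotone
piecewise-cubic (PCHIP) curves:

* ETRmax rises linearly from 24.6 (PAR 6) to 62.7 (PAR 860) umol electrons
  m-2 s-1 (day 5), unchanged on day 25.
* alpha peaks at 0.173 at the 74 level; on day 25 the high-light (>= 355)
  alpha is raised to 0.15, reproducing the observed day-5 -> day-25 increase
  at high light only (Ek falls there as a consequence).
* NPP is anchored at (0, -0.35) - the dark respiration anchor - crosses
  zero at the compensation irradiance 13.7, and plateaus near 1.0 from the
  74 level up.
* Respiration is -0.28 at the low-light levels and -0.55 / -0.54 / -0.53 at
  355 / 503 / 860 (umol O2 cm-2 h-1, signed).
* Chlorophyll a falls from 1.8 to 0.65 mg g-1 FW (an almost three-fold
  spread), while the leaf optics apply a strong package effect: pigment
  optical depth saturates with chlorophyll content, so absorptance barely
  responds to the pigment gradient.

Fluorescence staircases are built by inverting the ETR equation under the
default AF = 0.44 convention (truth parameters are therefore expressed in
that convention); incubation series invert the slope equations.  In the
noiseless limit every analyzer stage recovers the truth exactly, which is
the generator's core contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.optimize import brentq

from .exceptions import ConfigError
from .fluorescence import ACTINIC_STEPS, AF_DEFAULT, PSII_FRACTION
from .rlc_fitting import platt_model

__all__ = [
    "GeneratorConfig",
    "TruthSurfaces",
    "TruthBundle",
    "default_truth_surfaces",
    "simulate_rlc",
    "simulate_spectrum",
    "simulate_incubation",
    "simulate_experiment",
]

TREATMENT_LEVELS = (6.0, 36.0, 74.0, 133.0, 355.0, 503.0, 860.0)

#: Maximum physiologically plausible effective quantum yield.
YII_CEILING = 0.83

_ALPHA_DAY5 = {6: 0.123, 36: 0.150, 74: 0.173, 133: 0.160,
               355: 0.130, 503: 0.120, 860: 0.120}
_ALPHA_DAY25 = {6: 0.123, 36: 0.150, 74: 0.173, 133: 0.160,
                355: 0.150, 503: 0.150, 860: 0.150}
#: Design knots of the NPP truth surface: PAR 0 (the dark anchor) plus the
#: seven treatment levels.  The PAR-6 value is solved so the surface's first
#: zero crossing - the true compensation irradiance - is exactly at
#: :data:`TRUE_COMPENSATION_PAR`.
_NPP_KNOTS = np.array([0.0, 6.0, 36.0, 74.0, 133.0, 355.0, 503.0, 860.0])
_NPP_FIXED = {0.0: -0.35, 36.0: 0.55, 74.0: 1.0, 133.0: 1.0,
              355.0: 0.95, 503.0: 1.0, 860.0: 1.0}
TRUE_COMPENSATION_PAR = 13.7
_R_ANCHORS = [(0.0, -0.28), (133.0, -0.28), (355.0, -0.55),
              (503.0, -0.54), (860.0, -0.53)]
_CHLA_ANCHORS = [(6.0, 1.80), (36.0, 1.75), (74.0, 1.70), (133.0, 1.60),
                 (355.0, 1.00), (503.0, 0.80), (860.0, 0.65)]
_CAR_ANCHORS = [(6.0, 0.45), (133.0, 0.42), (860.0, 0.33)]
_CHLB_FRACTION = 0.35


def _pchip(anchors) -> PchipInterpolator:
    xs, ys = zip(*anchors)
    return PchipInterpolator(np.array(xs), np.array(ys), extrapolate=True)


def _npp_surface() -> CubicSpline:
    """Natural cubic NPP spline crossing zero exactly at 13.7.

    Using the same spline family the response models fit keeps the noiseless
    generator/analyzer round trip coherent; the free value at PAR 6 is
    solved by bisection.
    """
    def spline_with(v6: float) -> CubicSpline:
        values = [_NPP_FIXED.get(k, v6) for k in _NPP_KNOTS]
        return CubicSpline(_NPP_KNOTS, values, bc_type="natural")

    v6 = brentq(lambda v: float(spline_with(v)(TRUE_COMPENSATION_PAR)),
                -0.34, 0.40, xtol=1e-12)
    return spline_with(v6)


@dataclass(frozen=True)
class TruthSurfaces:
    """Callable treatment-PAR response surfaces defining the ground truth."""

    alpha_day5: Callable
    alpha_day25: Callable
    etr_max: Callable
    npp: Callable
    r: Callable
    chla: Callable
    carotenoids: Callable
    total_to_ps_surface: float = 1.25

    def alpha(self, par, day: int):
        return self.alpha_day5(par) if day == 5 else self.alpha_day25(par)

    def ek(self, par, day: int):
        return self.etr_max(par) / self.alpha(par, day)

    def chlb(self, par):
        return _CHLB_FRACTION * self.chla(par)

    def gpp(self, par):
        """GPP implied by the npp and r surfaces through the rate identities."""
        return self.npp(par) - self.r(par) * self.total_to_ps_surface


def default_truth_surfaces() -> TruthSurfaces:
    """Truth surfaces interpolating the study's reported response anchors."""
    etr_slope = (62.7 - 24.6) / (860.0 - 6.0)
    return TruthSurfaces(
        alpha_day5=_pchip(sorted(_ALPHA_DAY5.items())),
        alpha_day25=_pchip(sorted(_ALPHA_DAY25.items())),
        etr_max=lambda par: 24.6 + etr_slope * (np.asarray(par, float) - 6.0),
        npp=_npp_surface(),
        r=_pchip(_R_ANCHORS),
        chla=_pchip(_CHLA_ANCHORS),
        carotenoids=_pchip(_CAR_ANCHORS),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Design layout, noise model and random-effect settings for one run.

    Noise defaults: 5% multiplicative Gaussian noise on quantum yields, 5%
    lognormal scatter on the Fm' baseline, 0.8 umol L-1 Gaussian noise on O2
    readings (about 2% of a typical light-phase range), 10% relative noise
    on pigment contents, and 12% / 3% relative noise on the photosynthetic /
    NIR optical depths of the leaf spectra.  Container and shoot random
    effects are multiplicative on ETRmax and additive on the metabolic
    rates.  All randomness flows from ``seed``.
    """

    treatment_levels: tuple = TREATMENT_LEVELS
    containers_per_treatment: int = 3
    shoots_per_container: int = 3
    days: tuple = (5, 25)
    rlc_steps: tuple = ACTINIC_STEPS
    af_convention: float = AF_DEFAULT
    fm_baseline: float = 600.0
    fm_lognorm_sd: float = 0.05
    yield_noise_sd: float = 0.05
    o2_noise_sd: float = 0.8
    o2_baseline: float = 250.0
    incubation_volume_l: float = 0.3
    ps_surface_mean_cm2: float = 12.0
    ps_surface_sd_cm2: float = 1.5
    pigment_noise_rel: float = 0.10
    package_strength: float = 6.0
    baseline_a750: float = 0.37
    af_photo_target: float = 0.18
    spectrum_photo_noise_rel: float = 0.12
    spectrum_nir_noise_rel: float = 0.03
    wavelength_step_nm: float = 1.0
    container_sd_rel: float = 0.05
    shoot_sd_rel: float = 0.07
    metabolic_re_sd: float = 0.06
    alpha_noise_rel: float = 0.03
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.package_strength <= 0:
            raise ConfigError("package_strength must be > 0")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class TruthBundle:
    """Per-shoot ground truth emitted alongside every synthetic dataset."""

    config: GeneratorConfig
    shoots: pd.DataFrame

    def to_json(self) -> str:
        payload = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
            "shoots": self.shoots.to_dict(orient="list"),
        }
        import json

        return json.dumps(payload, indent=1, sort_keys=True)


def simulate_rlc(
    ps: float, alpha: float, beta: float, af: float, steps,
    noise_sd: float, rng: np.random.Generator,
    fm_baseline: float = 600.0, fm_lognorm_sd: float = 0.05,
) -> pd.DataFrame:
    """Fluorescence staircase realizing a known light-response curve.

    YII(E) = P(E) / (E x AF x 0.5) is inverted into (F, Fm') pairs:
    Fm' = baseline x lognormal scatter, F = Fm' (1 - YII (1 + eps)).  The
    noiseless path reproduces the true ETR exactly through the analyzer.
    """
    steps = np.asarray(steps, dtype=float)
    yii = platt_model(steps, ps, alpha, beta) / (steps * af * PSII_FRACTION)
    if np.any(yii > YII_CEILING):
        raise ConfigError(
            f"true YII exceeds the physiological ceiling {YII_CEILING} "
            f"(max {float(np.max(yii)):.3f}); lower alpha or raise AF"
        )
    fm_prime = fm_baseline * np.exp(rng.normal(0.0, fm_lognorm_sd, steps.size))
    yii_obs = yii * (1.0 + rng.normal(0.0, noise_sd, steps.size)) if noise_sd > 0 else yii
    f = fm_prime * np.clip(1.0 - yii_obs, 1e-6, None)
    return pd.DataFrame({
        "step_index": np.arange(1, steps.size + 1),
        "actinic_par": steps, "F": f, "Fm_prime": fm_prime,
    })


_BAND_CENTERS = ((435.0, 25.0, 1.0), (675.0, 12.0, 0.9),
                 (470.0, 20.0, 0.55), (650.0, 15.0, 0.45))


def _pigment_shape(wavelengths: np.ndarray) -> np.ndarray:
    """Fixed in-vivo pigment absorption shape, band-mean 1, ~0 in the NIR."""
    wl = np.asarray(wavelengths, dtype=float)
    shape = np.full(wl.shape, 0.35)
    for center, width, weight in _BAND_CENTERS:
        shape = shape + weight * np.exp(-0.5 * ((wl - center) / width) ** 2)
    # taper to zero above the photosynthetic band
    taper = np.clip((725.0 - wl) / 35.0, 0.0, 1.0)
    shape = shape * np.where(wl > 690.0, taper, 1.0)
    band = (wl >= 400.0) & (wl <= 700.0)
    return shape / np.mean(shape[band])


def _solve_dmax(wavelengths, shape, d750, af_photo_target) -> float:
    """Photosynthetic optical-depth scale hitting the AF_photo target."""
    band = (wavelengths >= 400.0) & (wavelengths <= 700.0)
    trans_nir = 10.0 ** (-d750)

    def gap(dmax):
        ap = trans_nir * (1.0 - 10.0 ** (-dmax * shape[band]))
        return float(np.mean(ap)) - af_photo_target

    return brentq(gap, 1e-4, 10.0, xtol=1e-10)


def simulate_spectrum(
    chla: float, config: GeneratorConfig, rng: Optional[np.random.Generator] = None,
    noiseless: bool = False,
) -> pd.DataFrame:
    """Leaf absorbance spectrum with a saturating (package-effect) pigment term.

    Optical depth D(lambda) = d750 + dmax x sat(chla) x S(lambda), with
    sat(c) = 1 - exp(-package_strength x c): pigment content raises optical
    depth only up to saturation, so a three-fold chlorophyll spread moves
    the realized AF_photo by only a few percent - the package effect.
    """
    wl = np.arange(400.0, 750.0 + config.wavelength_step_nm,
                   config.wavelength_step_nm)
    shape = _pigment_shape(wl)
    d750 = -np.log10(1.0 - config.baseline_a750)
    dmax = _solve_dmax(wl, shape, d750, config.af_photo_target)
    sat = 1.0 - np.exp(-config.package_strength * chla)
    if noiseless or rng is None:
        photo_scale, nir_scale = 1.0, 1.0
    else:
        photo_scale = 1.0 + rng.normal(0.0, config.spectrum_photo_noise_rel)
        nir_scale = 1.0 + rng.normal(0.0, config.spectrum_nir_noise_rel)
    d = d750 * max(nir_scale, 0.05) + dmax * sat * max(photo_scale, 0.05) * shape
    return pd.DataFrame({"wavelength_nm": wl, "absorbance": d})


def simulate_incubation(
    npp: float, r: float, ps_surface: float, total_surface: float,
    volume_l: float, o2_baseline: float, noise_sd: float,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Four-point dark and light O2 series realizing known NPP and R.

    slope_light = NPP x ps_surface / vol and slope_dark = R x total_surface
    / vol; readings 20 min apart; noiseless series round-trip exactly
    through the rate equations.
    """
    times = np.array([0.0, 1.0, 2.0, 3.0]) / 3.0
    slope_light = npp * ps_surface / volume_l
    slope_dark = r * total_surface / volume_l
    frames = []
    for phase, slope in (("dark", slope_dark), ("light", slope_light)):
        o2 = o2_baseline + slope * times
        if noise_sd > 0 and rng is not None:
            o2 = o2 + rng.normal(0.0, noise_sd, times.size)
        frames.append(pd.DataFrame({
            "phase": phase, "time_h": times, "o2_umol_l": o2,
            "volume_l": volume_l, "ps_surface_cm2": ps_surface,
            "total_surface_cm2": total_surface,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_experiment(
    config: Optional[GeneratorConfig] = None,
    surfaces: Optional[TruthSurfaces] = None,
    noiseless: bool = False,
) -> tuple[dict, TruthBundle]:
    """Generate the full experiment: all four data streams plus ground truth.

    Returns ``(datasets, truth)`` where datasets maps stream names
    (``rlc_steps``, ``pigments``, ``spectra``, ``incubations``) to tidy
    DataFrames in the canonical schemas.  Container and shoot random
    intercepts are drawn once and shared across streams.  With ``noiseless``
    every noise and random-effect term is forced to zero.
    """
    config = config or GeneratorConfig()
    truth_surfaces = surfaces or default_truth_surfaces()
    root = np.random.SeedSequence(config.seed)
    rng_design, rng_rlc, rng_pig, rng_spec, rng_inc = (
        np.random.default_rng(s) for s in root.spawn(5)
    )

    rlc_rows, pigment_rows, spectra_rows, incubation_rows, truth_rows = [], [], [], [], []
    for par in config.treatment_levels:
        for c in range(config.containers_per_treatment):
            container_id = f"T{int(par)}_C{c + 1}"
            c_eff = 0.0 if noiseless else rng_design.normal(0.0, config.container_sd_rel)
            c_met = 0.0 if noiseless else rng_design.normal(0.0, config.metabolic_re_sd)
            for s in range(config.shoots_per_container):
                shoot_id = f"{container_id}_S{s + 1}"
                s_eff = 0.0 if noiseless else rng_design.normal(0.0, config.shoot_sd_rel)
                s_met = 0.0 if noiseless else rng_design.normal(0.0, config.metabolic_re_sd)

                ps_surface = float(np.clip(
                    config.ps_surface_mean_cm2
                    + (0.0 if noiseless else rng_design.normal(0.0, config.ps_surface_sd_cm2)),
                    6.0, 20.0))
                total_surface = ps_surface * (
                    truth_surfaces.total_to_ps_surface if noiseless
                    else float(rng_design.uniform(1.15, 1.35)))

                etr_scale = max(1.0 + c_eff + s_eff, 0.3)
                shoot_truth = {"shoot_id": shoot_id, "container_id": container_id,
                               "treatment_par": par,
                               "ps_surface_cm2": ps_surface,
                               "total_surface_cm2": total_surface}

                # --- rapid light curves, both measurement days ---
                for day in config.days:
                    alpha = float(truth_surfaces.alpha(par, day))
                    if not noiseless:
                        alpha *= 1.0 + rng_design.normal(0.0, config.alpha_noise_rel)
                    # keep YII under its physiological ceiling
                    alpha = float(np.clip(alpha, 0.02, 0.180))
                    etr_max = float(truth_surfaces.etr_max(par)) * etr_scale
                    shoot_truth[f"alpha_day{day}"] = alpha
                    shoot_truth[f"etr_max_day{day}"] = etr_max
                    shoot_truth[f"ek_day{day}"] = etr_max / alpha
                    if not noiseless and rng_design.uniform() < config.dropout_rate:
                        continue
                    trace = simulate_rlc(
                        ps=etr_max, alpha=alpha, beta=0.0,
                        af=config.af_convention, steps=config.rlc_steps,
                        noise_sd=0.0 if noiseless else config.yield_noise_sd,
                        rng=rng_rlc, fm_baseline=config.fm_baseline,
                        fm_lognorm_sd=0.0 if noiseless else config.fm_lognorm_sd,
                    )
                    trace.insert(0, "shoot_id", shoot_id)
                    trace.insert(1, "container_id", container_id)
                    trace.insert(2, "treatment_par", par)
                    trace.insert(3, "day", day)
                    rlc_rows.append(trace)

                # --- pigments (end of experiment) ---
                chla = float(truth_surfaces.chla(par))
                chlb = float(truth_surfaces.chlb(par))
                car = float(truth_surfaces.carotenoids(par))
                if not noiseless:
                    jitter = 1.0 + rng_pig.normal(0.0, config.pigment_noise_rel)
                    chla, chlb, car = (max(v * jitter, 0.01) for v in (chla, chlb, car))
                shoot_truth.update(chla=chla, chlb=chlb, carotenoids=car)
                fresh_weight = 0.1
                volume = 10.0
                # invert the extract equations: contents -> absorbances
                chla_ugml = chla * 1000.0 * fresh_weight / volume
                chlb_ugml = chlb * 1000.0 * fresh_weight / volume
                car_ugml = car * 1000.0 * fresh_weight / volume
                a662 = (chla_ugml * 20.13 + chlb_ugml * 2.04) / (11.24 * 20.13 - 2.04 * 4.19)
                a645 = (chlb_ugml + 4.19 * a662) / 20.13
                a470 = (214.0 * car_ugml + 1.90 * chla_ugml + 63.14 * chlb_ugml) / 1000.0
                pigment_rows.append({"shoot_id": shoot_id, "a470": a470, "a645": a645,
                                     "a662": a662, "extract_volume_ml": volume,
                                     "fresh_weight_g": fresh_weight})

                # --- leaf spectrum ---
                spectrum = simulate_spectrum(chla, config,
                                             rng=None if noiseless else rng_spec,
                                             noiseless=noiseless)
                spectrum.insert(0, "shoot_id", shoot_id)
                spectra_rows.append(spectrum)

                # --- O2 incubation ---
                npp = float(truth_surfaces.npp(par)) + (0.0 if noiseless else c_met + s_met)
                r = float(truth_surfaces.r(par)) + (
                    0.0 if noiseless else rng_design.normal(0.0, 0.04))
                shoot_truth.update(npp=npp, r=r,
                                   gpp=npp - r * total_surface / ps_surface)
                inc = simulate_incubation(
                    npp=npp, r=r, ps_surface=ps_surface,
                    total_surface=total_surface,
                    volume_l=config.incubation_volume_l,
                    o2_baseline=config.o2_baseline,
                    noise_sd=0.0 if noiseless else config.o2_noise_sd,
                    rng=rng_inc,
                )
                inc.insert(0, "shoot_id", shoot_id)
                incubation_rows.append(inc)

                truth_rows.append(shoot_truth)

    datasets = {
        "rlc_steps": pd.concat(rlc_rows, ignore_index=True),
        "pigments": pd.DataFrame(pigment_rows),
        "spectra": pd.concat(spectra_rows, ignore_index=True),
        "incubations": pd.concat(incubation_rows, ignore_index=True),
    }
    truth = TruthBundle(config=config, shoots=pd.DataFrame(truth_rows))
    return datasets, truth
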