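# photoacclim

Analysis pipeline for seagrass (eelgrass, *Zostera marina*) photoacclimation
experiments: from raw PAM-fluorometry rapid light curves, pigment-extract
absorbances, leaf spectra and sealed-bottle O2 incubations to photosynthetic
parameters, absorption-corrected electron transport rates, metabolic rates,
hierarchical irradiance-response curves, light thresholds and the
compensation irradiance (minimum quantum requirement, MQR). A seeded
synthetic-experiment generator with known ground truth makes every stage
testable without laboratory data.

Intended users: plant ecophysiologists and seagrass ecologists analysing
light-gradient acclimation experiments (7 irradiance treatments from 6 to
860 umol photons m-2 s-1, shoots nested in containers, two measurement
dates), and anyone who needs a reproducible, QC-audited path from raw
fluorescence staircases to light-requirement estimates.

## The models

**Electron transport.** Each rapid-light-curve step gives the effective
PSII quantum yield YII = (Fm' − F)/Fm' and

ETR = YII × PAR × AF × 0.5  [umol electrons m-2 s-1]

with AF the leaf absorption factor (instrument default 0.44 for eelgrass)
and 0.5 the assumed PSII share of absorbed photons. ETR-vs-E curves are
fitted to the double-exponential photoinhibition model (Platt / Ralph &
Gademann)

P(E) = Ps (1 − e^(−αE/Ps)) e^(−βE/Ps)

by bounded trust-region least squares, giving the initial slope α
(photosynthetic efficiency), ETRmax = Ps [α/(α+β)] [β/(α+β)]^(β/α)
(capacity; ETRmax = Ps when β = 0) and the saturation onset Ek = ETRmax/α.
Curves with no saturation inside the actinic range are rejected by QC.

**Leaf optics.** Spectral absorbance D(λ) converts to absorptance
A = 1 − 10^(−D); subtracting the near-infrared absorptance A750 isolates
the photosynthetic component. Band means over 400–700 nm give AF_total and
AF_photo, and the ETR fits are re-expressed under the measured AF (Ek is
invariant; Ps, α, ETRmax scale by the AF ratio).

**Pigments.** Chl a, chl b and total carotenoids from 470/645/662 nm
extract absorbances (Lichtenthaler coefficients, 100% acetone), in
mg pigment g-1 fresh weight.

**Metabolism.** OLS slopes of O2 on time in dark and light incubation
phases give NPP = α_light·vol/PS-surface, GPP = (α_light − α_dark)·vol/
PS-surface and R = α_dark·vol/total surface.

**Irradiance-response models.** Responses are modeled as penalized natural
cubic regression splines of treatment PAR (basis dimension ≤ 7, knots at
quantiles of the design levels) with date- or method-specific smooths and
ridge-penalized random intercepts for container and shoot, smoothing
selected by GCV. The NPP smooth, anchored at (PAR = 0, −|mean R|), yields
the MQR as its first zero crossing; instantaneous PAR converts to daily
dose as PAR × 3600 × photoperiod × 1e-6 mol m-2 d-1 (14 h photoperiod).

## Worked example

Simulate a full experiment and run every stage:

```bash
photoacclim run-all --seed 1 --outdir demo_run
```

prints

```
MQR = 11.42 umol photons m-2 s-1; daily dose 0.576 mol m-2 d-1
```

and writes `fits_default.csv` (per-shoot Ps, α, β, ETRmax, Ek with QC
flags), `fits_af_photo.csv` (the same fits under each shoot's measured
photosynthetic absorptance), `absorptance.csv`, `pigments_out.csv`,
`rates.csv` (NPP/GPP/R), `model_summaries.csv` (per-term statistics,
adjusted R² and deviance explained of the smooths) and `manifest.json`
(seed, config hash, package version — enough to reproduce the run
bit-for-bit).

The MQR printed above is the irradiance at which the fitted net-production
curve crosses zero: below ~11–14 umol photons m-2 s-1 (about 0.6–0.7 mol
m-2 d-1 over a 14-h day) an acclimated shoot respires more O2 than it
produces. The generator's true compensation irradiance is 13.7; a single
noisy experiment recovers it to within roughly ±15%, with the mild downward
pull coming from anchoring at the measured grand-mean respiration of the
balanced design (≈0.39 umol O2 cm-2 h-1) rather than the surface's 0.35
dark anchor.

Stages are also exposed individually (`simulate`, `fit-rlc`, `pigments`,
`absorptance`, `metabolism`, `respond`, `mqr`) and as plain library calls
(`photoacclim.rlc_fitting.fit_rlc_table`, `photoacclim.response_models.
fit_hgam`, ...).

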