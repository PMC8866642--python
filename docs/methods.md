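# Methods

This note documents the models, numerical choices and design decisions
behind `photoacclim`, and what the synthetic-data tests do and do not
demonstrate about real measurements.

## Fluorescence primitives

Effective quantum yield is the Genty ratio YII = (Fm' − F)/Fm'; electron
transport is ETR = YII × PAR × AF × 0.5 with the 0.5 factor assuming an
even photon split between photosystems. Negative yields and quenching
values produced by instrument noise are **flagged, never clipped or
silently dropped at this level** — the curve builder performs the drop and
logs it, so QC decisions are auditable downstream.

The quenching conventions are the ones Diving-PAM-class instruments
report: Stern–Volmer NPQ = (Fm − Fm')/Fm' and puddle-model
qP = (Fm' − F)/(Fm' − Fo'). When Fo' was not measured it is estimated by
the Oxborough–Baker relation Fo' = Fo/(Fv/Fm + Fo/Fm') and flagged
`fo_prime_estimated`; with no dark-adapted values at all, qP is reported
missing rather than guessed. The protocol shades the leaf only briefly
before a rapid light curve, so the first staircase step is quasi-dark at
best; the package does **not** treat its Fm' as a dark-adapted Fm.

## Light-curve fitting

The photoinhibition model P(E) = Ps(1 − e^(−αE/Ps))e^(−βE/Ps) is fitted by
bounded trust-region least squares (`scipy.optimize.least_squares`, `trf`)
on (Ps, α, f) with β = f·α and f ∈ [0, 1], which realizes the bound
β ≤ α as a box constraint. Initialization: α0 is the through-origin OLS
slope of the three lowest-irradiance points, Ps0 the maximum observed ETR,
with two starts f0 ∈ {0, 0.01} to probe the β = 0 boundary. Bounds:
Ps ∈ (0, 10·max ETR], α ∈ (0, 10·max secant slope]. Fits landing on the
β boundary report β = 0 (no photoinhibition). SSE is unweighted by
default (relative weighting is an option). Optimizer failure yields a
non-converged flagged fit, not an exception.

Derived quantities use the closed forms ETRmax =
Ps[α/(α+β)][β/(α+β)]^(β/α) (continuous at β → 0 where ETRmax = Ps) and
Ek = ETRmax/α; tests cross-check them against brute-force maximization and
a coarse grid-search SSE oracle.

**Saturation QC.** A curve is rejected as "no saturation" when the fitted
Ek exceeds the highest actinic irradiance **or** the last-two-step secant
slope exceeds 50% of the fitted α. The intent (discard curves that never
plateau) is standard practice; the quantitative rule is this package's
own, so both sub-rules are logged separately and rejection is recorded as
data, never raised. Ten-second steps mean the curves are non-steady-state
"rapid" curves; no steady-state correction is applied.

## Leaf optics

A = 1 − 10^(−D) pointwise; AP = A − A750 clipped at 0 with the clip count
reported (unclipped AP can be negative where A < A750; clipping keeps
AF_photo physical and the counter makes the deviation visible). A750 is
read at the grid point nearest 750 nm — deliberately literal rather than a
fitted NIR plateau. Band means over 400–700 nm use a 1-nm linear
interpolation grid; a bandwidth-weighted trapezoid alternative agrees to
<0.5% on smooth spectra and is available by option. ETR re-correction
defaults to rescale-then-refit so noisy data follow the same path as the
original fits; the exact linear covariance (Ps, α, β, ETRmax scale by the
AF ratio, Ek invariant) is used when only fitted parameters are available,
and both paths agree to machine precision on noiseless data.

## Pigments

Lichtenthaler-type coefficients for 100% acetone (the extraction solvent):
chla = 11.24·A662 − 2.04·A645, chlb = 20.13·A645 − 4.19·A662,
carotenoids = (1000·A470 − 1.90·chla − 63.14·chlb)/214 (ug mL-1), then
× volume/fresh weight into mg g-1 FW. The coefficients sit in one
solvent-keyed table so another set can be swapped in. Path length is fixed
at 1 cm; no turbidity (A750) correction is applied to extracts by default.
Negative intermediate concentrations are QC failures reported as missing.

## Metabolism

O2 slopes are OLS **with intercept** — the first reading of a bottle is
not a defined zero. NPP and GPP standardize to one-sided green
(photosynthetic) leaf area, respiration to one-sided total area; no
doubling of surfaces. Slopes and R keep their measured sign (respiration
negative); the compensation analysis uses |mean R| as its dark anchor.
The identity GPP − NPP = −slope_dark·vol/PS-surface holds algebraically on
every record and is asserted in tests.

## Hierarchical irradiance-response smooths

The smoother is a natural cubic regression spline parametrized by its
values at k ≤ 7 knots placed at quantiles of the unique PAR levels, with
the integrated-squared-second-derivative penalty (the banded B/D
construction; penalty null space = straight lines for any knot layout).
Group-specific smooths (by measurement day, or by absorption-factor
method) are separate basis blocks sharing one smoothing parameter; random
intercepts for container and shoot are ridge-penalized dummy blocks.
Smoothing parameters are selected by GCV over a log-spaced grid (fixed
penalties are available, used heavily by the tests); the penalty matrix is
Frobenius-normalized so the grid is scale-free. Confidence bands are
pointwise Gaussian intervals from the penalized ("Bayesian") coefficient
covariance σ²(XᵀX + S_λ)⁻¹, with random effects set to zero for
population-level prediction; whether such bands are pointwise or
simultaneous was an open choice and **pointwise** was adopted. The basis
was verified against an independent GAM implementation: an unpenalized fit
on identical knots is plain least squares on the same function space, and
fitted values agree to ~1e-14.

Treatment PAR enters as a continuous covariate; an optional log1p(PAR)
transform acknowledges the near-geometric spacing of the design levels but
is off by default. Summary tables label smooth-term Wald statistics as
F-type and random/parametric terms separately, without claiming
equivalence to any particular reference implementation's statistics.

Threshold confirmation uses Welch's t-test (the pooled variant is an
option), with Shapiro normality and Fligner homoscedasticity p-values
attached as assumption flags that never auto-switch the test. A power
note: at a 3-pooled-SD shift with n = 9 per group, the analytic
noncentral-t power is ≈0.975 at the 0.001 level and ≈0.9999 at the 0.05
level; the simulation tests assert exactly these oracle values.

**Compensation irradiance (MQR).** The NPP smooth includes the dark
anchor (PAR = 0, NPP = −|mean R|) as a data row with no random-effect
membership. The MQR is the smallest root of the population-level fitted
curve on [0, PAR at fitted NPP maximum], found by Brent bisection to an
absolute tolerance of 0.01 umol photons m-2 s-1 (bracket and tolerance
are this package's choices). A curve with no sign change returns a
flagged no-compensation-point result. Daily dose conversion is
PAR × 3600 × photoperiod × 1e-6 with the 14-h experimental photoperiod.

## Synthetic experiments

The generator reproduces the study design: 7 treatments (6, 36, 74, 133,
355, 503, 860 umol photons m-2 s-1) × 3 containers × 3 shoots, rapid
light curves on days 5 and 25 over the 10-step staircase (38…1246), and
end-of-experiment pigments, spectra and incubations — 63 shoots, 126
traces, 63 of each physiological stream.

Truth surfaces interpolate the reported response anchors: ETRmax linear
24.6 → 62.7 over the PAR range; α peaking at 0.173 at the 74 level (day
25 raises high-light α to 0.15, which lowers Ek there — only the ≥355
treatments change between dates); chl a falling 1.8 → 0.65 mg g-1 FW
(≈2.8-fold); R at −0.28 (low light) and −0.55/−0.54/−0.53 (high light).
Most surfaces are monotone PCHIP interpolants; the NPP surface is instead
a **natural cubic spline on the design knots** (PAR 0 dark anchor −0.35
plus the 7 levels, plateau ≈1.0 from 74 up) with its free PAR-6 value
solved so the first zero crossing — the true compensation irradiance — is
exactly 13.7. Using the same spline family as the analysis models makes
the noiseless generator → analyzer round trip exact for the MQR as well
as for every per-shoot quantity. GPP truth is derived from the NPP and R
surfaces through the rate identities (the independently reported GPP
range 0.56–2.04 is an emulation target, not a separate surface, because a
separate interpolant would contradict the identities). Note one
consequence of respecting the printed treatment means: the balanced-design
grand-mean respiration is ≈0.39, while the unbalanced in-study mean was
0.35; the pipeline anchors at the measured value, giving the recovered
MQR a mild (~−7% median) downward pull that is documented, not corrected.

Fluorescence staircases invert the ETR equation under the AF = 0.44
convention (truth Platt parameters are expressed in that convention):
YII(E) = P(E)/(E·AF·0.5), Fm' = 600 × lognormal(σ = 0.05) scatter,
F = Fm'(1 − YII(1 + ε)) with ε Gaussian (σ = 0.05). Per-shoot α draws are
clipped at 0.180 so YII can never exceed the 0.83 physiological ceiling
the generator enforces. Incubations are 4 points 20 min apart in a 0.3-L
bottle with Gaussian O2 noise (σ = 0.8 umol L-1, ≈2% of a typical
light-phase range); surfaces ~N(12, 1.5²) cm² one-sided with a total/green
ratio of 1.15–1.35.

**Leaf optics and the package effect.** Spectral optical depth is
D(λ) = d750 + dmax · sat(chla) · S(λ) with a fixed pigment band shape
S(λ) (band-mean 1, tapered to zero in the NIR), d750 set from a baseline
non-photosynthetic absorptance of 0.37, and the saturating self-shading
term sat(c) = 1 − e^(−6c). dmax is solved once so the saturated AF_photo
hits 0.18; AF_total then lands near 0.55. Because sat() is nearly flat
over the realized chlorophyll range, a ~3-fold pigment spread moves
AF_photo by only a few percent and the shoot-level correlation between
chl a and AF_photo is dominated by optical noise — the package effect the
study observed. Container and shoot random intercepts are drawn once and
shared across data streams; every random draw descends from a single seed
through spawned generators, so equal seeds give byte-identical CSVs.

## What the synthetic tests show — and what they do not

Passing tests demonstrate that the estimators are unbiased and tight
under the generator's assumptions (Gaussian/lognormal noise, exactly
balanced design, truth surfaces in the fitted function family, no
instrument drift, no epiphyte or handling artifacts, uniform random
dropout only if configured). They do not demonstrate robustness to
heteroscedastic fluorescence noise, O2 micro-bubble outliers, systematic
absorptance geometry errors, or real biological shoot-by-treatment
interactions. Recovery figures at default noise (relative RMSE ≈5% for α
and ETRmax, ≈8% for Ek; median MQR within ~7% with ±15% run-to-run
spread) are properties of these study conditions, not guarantees for
field data.

## Problem sizes and determinism

Default analyses operate on one 63-shoot experiment (126 light-curve fits,
~100-coefficient penalized solves on ≤130 observations); the recovery
study in the test suite uses 50 seeded replicate experiments. Every
stochastic routine takes an explicit seed or generator; stage-level
sub-seeds are spawned deterministically from the run seed.

## Known limitations

* One smooth family (Gaussian response, single covariate, random
  intercepts); no tensor smooths, non-Gaussian links, or model selection
  beyond the fixed structures used here.
* Alternative light-curve models (Eilers–Peeters, Jassby–Platt) are not
  implemented; the fitting surface accepts only the double-exponential.
* Pigments are fresh-weight standardized only; no dry-weight conversion
  is invented.
* Respiration carry-over between the dark-then-light incubation phases is
  not modelled; rejected light curves are dropped and logged, never
  re-measured.
* The reported ~67% reduction of corrected ETRmax versus the ~59% implied
  by mean AF ratios in the source experiment reflects per-shoot AFs and
  refitting; the package documents, and does not force, either figure.
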