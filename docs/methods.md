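# Methods

`ramancal` implements a generic (instrument-transferable) Raman chemometrics
workflow for bioprocess metabolite monitoring and exercises it end-to-end on
seeded synthetic data that emulate a proprietary multi-site CHO-cultivation
corpus.  This note documents the model, the numerical conventions, the
synthetic study conditions, and the design decisions that were genuinely
open.

## The analysis chain

**Wavenumber standardization.** Spectrometers differ in spectral coverage
and pixel-to-wavenumber mapping, so spectra are re-sampled onto one common
grid before any multivariate analysis.  The common grid is the largest
3 cm⁻¹ ladder starting at 300 cm⁻¹ that does not exceed 3400 cm⁻¹ — 1034
channels ending at 3399 cm⁻¹ — i.e. the least common denominator of the
supported instrument families (100–3425 cm⁻¹ @ 1 cm⁻¹ and 100–4000 cm⁻¹ @
3 cm⁻¹).  Re-sampling uses a not-a-knot cubic spline, chosen because it is
exact on cubic polynomials; extrapolation is never performed — a spectrum
that does not cover the common grid is rejected.  The implicit assumption is
that instruments are reasonably well wavenumber-calibrated; the spline
interpolates intensities but does not re-calibrate the axis.

**Preprocessing.** A Savitzky–Golay first derivative (2nd-order polynomial,
31-point window) followed by standard normal variate (SNV) normalization.
Conventions: the derivative is taken per cm⁻¹ (divided by the grid
increment), so results are invariant to the grid spacing; edges are trimmed
to the interior where the full window fits, (31−1)/2 = 15 channels per end
(1034 → 1004 channels), rather than fit asymmetric edge polynomials —
deterministic and artifact-free; SNV uses the sample standard deviation
(n−1) and is applied per spectrum over all retained channels, after the
derivative.  The derivative removes additive offsets exactly and suppresses
smooth fluorescence drift (a degree-d polynomial baseline becomes a
degree-(d−1) residual whose amplitude is smaller by roughly the ratio of
band width to spectral span); SNV removes the per-spectrum multiplicative
scatter factor exactly.  Every preprocessed data set carries a fingerprint
(hash of the configuration and resulting grid); models record it and refuse
incompatibly prepared spectra.

**Regression.** One PLS1 model per analyte (glucose, lactate, glutamine,
glutamate), fitted by NIPALS with X-only deflation on mean-centered data; no
channel autoscaling (SNV has already normalized the spectra).  The
regression vector is B = W(PᵀW)⁻¹q.  Fitting more components than the
predictive rank of X is an error in direct fits; inside cross-validation,
rank-exhausted folds reuse their last valid component set so the RMSECV
curve stays defined.

**Model selection.** RMSECV from group-wise cross-validation: folds are
formed over whole cultivation batches (default 10 folds), because spectra
within a batch are serially correlated and a per-spectrum split would leak
information and understate the error.  For multi-site data the folds are
additionally stratified by site, so that no fold removes an instrument from
the training data entirely — a pooled "generic" calibration by construction
always contains every instrument, and an unstratified fold that strips one
site would measure cross-instrument extrapolation instead of model
complexity (in development this produced RMSECV spikes and erratic LV
choices).  The chosen LV count is the smallest whose RMSECV lies within 1%
(configurable) of the curve minimum; ties resolve downward.  This parsimony
rule deliberately refuses to chase shallow minima in flat curves — for a
signal-poor analyte it returns a small LV count rather than an overfitted
large one.

**Evaluation.** RMSE = √(Σ(ŷᵢ−yᵢ)²/N); SEC/SEP(%) = 100·RMSE/Yrange with
Yrange the evaluated set's own reference range (max − min).  SEC
(calibration) and SEP (test/external) use the identical formula; the role
tag is metadata, and every report row re-verifies the identity at
construction.  R² defaults to 1 − SSres/SStot (it can be negative for
worse-than-mean predictions); squared Pearson correlation is available via
`r_squared(..., method="pearson")` for cross-checking.  SEP below 5% is
annotated "very good" and above 10% "too high" — annotations only, never
hard failures.  Min–max scaling to [0, 1] is provided for reporting; it
leaves SEP% unchanged (numerator and denominator scale identically).

**Train/test split.** 70/30 by whole batches, seeded, targeting the
spectrum-count fraction as closely as batch sizes allow; stratified by site
for multi-site sets so every instrument keeps ≈70% of its spectra in
calibration.

## The synthetic study conditions

The generator emulates a four-site industrial corpus (305/958/295/148
spectra over 6/22/4/7 batches; the published per-site counts sum to 1706)
plus two held-out data sets: a ten-level dilution series in triplicate on a
fifth instrument, and an independent fed-batch culture on a sixth.  A
desk-scale corpus (~10% of the spectrum counts, same structure) is packaged
for fast experiments; the full-scale corpus is used for the count contract.

*Spectra.* I(ν) = m·[Σₐ cₐ·Σ_b coeff_b·shape(ν; center_b+δ, width_b·β)
+ matrix(ν)] + baseline(ν) + ε(ν).  Each analyte has 3–4 stylized
Gaussian/Lorentzian bands; bands of different analytes partially overlap
(e.g. 1045/1065/1090 cm⁻¹) so concentration estimation requires
multivariate resolution.  Glutamate's coefficients are ~20× weaker than
glucose's and its culture concentrations are sub-millimolar, making it the
hard analyte by construction.  The constant matrix background (water
bending ~1640, O–H stretch ~3230, CH ~2935 cm⁻¹ bands) dominates total
intensity, as in real aqueous cell-culture spectra; this also keeps the SNV
divisor nearly concentration-independent, so the spectrum–concentration map
stays close to linear over the extrapolated external range.  Channel noise
is at a realistic shot-noise level (band signal-to-noise of order 10², not
10⁴): with unrealistically low noise, every microscopic instrument
idiosyncrasy becomes statistically learnable and cross-validation keeps
adding non-transferable components.  The per-spectrum polynomial baseline
(degree 3–5, random coefficients) emulates fluorescence drift; a log-normal
scatter factor emulates focus/turbidity variation.

*Instruments.* Two grid families (1 vs 3 cm⁻¹) with small systematic
wavenumber offsets (|δ| ≤ 0.5 cm⁻¹, the accuracy of neon-referenced
calibration), a few percent spread in effective band width (resolution),
and per-batch session drift (offset jitter 0.03 cm⁻¹, broadening jitter
1%) for probe alignment and temperature effects.  Site concentration
setpoints are arranged so the two instrument families see similar overall
concentration distributions: if the detectable family signature correlated
with concentration range, a pooled model could use the instrument identity
as a concentration proxy — a confound that cross-validates well and fails
on any new instrument.

*Trajectories.* Event-driven fed-batch kinetics: glucose is consumed at a
growth-ramped rate and replenished to a setpoint at daily feeds (it strictly
decreases between feeds), lactate is produced proportionally to glucose
consumption until a metabolic shift and consumed afterwards, glutamine is
fed to a low setpoint, and glutamate accumulates slowly from glutamine
metabolism (range ≲ 2 mmol/L).  Per-batch log-normal jitter (20% generally,
40% on lactate metabolism) emulates different cell lines and process
conditions.  Reference tables carry the *measured* off-line values — truth
plus 2% relative assay error, as a Cedex-type analyzer would report — while
spectra are generated from the truth; this reference error is the realistic
floor of every RMSECV curve.  Dilution-series references are exact
(gravimetric preparation), and the series dilutes one stock of culture-like
composition (glucose 100, lactate 30, glutamine 8, glutamate 4 g/L at the
top level; the printed levels are glucose concentrations — glutamine and
glutamate are not soluble at 100 g/L).

*What the generator does not emulate:* real Raman cross-sections and band
assignments, cosmic-ray spikes, detector nonlinearity, cell-density and
product-titer signals, water-band temperature shifts, or time misalignment
between spectra and off-line samples (synthetic spectra are emitted exactly
at sampling times).  Passing tests therefore demonstrate that the *pipeline*
behaves correctly under the stated statistical structure, not that any real
instrument pair can be bridged without recalibration.

## The transfer experiment

`run_generic_experiment(seed, scenario="desk")` generates the corpus,
standardizes and preprocesses it, then: (1) fits pooled and per-site models
(70/30 batch split, grouped CV, parsimony LV selection); (2) validates every
model externally on the held-out-instrument dilution series; (3) applies the
pooled models to the independent culture.  At desk scale (~170 calibration
spectra) a seeded run takes a few seconds on one CPU; problem sizes were
chosen so the full experiment, including all five models and four analytes,
remains interactive.  Typical desk-scale outcomes: pooled glucose/lactate
SEC ≈ 0.5–3% with 4–12 LVs and external SEP ≈ 0.2–4%, single-site glucose
models externally worse than the pooled model, glutamine marginal (weak
signal against realistic noise) and glutamate far above the 10%
acceptability bound with a flat RMSECV curve — the hard-analyte pattern.
The independent culture exposes the narrow-range failure mode: with glucose
controlled at 2–4 g/L, even small absolute errors are large against the
tiny reference range, so SEP is high although predictions track the trend.

## Numerical details and degenerate inputs

- NIPALS stops (or errors, in strict mode) when ‖Xᵀy‖ falls below 1e−10 of
  its initial value — the predictive rank is exhausted.
- The CV LV ceiling is clamped to min(max_lv, channels, smallest training
  fold size − 1).
- SNV errors on spectra whose derivative SD is at or below `sd_floor`
  (default 1e−12), naming the offending sample ids.
- Zero-variance y, empty curves/inputs, non-uniform grids, extrapolating
  target grids, duplicated sample ids and fingerprint mismatches are all
  rejected with descriptive errors rather than silently handled.
- CSV I/O is lossless: `%.17g` on write, `float_precision="round_trip"` on
  read.
- All randomness flows through `numpy.random.SeedSequence` spawning, so a
  (config, seed) pair reproduces every dataset and report bit-identically.

## Known limitations

- The stylized band library is not spectroscopically curated; absolute
  SEC/SEP values depend on the chosen signal-to-noise and are meaningful as
  orderings and magnitudes, not as predictions for a specific instrument.
- Glutamine sits near the detection limit under the default noise level, so
  its figures of merit are poor; this is a property of the chosen study
  conditions, not of the estimator.
- The parsimony LV rule anchored at the curve minimum can still select a
  large LV count when the curve has a late shallow minimum; the tolerance is
  configurable (`CVConfig.selection_tol`).
- PLS is linear: predictions extrapolate outside the calibration range only
  as far as the signal stays linear and the SNV divisor stays
  concentration-stable.
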