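# Methods

This note documents the models, numerical choices and limitations of
`dyadsync`, in the package's own words.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Synthetic dyad model

Each dyad watches three 5-minute videos (negative, neutral, positive,
in a seeded random order).  A latent arousal driver per member per
video controls all channels:

* **Driver.** A unit-variance Gaussian process band-limited to
  0.01–0.4 Hz (sampled at 4 Hz), so that the shared fluctuations fall
  inside the frequency bands analysed downstream.  Member drivers mix a
  video-level common trace and an idiosyncratic trace as
  `coupling·common + (1−coupling)·idiosyncratic`, both components
  standardized before mixing.  Under this rule the inter-member driver
  correlation is `c²/(c² + (1−c)²)` — strongly convex, so low coupling
  produces weak correlation (≈0.155 at c = 0.3, ≈0.99 at c = 0.9).
* **Cardiac.** The inter-beat interval (IBI) at time t is the
  condition-adjusted mean plus an intrinsic 0.04–0.4 Hz fluctuation
  (SD `ibi_sd_ms`, default 15 ms) minus `arousal_ibi_gain_ms` (default
  80 ms per driver SD) times the driver; beats accumulate until the
  record ends.  The defaults make the stimulus-driven component
  dominate intrinsic variability (total SDNN ≈ 80 ms, within the
  normal range for young adults).  This split is a deliberate design
  choice: the generator exists to express the coupling manipulation in
  the analysed band, and with the convex mixing rule above a weaker
  gain would make the low end of the coupling grid physically
  undetectable by any synchrony estimator at realistic sample sizes.
  Condition offsets (+8 / −12 / +5 ms for negative / neutral /
  positive) calibrate mean IBI to 808 / 788 / 805 ms.
* **ECG.** A Mexican-hat biphasic pulse (σ = 13 ms, ≈80 ms footprint,
  1 mV) is placed at each sample-aligned beat time; Gaussian noise is
  added at a configurable SD (`noise_sd_for_snr` converts a target
  SNR in dB).  Ground-truth R-peak times are returned.
* **Respiration.** A phase oscillator whose instantaneous rate wanders
  around the configured breaths/min (multiplicative 0.01–0.05 Hz
  jitter, 5 %) plus 1 bpm per driver SD; the chest trace is
  `amplitude·sin(phase)` (300 mcV) with 5 mcV sensor noise.
  Expiration onsets (signal maxima) are returned as truth.  Condition
  offsets give 20.9 / 19.9 / 22.0 breaths/min.
* **Skin conductance.** Tonic level (6.7 μS base; condition offsets
  0 / −1.9 / +1.8 μS → 6.7 / 4.8 / 8.5 μS) plus a slow drift
  (≤0.01 Hz, 0.3 μS) plus SCR events from an inhomogeneous Poisson
  process (4 events/min base, +50 % per driver SD) convolved with a
  rise-0.75 s / decay-2 s two-exponential kernel with lognormal
  amplitudes around 0.4 μS.
* **Ratings.** Latent Gaussians rounded and clipped to the Likert
  bounds (9-point valence/arousal, 7-point connectedness and attitude
  items).  A per-video dyad-level arousal deviation d_v ~ N(0,1)
  shifts both members' arousal reports and — with slope 0.8 under
  joint attention, 0 under disjoint — the latent connectedness, which
  also carries a dyad random effect (SD 0.4).  Valence/arousal/
  connectedness condition means follow typical printed summaries for
  such stimuli.  All generating latents are retained on the session
  for parameter-recovery tests.

Sampling rates default to the acquisition standard of 1 kHz per
channel; tests and examples lower them (and the 300 s duration) where
the property under test does not depend on them, to keep the suite
fast.  One master seed drives everything through `SeedSequence`
spawning; identical configuration ⇒ bit-identical session.

**What the generator does not emulate:** movement and electrode
artifacts arising from real hardware (the artifact rules are exercised
on hand-built boundary fixtures instead), ectopic beats, respiratory
sinus arrhythmia as an explicit cardio-respiratory coupling, facial or
behavioural channels, and any video-content-specific temporal
structure.  Passing tests therefore demonstrate correctness of the
analysis chain and its operating characteristics under the stated
statistical model, not robustness to every failure mode of real
recordings.

## Preprocessing

* All Butterworth filters are applied forward–backward
  (`sosfiltfilt`), which preserves peak timing across channels at the
  cost of doubling the effective order; second-order sections keep the
  0.04–0.4 Hz band-pass at 20 Hz numerically stable.
* R-peak detection: the QRS template is the median 160 ms beat around
  the 30 strongest local maxima; the ECG is cross-correlated with the
  template, the correlation z-scored, and peaks above 0.6 SD with a
  250 ms refractory period (240 bpm ceiling) accepted, then refined to
  the local ECG maximum within ±30 ms.  Flat signals raise a "no QRS
  template" error; zero detections raise rather than return empty.
* IBI series: intervals are assigned to the second beat of each pair,
  cubic-spline interpolated over [first, last] peak, resampled at
  20 Hz and band-passed 0.04–0.4 Hz; the mean IBI is recorded before
  filtering.
* Expiration onsets: local maxima with ≥1 s separation and prominence
  ≥25 % of the trace SD; recordings shorter than 30 s are rejected.
* The "slope exceeding 2 μS" electrodermal rule is computed per
  second: least-squares slope over non-overlapping 1 s windows, rule
  fires when |slope| > 2 μS/s covers more than 5 % of a video.
* The respiration variance rule reads "variance … three times the
  standard deviation above the sample mean" as
  `var_i > mean(vars) + 3·SD(vars)` over all recordings in the sample;
  `variance_rule="sd"` applies the same screen to the per-video SDs
  instead, since the rule's units are ambiguous in common usage.
* Quartiles for the 3×IQR outlier rule use the linear-interpolation
  (type-7) convention, the most common default.

## Wavelet coherence

Morlet ω₀ = 6, 12 voices per octave, smallest scale 2·dt, largest
scale a quarter of the record; signals are mean-removed and
zero-padded to a fast FFT length.  Smoothing is Gaussian in time with
SD = scale/√2 and a boxcar over 0.6 octaves in scale (the boxcar width
in the classic implementation of the procedure is expressed in octaves
of the log2-spaced scale axis, i.e. 0.6/dj points).  Coherence is the
magnitude-squared form; `WtcConfig(squared=False)` averages its square
root instead.  The cone of influence excludes cells closer than
√2·scale to either record edge from every average.  By Cauchy–Schwarz
the estimator is bounded in [0, 1]; values are clipped against float
round-off.  Cells where the denominator vanishes (signals with no
energy at that scale) are NaN and excluded from averages — for
band-limited inputs the self-coherence identity therefore holds
exactly in-band and to ~1e-4 in the energy-free tails.

**Decimated engine.** For band-restricted sweeps (the surrogate
bootstrap computes thousands of pairs) the engine can evaluate the
transforms on a coarser time grid by spectral folding.  The analytic
Morlet coefficients at the retained scales are band-limited, so
decimation is exact up to the kernel tails; the band averages agree
with the full-resolution path to ≲1e-3 (tested).  The full-resolution
path remains the default for maps.

Pre-analysis sampling: cardiac IBI at 20 Hz (fixed), respiration and
phasic skin conductance decimated to 10 Hz — their frequencies of
interest lie far below 5 Hz and this keeps maps tractable.

## Surrogate-dyad null

Surrogate pairs are all cross-dyad pairings of individuals matched on
attention condition and video identity.  The statistic is
mean(real synchrony) − mean(surrogate synchrony).  The null
distribution re-pairs the individuals of each matched group into
random vertex-disjoint matchings n_boot times — the same dependence
structure as the real pairing (each individual used exactly once per
draw) — and the two-sided p-value is `(1 + #{|D_b| ≥ |D|})/(n_boot+1)`.
An earlier iid resampling of surrogate values was discarded because
pair values sharing an individual are correlated, which made that
bootstrap mildly anticonservative; the matching null is calibrated
(rejection rate ≈ α under zero coupling, verified by Monte Carlo in
the test suite).  The bootstrap seed is explicit and recorded in the
result object.

## Dyad-level indices

Connectedness is averaged over its four items per member (desire for
future interaction over its seven) *before* the within-dyad product is
taken.  Missing members or time points propagate as errors or dropped
rows — never imputed.  Neutral-baseline correction emits two rows per
complete dyad (positive−neutral, negative−neutral) for every
correctable column and drops dyads lacking the neutral video with a
reason.

## Mixed models and selection

Fitting is delegated to statsmodels `MixedLM`: a single random
intercept uses the grouped parameterization; crossed intercepts
(dyad × video valence × video index) become variance components inside
one all-encompassing group.  Optimizers are tried in the order lbfgs,
bfgs, cg, powell; non-convergence is reported through a flag, never
silently.  Coefficient p-values use the normal approximation;
likelihood-ratio tests on ML fits are authoritative for model
comparison and selection (REML log-likelihoods are rejected there).
Marginal/conditional R² follow the variance-partition convention
(fixed-effects variance over, respectively plus, random and residual
variance); ICC = τ₀₀/(τ₀₀+σ²).

Backward-stepwise selection (α_keep = 0.05, configurable): candidate
terms are first ordered by their single-term deletion-LRT p-value; if
the full model fails to converge the least-contributing droppable
terms are pruned until it does; then the droppable term with the
largest deletion p is removed repeatedly until every remaining fixed
effect is significant.  Marginality is enforced — a main effect is
never dropped while one of its interactions remains.  The final model
is reported from the ML fit so that post hoc nesting comparisons are
valid; the full trace (ordering, convergence drops, per-step χ², df,
p) is replayable.

Likert responses are modelled as continuous throughout: the headline
dyad-level responses (mutual products, dyadic means) are products or
means of item averages and effectively continuous, and this keeps the
selection machinery uniform.  Ordinal cumulative-logit models are out
of scope.

## Problem sizes in the test suite

Monte-Carlo suites use the sizes at which the operating
characteristics are stated: 200 simulations × 20 dyads × 200
bootstrap draws for the surrogate calibration; 20 dyads per level ×
three videos for the coupling grid; 100 simulations each for mixed
model recovery (50 groups × 6 observations) and stepwise selection
(40 dyads × 2 rows, six candidates).  Unit tests use 60–120 s
recordings at reduced sampling rates where the property tested is
rate-independent.

## Known limitations

* The coupling grid's lowest step (0 → 0.3) maps to a driver
  correlation of only ≈0.155 under the pinned mixing rule, so its
  synchrony increment is intrinsically small (~0.01 in band-averaged
  WTC); the grid test gains its resolution from 60 pair-values per
  level.
* Significance contours on individual coherence maps, phase-lag
  analysis, cross-recurrence metrics and EDA deconvolution are not
  implemented.
* The artifact rules are deterministic stand-ins for steps that are
  interactive (visual inspection) in laboratory practice.
* `MixedLM` variance components are reported without standard errors;
  selection relies on LRTs, not on Wald tests of variance terms.
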