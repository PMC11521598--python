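# dyadsync

Dyadic psychophysiology analysis: do two people who share an emotional
experience synchronize physiologically, and does the intensity of that
shared arousal predict how bonded they feel afterwards?

`dyadsync` implements the full analysis chain used to answer such
questions for pairs of co-seated participants watching emotion-eliciting
videos while ECG, a respiration belt, and skin conductance are recorded:

1. **Synthetic dyad generation** (`dyadsync.simulate`) — paired
   physiological recordings with a tunable inter-member `coupling`
   parameter, plus Likert ratings (SAM valence/arousal, connectedness,
   social attitudes) generated from a latent-Gaussian model whose
   coefficients are retained for recovery testing.
2. **Per-channel preprocessing** (`dyadsync.preprocess`) — Butterworth
   band-passes (ECG 1–100 Hz; inter-beat intervals 0.04–0.4 Hz; skin
   conductance 0.05–5 Hz phasic), template-matched R-peak detection
   (0.6 SD threshold on the z-scored template correlation, 250 ms
   refractory period), cubic-spline IBI resampling at 20 Hz, expiration
   onset detection, and the artifact/outlier screening rules
   (5 % null-run and 3 SD variance rules for respiration, all-video
   unresponsiveness and 2 μS/s slope rules for electrodermal activity,
   3×IQR statistical outliers).
3. **Interpersonal synchrony** (`dyadsync.synchrony`) — wavelet
   transform coherence (WTC) and its surrogate-dyad null (below).
4. **Dyad-level indices** (`dyadsync.indices`) — within-dyad means,
   absolute differences, mutual products (connectedness, social
   identification, desire for future interactions), t1−t0 change
   scores, and neutral-baseline corrections.
5. **Mixed-effects modelling** (`dyadsync.models`) — linear mixed
   models with dyad (optionally crossed) random intercepts,
   likelihood-ratio tests, buildmer-style backward-stepwise selection,
   Holm adjustment, and Spearman / Wilcoxon–Mann–Whitney post hocs.
6. **Pipeline & CLI** (`dyadsync.pipeline`, `dyadsync` command) —
   simulate → preprocess → synchrony → indices → model with YAML
   configuration, JSON-lines logging and a digest manifest.

## The core statistic

For two signals x, y the magnitude-squared wavelet coherence at scale
s and time t is

    R²(s,t) = |S(s⁻¹ W_xy(s,t))|² / ( S(s⁻¹|W_x(s,t)|²) · S(s⁻¹|W_y(s,t)|²) )

where W_x is the continuous Morlet transform (ω₀ = 6, 12 voices per
octave over logarithmic scales), W_xy = W_x W_y*, and S is smoothing by
a Gaussian in time (SD = s/√2) and a 0.6-octave boxcar in scale.
R² lies in [0, 1]; cells closer to a record edge than √2·s lie inside
the cone of influence and are excluded from every average.  Dyad-level
synchrony is the time–frequency average of R², either full-band or
restricted to the low-frequency (0.05–0.15 Hz) or high-frequency
(0.15–0.4 Hz) heart-rate-variability bands.

Because smoothing biases coherence upward even for independent signals,
observed synchrony is compared against **surrogate dyads**: all
cross-dyad pairings of individuals matched on attention condition and
video.  The test statistic is mean(real) − mean(surrogate), referenced
to a bootstrap null of random cross-dyad matchings.

## Worked example

```python
import numpy as np
from dyadsync import simulate, synchrony

cfg = simulate.DyadSimConfig(coupling=0.6, seed=7)   # moderately coupled dyads
sessions = simulate.simulate_study(6, cfg, channels=(), seed=7)

for s in sessions[:2]:
    for v, cond in enumerate(s.video_conditions):
        x, fs = synchrony.member_trace(s, 0, v, "ibi")
        y, _ = synchrony.member_trace(s, 1, v, "ibi")
        n = min(x.size, y.size)
        wtc = synchrony.wavelet_coherence(x[:n], y[:n], fs)
        val = synchrony.average_synchrony(wtc, "lf").value
        print(f"{s.dyad_id}  {cond:<9} LF synchrony = {val:.3f}")

res = synchrony.surrogate_null(sessions, band="lf", n_boot=500, seed=1)
print(f"real mean = {res.real_values.mean():.3f}, "
      f"surrogate mean = {res.surrogate_values.mean():.3f}")
print(f"difference = {res.statistic:+.3f}, two-sided p = {res.p_value:.3f}")
```

prints

```
dyad000  negative  LF synchrony = 0.601
dyad000  neutral   LF synchrony = 0.657
dyad000  positive  LF synchrony = 0.583
dyad001  neutral   LF synchrony = 0.550
dyad001  positive  LF synchrony = 0.648
dyad001  negative  LF synchrony = 0.519
real mean = 0.587, surrogate mean = 0.428
difference = +0.159, two-sided p = 0.002
```

The surrogate mean (~0.43) is the smoothing-bias floor of WTC for
independent signals; with coupling 0.6 the co-tested pairs sit well
above it and the matching bootstrap rejects the null.  With
`coupling=0` the difference vanishes and the p-values are uniform.

The same analysis runs from the shell:

```bash
dyadsync simulate --out run/sessions --seed 7 --n-dyads 6
dyadsync synchrony --in run --channel ibi --band lf --surrogate --seed 1
dyadsync indices --in run --out run/dyad_indices.csv --baseline-correct
```

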