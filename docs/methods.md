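# Methods

## Signal model and assumptions

Surface EMG is modeled as a zero-mean broadband stochastic process whose
*amplitude envelope* carries the physiological information: when a gesture is
held, each electrode channel sees a contraction intensity determined by the
underlying muscle group, and the ratio of intensities across channels is the
discriminative pattern. The pipeline therefore assumes:

- amplitudes in the ~10⁻⁶–10⁻⁴ V range typical of surface electrodes;
- signal power concentrated in roughly 10–500 Hz;
- windowed average power approximately lognormal within a channel — the
  empirical motivation for the base-10 log stage, since the log of a
  lognormal variable is normal;
- recordings are single-gesture by contract (no transition windows).

## The mapping chain

| Stage | Formula | Parameter, default, why |
|---|---|---|
| power | mean of squared samples over `w` | `w` = 200 samples (100 ms at 2000 Hz): long enough to average the carrier, short enough to track activation; sEMG precedes visible movement by 50–100 ms |
| lg | `|log10(max(p, ε))|` | `ε` = 1e−20 V², far below the physiological power scale (~1e−12–1e−8 V²), so flooring only guards exact zeros |
| compress | affine onto `[−a, +a]` | `a` = 4: amplitudes span ≈100-fold, so log-power spans `2·lg 100 = 4` decades; ±4 is also where the logistic saturates at 0.018/0.982 |
| sigmoid | `1/(1+e^{−v})` | no parameters; compresses outliers, preserves central detail |

Numerical/contract details:

- **Length contract**: an `n`-sample channel yields `n − w + 1` power values
  (stride 1, no tail padding); all later stages preserve length.
- **Absolute value and order reversal**: physiological powers are ≪ 1, so
  their log10 is negative and `|log10|` *reverses* ordering — larger muscle
  power maps to a smaller T4 output. Because the compression stage is a
  min–max affine map, this reversal is cosmetic for classification (the
  pattern is mirrored, not destroyed), but it matters when reading T3/T4
  values directly. `use_abs=False` gives the order-preserving variant.
- **Compression scope**: the min/max of the compression stage default to the
  whole recording (all channels jointly). Per-channel normalization would
  erase exactly the inter-channel activity differences the method feeds on;
  it is available as an option for sensitivity analyses.
- **Degenerate inputs**: constant scopes map to the interval midpoint
  (compression) or to all-zero images (grayscale) with a logged warning
  rather than an exception; statistics that are undefined on constant
  samples raise a `StatisticsError` that the reporting layer converts to a
  per-channel note.

## Denoising

A 4th-order zero-phase Butterworth band-pass, 10–500 Hz. The band matches
where sEMG power lives; zero-phase (forward–backward) application avoids
shifting feature timing relative to window boundaries. An upper edge at or
above Nyquist is clamped to 0.99·fs/2 with a warning so 1000 Hz wristband
hardware works unmodified. A pure low-pass variant is available
(`kind="lowpass"`).

## Imaging

Feature matrices are segmented *after* mapping (map the whole recording,
then window), with `L = k·f/1000` samples per window (`k` = 200 ms) and a
50 ms stride. Grayscale rescaling defaults to per-window min/max — maximal
contrast per image, the usual choice for classifier inputs — with a global
scope available. Rounding is half-up with a 1e−9 nudge before the floor so
values that are an ulp below a half-integer (float artifacts of the affine
rescale) round as the exact rational would. Images are written as 8-bit
single-channel PNGs (lossless; round-trips are bit-exact) with a CSV
manifest.

## Distribution diagnostics

Skewness and kurtosis use the bias-corrected sample formulas
(SK = m/((m−1)(m−2))·Σz³; K = m(m+1)Σz⁴/((m−1)(m−2)(m−3)) −
3(m−1)²/((m−2)(m−3)), z standardized by the (m−1)-denominator SD), defined
for m ≥ 4. Two kurtosis conventions circulate; both are reported:
`K_excess` (normal → 0, what the correction formula produces) and
`K_raw = K_excess + 3` (normal → 3); comparisons against the "benchmark of
3" use `K_raw`. The Jarque–Bera statistic is JB = m/6·(SK² + K_excess²/4)
with the asymptotic χ²(2) p-value — appropriate at the sample sizes the
pipeline produces (thousands of windows); no small-sample table is used.
A constant sample can yield a nonzero floating-point SD through mean
rounding, so degeneracy is detected via the value range (ptp), not the
computed SD.

## Synthetic generator

Channel `c` of a class-`k` recording is

```
x_c(t) = G[k,c] · env(t) · m_c(t) · carrier_c(t) + noise + interference
```

- **Gains `G`**: per-(class, channel) amplitude scales, drawn log-uniformly
  from [1e−6, 1e−4] V with a minimum inter-class separation (default 0.3
  decades on at least one channel). This is the discriminative structure —
  the analogue of distinct muscle-activation patterns.
- **Carrier**: Gaussian white noise band-limited to 20–450 Hz and normalized
  to unit variance. Chosen over sinusoids because sEMG is stochastic and
  broadband; the band sits inside the 10–500 Hz denoising pass-band.
- **Modulation `m_c`**: `exp(μ + σ·g(t))` with σ = 0.4 and `g` slow
  (50 ms Gaussian smoothing) — this makes the windowed power approximately
  lognormal, the distributional assumption the lg stage corrects. `g` is
  passed through a rank-based inverse-normal transform so its empirical
  marginal is exactly the normal-score distribution: plain smoothed noise
  leaves only a few dozen effective independent modulation draws per 5 s
  recording, and their sampling skewness would otherwise dominate the
  log-power distribution and make its moments unstable across seeds.
- **Envelope**: optional smoothed on/off bursts; the default is a sustained
  contraction (envelope ≡ 1), matching recordings where each file is one
  held gesture.
- **Noise and interference**: additive white noise (5e−7 V) and optional
  50 Hz power-line sine (off by default).

Defaults are the study conditions throughout: 8 channels, 2000 Hz, 6 gesture
classes, 5 s recordings, 4 repetitions per class in a round-robin dataset.
Per-recording seeds derive from `SeedSequence(top_seed, spawn_key=(class,
rep))` — platform-stable, emitted in the dataset manifest (reduced mod 2³¹).

Two packaged regimes: `easy_spec` (independent log-uniform gain patterns —
classes separable almost perfectly, used for end-to-end recovery) and
`hard_spec` (one base pattern with ±25 % per-class perturbations — raw
amplitude views barely distinguish classes, power-based features still do;
used for the ablation ordering).

**What the generator does *not* emulate** — and hence what passing tests do
not show about real data: motor-unit action-potential shapes and recruitment
dynamics, electrode shift, skin-impedance drift, fatigue, inter-subject
variability, crosstalk between adjacent electrodes, and gesture transition
periods. Accuracy numbers on synthetic data validate the pipeline's
mechanics and relative ordering of its variants, not field performance.

## Evaluation protocol

Windows are ordered chronologically within each (subject, gesture) stream;
the first 80 % train, the last 20 % test. Because 200 ms windows at a 50 ms
stride overlap, a test window adjacent to the boundary can share raw samples
with a training window; the split therefore drops test windows whose sample
span intersects any training window's span in the same recording
(overlap-safety, on by default). The `rate distribution` metric is the
max − min of per-subject accuracies.

The default back end is multinomial logistic regression on flattened pixels
(scaled to [0, 1]); a one-hidden-layer MLP is included, and any external
image classifier (e.g. a deep CNN trained elsewhere) can be plugged in via
the `fit`/`predict` adapter contract. A single-class training set short-
circuits to constant prediction. The label-shuffle control permutes labels
at the *window* level before splitting: an honest split then scores at
chance (1/n_classes), while a leaky split that lets a window reach both
sides would let the classifier memorize its shuffled label. (Shuffling at
the recording level is not a chance-calibrated control: plurality voting
among a class's repetitions inflates it above 1/n_classes even without
leakage.)

## Problem sizes

The packaged evaluations use the default study conditions — 6 classes ×
4 repetitions × 5 s at 2000 Hz (24 recordings, 2280 windows, ≈440 test
windows) — for the end-to-end and ablation runs, and 100 seeded trials of
m = 10 000 for the distribution-correction rate. The unit-test suite uses
shorter recordings (0.25–2 s) where only the mechanics are under test.

## Known limitations

- The amplitude-range contract ("1st–99th percentile within [1e−7, 1e−3] V")
  is checked on the windowed RMS envelope, not raw signed samples: raw sEMG
  is zero-mean, so low percentiles of |x| are arbitrarily small for any
  zero-mean process; published amplitude ranges describe the envelope scale.
- T3 and T4 accuracies on the subtle-gain regime are close; the sigmoid
  stage's benefit is mainly outlier compression, which the bounded synthetic
  regime exercises only mildly.
- The linear back end evaluates feature quality, not ceiling performance; a
  CNN back end would be expected to widen the T1 vs T4 gap further on data
  with temporal structure.
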