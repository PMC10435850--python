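# Methods

## Signal model and pipeline

A water-swallow trial is a mono WAV recording of cervical auscultation
(electronic stethoscope at the top of the sternum; analog band roughly
2 Hz–20 kHz). The file's content is taken as the auscultation interval;
0.2 s at each end is excluded (`trim_auscultation`), expressed in whole
samples (`round(edge_s * rate)`) so section lengths are exact. The
canonical internal rate is 44.1 kHz — the stored-file rate is not fixed
by the recording hardware's spec, so 44.1 kHz was chosen as the smallest
standard rate covering the 20 kHz band edge; other rates are polyphase
resampled on ingest.

Frames are placed every 12 ms with a 24-ms Hann-tapered analysis window
(two hops: a window longer than the hop is needed for stable cepstra;
both are config keys). Frame *k* covers samples `[k*hop, k*hop+window)`;
`n_frames = floor((n - window)/hop) + 1`.

## The 148-feature layout

The deployed discriminator consumes exactly 148 features per frame. The
layout, serialised with every model, is:

| group | n | definition |
|---|---|---|
| `mel_logE_*` | 40 | log₁₀ band energies (dB) of a triangular mel filter bank, 50 Hz–min(20 kHz, Nyquist) |
| `cep_*` | 24 | real-cepstrum coefficients c1–c24 of the frame's log magnitude spectrum; a low-time lifter (cutoff 24, configurable) zeroes higher quefrencies, isolating spectral-envelope structure |
| `dcep_*` | 24 | within-window delta cepstra: c1–c24 of the second half-window minus the first (frames stay mutually independent, preserving time-shift covariance) |
| `bandvar_*` | 40 | per mel band, variance of the band log-energy across 4 equal sub-blocks of the window — the local-variance signature of transient bursts |
| scalars | 20 | zero-crossing rate, spectral centroid, bandwidth, rolloff at the 10/25/50/75/90% quantiles, spectral flux (between half-windows), flatness, crest factor, log RMS, envelope skewness and kurtosis, and 6 high/low band-energy log-ratios split at 0.5/1/2/4/8/16 kHz |

Numerical choices: band energies are floored at −80 dB relative to full
scale so silence maps to a fixed, finite vector; shape statistics
(centroid, bandwidth, rolloff, skew/kurtosis) are defined as 0 on
frames below the floor. Features are min–max normalised per feature to
[−1, 1] against the training set, with clipping outside the training
range; a constant training feature maps to 0. Min–max (not z-scoring)
is used because the classifier's contract requires |xᵢ| ≤ 1 exactly.

## Classifier

Weak learners are depth-1 decision stumps on single normalised features.
Discrete AdaBoost (default 100 rounds) combines them; initial example
weights are balanced per class because crackle frames are a small
minority of recording frames. The stump search is exhaustive over all
features and all midpoint thresholds each round, so training is
deterministic and independent of clip order; the seed is recorded in
the model metadata for provenance only.

The deployed form is strictly linear: the boosted margin H(x) is
projected onto y = Σ aᵢxᵢ by least squares over the training frames
(no intercept — the decision threshold absorbs any offset). This keeps
the deployment contract (a single 148-vector of coefficients plus a
threshold) while the boosted ensemble is retained in `training_meta`
for diagnostics. The threshold maximises balanced accuracy on the
training frames over midpoint candidates; tied optima resolve to the
middle candidate, and an all-equal score distribution is flagged
degenerate. Whether a threshold should be tuned on held-out data
instead is an open design point; balanced accuracy on training data is
the declared choice here.

Models serialise to a single JSON document (layout, normaliser, a,
threshold, metadata); save→load→score is bitwise reproducible.

## Index computation

Frames are bucketed by start time into whole seconds. FCQV(s) is the
fraction (or ×100 percent) of frames in second *s* classified positive;
a trailing partial second is computed over its actual frame count
rather than discarded, because short 3-mL swallow recordings would
otherwise lose data. The trial index is the whole-section fraction
`n_target / n_total`; the participant index is the maximum over trials.
The printed ×100 definition and the ≤1 magnitudes reported in practice
are both honoured by carrying fraction and percent scales side by side,
with fraction as the default reporting scale. An alternative reading of
the trial statistic (max per-second FCQV instead of the section
fraction) is available via `compute_fcqv` + `max`, but the section
fraction is the default.

## Synthetic data

The generator replaces unavailable teacher clips and patient recordings
in all testing; its defaults are the study conditions.

*Audio.* A fine crackle is modelled as an exponentially damped sinusoid
`a·e^(−t/τ)·sin(2πft)` — the standard parsimonious crackle surrogate —
with centre frequency 650 Hz, τ = 4 ms, duration 10 ms. A trial is
white Gaussian background noise (RMS 0.02) plus bursts at homogeneous
Poisson times (default 8 bursts/s) inside a swallow window placed
within the trimmed region, with the summed burst component rescaled so
its power over the burst support sits a target SNR (default 10 dB)
above the noise power. Ground-truth labels mark every frame whose
sample interval overlaps a burst. Teacher sets default to 50 clips of
1 s, half positive (2–5 bursts each), half noise-only, with exact frame
labels. What this does **not** emulate: physiological swallow acoustics
(laryngeal elevation sounds, bolus-size effects), stethoscope transfer
function, or motion artifacts; room noise is white Gaussian by default
(the simplest controllable null), with a 1/f "pink" option
(`noise_color="pink"`). Passing tests therefore demonstrate the pipeline's mechanics and
detection behaviour under controlled SNR, not clinical accuracy.

*Cohorts.* Covariates are truncated normals shaped like an ALS clinic
population (age 64 ± 11.8; ALSFRS-R total within 18–47; bulbar
sub-score within 4–12; %VC 80.5 ± 20.4; tongue pressure 27.6 ± 16.2 kPa;
MASA totals ≤ 200 / pharyngeal ≤ 70). The index is
`β₀ + Σ βⱼ·covⱼ + ε`, ε ~ N(0, σ), clipped to [0, 1]. Defaults: a
planted 0.006 index-units-per-ALSFRS-R-point effect, σ = 0.06 (the SD
used in the power analysis), intercept −0.025 so the mean index is near
0.21. Recovery/coverage runs use σ = 0.02 so the [0, 1] clipping stays
inactive and the linear model is exactly specified.

## Statistics layer

- Group comparison: two-sided Welch t-test by default (Student's
  variant would assume equal variances that small clinical groups don't
  warrant); χ² without continuity correction for categoricals.
- Two-step factor analysis: simple OLS of the index on each factor;
  factors with p < 0.05 plus age (always) go into one **age-adjusted
  OLS per factor** (index ~ factor + age) — separate small models, not
  one joint model, matching the per-factor reporting convention and the
  n≈24 feasibility of such cohorts. Linear (not logistic) regression is
  the default because the coefficient scale of interest is index units
  per covariate unit; a logistic variant (outcome = index below a
  cutoff) sits behind `family="logistic"`. Collinearity with age is
  guarded by a correlation/condition-number check.
- ROC: AUC is the Mann–Whitney concordance probability; the impaired
  class is expected to have *low* index, with automatic direction
  flipping (reported) if the data run the other way. The cutoff
  maximises Youden's J over observed index values, ties resolved to the
  lower cutoff (favouring sensitivity). AUC is invariant to monotone
  transforms of the index.
- Sample size: smallest even total n such that a two-sided two-sample
  t-test reaches the target power, solved by iterating per-group n with
  noncentral-t power at t critical values. The reference design
  (difference 0.08, SD 0.06, α 0.05, power 0.80) needs 20 participants.

## Problem sizes in the test suite

The suite runs entirely on synthetic data: classifier-level tests use a
16-clip teacher set (0.6-s clips, 40 rounds); the end-to-end checks use
the standard 50-clip/100-round condition with a 20-clip held-out set;
the null-calibration check of the univariate screen uses 1 000
replicates of n = 24 cohorts (band: 3 binomial standard errors); CI
coverage uses 100 cohorts of n = 500; Monte-Carlo power validation uses
10 000 simulated trials. These sizes keep the full suite around
10–15 s while leaving the statistical bands meaningful.

## Known limitations

- The 148-feature layout is a documented, reproducible choice covering
  the named technique families; other layouts of the same size are
  admissible and would yield different coefficients.
- The linear collapse of the boosted ensemble loses the stumps'
  nonlinearity; on synthetic data the loss is small (held-out balanced
  accuracy ≥ 0.9 at 10 dB SNR), but the gap is not bounded in general.
- Clinical reference values (patient index 0.209 ± 0.088, healthy
  0.369 ± 0.111, AUC 0.792, cutoff 0.228) come from unpublished patient
  recordings and are documentation context only — nothing in this
  package reproduces them, and no test asserts them.
- Swallow onset detection beyond the FCQV threshold rule, aspiration
  classification, and device capture are out of scope.
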