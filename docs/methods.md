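# Methods

`wristgait` re-creates, at desk scale and on synthetic signals, a pipeline
for estimating spatio-temporal gait metrics — gait speed (cm/s), stride
length (cm), cadence (steps/min) and stride regularity (unitless, 0–1) —
from tri-axial wrist accelerometry, together with the evaluation and
clinical-classification machinery such a pipeline needs. This note records
the models, conventions and design choices; every empirical number quoted
here is computed by the test suite or by `scripts/acceptance.py`, nothing
else.

## Signal model (the simulator)

Real free-living datasets with multi-sensor stride references are not
shippable; the `simulate` module generates signals whose *statistical
structure* supports the same analyses.

**Walking bout.** A bout is parameterized by `GaitParams`: speed `v`,
cadence `C`, stride length `L` with the kinematic identity

    v = L · C / 120        (C/120 = strides per second)

holding exactly by construction. A stride clock emits stride intervals of
nominal duration `120/C` s perturbed by i.i.d. Gaussian jitter
(`jitter_sd_s`, truncated to ±50 %); each realized stride is annotated with
its start/end, speed `v` and length `v · duration`, so the identity holds
per stride up to timing jitter.

**Wrist channel.** Gravity is projected through a slowly drifting
orientation angle (amplitude 0.15 rad, 0.01–0.04 Hz). Arm swing is a
pendular oscillation at the stride frequency `C/120` Hz, decomposed into a
radial component (along the instantaneous gravity direction, amplitude
`swing_amp_g`) and a smaller tangential component (0.4 ×). The radial
alignment makes the acceleration-magnitude envelope equal to `swing_amp_g`
to first order *independently of orientation*, which keeps the configured
affine coupling

    swing_amp_g = 0.05 + 0.002 · v      (g per cm/s)

invertible from the observable signal — the property that guarantees the
regression problem is solvable and makes parameter-recovery tests
meaningful rather than lucky. A step-impact harmonic (0.1 g at `2C/120` Hz)
and white sensor noise (default 0.03 g) are added.

**Lower-back channel.** The vertical axis repeats a fixed stride template —
sinusoids at the stride frequency and its first two harmonics (relative
amplitudes 1 : 0.4 : 0.2, amplitude 0.3 g) — driven by the same jittered
stride clock. This is the simplest waveform with a well-defined second
autocorrelation peak; timing jitter degrades that peak monotonically, which
is exactly what the stride-regularity label measures.

**Wear-gain variability.** Free-living (default) cohorts additionally draw
a per-subject multiplicative lognormal gain (σ = 0.15) on the wrist
signal's dynamic components, standing in for device wear looseness and
arm-use habits. The gain is independent of mobility by construction: it
corrupts amplitude-based PA summaries of multi-day wear but not
reference-anchored gait labels — the asymmetry that, in real data too,
separates gait metrics from raw activity magnitude. The single-session
`CohortConfig.training()` preset keeps the gain off, emulating a snugly
fitted device in a supervised validation recording; the two presets mirror
the validation-dataset / free-living-cohort split such studies have.

**Cohort.** Each subject draws a standard-normal latent mobility factor
that shifts mean gait speed (+25 cm/s per SD) and cadence (+8 spm per SD),
scales stride-timing jitter (0.015 s · e^(−0.5·latent)), and modulates the
number (Poisson, mean 5 + latent) and duration (14–40 s + 4·latent,
clipped to [12, 60] s) of daily bouts. Disability is the indicator
`latent < Φ⁻¹(prevalence)` (default prevalence 0.3) with a 5 % label-flip
probability so classification is non-degenerate. Wear days are drawn from
a configured range (default 2–7; all simulated days are flagged valid) so
the ≥3-valid-day filter is exercisable. Idle segments (gravity + noise +
occasional movement bursts) separate bouts and carry no stride
annotations; no biomechanical realism is claimed for them.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: soft-tissue and impact transients, turning,
inclines, device micro-movement, inter-device clock skew, non-walking
activities resembling gait (cycling, stirring), missing data and non-wear.
The recovery results bound what the architecture can learn when the signal
carries the information; they say nothing about wrist signals where the
coupling between swing and speed is weaker or non-affine.

## Windows and reference labels

Recordings are resampled to 30 Hz (polyphase FIR; gait content is well
below the 15 Hz Nyquist limit). Each bout *strictly* longer than 10 s is
cut into 10-s windows hopping by 1 s (90 % overlap), anchored at the bout
start, trailing partial windows dropped; a 10.0-s bout therefore yields no
window, and the count for duration `d` is `floor((d−10)/1)+1`. Windows
never span bouts.

Per window: speed and stride length are the **median** over complete
strides (start and end inside the window; even-count median = mean of the
central pair); cadence is `12 × N` steps/min for `N` complete strides (one
stride = two steps, 10-s window → ×6 per-minute stride rate, ×2 steps) —
note the label is therefore quantized in steps of 12 spm; regularity is
the Moe-Nilssen index of the lower-back vertical segment: demean, scale to
unit variance, unbiased autocorrelation A(m) = Σxᵢxᵢ₊ₘ/(N−m) normalized by
A(0), evaluated at the second dominant peak searched within ±25 % of the
mean stride lag, clipped to [0, 1]. For an exactly periodic signal with an
integer number of periods in the window the index is exactly 1 (the
acceptance script recomputes this analytic value). A window with no
complete stride carries invalid flags rather than imputed values.

The cadence-wording note: a literal "divide the stride count by the 10-s
window and multiply by six" gives 0.6·N, which cannot be steps/min; the
implementation uses 12·N (strides → steps → per minute), the only reading
consistent with the stated unit.

## Biomechanical baseline

Five predefined features of the magnitude signal per window: cadence
estimate (120 × dominant spectral peak in the physiologic stride band
0.3–1.5 Hz, spectrum zero-padded ×8), acceleration energy (variance),
mean absolute jerk (mean |Δm|·fs), hand-swing intensity (RMS of the ±0.2 Hz
band around the stride peak), and mean acceleration norm. Altitude-change
features are excluded (no barometric channel). Exact formulas for this
comparator family are not standardized; these are conventional readings of
the feature names, stated so the comparator is reproducible, and computed
on the magnitude (not per-axis) signal. The default regressor is
gradient-boosted trees with a linear fallback; the noiseless-coupling
recovery check uses the linear variant because the coupling is affine by
construction and tree ensembles do not extrapolate across unseen subject
means.

## Neural regressor

Because the pipeline must run on a single CPU in minutes, the network is a
compact 1-D residual CNN (~100k parameters) implemented in numpy with
explicit backpropagation (`wristgait.nn`): a stride-2 stem convolution,
three residual blocks (16/32/48 channels, kernel 9, stride 2 each, batch
norm), global average pooling, then a three-layer fully connected adapter
emitting a fixed 128-d feature, and a 0–3-layer scalar head per outcome.
Float32 compute; all initialization, shuffling and dropout flow through a
seeded generator, so training is bit-reproducible. Checkpoints snapshot
parameters *and* batch-norm running statistics — restoring weights without
their matching normalization statistics silently corrupts a model.

**Self-supervised pretraining.** Three binary pretext tasks, each applied
independently with probability 0.5 per window: time reversal, random
non-identity axis permutation, and smooth sinusoidal time warping (±4–10
samples). One linear head per task on the 128-d feature; joint loss is the
sum of the three binary cross-entropies. These tasks are this package's
concrete instantiation of multi-task SSL for accelerometry. Since no
large-scale pretrained backbone exists at desk scale, SSL trains backbone
and adapter jointly (freezing remains available and is contract-tested:
a frozen backbone is bit-identical before and after training).

**Fine-tuning.** Per outcome, end-to-end, L1 loss on a standardized
target, Adam (lr 1e-3, batch 64), subject-grouped 20 % validation split,
early stopping with patience 5, best-validation checkpoint kept.
Hyperparameter search is pure random search under 5-fold subject-grouped
(optionally cohort-stratified) CV, selecting the lowest mean validation
MAE — deterministic for a given seed, which matters more at desk scale
than sampler sophistication.

**Stride-length fusion.** Stride length is predicted directly and derived
kinematically as `120 · v̂ / Ĉ`; the final estimate is the simple average,
which always lies between the two.

## Evaluation stack

MAE, RMSE, MAPE (%, reference-zero pairs excluded and counted), R². Method
agreement: ICC(2,1) — two-way random effects, absolute agreement, single
measurement (computed via pingouin; the test suite checks it against a
brute-force ANOVA mean-squares oracle) — and Bland-Altman limits of
agreement (mean ± 1.96 sample SD) on bout-level unweighted means of window
values. Metrics are aggregated per subject first; cohort summaries are the
median and [25th, 75th] percentiles across subjects with linear
interpolation. Model comparison: Shapiro-Wilk per column (logged,
informational — the nonparametric path is always taken), Friedman omnibus
for ≥3 models gating post hoc two-sided Wilcoxon signed-rank tests (exact
null for ≤25 pairs, normal approximation with continuity correction above,
zero differences dropped), Bonferroni adjustment `min(1, p·m)`.

## Clinical utility stage

Subjects with fewer than 3 valid wear days are excluded (inclusive
boundary; "valid day" is an explicit simulator flag here, and for real
data would be a configurable wear-time rule, e.g. ≥18 h). Per subject,
each gait metric is summarized by mean, median, sample SD, excess
kurtosis, skewness, range and the 10th–90th deciles, at window level and
at bout level; free-living regularity is recomputed from the wrist signal
alone with the autocorrelation lag taken from the estimated cadence, since
no stride annotations exist in daily life. PA features apply the same
statistics to the acceleration magnitude per day (whole recording and
walking segments), then average across days. The supervised-assessment arm
is emulated as two short instrumented walks per subject summarized by
per-test means. Classification is an XGBoost classifier under nested CV
(5-fold inner randomized search, 10-fold outer, stratified; one feature
row per subject makes partitioning subject-wise by construction), fold
AUCs compared across feature sets with the Friedman/Wilcoxon machinery.

The ordering experiments feed the classifier *reference* window labels as
the daily-living gait metrics, so the feature-set comparison measures the
information content of gait summaries vs PA summaries rather than
compounding network error; this is the package's design choice for those
experiments.

## Experiment scales and scope of the checks

Problem sizes are the package's own desk-scale study conditions: recovery
runs use 100 single-day subjects (~7,000 overlapping windows, 80/20
subject split); the label-scarcity comparison pretrains on a 30-subject
unlabeled pool and fine-tunes on 10 labeled subjects whose windows are
thinned to a 5-s hop — with the full 1-s hop, ten subjects contribute ~600
near-duplicate windows and are effectively label-rich, which would test
redundancy rather than label scarcity; the feature-set ordering uses
60-subject multi-day cohorts over five seeds; the label-permutation null
for classification is estimated over 15 permutations because a single
permuted 40-subject cohort has a held-out-AUC SD of ~0.14. Thresholds quoted in the
acceptance tests (R² ≥ 0.95 noiseless baseline, ≥ 0.8 network speed and
cadence, ≥ 0.6 fused stride length; orderings; chance-level negative
controls) are repository acceptance values for these synthetic conditions,
not claims about any real cohort.

## Known limitations

- The numpy network trains on one CPU; it is intentionally small and makes
  no claim of matching large pretrained accelerometry backbones.
- Cadence labels are quantized (12 spm); the network can exceed the naive
  quantization ceiling only because overlapping windows share information.
- Regularity in the default cohort spans a narrow high range (~0.95–0.99);
  discriminating regularity models is therefore not a sensitive test here.
- The disability construct is a generic latent-threshold label, not any
  specific clinical instrument's dichotomization.
- The idle/arm-movement model between bouts is a stand-in with no claim of
  realism; bout boundaries are always taken from annotations, never
  detected.
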