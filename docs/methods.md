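# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `sleepscope`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The analysis chain

### Saccade detection and kinematics

Eye-angle traces (radians, uniform grid) are preprocessed in three steps: a
200 s running mean is subtracted (slow-drift baseline; a literal 200 s
smoother would erase saccades, so the mean is interpreted as a baseline), a
1.5 s running median suppresses impulsive noise, and a fused-lasso
(1-D total-variation) filter with λ = 0.25 produces a piecewise-constant
estimate. λ is defined per sample at the native rate. The TV solver is a
direct taut-string sweep returning the exact minimizer of
½Σ(yᵢ−xᵢ)² + λΣ|xᵢ₊₁−xᵢ|; the test suite checks it to 1 × 10⁻⁶ against an
independent convex solver (the dual box-constrained least-squares problem
solved by `scipy.optimize.lsq_linear`).

Conjugate saccade candidates are local maxima of the product of left and
right eye velocities (central differences of the denoised traces) above
0.32 rad²/s² (single-animal recordings) or 0.60 rad²/s² (multi-animal),
greedily pruned to a 1.5 s minimum inter-saccade interval. Candidates are
accepted when the rolling interocular Pearson correlation (5 s window)
exceeds 0.5 and the rolling mean absolute fused-lasso residual (15 s window,
both eyes pooled) stays below 0.45 rad.

Scoring works on the raw trace. Onset/offset are the last/first samples
around the velocity peak where the raw binocular speed falls below 10% of
the peak (the raw trace is used because the running median erases the brief
high-velocity portion of the saccade, and the offset must land after it so
the post-saccadic amplitude A = raw(offset) − baseline is measured at the
plateau; baseline = median over 1 s pre-onset). The fixation duration is the
time from offset to the first crossing of baseline + 0.33 A; the decay slope
is the absolute OLS slope of the raw angle from offset up to the last sample
still above that threshold (the first sub-threshold sample belongs to the
movement that ended the fixation and would bias the estimate); events cut
short by the next saccade or the end of quiescence are censored at that
boundary. Peak speed is the largest absolute central-difference velocity
between onset and offset, per eye, averaged binocularly and reported in
deg/s.

### Sleep periods and substate classification

Sleep is rolling locomotor speed (5 s window) below 0.5 mm/s for at least
60 s. Periods are cut into 60 s bins; a terminal remainder ≤ 30 s merges
into the preceding bin, a longer remainder stands alone, so every bin lasts
60–90 s except a possible 30–60 s terminal bin. Per bin: saccade count, mean
decay slope, mean fixation duration (censored fixations enter at their
censored value; saccades are assigned to bins by onset time). Bins without
saccades are QNEM by rule.

Saccade-containing bins are classified by a 3-component diagonal Gaussian
mixture. Features are log-transformed and then z-standardized before the
fit, and the transform is recorded in the serialized model. The log
transform matters: all three features are positive and right-skewed, and in
linear feature space the EM spends a component on the heavy fixation tail
instead of the substates. EM is initialized diagonally dominant (+1 SD on
the component's own feature). Components map to substates by their implied
raw-scale means exp(μ + σ²/2): highest count → QEM-1, steepest slope →
QEM-2, longest fixation → QEM-3. The raw-scale (rather than log-scale)
comparison is essential for the fixation axis: a heavy-tailed component can
carry the largest mean fixation while its median is modest. Model order is
supported by the sample-size adjusted BIC, SABIC(k) = −2 log L +
p·ln((n+2)/24), reported for k = 1..6.

A fitted mixture can be frozen to JSON (standardization, parameters, and
component map) and re-applied to other recordings, mirroring reference-fit
reuse across conditions and species.

### Circadian gating model

State probabilities per 1-min step are modeled from four inputs —
luminosity (0/1), introduction-to-chamber (1 on the loading day), and
cos/sin of clock time with a 24 h period — through a 4 → 24 → 1 → 24 → 5
bottleneck network with sigmoid activations (ReLU available) and a softmax
output. The scalar latent forces all five state probabilities onto a single
ordered axis. Training is full-batch Adam (learning rate 3 × 10⁻³, at most
800 epochs, early stop after 60 epochs without a 10⁻⁴ loss improvement) on
cross-entropy, in float32; these optimizer settings are the package's own
(chosen for single-CPU ensembles), and the implementation is a small
self-contained numpy network. Fitting is k-fold cross-validation over fish
with repetitions; performance is the Pearson correlation between model and
observed per-state probabilities (fraction of held-out fish per minute,
smoothed with a 30 min moving average). Ablations permute one input in time
(cos and sin jointly for the circadian pair) with identical folds; the drop
in held-out r with a paired signed-rank test measures that input's
contribution.

### Neural post-processing

Duplicate sources (≤ 4 µm apart in every dimension and correlated > 0.8 on
co-observed samples) are grouped transitively; the best-covered member of
each group survives. Neurons observed in fewer than 50% of samples are
dropped. Bleaching is removed per neuron by least-squares fitting
A·e^(−t/τ) + C (A ≥ 0, τ > 0) on observed samples and subtracting the
decaying part. Missing samples are linearly interpolated before PCA,
decoding and event detection. Transient events are runs above
mean + 2 × noise SD of the baseline-subtracted trace lasting ≥ 2 s, with
events closer than 6 s merged into one spanning both; the baseline is the
mean of samples below the rolling 10th percentile (centered 45 s window) and
the noise SD is the RMS of median-centered negative deviations — the
median-centering is needed because deviations below a *low-percentile*
baseline are a truncated tail whose naive SD underestimates the noise by
about 2× and floods flat traces with false events. Per-state event rates
are events per second of each state instance, averaged over instances;
neurons above 0.014 events/s in both compared states are flagged
dual-active.

### Encoding models, ramps, enrichment

Each neuron is regressed on nine series: speed, roll, pitch, left/right eye
angle, turn bias (heading change convolved with a σ = 8 min Gaussian), a
QEM-1 indicator, its within-period integral (seconds, reset at each period
start — the onset kernel is per-period, so a per-period integral is the
consistent choice), and an onset impulse convolved with an exponential
kernel of τ = period duration / 15. Fits use 10-fold blocked (contiguous)
cross-validation; partial models permute one regressor group in time
(eyes, turn bias, or the QEM-1 triple — preserving the parameter count) on
identical folds, and a group is significant when the drop in mean held-out
R² exceeds twice the SE of the full model's per-fold R². Rank-deficient
designs fall back to a tiny ridge (10⁻⁶) with a flag.

Ramp classification: activity in each QEM-1 period ≥ 3 min is linearly
resampled to 1000 points of relative time, averaged across periods, min-max
normalized to [0, 1], and fit with a·e^(−t̃/b) + c against
a·(1 − e^(−t̃/b)) + c by bounded least squares (multiple starts for b); the
higher R² decides ramp-down vs ramp-up. Bounds are 0 < a ≤ 2 and
0 < b ≤ 2000: the amplitude bound must exceed 1 because a min-max normalized
exponential has a = 1/(1 − e^(−1/b)) > 1 exactly; a unit bound would forbid
the true model and bias b low. A literal reading of the exponent as
−1/(b·t) is available behind a flag; the default e^(−t̃/b) is the only form
under which sub-unit time constants on relative time are meaningful.

Anatomical enrichment: per region, P(X) = n_pos/n_tot; each of 100 null
draws samples n_tot(X) neurons without replacement from the whole population
and computes P₀(X) the same way; E(X) = P(X)/mean(P₀); a region is
significant per fish when P(X) > P₀(X) in at least 95 draws, and across fish
when at least ⌈0.7·n⌉ fish agree. Sampling n_tot(X) neurons (not n_pos) is
the only convention under which a region containing all neurons gives
E = 1 exactly and the expectation oracle E[P₀] = overall positive fraction
holds.

### Population dynamics

State PCA reduces each period to a neuron × 10 decile-mean matrix, averages
the matrices across periods, and takes the top two principal components of
the mean matrix (signs fixed so scores increase with within-period time);
the full experiment is projected onto this plane. Entanglement smooths one
period's 2-D trajectory (Gaussian, σ = 12.5 s), forms N−1 segments, counts
unordered pairs of non-adjacent segments that properly intersect (iterating
unordered pairs once is equivalent to halving a double-counted enumeration),
and divides by the period duration. Relative-time decoding z-scores
activity within the state, averages each eligible period (≥ 3 min) into 100
relative-time bins, trains an elastic net (mixing ∈ {0.1, 0.5, 0.9},
penalty ∈ 10⁻⁴..1, inner leave-one-training-period-out selection) on all
periods but one, predicts the held-out period, applies a scalar gain fit on
the other folds, and pools R² against the 0 → 1 ramp. Neurons with
consistently signed median weights across fits are the consistent ramp-up
(positive) and ramp-down (negative) populations.

The circular-shift control shifts each neuron independently within each
state period by an offset uniform over the *full* period. This is a
deliberate design point: excluding a band of small shifts (for example,
enforcing a 30 s minimum) leaves the ensemble mean of the shifted traces
time-dependent — the mean of g(t−s) over a truncated shift distribution is
not constant — and a linear decoder reads that structure across periods
(measured R² ≈ 0.5 on ramp populations). Full-circle shifts preserve lag-1
autocorrelation while collapsing decoding to R² ≈ 0.

## The synthetic-data generator

No raw recordings ship with the package (the source data are tens of
terabytes, available only on request), so the generator is first-class,
tested code that defines the study conditions.

**State schedules** are semi-Markov: states are drawn per segment with
probabilities given by occupancy targets (per light phase if desired),
segment durations uniform on 2–6 min, truncated at light transitions.
Quiescent segments always last ≥ 60 s.

**Saccades.** The published per-substate numbers constrain the waveform
more than is first apparent, because three of them are measured from the
same decay:

* a peak speed of 849 °/s cannot be expressed by a monotone rise to a small
  post-saccadic amplitude at 50 Hz (a central difference can report at most
  A·fs/2), so the rise overshoots: a yoked linear rise at the sampled peak
  speed to n·(v/fs) ≥ A + 3°, then a fast settle onto the plateau A;
* a decay slope of 0.32 °/s with a fixation of 4.9 s implies the 33%
  crossing is not produced by the slow decay itself (that would take ~25 s
  at the default amplitude), so each eye holds the slow linear decay for a
  solved hold time and then makes a fast return plunge; the hold is chosen
  per eye so the crossing lands exactly at the sampled fixation duration
  (steep decays that cross during the hold are logged at their actual
  crossing time);
* the two eyes are similar but not sample-identical: plateau amplitude
  (±8%), decay slope (sign-split ±10–30%) and plunge speed (±15–30%) carry
  mean-preserving per-eye jitter, and the plunges are staggered by
  ±0.2–0.35 s. Perfectly yoked slow ramps would be quantized by the fused
  lasso into time-aligned steps in both eyes — spurious conjugate velocity
  events — and a shared plunge would be detected as a saccade; the
  staggered monocular plunges keep the velocity product at zero.

Kinematics are drawn per saccade: amplitude and peak speed from
symmetrically truncated normals (mean-preserving), decay slope and fixation
duration from lognormals at the published (mean, sd) — the published QEM-3
fixation dispersion exceeds its mean, so any symmetric distribution would
need mean-shifting truncation. Fixations are floored at 2 s (shorter
plateaus are erased by the 1.5 s running median and cannot be recovered by
any detector behind that filter). Inter-saccade gaps are
gap₀·((1−regularity)·Exp(1) + regularity) with gap₀ solved so the mean
interval matches the preset rate, floored at 1 s of per-eye baseline so the
running median can return between events. At the QEM-1 parameters the cycle
is nearly saturated by the fixation itself, so the realized rate is ~9.6–9.9
saccades/min against the nominal 10.2 — a ~4% structural shortfall that the
detector recovers exactly (injected and detected rates agree).

Free parameters not printed anywhere: plateau amplitude 12 ± 3° for all
three substates and QEM-2/3 peak speeds 500 ± 150 °/s. The amplitude value
balances two failure modes measured against the chain: large plateaus
inflate the OLS slope window's plunge contamination, small ones drop the
filtered step below the detection threshold.

**Wake** segments carry ~0.4 s swim bouts (sinusoidal speed bursts,
5–30 mm/s, interbout ≈ 1 s) with bout-coupled saccades and sustained
AR(1) turn bias in the heading; quiescent speed stays below 0.5 mm/s.

**Head frames** render two soft-edged dark ellipses (0.20 × 0.10 mm, ~1 px
skirt) on a noisy lighter background in a 0.9 mm egocentric ROI, body axis
along rows, at 20 or 50 µm/px; ground-truth angles and centers go to a JSON
sidecar. At 50 µm/px the eye is ~4 × 2 px and the moment-based angle is
quantization-bound: mean recovery error stays under 2° over ±30° while
single-frame extremes can reach ~2.5°.

**Neural populations** mix suppressed cells (mean drop in QEM-1), ramp-down
cells following e^(−t̃/τ) of relative time within each QEM-1 period
(τ ~ N(0.91, 0.03)), ramp-up cells (1 − e^(−t̃/τ)), event cells emitting
boxcar transients, and noise cells; multiplicative bleaching, Gaussian noise
and a random missing mask are applied last, and class labels, time
constants and event times are logged.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis assumes —
state-dependent saccade processes, quiescence thresholds, ramping and
suppressed populations, bleaching, missing samples — but not free-swimming
kinematic richness (smooth pursuit, vergence dynamics, tail-driven artifact
coupling), non-stationary substate kinematics, real photon noise, or neural
correlations beyond the modeled classes. Passing recovery tests therefore
demonstrates that the pipeline is a consistent estimator of its own
generative model at the published parameter values, not that it would
extract identical numbers from raw video or volumetric imaging.

## Problem sizes

Tests run the behavior chain at 10–50 Hz on minutes-to-hours of synthetic
data, neural analyses at 2 Hz with 50–125 neurons, the circadian ensemble
at 6–20 fish with 5-fold × 1–2 repetitions, and calibration batteries at
500 noise neurons / 500 regions; `scripts/acceptance.py` uses 200 min of
QEM-1, 60 min of QEM-2, 120 min of QEM-3 at 50 Hz and 20 repetitions of the
600-bin mixture-order selection. These sizes are the package's own choices;
all scale linearly if larger runs are wanted.

## Known limitations

* The QEM-3 recovered mean fixation carries ≈ 10% sampling noise at the
  120 min scale: the published dispersion (14.9 s) exceeds the mean
  (9.7 s), so the SE of a ~210-saccade mean is ~1 s for any draw
  distribution with that sd.
* The recovered decay slope carries a small positive bias for shallow
  decays (~+0.03 °/s for QEM-2, ~+0.03–0.16 for QEM-3 depending on
  fixation length) from residual plunge samples inside the OLS window.
* At 50 µm/px the eye-angle error is quantization-dominated; sub-degree
  accuracy needs the 20 µm/px scale.
* The circadian model deliberately has no history dependence; conditions
  whose state distributions depend on prior nights are out of scope.
* The substate mixture is fit and applied on log features; a frozen model
  records this, and models serialized by other tools without the transform
  flag are interpreted as linear-space fits.
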