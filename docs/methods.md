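# Methods

`glyco` reconstructs clean, uniformly sampled glucose–insulin time
series from noisy free-living insulin-pump/CGM exports and detects
unannounced meal and physical-activity events with recurrent sequence
classifiers. This note documents the models, the numerical choices, and
what the synthetic study does and does not demonstrate.

## Data model and gridding

All processing happens on a uniform 5-minute grid (the native CGM
sampling period). Time is Unix seconds UTC; glucose is held internally
in mg/dL (18.0182 mg/dL per mmol/L); missing samples are NaN with a
parallel per-channel provenance code (observed / imputed / rejected /
missing). The grid is anchored at the first observation rounded down to
a multiple of 300 s from midnight UTC so that time-of-day structure
aligns across days. Raw observations snap to the nearest grid point
(exact midpoints toward the earlier point); when two observations of one
channel land on the same point the first wins, which is also the
duplicate policy at parse time. Basal rate is a pump *setting*, so it is
expanded piecewise-constant from each recorded change to the next.
Square/dual-bolus `duration` is carried as metadata; bolus insulin is
assigned wholly to its start sample.

## Outlier rejection

CGM artifacts are removed with physiological rules rather than
statistical fences: (a) outside the 0–400 mg/dL calibration range;
(b) a rise of more than 30 mg/dL per sample with no carbohydrate entry
in the trailing 10 samples; (c) a drop of more than 30 mg/dL per sample
with neither a bolus nor recorded activity in the trailing 7 samples;
(d) disagreement with a concurrent fingerstick by more than 18 mg/dL.
Rules apply sequentially in one forward pass (a rejected sample cannot
anchor the next sample's difference), which makes the pass idempotent.
Sparse diary channels treat "no record" as zero inside the rule windows.
The drop rule is the mirror image of the rise rule and requires *both*
explanations to be absent; reading the two conditions independently
would reject essentially every large drop, since boluses and activity
rarely co-occur. An inner-Tukey-fence count (±2.72 SD) is reported as a
diagnostic only: CGM is skewed, and fence-based deletion would remove
genuine hypo- and hyperglycemia.

## Imputation

*Basal*: forward fill (backward fill at the series head) for gaps up to
2 h; longer gaps copy the value 288 samples (24 h) earlier, because
basal schedules repeat daily; if that sample is also missing the gap
remains. *Sparse channels* (bolus, carbohydrate, fingerstick, durations,
distance): median of the observed samples, which is 0 for genuinely
sparse event channels. 

*CGM* is imputed with probabilistic PCA on lagged matrices. Column *j*
stacks the trailing 25 samples (2 h) of five variables — CGM, total
delivered insulin (basal per sample + bolus), carbohydrate, energy
expenditure, activity duration — giving M = 125 rows. The model is
x_j = W t_j + μ + ε with isotropic noise ε ~ N(0, σ²I) and t_j ~ N(0, I_q),
fitted by EM over the observed cells only (Rubin–Thayer style): the
E-step posterior per column uses the rows observed in that column,
Cvar_j = σ²(σ²I_q + Σ_{i∈η_j} W_i W_iᵀ)⁻¹; the M-step updates μ, W, σ²
as exact conditional maximizers under that posterior, so the
observed-data log-likelihood is non-decreasing (verified per iteration
in the tests). Because σ² is shared across rows, the variable blocks are
standardized to unit scale before fitting (activity is in milliseconds,
CGM in mg/dL) and unscaled on reconstruction. Each missing CGM grid
sample appears in up to 25 (lag, column) positions; its estimate is the
unweighted mean of all reconstructed occurrences (diagonal averaging).
Runs longer than 25 consecutive missing samples are left missing —
extrapolation across multi-hour sensor dropouts is unreliable, and the
detectors exclude unimputed windows instead. Defaults: q = 10 (the
latent dimension is not critical; it must capture multi-lag structure
while q ≪ 125), tol 1e-6 on the relative change of σ² and ‖W‖_F,
max_iter 500, seeded Gaussian initialization of W.

## Denoising (singular-spectrum analysis)

Each maximal run of q_i consecutive CGM samples is embedded in a
w_i × p_i Hankel matrix (p_i = ⌊q_i/2⌋, w_i = q_i − p_i + 1), its SVD
truncated, and the run recovered by anti-diagonal averaging (the exact
inverse of the embedding when nothing is truncated). Components are
retained until the cumulative normalized singular-value spectrum reaches
0.95, *including* the component that crosses the cut and always at least
one. Retention must include the crossing component: an exactly rank-2
signal (a sampled sinusoid) concentrates η ≈ [0.5, 1.0], and excluding
the crossing component would delete half the signal instead of the noise
tail. Runs shorter than 4 samples pass through. Ordering: rejection
first (it creates gaps), imputation second, denoising last on the
reconciled series.

## Physiological model and state estimation

The glucose–insulin dynamics are the Hovorka compartment model:
subcutaneous insulin absorption S1→S2 (time constant t_maxI), plasma
insulin I with elimination k_e, three remote insulin actions x1–x3
(distribution, disposal, EGP suppression), glucose masses Q1/Q2, and
sensor glucose Gsub lagging plasma glucose with time constant τ.
Nominal parameters follow the standard published set; per-kg fluxes
(EGP_0 = 0.0161, F_01 = 0.0097 mmol·kg⁻¹·min⁻¹) scale with body weight,
V_g = 0.16·BW, V_I = 0.12·BW. The parameter table gives no nominal τ or
t_maxI; the standard companion values τ = 15 min and t_maxI = 55 min are
used (configurable). Renal clearance above 9 mmol/L is scaled by V_g for
unit consistency (it removes mass from Q1), and EGP is clamped at zero
when x3 > 1. Body weight is estimated as the modal daily insulin total
(complete days, rounded to 1 U, smallest mode on ties) divided by
0.5 U·kg⁻¹·day⁻¹.

Integration is fixed-step RK4 at 60 s (halving the step changes Gsub by
< 0.01 mmol/L over a day), with inputs held constant within each 5-min
grid interval.

For estimation the state is extended with t_maxI, k_e and U_G (gut
absorption). A bootstrap particle filter (N_s = 500 default) propagates
the ensemble through the model plus Gaussian process noise, weights by
the CGM likelihood (R = 0.04 (mmol/L)², matching a ~3.6 mg/dL sensor
noise SD), normalizes, and resamples systematically when
N_eff = 1/Σw² < N_s/2 (resampling on *every* step would needlessly
impoverish the ensemble). Particles are clipped to physiological bounds
(Gsub ≤ 33.3 mmol/L, I ≤ 300 mU/L, all states non-negative). Process
noise is ~1% of nominal state magnitudes for the physical states and
random-walk scales of 0.1 min, 2e-4 min⁻¹ and 0.5 mmol/min per step for
t_maxI, k_e and U_G. The U_G walk is what lets the filter infer
unannounced meals from CGM alone. Two estimation details matter:

* the augmented parameter states revert to their nominal values with a
  360-min time constant. A free random walk is unidentifiable here —
  the U_G walk can absorb any glucose mismatch, so k_e/t_maxI drift and
  bias the plasma-insulin estimate; gentle mean reversion keeps
  adaptation while bounding the drift;
* U_G is also reported with an 8-sample fixed-lag smoother (the
  resampling genealogy is carried through a short buffer). The causal
  filtered estimate peaks systematically late because glucose responds
  to absorption through two lags (Q1 integration and the sensor lag τ);
  the smoothed estimate centers the absorption bumps. Peak timing is
  extracted from the smoothed trace with a 9-sample centered moving
  average and prominence-based peak picking — the bump tops are flat,
  so a raw argmax wanders on noise wiggles. A meal's absorption peaks
  t_maxG after intake by construction, so implied meal start = peak
  time − t_maxG.

In a twin experiment (simulated day, three meals, 3 mg/dL sensor noise,
perturbed ensemble initialization) the filter recovers plasma insulin
with RMSE of a few percent of its range and meal starts within ±3
samples (15 min).

## Features and selection

Per sample: raw CGM and total insulin; 4th-order backward-difference
first/second derivatives (stencils (25,−48,36,−16,3)/12 and
(45,−154,214,−156,61,−10)/12, undefined where the window is incomplete);
sign and magnitude products of the derivatives; trailing-24-sample
statistics of CGM (mean, variance, SD, median, skewness, min, max,
range) plus covariance, Pearson correlation and Gaussian-kernel
similarity for the pairs (CGM,d1), (CGM,d2), (d1,d2) — zero-variance
correlation defined as 0, kernel bandwidth from the median pairwise
window distance; the magnitudes and frequencies (cycles/day) of the top
three local maxima of the mean-removed periodogram of the trailing 24-h
window (padded with (0,0)); and the particle-filter PIC and U_G
estimates. Thirty-one features in total; every feature is causal, and
any row whose contributing windows touch a missing sample is flagged
invalid (never zero-filled). Standardization statistics come from
training rows only.

Selection is two-step. First a marginal deviance screen: each feature's
single-feature multinomial logistic model against the intercept-only
model by likelihood-ratio test (df = 3), dropping p > 0.05 and constant
features. Second, sequential floating forward selection scored by
stratified cross-validated accuracy of a random forest (30 trees, depth
6), with conditional backward exclusion, returning exactly 20 features
(ties in CV score break toward the earlier candidate to keep the
procedure deterministic). On sparse one-sample event labels the
derivative-family features carry little *same-sample* marginal signal —
a meal's CGM response appears after the labeled sample — so on short
synthetic studies fewer than 20 features may survive the screen; the
selector then returns all survivors with a warning, as specified.

## Labels

T(k) = ⌈AD(k)/3×10⁵⌉ converts an activity entry's milliseconds into
samples. Samples in [k, k+T(k)−1] are exercise; the span is
meal+exercise when a carbohydrate entry falls in [k+1, k+T(k)] (the
window as printed; a config toggle also admits sample k). Outside spans,
a sample with a carbohydrate entry is a meal, else background.
Overlapping spans union; a sample covered by both a meal-span and a
non-meal span resolves to meal+exercise. Labeling is independent of CGM
and verified against a literal set-builder construction on random
sequences.

## Detectors

Windows of 24 consecutive valid feature rows predict the class of their
last sample ("one sample backward": the event's effect must be visible
before it can be recognized). Four architectures, all ending in a
4-way softmax: (a) masking layer + LSTM + two dense layers; (b) two
Conv1D+max-pool blocks along the lag axis (features as channels), then
LSTM + dense; (c) a ConvLSTM on the 1×1 spatial grid the input shape
prescribes — where the convolutional gates reduce exactly to dense
gates — + dropout + two dense; (d) the conv stack of (b) with a
bidirectional LSTM (whose recurrent parameter count is exactly twice
(b)'s, satisfying the ≥ 54% overhead the architecture comparison
expects). ReLU in conv/dense layers, conventional sigmoid/tanh gates in
the recurrent cells, L1 penalties on all weights and biases, dropout
(including variational recurrent dropout in (a)).

No deep-learning framework is assumed: the layers are implemented in
NumPy with manual backpropagation (gradients verified against central
differences to ~1e-6 relative) and seeded Adam, so training is bitwise
reproducible. Unstated sizes default to LSTM width 64, dense 32, conv
filters 32/64 with kernel 3 and pool 2, dropout 0.2, L1 1e-4, learning
rate 1e-3 (5e-4 for convolutional models, which prefer smaller steps),
batch size 2% of the training split, early stopping on validation loss.

Training protocol: the chronologically last 12.5% of windows is the test
split (free-living data — a random split would leak across time);
stratified 6-fold CV inside the development split; inverse-class-size
sample weights (total/(4·class size)); several seeded restarts per fold;
metrics reported as mean (SD). Evaluation: accuracy, per-class
precision/recall/F1, support-weighted F1, and the 4×4 confusion matrix.

## Synthetic data generator

The generator defines the study conditions. A scenario draws events from
time-of-day probability profiles over 48 half-hour bins: three daily
meals (modes 08:00, 12:30, 18:30, SD 45 min; log-normal sizes, median
45 g, σ = 0.35), exercise on ~40% of days (30–60 min, late-afternoon
mode), a two-level basal profile (0.33 U/h day, 0.30 U/h night), boluses
at carb ratio 30 g/U, and a 5% chance an event goes unlogged — an
unreported meal also receives no bolus, which is precisely the
unannounced-event failure mode the detectors target. The dosing is
chosen to be *consistent with the model's* insulin sensitivity (the
nominal parameter set is far more insulin-sensitive than a typical
adult, so population-typical carb ratios would drive simulated glucose
to zero); with these defaults the rendered glucose has mean ≈155 mg/dL
with realistic hypo/hyper tails. CGM = Gsub·18.0182 + AR(1) noise
(SD 7 mg/dL, ρ 0.7). Corruption injects dropout gaps to a target 8%
missingness (geometric lengths plus occasional 30–60-sample gaps beyond
the imputation cap), isolated spikes that violate the outlier rules
(each ledgered with its rejectability), stuck-sensor duplicates, and
twice-daily fingersticks with bias. Ground truth — clean CGM, true
labels including unreported events, and the defect ledger — is always
returned alongside.

What passing on this generator does **not** show: real sensor error is
not AR(1)-Gaussian (calibration drift, compression lows), real meals
vary in absorption dynamics, real behavior is weekday/weekend
structured, and the generator's physiology *is* the estimation model
(no structural mismatch except the corrupted channels and the estimated
body weight). Results on it validate the machinery, not clinical
performance.

## Problem sizes in the shipped experiments

The test suite and the acceptance script run the full pipeline on 14
simulated days with 300 particles, a 24/16/16-24 network, 2 CV folds and
single-seed training, and the component experiments on single days or a
few hundred samples; these sizes were chosen so the whole battery runs
in minutes while every check still exercises the full code path. All
defaults scale up by configuration.

## Known limitations

* Per-subject Hovorka parameters are not fitted; only body weight is
  estimated from insulin totals.
* The marginal deviance screen is blind to features whose association
  with events is lagged (see above); a lag-aware screen would be a
  natural extension.
* The ConvLSTM implementation covers the 1×1 spatial grid used here,
  not general spatial inputs.
* Timezone handling is a fixed UTC offset; vendor-specific pump export
  dialects are out of scope.
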