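# Methods

This note documents the models, parameter defaults and numerical
conventions behind `actimet`, in the spirit of the methods documentation
of packages like statsmodels or msprime: what is computed, under which
assumptions, and what a passing test does and does not establish.

## 1. Calorimetry criterion

Breath-by-breath VO₂/VCO₂ records are assigned to consecutive left-closed
10-s bins (bin count = ⌊span/10 s⌋), per-bin means are taken, empty
interior bins are linearly interpolated, and the series is smoothed with a
60-s moving average. The average is **centred** with shrinking windows at
the edges (a trailing variant is available via `centred=False`); for the
even six-bin width the extra bin sits on the trailing side. Whether the
original instrumentation pipeline centred its average is not knowable from
the outside; centring was chosen because it keeps the criterion aligned
with the window grid instead of lagging it by 30 s.

EE uses the abbreviated Weir equation, EE = 3.941·V̇O₂ + 1.106·V̇CO₂
(kcal/min, L/min), ignoring urinary nitrogen — standard for portable
calorimetry. Resting EE uses Schofield's weight-and-height equations for
ages 3–10 y (male 0.082·W + 0.545·H + 1.736, female 0.071·W + 0.677·H +
1.553, MJ/day; ×239.006 → kcal/day), since sex, height and mass are the
available predictors. METs = EE / (REE/1440).

## 2. Feature catalog

118 features per 10-s window: 28 statistics per axis and per vector
magnitude, three cross-axis Pearson correlations, and tilt/roll/pitch from
the window-mean gravity vector. The field's literature names these
features but rarely pins down definitions, so each one is given a single
operational definition (module docstring of `actimet.features`) and locked
by a brute-force oracle test (explicit per-window loops and scipy
reference statistics, coded separately from the vectorised
implementation). Notable choices:

- SD/variance are sample statistics (ddof = 1); skewness and Pearson
  kurtosis use biased central moments; CV = SD/|mean|·100.
- Median (zero) crossings count sign changes of the median- (mean-)
  centred signal; exact zeros carry the previous sign. Zero-variance
  windows (max = min) report 0 for all correlation-, moment- and
  crossing-type features — a sentinel that keeps model inputs finite.
- Activation features (active samples, activation count, mean run
  duration, run-duration SD) are computed on the mean-removed rectified
  signal after a zero-phase 4th-order Butterworth 5-Hz lowpass; the
  activity threshold defaults to 0.01 g and is configurable, since the
  upstream definition is not recoverable.
- Dominant frequency/magnitude: untapered magnitude spectrum of the
  mean-removed window, restricted to [0.25, 5.0] Hz inclusive; ties break
  toward the lower frequency.

Windows are strictly non-overlapping and complete; a trailing partial
window is discarded (1,578,000 samples at 100 Hz ⇒ exactly 1,578
windows). Feature windows are joined to the EE criterion by identical
start times (a nearest-within-tolerance mode exists for misaligned
clocks).

## 3. mRMR selection

Greedy forward selection. Relevance of a feature is the F statistic of
the univariate regression of EE (kcal/min — chosen over METs so that the
selection target equals the modelling target) on the feature. Redundancy
against the already-selected set is the mean of the *same F statistic*
applied to the feature/selected-feature correlations, and the step score
is relevance/max(redundancy, 10⁻⁶). Measuring both sides of the quotient
on the F scale is deliberate: with redundancy capped at |r| ≤ 1, a highly
relevant exact duplicate of an already-selected feature would win every
step; on the F scale a duplicate has unbounded redundancy, scores 0, and
is deprioritised below any feature carrying independent signal — the
behaviour mRMR exists to provide. A mutual-information variant
(equal-frequency discretisation, default 10 bins, MI on both sides) is
available via `method="mi"`. Constant features receive relevance 0; ties
break by catalog order; the greedy construction makes the k = 10 set a
prefix of k = 15 and k = 20.

Selection is re-run inside each LOSO training fold by default
(leakage-safe); a pooled, non-nested mode reproduces one-shot
calibration-study methodology and is used for the "retrained laboratory"
model arm.

## 4. Models and cross-validation

Hyperparameters are fixed at the values reported as optimal for this
population: RF 500 trees with 3 features per split; RBF SVM with C = 6.0,
γ = 0.1 (ε = 0.1, unstated upstream, is the scikit-learn default and is
configurable); ANN with one hidden layer of 11 neurons and weight decay
0.1 (lbfgs solver, ≤ 500 iterations). SVM and ANN inputs are standardised
with training-fold statistics; the forest consumes raw features.
Predictions are clipped below at zero because EE is physically
non-negative. LOSO-CV yields per-subject RMSE (kcal/min; divided by the
subject's predicted resting EE for the MET scale) and MAPE (windows with
zero observed EE are excluded and counted); summaries are means and SDs
**across subjects**. Hold-out evaluation refuses any subject overlap with
the training sample.

The two provenance arms differ only in how features are chosen: the
free-living arm uses nested per-fold mRMR with each model's best k (hip
RF 20, hip ANN 15, wrist RF 15, wrist SVM 15), while the retrained-lab
arm refits the laboratory architectures with a single pooled k = 20
selection. Original laboratory model weights are out of scope.

## 5. Evaluation battery

- **RMSE/MAPE** as usual; session-total EE = Σ(kcal/min)·(10/60) per
  subject.
- **Bland-Altman** works in the percent-error space that agreement plots
  for this problem use: d = (observed − predicted)/observed·100 per
  subject, regressed on observed kcal by OLS. Reported: mean bias and
  mean ± 1.96·SD limits of agreement in both percent and raw kcal, the
  Pearson correlation of percent error with observed total (proportional
  bias), and prediction limits at requested observed-kcal values as the
  regression line ± 1.96·residual SD. Constant-LOA and regression-based
  limits are both emitted because either convention appears in practice.
- **RM-ANOVA**: classic two-way decomposition without replication —
  subjects as blocks, error term = model×subject interaction MS, df =
  (m−1, (m−1)(n−1)), no sphericity correction. When the omnibus F is
  significant at α = 0.05, Fisher-LSD pairwise comparisons use the pooled
  error MS (unadjusted t tests, by definition of LSD). The implementation
  is cross-checked against `statsmodels` AnovaRM in the tests.

## 6. The synthetic world

The generator emulates the data-collection setting — 3–5-year-olds in
~20-minute free-play sessions wearing hip and wrist monitors (100 Hz,
±8 g) and a portable calorimeter — with a planted, recoverable
structure:

- **Cohort**: ages drawn 36%/28%/36% over 3/4/5 y, 80% male (matching
  the observed sample), heights/masses from age- and sex-conditional
  normals near growth-reference medians (SD 4 cm / 1.5 kg).
- **Schedule**: per-activity session totals drawn around energetic play
  11.7, walking 2.8, running 2.4, seated 4.3 min (observed free-play
  means; SDs 4.0/1.9/1.1/2.3), rescaled to the session length (so in a
  20-min session the seated expectation is 4.3·20/21.2 ≈ 4.06 min),
  split into bouts and interleaved in random order with seated
  transitions.
- **EE path**: target METs per activity (seated 1.3, walking 3.7,
  running 6.0, energetic play 4.5); steady-state EE = REE·MET follows
  bout transitions with first-order on-kinetics, τ = 30 s; each 10-s slot
  gets mean-one lognormal noise, σ = 0.10. Breaths invert the Weir
  equation at RER 0.85 with 5% per-breath noise and a MET-dependent
  respiratory rate.
- **Acceleration**: site-specific gravity orientation plus a band-limited
  oscillation (fundamental + first harmonic) whose amplitude and dominant
  frequency increase monotonically with the target MET, with white sensor
  noise (0.012 g) and per-bout amplitude jitter. Movement switches
  instantly at bout boundaries, while EE lags through its kinetics.

All of these values are package defaults chosen for physiological
plausibility — no public generative model for this setting exists — and
every one is exposed in `SessionParams`/`RunConfig`.

**Noise floor.** Parameter-recovery tests compare model RMSE to the
generator's irreducible error. Because the criterion is 60-s-smoothed and
EE lags activity through τ, a floor computed from σ alone is unattainable
*by construction*: no model seeing only the current window's acceleration
can reproduce the kinetic lag at bout transitions. The floor is therefore
the pooled within-(subject, activity) RMSE of the criterion around its
conditional mean — the error of an ideal predictor that knows the subject
and the window's true activity state. It reduces to the σ-only value as
τ → 0 and the smoothing window → 0. On default cohorts the free-living
hip RF reaches ≈ 1.4× this floor; the remaining gap is cross-subject REE
variation (the features carry no anthropometry) plus transition windows.

**What a green test does not establish.** The generator's movement model
is a stylised oscillator, not biomechanics: it has no inter-subject gait
idiosyncrasy, no non-wear or mask-leak artifacts, and its feature→EE map
is cleaner than reality — absolute error levels are therefore optimistic
(synthetic LOSO RMSE ≈ 0.42–0.53 kcal/min versus ≈ 0.63 reported on human
free-play data), and only structural claims (ordering, calibration,
recovery, leakage-freedom) transfer.

## 7. Determinism and seeds

Every stochastic component takes an explicit integer seed; pipeline stage
seeds derive from the master seed by `SeedSequence` spawning. Re-running a
configuration reproduces all numeric outputs bit-for-bit (asserted in the
tests); the provenance block of `metrics.json` records the seed and a
hash of the analytic configuration (output paths excluded).

## 8. Known limitations

- The raw-CSV reader infers the sampling rate from median timestamp
  spacing; irregular clocks are rejected rather than resampled.
- MAPE is undefined at zero observed EE; such windows are excluded and
  counted instead of imputed.
- The ANN relies on lbfgs convergence; on tiny degenerate fixtures it may
  stop at the iteration cap (warnings are left visible deliberately).
- No attempt is made to emulate proprietary device formats ("counts",
  GT3X+ binaries) — the CSV dialects in `actimet.io` are the interchange
  boundary.
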