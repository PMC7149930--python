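# Methods

## The HRnV representation

Let `x_1 … x_N̂` be the NN intervals of a recording (ms) and `t_i` the
cumulative time at which interval `i` ends. The composite sequence with
window `n` and stride `m` (`1 ≤ m ≤ n ≪ N̂`) has elements

    y_k = x_{km+1} + … + x_{km+n},      k = 0 … ⌊(N̂−n)/m⌋,

so `len(y) = ⌊(N̂−n)/m⌋ + 1`. `m = n` gives the non-overlapping RRnI
family, `m < n` the overlapping RRnIm family, and `n = 1` reproduces the
raw series element-wise (the implementation sums explicit windows, not
cumulative-sum differences, so this reduction is bit-exact). Each
composite inherits the end time of its last constituent beat, keeping the
sequence on the true, uneven time axis for spectral analysis.

Conventions chosen where the representation itself leaves freedom:

- **Start phase.** Every sequence starts at the first interval; alternative
  phase offsets would give `m` near-copies per (n, m) and are not computed.
- **Remainders.** Trailing intervals that do not fill a complete window are
  dropped; partial windows would break the equal-`n` interpretation of the
  parameters.
- **Units.** Milliseconds throughout (intervals, SDNN, RMSSD, SD1/SD2;
  powers in ms²).
- **`m = n`** is accepted as an alias of RRnI to simplify sweeps.

## Parameter panel

21 parameters per sequence, plus NN50n/pNN50n (threshold `50·n` ms) on
composite sequences only (23 per HRnV set; `n_max = 3` ⇒ 136 columns).

Time domain: SDNN uses the sample (n−1) denominator by default
(configurable); pNN50 divides by the element count rather than the pair
count (configurable); NN50 uses a strict `> 50 ms` inequality; kurtosis is
reported in the Pearson convention (normal → 3; excess available); the
triangular index uses 1/128 s ≈ 7.8125 ms bins aligned to multiples of the
bin width, not rescaled with `n`.

Frequency domain: Lomb–Scargle periodogram on the native uneven
timestamps of the mean-subtracted series — no resampling, no polynomial
detrend (VLF is sensitive to this choice and should be compared across
implementations with care). The raw periodogram is scaled by `2T/N`
(T = time span, N = sample count), which makes the trapezoidal integral of
the density approximate the series variance (Parseval within ~5% on evenly
sampled input). The grid oversamples the fundamental 1/T by 4× and extends
to max(0.4 Hz, half the median beat rate) so the conventional bands —
VLF (0, 0.04], LF (0.04, 0.15], HF (0.15, 0.4] Hz, half-open so no bin is
double-counted — are always covered. Band edges are deliberately **not**
rescaled with `n`. Total power is defined as VLF+LF+HF and `hf_norm` as
`100 − lf_norm`, making the partition identities exact by construction.

Nonlinear: SD1/SD2 come from the lag-1 difference formulas; the transverse
Poincaré coordinate is taken about zero (the mean successive difference is
the negligible drift `(x_N̂ − x_1)/(N̂−1)`), so SD1 = RMSSD/√2 holds exactly
under the population convention. ApEn and SampEn use m = 2,
r = 0.2·SD of the sequence being analysed — composite sequences therefore
get composite-scale tolerance, and both entropies are affine-invariant.
SampEn with no length-(m+1) matches is **undefined**: the implementation
returns NaN with an `*_undefined` flag instead of a sentinel blow-up.
Short non-overlapping composites (a 5–6 min record leaves ~100–200 HR3V
points) genuinely hit this regime; downstream statistics must treat it as
missingness (the risk pipeline drops rows with missing predictors).

DFA integrates the mean-centred series, removes a per-box linear trend in
non-overlapping boxes, and fits log F(s) against log s over boxes 4–16
(α1) and 16–64 (α2). A caveat established while validating against
theoretical limits: for white noise, the *exact* expectation of the DFA-1
log-fluctuation slope over boxes 4–16 is 0.583, not 0.5 — a small-box bias
inherent to the estimator, reproduced here from the detrending projection
matrix, not an implementation artifact. The asymptotic exponents
(0.5 white, 1.5 Brownian, ~1.0 for 1/f) are recovered on the long-scale
range; tests and the acceptance script therefore check the white-noise
limit on α2 and document the α1 bias explicitly.

## ECG front-end

`detect_beats` is a derivative/energy QRS detector: 5–15 Hz zero-phase
bandpass, derivative, squaring, 150 ms moving-window integration, peak
picking above 0.25× the 99th-percentile envelope with a 200 ms refractory
period, and apex refinement on the raw trace (±50 ms). It targets short
triage strips at fs ≥ 100 Hz; flatline or saturated traces are rejected.

`clean_nn` applies physiological bounds [300, 2000] ms and an ectopic rule
(> 20% deviation from the running median of the last 5 accepted
intervals). Outliers are excised, never merged or interpolated — the
surviving timestamps stay on the true time axis, which the Lomb estimator
tolerates by design. Records losing > 20% of intervals are rejected as
non-sinus/noisy. The bounds and fractions are configurable; they follow
common HRV-toolbox defaults.

## Synthetic substrates

`gen_rr` draws intervals `mean_nn + a_LF sin(2π·0.1t) + a_HF sin(2π·0.25t)
+ N(0, σ²)` with optional ectopic short-long pairs (0.55/1.45 of the local
cycle). A sinusoidal-modulation model (rather than an integral pulse
frequency modulation model) is sufficient here because validation only
needs *known* band powers (a²/2) and means; it does not emulate
respiratory coupling, circadian drift or the inter-parameter correlation
structure of real HRV panels, so passing tests demonstrate correctness of
the estimators, not clinical performance. Default duration 330 s — the
midpoint of a five-to-six-minute triage recording.

`gen_cohort` draws 16 predictors and samples a binary 30-day MACE outcome
from a logistic model whose default log-odds coefficients are on the scale
of published adjusted odds ratios for this setting (e.g. troponin code
4.41, cardiac history 7.84 per step, HR2V ApEn 0.095, HR2V1 ApEn 19.7);
the intercept is solved by root finding so the mean event probability hits
the target prevalence (default 0.31, n = 795). Age is anchored to
published baseline characteristics (59.6 ± 12.9 y) and the HRV/HRnV
parameter marginals to published descriptive panels; blood pressure, pain
score, ECG-finding prevalences and code frequencies are plausible
emergency-department values chosen once and kept fixed. Predictors are
drawn independently — real cohorts are collinear, so the synthetic AUC
(~0.87–0.89 under the defaults) characterises the pipeline, not the
clinic.

## Risk pipeline

- Univariable screening keeps candidates with Wald p < 0.2; a
  (quasi-)separation heuristic (|β| > 15 or SE > 30, or non-convergence)
  flags and excludes degenerate candidates.
- Backward stepwise elimination drops the largest-p variable while any
  p > 0.05 (an AIC criterion is available); deterministic given the data.
- Fits use Newton iteration with an lbfgs fallback — Newton is much more
  robust to poorly scaled designs such as raw spectral powers.
- Troponin coding: 0 for ≤ 0.03 ng/mL, 1 for (0.03, 0.09] (the 3× boundary
  maps to 1), 2 above. Cardiac history (0/1/2) enters as a numeric score.
- LOOCV by default fixes the variable list chosen on the full data and
  cross-validates the coefficients only; this is the common but optimistic
  procedure, so a `strict_cv` mode repeats screening and stepwise selection
  inside every fold and reports both AUCs, making the optimism gap visible.
- ROC: empirical curve over all distinct thresholds; trapezoid AUC (equal
  to the Mann–Whitney concordance, ties counted half); DeLong
  placement-value CI; optimal cut-off by minimal Euclidean distance to
  (0, 1); operating-point metrics with normal-approximation binomial CIs.

## Problem sizes and numerical tolerances

The test suite and acceptance script use: 1,000 random series for the
construction oracle; 200 series of length 50–300 for the O(N²) entropy
oracles (equality to 1e-9); length 2^14 for the DFA limits; a
100,000-patient cohort for coefficient recovery (each nonzero log-OR
within ±10%); 1,000-patient cohorts for the LOOCV checks (shuffled-outcome
AUC in [0.45, 0.55]); 500 small data sets for the exact AUC/pair-count and
cut-off scans. The acceptance script completes in well under a minute on a
single core.

## Known limitations

- Spectral values are estimator-dependent (windowing/detrending choices
  differ across HRV toolboxes); only closed-form ground truth is asserted.
- The ECG model is stylised (no baseline wander, muscle noise or electrode
  artifacts beyond additive Gaussian noise).
- The cohort generator's independence assumption understates the variance
  inflation real collinearity causes in stepwise selection.
- HEART/TIMI/GRACE scores are not implemented; comparator scores can be
  supplied as columns and analysed with the same ROC machinery.
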