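# Methods

This note documents the models, estimators and design choices behind
`neohrv`, and what the synthetic cohort does and does not establish about
real neonatal data.

## Data model and windowing

A recording is an `RRSeries`: strictly increasing beat-onset times (s) and
positive RR intervals (ms), self-consistent to 1 ns, with subject metadata
(gestational age GA at birth, post-menstrual age PMA at recording; both in
weeks, PMA ≥ GA).  PMA classes are `<28`, `28–32`, `32–36`, `≥36` weeks,
left-closed at the lower edge.

Windows of the four length classes — US = 120 s, S5 = 300 s, S10 = 600 s,
L = 900 s — are extracted consecutively with 50 % overlap.  A beat belongs
to window k iff its onset lies in the half-open interval
`[k·T/2, k·T/2 + T)` of recording time; half-open membership prevents
double counting at boundaries.  The recording duration includes the final
RR interval, so a nominal 900 s recording yields exactly 14/5/2/1 windows.
Windows shorter than 20 beats are rejected for feature extraction.

Screening replaces the study's manual RR verification with a deterministic
rule: beats outside 200–750 ms (bracketing neonatal heart rates of 80–300
bpm) or changing by more than 50 % from the preceding beat are replaced by
linear interpolation of the nearest valid neighbours; a recording with more
than 20 % flagged beats is rejected.  All limits are configurable.
Screening is idempotent on its own output.

## Feature estimators: numerical choices

* **SD** uses the sample divisor (n−1); **rMSSD** is the root mean square
  of successive differences.
* **Spectral analysis.** The tachogram is interpolated by a natural cubic
  spline against onset time and sampled at 4 Hz.  AR(12) coefficients are
  estimated by the Burg method (stable on short windows; Yule-Walker is a
  config option) after mean removal only.  The one-sided PSD is evaluated
  on a dense 4096-point grid and rescaled so that its integral over
  (0, fs/2] equals the series variance; LF (0.02–0.2 Hz) and HF (0.2–2 Hz)
  powers are trapezoidal integrals in ms².  Frequencies below 0.02 Hz are
  not reported.  LF/HF is undefined (NaN) when HF power is zero.
* **Poincaré.** SD1 is defined through the uncentred second moment of the
  successive differences, `sd1 = sqrt(mean(Δ²)/2)`, which makes the
  identity SD1 = rMSSD/√2 exact — the two are mathematically the same
  short-term index and the package treats them as such.  SD2 is the
  (population) SD of the lagged sums divided by √2.  A consequence worth
  noting: a pure linear trend contributes to SD1 through the constant
  successive difference, unlike the centred-variance convention.
* **Sample entropy.** Tolerance r is a fraction (default 0.25) of the
  *analyzed window's* SD (population divisor), distance is Chebyshev, both
  template sets use the same N−m starting points, and self-matches are
  excluded; strictly periodic series therefore give exactly 0.  Zero match
  counts yield NaN rather than an exception.  The (m, r) selection utility
  scores each pair by the median over a window corpus of the relative
  error of the conditional-probability estimate, approximated binomially:
  `sqrt(CP(1−CP)/(B/2))/CP` where B is the ordered m-match count.  This is
  a documented reconstruction of the published efficiency-based strategy,
  not a verbatim reproduction of it.
* **DFA.** The mean-centred series is integrated; non-overlapping boxes of
  ~10 log-spaced sizes per range are linearly detrended; F(n) is the RMS
  residual; α is the unweighted least-squares slope of log F vs log n.
  α₁ spans 4–40 beats (needs ≥ 80 beats), α₂ spans 40 to N/4 beats and is
  NaN when N/4 ≤ 44.  First-order DFA is biased at small boxes: for
  uncorrelated data E F(n) = σ√(n/15)·√(1−4/n²) exactly, which would push
  the fitted α₁ of white noise to ≈ 0.55 over 4–40.  Each F(n) is therefore
  divided by √(1−4/n²) by default (`finite_size_correction`); the factor is
  exact for uncorrelated data and a first-order correction otherwise, and
  restores the textbook calibration values (0.5 / ~1 / ~1.5) at these
  scales.
* **PRSA.** Anchors are interior beats strictly longer (DC) or shorter
  (AC) than their predecessor; ties anchor neither.  Segments span offsets
  −2…+1 around the anchor (exactly what the four-term estimator
  `(X̄(0)+X̄(1)−X̄(−1)−X̄(−2))/4` needs).  Time reversal maps DC to −AC
  exactly on tie-free series.
* **HVG motifs.** Edge (i, j) exists iff every sample strictly between is
  strictly lower than both endpoints.  Each consecutive quadruple is
  classified by the chord indicators (1–3, 2–4, 1–4).  Six triples are
  logically possible (both short chords together are contradictory); five
  occur for distinct values and the sixth only under the tie x₂ = x₃, so
  it has zero frequency on continuous data.  Labels Z1–Z6 are this
  package's lexicographic convention; published motif numberings cannot be
  recovered from labels alone, so clustering results involving specific
  Zk labels are comparable only up to relabeling.  Tie-containing
  quadruples are counted normally and flagged (`n_ties`).

## Synthetic cohort

The generator emulates the study design: one subject per draw from the GA
distribution (default: the 39-infant distribution 2/1/5/16/7/4/4 for GA
25–31 wk), weekly 15-minute recordings from birth to 41 weeks PMA or
geometric dropout (default hazard 0.05/week).

Each recording follows an additive beat-domain model

    rr(t) = μ + a_lf·sin(2π f_lf t) + a_hf·sin(2π f_hf t)
            + σ_pink·p(t) + σ_white·ε(t)

with p a unit-SD spectrally synthesized 1/f series generated once per
recording at the beat count, and ε white Gaussian.  Defaults (μ = 400 ms,
i.e. 150 bpm, a typical preterm quiet-sleep rate; a_lf = 15 ms at 0.05 Hz;
a_hf = 8 ms at 0.6 Hz; σ_pink = 10 ms; σ_white = 5 ms) keep RR within
physiological bounds by construction (a margin check rejects parameter sets
that could not).  Maturation enters as linear growth of a_hf (0.6 ms/wk)
and μ (1.5 ms/wk) around a 30-week reference, plus a Gaussian subject
intercept on μ (SD 5 % of μ), which makes the mixed-model stage
identifiable.  Every generator is a pure function of its parameters
including the seed, and the ground-truth table suffices to re-derive every
injected effect by regression.

This model is deliberately *not* physiological: it is not an
integral-pulse-frequency-modulation model, and it contains no apnea or
bradycardia events, feeding artifacts, respiration coupling, or sleep-state
structure.  What it provides is a known target for every feature family
(band powers a²/2, DFA exponents from the 1/f component, maturation slopes,
subject variance components).  Passing tests therefore demonstrate that the
estimators recover known structure and that the statistical machinery is
calibrated — not that clinical effect sizes (e.g. the printed bias
percentages or the cohort's k = 8 feature clusters) are reproduced, which
would require the original recordings.

## Robustness statistics

* **MAD (random error).**  For each feature × length × PMA-class cell, all
  window realizations across recordings and subjects are pooled and
  `MAD = median(|X − median(X)|)` computed.  Pooling across recordings is
  required for the quantity to be meaningful at L (one window per
  recording).
* **Length/PMA mixed models.**  `value ~ length_class (ref L) + pma_class
  + ga_weeks + (1 | subject)` by maximum likelihood; the joint length
  effect is a likelihood-ratio test.  When a Shapiro-Wilk test on the
  marginal residuals of the untransformed fit rejects at 5 %, the response
  is Box-Cox transformed (λ by profile likelihood on a grid over [−3, 3];
  sign-indefinite features are shifted by 1 − min first and the shift
  recorded).  Optimizer fallbacks (default cascade, then Powell, then CG)
  handle boundary fits; a residual singular fit is reported as an error for
  that feature rather than aborting the run.  No multiple-testing
  correction is applied across features; p-values are rendered with the
  customary 4-level stars.
* **Bias and limits of agreement.**  Window replicates are averaged within
  recording × length; each length's percentage difference from a
  per-recording reference is modelled with the same fixed and random
  effects.  The default reference is the mean across the recording's
  available length classes; the 15-min window as gold standard is a config
  option (`bias_reference: L`).  Note the arithmetic consequence: under the
  mean reference a pure −15 % distortion of US appears as ≈ −11.7 % against
  the (contaminated) reference, while under the L reference it is recovered
  as −15 %.  Bias is the adjusted marginal mean (fixed-effects prediction
  averaged over the observed covariate distribution); LoA = bias ±
  1.96·√(subject variance + residual variance).  If all differences are
  exactly zero the model is degenerate and bias/LoA collapse to 0 directly.
* **PCA / clustering.**  Observations are recordings (window replicates
  averaged), by default one PCA per length class.  Variables are
  standardized; coordinates are loadings × √eigenvalue (equal to the
  variable-score correlation), contribution = cos² × 100 / component total
  cos².  GA and PMA are projected as supplementary variables.  Features are
  clustered as points in their leading PCA coordinates (components covering
  ≥ 80 % variance by default) by k-means with 20 restarts and a fixed seed;
  k maximizes the average silhouette width over the searched range (ties to
  the smaller k); a Ward linkage of the same points provides the
  dendrogram.

## Missing values

Undefined features (SampEn with no matches, α₂ on windows with N/4 ≤ 44,
DC/AC without anchors, LF/HF with zero HF power) propagate as explicit NaN
rows of the feature table; every statistics stage drops them per feature
with the per-cell n reported, and stage failures are collected in an error
manifest rather than aborting the pipeline.

## Problem sizes used in the shipped checks

The test-suite simulations were sized to exercise each claim at desk
scale: DFA calibration uses 20 series of 10⁴ (white/Brownian) and 2¹⁴
(1/f) samples; oracle-equivalence checks use 100 randomized windows of up
to 300 beats; bias recovery uses a 200-recording synthetic feature table;
type-I calibration uses 100 null cohorts of 30 subjects; the qualitative
window-length checks extract all features from a 30-recording stationary
cohort and short-term features from a 90-recording maturing cohort; the
planted-structure check uses 8 blocks × 3 features over 50 seeds.

## Known limitations

* The additive beat-domain generator cannot validate features against
  physiological mechanisms (respiratory sinus arrhythmia, baroreflex), only
  against injected mathematical structure.
* The finite-size DFA correction is exact only for uncorrelated data; for
  strongly correlated series the calibration constants are recovered to
  within ~0.05.
* The efficiency metric for (m, r) selection is a binomial approximation
  that ignores template-pair overlap, so it underestimates the true
  standard error; it is used only to rank parameter pairs.
* Integer-quantized RR series (whole-ms monitors) produce frequent ties;
  the HVG tie flag should be inspected before interpreting motif
  frequencies on such data.
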