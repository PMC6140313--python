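# Methods

## The measurement problem

Upper thermal limits of small motile animals are commonly operationalised as
the time until locomotion ceases at a lethal static temperature ("time to
immobilisation", T_imm, a knock-down time). Scored by eye, the endpoint is
subjective. With video tracking, each individual yields a velocity time
series (mm/s, here at 3 observations/s) and the endpoint becomes a
signal-detection problem: tracking data carry jitter (apparent movement of
the detected centroid when the animal is still), dropout frames (animal not
detected), and genuine transient pauses, so neither "first zero velocity"
nor any raw-sample rule is usable.

## Detector

Each series is smoothed with a moving median of width `w` observations —
medians reject isolated spikes and dropouts outright — and T_imm is the
first time the smoothed velocity falls below a threshold `v_thresh` (mm/s),
referenced to the moment the animal entered its heated well
(`intro_offset_s` before recording start; set offsets to zero for
video-clock timing).

Choices a median filter forces, and what we chose:

- **Alignment.** Default `centered`: the window spans
  `[i − ⌊w/2⌋, i + ⌈w/2⌉ − 1]`, which keeps the crossing estimate unbiased
  in time. `trailing` (`[i − w + 1, i]`, online behaviour, delays the
  crossing by about `w/(2·rate)`) is a config switch. Windows shrink at the
  series edges instead of emitting missing values.
- **Even widths.** Allowed; an even-count median is the mean of the two
  middle values.
- **Missingness.** Medians are taken over detected frames only; a smoothed
  value is reported missing when more than `max_missing_frac` (default 0.5)
  of its window slots are missing — the median of a handful of frames is
  not evidence.
- **Crossing mode.** Default `first` ("drops below"); `sustained` (every
  later present value stays below) is available for traces that re-cross,
  though wide medians make the two nearly coincide.
- **Censoring.** A trace whose smoothed velocity never crosses the
  threshold is censored, a first-class outcome, not an error: thresholds at
  or below the jitter floor censor most subjects.

A subject's T_imm can be biased early by at most roughly half a window if a
quiet stretch precedes true immobilisation, and the centred filter delays
nothing on average; `w/(2·rate)` (46.7 s at the canonical `w = 280`,
3 obs/s) is the natural error scale.

## Calibrating (v_thresh, w)

Neither parameter is identifiable from a single trace, and the optimum is
organism- and setup-specific. The calibration criterion exploits known
biology: T_imm rises with warm acclimation and falls with body size. For
every candidate pair on a grid (default: thresholds 0.01–1.00 mm/s in steps
of 0.01 × widths 20–1080 observations in steps of 20; 5400 cells, window
durations 6.67–360 s at 3 obs/s), T_imm is computed for all subjects and an
ordinary linear model

    T_imm ~ treatment (categorical) + body size (mm, continuous)

is fitted; the cell with maximal R² wins. An interactive form (adding
treatment × size) is available and, on data without a true interaction,
selects the same cell. Details:

- **Censor policy.** Default `end_of_record`: censored subjects enter the
  fit at the last recorded time. Dropping them (`exclude`) would reward
  absurd thresholds by silently removing exactly the hard-to-immobilise
  animals. Either way the censored count is reported per cell, and cells
  censoring more than `max_censored_frac` (default 0.1) of subjects are
  inadmissible for selection: their "T_imm" is mostly truncation.
- **Ties.** Exact R² ties break to smaller `w`, then smaller `v_thresh`
  (the less-smoothing, more conservative choice).
- **Degenerate cells.** A window longer than a series, a (numerically)
  constant response, a rank-deficient design, or too few usable subjects
  mark the cell invalid with a reason; the search continues.
- **Partial R².** The surface export carries both the full-model R² and the
  treatment increment over a covariate-only fit, since "variance explained
  by treatment" can mean either.
- **No multiplicity correction.** Per-cell coefficient p-values are
  reported as-is; the grid is one calibration objective, not 5400
  hypothesis tests.
- **Block/run labels** are carried through but not modelled by default; an
  option adds them as categorical covariates.

The R² surface over the admissible region is typically a ridge: every
(v_thresh, w) that clears the jitter floor and out-spans transient pauses
detects the same collapse within seconds, so cell-to-cell differences are
sampling noise at small n and the argmax sharpens as n grows. This is why
the additive/interactive agreement check is run at large group sizes, and
why the selected cell should be read as "a point on the good ridge", not a
sharp physical constant.

## Synthetic experiments

No tracking data are distributed with the package; the simulator generates
experiments with known ground truth so every stage is testable. Its
structure and anchors:

- **Ground truth.** Per subject,
  `T* = t_star_base + effect(treatment) + beta_size·(size − mid) + N(0, sigma_t)`,
  floored at 60 s. Defaults: base 1200 s; two-treatment "calibration"
  preset with labels 17/22 and effect 566.58 s; `beta_size` −114.97 s/mm;
  `sigma_t` 240 s — the effect and slope are the anchor study's point
  estimates, and `sigma_t` is back-calculated from that study's reported
  standard error of the treatment effect (19.23 ≈ 240·√(2/315)); these
  choices jointly imply a full-model R² near 0.59 and a five-temperature
  validation R² near 0.87–0.90, matching the anchor values without either
  being targeted directly. Body sizes are uniform on 1.5–3.5 mm (mature
  *Daphnia magna* across a 1–13-day age spread). The "validation" preset
  uses five labels (12–28 °C, nine subjects each) with effects linear in
  temperature at 566.58/5 s/°C.
- **Velocity process.** Sampled directly at the analysis rate (3 obs/s —
  the pipeline never sees the raw 30 fps video). Active swimming: gamma
  draws with within-subject CV 0.5 around a per-subject mean (lognormal,
  mean 2 mm/s, CV 0.3 — individuals differ in baseline speed, which makes
  the threshold choice matter in a way identical subjects would not).
  Pauses: an alternating renewal process with stationary occupancy 4%,
  geometric bouts of mean 5 s **truncated at 20 s**, and a guaranteed 30 s
  of swimming after each bout. The truncation and refractory period are
  semantic, not cosmetic: a voluntary pause lasting minutes would be
  indistinguishable from immobilisation and would falsify the ground-truth
  label itself, and the refractory period bounds the pause fraction of any
  median window, so windows of ≥140 observations can never cross on pauses
  alone, while narrow windows (≤60) remain pause-sensitive — the structure
  the calibration is supposed to discover. Decline: a per-subject lognormal
  duration (mean 60 s, CV 0.6) over which swimming becomes intermittent —
  fading bursts with probability falling linearly to zero, moribund
  flickers (exponential, mean 0.05 mm/s) between them; with pauses disabled
  the decline degenerates to a clean linear ramp (the exact noise-free
  limit). After T*: unsigned Gaussian jitter with per-subject SD
  (lognormal, mean 0.02 mm/s, CV 0.3 — tracking noise varies with well
  position and lighting; its heterogeneity is what penalises thresholds at
  the jitter floor). Frames drop out independently at 1%.
- **Design plumbing.** Introduction offsets cycle within 45-well plates at
  4.5 s spacing; each treatment is a separate block; recording covers the
  last immobilisation plus 120 s (endpoint inspection every ~2 min). One
  RNG stream per subject, derived from (seed, subject index), so traces are
  reproducible independently of collection order.

What the simulator does **not** emulate: arena geometry and wall-following,
temperature ramping, autocorrelated swimming speed within bouts,
size-dependent speed or noise, drift in tracking quality over a recording,
and any pixel-level artefacts. Passing tests therefore show that the
algorithmic pipeline recovers known structure under realistic nuisance —
not that the canonical (0.03 mm/s, 280) optimum transfers to any real
setup; the calibration step exists precisely because it does not.

## Problem sizes used in the test suite and acceptance script

Grid searches in tests and the acceptance script use a 10 × 9 screening
grid spanning the full default ranges (log-spaced thresholds including
0.03; widths 20–1080 including 280). Replicate-based checks use 20 seeds at
40 subjects per treatment; the additive/interactive agreement check uses
150 per treatment (half the full design — the surface must be resolved for
the argmax to be meaningful); the acceptance script runs the full 315 per
treatment once. These are the package's own choices of problem size for
routine verification; the full 5400-cell grid is exercised end-to-end by
the `optimize` command.

## Numerical and implementation notes

- The moving median is computed via pandas' rolling median (skips missing
  values) with right-padding to realise the centred window; an independent
  brute-force per-window oracle verifies both alignments, even/odd widths
  and missingness handling in the tests.
- OLS goes through statsmodels; R², SEs, t and two-sided p use the usual
  unbiased residual-variance estimator. A separate normal-equations oracle
  verifies coefficients and SEs in the tests.
- Grid evaluation caches the smoothed series per window width and shares
  detections across thresholds and model forms; parallel evaluation over
  widths (joblib) is bit-identical to sequential.
- Tracking reads reconstruct each subject's uniform grid from its time
  stamps: with a configured rate, every interval must be an integer number
  of steps (within 1% of a step); otherwise the step is the approximate GCD
  of the intervals (robust when dropped frames make gaps outnumber single
  steps). The grid is anchored at the subject's first observed time. Writes
  use shortest-round-trip float formatting, so write → read reproduces
  values bit-for-bit.
- Every CLI command echoes its effective configuration; re-running from the
  echo with the same seed reproduces outputs byte-identically.

## Known limitations

- T_imm from the `first` crossing of a centred median is biased early by up
  to about half the intermittent-decline duration on traces with a long
  fade; this bias is shared across subjects and largely cancels in
  treatment contrasts, but absolute T_imm values should be read with the
  `w/(2·rate)` error scale in mind.
- The calibration objective assumes the covariates truly drive T_imm; with
  weak or absent treatment/size effects the R² surface is uninformative and
  the selected cell arbitrary.
- Censored subjects under `end_of_record` bias cell R² conservatively; no
  survival-model treatment of censoring is attempted.
- Single-subject treatment groups get no confidence interval in reports.
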