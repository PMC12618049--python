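# Methods

## The two-process model of early saccades

The package analyzes saccades launched during the foreperiod (FP) of a
warning-stimulus / go-signal task.  Latencies are measured from the offset
of the warning stimulus (FP onset).  The working model is that two
independent processes can produce a pre-target ("early") response:

* **Impulsive process** (1st mode).  A release-of-inhibition response with
  latency `L ~ N(mu_imp, sigma_imp)` independent of FP duration; its
  per-trial occurrence probability decays log-linearly with FP,
  `P(impulsive) = exp(b0 + b1 FP) * f_SU * m_s`.
* **Anticipatory process** (2nd mode).  A timed response with
  `L ~ N(mu0 + beta_mu FP, sigma0 + beta_sigma FP)` — mean *and* SD grow
  linearly with the timed interval (scalar expectancy) — and an
  FP-independent per-trial occurrence probability
  `P(anticipatory) = r * f_SU * m_s`.

`f_SU` is a spatial-uncertainty rate factor shared by both processes and
`m_s` a per-subject lognormal "disinhibition" multiplier, also shared,
which is what induces the positive between-subject correlation of 1st- and
2nd-mode counts.  At most one early saccade occurs per trial; the impulsive
process is sampled first and pre-empts the anticipatory one (whether both
processes can fire in one real trial is unknowable from latency data; one
event per trial is the parsimonious choice).  Early latencies beyond
`FP + 100` ms are censored — the movement would land in the visually guided
window — and the trial reverts to a visually-guided-only trial.

Mode separation mirrors the analysis such data receive in practice: pool
each FP block's early latencies across subjects, fit k-component Gaussian
mixtures by EM for k = 2..5, select k, and cut the latency axis at the
**crossing point** where the two weighted component densities are equal.
Saccades below the cut are "first mode", at or above it "second mode".

## Generator calibration

Defaults are the study conditions: 25 subjects, 4 blocks (FP 400/900/1400/
1900 ms, order permuted per subject), 120 trials per block balanced over
four SU levels (target probabilities 1, 1/2, 1/3, 1/4; 30 trials each).

Reported effect sizes are taken as generating values: `beta_mu = 0.61`
ms/ms, `beta_sigma = 0.17` ms/ms, impulsive log-rate slope `-0.001`/ms,
anticipatory Vmax bonus `21.2` deg/s (with an FP-centered slope of
`-0.02` deg/s per ms), amplitude bonus `0.8` deg, SU rate ratios
`1 : 1/3.5 : 1/3.5 : 1/4.5`, impulsive latency mean 200 ms.

Quantities the data pattern constrains only loosely were fixed once,
analytically, and documented here rather than re-tuned:

* `anticipatory_mu_intercept = 196` ms puts the 2nd-mode mean at 440 ms in
  the 400 ms block, just past the classic ~375 ms cut;
  `anticipatory_sigma_intercept = 1` ms keeps the SD essentially
  `0.17 * FP`.
* `impulsive_sigma = 60` ms.
* Occurrence intercepts: with the SU factors averaging 0.448 and
  `exp(-0.001 FP)` averaging 0.369 over the four blocks, an impulsive base
  rate of `exp(-1.740) = 0.1755` and an anticipatory per-trial rate of
  `0.157` give an expected early-trial incidence near 10% split roughly
  1 : 2.2 between the processes (the observed split after censoring and
  thresholding lands near 340 : 680 per experiment).
* Main sequence `Vmax = 320 (1 - exp(-A / 3.2))` deg/s: near-saturated at
  the task's 10–13 deg amplitudes, so a 1st-mode saccade of ~11 deg peaks
  near 306 deg/s and the amplitude pathway adds only ~2 deg/s to the
  2nd-mode bonus, keeping the pooled Vmax difference near 21 deg/s.
  Velocity noise SD 35 deg/s, amplitude SD 2 deg (floored at 1.5 deg).
* Visually guided responses: reaction time `N(200, 50)` ms (floored at
  105 ms so a VG response never lands in the early window), endpoint
  scatter SD 1.35 deg per axis around the target-box center.  With the
  5.7 x 4.3 deg boxes this gives a ~86% box-hit rate, hence ~78% of trials
  ending in an accepted VG saccade — the calibration guide for the
  surviving-trial fraction.
* Subject multiplier `m_s = exp(0.5 z - 0.125)` (lognormal, mean 1,
  sigma_log 0.5), chosen so the implied between-subject count correlation
  is ~0.8.

### Raw traces

Traces run from trial start (300 ms of pre-WS fixation) to 800 ms past go
onset at 500 Hz.  Each ground-truth saccade is a raised-cosine position
ramp `s(t) = (A/2)(1 - cos(pi t / D))` toward its landing point — chosen
over minimum-jerk because its peak velocity has the closed form
`(pi/2) A / D`, which the detection tests exploit.  The profile duration is
set so the realized peak velocity equals `min(truth, main-sequence bound)`;
consequently raw-trace kinematics saturate at the main-sequence bound and
the 2nd-mode velocity bonus is fully expressed only at the event level.
Additive Gaussian position noise (default 0.05 deg) models tracker noise;
with probability 0.05 per trial a rectangular invalid gap of 100–300 ms is
inserted away from saccade intervals (a lid-free blink stand-in that
exercises artifact rejection).  One cyclopean trace is emitted per trial.

### What the generator does not emulate

No pursuit, drift, microsaccades, corrective saccades, glissades/PSO, pupil
dynamics, vergence or head movement; noise is white, calibration is
perfect unless injected.  Passing tests therefore demonstrate that the
pipeline recovers a known two-process structure under idealized recording
statistics — not that the detector or the mixture cut is robust to every
pathology of real recordings.

## Detection

Speed is the magnitude of a Savitzky–Golay first derivative (order 2,
window 11 samples = 22 ms at 500 Hz) of (x, y); acceleration is the same
filter applied to speed.  The window is the central noise/passband
compromise: at 0.15 deg position noise the per-axis velocity noise floor is
~7 deg/s (sample-wise exceedance of the 22 deg/s threshold < 1%), while the
peak velocity of a raised-cosine saccade is attenuated by <3% for durations
above ~70 ms (~3% at 60 ms, more for very brief saccades — which never
threatens detection, only peak-velocity readout).  A 5-point window would
put the noise floor above the velocity threshold itself.

Candidate events are maximal runs of valid samples with speed above
22 deg/s; runs separated by under 20 ms of valid samples are merged (one
saccade should not split on a noise dip); a candidate is kept iff its peak
|acceleration| exceeds 3,800 deg/s^2 **and** its start-to-end displacement
exceeds 1 deg.  Velocity is the only samplewise criterion; amplitude and
acceleration are event properties.  Samples within one half-window of an
invalid gap carry no kinematics.

Trial-level artifact rules: invalid fraction > 20%, any gap > 500 ms,
adjacent-sample jumps > 3 deg (discontinuity), or pre-WS median fixation
more than 3 deg from the cross (drift proxy).  These thresholds are package
choices standing in for manual screening; note that with per-trial blink
probability p and U(100, 600) ms gaps they reject only the minority of
blink trials whose gap trips a rule, not every blink trial.

## Classification

Latency = saccade onset − WS offset.  Windows: negative latencies are
rejected (`pre_fp`); `0 <= latency < FP + 100` is early (0 inclusive);
`latency >= FP + 100` is a visually-guided candidate, then rejected when
latency − FP > 1,000 ms, when an earlier early saccade exists
(`after_early`; the rule never discards early saccades themselves), when
the endpoint misses the trial's target box (`wrong_box`; closed rectangle,
saccade endpoint rather than post-saccadic fixation), or when a VG saccade
already survived (`after_vg`).  Multiple early saccades in one trial are
all retained and flagged in the audit.  The 100 ms grace window counts from
go *onset*.  Mode assignment: first strictly below the threshold, second at
or above — monotone in the threshold by construction.

## Mixture fitting and the crossing point

EM on the pooled per-block latencies: responsibilities from the current
weighted normal densities, then weighted mean/SD/weight updates; SDs are
floored at 1 ms to prevent variance collapse; convergence when the
log-likelihood improves by less than 1e-8 (cap 1,000 iterations).
Initialization: means at k evenly spaced sample quantiles, pooled SD,
uniform weights, plus 9 mean-jittered restarts from a fixed-seed stream;
best final log-likelihood wins; components are relabeled in ascending-mean
order, so input order is irrelevant (the sample is sorted on entry).
Degenerate outcomes (weight < 1/n, SD at floor, zero-variance input) are
flagged or raised, never silently returned.

Selection: `bic` minimizes `-2 LL + (3k - 1) log n`; `lowest_ll`
takes the literal minimal log-likelihood, which — since LL is
non-decreasing in k — effectively picks the smallest k and is kept, with a
logged warning, because that convention appears in the applied literature.
Ties break toward smaller k.  On the default generator both rules land on
k = 2.

The crossing point solves `w1 N(x; mu1, s1) = w2 N(x; mu2, s2)` via the
quadratic in the log densities (linear when s1 = s2), using the
numerically stable quadratic-root form; the root returned is the one in the
open interval (mu1, mu2) where dominance flips from the low-mean to the
high-mean component, validated in tests against a 0.001 ms grid search.
If a selected fit has k > 2 the crossing of the two lowest-mean components
is used (warned).  The density cut equals the maximum-posterior cut except
in the multi-root geometry created by strong weight asymmetry;
`posterior_cut_discrepancy` measures the affected observations.

Censoring at `FP + 100` ms is deliberately ignored by the fit, as it is in
practice; in the 400 ms block this truncates the anticipatory component
(~19% of its mass), compressing its fitted mean and SD by a roughly
FP-stable amount, which is why trend recovery survives it: the measured
mean shifts are nearly constant across blocks and the SD slope bias is
below 0.005 ms/ms.  The tests measure this bias rather than correct it.

## Trend estimators

* **Two-stage slope**: OLS slope per subject, then group mean and
  SE = SD/sqrt(n) across subjects — the transparent equivalent of the
  fixed effect in a subject-random-intercept model on balanced data, and
  validated against statsmodels MixedLM within combined uncertainty.  With
  n subjects the 2-SE interval has t(n-1) coverage, ~94.5% at n = 25.
* **SD trend**: block-level pooled SDs regressed on FP by simple least
  squares; the SE propagates `var(SD_b) ~= SD_b^2 / (2(n_b - 1))` through
  the OLS coefficients, because a residual SE on four nearly collinear
  points is numerically meaningless.
* **Rate trend**: Poisson log-linear slope of subject x block counts on FP
  (statsmodels GLM/IRLS) with per-subject log-mean offsets absorbing
  subject level; the anticipatory occurrence probability is per *trial*,
  not per unit time — a per-time hazard would be an equally defensible
  model the data cannot distinguish.
* **Spearman**: Pearson correlation of midranked data (average ranks on
  ties), checked against a brute-force midrank oracle and scipy.
* **Random-intercept contract**: Gaussian via MixedLM (ML; BIC =
  `-2 LL + p log n`, p = fixed effects + 2 variance parameters); Poisson
  via GLM with subject offsets as a documented approximation.  Estimates
  and SEs are reported; the alpha = 0.01 convention is carried only as a
  reporting default, no p-value gating.

## Problem sizes

The test suite and `scripts/acceptance.py` use the full default experiment
(12,000 trials) for event-level analyses, 560 rendered trials (5 subjects x
4 x 28, noise 0.15 deg, amplitudes >= 2 deg) for detector fidelity, 2,000
points for EM recovery, and 100 random mixtures for the crossing-point
oracle — sizes at which every sampling-error band in the tests is
comfortably inside its tolerance.

## Known limitations

* The latency mixture ignores censoring; thresholds in the 400 ms block
  are biased a few ms low relative to the uncensored process.
* Threshold-based mode labels are contaminated near the cut (anticipatory
  mass below it, impulsive mass above it); with adaptive per-block
  thresholds the contamination is small, but mode-conditional statistics
  (e.g., the 1st-mode SD) inherit a detectable truncation signature.
* The detector has no adaptive (noise-scaled) thresholds and no
  glissade/PSO handling; binocular conjugacy is out of scope (one
  cyclopean trace).
* Whether two early processes can fire in a single trial, and whether the
  anticipatory occurrence is per-trial or per-time, are modeling choices,
  not inferences.
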