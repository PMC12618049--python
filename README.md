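# saccmix

Two-process analysis of **early saccades** in blocked-foreperiod oculomotor
tasks, for researchers studying anticipation, impulsivity and oculomotor
timing.

In a foreperiod (FP) paradigm, a warning stimulus (WS) offset starts a
delay — here 400, 900, 1,400 or 1,900 ms, constant within a block — after
which a "go" target appears in one of four eccentric boxes whose prior
probability is set by a spatial cue (SU levels with target probabilities 1,
1/2, 1/3, 1/4; Shannon surprise `SU_n = -log2 P(TB_n)` bits).  Saccades
launched before the target can be visually driven are *early*, and their
latency distribution is bimodal:

* a **1st (impulsive) mode** peaking near 200 ms after WS offset, whose
  latency is independent of the foreperiod and whose occurrence rate decays
  log-linearly with FP;
* a **2nd (anticipatory) mode** whose latency mean and SD grow linearly
  with FP (*scalar expectancy*), with larger amplitude and peak velocity.

`saccmix` implements the full analysis chain plus a calibrated synthetic
generator so every stage is testable without recordings:

1. **simulate** — per-trial 500 Hz gaze traces and ground-truth events from
   the two-process model (25 subjects x 4 blocks x 120 trials by default);
2. **detect** — saccade detection by amplitude (>1 deg), velocity
   (>22 deg/s) and acceleration (>3,800 deg/s^2) criteria on
   Savitzky–Golay-differentiated traces, with blink/drift artifact
   rejection;
3. **classify** — latency windows on the FP-onset clock: early
   (`0 <= latency < FP + 100` ms) vs visually guided (`>= FP + 100` ms),
   with the standard exclusions (latency > 1,000 ms after go, saccade after
   an early saccade, wrong target box);
4. **fit-mixture** — from-scratch EM fitting of k-component Gaussian
   mixtures (k = 2..5, max 1,000 iterations, restarts) to each block's
   early-latency distribution, model selection, and the analytic
   **crossing point** of the two components — the latency where
   `w1 N(x; mu1, s1) = w2 N(x; mu2, s2)` — as the mode threshold;
5. **stats** — mode x FP x SU summaries, two-stage per-subject slopes,
   block-SD trends, Poisson rate trends, Spearman rank correlation, and a
   delegated random-intercept mixed-model fit with BIC.

## Worked example

```sh
saccmix run --seed 3 --outdir out --rule bic
```

runs the default experiment event-level and prints (abridged):

```
trials: 12000  seed: 3
surprise (bits): SU1=0.00, SU2=1.00, SU3=1.58, SU4=2.00
early-trial fraction: 0.075  VG-trial fraction: 0.793
FP 400 ms: k=2, threshold=344.9 ms, means=[201.4, 428.5]
FP 900 ms: k=2, threshold=345.0 ms, means=[194.3, 730.5]
FP 1400 ms: k=2, threshold=388.8 ms, means=[213.3, 1047.9]
FP 1900 ms: k=2, threshold=423.9 ms, means=[201.8, 1366.9]
mode2_latency_vs_fp: +0.6179 (SE 0.016)
mode1_latency_vs_fp: +0.006408 (SE 0.0067)
mode2_sd_vs_fp: +0.1637 (SE 0.0099)
mode1_sd_vs_fp: +0.001936 (SE 0.0052)
mode1_log_rate_vs_fp: -0.001021 (SE 0.00011)
mode2_log_rate_vs_fp: +0.0002765 (SE 7.5e-05)
Vmax mode2-mode1: +14.2 deg/s  amplitude mode2-mode1: +0.65 deg
mode-count Spearman r: 0.69  counts: {'first': 325, 'second': 576}
```

Reading this: about 8% of trials contain an early saccade and 79% end in an
accepted visually guided response.  Each FP block's early-latency
distribution is best described by two Gaussian components whose crossing
point (~345–424 ms here, compare the classic 375 ms cut) splits impulsive
from anticipatory responses.  The recovered trends match the generating
two-process structure: anticipatory latency grows at ~0.61 ms per ms of
foreperiod and its SD at ~0.17 ms/ms, while impulsive latency is flat and
the impulsive rate falls at ~-0.001 log-units per ms.  Anticipatory
saccades are faster and larger, and subjects who make many impulsive
saccades also make many anticipatory ones (Spearman r ~ 0.7 at this seed).

The same pipeline runs on raw traces (`saccmix simulate --traces`,
`saccmix detect`, `saccmix classify`, `saccmix fit-mixture`), or from the
library:

```python
from saccmix import build_default_config, run_analysis
report = run_analysis(build_default_config(), seed=3)
```

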