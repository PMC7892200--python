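# Methods

This note documents the generative model behind the synthetic cohorts, the
analysis conventions the pipeline commits to, the places where the design
was genuinely open and what was decided, and the limits of what passing
tests demonstrate.

## Generative model

A trial's F1 track on the 3 ms frame grid (time `t` in ms from voice
onset, trial duration 2000 ms) is

```
f1(t) = f1_baseline
      + trend_amplitude · exp(−t / trend_tau)      # vowel-onset transient
      + s                                          # feedforward state
      + c(t)                                       # feedback compensation
      + ε_trial + ε_frame(t)                       # Normal(0, σt²), Normal(0, σf²)
```

For a perturbation of signed magnitude `p` starting at `t_p`, compensation
opposes the shift with gain `g`, sensing latency `L` and a first-order
rise:

```
c(t) = 0                                            t < t_p + L
c(t) = −g·p·(1 − exp(−(t − t_p − L)/τc))            while perturbed
c(t) → 0 with time constant τc                      after a transient ends
```

The offset of a transient perturbation is sensed with the same latency
`L` as its onset — a symmetric-latency assumption; the underlying
experiment provides no post-offset decay data, so the symmetric decay is a
modeling choice, not an empirical claim. `τc = 0` degenerates to a step.

The gain is magnitude-dependent: gentle (|p| ≤ 100 Hz) perturbations are
opposed with `g × boost`, where the participant-specific boost (mean 2.0,
SD 0.5) reproduces the robust empirical finding that *percent*
compensation is roughly twice as large for 50 Hz as for 200 Hz shifts.
The boost is drawn separately for mid- and whole-utterance control but
correlated by the same knob that couples the base gains (below), so
uncoupled cohorts carry no hidden within-participant association.

Across the trials of an adaptation session the feedforward state follows
a single-rate learning rule,

```
s[k+1] = r·s[k] − β·p[k],    s[1] = 0,
```

with retention `r ∈ [0, 1)` and learning rate `β`; a constant `p` drives
`s` to the plateau `−β·p/(1−r)`, i.e. `100·β/(1−r)` percent adaptation.
Single-rate learning is a deliberate minimal fixture: the analysis
pipeline quantifies adaptation non-parametrically and never fits this (or
any) learning model, so richer two-rate or context-dependent dynamics are
out of scope by design.

## Cohort-level parameters

`CohortConfig` draws each participant's parameters from independent
normals except for the triple (g_mid, g_whole, β), which shares a
correlation matrix with two knobs: `rho_mid_whole` couples the two
compensation gains (and the two boosts), `rho_comp_adapt` couples both
gains with the adaptation rate. Defaults of the "realistic" preset
(`rho_mid_whole = 0.8`, `rho_comp_adapt = 0.0`) encode the study's
qualitative findings — mid- and whole-utterance compensation correlated,
compensation and adaptation not.

Realistic-preset population values (mean, SD):

| parameter | mean | SD | units | basis |
|---|---|---|---|---|
| f1_baseline | 600 | 50 | Hz | typical sustained /ɛ/ F1 |
| trend_amplitude / trend_tau | 30 / 80 | 10 / 15 | Hz / ms | onset transient of sustained vowels |
| g_mid / g_whole | 0.03 / 0.05 | 0.027 / 0.045 | – | group means ~3 % and ~5 %; SDs set so participant-level percent spreads match published group SEMs × √n (~3–5 % SD at ±200 Hz), which also yields a realistic minority of non-compensators |
| small-perturbation boost | 2.0 | 0.5 | – | 50 Hz percent responses ≈ 2× the 200 Hz ones |
| comp_latency L | 275 | 30 | ms | response onsets cluster at 200–325 ms |
| comp_tau τc | 120 | 25 | ms | sub-second saturation of the rise |
| adapt_rate β / retention r | 0.0045 / 0.95 | 0.005 / 0.015 | – | plateau 100·β/(1−r) ≈ 9 % with an ~11 % participant SD, matching published adaptation means and spreads |
| noise_frame σf / noise_trial σt | 6 / 12 | 1 / 3 | Hz | formant-tracking jitter vs. trial-to-trial production variability |

~3 % of "head" trials are flagged excluded under the realistic preset to
exercise the screening path. Presets: `realistic` (defaults above),
`clean` (all SDs and noise zero, boost 1 — closed-form checks),
`high_snr` (σf = 1, σt = 1.5, fixed latency — recovery tests),
`compensator` (gains clipped non-negative).

## Analysis conventions

All timestamps are milliseconds from voice onset; windows are half-open
`[a, b)`. The 25 ms smoothing bins are anchored at the alignment zero
(perturbation onset for compensation analyses), with frames assigned by
half-open membership; with 3 ms frames a bin holds 8–9 frames.

**Trend (step 1).** Per participant, the mean of all good unperturbed
"head" trials across the three unpredictable sessions, each re-referenced
to its voice-onset value. Per-session re-analyses (carry-over checks)
still use this pooled trend — a session-restricted trend from ≤10 trials
would inject avoidable noise.

**Onset latency.** The threshold is mean ± 2 SD of the pooled group-mean
bins in [0, 50) ms across the four magnitudes of a perturbation type. Two
corrections to the naive reading were required to make the detector
usable:

* *Pool-SD inflation.* Step-2 re-referencing forces each trial's mean over
  [0, 50) ms to zero, so the pooled onset-window bins have their variance
  deflated by (m−1)/m relative to the bins being scanned (m bins per
  condition in the window; m = 2 here). The pool SD is multiplied by
  √(m/(m−1)) to undo this. Without the correction the nominal 2 SD
  threshold is ≈1.4 SD of the scanned bins.
* *Persistence.* A crossing must hold for 3 consecutive bins (75 ms).
  Against an estimated threshold, a single-bin rule false-alarms on ~5 %
  of scanned bins at *any* noise level (the rate is scale-free), so with
  11–18 pre-response bins a spurious early latency would occur in roughly
  40 % of runs. Sustained responses — the only kind this experiment
  elicits — still date from their first crossing bin.

Even with both corrections, scanning ~30–80 bins means null data produce
occasional spurious crossings; a detected latency should be read jointly
with the magnitude tests, not as stand-alone evidence of a response.

**Peak compensation.** The group peak latency is the extremum of the
group-mean response in the compensatory direction, searched from the
onset latency (or the end of the reference window if none was detected)
to perturbation offset + 300 ms for transient perturbations or the end of
common coverage for whole-utterance ones; exact ties — flat plateaus of
noise-free responses — resolve to the middle of the tied run so the
200 ms window sits inside the plateau. The participant statistic is the
mean over the window [peak − 100, peak + 100) ms, converted to percent
with compMult = −sign(p); the signed extremum (not |response|) defines
the peak, so anti-compensatory "following" responses are never promoted.

**Adaptation.** Early means use [0, 75) ms (25 frames); the baseline
reference is head trials 1–30; the late-phase statistic is head trials
76–90; five-trial smoothing drops a trailing remainder. Head ordinals are
assigned from the schedule, so screened-out trials keep their position
and contribute missing values; up to 3 missing trials are tolerated per
15-trial analysis window (and 6 per 30-trial baseline), with means over
the available trials.

**Outlier rule.** A participant is excluded when their adaptation
percentage lies more than 3 cohort SDs (computed about the mean) from the
cohort *median*, per direction, single pass, union over directions. The
centering/dispersion pairing of "SDs from the median" is ambiguous in
common usage; this pairing is the package's reading and is applied before
all downstream analyses.

**Within-trial dynamics.** Analysis phases are head trials 16–30, 31–45,
76–90 and 106–120; time-courses are normalized by the participant's mean
time-course over head trials 1–30 (head trials, not all trials — matching
the baseline convention of the across-trial analysis). The late-adaptation
onset-window percent equals the across-trial adaptation statistic by
construction (linear operations commute); this identity is regression-
tested at 1e−9.

**Mixed models.** Fitted by REML via statsmodels `MixedLM`. Term tests
are Wald F tests with residual df (n_obs − rank X); the participant-level
regressions (`whole ~ mid`, `adapt ~ unpredict`) instead use group-level
df (n_groups − 2), since their regressors carry one unit of information
per participant — residual df proved anti-conservative (type-I ≈ 0.065
vs. ≈ 0.053 with group df in a 400-replicate pilot). With one observation
per group the random intercept is unidentifiable and the fit collapses to
OLS (flagged `reduced_to_ols`); singular-Hessian boundary fits likewise
fall back to a flagged OLS fit rather than raising. No multiple-testing
correction is applied anywhere by default; `benjamini_hochberg` is
available for users who want one. Exact replication of any particular
software's denominator-df arithmetic is a non-goal.

## Problem sizes in the test suite

Closed-form and formula tests run on miniature schedules. The stochastic
recovery tests use 22-participant cohorts with reduced trial counts per
condition (10–20 "head" trials instead of 45, catch trials omitted) —
sizes chosen to keep the per-participant measurement error well below the
tolerances being asserted: latency recovery uses 51 high-SNR cohorts
(3 true latencies × 17 replicates, 4 conditions each), regression power
uses 60 measured cohorts at 12 trials/condition, and type-I calibration
uses 1000 replicates of the cohort parameter draws with per-direction
measurement noise at the precision the full design implies (≈0.9 % for
±200 Hz compensation means, ≈1.9 % for adaptation percentages) —
simulating full track-level cohorts a thousand times would add nothing to
what the draw-level test checks (the generator's coupling knobs and the
inference layer) at three orders of magnitude more compute.

## What the synthetic cohorts do and do not establish

The simulator emulates: sustained-vowel F1 tracks on the real frame grid,
participant-level heterogeneity in gains, latencies and learning rates at
published spreads, magnitude-dependent percent compensation, trial- and
frame-level noise, catch trials, jittered transient perturbations, and a
realistic screening exclusion rate. It does not emulate: formant-tracking
gross errors or octave jumps, voicing onset/offset detection errors,
session-level drift or fatigue, somatosensory contributions, response
shapes other than first-order exponentials, or adaptation dynamics beyond
a single-rate rule. Passing recovery tests therefore demonstrates that
the pipeline measures what the model generates at realistic noise — not
that real speakers behave like the model; conclusions about real data
inherit only the pipeline's arithmetic correctness, its invariances, and
its calibrated inference, not the effect sizes of the presets.

## Numerical choices

Normalization invariants hold to 1e−9 Hz and are enforced by tests at
that tolerance. Binning uses exact half-open floor division; CSV/TSV
round trips are lossless (17-significant-digit floats, round-trip float
parsing). Degenerate statistics (zero variance) are reported with flags,
never as silent NaNs: a one-sample t on a constant nonzero sample reports
p = 0 with `degenerate=True`. Zero-SD onset pools raise unless the
scanned response is exactly constant (then: no latency). The
whole-utterance perturbation duration is `inf` end-to-end, serialized as
`inf` in CSV. One top-level seed drives everything; per-participant
streams are derived from it with fixed labels, so schedules, cohorts and
full pipeline runs are byte-reproducible.
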