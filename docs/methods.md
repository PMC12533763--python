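# Methods

## The estimand and the procedure

Let `p_r(t)` be the proportion of valid gaze samples inside image role
`r`'s region of interest in the 20 ms bin starting at `t`, averaged over a
participant's trials. For a contrast between roles `a` and `b`, the
divergence point (DP) is the start of the first run of `k = 10`
consecutive bins in which a one-sample t test of the participant-level
differences `d_i(t) = p_a,i(t) − p_b,i(t)` against zero is significant at
`α = 0.05`. Ten consecutive 20 ms bins = 200 ms of sustained difference;
the run requirement is what protects the onset estimate against isolated
significant bins.

The DP's sampling distribution is estimated by a nonparametric bootstrap
over participants: each of `B = 2000` resamples draws `n` participants
with replacement within the group (a participant drawn twice counts
twice), recomputes every bin test and the run scan, and records the onset.
Resamples with no qualifying run are *nonconvergent*: they are excluded
from the mean and CI and counted (a warning fires above 20%). The summary
is the arithmetic mean of convergent onsets plus a percentile 95% CI.

Group contrasts pair resample `j` of one group with resample `j` of the
other (groups are bootstrapped independently; index pairing is an
arbitrary but valid coupling) over pairs where both converged. The mean
difference is reported as comparison-group minus reference-group, with a
percentile CI and a three-way verdict: `not_different` if the CI strictly
straddles 0, `marginal` if a bound sits exactly at 0, `different` if 0
lies outside the CI.

## Statistical choices

* **Test.** Paired one-sample t test on participant-level differences,
  one-sided (`a > b`) by default because every standard contrast is
  directional; two-sided available per contrast. Bins with fewer than two
  contributing participants are never significant. Zero-variance bins
  follow the limiting t statistic: a constant positive difference is
  significant, constant zero or negative is not.
* **CI flavor.** Simple percentile (2.5th/97.5th), taken with
  closest-observation quantiles so endpoints are themselves observed,
  bin-aligned onsets. The bootstrap mean is fractional.
* **Resampling unit.** Participants only, items fixed — the minimal
  scheme that matches the t test's unit of analysis. Item-level
  resampling is not implemented; with only participant-level aggregated
  series in the bootstrap there is nothing for it to act on. This is a
  known limitation: resampling trials as well would widen the CIs
  slightly.
* **Onset-search windows.** Each contrast restricts its search to the
  span where the effect is theoretically possible: from the (bin-rounded)
  verb onset, 700 ms, for verb-driven prediction contrasts, and from the
  object-word onset, 1440 ms, for integration and filler contrasts.
  Fixations are several bins long, so bin-wise tests are strongly
  autocorrelated; over a long pre-divergence baseline, chance runs of ten
  significant bins occur in a nontrivial fraction of resamples (about 7%
  in pilot simulations with a full-sentence window), biasing the
  bootstrap mean early. Cropping the timecourse to the window of interest
  is standard DPA practice and removes this contamination. Windows are
  per-contrast configuration, not fixed constants.
* **Randomness.** One master seed; each (group, contrast) pair gets a
  deterministic substream (CRC-32 spawn keys), so adding a group or
  contrast never perturbs another's resamples, and identical configs
  reproduce bit-for-bit.

## Preprocessing rules

* ROI containment is closed on all edges; the four padded boxes are
  pairwise disjoint so membership is unique. The screen geometry places
  300×300 px images in the corners of a 1024×768 screen inset by a 32 px
  margin; the 50 px pad is clamped at screen edges. (Two 400 px padded
  boxes cannot both fit unclamped in 768 px; the 32 px margin keeps the
  clamped boxes disjoint with a 4 px gap. The margin is this package's
  choice — any value ≤ 34 px preserves disjointness.)
* A bin's proportion for a role is `(valid samples in ROI) / (valid
  samples in bin)`; off-ROI looks stay in the denominator, so role
  proportions sum to ≤ 1 and the remainder is off-ROI looking.
* Invalid samples (blinks, track loss, saccade gaps) are removed from
  numerator and denominator; a bin with no valid samples is missing, not
  zero — zeroing would bias proportions downward during blinks.
* Participant timecourses are unweighted means over trial-level bin
  proportions (each trial equal weight); missing trial-bins are excluded
  bin-wise with per-bin `n_trials` bookkeeping.
* Accuracy is recomputed from the clicked role against the condition's
  correct role; a supplied accuracy column is cross-checked and mismatches
  logged. Incorrect trials are dropped from the DPA by default.
* Fixation-event reports are expanded to the sample grid before binning,
  so both input flavors share one representation.
* Time zero is audio onset. The 2000 ms preview lives at negative times
  and is excluded from the default analysis window, which runs to the
  selection cue (audio end + 2000 ms). The sentence frame is
  duration-normalized, so one set of word onsets (verb at 706.30 ms,
  object word at 1438.62 ms) applies to every item; `round_to_bin`
  (nearest bin multiple, half-bin ties up) maps these to the reporting
  grid (700, 1440).

## The synthetic generator

The generator emulates what the analysis consumes, not the oculomotor
system:

* **Fixation persistence.** Durations are Gamma(shape 4, mean 250 ms);
  landing role is drawn once per fixation, at its onset, from the
  condition's role-probability curves. This produces the bin-to-bin
  autocorrelation that makes bin-wise tests non-independent — per-sample
  independence would make the t tests anticonservative and the recovery
  tests meaningless. 30 ms invalid gaps between fixations exercise the
  missing-sample rules.
* **Looking curves.** Piecewise-logistic role probabilities that always
  sum to 1. Baselines are equal across roles (0.25), so each contrast's
  latency parameter is exactly the time its two roles' probabilities
  separate — the estimand DPA targets. The default logistic scale is
  5 ms, a near-categorical switch: with graded slopes (≥ 25 ms) the
  "true latency" becomes ill-defined at bin resolution because the curves
  separate detectably well before the midpoint. Asymptotes: target 0.85,
  other roles 0.05; the two-stage condition passes through a shared
  0.45/0.45 stage between its early and late transitions.
* **Design structure.** Default item counts 24 + 24 constraining items,
  16 two-stage items, 40 fillers; groups of ~30 participants; per-trial
  counterbalanced rotation of image placements. Default group latencies
  mirror the qualitative pattern the design anticipates: identical
  early-stage latencies across groups, late-stage latencies delayed by
  +115/+190 ms in the two hearing-loss groups. These offsets are
  generator defaults for producing realistic-looking cohorts, not
  empirical claims.
* **Metadata.** Intelligibility, effort, age and hearing level are
  clipped-normal stand-ins per group so filtering and regrouping
  operations have realistic inputs.

What passing recovery tests show: the estimator correctly localizes a
sharp, participant-homogeneous preference shift under realistic fixation
dynamics and sampling noise. What they do not show: behavior under graded
or participant-heterogeneous shifts, lexical competition dynamics,
verb-driven transient looks, smooth pursuit, or drift/calibration error —
none of which the generator models.

## Numerical and degenerate-input conventions

* Bins are half-open `[t, t + 20)`; a trailing partial bin is dropped.
* Zero-variance detection uses a 1e-12 tolerance on the sample SD
  (constant columns accumulate ~1e-17 rounding noise).
* `detect_onset` returning "no divergence" is a valid outcome, not an
  error; zero convergent resamples is an estimation error, reported as
  such rather than silently dropped.
* An empty group, fewer than two participants, a search window shorter
  than the run criterion, overlapping regrouping rules, and unknown
  metadata fields all fail fast with named errors before computation.
* Problem sizes in the test suite: recovery studies use 50 cohorts of 30
  participants × 24 items at 200 resamples — large enough that
  Monte-Carlo error on coverage is a few percent, which the ≥ 85%
  coverage threshold absorbs.

## Pipeline configuration

`vwpdpa run --config config.yaml` drives load → filter → regroup →
bin → DPA → report. The YAML surface:

```yaml
paths: {samples: samples.tsv, trials: trials.csv, participants: participants.csv}
timeline:
  durations: {the1: 93.58, agent: 612.72, verb: 602.05, the2: 130.27, object: 464.45}
  post_delay_ms: 2000
bin: {bin_ms: 20, window_start_ms: 0, window_end_ms: null}   # null → selection cue
filters:
  - {field: intelligibility_pct, op: ">=", value: 50, name: poor_intelligibility}
regroup:            # optional, e.g. effort-based regrouping
  - {label: PwHL_low_effort,  rules: [{field: group, op: "!=", value: PwNH},
                                      {field: effort_rating, op: "<", value: 15}]}
reference_group: PwNH
dpa: {n_boot: 2000, alpha: 0.05, tail: greater, consec_bins: 10, ci: [2.5, 97.5]}
seed: 1
output_dir: results
```

Contrasts default to the five standard ones (prediction, cost, early,
late, filler) and can be overridden per run. Outputs: accuracy summary
CSV, filter log JSON, DPA results CSV/JSON (config echoed for bit-for-bit
reproduction), group differences CSV with verdicts, one figure per
contrast with word-onset lines, DP marker and CI whisker (plus a
`_data.csv` of the plotted curves), and a JSON-lines stage log with
per-stage counts.
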