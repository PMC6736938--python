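# Methods

## The assessment and its scoring model

The protocol presents ten short task movies and pictures over 178 s on a
monitor (modeled after a 1280 × 1024 display) while gaze is sampled at a
nominal 50 Hz. Each scored task shows a correct-answer image (the target)
among distractors; a rectangular region of interest (ROI) covers the
target. The per-task measure is the fraction of *valid* gaze samples in
the task's choice window that fall inside the target ROI. Two modeling
commitments follow from how such scores are defined in practice:

* **Sample counting, not event parsing.** No fixation/saccade
  segmentation is performed; every valid sample contributes one nominal
  sampling period (1/50 s) of dwell. At a fixed nominal rate, sample
  counts and dwell time are proportional, and counts are robust to
  dropped frames.
* **Valid-time denominator.** The denominator is the count of valid
  samples in the window, never the window duration, so blinks and
  tracking loss affect precision but not the expected score. A sample
  flagged invalid is excluded from numerator and denominator alike and
  its coordinates are never read.

The aggregate score is 100 × the unweighted mean of the per-task
fractions over the nine scored tasks (3, 4, 5, 6, 7, 8, 9, 10 and the
memory-recall task 1-b). Tasks 1-a (memory encoding) and 2 (smooth
pursuit, a qualitative oculomotor check) are displayed but unscored.

### Default timeline

Printed task durations are 14 s (1-a), 11 s (2), 10 s (3), 20 s (4),
56 s combined (5–7), 24 s combined (8–9), 20 s (10) and 10 s (1-b),
summing to 165 s; the recall task begins 154 s after encoding ends and
the sequence lasts 178 s in total. The remaining 13 s are inter-task
transitions; we place 1 s after each of tasks 2–9 and 5 s after task 10
(all before recall), which is the arithmetic that reconciles all three
anchors: 14 + 154 = 168 s recall onset, 168 + 10 = 178 s total. The
combined blocks are split 14/18/24 s (difficulty and therefore length
rise across the attention/calculation tasks 5–7) and 12/12 s. Two-part
tasks (4, 5–7, 8–9, 10) consist of a cue/count display followed by the
choice display; only the choice part is scored, and the default split is
the second half of the task window. All of this is config-editable YAML;
scoring is split-invariant for analyses that consume per-task fractions.

Default ROI rectangles place the target in a plausible grid cell of each
task's layout (e.g. one cell of a 3 × 2 array for the odd-one-out task).
The true stimulus geometry is not published, so these defaults are
placeholders that must be recalibrated against the actual media before
scoring real recordings. Containment is half-open, [x0, x1) × [y0, y1),
and window membership is half-open in time, so tiled ROIs and adjacent
windows never double-count a sample.

### Quality control

A task fraction is *undefined* — never coerced to 0 — when fewer than
10% of the window's samples are valid (`min_valid_fraction`), preventing
a lone surviving sample from becoming a 0% or 100% task score. The
aggregate is the mean of the defined fractions with `n_tasks_used`
reported; overall QC fails below 7 of 9 tasks (`min_tasks`). Both
thresholds are package choices (the score definition itself is silent on
missing-task handling); averaging the available tasks preserves the
unweighted-mean definition. Recording efficiency is the valid fraction
over the whole sequence span.

## Heatmaps

The dwell grid deposits one sampling period per valid sample into the
containing cell of an r × c grid over the unit square (half-open cell
edges; the coordinate 1.0 folds into the last cell). In histogram mode
the cell sum equals the valid dwell time in the window exactly. Optional
Gaussian smoothing uses reflected boundaries and rescales to the
pre-smoothing total, so mass is conserved to floating-point precision;
consequently, when the grid is aligned to a task's ROI edges, the grid's
ROI mass fraction equals the task score exactly — a cross-module identity
the tests assert.

## Synthetic gaze generator

The generator reproduces the statistical structure the score depends on,
not saccade kinematics. During a choice window, gaze alternates between
an on-target state (ROI center + isotropic Gaussian jitter, SD 0.03 of
screen width, clipped inside the ROI) and an off-target state (uniform
over the non-ROI screen), with independent exponential dwell times. For
exponential dwells the long-run occupancy has the closed form

    p_target = E[dwell_on] / (E[dwell_on] + E[dwell_off]),

and the process is the two-state continuous-time Markov chain whose
indicator autocovariance is p(1−p)·exp(−r|u|) with
r = 1/E[dwell_on] + 1/E[dwell_off]; hence the time-average occupancy over
a window of length T has asymptotic variance ≈ 2p(1−p)/(rT). That
closed form is the oracle for the parameter-recovery tests: measured
fractions must fall inside the CLT interval around p_target, and the
recovery error must shrink like 1/√T. The default on-dwell mean is 1 s.

Outside choice windows gaze follows a center-biased AR(1) walk
(stationary SD 0.12, lag-one coefficient 0.95 at 50 Hz) — unscored,
present so heatmaps and efficiency traces look plausible. Tracking loss
(blinks, head turns) arrives as a Poisson episode process (default rate
0.1/s) with exponential durations (default mean 0.25 s), including a
lead-in so episodes already in progress at the first sample are
represented; the long-run invalid fraction is 1 − exp(−rate·mean), about
2.5% at the defaults.

### Cohorts

The default cohort reproduces the three-group clinical design: 27
healthy controls, 26 MCI, 27 dementia, with MMSE drawn from truncated
rounded normals with the published group means (SD): 28.7 (1.6),
25.7 (3.0), 16.0 (4.4). Group target occupancies are 0.75 / 0.55 / 0.35
— free parameters chosen to give clear but overlapping separation, not
estimates of any published value. A subject's occupancy is

    p = clip(p_group + 0.5 · 0.1 · z_MMSE + N(0, 0.08), 0.02, 0.98)

where z_MMSE is the subject's within-group MMSE z-score. The middle term
is the MMSE–gaze coupling knob (weight 0.5, scale 0.1 occupancy per
z-unit; set the weight to 0 for independence). The last term is
between-subject heterogeneity the clinical score does not explain;
without it the group score distributions separate perfectly (AUC = 1),
which no real screening instrument achieves. With both terms the
simulated cohorts sit in a clinically plausible regime — Spearman
ρ(et_score, MMSE) ≈ 0.8, MCI-vs-HC AUC ≈ 0.9 — without being tuned to
reproduce any particular published estimate. Per-subject RNG streams are
spawned from the master seed keyed by global subject index, so the same
seed reproduces a cohort byte-for-byte and appending subjects never
perturbs existing ones.

What the generator does **not** emulate: saccade latency/velocity
profiles, smooth-pursuit gain, pupil dynamics, calibration drift,
off-monitor gaze (treated as loss), age/education effects, and any
dependence of tracking loss on disease severity. Passing tests therefore
demonstrate the pipeline's internal correctness and calibration, not
clinical validity on real recordings.

## Statistical layer

* **Spearman correlation** uses midranks for ties; the two-sided p is an
  exact full permutation enumeration for n ≤ 10 and the t-approximation
  on n − 2 df otherwise.
* **Kruskal–Wallis** reports the tie-corrected H with a chi-square p on
  k − 1 df (optionally Monte-Carlo permutation or exhaustive
  enumeration). The effect size is epsilon-squared, H/(n − 1), the rank
  analogue of eta-squared. (Reporting Cramér's V for a rank test, as is
  sometimes seen, is nonstandard; V is reported only for contingency
  tables.) An all-identical sample is degenerate: H = 0, p = 1.
* **Steel–Dwass** computes, per pair, the Wilcoxon rank-sum statistic on
  that pair alone, standardizes with the tie-corrected variance, and
  refers √2·|t| to the studentized-range distribution with k groups and
  infinite df. Exact small-sample tables are out of scope.
* **One-way ANOVA** reports F, eta-squared = SS_between/SS_total, and
  Tukey–Kramer pairwise p-values (unequal-n form via the
  studentized-range distribution).
* **Chi-square independence** is the Pearson statistic without
  continuity correction (the comparisons of interest have df = 2; the
  Yates correction applies to 2 × 2 tables).
* **ROC/AUC** fixes the direction lower score ⇒ impaired (both the
  eye-tracking score and the MMSE fall with impairment):
  AUC = P(score_impaired < score_healthy) + ½·P(tie), the normalized
  Mann–Whitney U. The 95% CI is a stratified percentile bootstrap
  (default 2000 replicates, seed required). Percentile intervals can, in
  skewed boundary cases, straddle the point estimate; bounds are widened
  to include it so the ordering ci_low ≤ AUC ≤ ci_high always holds.
  At n ≈ 27 per class, percentile intervals cover mildly below nominal
  (≈ 91–92% observed in the null-calibration suite), a known property of
  the method.

`cohort_report` runs the full battery — correlations against each
available clinical score, group comparisons by clinical group and MMSE
band (Low 0–20, Middle 21–26, High 27–30), four ROC analyses, and
Table-1-style demographics (group sizes, per-score Kruskal–Wallis +
Steel–Dwass, MMSE-band-by-group chi-square) — skipping, with a logged
reason, any analysis whose inputs are missing; clinical subscores are
routinely available only for subsets.

## Numerical and design choices

* Coordinates are normalized to [0,1]² with origin top-left; pixel
  inputs are divided by the screen dimensions at ingest. Out-of-range
  coordinates on valid samples are an error, never clamped.
* Timestamps are seconds; irregular sampling is tolerated (no
  resampling) because scoring counts samples.
* Gaze-log and cohort CSVs are written with shortest-round-trip float
  formatting and read with round-trip float parsing, so write → read is
  an exact identity (property-tested).
* A single gaze stream per recording; binocular sources are expected to
  be averaged upstream.
* Blink encoding is assumed to be an explicit per-sample validity flag;
  whether real devices also emit off-monitor valid samples is
  device-specific, and such samples should be marked invalid at export.
* Problem sizes in the test suite (e.g. 200 null cohorts of n = 80,
  600-s recovery windows, 1000 random AUC fixtures) were chosen as the
  smallest sizes at which the Monte-Carlo bands are meaningfully tight.

## Known limitations

* Default ROI geometry and the cue/choice split are placeholders until
  calibrated against real stimulus media.
* The clinical point estimates reported for the original 80-subject
  study (e.g. ρ = 0.74 with MMSE, MCI-vs-HC AUC = 0.845) cannot be
  recomputed here: the subject-level data are not publicly deposited.
  The simulated cohorts are statistical stand-ins whose group-level
  inputs (sizes, MMSE distributions) follow the published demographics
  but whose gaze parameters are free choices.
* The Steel–Dwass reference is asymptotic; p-values for very small
  groups (n < 5) are approximate.
* Exact Spearman permutation p is limited to n ≤ 10 by factorial cost.
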