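# Methods

This note documents the models, free parameters, numerical choices, and
limitations of `numact`. It describes what the code computes; every number
quoted here is produced by the test suite, the examples, or
`scripts/acceptance.py`.

## Block design

A session is nine runs. Each run has four cycles; a cycle is one fixation
trial (2.7-s "random" instruction, 5.4-s fixation, 2.7-s response) followed
by the four discrimination blocks — "1-action", "3-actions", "1-ball",
"3-balls" — each a 2.7-s instruction plus two trials of 5.4-s video and
2.7-s response. Everything is aligned to the 2.7-s TR, giving 128 TRs
(345.6 s) per run, 8 trials per sub-condition per run and 72 per session.

The stimulus space crosses majority action (push/flick), actor gender,
majority ball color (white/orange), actor position (right/left), and
3-level order variants for actions and balls: 144 videos. The balanced
72-video half is chosen by stratifying the 144 videos into the 16 cells of
the four binary factors (9 videos each) and drawing 5 videos from
even-parity cells and 4 from odd-parity cells (seeded within-cell draw);
this guarantees the four 36/36 margins exactly for every seed. Which
videos form the half, and where the single minority event sits within a
clip (serial position = order variant + 1), are free choices of this
implementation; no downstream statistic depends on them.

Within a run the 8 videos form 4 fixed pairs; in cycle *c* the block at
slot *j* shows pair (*j* − *c*) mod 4, a Latin-square rotation under which
every video appears exactly once per block label per run — the multiset of
stimuli is identical across the four attention conditions. Block order per
cycle follows a balanced 4×4 Latin square rotated across runs under a
seeded label permutation, so over the 36 cycles each label occupies each
within-cycle position exactly 9 times. By default the same 72 videos and
schedules are shared across simulated subjects (per-session seed).

## Synthetic BOLD model

Voxels belong to four classes: action-numerosity-tuned, ball-numerosity-
tuned, attention-only, and null. A voxel's noiseless signal is

    y(t) = b · [1 + Σ_c a_c · (h ⊛ x_c)(t) / 100]

with baseline *b*, condition boxcars x_c covering the video periods (and
the 5.4-s fixation periods for Fix), and the canonical double-gamma HRF
*h* (SPM form, via nilearn). Amplitudes a_c are in percent of baseline:
for an action block, a = attention gain + (tuning depth δ_action if the
block's numerosity is the voxel's preferred one); ball blocks analogously;
Fix has amplitude 0. Because simulator and GLM build identical regressors,
OLS recovers the programmed amplitudes exactly on noiseless data (verified
to ~1e-13), which keeps every downstream oracle sharp.

Free parameters (the study reports no effect sizes; these are this
package's defaults, chosen as plausible task-fMRI magnitudes, and all
overridable): baseline 100 a.u. (SD 5 across voxels), attention gains
0.8% (action) and 0.6% (ball) with SD 0.2, tuning depths δ = 0.5% with SD
0.15, preferred numerosity a fair coin, white Gaussian noise SD 1 a.u.
(1% of baseline). Subject variability is a lognormal multiplicative gain
(SD 0.15) plus an additive baseline offset (SD 2 a.u.). Optional AR(1)
noise and linear drift are off by default so that the OLS oracle equalities
stay exact. Six smoothed zero-mean random walks serve as motion nuisance
regressors. Per-ROI class mixtures default to values emulating the
*direction* of the reported selectivity pattern (action-tuned majority in
NPC3/OTS, ball-tuned elsewhere, near-even phAIP); they are free parameters,
not measurements. ROI sizes default to the tabulated voxel counts (449,
417, 470, 306, 152, 86, 203, 419).

`simulate_psc_runs` draws per-run PSC estimates directly (programmed
amplitude + Gaussian estimation noise), the distributional shortcut to the
simulate→GLM path. Property tests that need thousands of replicate
experiments use it; the full path has its own recovery and unbiasedness
tests.

## GLM and percent signal change

One GLM per run (OLS, no prewhitening): condition regressors (3 or 5,
HRF-convolved video/fixation boxcars), six motion columns, and an explicit
constant. PSC_c = 100(β_c − β_Fix)/β_constant, so Fix maps to 0 by
construction and PSC is invariant to rescaling the raw signal. Fitting per
run (rather than one nine-run model) gives the run-resolved responses the
84-split recoding needs without per-split refits; per-split responses are
means of per-run PSCs. Instruction and response periods carry no
regressor; they are nuisance-free gaps by design.

Per-trial MR samples for decoding are the two TRs of each video period
shifted by a hemodynamic lag of 2 TRs (5.4 s, configurable — near the HRF
peak), expressed as % change from the run's equally-shifted fixation-TR
mean. The final trial of a run clips the lag-shifted index at the run
boundary (one duplicated TR); with a trailing response period this affects
at most one sample per run.

## Cross-validated recoding

All C(9, k) selection/evaluation splits are enumerated (k = 3 → 84 splits;
k is configurable 1..8). Preference is the argmax of the unweighted
selection-run mean; the attributed response is the evaluation-run mean of
the correspondingly labelled sub-condition; results are averaged over
splits (the literal reading: responses, not labels, are averaged when
preferences flip between splits). Exact selection ties — impossible with
continuous noise, certain on constant fixtures — are broken by a seeded
coin flip and flagged. Per-split values are kept by default; they are
required by the refined group analysis. The vectorised implementation is
tested for exact equality with the explicit per-split loop.

## ROI ANOVA and Holm

For a 2×2 within design each effect is a single per-subject contrast, so
F = t² of the one-sample t on that contrast with df (1, n−1) — the exact
classical repeated-measures partition (no sphericity issue with 2-level
factors). This closed form is cross-checked against statsmodels AnovaRM
and a textbook sums-of-squares oracle at 1e-10. Holm's step-down rule is
implemented as stated (compare the k-th smallest p with α/(n−k+1), stop at
the first failure) and applied per effect family across the 8 ROIs.

## Selectivity and shuffled null

Ties (dAction = dBall) count as *not below* (strict inequality); with
continuous data this is immaterial, on constant fixtures it is
deterministic. The shuffle reassigns labels within each voxel's action
pair and, independently, its ball pair with probability ½ (the reading
that preserves each measure's marginal distribution and reproduces the
≈50% null mean with binomially scaled SD, ≈100·√(0.25/N)); a full 4-value
permutation per voxel is available behind `scheme="full_permutation"`.
Histograms use 100 equal bins spanning [0, 100] % (the parameter-free
choice); the null mean and SD are computed from the subject-averaged
binned distribution using bin centers. The observed group-average
statistic is computed from subject-averaged responses while the null is
built from per-subject shuffles — this asymmetry mirrors the procedure
being reproduced and is intentionally not "fixed". χ² comparisons are
Pearson, df 1, no continuity correction, with counts recovered from
percentages by rounding (the variant that reproduces the tabulated
worked-example values 80.51 and 21.56). The group analysis computes
per-subject below-diagonal percentages either from replication-averaged
responses (standard) or per replication then averaged (refined); the
refined variant demonstrably reduces across-subject spread.

## Decoding

Linear SVC (libsvm via scikit-learn), C = 1 by default (the regularization
constant is not specified by the procedure being reproduced; 1 is the
conventional default, exposed in config). No per-voxel standardization by
default (z-scoring by training-set statistics is behind a flag). "128
training samples" is read as per class (8 runs × 8 trials × 2 samples);
`sampling="one_per_trial"` provides the halved-count reading for
sensitivity analyses. Fold accuracy is pooled over classes (test sets are
balanced). Chance-level controls permute labels at the trial level within
each run, keeping a trial's two samples together and classes balanced.

## Problem sizes

The test suite and acceptance script scale simulations to desk size as this
package's own defaults for automated verification: the shuffle-null check
uses the full 203 voxels × 21 subjects × 10,000 shuffles; decoding-chance
uses 50 voxels × 21 subjects; unbiasedness uses 2,000 simulated voxels;
the type-I-error check uses 1,000 simulated experiments of 21 subjects ×
16 voxels. The full eight-ROI pipeline at tabulated voxel counts runs from
the CLI in minutes.

## Limitations

No spatial structure (no voxel geometry, smoothing, or registration), no
physiological noise, no slice timing or motion *correction* (only motion
nuisance regressors), and no whole-brain inference — the package starts
where preprocessing ends. Synthetic subjects share schedules and tuning
populations (only gains/baselines vary), so passing tests demonstrate the
statistical machinery's calibration and recovery properties, not the
reliability structure of real BOLD data; in particular the simulator's
voxel reliabilities are homogeneous, unlike real cortex. Real data enter
only as per-voxel, per-run, per-condition PSC tables; upstream artifacts
(acquisition, preprocessing quality) are out of scope.
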