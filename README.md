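# numact

Voxel-level analysis of the **numerosity of observed actions** in
block-design task fMRI.

When we watch someone act on objects, parietal cortex appears to encode not
only *which* action is performed but *how many times*. A featural-attention
paradigm can isolate this: subjects view identical videos — an actor
performs four manipulative acts (push or flick, one act 1× and the other
3×) on four colored balls (white or orange, one color 1× and the other 3×)
— and discriminate either the action numerosity ("1-action"/"3-actions"
blocks) or the ball-color numerosity ("1-ball"/"3-balls" blocks). Because
the stimuli are identical across tasks, any voxel whose numerosity tuning
is deeper under action than ball attention is a candidate
action-numerosity processor. `numact` implements the complete analysis
chain for this design, driven by a synthetic-data module with known ground
truth, and accepts real per-voxel percent-signal-change tables in the same
tidy format.

## What the package computes

- **Stimulus design** — the 2×2×2×2×3×3 = 144-video factorial space, a
  balanced 72-video half (equal margins on gender, majority action,
  majority ball color, actor position), and nine counterbalanced runs of
  4 cycles × (1 fixation trial + 4 discrimination blocks of 2 trials),
  all on a 2.7-s TR grid; BIDS-style events TSVs.
- **GLM / PSC** — per-run OLS fits of 9- or 11-regressor models
  (conditions convolved with the canonical HRF + 6 motion parameters +
  baseline); percent signal change
  `PSC_c = 100 (β_c − β_Fix) / β_baseline`, and per-trial MR samples for
  decoding.
- **Cross-validated recoding** — for every voxel and each of the
  C(9,3) = 84 splits, the action (and ball) sub-condition with the larger
  mean PSC in the 3 selection runs is labelled *preferred*, and the
  response attributed from the 6 evaluation runs; averaging over splits
  yields PA, nPA, PB, nPB. Selection and evaluation never share data, so
  E[PA − nPA] = 0 for untuned voxels (a deliberately circular variant is
  included to demonstrate the bias it would reintroduce).
- **ROI ANOVA** — 2×2 repeated-measures ANOVA (attended feature ×
  preference), each effect tested with df (1, n−1), Holm step-down
  correction (α/(n−k+1)) across ROIs.
- **Single-voxel selectivity** — dAction = PA − nPA vs dBall = PB − nPB
  per voxel; the ROI metric is the percentage of voxels *below the
  diagonal* (dAction > dBall). Significance comes from a shuffled null:
  per subject, 10,000 random relabellings within each voxel's action pair
  and ball pair, the resulting percentage distributions histogrammed into
  100 bins and averaged bin-per-bin across subjects; the observed value is
  expressed as `(observed − null mean) / null SD`. Pairwise Pearson χ²
  (df = 1, no continuity correction) and paired t tests compare ROIs.
- **MVPA** — leave-one-run-out linear-SVM decoding of "1-action" vs
  "3-actions" from the two video-period MR samples of each trial
  (128 training / 16 test samples per class per fold).

## Worked example

```python
from numact import make_population, recode_all, simulate_psc_runs
from numact.selectivity import (compute_scatter, prop_below_diagonal,
                                sd_distance, shuffle_null)

pop = make_population("NPC3_L", mixture=(0.45, 0.10, 0.25, 0.20), seed=1)
recs = [recode_all(simulate_psc_runs(pop, 9, 1.0, seed=100 + s), k=3, seed=s)
        for s in range(21)]
points = compute_scatter(recs, mode="group_average")
observed = prop_below_diagonal(points)
null = shuffle_null(recs, n_shuffles=10000, n_bins=100, seed=2)
print(observed, null.mean, null.sd, sd_distance(observed, null))
```

prints (see `examples/05_selectivity_null.py`):

```
observed % below diagonal (dAction > dBall): 64.04
shuffled null: mean 50.000 %, SD 3.565 %
distance from chance: +3.94 SD
```

64% of the simulated 203-voxel ROI (45% of voxels action-tuned at 0.5%
tuning depth, 1% estimation noise) lands below the diagonal; the shuffled
null is centred at 50% with SD ≈ 100·√(0.25/203) ≈ 3.5%, so the observed
value sits ~4 SD above chance. The other capabilities each have a short
narrative script under `examples/`.

A thin CLI wraps the full pipeline:

```bash
numact init-config cfg.yaml        # all study parameters, overridable
numact all --config cfg.yaml --seed 1 --out-dir out/
```

writing the events files, the ANOVA/selectivity/null/group/MVPA report
tables, and per-ROI scatter exports; identical config + seed regenerates
every file bit-identically.

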