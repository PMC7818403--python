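"""Single-voxel selectivity for action versus ball numerosity.

For each voxel, dAction = PA - nPA and dBall = PB - nPB (cross-validated
preferred minus non-preferred responses).  The selectivity metric of an ROI
is the percentage of voxels strictly below the diagonal of the
dAction-dBall plane (dAction > dBall), i.e. voxels whose numerosity tuning
is deeper under action than under ball attention.  Significance of the
observed percentage is judged against a shuffled null built per subject
(random relabelling within each voxel's action pair and ball pair), binned,
and averaged bin-per-bin across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .recoding import RecodedResponse


def _stack_subject_values(recoded_by_subject) -> np.ndarray:
    """-> (n_subjects, n_voxels, 4) array of recoded responses."""
    arrs = []
    for rec in recoded_by_subject:
        arr = rec.as_array() if isinstance(rec, RecodedResponse) else \
            np.asarray(rec, dtype=float)
        arrs.append(arr)
    out = np.stack(arrs)
    if out.ndim != 3 or out.shape[2] != 4:
        raise ValueError("expected per-subject (n_voxels, 4) recoded values")
    return out


def compute_scatter(recoded_by_subject, mode: str = "group_average"
                    ) -> np.ndarray:
    """dAction/dBall scatter points.

    ``group_average``: average each voxel's four recoded values across
    subjects first, then difference -> (n_voxels, 2).
    ``per_subject``: difference within subject -> (n_subjects, n_voxels, 2).
    Columns are (dAction, dBall).
    """
    vals = _stack_subject_values(recoded_by_subject)
    if mode == "group_average":
        m = vals.mean(axis=0)
        return np.column_stack([m[:, 0] - m[:, 1], m[:, 2] - m[:, 3]])
    if mode == "per_subject":
        return np.stack([vals[..., 0] - vals[..., 1],
                         vals[..., 2] - vals[..., 3]], axis=-1)
    raise ValueError(f"unknown mode {mode!r}")


def prop_below_diagonal(points: np.ndarray) -> float:
    """Percentage of points with dAction strictly greater than dBall."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("empty scatter")
    return float(100.0 * np.mean(pts[..., 0] > pts[..., 1]))


def paired_t_voxels(points: np.ndarray):
    """Paired t test of dAction vs dBall across voxels: (t, df, p)."""
    pts = np.asarray(points, dtype=float)
    d = pts[:, 0] - pts[:, 1]
    if d.size < 2:
        raise ValueError("need at least two voxels")
    if np.allclose(d.var(ddof=1), 0) and not np.allclose(d.mean(), 0):
        raise ValueError("zero variance in differences")
    res = stats.ttest_1samp(d, 0.0)
    return float(res.statistic), d.size - 1, float(res.pvalue)


def pairwise_chi2(p1: float, n1: int, p2: float, n2: int):
    """Pearson chi-square (df = 1, no continuity correction) comparing two
    below-diagonal percentages; counts are the rounded percentages."""
    k1 = int(round(p1 * n1 / 100.0))
    k2 = int(round(p2 * n2 / 100.0))
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate contingency table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


@dataclass(frozen=True)
class ShuffleNull:
    bin_edges: np.ndarray  # 101 edges on [0, 100] for 100 bins
    probabilities: np.ndarray  # subject-averaged, sums to 1
    mean: float  # %
    sd: float  # %
    n_shuffles: int
    subject_props: Optional[np.ndarray] = None  # (n_subjects, n_shuffles)


def shuffle_null(recoded_by_subject, n_shuffles: int = 10000,
                 n_bins: int = 100, seed: Optional[int] = None,
                 rng: Optional[np.random.Generator] = None,
                 scheme: str = "pair_swap",
                 keep_subject_props: bool = False,
                 chunk: int = 500) -> ShuffleNull:
    """Shuffled null of the below-diagonal percentage.

    Per subject and shuffle the preferred/non-preferred labels are randomly
    reassigned within each voxel's action pair and, independently, its ball
    pair (``pair_swap``; ``full_permutation`` instead permutes all four
    values of a voxel across the four labels).  The per-subject percentage
    distributions are histogrammed into ``n_bins`` equal bins on [0, 100],
    averaged bin-per-bin across subjects, and summarised by the mean and SD
    of the averaged distribution.
    """
    vals = _stack_subject_values(recoded_by_subject)
    n_subj, n_vox, _ = vals.shape
    if rng is None:
        rng = np.random.default_rng(seed)
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    probs = np.zeros(n_bins)
    all_props = np.empty((n_subj, n_shuffles)) if keep_subject_props else None
    for s in range(n_subj):
        dA = vals[s, :, 0] - vals[s, :, 1]
        dB = vals[s, :, 2] - vals[s, :, 3]
        props = np.empty(n_shuffles)
        done = 0
        while done < n_shuffles:
            m = min(chunk, n_shuffles - done)
            if scheme == "pair_swap":
                sa = rng.integers(0, 2, size=(m, n_vox)) * 2 - 1
                sb = rng.integers(0, 2, size=(m, n_vox)) * 2 - 1
                below = (dA[None, :] * sa) > (dB[None, :] * sb)
            elif scheme == "full_permutation":
                perm = np.argsort(rng.random((m, n_vox, 4)), axis=2)
                v = np.take_along_axis(
                    np.broadcast_to(vals[s][None], (m, n_vox, 4)), perm,
                    axis=2)
                below = (v[..., 0] - v[..., 1]) > (v[..., 2] - v[..., 3])
            else:
                raise ValueError(f"unknown shuffle scheme {scheme!r}")
            props[done:done + m] = 100.0 * below.mean(axis=1)
            done += m
        hist, _ = np.histogram(props, bins=edges)
        probs += hist / n_shuffles
        if keep_subject_props:
            all_props[s] = props
    probs /= n_subj
    mean = float(np.sum(probs * centers))
    sd = float(np.sqrt(np.sum(probs * (centers - mean) ** 2)))
    return ShuffleNull(bin_edges=edges, probabilities=probs, mean=mean,
                       sd=sd, n_shuffles=n_shuffles,
                       subject_props=all_props)


def sd_distance(actual_prop: float,
                null: Union[ShuffleNull, tuple]) -> float:
    """Distance of the observed percentage from the null mean, in null SDs."""
    if isinstance(null, ShuffleNull):
        mean, sd = null.mean, null.sd
    else:
        mean, sd = null
    if sd <= 0:
        raise ValueError("null SD must be positive")
    return (actual_prop - mean) / sd


def selectivity_summary(recoded_by_roi: Dict[str, Sequence],
                        reference_roi: str = "NPC3_L") -> pd.DataFrame:
    """Group-average selectivity per ROI (scatter metric, paired t, and
    pairwise chi-square against the reference ROI)."""
    props, sizes, trows = {}, {}, {}
    for roi, recs in recoded_by_roi.items():
        pts = compute_scatter(recs, "group_average")
        props[roi] = prop_below_diagonal(pts)
        sizes[roi] = pts.shape[0]
        trows[roi] = paired_t_voxels(pts)
    rows = []
    for roi in recoded_by_roi:
        t, df, p = trows[roi]
        if roi == reference_roi:
            chi2_stat = chi2_p = np.nan
        else:
            chi2_stat, chi2_p = pairwise_chi2(
                props[reference_roi], sizes[reference_roi],
                props[roi], sizes[roi])
        rows.append({"roi": roi, "n_voxels": sizes[roi],
                     "prop_below": props[roi], "t": t, "df": df, "p": p,
                     "chi2_vs_ref": chi2_stat, "chi2_p": chi2_p})
    return pd.DataFrame(rows)


def group_prop_analysis(recoded_by_subject, refined: bool = False
                        ) -> np.ndarray:
    """Per-subject below-diagonal percentages for one ROI.

    Standard: computed from each subject's replication-averaged responses.
    Refined: computed per cross-validation replication, then averaged
    across replications within subject (requires kept replications);
    reduces the impact of unreliable voxels on the subject-level metric.
    """
    out = []
    for rec in recoded_by_subject:
        if refined:
            if not isinstance(rec, RecodedResponse) or rec.replications is None:
                raise ValueError("refined analysis needs per-replication "
                                 "recoded values")
            reps = rec.replications  # (n_vox, n_splits, 4)
            below = (reps[..., 0] - reps[..., 1]) > (reps[..., 2] - reps[..., 3])
            out.append(float(100.0 * below.mean(axis=0).mean()))
        else:
            arr = rec.as_array() if isinstance(rec, RecodedResponse) else \
                np.asarray(rec, dtype=float)
            pts = np.column_stack([arr[:, 0] - arr[:, 1],
                                   arr[:, 2] - arr[:, 3]])
            out.append(prop_below_diagonal(pts))
    return np.asarray(out)


def group_prop_report(recoded_by_roi: Dict[str, Sequence],
                      refined: bool = False,
                      reference_roi: str = "NPC3_L") -> pd.DataFrame:
    """Subject-level group analysis per ROI: mean %, SD %, one-tailed t
    against 50%, and paired t of the reference ROI against each other."""
    per_subject = {roi: group_prop_analysis(recs, refined=refined)
                   for roi, recs in recoded_by_roi.items()}
    ref = per_subject.get(reference_roi)
    rows = []
    for roi, props in per_subject.items():
        if props.size < 2:
            raise ValueError("need at least 2 subjects")
        if props.std(ddof=1) == 0:
            # degenerate fixtures: zero spread -> t = 0 at the null value
            t_stat = 0.0 if props.mean() == 50.0 else float(
                np.inf * np.sign(props.mean() - 50.0))
            p_one = float(stats.t.sf(t_stat, props.size - 1))
        else:
            res = stats.ttest_1samp(props, 50.0, alternative="greater")
            t_stat, p_one = float(res.statistic), float(res.pvalue)
        if roi == reference_roi or ref is None:
            pt = pp = np.nan
        else:
            pr = stats.ttest_rel(ref, props)
            pt, pp = float(pr.statistic), float(pr.pvalue)
        rows.append({"roi": roi, "mean": float(props.mean()),
                     "sd": float(props.std(ddof=1)),
                     "t_vs_50": t_stat,
                     "df": props.size - 1,
                     "p_one_tailed": p_one,
                     "paired_t_vs_ref": pt, "paired_p_vs_ref": pp})
    return pd.DataFrame(rows)
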