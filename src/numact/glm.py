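"""Per-run GLM fitting and percent-signal-change extraction.

Two model variants mirror the block-design analysis:

``three_condition``
    9 regressors — Action, Ball, Fix plus six motion parameters;
``five_condition``
    11 regressors — the four sub-conditions ("1-action", "3-actions",
    "1-ball", "3-balls"), Fix, plus six motion parameters.

An explicit constant baseline column is appended in addition to the counted
regressors.  Betas are converted to percent signal change relative to the
active-fixation condition:  PSC_c = 100 (beta_c - beta_Fix) / beta_baseline.

GLMs are fit per run (ordinary least squares, no prewhitening) so that the
cross-validated recoding can operate on run-resolved responses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd

from .design import BLOCK_LABELS, TR, RunSchedule
from .bold import condition_regressors

VARIANT_CONDITIONS = {
    "three_condition": ("Action", "Ball", "Fix"),
    "five_condition": BLOCK_LABELS + ("Fix",),
}

BASELINE_COLUMN = "baseline"
MOTION_COLUMNS = tuple(f"motion{i+1}" for i in range(6))


@dataclass(frozen=True)
class DesignMatrix:
    matrix: np.ndarray  # (n_TR, n_columns)
    columns: tuple
    model_variant: str

    @property
    def n_regressors(self) -> int:
        """Counted regressors: conditions + motion (baseline excluded)."""
        return len(self.columns) - 1

    def column_index(self, name: str) -> int:
        return self.columns.index(name)


def build_design_matrix(schedule: RunSchedule, motion: np.ndarray,
                        variant: str = "five_condition") -> DesignMatrix:
    """HRF-convolved condition regressors + motion + explicit baseline."""
    if variant not in VARIANT_CONDITIONS:
        raise ValueError(f"unknown model variant {variant!r}")
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[0] != 6:
        raise ValueError("motion must be a (6, n_TR) array")
    if motion.shape[1] != schedule.n_tr:
        raise ValueError("motion length does not match the schedule "
                         f"({motion.shape[1]} TRs vs {schedule.n_tr})")
    conditions = VARIANT_CONDITIONS[variant]
    R = condition_regressors(schedule, conditions)
    X = np.column_stack([R, motion.T, np.ones(schedule.n_tr)])
    columns = conditions + MOTION_COLUMNS + (BASELINE_COLUMN,)
    return DesignMatrix(matrix=X, columns=columns, model_variant=variant)


def fit_glm(bold: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """OLS betas, one row per voxel (accepts a 1-D series for one voxel)."""
    X = design.matrix
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    Y = np.atleast_2d(np.asarray(bold, dtype=float))
    if Y.shape[1] != X.shape[0]:
        raise ValueError("BOLD length does not match the design matrix")
    betas, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    out = betas.T  # (n_voxels, n_columns)
    return out[0] if np.asarray(bold).ndim == 1 else out


def percent_signal_change(betas: np.ndarray, design: DesignMatrix
                          ) -> Dict[str, np.ndarray]:
    """PSC per experimental condition, % of the baseline beta.

    The Fix condition maps to 0 by construction and is omitted.
    """
    B = np.atleast_2d(betas)
    b_base = B[:, design.column_index(BASELINE_COLUMN)]
    if np.any(b_base <= 0):
        raise ValueError("baseline beta must be positive for PSC")
    b_fix = B[:, design.column_index("Fix")]
    out = {}
    for cond in VARIANT_CONDITIONS[design.model_variant]:
        if cond == "Fix":
            continue
        b_c = B[:, design.column_index(cond)]
        psc = 100.0 * (b_c - b_fix) / b_base
        out[cond] = psc[0] if np.asarray(betas).ndim == 1 else psc
    return out


def run_psc(bold: np.ndarray, schedule: RunSchedule, motion: np.ndarray
            ) -> np.ndarray:
    """Fit the five-condition GLM for one run; (n_voxels, 4) sub-condition
    PSC in BLOCK_LABELS order."""
    design = build_design_matrix(schedule, motion, "five_condition")
    betas = fit_glm(bold, design)
    psc = percent_signal_change(betas, design)
    return np.column_stack([psc[c] for c in BLOCK_LABELS])


def subject_psc(dataset) -> np.ndarray:
    """Per-run PSC for a simulated SubjectDataset: (n_voxels, n_runs, 4)."""
    per_run = [run_psc(b, s, m) for b, s, m in
               zip(dataset.bold, dataset.schedules, dataset.motion)]
    return np.stack(per_run, axis=1)


# ---------------------------------------------------------------------------
# per-trial MR samples for decoding

def extract_trial_samples(bold: np.ndarray, schedule: RunSchedule,
                          lag_tr: int = 2) -> Dict[str, np.ndarray]:
    """The two MR samples of each discrimination trial, in PSC units.

    The video period of a trial spans exactly two TRs; both samples are
    taken ``lag_tr`` TRs after video onset to account for hemodynamic delay,
    and expressed as % change relative to the mean of the run's (equally
    lag-shifted) fixation-period TRs.  Returns, per sub-condition, an array
    (n_trials * 2, n_voxels) with the two samples of a trial adjacent.
    """
    Y = np.atleast_2d(np.asarray(bold, dtype=float))
    if Y.shape[1] != schedule.n_tr:
        raise ValueError("BOLD length does not match the schedule")
    n_video_tr = int(round(5.4 / TR))
    fix_idx = []
    for e in schedule.fixation_events():
        start = int(round(e.onset / TR)) + lag_tr
        fix_idx.extend(range(start, start + n_video_tr))
    fix_idx = [i for i in fix_idx if i < Y.shape[1]]
    fix_mean = Y[:, fix_idx].mean(axis=1)
    if np.any(fix_mean <= 0):
        raise ValueError("non-positive fixation baseline")
    out: Dict[str, np.ndarray] = {}
    for label in BLOCK_LABELS:
        samples = []
        for e in schedule.video_events(label):
            start = int(round(e.onset / TR)) + lag_tr
            idx = [min(i, Y.shape[1] - 1) for i in
                   range(start, start + n_video_tr)]
            for i in idx:
                samples.append(100.0 * (Y[:, i] - fix_mean) / fix_mean)
        out[label] = np.stack(samples)
    return out


# ---------------------------------------------------------------------------
# tidy PSC table I/O (also the entry point for real per-voxel data)

PSC_TABLE_COLUMNS = ["subject", "roi", "voxel", "run", "condition", "psc"]


def psc_to_frame(psc: np.ndarray, subject: int, roi: str) -> pd.DataFrame:
    """(n_voxels, n_runs, 4) -> tidy frame with one PSC value per row."""
    n_vox, n_runs, _ = psc.shape
    vox, run, cond = np.meshgrid(np.arange(n_vox), np.arange(1, n_runs + 1),
                                 np.arange(4), indexing="ij")
    return pd.DataFrame({
        "subject": subject,
        "roi": roi,
        "voxel": vox.ravel(),
        "run": run.ravel(),
        "condition": np.array(BLOCK_LABELS)[cond.ravel()],
        "psc": psc.ravel(),
    }, columns=PSC_TABLE_COLUMNS)


def frame_to_psc(df: pd.DataFrame) -> np.ndarray:
    """Tidy frame (one subject, one ROI) -> (n_voxels, n_runs, 4)."""
    voxels = np.sort(df["voxel"].unique())
    runs = np.sort(df["run"].unique())
    out = np.full((len(voxels), len(runs), 4), np.nan)
    vmap = {v: i for i, v in enumerate(voxels)}
    rmap = {r: i for i, r in enumerate(runs)}
    cmap = {c: i for i, c in enumerate(BLOCK_LABELS)}
    for row in df.itertuples(index=False):
        out[vmap[row.voxel], rmap[row.run], cmap[row.condition]] = row.psc
    if np.isnan(out).any():
        raise ValueError("incomplete PSC table")
    return out
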