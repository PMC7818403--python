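"""Cross-validated recoding of sub-conditions into preferred / non-preferred
responses per voxel.

The nine runs are split into k selection runs (default 3) and the remaining
evaluation runs.  The action sub-condition with the larger mean PSC in the
selection runs is the voxel's "preferred action"; the response attributed to
it is the evaluation-run mean of that sub-condition (and symmetrically for
the non-preferred action and the two ball sub-conditions).  Because all
C(9,3) = 84 splits are enumerated and the attributed responses averaged,
selection and evaluation never share data, which keeps the recoded contrast
unbiased for untuned voxels — the deliberately circular variant (evaluating
on the selection runs) is provided to demonstrate the selection bias it
reintroduces.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional

import numpy as np

#: column order of recoded responses
RECODED_ORDER = ("PA", "nPA", "PB", "nPB")


@dataclass(frozen=True)
class SplitPlan:
    selection_runs: tuple
    evaluation_runs: tuple

    @property
    def k_selection(self) -> int:
        return len(self.selection_runs)


@dataclass
class RecodedResponse:
    """Replication-averaged recoded responses for one subject/ROI.

    ``replications`` holds the per-split values (n_voxels, n_splits, 4) in
    RECODED_ORDER when kept (needed for the refined group analysis).
    """

    PA: np.ndarray
    nPA: np.ndarray
    PB: np.ndarray
    nPB: np.ndarray
    n_splits: int
    replications: Optional[np.ndarray] = None
    tie_fraction: float = 0.0

    def as_array(self) -> np.ndarray:
        """(n_voxels, 4) in RECODED_ORDER."""
        return np.column_stack([self.PA, self.nPA, self.PB, self.nPB])


def enumerate_splits(n_runs: int, k: int) -> List[SplitPlan]:
    """All C(n_runs, k) selection/evaluation splits, deterministic order."""
    if not 1 <= k <= n_runs - 1:
        raise ValueError(f"k must be in 1..{n_runs - 1}, got {k}")
    runs = range(n_runs)
    plans = []
    for sel in combinations(runs, k):
        ev = tuple(r for r in runs if r not in sel)
        plans.append(SplitPlan(selection_runs=sel, evaluation_runs=ev))
    return plans


def _pair_recode(sel: np.ndarray, ev: np.ndarray, rng: np.random.Generator):
    """Preferred/non-preferred attribution for one condition pair.

    ``sel``/``ev``: (..., 2) selection and evaluation means for the
    (1, 3) sub-conditions.  Exact selection ties are broken by a seeded
    coin flip.  Returns (preferred, non_preferred, tie_mask).
    """
    ties = sel[..., 0] == sel[..., 1]
    pref_hi = sel[..., 1] > sel[..., 0]
    if np.any(ties):
        pref_hi = np.where(ties, rng.integers(0, 2, size=ties.shape) == 1,
                           pref_hi)
    preferred = np.where(pref_hi, ev[..., 1], ev[..., 0])
    non_preferred = np.where(pref_hi, ev[..., 0], ev[..., 1])
    return preferred, non_preferred, ties


def recode_replication(psc_by_run: np.ndarray, split: SplitPlan,
                       seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None,
                       cross_validated: bool = True) -> dict:
    """Recode one split.

    ``psc_by_run``: (n_voxels, n_runs, 4) sub-condition PSC (1-action,
    3-actions, 1-ball, 3-balls).  Returns per-voxel arrays PA, nPA, PB, nPB
    plus tie masks.  With ``cross_validated=False`` the responses are taken
    from the selection runs themselves (the circular control).
    """
    psc = np.asarray(psc_by_run, dtype=float)
    if psc.ndim != 3 or psc.shape[2] != 4:
        raise ValueError("psc_by_run must be (n_voxels, n_runs, 4)")
    if np.isnan(psc).any():
        raise ValueError("missing run data in PSC array")
    if rng is None:
        rng = np.random.default_rng(seed)
    sel = psc[:, list(split.selection_runs), :].mean(axis=1)
    ev = (psc[:, list(split.evaluation_runs), :].mean(axis=1)
          if cross_validated else sel)
    PA, nPA, ties_a = _pair_recode(sel[:, :2], ev[:, :2], rng)
    PB, nPB, ties_b = _pair_recode(sel[:, 2:], ev[:, 2:], rng)
    return {"PA": PA, "nPA": nPA, "PB": PB, "nPB": nPB,
            "ties_action": ties_a, "ties_ball": ties_b}


def recode_all(psc_by_run: np.ndarray, k: int = 3,
               seed: Optional[int] = None,
               rng: Optional[np.random.Generator] = None,
               cross_validated: bool = True,
               keep_replications: bool = True) -> RecodedResponse:
    """Average the recoding over all C(n_runs, k) splits (vectorised).

    The result is independent of split enumeration order by construction
    (a plain mean over replications).
    """
    psc = np.asarray(psc_by_run, dtype=float)
    if psc.ndim != 3 or psc.shape[2] != 4:
        raise ValueError("psc_by_run must be (n_voxels, n_runs, 4)")
    if np.isnan(psc).any():
        raise ValueError("missing run data in PSC array")
    n_runs = psc.shape[1]
    plans = enumerate_splits(n_runs, k)
    if rng is None:
        rng = np.random.default_rng(seed)
    sel_mask = np.zeros((len(plans), n_runs))
    for i, p in enumerate(plans):
        sel_mask[i, list(p.selection_runs)] = 1.0
    ev_mask = 1.0 - sel_mask
    sel_mask /= sel_mask.sum(axis=1, keepdims=True)
    ev_mask /= ev_mask.sum(axis=1, keepdims=True)
    # (n_voxels, n_splits, 4)
    sel = np.einsum("vrc,sr->vsc", psc, sel_mask)
    ev = np.einsum("vrc,sr->vsc", psc, ev_mask) if cross_validated else sel
    PA, nPA, ties_a = _pair_recode(sel[..., :2], ev[..., :2], rng)
    PB, nPB, ties_b = _pair_recode(sel[..., 2:], ev[..., 2:], rng)
    reps = np.stack([PA, nPA, PB, nPB], axis=2)  # (n_vox, n_splits, 4)
    mean = reps.mean(axis=1)
    tie_fraction = float(np.mean(ties_a) + np.mean(ties_b)) / 2.0
    return RecodedResponse(
        PA=mean[:, 0], nPA=mean[:, 1], PB=mean[:, 2], nPB=mean[:, 3],
        n_splits=len(plans),
        replications=reps if keep_replications else None,
        tie_fraction=tie_fraction,
    )
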