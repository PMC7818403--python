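"""ROI-averaged univariate analysis: 2 x 2 repeated-measures ANOVA with
Holm step-down correction across ROIs.

The two within-subject factors are attended feature (action vs ball) and
preference (preferred vs non-preferred numerosity).  With two levels per
factor each effect is a single per-subject contrast, so the classical
repeated-measures F equals the squared one-sample t of that contrast with
df (1, n_subjects - 1); this closed form is exact and needs no sphericity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .recoding import RECODED_ORDER, RecodedResponse

EFFECTS = ("feature", "preference", "interaction")

#: contrast weights over (PA, nPA, PB, nPB)
_CONTRASTS = {
    "feature": np.array([0.5, 0.5, -0.5, -0.5]),
    "preference": np.array([0.5, -0.5, 0.5, -0.5]),
    "interaction": np.array([1.0, -1.0, -1.0, 1.0]),
}


@dataclass(frozen=True)
class AnovaResult:
    effects: Dict[str, tuple]  # name -> (F, (df1, df2), p)

    def __getitem__(self, name: str) -> tuple:
        return self.effects[name]


def roi_average(recoded_by_subject: Sequence[RecodedResponse]) -> np.ndarray:
    """Average recoded responses over the voxels of the ROI.

    Returns (n_subjects, 4) in RECODED_ORDER, one quadruple per subject.
    """
    rows = []
    for rec in recoded_by_subject:
        arr = rec.as_array() if isinstance(rec, RecodedResponse) else \
            np.asarray(rec, dtype=float)
        if arr.size == 0:
            raise ValueError("empty ROI")
        rows.append(arr.mean(axis=0))
    return np.stack(rows)


def rm_anova_2x2(data: np.ndarray) -> AnovaResult:
    """Two-way repeated-measures ANOVA for a 2 x 2 within design.

    ``data``: (n_subjects, 4) condition means in RECODED_ORDER.  Each
    effect is tested against its own subject-by-effect error term,
    df (1, n_subjects - 1).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != 4:
        raise ValueError("data must be (n_subjects, 4)")
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.isnan(data).any():
        raise ValueError("missing cells")
    out = {}
    for name, w in _CONTRASTS.items():
        L = data @ w
        mean = L.mean()
        var = L.var(ddof=1)
        if var == 0:
            F = np.inf if mean != 0 else 0.0
        else:
            F = n * mean ** 2 / var
        p = float(stats.f.sf(F, 1, n - 1))
        out[name] = (float(F), (1, n - 1), p)
    return AnovaResult(effects=out)


@dataclass(frozen=True)
class HolmDecision:
    p_values: tuple  # original order
    order: tuple  # indices sorting p ascending
    thresholds: tuple  # alpha/(n-k+1) for the k-th smallest p
    significant: tuple  # flags in original order

    @property
    def n_significant(self) -> int:
        return int(sum(self.significant))


def holm_correct(p_values: Sequence[float], alpha: float = 0.05
                 ) -> HolmDecision:
    """Holm's step-down rule: compare the k-th smallest p with
    alpha/(n-k+1), stopping at the first failure."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    thresholds = tuple(alpha / (n - k + 1) for k in range(1, n + 1))
    flags = np.zeros(n, dtype=bool)
    for k, idx in enumerate(order):
        if p[idx] <= thresholds[k]:
            flags[idx] = True
        else:
            break
    return HolmDecision(p_values=tuple(p), order=tuple(int(i) for i in order),
                        thresholds=thresholds,
                        significant=tuple(bool(f) for f in flags))


def anova_report(roi_means: Dict[str, np.ndarray], alpha: float = 0.05
                 ) -> pd.DataFrame:
    """Per-ROI 2x2 ANOVA with Holm correction applied per effect family
    across ROIs; mirrors the univariate ROI analysis summary table."""
    rois = list(roi_means)
    results = {roi: rm_anova_2x2(roi_means[roi]) for roi in rois}
    rows = []
    for effect in EFFECTS:
        ps = [results[roi][effect][2] for roi in rois]
        holm = holm_correct(ps, alpha)
        for roi, flag in zip(rois, holm.significant):
            F, (d1, d2), p = results[roi][effect]
            rows.append({"roi": roi, "effect": effect, "F": F,
                         "df1": d1, "df2": d2, "p": p,
                         "holm_significant": flag})
    return pd.DataFrame(rows)
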