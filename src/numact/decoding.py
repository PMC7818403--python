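"""Leave-one-run-out linear decoding of "1-action" vs "3-actions".

Each discrimination trial contributes its two video-period MR samples (in
percent signal change relative to active fixation), so a nine-run session
yields, per fold, 128 training samples and 16 test samples per class.  A
linear support vector machine is trained on eight runs and tested on the
held-out run; the nine fold accuracies are averaged within subject, then
across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.svm import SVC

from .design import ACTION_BLOCKS

SAMPLES_PER_TRIAL = 2


@dataclass
class DecodingFold:
    test_run: int
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray


@dataclass
class DecodingResult:
    fold_accuracies: np.ndarray  # (n_subjects, n_folds), %
    subject_means: np.ndarray  # (n_subjects,), %

    @property
    def group_mean(self) -> float:
        return float(self.subject_means.mean())

    @property
    def group_sd(self) -> float:
        return float(self.subject_means.std(ddof=1))


def _run_xy(samples: Dict[str, np.ndarray], sampling: str):
    """Stack one run's action-block samples into (X, y); y=0 for 1-action."""
    xs, ys = [], []
    for label_idx, label in enumerate(ACTION_BLOCKS):
        X = samples[label]
        if sampling == "one_per_trial":
            X = X[::SAMPLES_PER_TRIAL]
        elif sampling != "per_class":
            raise ValueError(f"unknown sampling mode {sampling!r}")
        xs.append(X)
        ys.append(np.full(X.shape[0], label_idx))
    return np.vstack(xs), np.concatenate(ys)


def make_folds(samples_per_run: Sequence[Dict[str, np.ndarray]],
               sampling: str = "per_class") -> List[DecodingFold]:
    """One fold per held-out run.

    ``samples_per_run``: per run, a dict mapping sub-condition label to a
    (n_samples, n_voxels) array (as produced by glm.extract_trial_samples).
    ``sampling='per_class'`` keeps both MR samples of each trial (the
    default); ``'one_per_trial'`` keeps only the first sample of each trial
    (a sensitivity variant halving the sample counts).
    """
    n_runs = len(samples_per_run)
    if n_runs < 2:
        raise ValueError("need at least two runs")
    xy = [_run_xy(s, sampling) for s in samples_per_run]
    folds = []
    for test in range(n_runs):
        X_tr = np.vstack([xy[r][0] for r in range(n_runs) if r != test])
        y_tr = np.concatenate([xy[r][1] for r in range(n_runs) if r != test])
        folds.append(DecodingFold(test_run=test, X_train=X_tr, y_train=y_tr,
                                  X_test=xy[test][0], y_test=xy[test][1]))
    return folds


def train_eval_fold(fold: DecodingFold, C: float = 1.0,
                    standardize: bool = False) -> float:
    """Fit a linear SVM on the training samples; accuracy (%) on the test
    run.  Optional z-scoring uses training-set statistics only."""
    if len(np.unique(fold.y_train)) < 2:
        raise ValueError("training set contains a single class")
    X_tr, X_te = fold.X_train, fold.X_test
    if standardize:
        mu = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0)
        sd[sd == 0] = 1.0
        X_tr = (X_tr - mu) / sd
        X_te = (X_te - mu) / sd
    clf = SVC(kernel="linear", C=C)
    clf.fit(X_tr, fold.y_train)
    return float(100.0 * clf.score(X_te, fold.y_test))


def decode_subject(samples_per_run: Sequence[Dict[str, np.ndarray]],
                   C: float = 1.0, standardize: bool = False,
                   sampling: str = "per_class") -> np.ndarray:
    """Leave-one-run-out fold accuracies (%) for one subject."""
    folds = make_folds(samples_per_run, sampling)
    return np.array([train_eval_fold(f, C=C, standardize=standardize)
                     for f in folds])


def decode_roi(samples_by_subject: Sequence[Sequence[Dict[str, np.ndarray]]],
               C: float = 1.0, standardize: bool = False,
               sampling: str = "per_class") -> DecodingResult:
    """Decode every subject and aggregate (mean over folds, then subjects)."""
    accs = np.stack([decode_subject(s, C=C, standardize=standardize,
                                    sampling=sampling)
                     for s in samples_by_subject])
    return DecodingResult(fold_accuracies=accs,
                          subject_means=accs.mean(axis=1))


def permute_trial_labels(samples_per_run: Sequence[Dict[str, np.ndarray]],
                         seed: Optional[int] = None,
                         rng: Optional[np.random.Generator] = None
                         ) -> List[Dict[str, np.ndarray]]:
    """Randomly reassign the 1-action/3-actions labels at the trial level
    within each run (both MR samples of a trial move together), preserving
    class balance — the chance-level control for the decoder."""
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    for samples in samples_per_run:
        X = np.vstack([samples[label] for label in ACTION_BLOCKS])
        n_trials = X.shape[0] // SAMPLES_PER_TRIAL
        trials = X.reshape(n_trials, SAMPLES_PER_TRIAL, -1)
        perm = rng.permutation(n_trials)
        trials = trials[perm]
        half = n_trials // 2
        new = dict(samples)
        new[ACTION_BLOCKS[0]] = trials[:half].reshape(-1, X.shape[1])
        new[ACTION_BLOCKS[1]] = trials[half:].reshape(-1, X.shape[1])
        out.append(new)
    return out
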