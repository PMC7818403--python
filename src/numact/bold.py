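"""Synthetic voxel populations and HRF-convolved BOLD time series.

Each voxel is described by a latent tuning parameter set: a baseline signal,
attention gains for the action and ball tasks (the main effect of attended
feature), and a tuning depth ``delta`` for one preferred numerosity (1 or 3)
of the attended feature.  Condition amplitudes are expressed in percent of
baseline so that the downstream GLM percent-signal-change estimates are
directly comparable to the programmed values.

The generator knows four voxel classes:

``action_numerosity``
    responds more to its preferred action numerosity (delta_action > 0,
    delta_ball = 0);
``ball_numerosity``
    the mirror image (delta_ball > 0, delta_action = 0);
``attention_only``
    task gains but no numerosity tuning;
``null``
    no task-related signal at all.

Effect sizes are free parameters of the simulator (the underlying study
reports no tuning depths); defaults are documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from nilearn.glm.first_level.hemodynamic_models import compute_regressor

from .design import BLOCK_LABELS, TR, RunSchedule

TUNING_CLASSES = ("action_numerosity", "ball_numerosity", "attention_only",
                  "null")

#: ROI voxel counts used throughout (left MT+, left MTG, left OTS, right MT+,
#: left NPC1, left NPC2, left NPC3, left phAIP)
ROI_VOXEL_COUNTS = {
    "MT+_L": 449,
    "MTG_L": 417,
    "OTS_L": 470,
    "MT+_R": 306,
    "NPC1_L": 152,
    "NPC2_L": 86,
    "NPC3_L": 203,
    "phAIP_L": 419,
}

ROI_NAMES = tuple(ROI_VOXEL_COUNTS)

#: simulation conditions in canonical order: the four sub-conditions plus Fix
CONDITION_ORDER = BLOCK_LABELS + ("Fix",)


@dataclass(frozen=True)
class VoxelTuning:
    baseline: float
    attend_gain_action: float  # % of baseline
    attend_gain_ball: float
    preferred_action_numerosity: int  # 1 or 3
    delta_action: float  # % of baseline, preferred minus non-preferred
    preferred_ball_numerosity: int
    delta_ball: float
    noise_sd: float  # signal units
    tuning_class: str

    def __post_init__(self):
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.tuning_class not in TUNING_CLASSES:
            raise ValueError(f"unknown tuning class {self.tuning_class!r}")

    def condition_amplitudes(self) -> np.ndarray:
        """Amplitudes in % of baseline for CONDITION_ORDER."""
        a1 = self.attend_gain_action + (
            self.delta_action if self.preferred_action_numerosity == 1 else 0.0)
        a3 = self.attend_gain_action + (
            self.delta_action if self.preferred_action_numerosity == 3 else 0.0)
        b1 = self.attend_gain_ball + (
            self.delta_ball if self.preferred_ball_numerosity == 1 else 0.0)
        b3 = self.attend_gain_ball + (
            self.delta_ball if self.preferred_ball_numerosity == 3 else 0.0)
        return np.array([a1, a3, b1, b3, 0.0])


@dataclass(frozen=True)
class EffectSizes:
    """Free parameters of the voxel generator (see docs/methods.md)."""

    baseline_mean: float = 100.0
    baseline_sd: float = 5.0
    attend_gain_action: float = 0.8  # % of baseline
    attend_gain_ball: float = 0.6
    gain_sd: float = 0.2
    delta_action: float = 0.5  # tuning depth, % of baseline
    delta_ball: float = 0.5
    delta_sd: float = 0.15
    noise_sd: float = 1.0  # signal units


@dataclass(frozen=True)
class ROIPopulation:
    roi_name: str
    n_voxels: int
    class_mixture: tuple  # proportions over TUNING_CLASSES, sum 1
    voxels: tuple  # of VoxelTuning

    def amplitudes(self) -> np.ndarray:
        """(n_voxels, 5) condition amplitudes in % of baseline."""
        return np.stack([v.condition_amplitudes() for v in self.voxels])

    @property
    def baselines(self) -> np.ndarray:
        return np.array([v.baseline for v in self.voxels])

    @property
    def noise_sds(self) -> np.ndarray:
        return np.array([v.noise_sd for v in self.voxels])


def make_population(roi_name: str,
                    mixture: Sequence[float],
                    n_voxels: Optional[int] = None,
                    effects: EffectSizes = EffectSizes(),
                    seed: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None) -> ROIPopulation:
    """Draw a voxel population with classes sampled from ``mixture``.

    ``mixture`` gives proportions over (action_numerosity, ball_numerosity,
    attention_only, null).  ``n_voxels`` defaults to the ROI's tabulated
    voxel count.
    """
    mixture = np.asarray(mixture, dtype=float)
    if mixture.shape != (4,) or np.any(mixture < 0) or not np.isclose(
            mixture.sum(), 1.0):
        raise ValueError("mixture must be 4 non-negative proportions "
                         "summing to 1")
    if n_voxels is None:
        if roi_name not in ROI_VOXEL_COUNTS:
            raise ValueError(f"unknown ROI {roi_name!r}; pass n_voxels")
        n_voxels = ROI_VOXEL_COUNTS[roi_name]
    if rng is None:
        rng = np.random.default_rng(seed)

    classes = rng.choice(len(TUNING_CLASSES), size=n_voxels, p=mixture)
    voxels = []
    for c in classes:
        cls = TUNING_CLASSES[c]
        baseline = max(float(rng.normal(effects.baseline_mean,
                                        effects.baseline_sd)),
                       0.1 * effects.baseline_mean)
        if cls == "null":
            ga = gb = da = db = 0.0
        else:
            ga = abs(float(rng.normal(effects.attend_gain_action,
                                      effects.gain_sd)))
            gb = abs(float(rng.normal(effects.attend_gain_ball,
                                      effects.gain_sd)))
            da = db = 0.0
            if cls == "action_numerosity":
                da = abs(float(rng.normal(effects.delta_action,
                                          effects.delta_sd)))
                da = max(da, 1e-6)
            elif cls == "ball_numerosity":
                db = abs(float(rng.normal(effects.delta_ball,
                                          effects.delta_sd)))
                db = max(db, 1e-6)
        voxels.append(VoxelTuning(
            baseline=baseline,
            attend_gain_action=ga,
            attend_gain_ball=gb,
            preferred_action_numerosity=int(rng.choice((1, 3))),
            delta_action=da,
            preferred_ball_numerosity=int(rng.choice((1, 3))),
            delta_ball=db,
            noise_sd=effects.noise_sd,
            tuning_class=cls,
        ))
    return ROIPopulation(roi_name=roi_name, n_voxels=n_voxels,
                         class_mixture=tuple(mixture), voxels=tuple(voxels))


# ---------------------------------------------------------------------------
# regressor construction shared by the simulator and the GLM

def condition_regressors(schedule: RunSchedule,
                         conditions: Sequence[str] = CONDITION_ORDER
                         ) -> np.ndarray:
    """HRF-convolved boxcar regressors (n_TR, n_conditions).

    Condition boxcars cover the video period of each discrimination trial
    (grouped by block label) and the 5.4-s fixation periods for "Fix";
    instruction and response periods carry no regressor.  The canonical
    (SPM double-gamma) HRF is used.
    """
    frame_times = np.arange(schedule.n_tr) * TR
    cols = []
    for cond in conditions:
        if cond == "Fix":
            evs = schedule.fixation_events()
        elif cond == "Action":
            evs = (schedule.video_events("1-action")
                   + schedule.video_events("3-actions"))
        elif cond == "Ball":
            evs = (schedule.video_events("1-ball")
                   + schedule.video_events("3-balls"))
        else:
            evs = schedule.video_events(cond)
        if not evs:
            raise ValueError(f"schedule has no events for condition {cond!r}")
        onsets = np.array([e.onset for e in evs])
        durations = np.array([e.duration for e in evs])
        amplitudes = np.ones(len(evs))
        reg, _ = compute_regressor((onsets, durations, amplitudes), "spm",
                                   frame_times)
        cols.append(reg.ravel())
    return np.column_stack(cols)


def simulate_bold(pop: ROIPopulation, schedule: RunSchedule,
                  seed: Optional[int] = None,
                  rng: Optional[np.random.Generator] = None,
                  subject_gain: float = 1.0,
                  baseline_shift: float = 0.0,
                  ar1: float = 0.0,
                  drift_amplitude: float = 0.0) -> np.ndarray:
    """Simulate one run's BOLD matrix (n_voxels, n_TR).

    The noiseless signal of voxel v is

        baseline_v + baseline_v/100 * sum_c amp_vc * (HRF (*) boxcar_c)

    with amplitudes in % of baseline, so an OLS GLM built from the same
    regressors recovers the programmed percent signal changes exactly on
    noiseless data.  Gaussian white noise with the voxel's noise_sd is
    added; optional AR(1) colouring and a linear drift are off by default.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    R = condition_regressors(schedule)  # (n_TR, 5)
    amps = pop.amplitudes() * subject_gain  # (n_vox, 5)
    base = pop.baselines + baseline_shift
    signal = base[:, None] * (1.0 + (amps @ R.T) / 100.0)
    noise = rng.standard_normal(signal.shape) * pop.noise_sds[:, None]
    if ar1:
        from scipy.signal import lfilter
        noise = lfilter([1.0], [1.0, -ar1], noise, axis=1)
    if drift_amplitude:
        t = np.linspace(-1.0, 1.0, signal.shape[1])
        noise = noise + drift_amplitude * t
    return signal + noise


def make_motion_regressors(n_tr: int, seed: Optional[int] = None,
                           rng: Optional[np.random.Generator] = None,
                           amplitude: float = 0.05) -> np.ndarray:
    """Six smooth, zero-mean nuisance series (6, n_TR) mimicking head motion
    parameters (slow random walks, low amplitude)."""
    if n_tr <= 0:
        raise ValueError("n_tr must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    steps = rng.standard_normal((6, n_tr)) * amplitude
    walk = np.cumsum(steps, axis=1)
    # light smoothing to emulate slow drifts
    kernel = np.ones(5) / 5.0
    smooth = np.apply_along_axis(
        lambda x: np.convolve(x, kernel, mode="same"), 1, walk)
    return smooth - smooth.mean(axis=1, keepdims=True)


def simulate_psc_runs(pop: ROIPopulation, n_runs: int,
                      psc_noise_sd: float,
                      seed: Optional[int] = None,
                      rng: Optional[np.random.Generator] = None
                      ) -> np.ndarray:
    """Draw per-run percent-signal-change estimates directly.

    Returns (n_voxels, n_runs, 4) PSC values for the four sub-conditions:
    the programmed condition amplitudes plus i.i.d. Gaussian estimation
    noise of standard deviation ``psc_noise_sd`` (in PSC %).  This is the
    distributional shortcut for the full simulate -> GLM path, used where
    many replicate experiments are needed; the full path is exercised by
    its own recovery tests.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    amps = pop.amplitudes()[:, :4]
    return (amps[:, None, :]
            + rng.standard_normal((pop.n_voxels, n_runs, 4)) * psc_noise_sd)


@dataclass
class SubjectDataset:
    """All simulated runs of one subject for one ROI."""

    subject_id: int
    bold: list  # per run: (n_voxels, n_TR)
    schedules: list  # per run: RunSchedule
    motion: list  # per run: (6, n_TR)


def simulate_subject(pop: ROIPopulation, schedules: Sequence[RunSchedule],
                     subject_id: int,
                     seed: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None,
                     subject_gain_sd: float = 0.15,
                     baseline_jitter_sd: float = 2.0,
                     motion_amplitude: float = 0.05) -> SubjectDataset:
    """Simulate all runs of one subject.

    Subject variability is a multiplicative gain on all condition amplitudes
    (lognormal-like, SD ``subject_gain_sd``) plus an additive baseline
    offset, both constant across the subject's runs.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    gain = float(np.exp(rng.normal(0.0, subject_gain_sd)))
    shift = float(rng.normal(0.0, baseline_jitter_sd))
    bold, motion = [], []
    for sched in schedules:
        bold.append(simulate_bold(pop, sched, rng=rng, subject_gain=gain,
                                  baseline_shift=shift))
        motion.append(make_motion_regressors(sched.n_tr, rng=rng,
                                             amplitude=motion_amplitude))
    return SubjectDataset(subject_id=subject_id, bold=bold,
                          schedules=list(schedules), motion=motion)
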