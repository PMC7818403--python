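"""Pipeline configuration: every study parameter as an overridable key.

Defaults reproduce the study conditions: 21 subjects, 9 runs, 3 selection
runs (hence 84 cross-validation splits), 10,000 shuffles, 100 bins, and the
tabulated ROI voxel counts.  Class-mixture and effect-size defaults are
free parameters of the simulator (see docs/methods.md); the per-ROI
mixtures are chosen to emulate the direction of the reported selectivity
pattern (action-tuned majority in NPC3 and OTS, ball-tuned majority in the
occipito-temporal regions, near-even phAIP).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List

import yaml

from .bold import ROI_VOXEL_COUNTS, EffectSizes

#: mixtures over (action_numerosity, ball_numerosity, attention_only, null)
DEFAULT_MIXTURES = {
    "MT+_L": (0.10, 0.40, 0.30, 0.20),
    "MTG_L": (0.08, 0.45, 0.27, 0.20),
    "OTS_L": (0.35, 0.15, 0.30, 0.20),
    "MT+_R": (0.10, 0.40, 0.30, 0.20),
    "NPC1_L": (0.15, 0.25, 0.30, 0.30),
    "NPC2_L": (0.10, 0.35, 0.30, 0.25),
    "NPC3_L": (0.45, 0.10, 0.25, 0.20),
    "phAIP_L": (0.22, 0.25, 0.33, 0.20),
}


@dataclass
class ROISpec:
    n_voxels: int
    mixture: tuple

    @classmethod
    def default(cls, roi: str) -> "ROISpec":
        return cls(n_voxels=ROI_VOXEL_COUNTS[roi],
                   mixture=tuple(DEFAULT_MIXTURES[roi]))


def _default_rois() -> Dict[str, ROISpec]:
    return {roi: ROISpec.default(roi) for roi in ROI_VOXEL_COUNTS}


@dataclass
class PipelineConfig:
    seed: int = 0
    n_subjects: int = 21
    n_runs: int = 9
    k_selection: int = 3
    n_shuffles: int = 10000
    n_bins: int = 100
    shuffle_scheme: str = "pair_swap"
    alpha: float = 0.05
    svm_c: float = 1.0
    standardize_samples: bool = False
    lag_tr: int = 2
    reference_roi: str = "NPC3_L"
    subject_gain_sd: float = 0.15
    baseline_jitter_sd: float = 2.0
    run_anova: bool = True
    run_selectivity: bool = True
    run_mvpa: bool = True
    rois: Dict[str, ROISpec] = field(default_factory=_default_rois)
    effects: EffectSizes = field(default_factory=EffectSizes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rois"] = {k: {"n_voxels": v["n_voxels"],
                         "mixture": list(v["mixture"])}
                     for k, v in d["rois"].items()}
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw)
    rois = raw.pop("rois", None)
    effects = raw.pop("effects", None)
    cfg = PipelineConfig(**raw)
    if rois is not None:
        cfg.rois = {name: ROISpec(n_voxels=int(spec["n_voxels"]),
                                  mixture=tuple(spec["mixture"]))
                    for name, spec in rois.items()}
    if effects is not None:
        cfg.effects = EffectSizes(**effects)
    return cfg


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def validate_config(cfg: PipelineConfig) -> List[str]:
    """Return a list of problems; empty for a usable configuration."""
    problems = []
    for name in ("n_subjects", "n_runs", "k_selection", "n_shuffles",
                 "n_bins"):
        if getattr(cfg, name) <= 0:
            problems.append(f"{name} must be positive")
    if cfg.n_runs != 9:
        problems.append("the block design is defined for exactly 9 runs")
    if cfg.k_selection >= cfg.n_runs:
        problems.append("k_selection must be smaller than n_runs")
    if cfg.effects.noise_sd < 0:
        problems.append("noise_sd must be non-negative")
    if cfg.effects.baseline_mean <= 0:
        problems.append("baseline_mean must be positive")
    if cfg.shuffle_scheme not in ("pair_swap", "full_permutation"):
        problems.append(f"unknown shuffle scheme {cfg.shuffle_scheme!r}")
    if not 0 < cfg.alpha < 1:
        problems.append("alpha must lie in (0, 1)")
    if cfg.svm_c <= 0:
        problems.append("svm_c must be positive")
    if not cfg.rois:
        problems.append("at least one ROI is required")
    if cfg.reference_roi not in cfg.rois:
        problems.append(f"reference ROI {cfg.reference_roi!r} not in rois")
    for name, spec in cfg.rois.items():
        if spec.n_voxels <= 0:
            problems.append(f"ROI {name}: n_voxels must be positive")
        m = list(spec.mixture)
        if len(m) != 4 or any(x < 0 for x in m) or abs(sum(m) - 1) > 1e-9:
            problems.append(f"ROI {name}: mixture must be 4 proportions "
                            "summing to 1")
    return problems
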