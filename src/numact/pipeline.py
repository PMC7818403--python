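"""End-to-end orchestration: design -> simulate -> GLM -> recode -> ANOVA
-> selectivity -> MVPA -> report bundle.

All randomness flows from the single config seed through named
SeedSequence children, so regenerating with the same config reproduces
every report file bit-identically (timings are logged, never written into
the bundle).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import anova as anova_mod
from . import bold, decoding, design, glm, recoding, selectivity
from .config import PipelineConfig, validate_config

logger = logging.getLogger("numact")

STAGES = ("design", "simulate", "recode", "anova", "selectivity", "mvpa")


@dataclass
class ReportBundle:
    out_dir: Path
    tables: Dict[str, Path] = field(default_factory=dict)
    events_dir: Optional[Path] = None
    scatter_files: Dict[str, Path] = field(default_factory=dict)
    log_file: Optional[Path] = None


def _stage_seeds(seed: int) -> Dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return dict(zip(STAGES, children))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineState:
    """In-memory intermediates, re-loadable stage by stage."""

    schedules: Optional[list] = None
    populations: Optional[dict] = None  # roi -> ROIPopulation
    psc: Optional[dict] = None  # roi -> (n_subj, n_vox, n_runs, 4)
    samples: Optional[dict] = None  # roi -> per subject per run samples
    recoded: Optional[dict] = None  # roi -> list of RecodedResponse


def run_design(cfg: PipelineConfig,
               seeds: Optional[dict] = None) -> list:
    seeds = seeds or _stage_seeds(cfg.seed)
    s = int(seeds["design"].generate_state(1)[0] % (2 ** 31))
    videos = design.enumerate_videos()
    subset = design.select_balanced_subset(videos, seed=s)
    return design.build_session(subset, seed=s)


def run_simulation(cfg: PipelineConfig, schedules: list,
                   seeds: Optional[dict] = None,
                   with_samples: bool = True) -> PipelineState:
    """Simulate every subject and ROI; fit per-run GLMs; extract samples."""
    seeds = seeds or _stage_seeds(cfg.seed)
    rng = np.random.default_rng(seeds["simulate"])
    populations, psc, samples = {}, {}, {}
    for roi, spec in cfg.rois.items():
        pop = bold.make_population(roi, spec.mixture, n_voxels=spec.n_voxels,
                                   effects=cfg.effects, rng=rng)
        populations[roi] = pop
        roi_psc, roi_samples = [], []
        for subj in range(cfg.n_subjects):
            ds = bold.simulate_subject(
                pop, schedules, subject_id=subj, rng=rng,
                subject_gain_sd=cfg.subject_gain_sd,
                baseline_jitter_sd=cfg.baseline_jitter_sd)
            roi_psc.append(glm.subject_psc(ds))
            if with_samples and cfg.run_mvpa:
                roi_samples.append([
                    glm.extract_trial_samples(b, s, lag_tr=cfg.lag_tr)
                    for b, s in zip(ds.bold, ds.schedules)])
        psc[roi] = np.stack(roi_psc)
        if with_samples and cfg.run_mvpa:
            samples[roi] = roi_samples
    return PipelineState(schedules=schedules, populations=populations,
                         psc=psc, samples=samples or None)


def run_recode(cfg: PipelineConfig, state: PipelineState,
               seeds: Optional[dict] = None) -> dict:
    seeds = seeds or _stage_seeds(cfg.seed)
    rng = np.random.default_rng(seeds["recode"])
    recoded = {}
    for roi, arr in state.psc.items():
        recoded[roi] = [recoding.recode_all(arr[s], k=cfg.k_selection,
                                            rng=rng)
                        for s in range(arr.shape[0])]
    state.recoded = recoded
    return recoded


def run_pipeline(cfg: PipelineConfig, out_dir) -> ReportBundle:
    """Execute the full pipeline and write the report bundle."""
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out_dir)
    seeds = _stage_seeds(cfg.seed)

    def _timed(stage, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise PipelineError(stage, exc) from exc
        logger.info("stage %-12s %.1f s", stage, time.perf_counter() - t0)
        return result

    schedules = _timed("design", run_design, cfg, seeds)
    events_dir = out_dir / "events"
    design.write_session_events(schedules, events_dir)
    bundle.events_dir = events_dir

    state = _timed("simulate", run_simulation, cfg, schedules, seeds)
    recoded = _timed("recode", run_recode, cfg, state, seeds)

    if cfg.run_anova:
        def _anova():
            roi_means = {roi: anova_mod.roi_average(recs)
                         for roi, recs in recoded.items()}
            return anova_mod.anova_report(roi_means, alpha=cfg.alpha)
        table4 = _timed("anova", _anova)
        p = out_dir / "roi_anova.tsv"
        table4.to_csv(p, sep="\t", index=False, float_format="%.6g")
        bundle.tables["anova"] = p

    if cfg.run_selectivity:
        def _selectivity():
            summary = selectivity.selectivity_summary(
                recoded, reference_roi=cfg.reference_roi)
            rng = np.random.default_rng(seeds["selectivity"])
            null_rows = []
            for roi, recs in recoded.items():
                null = selectivity.shuffle_null(
                    recs, n_shuffles=cfg.n_shuffles, n_bins=cfg.n_bins,
                    rng=rng, scheme=cfg.shuffle_scheme)
                actual = float(
                    summary.loc[summary.roi == roi, "prop_below"].iloc[0])
                null_rows.append({
                    "roi": roi, "null_mean": null.mean, "null_sd": null.sd,
                    "sd_distance": selectivity.sd_distance(actual, null)})
            group = selectivity.group_prop_report(
                recoded, reference_roi=cfg.reference_roi)
            return summary, pd.DataFrame(null_rows), group
        summary, nulls, group = _timed("selectivity", _selectivity)
        for name, df in (("selectivity", summary), ("shuffle_null", nulls),
                         ("group_props", group)):
            p = out_dir / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False, float_format="%.6g")
            bundle.tables[name] = p
        for roi, recs in recoded.items():
            pts = selectivity.compute_scatter(recs, "group_average")
            p = out_dir / f"scatter_{roi.replace('+', 'p')}.tsv"
            pd.DataFrame({"voxel": np.arange(len(pts)),
                          "dAction": pts[:, 0], "dBall": pts[:, 1]}
                         ).to_csv(p, sep="\t", index=False,
                                  float_format="%.6g")
            bundle.scatter_files[roi] = p

    if cfg.run_mvpa:
        def _mvpa():
            rows = []
            for roi, subj_samples in state.samples.items():
                res = decoding.decode_roi(
                    subj_samples, C=cfg.svm_c,
                    standardize=cfg.standardize_samples)
                rows.append({"roi": roi, "mean_accuracy": res.group_mean,
                             "sd": res.group_sd, "chance_level": 50.0})
            return pd.DataFrame(rows)
        table8 = _timed("mvpa", _mvpa)
        p = out_dir / "mvpa.tsv"
        table8.to_csv(p, sep="\t", index=False, float_format="%.6g")
        bundle.tables["mvpa"] = p

    log_path = out_dir / "run_log.txt"
    log_path.write_text(
        f"seed: {cfg.seed}\nconfig_hash: {cfg.config_hash()}\n"
        f"stages: {', '.join(STAGES)}\n")
    bundle.log_file = log_path
    return bundle
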