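"""End-to-end orchestration: simulate (or load), screen, analyze, report.

A :class:`RunConfig` fully determines a run; the results bundle (file
contents, excluding wall-clock log timings) is a pure function of it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adaptation as ad
from . import compensation as comp
from . import inference
from .cohort import preset, simulate_cohort
from .dataio import (Dataset, ScreenRules, config_hash, from_cohort,
                     load_dataset, screen_trials, write_dataset)

log = logging.getLogger("fpl")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    seed: int = 0
    preset: str = "realistic"
    n_participants: int | None = None
    data_dir: str | None = None     # load instead of simulate when set
    out_dir: str = "results"
    write_data: bool = False
    exclude_outliers: bool = True
    stages: dict = field(default_factory=lambda: {
        "screen": True, "compensation": True, "adaptation": True,
        "dynamics": True, "stats": True, "report": True})
    cohort_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        from .dataio import _jsonable
        Path(path).write_text(yaml.safe_dump(_jsonable(self)))


@dataclass
class ResultsBundle:
    config: RunConfig
    dataset: Dataset
    screening_report: pd.DataFrame | None = None
    comp: pd.DataFrame | None = None
    comp_summary: pd.DataFrame | None = None
    latencies: pd.DataFrame | None = None
    group_tc: pd.DataFrame | None = None
    adaptation_records: list | None = None
    adaptation_summary: pd.DataFrame | None = None
    outlier_report: pd.DataFrame | None = None
    responders: dict | None = None
    dynamics_window_means: pd.DataFrame | None = None
    dynamics_timecourses: pd.DataFrame | None = None
    models: dict = field(default_factory=dict)
    files: list = field(default_factory=list)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kw)
            except Exception as exc:  # noqa: BLE001 - named stage abort
                raise StageError(name, exc) from exc
            log.info("stage %-12s done in %.2f s", name,
                     time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("data")
def _acquire_data(config: RunConfig) -> Dataset:
    if config.data_dir:
        return load_dataset(config.data_dir)
    overrides = dict(config.cohort_overrides)
    if isinstance(overrides.get("schedule"), dict):
        from .design import ScheduleConfig
        sched = {k: tuple(v) if isinstance(v, list) else v
                 for k, v in overrides["schedule"].items()}
        overrides["schedule"] = ScheduleConfig(**sched)
    if config.n_participants is not None:
        overrides["n_participants"] = config.n_participants
    cc = preset(config.preset, rng_seed=config.seed, **overrides)
    return from_cohort(simulate_cohort(cc))


def _drop_participants(dataset: Dataset, drop: set[str]) -> Dataset:
    keep = ~dataset.schedule.participant_id.isin(drop)
    return Dataset(dataset.schedule[keep].reset_index(drop=True),
                   {k: v for k, v in dataset.tracks.items()
                    if k[0] not in drop},
                   dataset.participants[
                       ~dataset.participants.participant_id.isin(drop)
                   ].reset_index(drop=True),
                   dataset.provenance, dataset.ground_truth,
                   dataset.true_states)


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Design -> simulate/load -> screen -> analyses -> stats -> report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run(config: RunConfig, out: Path) -> ResultsBundle:
    dataset = _acquire_data(config)
    bundle = ResultsBundle(config, dataset)
    prov = dict(dataset.provenance)
    prov["run_config_hash"] = config_hash(config)
    (out / "provenance.json").write_text(json.dumps(prov, indent=2,
                                                    sort_keys=True))
    bundle.files.append(out / "provenance.json")
    if config.write_data:
        write_dataset(dataset, out / "data")

    if config.stages.get("screen", True):
        dataset, report = _screen(dataset)
        bundle.dataset = dataset
        bundle.screening_report = report
        _save(bundle, report, out / "screening_report.csv")

    if config.stages.get("adaptation", True):
        _adaptation_stage(config, bundle, out)

    if config.stages.get("compensation", True):
        _compensation_stage(bundle, out)

    if config.stages.get("dynamics", True) and bundle.comp is not None \
            and bundle.adaptation_records is not None:
        _dynamics_stage(bundle, out)

    if config.stages.get("stats", True) and bundle.comp is not None:
        _stats_stage(bundle, out)

    if config.stages.get("report", True):
        from .report import make_report
        bundle.files += make_report(bundle, out)
    return bundle


@_stage("screen")
def _screen(dataset):
    return screen_trials(dataset, ScreenRules())


def _save(bundle: ResultsBundle, df: pd.DataFrame, path: Path,
          sep: str = ",") -> None:
    df.to_csv(path, index=False, sep=sep)
    bundle.files.append(path)


@_stage("adaptation")
def _adaptation_stage(config: RunConfig, bundle: ResultsBundle,
                      out: Path) -> None:
    records = ad.adaptation_records(bundle.dataset)
    if config.exclude_outliers:
        kept, report = ad.exclude_outlier_participants(
            ad.records_frame(records))
        bundle.outlier_report = report
        _save(bundle, report, out / "outlier_report.csv")
        dropped = set(bundle.dataset.participant_ids) - set(kept)
        if dropped:
            log.info("outlier exclusion removed %s", sorted(dropped))
            bundle.dataset = _drop_participants(bundle.dataset, dropped)
            records = ad.adaptation_records(bundle.dataset)
    bundle.adaptation_records = records
    bundle.adaptation_summary = ad.adaptation_table(records)
    traj = pd.concat([
        pd.DataFrame({"participant_id": r.participant_id,
                      "direction": r.direction,
                      "window_index": np.arange(1, len(r.smoothed_hz) + 1),
                      "normalized_hz": r.smoothed_hz})
        for r in records], ignore_index=True)
    _save(bundle, traj, out / "adaptation_trajectories.csv")
    _save(bundle, ad.records_frame(records), out / "adaptation.csv")
    _save(bundle, bundle.adaptation_summary, out / "adaptation_summary.csv")


@_stage("compensation")
def _compensation_stage(bundle: ResultsBundle, out: Path) -> None:
    dataset = bundle.dataset
    part_tc = comp.participant_timecourses(dataset)
    bundle.group_tc = comp.group_timecourse(part_tc)
    c, summary, lat = comp.compensation_table(dataset)
    bundle.comp, bundle.comp_summary, bundle.latencies = c, summary, lat
    _save(bundle, part_tc, out / "timecourses.tsv", sep="\t")
    _save(bundle, bundle.group_tc, out / "group_timecourses.tsv", sep="\t")
    _save(bundle, c, out / "compensation.csv")
    _save(bundle, summary, out / "compensation_summary.csv")
    _save(bundle, lat, out / "latencies.csv")


@_stage("dynamics")
def _dynamics_stage(bundle: ResultsBundle, out: Path) -> None:
    adapt_df = ad.records_frame(bundle.adaptation_records)
    responders, wm_parts, tc_parts = {}, [], []
    for direction in (200.0, -200.0):
        subset = ad.select_positive_responders(bundle.comp, adapt_df,
                                               direction)
        responders[direction] = subset
        if not subset:
            log.info("dynamics: no positive responders for %+g Hz; skipped",
                     direction)
            continue
        wm, tc = ad.phase_dynamics(bundle.dataset, subset, direction)
        wm_parts.append(wm)
        tc_parts.append(tc)
    bundle.responders = responders
    rdf = pd.DataFrame([{"direction": d, "participant_id": pid}
                        for d, pids in responders.items() for pid in pids])
    _save(bundle, rdf, out / "responders.csv")
    if wm_parts:
        bundle.dynamics_window_means = pd.concat(wm_parts, ignore_index=True)
        bundle.dynamics_timecourses = pd.concat(tc_parts, ignore_index=True)
        _save(bundle, bundle.dynamics_window_means,
              out / "dynamics_window_means.csv")
        _save(bundle, bundle.dynamics_timecourses,
              out / "dynamics_timecourses.tsv", sep="\t")


@_stage("stats")
def _stats_stage(bundle: ResultsBundle, out: Path) -> None:
    models: dict = {}
    c = bundle.comp.copy()
    c["magnitude"] = c.pert_hz.abs()
    c["direction"] = np.where(c.pert_hz > 0, "pos", "neg")
    models["compensation_factorial"] = inference.factorial_lme(
        c, "peak_pct", ["magnitude", "direction", "pert_kind"],
        covariates=[cv for cv in ("age", "baseline_f1") if cv in c],
        group="participant_id")

    wide = c.pivot_table(index=["participant_id", "pert_hz"],
                         columns="pert_kind", values="peak_pct").reset_index()
    if {"mid_utterance", "whole_utterance"} <= set(wide.columns):
        wide = wide.rename(columns={"mid_utterance": "mid",
                                    "whole_utterance": "whole"})
        models["mid_whole_slope"] = inference.random_intercept_slope(
            wide, "mid", "whole", "participant_id")

    if bundle.adaptation_records is not None:
        adapt = ad.records_frame(bundle.adaptation_records)
        merged = adapt.merge(
            c[["participant_id", "pert_kind", "pert_hz", "peak_pct"]],
            left_on=["participant_id", "direction"],
            right_on=["participant_id", "pert_hz"])
        for kind, label in (("whole_utterance", "whole"),
                            ("mid_utterance", "mid")):
            sub = merged[merged.pert_kind == kind].rename(
                columns={"peak_pct": "unpredict",
                         "adaptation_pct": "adapt"})
            if len(sub):
                models[f"comp_adapt_slope_{label}"] = \
                    inference.random_intercept_slope(
                        sub, "unpredict", "adapt", "participant_id")

    if bundle.dynamics_window_means is not None:
        wm = bundle.dynamics_window_means
        wm = wm[wm.phase != "late_baseline"]
        models["dynamics_factorial"] = inference.dynamics_lme(wm)
        for d, g in wm.groupby("direction"):
            models[f"dynamics_{'plus' if d > 0 else 'minus'}200"] = \
                inference.dynamics_lme(g)

    sessions = sorted(set(bundle.dataset.schedule.session) & {1, 3, 5})
    if len(sessions) == 3:
        so = inference.session_order_checks(bundle.dataset)
        models["session_order_lme"] = so["per_session_lme"]
        models["session_order_anova"] = so["baseline_f1_anova"]

    bundle.models = models
    mdir = out / "models"
    mdir.mkdir(exist_ok=True)
    for name, res in models.items():
        path = mdir / f"{name}.json"
        if isinstance(res, inference.MixedModelResult):
            path.write_text(res.to_json(indent=2))
        else:
            path.write_text(json.dumps(res, indent=2, default=float))
        bundle.files.append(path)
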