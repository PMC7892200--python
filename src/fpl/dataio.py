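"""Dataset assembly, on-disk formats, and trial screening.

Layout of a data directory written by :func:`write_dataset`:

    schedule.csv                     all trials, all participants
    participants.csv                 participant_id, group, age
    ground_truth.csv                 simulator parameters (if available)
    true_states.csv                  per-trial adaptation states (if available)
    provenance.json                  seed + config hash
    tracks/<pid>_s<session>.tsv      trial_index, frame, time_ms, f1_hz
    tracks/<pid>_s<session>.json     voice markers, quality flags, trial echo

All timestamps are milliseconds relative to voice onset; analysis windows
are half-open ``[a, b)``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortData, FormantTrack
from .design import SCHEDULE_COLUMNS, frame_to_schedule


@dataclass
class Dataset:
    """Analysis-ready container joining schedules, tracks and metadata."""

    schedule: pd.DataFrame
    tracks: dict
    participants: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    ground_truth: pd.DataFrame | None = None
    true_states: pd.DataFrame | None = None

    @property
    def participant_ids(self) -> list[str]:
        return list(self.participants["participant_id"])

    def get_track(self, participant_id: str, session: int,
                  trial_index: int) -> FormantTrack:
        return self.tracks[(participant_id, int(session), int(trial_index))]

    def trials(self, participant_id: str | None = None,
               session: int | None = None, word: str | None = None,
               phase: str | None = None,
               pert_kind: str | None = None) -> pd.DataFrame:
        df = self.schedule
        if participant_id is not None:
            df = df[df.participant_id == participant_id]
        if session is not None:
            df = df[df.session == session]
        if word is not None:
            df = df[df.word == word]
        if phase is not None:
            df = df[df.phase == phase]
        if pert_kind is not None:
            df = df[df.pert_kind == pert_kind]
        return df

    def good_head_trials(self, **kw) -> pd.DataFrame:
        """Analyzable trials: word 'head', track present, not screened out."""
        df = self.trials(word="head", **kw)
        keep = [
            (r.participant_id, r.session, r.trial_index) in self.tracks
            and self.tracks[(r.participant_id, r.session,
                             r.trial_index)].quality_flag == "good"
            for r in df.itertuples(index=False)]
        return df[np.asarray(keep, dtype=bool)] if len(df) else df


def from_cohort(cohort: CohortData) -> Dataset:
    """Wrap an in-memory simulated cohort as a Dataset (no file round trip)."""
    prov = {"rng_seed": cohort.config.rng_seed,
            "config_hash": config_hash(cohort.config)}
    return Dataset(cohort.schedule.copy(), dict(cohort.tracks),
                   cohort.participants.copy(), prov,
                   cohort.ground_truth.copy(), cohort.true_states.copy())


def config_hash(config) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ------------------------------------------------------------------ write

def write_dataset(data: CohortData | Dataset, outdir) -> Path:
    outdir = Path(outdir)
    (outdir / "tracks").mkdir(parents=True, exist_ok=True)
    if isinstance(data, CohortData):
        data = from_cohort(data)
    data.schedule.to_csv(outdir / "schedule.csv", index=False)
    data.participants.to_csv(outdir / "participants.csv", index=False)
    if data.ground_truth is not None:
        data.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
    if data.true_states is not None:
        data.true_states.to_csv(outdir / "true_states.csv", index=False)
    (outdir / "provenance.json").write_text(
        json.dumps(data.provenance, indent=2, sort_keys=True))

    by_ps: dict[tuple[str, int], list[FormantTrack]] = {}
    for (pid, session, _idx), tr in data.tracks.items():
        by_ps.setdefault((pid, session), []).append(tr)
    for (pid, session), trs in sorted(by_ps.items()):
        trs.sort(key=lambda t: t.trial_index)
        stem = outdir / "tracks" / f"{pid}_s{session}"
        with open(f"{stem}.tsv", "w") as fh:
            fh.write("trial_index\tframe\ttime_ms\tf1_hz\n")
            for tr in trs:
                t = tr.times_ms
                for k in range(len(tr.f1)):
                    fh.write(f"{tr.trial_index}\t{k}\t{t[k]:.6g}\t"
                             f"{float(tr.f1[k])!r}\n")
        side = {str(tr.trial_index): {
            "voice_onset_frame": tr.voice_onset_frame,
            "voice_offset_frame": tr.voice_offset_frame,
            "frame_interval_ms": tr.frame_interval_ms,
            "quality_flag": tr.quality_flag,
        } for tr in trs}
        Path(f"{stem}.json").write_text(json.dumps(side, indent=0))
    return outdir


# ------------------------------------------------------------------- load

class DatasetError(ValueError):
    pass


def load_dataset(path) -> Dataset:
    """Load and validate a data directory written by :func:`write_dataset`.

    Raises :class:`DatasetError` on schema mismatches, orphan tracks, missing
    voice markers or non-uniform frame grids.
    """
    path = Path(path)
    schedule = pd.read_csv(path / "schedule.csv")
    missing = set(SCHEDULE_COLUMNS) - set(schedule.columns)
    if missing:
        raise DatasetError(f"schedule.csv missing columns: {sorted(missing)}")
    frame_to_schedule(schedule)  # validates perturbation invariants
    participants = pd.read_csv(path / "participants.csv")
    prov = {}
    if (path / "provenance.json").exists():
        prov = json.loads((path / "provenance.json").read_text())
    truth = states = None
    if (path / "ground_truth.csv").exists():
        truth = pd.read_csv(path / "ground_truth.csv")
    if (path / "true_states.csv").exists():
        states = pd.read_csv(path / "true_states.csv")

    keys = {(r.participant_id, int(r.session), int(r.trial_index))
            for r in schedule.itertuples(index=False)}
    tracks: dict = {}
    for tsv in sorted((path / "tracks").glob("*.tsv")):
        pid, s = tsv.stem.rsplit("_s", 1)
        session = int(s)
        side = json.loads(tsv.with_suffix(".json").read_text())
        df = pd.read_csv(tsv, sep="\t", float_precision="round_trip")
        for trial_index, g in df.groupby("trial_index"):
            key = (pid, session, int(trial_index))
            if key not in keys:
                raise DatasetError(f"orphan track with no scheduled trial: {key}")
            meta = side.get(str(int(trial_index)))
            if meta is None or meta.get("voice_onset_frame") is None:
                raise DatasetError(
                    f"trial {key}: missing voice_onset marker in sidecar")
            g = g.sort_values("frame")
            dt = np.diff(g["time_ms"].to_numpy())
            if len(dt) and (np.abs(dt - dt[0]) > 1e-6).any():
                raise DatasetError(f"trial {key}: non-uniform frame grid")
            tracks[key] = FormantTrack(
                pid, session, int(trial_index),
                float(meta["frame_interval_ms"]), g["f1_hz"].to_numpy(),
                int(meta["voice_onset_frame"]),
                int(meta["voice_offset_frame"]),
                meta.get("quality_flag", "good"))
    return Dataset(schedule, tracks, participants, prov, truth, states)


# -------------------------------------------------------------- screening

@dataclass(frozen=True)
class ScreenRules:
    """Trial-level screening thresholds.

    ``min_coverage_ms`` is the minimum voiced coverage a trial must have to
    stay in the dataset at all; analyses that need later windows (e.g.
    [600, 800) ms) additionally check coverage themselves, so a short trial
    can remain valid for early-window analyses.
    """

    min_coverage_ms: float = 100.0
    require_finite: bool = True
    drop_flagged: bool = True


def screen_trials(dataset: Dataset, rules: ScreenRules = ScreenRules(),
                  ) -> tuple[Dataset, pd.DataFrame]:
    """Apply screening rules; returns the screened dataset and a report.

    The report has one row per participant with head-trial exclusion
    percentages. Screening is idempotent: reapplying it to its own output
    removes nothing further.
    """
    reasons: dict[tuple, str] = {}
    for key, tr in dataset.tracks.items():
        if rules.drop_flagged and tr.quality_flag != "good":
            reasons[key] = "flagged"
        elif rules.require_finite and not np.isfinite(
                tr.f1[tr.voice_onset_frame:tr.voice_offset_frame]).all():
            reasons[key] = "non_finite_f1"
        elif tr.duration_ms < rules.min_coverage_ms:
            reasons[key] = "too_short"

    tracks = {k: v for k, v in dataset.tracks.items() if k not in reasons}
    rows = []
    head = dataset.schedule[dataset.schedule.word == "head"]
    for pid, g in head.groupby("participant_id"):
        n = len(g)
        n_missing = sum((r.participant_id, r.session, r.trial_index)
                        not in tracks for r in g.itertuples(index=False))
        rows.append({"participant_id": pid, "n_head_trials": n,
                     "n_excluded": n_missing,
                     "pct_excluded": 100.0 * n_missing / n if n else 0.0})
    report = pd.DataFrame(rows, columns=["participant_id", "n_head_trials",
                                         "n_excluded", "pct_excluded"])
    screened = Dataset(dataset.schedule, tracks, dataset.participants,
                       dict(dataset.provenance), dataset.ground_truth,
                       dataset.true_states)
    return screened, report
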