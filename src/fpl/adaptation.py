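"""Across-trial sensorimotor adaptation and within-trial dynamics.

Adaptation to the consistent +/-200 Hz whole-utterance perturbation is
quantified from the *initial feedforward* portion of each trial: the mean F1
over the first 75 ms from voice onset, a window that precedes any possible
auditory-feedback correction. Per participant and direction the per-trial
early means over the 120 "head" trials of an adaptation session are

* baseline-normalized by subtracting the mean over head trials 1-30,
* smoothed into non-overlapping five-trial windows for display, and
* summarized as the late-phase adaptation percentage: the mean normalized
  response over head trials 76-90 (the last 15 hold-phase head trials)
  converted to percent compensation of the perturbation.

The within-trial dynamics analysis compares full voice-onset-aligned F1
time-courses between four 15-trial analysis phases (late baseline 16-30,
early adaptation 31-45, late adaptation 76-90, late washout 106-120), each
normalized by the participant's mean time-course over head trials 1-30, and
summarizes them in two windows: onset "O" [0, 75) ms (feedforward) and
mid-utterance "M" [600, 800) ms (feedback-influenced).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compensation import AnalysisError, to_percent
from .dataio import Dataset
from .inference import one_sample_t

EARLY_WINDOW_MS = (0.0, 75.0)
MID_WINDOW_MS = (600.0, 800.0)
BASELINE_HEAD_TRIALS = 30
LATE_HOLD_ORDINALS = (76, 90)
SMOOTH_TRIALS = 5

PHASES = {
    "late_baseline": (16, 30),
    "early_adapt": (31, 45),
    "late_adapt": (76, 90),
    "late_washout": (106, 120),
}


def adaptation_session_for(dataset: Dataset, participant_id: str,
                           direction: float) -> tuple[int, float]:
    """(session, signed hold perturbation) matching a +/-200 direction."""
    hold = dataset.trials(participant_id=participant_id, phase="hold")
    for session, g in hold.groupby("session"):
        p = float(g.pert_hz.iloc[0])
        if np.sign(p) == np.sign(direction):
            return int(session), p
    raise AnalysisError(
        f"{participant_id}: no adaptation session with a "
        f"{'+' if direction > 0 else '-'} perturbation")


def head_trial_table(dataset: Dataset, participant_id: str,
                     session: int) -> pd.DataFrame:
    """Scheduled head trials of one session with 1-based head ordinals.

    Ordinals are assigned from the schedule, so screened-out trials keep
    their position (and simply contribute missing values downstream).
    """
    df = dataset.trials(participant_id=participant_id, session=session,
                        word="head").sort_values("trial_index").copy()
    df["head_ordinal"] = np.arange(1, len(df) + 1)
    return df


def early_means(dataset: Dataset, participant_id: str, session: int,
                window_ms: tuple[float, float] = EARLY_WINDOW_MS,
                ) -> pd.DataFrame:
    """Per-head-trial mean F1 over the early window; NaN where the trial was
    screened out or lacks coverage."""
    table = head_trial_table(dataset, participant_id, session)
    vals = []
    for r in table.itertuples(index=False):
        key = (r.participant_id, r.session, r.trial_index)
        tr = dataset.tracks.get(key)
        if tr is None or tr.quality_flag != "good":
            vals.append(np.nan)
            continue
        try:
            vals.append(tr.window_mean(*window_ms))
        except ValueError:
            vals.append(np.nan)
    table = table[["participant_id", "session", "trial_index",
                   "head_ordinal"]].copy()
    table["early_mean_hz"] = vals
    return table


@dataclass
class AdaptationRecord:
    participant_id: str
    direction: float            # signed hold perturbation, Hz
    session: int
    head_ordinals: np.ndarray
    early_means_hz: np.ndarray
    baseline_ref_hz: float
    normalized_hz: np.ndarray   # early means - baseline reference
    smoothed_hz: np.ndarray     # non-overlapping five-trial means
    adaptation_pct: float
    n_missing_late: int


def adaptation_trajectory(dataset: Dataset, participant_id: str,
                          direction: float,
                          max_missing: int = 3) -> AdaptationRecord:
    """Across-trial adaptation record for one participant and direction."""
    session, p = adaptation_session_for(dataset, participant_id, direction)
    em = early_means(dataset, participant_id, session)
    x = em.early_mean_hz.to_numpy()
    ordinals = em.head_ordinal.to_numpy()

    base_mask = ordinals <= BASELINE_HEAD_TRIALS
    base_vals = x[base_mask]
    if np.isnan(base_vals).sum() > 2 * max_missing:
        raise AnalysisError(f"{participant_id}: too many missing baseline "
                            f"trials in session {session}")
    ref = float(np.nanmean(base_vals))
    norm = x - ref

    n_win = len(norm) // SMOOTH_TRIALS
    smoothed = np.array([
        np.nanmean(norm[i * SMOOTH_TRIALS:(i + 1) * SMOOTH_TRIALS])
        if np.isfinite(norm[i * SMOOTH_TRIALS:(i + 1) * SMOOTH_TRIALS]).any()
        else np.nan
        for i in range(n_win)])

    lo, hi = LATE_HOLD_ORDINALS
    late = norm[(ordinals >= lo) & (ordinals <= hi)]
    n_missing = int(np.isnan(late).sum())
    if n_missing > max_missing or len(late) == 0:
        raise AnalysisError(
            f"{participant_id}: {n_missing} missing trials in head trials "
            f"{lo}-{hi} exceeds tolerance {max_missing}")
    pct = to_percent(float(np.nanmean(late)), p)
    return AdaptationRecord(participant_id, p, session, ordinals, x, ref,
                            norm, smoothed, pct, n_missing)


def adaptation_records(dataset: Dataset,
                       directions=(200.0, -200.0)) -> list[AdaptationRecord]:
    recs = []
    for pid in dataset.participant_ids:
        for d in directions:
            recs.append(adaptation_trajectory(dataset, pid, d))
    return recs


def records_frame(records: list[AdaptationRecord]) -> pd.DataFrame:
    return pd.DataFrame([{"participant_id": r.participant_id,
                          "direction": r.direction, "session": r.session,
                          "adaptation_pct": r.adaptation_pct}
                         for r in records])


def adaptation_table(records: list[AdaptationRecord]) -> pd.DataFrame:
    """Group mean, SEM and one-sample t vs 0 per perturbation direction."""
    df = records_frame(records)
    rows = []
    for d, g in df.groupby("direction"):
        if len(g) < 2:
            raise AnalysisError(f"direction {d:+g}: need >= 2 participants")
        t = one_sample_t(g.adaptation_pct.to_numpy())
        rows.append({"direction": d, "n": len(g), "mean_pct": t.mean,
                     "sem_pct": t.sem, "t": t.t, "df": t.df, "p_value": t.p})
    return pd.DataFrame(rows)


def exclude_outlier_participants(adapt: pd.DataFrame,
                                 n_sd: float = 3.0,
                                 ) -> tuple[list[str], pd.DataFrame]:
    """Single-pass participant outlier rule.

    A participant is removed when, in either direction, their adaptation
    percentage lies more than ``n_sd`` cohort standard deviations (computed
    about the mean) from the cohort *median*. Applied once, per direction,
    then unioned.
    """
    if adapt.participant_id.nunique() < 3:
        raise AnalysisError("outlier screening needs >= 3 participants")
    removed: dict[str, list] = {}
    for d, g in adapt.groupby("direction"):
        x = g.adaptation_pct.to_numpy()
        med = float(np.median(x))
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            continue
        for pid, v in zip(g.participant_id, x):
            if abs(v - med) > n_sd * sd:
                removed.setdefault(pid, []).append(
                    {"participant_id": pid, "direction": d,
                     "adaptation_pct": v, "median": med, "sd": sd,
                     "n_sd_from_median": abs(v - med) / sd})
    report = pd.DataFrame(
        [row for rows in removed.values() for row in rows],
        columns=["participant_id", "direction", "adaptation_pct", "median",
                 "sd", "n_sd_from_median"])
    kept = [pid for pid in adapt.participant_id.unique()
            if pid not in removed]
    return kept, report


def select_positive_responders(comp: pd.DataFrame, adapt: pd.DataFrame,
                               direction: float) -> list[str]:
    """Participants with positive whole-utterance compensation *and*
    positive adaptation for the given +/-200 Hz direction."""
    c = comp[(comp.pert_kind == "whole_utterance")
             & (comp.pert_hz == direction)]
    a = adapt[adapt.direction == direction]
    pos_c = set(c.loc[c.peak_pct > 0, "participant_id"])
    pos_a = set(a.loc[a.adaptation_pct > 0, "participant_id"])
    return sorted(pos_c & pos_a)


# -------------------------------------------------- within-trial dynamics

def _stacked_timecourses(dataset: Dataset, participant_id: str,
                         session: int) -> tuple[np.ndarray, np.ndarray,
                                                np.ndarray]:
    """(ordinals, times_ms, 2-D array trials x frames) for one session's
    head trials, truncated to the shortest available track; missing trials
    are NaN rows."""
    table = head_trial_table(dataset, participant_id, session)
    tracks = []
    for r in table.itertuples(index=False):
        tr = dataset.tracks.get((r.participant_id, r.session, r.trial_index))
        if tr is not None and tr.quality_flag == "good":
            tracks.append(tr)
        else:
            tracks.append(None)
    lengths = [tr.voice_offset_frame - tr.voice_onset_frame
               for tr in tracks if tr is not None]
    if not lengths:
        raise AnalysisError(f"{participant_id}: no usable head trials in "
                            f"session {session}")
    n = min(lengths)
    dt = next(tr for tr in tracks if tr is not None).frame_interval_ms
    mat = np.full((len(tracks), n), np.nan)
    for i, tr in enumerate(tracks):
        if tr is not None:
            mat[i] = tr.f1[tr.voice_onset_frame:tr.voice_onset_frame + n]
    return table.head_ordinal.to_numpy(), np.arange(n) * dt, mat


def phase_dynamics(dataset: Dataset, responders: list[str], direction: float,
                   max_missing: int = 3,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phase-wise within-trial time-courses for the responder subset.

    Returns ``(window_means, timecourses)``:

    * ``window_means``: participant x phase x window ("O" = [0,75) ms,
      "M" = [600,800) ms) means in Hz and percent compensation;
    * ``timecourses``: baseline-normalized per-participant phase mean
      time-courses (tidy, per frame).
    """
    if not responders:
        raise AnalysisError("responder subset is empty")
    wm_rows = []
    tc_parts = []
    for pid in responders:
        session, p = adaptation_session_for(dataset, pid, direction)
        ordinals, times, mat = _stacked_timecourses(dataset, pid, session)
        base_rows = mat[ordinals <= BASELINE_HEAD_TRIALS]
        baseline_tc = np.nanmean(base_rows, axis=0)
        for phase, (lo, hi) in PHASES.items():
            rows = mat[(ordinals >= lo) & (ordinals <= hi)]
            missing = int(np.isnan(rows).all(axis=1).sum())
            if missing > max_missing:
                raise AnalysisError(
                    f"{pid} {phase}: {missing} missing trials exceeds "
                    f"tolerance {max_missing}")
            tc = np.nanmean(rows, axis=0) - baseline_tc
            tc_parts.append(pd.DataFrame({
                "participant_id": pid, "direction": p, "phase": phase,
                "time_ms": times, "value_hz": tc}))
            for window, (a, b) in (("O", EARLY_WINDOW_MS),
                                   ("M", MID_WINDOW_MS)):
                m = (times >= a) & (times < b)
                if not m.any():
                    raise AnalysisError(
                        f"{pid} {phase}: no coverage of the "
                        f"[{a:g}, {b:g}) ms window")
                mean_hz = float(np.nanmean(tc[m]))
                wm_rows.append({"participant_id": pid, "direction": p,
                                "phase": phase, "window": window,
                                "mean_hz": mean_hz,
                                "pct": to_percent(mean_hz, p)})
    window_means = pd.DataFrame(wm_rows)
    timecourses = pd.concat(tc_parts, ignore_index=True)
    return window_means, timecourses


def group_phase_timecourses(timecourses: pd.DataFrame) -> pd.DataFrame:
    """Across-responder mean +/- SEM of the phase time-courses."""
    return (timecourses
            .groupby(["direction", "phase", "time_ms"])["value_hz"]
            .agg(mean_hz="mean", sem_hz="sem", n="size")
            .reset_index())
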