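"""Within-trial online compensation to unpredictable F1 perturbations.

The analysis turns raw per-trial F1 tracks into perturbation-aligned
response time-courses in three linear normalization steps:

1. subtract the participant's *unperturbed response trend* — the mean F1
   track over that participant's good unperturbed "head" trials, each
   re-referenced so F1(t=0)=0 at voice onset — removing the shared
   within-trial trajectory (e.g. the vowel-onset transient);
2. re-align time zero to perturbation onset and subtract the mean of the
   first 50 ms of post-onset data (a window that precedes any possible
   auditory-feedback response), removing across-trial offset variation;
3. average within non-overlapping 25 ms bins to suppress frame-to-frame
   formant-tracking noise.

Trials are then averaged per participant within each of the eight
conditions, and across participants into a group mean +/- SEM time-course.
The group onset latency is the first bin whose mean response exceeds two
standard deviations of the pooled first-50 ms bin values (pooled over the
four magnitudes of the same perturbation type) in the compensatory
direction. The peak compensation of a participant is the mean of their
normalized response in the 200 ms window centred on the group peak latency,
expressed as a percent of the perturbation:

    pct = window_mean_Hz / |p| * 100 * compMult,   compMult = -sign(p)

so that responses opposing the perturbation are positive regardless of the
perturbation's direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import FormantTrack
from .dataio import Dataset
from .design import MID, NONE, WHOLE
from .inference import TTestResult, one_sample_t

REF_MS = 50.0     # first-50 ms re-referencing window after perturbation onset
BIN_MS = 25.0     # smoothing bin width
PEAK_WINDOW_MS = 200.0   # window around the group peak latency
MID_SEARCH_PAST_OFFSET_MS = 300.0


class AnalysisError(ValueError):
    pass


def comp_mult(p_hz: float) -> float:
    """-1 for positive perturbations, +1 for negative ones."""
    if p_hz == 0:
        raise AnalysisError("compMult undefined for a zero perturbation")
    return -1.0 if p_hz > 0 else 1.0


def to_percent(mean_hz: float, p_hz: float) -> float:
    """Convert a normalized response (Hz) to percent compensation."""
    return mean_hz / abs(p_hz) * 100.0 * comp_mult(p_hz)


# ------------------------------------------------------------ step 1 trend

def unperturbed_trend(dataset: Dataset, participant_id: str,
                      sessions: tuple[int, ...] = (1, 3, 5),
                      include_familiarization: bool = True) -> np.ndarray:
    """Per-frame mean F1 of the participant's unperturbed "head" trials.

    Each trial is first re-referenced to its own voice-onset value so the
    trend starts at 0 Hz; the trend is defined on every frame covered by at
    least one contributing trial.
    """
    df = dataset.good_head_trials(participant_id=participant_id,
                                  pert_kind=NONE)
    df = df[df.session.isin(sessions)]
    if not include_familiarization:
        df = df[df.phase != "familiarization"]
    rows = [dataset.get_track(r.participant_id, r.session, r.trial_index)
            for r in df.itertuples(index=False)]
    if not rows:
        raise AnalysisError(
            f"participant {participant_id}: no unperturbed head trials")
    n = max(tr.voice_offset_frame - tr.voice_onset_frame for tr in rows)
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for tr in rows:
        f1 = tr.f1[tr.voice_onset_frame:tr.voice_offset_frame]
        acc[:len(f1)] += f1 - f1[0]
        cnt[:len(f1)] += 1
    return acc[cnt > 0] / cnt[cnt > 0]


# --------------------------------------------------------- steps 2-3

def normalized_frames(track: FormantTrack, trend: np.ndarray,
                      pert_onset_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Trend-subtracted, onset-re-referenced response at frame resolution.

    Returns ``(t_rel, values)`` where ``t_rel`` is ms relative to
    perturbation onset. The mean of ``values`` over ``[0, 50)`` ms is zero
    by construction.
    """
    f1 = track.f1[track.voice_onset_frame:track.voice_offset_frame]
    n = min(len(f1), len(trend))
    d = f1[:n] - trend[:n]
    t_rel = np.arange(n) * track.frame_interval_ms - pert_onset_ms
    ref = (t_rel >= 0) & (t_rel < REF_MS)
    if t_rel[-1] + track.frame_interval_ms < REF_MS or not ref.any():
        raise AnalysisError(
            f"trial {track.participant_id}/s{track.session}/"
            f"{track.trial_index}: no coverage of the first "
            f"{REF_MS:.0f} ms after perturbation onset")
    d = d - d[ref].mean()
    return t_rel, d


def bin_series(t_rel: np.ndarray, values: np.ndarray,
               bin_ms: float = BIN_MS) -> tuple[np.ndarray, np.ndarray]:
    """Average into non-overlapping bins anchored at t=0 (half-open)."""
    idx = np.floor(t_rel / bin_ms).astype(int)
    off = idx - idx.min()
    cnt = np.bincount(off)
    sums = np.bincount(off, weights=values)
    keep = cnt > 0
    starts = (np.arange(idx.min(), idx.max() + 1) * bin_ms)[keep]
    return starts, sums[keep] / cnt[keep]


def normalize_trial(track: FormantTrack, trend: np.ndarray,
                    pert_onset_ms: float, bin_ms: float = BIN_MS,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Full per-trial normalization: steps 1-3. Returns (bin_starts, values)."""
    t_rel, d = normalized_frames(track, trend, pert_onset_ms)
    return bin_series(t_rel, d, bin_ms)


# ----------------------------------------------------------- aggregation

def participant_timecourses(dataset: Dataset,
                            sessions: tuple[int, ...] = (1, 3, 5),
                            include_familiarization: bool = True,
                            bin_ms: float = BIN_MS,
                            trend_sessions: tuple[int, ...] = (1, 3, 5),
                            ) -> pd.DataFrame:
    """Per participant x condition binned mean time-courses (tidy).

    Columns: participant_id, pert_kind, pert_hz, bin_start_ms, value_hz,
    n_trials. The unperturbed trend is always pooled over
    ``trend_sessions`` (all three unpredictable sessions by default), even
    when ``sessions`` restricts which perturbed trials are analyzed — e.g.
    for per-session carry-over checks.
    """
    trends = {pid: unperturbed_trend(dataset, pid, trend_sessions,
                                     include_familiarization)
              for pid in dataset.participant_ids}
    df = dataset.good_head_trials()
    df = df[df.session.isin(sessions) & (df.pert_kind != NONE)]
    if not include_familiarization:
        df = df[df.phase != "familiarization"]
    cols: dict[str, list] = {k: [] for k in
                             ("participant_id", "pert_kind", "pert_hz",
                              "bin_start_ms", "value_hz")}
    for r in df.itertuples(index=False):
        track = dataset.get_track(r.participant_id, r.session, r.trial_index)
        starts, vals = normalize_trial(track, trends[r.participant_id],
                                       r.pert_onset_ms, bin_ms)
        cols["participant_id"].append(np.repeat(r.participant_id, len(starts)))
        cols["pert_kind"].append(np.repeat(r.pert_kind, len(starts)))
        cols["pert_hz"].append(np.repeat(r.pert_hz, len(starts)))
        cols["bin_start_ms"].append(starts)
        cols["value_hz"].append(vals)
    if not cols["bin_start_ms"]:
        raise AnalysisError("no analyzable perturbed head trials")
    tidy = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})
    out = (tidy.groupby(["participant_id", "pert_kind", "pert_hz",
                         "bin_start_ms"], as_index=False)
           .agg(value_hz=("value_hz", "mean"), n_trials=("value_hz", "size")))
    return out


def group_timecourse(part_tc: pd.DataFrame) -> pd.DataFrame:
    """Across-participant mean +/- SEM per condition and bin.

    Only bins covered by every participant contributing to the condition are
    retained, so group statistics compare like with like.
    """
    out = []
    for (kind, p), g in part_tc.groupby(["pert_kind", "pert_hz"]):
        n_pid = g.participant_id.nunique()
        agg = (g.groupby("bin_start_ms")["value_hz"]
               .agg(["mean", "sem", "count"]).reset_index())
        agg = agg[agg["count"] == n_pid]
        agg.insert(0, "pert_hz", p)
        agg.insert(0, "pert_kind", kind)
        out.append(agg.rename(columns={"mean": "mean_hz", "sem": "sem_hz",
                                       "count": "n"}))
    return pd.concat(out, ignore_index=True)


# -------------------------------------------------------------- latencies

def onset_latency(group_tc: pd.DataFrame, kind: str, p_hz: float,
                  ref_ms: float = REF_MS, n_persist: int = 3) -> float | None:
    """Group response onset latency for one condition, in ms; None if the
    response never exceeds threshold.

    The baseline pool is every group-mean bin value in ``[0, ref_ms)``
    across all magnitudes of the same perturbation type; the latency is the
    first bin (scanning forward from perturbation onset) whose value lies
    beyond mean(pool) +/- 2 sd(pool) in the compensatory direction and
    stays beyond it for ``n_persist`` consecutive bins (default 3, i.e.
    75 ms). The persistence requirement keeps isolated noisy bins from
    registering as a response onset; a genuine sustained response still
    dates from its first crossing bin.
    """
    same_kind = group_tc[group_tc.pert_kind == kind]
    in_ref = (same_kind.bin_start_ms >= 0) & (same_kind.bin_start_ms < ref_ms)
    pool = same_kind[in_ref]["mean_hz"].to_numpy()
    if len(pool) < 2:
        raise AnalysisError(f"{kind}: onset-response pool too small")
    mu = float(pool.mean())
    # The re-referencing step forces each trial's mean over [0, ref_ms) to
    # zero, which deflates the variance of the pooled onset-window bins by
    # (m-1)/m relative to the bins scanned for a crossing (m bins per
    # condition inside the reference window). Undo that deflation so the
    # 2 SD threshold reflects the noise scale of the scanned bins.
    m = int(in_ref.sum() // same_kind.pert_hz.nunique())
    infl = math.sqrt(m / (m - 1)) if m > 1 else 1.0
    sd = float(pool.std(ddof=1)) * infl
    cond = same_kind[(same_kind.pert_hz == p_hz)
                     & (same_kind.bin_start_ms >= 0)].sort_values("bin_start_ms")
    vals = cond["mean_hz"].to_numpy()
    if sd == 0.0:
        if np.allclose(vals, mu):
            return None
        raise AnalysisError(f"{kind}: degenerate onset pool (sd=0)")
    direction = comp_mult(p_hz)  # compensatory sign
    crossed = direction * (vals - mu) > 2.0 * sd
    if n_persist > 1 and len(crossed) >= n_persist:
        runs = np.ones(len(crossed) - n_persist + 1, dtype=bool)
        for k in range(n_persist):
            runs &= crossed[k:k + len(runs)]
        crossed = np.zeros_like(crossed)
        crossed[:len(runs)] = runs
    if not crossed.any():
        return None
    return float(cond["bin_start_ms"].to_numpy()[np.argmax(crossed)])


def peak_latency(group_tc: pd.DataFrame, kind: str, p_hz: float,
                 onset_ms: float | None, pert_duration_ms: float,
                 ) -> float:
    """Time of the extremum of the group response in the compensatory
    direction, searched from the onset latency (or the end of the reference
    window when no onset was detected) to the perturbation offset + 300 ms
    for transient perturbations, or to the end of common coverage for
    whole-utterance ones."""
    start = onset_ms if onset_ms is not None else REF_MS
    cond = group_tc[(group_tc.pert_kind == kind) & (group_tc.pert_hz == p_hz)]
    if math.isfinite(pert_duration_ms):
        stop = pert_duration_ms + MID_SEARCH_PAST_OFFSET_MS
    else:
        stop = cond.bin_start_ms.max() + BIN_MS
    win = cond[(cond.bin_start_ms >= start)
               & (cond.bin_start_ms < stop)].sort_values("bin_start_ms")
    if win.empty:
        raise AnalysisError(
            f"{kind} {p_hz:+g} Hz: empty peak search window [{start}, {stop})")
    score = comp_mult(p_hz) * win["mean_hz"].to_numpy()
    # exact ties (a flat plateau, e.g. noise-free saturated responses) are
    # broken to the middle of the tied run so the peak window sits inside it
    ties = np.flatnonzero(score == score.max())
    return float(win["bin_start_ms"].to_numpy()[ties[len(ties) // 2]])


def peak_compensation(bin_starts: np.ndarray, values: np.ndarray,
                      peak_ms: float, p_hz: float,
                      window_ms: float = PEAK_WINDOW_MS) -> float:
    """Percent compensation of one participant's time-course in the 200 ms
    window centred on the group peak latency."""
    half = window_ms / 2.0
    m = (bin_starts >= peak_ms - half) & (bin_starts < peak_ms + half)
    if m.sum() < window_ms / BIN_MS / 2:
        raise AnalysisError(
            f"time-course covers only {int(m.sum())} bins of the peak window "
            f"around {peak_ms:.0f} ms")
    return to_percent(float(values[m].mean()), p_hz)


# ---------------------------------------------------------------- tables

def baseline_f1_at_onset(dataset: Dataset, sessions=(1, 3, 5),
                         window_ms: float = REF_MS) -> pd.DataFrame:
    """Raw (non-normalized) F1 at perturbation onset per participant and
    condition: mean over the first ``window_ms`` after onset, averaged over
    trials. Used as a nuisance covariate."""
    df = dataset.good_head_trials()
    df = df[df.session.isin(sessions) & (df.pert_kind != NONE)]
    rows = []
    for r in df.itertuples(index=False):
        tr = dataset.get_track(r.participant_id, r.session, r.trial_index)
        rows.append({"participant_id": r.participant_id,
                     "pert_kind": r.pert_kind, "pert_hz": r.pert_hz,
                     "baseline_f1": tr.window_mean(r.pert_onset_ms,
                                                   r.pert_onset_ms + window_ms)})
    return (pd.DataFrame(rows)
            .groupby(["participant_id", "pert_kind", "pert_hz"],
                     as_index=False).mean())


def compensation_table(dataset: Dataset, sessions: tuple[int, ...] = (1, 3, 5),
                       include_familiarization: bool = True,
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full within-trial analysis.

    Returns ``(comp, summary, latencies)``:

    * ``comp``: one row per participant x condition with ``peak_pct`` and
      the raw-F1 covariate;
    * ``summary``: per condition mean, SEM and one-sample t vs 0;
    * ``latencies``: per condition group onset and peak latency (ms).
    """
    part_tc = participant_timecourses(dataset, sessions,
                                      include_familiarization)
    group_tc = group_timecourse(part_tc)
    base = baseline_f1_at_onset(dataset, sessions)

    comp_rows, lat_rows, sum_rows = [], [], []
    for (kind, p), cond in part_tc.groupby(["pert_kind", "pert_hz"]):
        try:
            onset = onset_latency(group_tc, kind, p)
        except AnalysisError as err:
            if "degenerate" not in str(err):
                raise
            onset = None  # noise-free pool: fall back to the default search

        duration = math.inf if kind == WHOLE else 400.0
        peak = peak_latency(group_tc, kind, p, onset, duration)
        lat_rows.append({"pert_kind": kind, "pert_hz": p,
                         "onset_latency_ms": onset, "peak_latency_ms": peak})
        pcts = []
        for pid, g in cond.groupby("participant_id"):
            pct = peak_compensation(g.bin_start_ms.to_numpy(),
                                    g.value_hz.to_numpy(), peak, p)
            pcts.append(pct)
            comp_rows.append({"participant_id": pid, "pert_kind": kind,
                              "pert_hz": p, "peak_pct": pct})
        t = one_sample_t(np.asarray(pcts))
        sum_rows.append({"pert_kind": kind, "pert_hz": p,
                         "mean_pct": t.mean, "sem_pct": t.sem, "t": t.t,
                         "df": t.df, "p_value": t.p})
    comp = pd.DataFrame(comp_rows).merge(
        base, on=["participant_id", "pert_kind", "pert_hz"], how="left")
    ages = dataset.participants[["participant_id", "age"]] \
        if "age" in dataset.participants else None
    if ages is not None:
        comp = comp.merge(ages, on="participant_id", how="left")
    return comp, pd.DataFrame(sum_rows), pd.DataFrame(lat_rows)
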