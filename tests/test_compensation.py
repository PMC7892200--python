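"""Within-trial normalization, latency detection and percent compensation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fpl
from fpl.cohort import ParticipantModel, simulate_trial
from fpl.compensation import (AnalysisError, bin_series, compensation_table,
                              group_timecourse, normalize_trial,
                              normalized_frames, onset_latency,
                              peak_compensation, unperturbed_trend)
from fpl.design import MID, WHOLE, PerturbationSpec, TrialSpec

from conftest import flat_track, make_dataset, schedule_row


def _unpert_rows(pid, n, length=400, maker=None):
    tracks, rows = {}, []
    for i in range(1, n + 1):
        f1 = maker(i) if maker else np.full(length, 600.0)
        tracks[(pid, 1, i)] = flat_track(pid, 1, i, f1)
        rows.append(schedule_row(pid, 1, i))
    return tracks, rows


class TestTrend:
    def test_identical_constant_trials_give_zero_trend(self):
        tracks, rows = _unpert_rows("P01", 3)
        ds = make_dataset(tracks, rows)
        assert np.allclose(unperturbed_trend(ds, "P01"), 0.0)

    def test_ramps_average_to_mean_slope(self):
        # slopes 1 and 3 Hz/frame -> trend slope 2 Hz/frame
        tracks, rows = _unpert_rows(
            "P01", 2, maker=lambda i: 500.0 + (2 * i - 1) * np.arange(300.0))
        ds = make_dataset(tracks, rows)
        trend = unperturbed_trend(ds, "P01")
        np.testing.assert_allclose(trend, 2.0 * np.arange(300.0), atol=1e-9)

    def test_recovers_simulated_transient_exactly(self, clean_dataset):
        pid = clean_dataset.participant_ids[0]
        truth = clean_dataset.ground_truth.set_index("participant_id")
        A = truth.loc[pid, "trend_amplitude"]
        tau = truth.loc[pid, "trend_tau"]
        trend = unperturbed_trend(clean_dataset, pid)
        t = np.arange(len(trend)) * 3.0
        expected = A * np.exp(-t / tau) - A  # onset-normalized transient
        np.testing.assert_allclose(trend, expected, atol=1e-9)

    def test_no_unperturbed_trials_is_an_error(self):
        tracks = {("P01", 1, 1): flat_track("P01", 1, 1,
                                            np.full(400, 600.0))}
        ds = make_dataset(tracks, [schedule_row("P01", 1, 1, word="hid")])
        with pytest.raises(AnalysisError, match="no unperturbed"):
            unperturbed_trend(ds, "P01")


class TestNormalization:
    def test_trial_equal_to_trend_is_zero(self):
        trend = 30.0 * np.exp(-np.arange(500) * 3.0 / 80.0)
        trend -= trend[0]
        track = flat_track("P01", 1, 1, 600.0 + trend)
        for extra in (0.0, 7.0):  # step 2 also removes constant offsets
            track2 = flat_track("P01", 1, 1, 600.0 + trend + extra)
            _, vals = normalize_trial(track2, trend, pert_onset_ms=300.0)
            np.testing.assert_allclose(vals, 0.0, atol=1e-9)

    def test_step_response_bins(self):
        """Noise-free +200 Hz whole-utterance trial with instant dynamics:
        0 Hz before the 250 ms step, -10 Hz from the bin containing it."""
        model = ParticipantModel("P01", f1_baseline=600.0, g_whole=0.05,
                                 comp_latency=250.0, comp_tau=0.0)
        trial = TrialSpec("P01", 1, 1, "head", "unpredictable",
                          PerturbationSpec(WHOLE, 200.0, 0.0, math.inf))
        tr = simulate_trial(model, trial, 0.0, np.random.default_rng(0))
        starts, vals = normalize_trial(tr, np.zeros(len(tr.f1)), 0.0)
        np.testing.assert_allclose(vals[starts < 250.0], 0.0, atol=1e-12)
        np.testing.assert_allclose(vals[starts >= 250.0], -10.0, atol=1e-12)

    def test_insufficient_reference_coverage_is_an_error(self):
        track = flat_track("P01", 1, 1, np.full(100, 600.0))  # 300 ms
        with pytest.raises(AnalysisError, match="coverage"):
            normalized_frames(track, np.zeros(100), pert_onset_ms=280.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 500.0))
    def test_reference_window_mean_is_zero(self, seed, onset):
        rng = np.random.default_rng(seed)
        f1 = 600.0 + rng.normal(0, 15, size=600) \
            + rng.uniform(-40, 40) * np.exp(-np.arange(600) / 30.0)
        track = flat_track("P01", 1, 1, f1)
        t_rel, d = normalized_frames(track, np.zeros(600), onset)
        ref = (t_rel >= 0) & (t_rel < 50.0)
        assert abs(d[ref].mean()) < 1e-9

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_binning_matches_naive_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 400))
        t = np.arange(n) * 3.0 - float(rng.uniform(0, 300))
        v = rng.normal(0, 10, size=n)
        starts, vals = bin_series(t, v)
        for s, got in zip(starts, vals):
            mask = (t >= s) & (t < s + 25.0)
            assert abs(got - v[mask].mean()) < 1e-9


def test_condition_average_and_sem():
    # two participants with opposite series +a/-a: group mean 0, SEM = a
    a = 4.0
    rows = []
    for pid, sign in (("P01", 1.0), ("P02", -1.0)):
        for b in range(4):
            rows.append({"participant_id": pid, "pert_kind": WHOLE,
                         "pert_hz": 200.0, "bin_start_ms": 25.0 * b,
                         "value_hz": sign * a, "n_trials": 3})
    gtc = group_timecourse(pd.DataFrame(rows))
    assert np.allclose(gtc.mean_hz, 0.0)
    assert np.allclose(gtc.sem_hz, a)
    assert (gtc.n == 2).all()


def _group_tc(series_by_mag, kind=MID):
    """Build a group time-course frame from per-magnitude value arrays."""
    rows = []
    for mag, vals in series_by_mag.items():
        for b, v in enumerate(vals):
            rows.append({"pert_kind": kind, "pert_hz": mag,
                         "bin_start_ms": 25.0 * b, "mean_hz": v,
                         "sem_hz": 0.1, "n": 22})
    return pd.DataFrame(rows)


class TestOnsetLatency:
    # deterministic onset-window pool: mean 0, sd ~1 after the
    # re-referencing-deflation correction
    POOL = {-200.0: [0.5, -0.5], -50.0: [1.0, -1.0],
            50.0: [0.3, -0.3], 200.0: [0.8, -0.8]}

    def series(self, tail_by_mag):
        return {m: self.POOL[m] + tail_by_mag.get(m, [0.0] * 18)
                for m in self.POOL}

    def test_constructed_crossing_at_bin_10(self):
        # -200 series rises to +5 (compensatory) at bin 10 and stays there
        s = self.series({-200.0: [0.0] * 8 + [5.0] * 10})
        assert onset_latency(_group_tc(s), MID, -200.0) == 250.0

    def test_zero_response_with_noisy_pool_is_none(self):
        assert onset_latency(_group_tc(self.series({})), MID, 50.0) is None

    def test_anti_compensatory_deflection_is_ignored(self):
        # a "following" response tracks the perturbation: for -200 Hz the
        # compensatory direction is positive, so -8 must not register
        s = self.series({-200.0: [-8.0] * 18})
        assert onset_latency(_group_tc(s), MID, -200.0) is None

    def test_degenerate_pool(self):
        series = {m: [0.0] * 12 for m in (-200.0, -50.0, 50.0, 200.0)}
        assert onset_latency(_group_tc(series), MID, 50.0) is None
        series[-200.0] = [0.0] * 4 + [3.0] * 8
        with pytest.raises(AnalysisError, match="degenerate"):
            onset_latency(_group_tc(series), MID, -200.0)


class TestPeakCompensation:
    def test_formula(self):
        starts = np.arange(0, 500, 25.0)
        vals = np.full_like(starts, -10.0)
        assert peak_compensation(starts, vals, 250.0, 200.0) == 5.0
        assert peak_compensation(starts, np.zeros_like(starts), 250.0,
                                 -50.0) == 0.0

    @pytest.mark.parametrize("p", [50.0, 200.0])
    def test_antisymmetry(self, p):
        rng = np.random.default_rng(3)
        starts = np.arange(0, 500, 25.0)
        vals = rng.normal(0, 5, len(starts))
        plus = peak_compensation(starts, vals, 250.0, p)
        minus = peak_compensation(starts, -vals, 250.0, -p)
        assert plus == pytest.approx(minus, abs=1e-12)

    def test_window_coverage_required(self):
        starts = np.arange(0, 100, 25.0)
        with pytest.raises(AnalysisError, match="window"):
            peak_compensation(starts, np.zeros_like(starts), 600.0, 200.0)


def test_identical_noise_free_compensators_give_exact_table():
    """Every condition's mean equals 100*g with zero SEM when all
    participants share one noise-free instant-response model."""
    from dataclasses import replace
    from conftest import small_schedule_config
    cfg = fpl.preset("clean", rng_seed=5, n_participants=2,
                     schedule=small_schedule_config(5))
    cfg = replace(cfg, means={**cfg.means, "comp_tau": 0.0})
    ds = fpl.from_cohort(fpl.simulate_cohort(cfg, sessions=(1, 3, 5)))
    comp, summary, lat = compensation_table(ds)
    mid = summary[summary.pert_kind == MID]
    whole = summary[summary.pert_kind == WHOLE]
    np.testing.assert_allclose(mid.mean_pct, 3.0, atol=1e-9)
    np.testing.assert_allclose(whole.mean_pct, 5.0, atol=1e-9)
    np.testing.assert_allclose(summary.sem_pct, 0.0, atol=1e-9)


def test_production_path_matches_brute_force_reimplementation():
    """Independent single-pass reimplementation of steps 1-3 agrees with the
    production path to < 1e-9 Hz on random noisy trials."""
    rng = np.random.default_rng(42)
    trend = rng.normal(0, 5, 666)
    for _ in range(30):
        f1 = 600 + rng.normal(0, 12) + rng.normal(0, 6, 666)
        onset = float(rng.uniform(200, 500))
        track = flat_track("P01", 1, 1, f1)
        starts, vals = normalize_trial(track, trend, onset)

        # brute force: plain python loops, no vectorized shortcuts
        d, t = [], []
        for k in range(666):
            d.append(f1[k] - trend[k])
            t.append(k * 3.0 - onset)
        ref = [x for x, tt in zip(d, t) if 0 <= tt < 50]
        ref_mean = sum(ref) / len(ref)
        d = [x - ref_mean for x in d]
        by_bin = {}
        for x, tt in zip(d, t):
            by_bin.setdefault(math.floor(tt / 25.0), []).append(x)
        expect = {25.0 * b: sum(v) / len(v) for b, v in by_bin.items()}
        for s, got in zip(starts, vals):
            assert abs(got - expect[s]) < 1e-9
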