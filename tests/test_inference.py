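"""t-tests, random-intercept regression, factorial mixed models."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import fpl
from fpl.inference import (benjamini_hochberg, dynamics_lme, factorial_lme,
                           one_sample_t, random_intercept_slope,
                           session_order_checks)


class TestOneSampleT:
    def test_matches_textbook_formula_on_random_vectors(self):
        rng = np.random.default_rng(0)
        import scipy.stats as sps
        for n in (3, 8, 25):
            x = rng.normal(1.0, 2.0, n)
            res = one_sample_t(x)
            # brute-force formula, written out independently
            mean = sum(x) / n
            sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
            t = mean / (sd / math.sqrt(n))
            p = 2 * (1 - sps.t.cdf(abs(t), n - 1))
            assert res.t == pytest.approx(t, rel=1e-12)
            assert res.p == pytest.approx(p, rel=1e-9)
            assert res.df == n - 1

    def test_zero_vector(self):
        res = one_sample_t([0.0, 0.0, 0.0])
        assert (res.t, res.p) == (0.0, 1.0) and res.degenerate

    def test_sign_balanced_pair(self):
        res = one_sample_t([1.0, -1.0])
        assert res.mean == 0.0 and res.t == 0.0

    def test_degenerate_nonzero_mean(self):
        res = one_sample_t([5.0, 5.0, 5.0])
        assert res.p == 0.0 and math.isinf(res.t) and res.degenerate

    def test_input_validation(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0])
        with pytest.raises(ValueError):
            one_sample_t([1.0, math.nan])


class TestRandomInterceptSlope:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "pid": np.repeat([f"P{i}" for i in range(8)], 4),
            "x": rng.normal(0, 2, 32)})
        df["y"] = df["x"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = random_intercept_slope(df, "x", "y", "pid")
        assert res.slope == pytest.approx(1.0, abs=1e-6)
        assert res.resid_var < 1e-8

    def test_singleton_groups_reduce_to_ols(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"pid": [f"P{i}" for i in range(15)],
                           "x": rng.normal(0, 1, 15),
                           "y": rng.normal(0, 1, 15)})
        res = random_intercept_slope(df, "x", "y", "pid")
        assert "reduced_to_ols" in res.flags
        b, a = np.polyfit(df.x, df.y, 1)  # closed-form least squares
        assert res.slope == pytest.approx(b, rel=1e-10)
        assert res.random_intercept_var == 0.0

    def test_type_i_error_calibration(self):
        """Independent x, y: the slope test rejects at ~alpha."""
        rej = 0
        n_rep = 300
        for i in range(n_rep):
            rng = np.random.default_rng(10_000 + i)
            g = np.repeat(np.arange(24), 3)
            x = np.repeat(rng.normal(0, 1, 24), 3) + rng.normal(0, 0.2, 72)
            y = np.repeat(rng.normal(0, 1, 24), 3) + rng.normal(0, 0.5, 72)
            df = pd.DataFrame({"pid": g, "x": x, "y": y})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = random_intercept_slope(df, "x", "y", "pid")
            rej += res.slope_p < 0.05
        assert 0.02 <= rej / n_rep <= 0.08

    def test_needs_two_groups(self):
        df = pd.DataFrame({"pid": ["a"] * 4, "x": range(4), "y": range(4)})
        with pytest.raises(ValueError):
            random_intercept_slope(df, "x", "y", "pid")


def _factorial_frame(effect=3.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    offsets = rng.normal(0, 1.0, 12)
    for i in range(12):
        for mag in (50.0, 200.0):
            for direction in ("neg", "pos"):
                y = 2.0 + effect * (mag == 200.0) + offsets[i] \
                    + rng.normal(0, noise)
                rows.append({"participant_id": f"P{i:02d}", "magnitude": mag,
                             "direction": direction, "y": y})
    return pd.DataFrame(rows)


class TestFactorialLme:
    def test_zero_noise_recovers_generating_effects(self):
        df = _factorial_frame(effect=3.0, noise=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = factorial_lme(df, "y", ["magnitude", "direction"])
        eff = res.effects.set_index("term")
        mag_term = [t for t in eff.index if "magnitude" in t
                    and ":" not in t][0]
        assert eff.loc[mag_term, "estimate"] == pytest.approx(3.0, abs=1e-6)
        terms = res.term_tests.set_index("term")
        mag_row = [t for t in terms.index if "magnitude" in t
                   and ":" not in t][0]
        assert terms.loc[mag_row, "p"] < 1e-6
        # no generating direction effect or interaction: every other
        # coefficient is zero
        for coef in eff.index:
            if coef != "Intercept" and coef != mag_term:
                assert abs(eff.loc[coef, "estimate"]) < 1e-6

    def test_p_values_invariant_to_observation_order(self):
        df = _factorial_frame(effect=1.0, noise=0.5, seed=3)
        shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = factorial_lme(df, "y", ["magnitude", "direction"])
            b = factorial_lme(shuffled, "y", ["magnitude", "direction"])
        np.testing.assert_allclose(a.term_tests.p.to_numpy(),
                                   b.term_tests.p.to_numpy(), rtol=1e-6)

    def test_constant_response_gives_zero_effects(self):
        df = _factorial_frame(effect=0.0, noise=0.0)
        df["y"] = 4.2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = factorial_lme(df, "y", ["magnitude", "direction"])
        eff = res.effects.set_index("term")
        for term in eff.index:
            if term != "Intercept":
                assert abs(eff.loc[term, "estimate"]) < 1e-8

    def test_covariates_accepted(self):
        df = _factorial_frame(effect=2.0, noise=0.3, seed=5)
        df["age"] = np.tile(np.repeat([20.0, 30.0, 40.0], 4), 12)[:len(df)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = factorial_lme(df, "y", ["magnitude"], covariates=["age"])
        assert "age" in set(res.term_tests.term)


def test_dynamics_lme_detects_window_effect():
    rng = np.random.default_rng(7)
    rows = []
    for i in range(14):
        off = rng.normal(0, 2)
        for phase in ("early_adapt", "late_adapt", "late_washout"):
            for window in ("O", "M"):
                rows.append({"participant_id": f"P{i:02d}", "phase": phase,
                             "direction": 200.0, "window": window,
                             "pct": 10.0 + 6.0 * (window == "M") + off
                             + rng.normal(0, 1)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = dynamics_lme(pd.DataFrame(rows))
    terms = res.term_tests.set_index("term")
    window_term = [t for t in terms.index if "window" in t
                   and ":" not in t][0]
    assert terms.loc[window_term, "p"] < 0.01


class TestSessionOrder:
    @pytest.fixture(scope="class")
    @staticmethod
    def small_dataset():
        from conftest import small_schedule_config
        cfg = fpl.preset("realistic", rng_seed=21, n_participants=6,
                         schedule=small_schedule_config(
                             21, head_per_condition=6, unperturbed_head=8))
        return fpl.from_cohort(fpl.simulate_cohort(cfg, sessions=(1, 3, 5)))

    def test_report_structure(self, small_dataset):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = session_order_checks(small_dataset)
        assert 0.0 <= out["baseline_f1_anova"]["p"] <= 1.0
        assert set(out["baseline_medians"].session) == {1, 3, 5}
        assert {1, 3, 5} == set(out["per_session_compensation"].session)
        assert out["per_session_lme"].n_obs > 0

    def test_injected_session_shift_is_detected(self, small_dataset):
        import copy
        shifted = copy.copy(small_dataset)
        shifted.tracks = {
            k: (v if k[1] != 5 else
                type(v)(v.participant_id, v.session, v.trial_index,
                        v.frame_interval_ms, v.f1 + 30.0,
                        v.voice_onset_frame, v.voice_offset_frame,
                        v.quality_flag))
            for k, v in small_dataset.tracks.items()}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = session_order_checks(shifted)
        assert out["baseline_f1_anova"]["p"] < 0.01

    def test_missing_session_is_an_error(self):
        cfg = fpl.preset("clean", rng_seed=2, n_participants=2)
        ds = fpl.from_cohort(fpl.simulate_cohort(cfg, sessions=(1, 3)))
        with pytest.raises(ValueError, match="missing"):
            session_order_checks(ds)


def test_benjamini_hochberg_monotone():
    p = np.array([0.001, 0.01, 0.04, 0.2, 0.9])
    adj = benjamini_hochberg(p)
    assert (np.diff(adj) >= 0).all() and (adj >= p).all()
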