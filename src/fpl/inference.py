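"""Inferential layer: t-tests, random-intercept regressions and factorial
mixed models.

All mixed models are random-intercept models fitted by restricted maximum
likelihood via statsmodels' ``MixedLM``. Wald tests on the fixed effects use
the residual-df convention (``df = n_obs - rank(X)``); exact replication of
any particular software package's denominator-df arithmetic is a non-goal.
Degenerate inputs (zero variance, singular fits) are reported through flags
on the result object, never as silent NaNs.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import AnovaRM
from statsmodels.tools.sm_exceptions import ConvergenceWarning


@dataclass(frozen=True)
class TTestResult:
    mean: float
    sem: float
    t: float
    df: int
    p: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.t, self.p))


def one_sample_t(values) -> TTestResult:
    """Two-tailed one-sample t-test against zero.

    With zero sample variance the statistic is degenerate: ``t=0, p=1`` for
    an all-zero sample, otherwise ``p=0`` with the ``degenerate`` flag set.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("one_sample_t requires a 1-d sample with n >= 2")
    if not np.isfinite(x).all():
        raise ValueError("one_sample_t requires finite values")
    n = len(x)
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / math.sqrt(n))
    if sem == 0.0:
        if mean == 0.0:
            return TTestResult(0.0, 0.0, 0.0, n - 1, 1.0, degenerate=True)
        return TTestResult(mean, 0.0, math.copysign(math.inf, mean), n - 1,
                           0.0, degenerate=True)
    t, p = sps.ttest_1samp(x, 0.0)
    return TTestResult(mean, sem, float(t), n - 1, float(p))


@dataclass
class MixedModelResult:
    """Fixed-effect estimates and term tests from one (mixed) model fit.

    ``effects`` has one row per fixed-effect coefficient (estimate, se,
    stat, df, p); ``term_tests`` one row per model term with a Wald F test.
    """

    formula: str
    effects: pd.DataFrame
    term_tests: pd.DataFrame
    random_intercept_var: float
    resid_var: float
    n_obs: int
    n_groups: int
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    @property
    def slope(self) -> float:
        # convenience for two-coefficient regression results
        fe = self.effects[self.effects.term != "Intercept"]
        return float(fe.estimate.iloc[0])

    @property
    def slope_p(self) -> float:
        fe = self.effects[self.effects.term != "Intercept"]
        return float(fe.p.iloc[0])

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "effects": self.effects.to_dict(orient="records"),
            "term_tests": self.term_tests.to_dict(orient="records"),
            "random_intercept_var": self.random_intercept_var,
            "resid_var": self.resid_var,
            "n_obs": self.n_obs, "n_groups": self.n_groups,
            "converged": self.converged, "flags": self.flags,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), default=float, **kw)


def _effects_frame(names, est, se, df_resid) -> pd.DataFrame:
    est = np.asarray(est, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / np.where(se > 0, se, 1.0), np.nan)
    p = 2.0 * sps.t.sf(np.abs(t), df_resid)
    return pd.DataFrame({"term": list(names), "estimate": est, "se": se,
                         "stat": t, "df": df_resid, "p": p})


def _term_tests(design_info, names, params, cov, df_resid) -> pd.DataFrame:
    """Wald F test for each model term (groups of coefficients)."""
    rows = []
    params = np.asarray(params, dtype=float)
    cov = np.asarray(cov, dtype=float)
    for term, slc in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        b = params[slc]
        V = cov[slc, slc]
        q = len(b)
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            rows.append({"term": term, "F": np.nan, "df_num": q,
                         "df_den": df_resid, "p": np.nan})
            continue
        F = stat / q
        rows.append({"term": term, "F": F, "df_num": q, "df_den": df_resid,
                     "p": float(sps.f.sf(F, q, df_resid))})
    return pd.DataFrame(rows, columns=["term", "F", "df_num", "df_den", "p"])


def _fit_mixedlm(formula: str, data: pd.DataFrame, group: str,
                 ) -> MixedModelResult:
    data = data.dropna(subset=[group]).reset_index(drop=True)
    model = smf.mixedlm(formula, data, groups=data[group])
    flags: list[str] = []
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(reml=True)
        except np.linalg.LinAlgError:
            # boundary fit with a singular Hessian (random-intercept
            # variance indistinguishable from zero): report the OLS fit
            # with a flag rather than raising
            ols_model = smf.ols(formula, data)
            ols = ols_model.fit()
            df_resid = int(ols.df_resid)
            effects = _effects_frame(ols_model.exog_names, ols.params,
                                     ols.bse, df_resid)
            terms = _term_tests(ols_model.data.design_info,
                                ols_model.exog_names, ols.params,
                                np.asarray(ols.cov_params()), df_resid)
            return MixedModelResult(formula, effects, terms, 0.0,
                                    float(ols.mse_resid), int(ols.nobs),
                                    int(data[group].nunique()), False,
                                    ["singular_fit_ols_fallback"])
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            flags.append(f"convergence: {w.message}")
        elif "singular" in str(w.message).lower() \
                or "boundary" in str(w.message).lower():
            flags.append(f"singular_fit: {w.message}")
    if not res.converged:
        converged = False
        flags.append("not_converged")
    k_fe = model.k_fe
    names = model.exog_names[:k_fe]
    df_resid = model.nobs - np.linalg.matrix_rank(model.exog)
    cov_fe = np.asarray(res.cov_params())[:k_fe, :k_fe]
    effects = _effects_frame(names, res.fe_params, res.bse_fe, df_resid)
    terms = _term_tests(model.data.design_info, names, res.fe_params, cov_fe,
                        df_resid)
    re_var = float(np.asarray(res.cov_re)[0, 0])
    if re_var <= 1e-10:
        flags.append("random_intercept_variance_zero")
    return MixedModelResult(formula, effects, terms, re_var,
                            float(res.scale), int(model.nobs),
                            int(data[group].nunique()), converged, flags)


def random_intercept_slope(data: pd.DataFrame, x: str, y: str,
                           group: str) -> MixedModelResult:
    """Fit ``y ~ 1 + x + (1 | group)`` by REML.

    With one observation per group the random intercept is unidentifiable
    and the model collapses to ordinary least squares (flagged
    ``reduced_to_ols``); the slope then equals the closed-form OLS estimate.

    The slope here is a participant-level predictor (its information scales
    with the number of participants, not observations), so p-values use
    group-level degrees of freedom, ``n_groups - 2``.
    """
    data = data[[x, y, group]].dropna().reset_index(drop=True)
    if data[group].nunique() < 2:
        raise ValueError("need at least two groups")
    formula = f"{y} ~ {x}"
    if data.groupby(group).size().max() == 1:
        model = smf.ols(formula, data)
        res = model.fit()
        df_resid = int(res.df_resid)
        effects = _effects_frame(model.exog_names, res.params, res.bse,
                                 df_resid)
        terms = _term_tests(model.data.design_info, model.exog_names,
                            res.params, np.asarray(res.cov_params()),
                            df_resid)
        return MixedModelResult(formula + f" + (1|{group})", effects, terms,
                                0.0, float(res.mse_resid), int(res.nobs),
                                int(data[group].nunique()), True,
                                ["reduced_to_ols"])
    out = _fit_mixedlm(formula, data, group)
    df_group = max(out.n_groups - 2, 1)
    est = out.effects.estimate.to_numpy()
    se = out.effects.se.to_numpy()
    out.effects = _effects_frame(out.effects.term, est, se, df_group)
    out.term_tests = out.term_tests.assign(
        df_den=df_group,
        p=[float(sps.f.sf(F, q, df_group)) for F, q in
           zip(out.term_tests.F, out.term_tests.df_num)])
    return out


def factorial_lme(data: pd.DataFrame, response: str, factors: list[str],
                  covariates: list[str] = (), group: str = "participant_id",
                  interactions: bool = True) -> MixedModelResult:
    """Factorial random-intercept model with Wald F tests per term.

    ``factors`` enter as categorical main effects (plus all interactions by
    default); ``covariates`` enter linearly.
    """
    if not factors:
        raise ValueError("need at least one factor")
    joiner = " * " if interactions else " + "
    rhs = joiner.join(f"C({f})" for f in factors)
    for cov in covariates:
        rhs += f" + {cov}"
    formula = f"{response} ~ {rhs}"
    return _fit_mixedlm(formula, data, group)


def dynamics_lme(window_means: pd.DataFrame, response: str = "pct",
                 factors: tuple[str, ...] = ("window", "phase", "direction"),
                 group: str = "participant_id") -> MixedModelResult:
    """Within-trial dynamics model: window x phase (x direction) factorial
    with a participant random intercept."""
    present = [f for f in factors if window_means[f].nunique() > 1]
    return factorial_lme(window_means, response, present, (), group)


def session_order_checks(dataset, sessions: tuple[int, ...] = (1, 3, 5),
                         ) -> dict:
    """Carry-over checks across the unpredictable sessions.

    1. Per-trial baseline F1 (mean of the first 50 ms from voice onset),
       per-participant per-session median, repeated-measures ANOVA on
       session.
    2. Peak percent compensation recomputed per session, then a
       random-intercept model with session, magnitude, direction and
       perturbation-type main effects.
    """
    from .compensation import compensation_table  # runtime import, no cycle

    have = sorted(set(dataset.schedule.session) & set(sessions))
    if len(have) < len(sessions):
        raise ValueError(f"missing unpredictable sessions: "
                         f"{sorted(set(sessions) - set(have))}")
    rows = []
    df = dataset.good_head_trials()
    df = df[df.session.isin(sessions)]
    for r in df.itertuples(index=False):
        tr = dataset.get_track(r.participant_id, r.session, r.trial_index)
        rows.append({"participant_id": r.participant_id, "session": r.session,
                     "baseline_f1": tr.window_mean(0.0, 50.0)})
    base = (pd.DataFrame(rows)
            .groupby(["participant_id", "session"], as_index=False)
            .median())
    anova = AnovaRM(base, depvar="baseline_f1", subject="participant_id",
                    within=["session"]).fit()
    arow = anova.anova_table.iloc[0]

    per_session = []
    for s in sessions:
        comp, _, _ = compensation_table(dataset, sessions=(s,))
        comp = comp.copy()
        comp["session"] = s
        per_session.append(comp)
    comp_all = pd.concat(per_session, ignore_index=True)
    comp_all["magnitude"] = comp_all.pert_hz.abs()
    comp_all["direction"] = np.where(comp_all.pert_hz > 0, "pos", "neg")
    lme = factorial_lme(comp_all, "peak_pct",
                        ["session", "magnitude", "direction", "pert_kind"],
                        covariates=(), group="participant_id",
                        interactions=False)
    return {
        "baseline_f1_anova": {"F": float(arow["F Value"]),
                              "df_num": float(arow["Num DF"]),
                              "df_den": float(arow["Den DF"]),
                              "p": float(arow["Pr > F"])},
        "baseline_medians": base,
        "per_session_compensation": comp_all,
        "per_session_lme": lme,
    }


def benjamini_hochberg(p_values) -> np.ndarray:
    """Optional multiple-testing adjustment (off everywhere by default)."""
    from statsmodels.stats.multitest import multipletests
    return multipletests(np.asarray(p_values), method="fdr_bh")[1]
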