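"""The seven registered analyses (RQ1-RQ7) and supporting machinery.

RQ1/RQ2 are descriptive (exposure-level distribution; TTS response table
with Sison-Glaz simultaneous CIs). RQ3-RQ7 are regression models:

* RQ3: ordinal (proportional-odds) logistic, TTSProp ~ DeviceVolumeAverage
* RQ4: logistic, TinLong ~ DeviceUse
* RQ5: logistic, TinLong ~ TTSGroup (two dummies against "none")
* RQ6: ear-wise tinnitus laterality, TinModelPresence ~ TinModelExposure +
  TinModelEar; with exactly one tinnitus-present ear per participant the two
  rows of a participant are perfectly negatively dependent, so the default
  estimator is a conditional (matched-pairs) logistic regression, which
  keeps Wald inference honest. ``method="pooled"`` fits the plain logistic
  on stacked ear rows (valid point estimates on the marginal scale, but
  anticonservative SEs; provided for comparison).
* RQ7: linear, DigitsDiff ~ DeviceUse + DeviceSide

Age (RQ3/RQ4/RQ5) and first-tested ear (RQ7) enter as covariates under an
explicit screening rule: the candidate is included iff it associates with
both the exposure and the outcome at p < .05 on the analysis sample. The
decision and both the adjusted and unadjusted fits are always recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.discrete.conditional_models import ConditionalLogit
from statsmodels.miscmodels.ordinal_model import OrderedModel

from . import derive
from .derive import TTS_LEVELS
from .multinomial import sison_glaz_ci

__all__ = [
    "Estimate",
    "FitResult",
    "covariate_rule",
    "rq1_describe",
    "rq2_describe",
    "rq3_ordinal",
    "rq4_logistic",
    "rq5_logistic",
    "rq6_earwise",
    "rq7_linear",
    "run_analysis",
]

Z95 = st.norm.ppf(0.975)


@dataclass(frozen=True)
class Estimate:
    term: str
    estimate: float
    ci_low: float
    ci_high: float
    statistic: float
    p: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(f"CI does not bracket the point estimate for {self.term}")


@dataclass
class FitResult:
    analysis_id: str
    n_used: int
    estimates: list[Estimate]
    scale: str  # "odds-ratio", "dB", "identity", "log-odds"
    covariate_included: bool | None = None
    covariate_log: dict = field(default_factory=dict)
    exclusion_log: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def term(self, name: str) -> Estimate:
        for e in self.estimates:
            if e.term == name:
                return e
        raise KeyError(name)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["estimates"] = [asdict(e) for e in self.estimates]
        return d


# ---------------------------------------------------------------------------
# covariate screening
# ---------------------------------------------------------------------------

def _assoc_p(df: pd.DataFrame, a: str, b: str) -> float:
    """p-value for association between two columns, choosing the test by type:
    numeric-numeric Pearson, numeric-categorical one-way ANOVA,
    categorical-categorical chi-square."""
    sub = df[[a, b]].dropna()
    if len(sub) < 3:
        return 1.0
    x, y = sub[a], sub[b]
    x_num = pd.api.types.is_numeric_dtype(x) and not pd.api.types.is_bool_dtype(x)
    y_num = pd.api.types.is_numeric_dtype(y) and not pd.api.types.is_bool_dtype(y)
    if x_num and y_num:
        return float(st.pearsonr(x, y).pvalue)
    if x_num != y_num:
        num, cat = (x, y) if x_num else (y, x)
        groups = [g.to_numpy() for _, g in num.groupby(cat.to_numpy()) if len(g) > 1]
        if len(groups) < 2:
            return 1.0
        return float(st.f_oneway(*groups).pvalue)
    tab = pd.crosstab(x, y)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return 1.0
    return float(st.chi2_contingency(tab).pvalue)


def covariate_rule(
    df: pd.DataFrame, candidate: str, exposure: str, outcome: str, alpha: float = 0.05
) -> tuple[bool, dict]:
    """Include ``candidate`` iff it associates with both the exposure and the
    outcome at p < alpha on the analysis sample. Decision is always logged."""
    p_exp = _assoc_p(df, candidate, exposure)
    p_out = _assoc_p(df, candidate, outcome)
    include = (p_exp < alpha) and (p_out < alpha)
    return include, {
        "candidate": candidate,
        "p_vs_exposure": p_exp,
        "p_vs_outcome": p_out,
        "included": include,
    }


# ---------------------------------------------------------------------------
# descriptive analyses
# ---------------------------------------------------------------------------

def rq1_describe(df: pd.DataFrame, action_value: float = 85.0) -> dict:
    """Distribution of the weekly-averaged exposure level among users.

    Expects derived rows for ear-piece users (positive exposure). Returns the
    median and percentiles of the weekly level, the fraction strictly
    exceeding the action value, and the companion medians (weekly exposure
    hours; energy-average level during exposure).
    """
    levels = df["weekly_level"].dropna()
    if levels.empty:
        return {"n": 0}
    weekly_hours = (df["exposure_hours"] / df["weeks_of_use"]).dropna()
    pct = {f"p{q}": float(np.percentile(levels, q)) for q in (10, 25, 50, 75, 90)}
    return {
        "n": int(levels.size),
        "median_weekly_level": float(levels.median()),
        **pct,
        "frac_above_action_value": float((levels > action_value).mean()),
        "median_weekly_exposure_hours": float(weekly_hours.median()),
        "median_level_during_exposure": float(
            df["avg_level_during_exposure"].dropna().median()
        ),
    }


def rq2_describe(df: pd.DataFrame, alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """TTS response-option table with Sison-Glaz simultaneous CIs, plus the
    headline summaries (ever / half-or-more / every shift)."""
    responses = df["tts_prop"].dropna()
    counts = np.array([(responses == lvl).sum() for lvl in TTS_LEVELS])
    ci = sison_glaz_ci(counts, alpha=alpha)
    table = pd.DataFrame(
        {
            "response": TTS_LEVELS,
            "count": counts,
            "proportion_pct": 100 * ci.proportions,
            "ci_low_pct": 100 * ci.lower,
            "ci_high_pct": 100 * ci.upper,
        }
    )
    n = counts.sum()
    p = counts / n
    summary = {
        "n": int(n),
        "pct_ever": float(100 * (1 - p[0])),
        "pct_half_or_more": float(100 * p[2:].sum()),
        "pct_every_time": float(100 * p[4]),
    }
    return table, summary


# ---------------------------------------------------------------------------
# regression helpers
# ---------------------------------------------------------------------------

def _wald_estimates(
    params: pd.Series, bse: pd.Series, terms: list[str], exponentiate: bool
) -> list[Estimate]:
    out = []
    for t in terms:
        b, se = float(params[t]), float(bse[t])
        z = b / se
        p = 2 * st.norm.sf(abs(z))
        lo, hi = b - Z95 * se, b + Z95 * se
        if exponentiate:
            with np.errstate(over="ignore"):  # separation: CI bound -> inf
                b, lo, hi = np.exp(b), np.exp(lo), np.exp(hi)
        out.append(Estimate(t, float(b), float(lo), float(hi), float(z), float(p)))
    return out


def _fit_logit(y: pd.Series, X: pd.DataFrame) -> sm.Logit:
    model = sm.Logit(y.astype(float), X.astype(float))
    return model.fit(disp=0, maxiter=100)


def _separation_flag(y: pd.Series, x: pd.Series) -> bool:
    tab = pd.crosstab(y, x)
    return bool((tab == 0).any().any())


# ---------------------------------------------------------------------------
# RQ3: ordinal logistic
# ---------------------------------------------------------------------------

def rq3_ordinal(sample: pd.DataFrame, include_age: bool | None = None) -> FitResult:
    """Proportional-odds fit of TTSProp on the average volume-control setting.

    Positive slope means higher settings shift responses toward more frequent
    TTS. ``include_age=None`` applies the covariate screening rule.
    """
    df = sample.dropna(subset=["tts_prop", "volume_average"]).copy()
    if df["volume_average"].nunique() < 2:
        raise ValueError("volume_average is constant: ordinal slope inestimable")
    cov_log: dict = {}
    if include_age is None:
        include_age, cov_log = covariate_rule(df, "age", "volume_average", "tts_prop")
    cat = pd.Categorical(
        df["tts_prop"], categories=TTS_LEVELS, ordered=True
    ).remove_unused_categories()  # cutpoints only for observed levels
    endog = pd.Series(cat, index=df.index)
    sparse = bool((endog.value_counts() < 5).any())
    cols = ["volume_average"] + (["age"] if include_age else [])
    exog = df[cols].astype(float)
    model = OrderedModel(endog, exog, distr="logit")
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with _warnings.catch_warnings():
        # near-flat likelihoods at the strict tolerance trip the optimizer
        # warning; convergence status is recorded on the result instead
        _warnings.simplefilter("ignore", ConvergenceWarning)
        res = model.fit(method="bfgs", disp=0, maxiter=500, gtol=1e-8)
    ests = _wald_estimates(res.params, res.bse, cols, exponentiate=False)
    return FitResult(
        analysis_id="RQ3",
        n_used=len(df),
        estimates=ests,
        scale="log-odds per % volume",
        covariate_included=include_age,
        covariate_log=cov_log,
        extra={
            "sparse_levels": sparse,
            "cutpoints": {
                k: float(v) for k, v in res.params.items() if k not in cols
            },
            "converged": bool(res.mle_retvals.get("converged", True)),
        },
    )


# ---------------------------------------------------------------------------
# RQ4 / RQ5: logistic regressions
# ---------------------------------------------------------------------------

def rq4_logistic(sample: pd.DataFrame, include_age: bool | None = None) -> FitResult:
    """Odds of prolonged spontaneous tinnitus in users vs nonusers."""
    df = sample.dropna(subset=["tin_long"]).copy()
    df["user"] = (df["device_use"] != "nonuser").astype(float)
    cov_log: dict = {}
    if include_age is None:
        include_age, cov_log = covariate_rule(df, "age", "user", "tin_long")
    y = df["tin_long"].astype(float)
    X_un = sm.add_constant(df[["user"]])
    res_un = _fit_logit(y, X_un)
    cols = ["user"] + (["age"] if include_age else [])
    X = sm.add_constant(df[cols])
    res = _fit_logit(y, X)
    return FitResult(
        analysis_id="RQ4",
        n_used=len(df),
        estimates=_wald_estimates(res.params, res.bse, cols, exponentiate=True),
        scale="odds-ratio",
        covariate_included=include_age,
        covariate_log=cov_log,
        extra={
            "separation": _separation_flag(y, df["user"]),
            "unadjusted": [
                asdict(e)
                for e in _wald_estimates(res_un.params, res_un.bse, ["user"], True)
            ],
        },
    )


def rq5_logistic(sample: pd.DataFrame, include_age: bool | None = None) -> FitResult:
    """Odds of tinnitus by TTS burden (1-100 and >100 instances vs none)."""
    df = sample.dropna(subset=["tin_long", "tts_group"]).copy()
    df["tts_1_100"] = (df["tts_group"] == "1-100").astype(float)
    df["tts_gt100"] = (df["tts_group"] == ">100").astype(float)
    cov_log: dict = {}
    if include_age is None:
        include_age, cov_log = covariate_rule(df, "age", "tts_group", "tin_long")
    y = df["tin_long"].astype(float)
    dummies = ["tts_1_100", "tts_gt100"]
    res_un = _fit_logit(y, sm.add_constant(df[dummies]))
    cols = dummies + (["age"] if include_age else [])
    res = _fit_logit(y, sm.add_constant(df[cols]))
    return FitResult(
        analysis_id="RQ5",
        n_used=len(df),
        estimates=_wald_estimates(res.params, res.bse, cols, exponentiate=True),
        scale="odds-ratio",
        covariate_included=include_age,
        covariate_log=cov_log,
        extra={
            "separation": _separation_flag(y, df["tts_group"]),
            "unadjusted": [
                asdict(e)
                for e in _wald_estimates(res_un.params, res_un.bse, dummies, True)
            ],
        },
    )


# ---------------------------------------------------------------------------
# RQ6: ear-wise tinnitus laterality
# ---------------------------------------------------------------------------

def rq6_earwise(ear_records: pd.DataFrame, method: str = "conditional") -> FitResult:
    """Association between tinnitus side and exposure side across ear pairs.

    ``conditional`` (default): matched-pairs conditional logistic; its
    exposure coefficient is logit of the within-pair concordance probability.
    ``pooled``: ordinary logistic on the stacked ear rows (the literal
    two-rows-per-participant formulation; SEs ignore the pairing).
    """
    df = ear_records.copy()
    df["exposed"] = df["exposed"].astype(float)
    df["ear_right"] = (df["ear"] == "right").astype(float)
    y = df["tin_present"].astype(float)
    n_part = df["participant_id"].nunique()
    separation = _separation_flag(y, df["exposed"]) or _separation_flag(
        y, df["ear_right"]
    )
    terms = ["exposed", "ear_right"]
    converged = True
    if method == "conditional":
        model = ConditionalLogit(
            y.to_numpy(), df[terms].to_numpy(), groups=df["participant_id"].to_numpy()
        )
        import warnings as _warnings

        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConvergenceWarning)
            res = model.fit(disp=0, maxiter=300)
        converged = bool(getattr(res, "mle_retvals", {}).get("converged", True))
        params = pd.Series(res.params, index=terms)
        bse = pd.Series(res.bse, index=terms)
    elif method == "pooled":
        res = _fit_logit(y, sm.add_constant(df[terms]))
        params, bse = res.params, res.bse
    else:
        raise ValueError("method must be 'conditional' or 'pooled'")
    return FitResult(
        analysis_id="RQ6",
        n_used=int(n_part),
        estimates=_wald_estimates(params, bse, terms, exponentiate=True),
        scale="odds-ratio",
        extra={
            "method": method,
            "n_ears": len(df),
            "separation": separation,
            "converged": converged,
        },
    )


# ---------------------------------------------------------------------------
# RQ7: linear model on the between-ear DIN difference
# ---------------------------------------------------------------------------

def rq7_linear(sample: pd.DataFrame, include_order: bool | None = None) -> FitResult:
    """Exposed-ear DIN deficit vs ear-piece use, controlling for side.

    Requires derived rows that passed DIN quality control, with imputed sides
    for nonusers. The first-tested-ear covariate enters per the screening
    rule when an ``ear_tested_first`` column is available.
    """
    nonuser = sample["device_use"] == "nonuser"
    if nonuser.any() and not sample.loc[nonuser, "device_side_full"].isin(
        ["right", "left"]
    ).all():
        raise derive.ContractViolation("nonusers present without imputed device side")
    df = sample.dropna(subset=["digits_diff"]).copy()
    df["user"] = (df["device_use"] != "nonuser").astype(float)
    df["side_right"] = (df["device_side_full"] == "right").astype(float)
    cov_log: dict = {"candidate": "ear_tested_first", "available": False}
    has_order = "ear_tested_first" in df.columns and df["ear_tested_first"].notna().any()
    if include_order is None:
        if has_order:
            include_order, cov_log = covariate_rule(
                df, "ear_tested_first", "user", "digits_diff"
            )
            cov_log["available"] = True
        else:
            include_order = False
    y = df["digits_diff"].astype(float)
    cols = ["user", "side_right"]
    if include_order and has_order:
        df["first_right"] = (df["ear_tested_first"] == "right").astype(float)
        cols.append("first_right")
    res = sm.OLS(y, sm.add_constant(df[cols].astype(float))).fit()
    ests = []
    for t in cols:
        b, se = float(res.params[t]), float(res.bse[t])
        tstat = b / se
        p = 2 * st.t.sf(abs(tstat), res.df_resid)
        half = st.t.ppf(0.975, res.df_resid) * se
        ests.append(Estimate(t, b, b - half, b + half, float(tstat), float(p)))
    users = df[df["user"] == 1]["digits_diff"]
    mean_ci = st.t.interval(0.95, len(users) - 1, loc=users.mean(), scale=st.sem(users))
    return FitResult(
        analysis_id="RQ7",
        n_used=len(df),
        estimates=ests,
        scale="dB SNR",
        covariate_included=include_order,
        covariate_log=cov_log,
        extra={
            "mean_digits_diff_users": float(users.mean()),
            "mean_digits_diff_users_ci": [float(mean_ci[0]), float(mean_ci[1])],
        },
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_analysis(derived: pd.DataFrame, analysis: str, **kwargs) -> FitResult | dict:
    """Filter the derived cohort per the registered rules and run one analysis."""
    if analysis == "RQ1":
        sample, log = derive.analysis_sample(derived, "RQ3")  # users only
        out = rq1_describe(sample, **kwargs)
        out["exclusion_log"] = log
        return out
    if analysis == "RQ2":
        sample, log = derive.analysis_sample(derived, "RQ3")
        table, summary = rq2_describe(sample, **kwargs)
        summary["exclusion_log"] = log
        return {"table": table, "summary": summary}
    if analysis == "RQ3":
        sample, log = derive.analysis_sample(derived, "RQ3")
        fr = rq3_ordinal(sample, **kwargs)
    elif analysis == "RQ4":
        sample, log = derive.analysis_sample(derived, "RQ4")
        fr = rq4_logistic(sample, **kwargs)
    elif analysis == "RQ5":
        sample, log = derive.analysis_sample(derived, "RQ5")
        fr = rq5_logistic(sample, **kwargs)
    elif analysis == "RQ6":
        sample, log = derive.analysis_sample(derived, "RQ6")
        ears = derive.earwise_reshape(sample)
        fr = rq6_earwise(ears, **kwargs)
    elif analysis == "RQ7":
        sample, log = derive.analysis_sample(derived, "RQ7")
        kept, excluded, _ = derive.din_outlier_filter(sample)
        log["excluded_din_qc"] = len(excluded)
        log["excluded_din_incomplete"] = len(sample) - len(kept) - len(excluded)
        fr = rq7_linear(kept, **kwargs)
    else:
        raise ValueError(f"unknown analysis {analysis!r}")
    fr.exclusion_log = log
    return fr
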