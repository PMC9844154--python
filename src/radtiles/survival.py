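"""Outcome statistics on predicted-TILes groups.

Kaplan-Meier curves with log-log (exponential Greenwood) confidence
intervals, the two-group log-rank test, Cox proportional-hazards regression
(univariate, and multivariate restricted to covariates with univariate
p < 0.05), and the rank/count statistics used alongside them (Spearman,
Wilcoxon rank-sum, Fisher's exact with odds ratio).

Kaplan-Meier and Cox estimation delegate to lifelines (Efron tie handling);
a compact Newton solver provides the Breslow tie option and the
partial-likelihood score test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cond_odds_ratio

__all__ = [
    "KMGroupFit",
    "SurvivalFit",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "rank_and_count_stats",
    "response_comparison",
]


@dataclass
class KMGroupFit:
    """Product-limit estimate of one group."""

    group: str
    n: int
    n_events: int
    survival: pd.DataFrame  # index: time; columns: estimate, ci_lower, ci_upper
    median: float  # NaN when not reached
    median_ci: tuple[float, float]

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)


@dataclass
class SurvivalFit:
    """Per-group KM curves plus test results and Cox tables."""

    groups: dict[str, KMGroupFit] = field(default_factory=dict)
    logrank_statistic: float | None = None
    logrank_p: float | None = None
    cox_table: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = []
        for g, fit in self.groups.items():
            med = f"{fit.median:.1f}" if fit.median_reached else "not reached"
            lo, hi = fit.median_ci
            ci = f" [95% CI {lo:.1f}-{hi:.1f}]" if np.isfinite(lo) or np.isfinite(hi) else ""
            lines.append(f"{g}: n={fit.n}, events={fit.n_events}, median {med}{ci} months")
        if self.logrank_p is not None:
            lines.append(
                f"log-rank chi2 = {self.logrank_statistic:.3f}, p = {self.logrank_p:.4g}"
            )
        if self.cox_table is not None:
            lines.append(self.cox_table.to_string())
        return "\n".join(lines)


def km_estimate(
    df: pd.DataFrame,
    time_col: str = "time_months",
    event_col: str = "event",
    group_by: str | None = None,
) -> SurvivalFit:
    """Kaplan-Meier estimates per group, with medians and log-log CIs.

    The median is the earliest time with S(t) <= 0.5 and is NaN ("not
    reached") when the curve never crosses 0.5.  Empty groups are omitted.
    """
    # all-censored input is legal: S identically 1, medians not reached
    fit = SurvivalFit()
    groups = [("all", df)] if group_by is None else list(df.groupby(group_by, sort=True))
    for gname, gdf in groups:
        if len(gdf) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(gdf[time_col], gdf[event_col], label=str(gname))
        surv = kmf.survival_function_.copy()
        surv.columns = ["estimate"]
        ci = kmf.confidence_interval_
        surv["ci_lower"] = ci.iloc[:, 0].to_numpy()
        surv["ci_upper"] = ci.iloc[:, 1].to_numpy()
        med = float(kmf.median_survival_time_)
        med_ci_df = median_survival_times(kmf.confidence_interval_)
        lo, hi = (float(med_ci_df.iloc[0, 0]), float(med_ci_df.iloc[0, 1]))
        fit.groups[str(gname)] = KMGroupFit(
            group=str(gname),
            n=len(gdf),
            n_events=int(gdf[event_col].sum()),
            survival=surv,
            median=med if np.isfinite(med) else np.nan,
            median_ci=(lo, hi),
        )
    return fit


def logrank_test(
    df: pd.DataFrame,
    group_by: str,
    time_col: str = "time_months",
    event_col: str = "event",
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its p-value."""
    levels = sorted(df[group_by].unique())
    if len(levels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {levels}")
    a = df[df[group_by] == levels[0]]
    b = df[df[group_by] == levels[1]]
    res = _ll_logrank(
        a[time_col], b[time_col], event_observed_A=a[event_col], event_observed_B=b[event_col]
    )
    return float(res.test_statistic), float(res.p_value)


def _prepare_design(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """One-hot non-numeric covariates (first sorted level = reference)."""
    out = {}
    for c in covariates:
        col = df[c]
        if pd.api.types.is_numeric_dtype(col):
            out[c] = col.astype(float)
        else:
            levels = sorted(col.astype(str).unique())
            for lv in levels[1:]:
                out[f"{c}[{lv}]"] = (col.astype(str) == lv).astype(float)
    return pd.DataFrame(out, index=df.index)


def cox_fit(
    df: pd.DataFrame,
    covariates: list[str],
    mode: str = "univariate",
    time_col: str = "time_months",
    event_col: str = "event",
    ties: str = "efron",
    entry_p: float = 0.05,
) -> SurvivalFit:
    """Cox proportional-hazards regression.

    ``mode="univariate"`` fits each covariate alone; ``mode="multivariate"``
    first runs all univariate fits and then fits jointly only the covariates
    with some univariate coefficient at p < ``entry_p`` (strict).  Ties are
    handled by Efron's method (lifelines); ``ties="breslow"`` switches to the
    in-package Newton solver.  Perfect separation / non-convergence is
    flagged with infinite CI bounds rather than raised.
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    design = _prepare_design(df, covariates)
    base = pd.concat([df[[time_col, event_col]], design], axis=1)
    if int(df[event_col].sum()) < design.shape[1]:
        raise ValueError("fewer events than coefficients to fit")

    def _fit(cols: list[str]) -> pd.DataFrame:
        data = base[[time_col, event_col] + cols].copy()
        if ties == "breslow":
            return _cox_newton_table(data, cols, time_col, event_col)
        cph = CoxPHFitter()
        try:
            cph.fit(data, duration_col=time_col, event_col=event_col)
        except Exception:
            return pd.DataFrame(
                {
                    "coef": np.nan,
                    "HR": np.nan,
                    "HR_ci_lower": 0.0,
                    "HR_ci_upper": np.inf,
                    "p": np.nan,
                    "flag": "non-convergence or separation",
                },
                index=cols,
            )
        s = cph.summary
        out = pd.DataFrame(
            {
                "coef": s["coef"],
                "HR": s["exp(coef)"],
                "HR_ci_lower": s["exp(coef) lower 95%"],
                "HR_ci_upper": s["exp(coef) upper 95%"],
                "p": s["p"],
                "flag": "",
            }
        )
        big = ~np.isfinite(out["coef"]) | (np.abs(out["coef"]) > 50)
        out.loc[big, "flag"] = "monotone likelihood"
        return out

    uni_parts = []
    for col in design.columns:
        part = _fit([col])
        part["covariate"] = col
        part["mode"] = "univariate"
        uni_parts.append(part)
    uni = pd.concat(uni_parts)

    result = SurvivalFit()
    if mode == "univariate":
        result.cox_table = uni
        return result

    entered = [c for c in design.columns if float(uni.loc[c, "p"]) < entry_p]
    tables = [uni]
    if entered:
        multi = _fit(entered)
        multi["covariate"] = entered
        multi["mode"] = "multivariate"
        tables.append(multi)
    result.cox_table = pd.concat(tables)
    result.cox_table.attrs["entered_multivariate"] = entered
    return result


# ---------------------------------------------------------------------------
# compact Newton partial-likelihood solver (Breslow ties, score test)


def _cox_loglik(beta, times, events, X, ties="breslow"):
    """Partial log-likelihood with gradient and Hessian."""
    order = np.argsort(-times, kind="stable")  # decreasing time
    times, events, X = times[order], events[order], X[order]
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    # cumulative risk-set sums built while walking down in time
    S0, S1, S2 = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        for k in range(i, j):  # all subjects at this time enter the risk set
            S0 += w[k]
            S1 += w[k] * X[k]
            S2 += w[k] * np.outer(X[k], X[k])
        dead = [k for k in range(i, j) if events[k] == 1]
        d = len(dead)
        if d:
            xsum = X[dead].sum(axis=0)
            ll += float(eta[dead].sum())
            if ties == "breslow":
                for _ in range(d):
                    ll -= np.log(S0)
                    grad_term = S1 / S0
                    hess_term = S2 / S0 - np.outer(grad_term, grad_term)
                    grad -= grad_term
                    hess -= hess_term
            else:  # efron
                D0 = sum(w[k] for k in dead)
                D1 = sum(w[k] * X[k] for k in dead)
                D2 = sum(w[k] * np.outer(X[k], X[k]) for k in dead)
                for l in range(d):
                    f = l / d
                    s0 = S0 - f * D0
                    s1 = S1 - f * D1
                    s2 = S2 - f * D2
                    ll -= np.log(s0)
                    grad_term = s1 / s0
                    grad -= grad_term
                    hess -= s2 / s0 - np.outer(grad_term, grad_term)
            grad += xsum
        i = j
    return ll, grad, hess


def _cox_newton_table(data, cols, time_col, event_col, ties="breslow"):
    times = data[time_col].to_numpy(dtype=np.float64)
    events = data[event_col].to_numpy(dtype=np.int64)
    X = data[cols].to_numpy(dtype=np.float64)
    beta = np.zeros(X.shape[1])
    flag = ""
    for _ in range(50):
        _, grad, hess = _cox_loglik(beta, times, events, X, ties=ties)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            flag = "singular information matrix"
            break
        beta = beta - step
        if np.abs(step).max() < 1e-10:
            break
        if np.abs(beta).max() > 50:
            flag = "monotone likelihood"
            break
    _, _, hess = _cox_loglik(beta, times, events, X, ties=ties)
    with np.errstate(all="ignore"):
        se = np.sqrt(np.diag(np.linalg.inv(-hess)))
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "coef": beta,
            "HR": np.exp(beta),
            "HR_ci_lower": np.exp(beta - 1.96 * se),
            "HR_ci_upper": np.exp(beta + 1.96 * se),
            "p": p,
            "flag": flag,
        },
        index=cols,
    )


def cox_score_test(
    df: pd.DataFrame,
    covariate: str,
    time_col: str = "time_months",
    event_col: str = "event",
) -> float:
    """Partial-likelihood score statistic at beta = 0 (chi-square, 1 df).

    With one binary covariate and no tied event times this equals the
    log-rank statistic exactly.
    """
    times = df[time_col].to_numpy(dtype=np.float64)
    events = df[event_col].to_numpy(dtype=np.int64)
    X = df[[covariate]].to_numpy(dtype=np.float64)
    _, grad, hess = _cox_loglik(np.zeros(1), times, events, X)
    return float(grad[0] ** 2 / -hess[0, 0])


# ---------------------------------------------------------------------------
# rank and count statistics


def rank_and_count_stats(
    x=None, y=None, table=None
) -> dict:
    """Spearman correlation, Wilcoxon rank-sum, and/or Fisher's exact test.

    Pass paired continuous vectors ``x, y`` for Spearman + Wilcoxon (x and y
    as the two groups), and/or a 2x2 integer ``table`` for Fisher's exact
    test with both the conditional-MLE odds ratio (consistent with the exact
    test) and the sample odds ratio (infinite on zero cells, flagged).
    """
    out: dict = {}
    if x is not None and y is not None:
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if len(x) == len(y):
            if np.std(x) == 0 or np.std(y) == 0:
                out["spearman_rho"] = np.nan
                out["spearman_p"] = np.nan
                out["spearman_flag"] = "constant input: rho undefined"
            else:
                rho = stats.spearmanr(x, y)
                out["spearman_rho"] = float(rho.statistic)
                out["spearman_p"] = float(rho.pvalue)
        mw = stats.mannwhitneyu(x, y, alternative="two-sided")
        out["wilcoxon_p"] = float(mw.pvalue)
        out["wilcoxon_statistic"] = float(mw.statistic)
    if table is not None:
        t = np.asarray(table)
        if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
            raise ValueError("Fisher test needs a 2x2 table of non-negative integers")
        _, p = stats.fisher_exact(t, alternative="two-sided")
        out["fisher_p"] = float(p)
        out["odds_ratio_cmle"] = float(_cond_odds_ratio(t, kind="conditional").statistic)
        a, b, c, d = t.ravel()
        if b * c == 0:
            out["odds_ratio_sample"] = np.inf if a * d > 0 else np.nan
            out["odds_ratio_flag"] = "zero cell: sample OR infinite/undefined"
        else:
            out["odds_ratio_sample"] = float(a * d / (b * c))
    return out


def response_comparison(
    scores: pd.Series, best_response: pd.Series
) -> dict[str, float | None]:
    """Wilcoxon rank-sum of predicted TILes by best ICI response.

    Two stated comparisons: responder vs progressive and stable vs
    progressive.  A comparison with an empty (or singleton) category is
    reported as None.
    """
    out: dict[str, float | None] = {}
    groups = {
        g: scores[best_response == g].to_numpy()
        for g in ("responder", "stable", "progressive")
    }
    for name, a in (("responder_vs_progressive", groups["responder"]),
                    ("stable_vs_progressive", groups["stable"])):
        b = groups["progressive"]
        if len(a) < 2 or len(b) < 2:
            out[name] = None
            continue
        out[name] = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return out
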