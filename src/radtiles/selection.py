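"""Feature selection and the predicted-TILes linear model.

The selection procedure runs four stages on a cohort feature matrix with a
TILes response:

1. median split + Student's t filter — each feature splits the cohort at its
   median (samples at the median go to the high group); features whose high
   and low groups differ in TILes at p < 0.005 (pooled-variance two-sample t
   test) survive;
2. alias removal — columns linearly dependent on earlier columns (including
   the constant) are dropped, keep-first by column position;
3. VIF filter — iteratively remove the worst feature while any variance
   inflation factor exceeds 10 (strictly);
4. LASSO — the L1-penalized Gaussian objective

       min (1/2N) sum_i (y_i - b0 - x_i' b)^2
           + lambda [ (1-alpha) ||b||_2^2 / 2 + alpha ||b||_1 ]

   solved by cyclic coordinate descent along a warm-started lambda path, with
   lambda chosen by seeded K-fold cross-validation; non-zero coefficients are
   the selected features.

`TilesLasso` wraps the whole procedure as a model object whose ``fit()``
returns a `TilesLassoResults` carrying the coefficients, the per-feature
filter report, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LassoModel",
    "TilesLasso",
    "TilesLassoResults",
    "median_split",
    "ttest_filter",
    "drop_aliased",
    "vif_filter",
    "lasso_path_fit",
    "lasso_fit",
    "run_selection_pipeline",
    "predict_tiles",
    "published_model",
]

STAGES = ("t_filter", "alias", "vif", "lasso_zero", "kept")


# ---------------------------------------------------------------------------
# stage 1: median split and t filter


def median_split(values: Sequence[float]) -> np.ndarray:
    """High/low labels by the median; samples at the median go high.

    Returns a boolean array (True = high).  An all-equal input is entirely
    high (degenerate; callers treat it as an unusable split).
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("median_split needs at least 2 values")
    return v >= np.median(v)


def ttest_filter(
    X: pd.DataFrame,
    y: np.ndarray,
    alpha: float = 0.005,
    welch: bool = False,
) -> pd.DataFrame:
    """Student's t filter of every feature against the TILes response.

    For each feature the cohort is median-split on that feature and the
    response compared between the two groups with a two-sample t test
    (pooled variance by default; ``welch=True`` drops the equal-variance
    assumption).  Features are retained when p < alpha strictly.

    Returns a per-feature DataFrame with columns ``t_stat``, ``p_value``,
    ``retained``, ``note``.
    """
    y = np.asarray(y, dtype=np.float64)
    rows = []
    for name in X.columns:
        high = median_split(X[name].to_numpy())
        n_hi, n_lo = int(high.sum()), int((~high).sum())
        if n_hi < 2 or n_lo < 2:
            rows.append((name, np.nan, np.nan, False, "degenerate split"))
            continue
        t, p = stats.ttest_ind(y[~high], y[high], equal_var=not welch)
        rows.append((name, float(t), float(p), bool(p < alpha), ""))
    return pd.DataFrame(
        rows, columns=["feature", "t_stat", "p_value", "retained", "note"]
    ).set_index("feature")


# ---------------------------------------------------------------------------
# stage 2: alias removal


def drop_aliased(X: pd.DataFrame, rtol: float = 1e-8) -> tuple[pd.DataFrame, list[str]]:
    """Remove columns linearly dependent on earlier columns.

    Dependence is detected with a rank-revealing pass: a column whose
    residual after projection onto the span of the constant and all earlier
    kept columns is below ``rtol`` (relative to its norm) is aliased.
    Keep-first order by column position.  Returns (reduced matrix, dropped
    names).
    """
    n = len(X)
    basis = [np.full(n, 1.0 / np.sqrt(n))]  # constant column first
    kept, dropped = [], []
    for name in X.columns:
        col = X[name].to_numpy(dtype=np.float64)
        norm = np.linalg.norm(col)
        resid = col.copy()
        for q in basis:
            resid -= (q @ resid) * q
        if norm == 0 or np.linalg.norm(resid) <= rtol * max(norm, 1.0):
            dropped.append(name)
        else:
            kept.append(name)
            basis.append(resid / np.linalg.norm(resid))
    return X[kept], dropped


# ---------------------------------------------------------------------------
# stage 3: VIF filter


def _vif_values(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 - R^2_j) regressing column j on the others + constant."""
    n, p = X.shape
    vifs = np.empty(p)
    for j in range(p):
        target = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(A, target, rcond=None)
        resid = target - A @ beta
        ss_tot = ((target - target.mean()) ** 2).sum()
        if ss_tot == 0:
            vifs[j] = np.inf
            continue
        r2 = 1.0 - (resid**2).sum() / ss_tot
        vifs[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return vifs


def vif_filter(
    X: pd.DataFrame, cutoff: float = 10.0, simultaneous: bool = False
) -> tuple[pd.DataFrame, list[str]]:
    """Remove multicollinear features by variance inflation factor.

    Default is iterative worst-first removal while max VIF > cutoff
    (strictly; a VIF of exactly 10 is kept).  ``simultaneous=True`` instead
    removes every feature above the cutoff in one pass.  Fewer than two
    features is a no-op.
    """
    work = X.copy()
    dropped: list[str] = []
    if work.shape[1] < 2:
        return work, dropped
    if simultaneous:
        vifs = _vif_values(work.to_numpy())
        bad = [c for c, v in zip(work.columns, vifs) if v > cutoff]
        return work.drop(columns=bad), bad
    while work.shape[1] >= 2:
        vifs = _vif_values(work.to_numpy())
        worst = int(np.argmax(vifs))
        if not vifs[worst] > cutoff:
            break
        dropped.append(work.columns[worst])
        work = work.drop(columns=work.columns[worst])
    return work, dropped


# ---------------------------------------------------------------------------
# stage 4: LASSO by cyclic coordinate descent


@dataclass
class LassoModel:
    """A fitted L1/L2-penalized linear model on named features.

    Coefficients are stored on the original feature scale.  ``intercept``
    may be unknown (``intercept_known=False``) for models whose published
    form omits it; every shipped downstream use (median grouping, rank
    correlation, proportional-hazards regression on the score) is invariant
    to an additive constant.
    """

    coefficients: dict[str, float]
    intercept: float | None
    intercept_known: bool
    lambda_: float
    alpha: float = 1.0
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def selected_features(self) -> list[str]:
        return [k for k, v in self.coefficients.items() if v != 0.0]

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Linear score; lacks the additive constant when intercept unknown."""
        missing = [f for f in self.coefficients if f not in X.columns]
        if missing:
            raise KeyError(f"feature matrix lacks model features: {missing}")
        score = np.zeros(len(X))
        for name, beta in self.coefficients.items():
            score = score + beta * X[name].to_numpy(dtype=np.float64)
        if self.intercept_known and self.intercept is not None:
            score = score + self.intercept
        return pd.Series(score, index=X.index, name="predicted_tiles")

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "predicted-TILes linear model",
                "version": 1,
                "coefficients": self.coefficients,
                "intercept": self.intercept,
                "intercept_known": self.intercept_known,
                "lambda": self.lambda_,
                "alpha": self.alpha,
                "standardization": self.standardization,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LassoModel":
        d = json.loads(text)
        return cls(
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            intercept=d.get("intercept"),
            intercept_known=bool(d.get("intercept_known", d.get("intercept") is not None)),
            lambda_=float(d["lambda"]) if d.get("lambda") is not None else 0.0,
            alpha=float(d.get("alpha", 1.0)),
            standardization={k: tuple(v) for k, v in d.get("standardization", {}).items()},
        )


def _coordinate_descent(
    Xs: np.ndarray,
    yc: np.ndarray,
    lam: float,
    alpha: float,
    beta0: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Cyclic coordinate descent on standardized X (unit 1/N-variance) and
    centered y.  Returns the coefficient vector."""
    n, p = Xs.shape
    beta = beta0.copy()
    r = yc - Xs @ beta
    denom = 1.0 + lam * (1.0 - alpha)
    thr = lam * alpha
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            bj = beta[j]
            rho = (Xs[:, j] @ r) / n + bj  # since (1/n) x_j'x_j = 1
            bnew = np.sign(rho) * max(abs(rho) - thr, 0.0) / denom
            if bnew != bj:
                r += Xs[:, j] * (bj - bnew)
                beta[j] = bnew
                max_delta = max(max_delta, abs(bnew - bj))
        if max_delta < tol:
            return beta
    raise RuntimeError(
        f"coordinate descent did not converge in {max_iter} sweeps "
        f"(objective {_objective(Xs, yc, beta, lam, alpha):.6g})"
    )


def _objective(Xs, yc, beta, lam, alpha) -> float:
    n = len(yc)
    r = yc - Xs @ beta
    return float(
        (r @ r) / (2 * n)
        + lam * ((1 - alpha) * (beta @ beta) / 2 + alpha * np.abs(beta).sum())
    )


def kkt_residual(Xs: np.ndarray, yc: np.ndarray, beta: np.ndarray, lam: float, alpha: float) -> float:
    """Max violation of the stationarity (subgradient) conditions."""
    n = Xs.shape[0]
    grad = Xs.T @ (yc - Xs @ beta) / n - lam * (1 - alpha) * beta
    viol = np.where(
        beta != 0,
        np.abs(grad - lam * alpha * np.sign(beta)),
        np.maximum(np.abs(grad) - lam * alpha, 0.0),
    )
    return float(viol.max()) if viol.size else 0.0


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # 1/N variance, glmnet convention
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def lasso_path_fit(
    X: pd.DataFrame,
    y: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    alpha: float = 1.0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Solve the penalized objective along a decreasing lambda path.

    Returns (lambda grid, coefficient matrix on the standardized scale with
    one row per lambda, standardization info).
    """
    Xv = X.to_numpy(dtype=np.float64)
    yv = np.asarray(y, dtype=np.float64)
    Xs, mu, sd = _standardize(Xv)
    yc = yv - yv.mean()
    n = len(yv)
    if lambda_grid is None:
        lam_max = np.abs(Xs.T @ yc).max() / (n * max(alpha, 1e-3))
        lambda_grid = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    lambda_grid = np.asarray(lambda_grid, dtype=np.float64)
    betas = np.zeros((len(lambda_grid), Xs.shape[1]))
    beta = np.zeros(Xs.shape[1])
    for k, lam in enumerate(lambda_grid):
        beta = _coordinate_descent(Xs, yc, float(lam), alpha, beta)
        betas[k] = beta
    info = {"mu": mu, "sd": sd, "y_mean": float(yv.mean())}
    return lambda_grid, betas, info


def lasso_fit(
    X: pd.DataFrame,
    y: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    alpha: float = 1.0,
    cv_folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "min",
) -> LassoModel:
    """Fit the LASSO with lambda chosen by seeded K-fold cross-validation.

    ``lambda_rule`` is "min" (lambda minimizing mean CV squared error) or
    "1se" (largest lambda within one standard error of the minimum).
    Coefficients are reported on the original feature scale; the fit is
    verified against the stationarity conditions to 1e-6.
    """
    yv = np.asarray(y, dtype=np.float64)
    n = len(yv)
    if cv_folds < 2 or n < cv_folds:
        raise ValueError("need N >= cv_folds >= 2")
    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")

    lambda_grid, _, _ = lasso_path_fit(X, yv, lambda_grid, alpha)

    rng = np.random.default_rng(seed)
    fold_of = np.repeat(np.arange(cv_folds), int(np.ceil(n / cv_folds)))[:n]
    rng.shuffle(fold_of)
    cv_err = np.zeros((cv_folds, len(lambda_grid)))
    for k in range(cv_folds):
        tr, va = fold_of != k, fold_of == k
        _, betas_k, info_k = lasso_path_fit(X.iloc[tr], yv[tr], lambda_grid, alpha)
        Xva = (X.iloc[va].to_numpy(dtype=np.float64) - info_k["mu"]) / info_k["sd"]
        pred = Xva @ betas_k.T + info_k["y_mean"]
        cv_err[k] = ((pred - yv[va][:, None]) ** 2).mean(axis=0)
    mean_err = cv_err.mean(axis=0)
    se_err = cv_err.std(axis=0, ddof=1) / np.sqrt(cv_folds)
    k_min = int(np.argmin(mean_err))
    if lambda_rule == "1se":
        ok = mean_err <= mean_err[k_min] + se_err[k_min]
        k_sel = int(np.flatnonzero(ok)[0])  # grid is decreasing in lambda
    else:
        k_sel = k_min
    lam = float(lambda_grid[k_sel])

    _, betas, info = lasso_path_fit(X, yv, lambda_grid, alpha)
    beta_std = betas[k_sel]
    Xs, _, _ = _standardize(X.to_numpy(dtype=np.float64))
    kkt = kkt_residual(Xs, yv - yv.mean(), beta_std, lam, alpha)

    beta_orig = beta_std / info["sd"]
    intercept = info["y_mean"] - float(beta_orig @ info["mu"])
    return LassoModel(
        coefficients={c: float(b) for c, b in zip(X.columns, beta_orig)},
        intercept=float(intercept),
        intercept_known=True,
        lambda_=lam,
        alpha=alpha,
        standardization={
            c: (float(m), float(s)) for c, m, s in zip(X.columns, info["mu"], info["sd"])
        },
        diagnostics={
            "kkt_residual": kkt,
            "cv_mean_error": mean_err.tolist(),
            "lambda_grid": lambda_grid.tolist(),
            "lambda_rule": lambda_rule,
            "cv_folds": cv_folds,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# pipeline and model objects


def run_selection_pipeline(
    X: pd.DataFrame,
    y: np.ndarray,
    t_alpha: float = 0.005,
    vif_cutoff: float = 10.0,
    alpha: float = 1.0,
    cv_folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "min",
    welch: bool = False,
) -> tuple[LassoModel | None, pd.DataFrame]:
    """t filter -> alias removal -> VIF filter -> LASSO, with a full audit.

    Returns the fitted model (None when no feature survives, an explicit
    empty-model outcome) and a FilterReport DataFrame in which every input
    feature carries its terminal stage: one of t_filter / alias / vif /
    lasso_zero / kept.
    """
    if X.isna().any().any():
        raise ValueError("missing values in the feature matrix")
    y = np.asarray(y, dtype=np.float64)

    report = ttest_filter(X, y, alpha=t_alpha, welch=welch)
    report["stage"] = np.where(report["retained"], "kept", "t_filter")
    survivors = list(report.index[report["retained"]])
    if not survivors:
        return None, report.drop(columns="retained")

    X1, aliased = drop_aliased(X[survivors])
    report.loc[aliased, "stage"] = "alias"

    X2, collinear = vif_filter(X1, cutoff=vif_cutoff)
    report.loc[collinear, "stage"] = "vif"
    if X2.shape[1] == 0:
        return None, report.drop(columns="retained")

    model = lasso_fit(
        X2, y, alpha=alpha, cv_folds=cv_folds, seed=seed, lambda_rule=lambda_rule
    )
    zeroed = [f for f in X2.columns if model.coefficients[f] == 0.0]
    report.loc[zeroed, "stage"] = "lasso_zero"
    kept = model.selected_features
    report.loc[kept, "stage"] = "kept"
    rho = stats.spearmanr(model.predict(X2).to_numpy(), y)
    model.diagnostics["spearman_rho_fitted_vs_y"] = float(rho.statistic)
    model.diagnostics["spearman_p_fitted_vs_y"] = float(rho.pvalue)
    return model, report.drop(columns="retained")


def predict_tiles(X: pd.DataFrame, model: LassoModel) -> pd.DataFrame:
    """Predicted-TILes scores and high/low median grouping for a cohort.

    Ties at the cohort median go to the high group, mirroring the
    training-cohort rule for features.
    """
    score = model.predict(X)
    high = median_split(score.to_numpy())
    return pd.DataFrame(
        {
            "predicted_tiles": score,
            "tiles_group": np.where(high, "high", "low"),
        },
        index=X.index,
    )


def published_model() -> LassoModel:
    """The published two-feature predicted-TILes model.

    GLSZM gray level variance has coefficient 1.71e-3 and GLSZM large area
    low gray level emphasis -2.48e-5; the intercept was never published, so
    the model is flagged intercept-unknown and its scores are defined up to
    an additive constant.
    """
    text = resources.files("radtiles").joinpath("assets/published_model.json").read_text()
    return LassoModel.from_json(text)


class TilesLasso:
    """Predicted-TILes model over a cohort feature matrix.

    Parameters
    ----------
    X : DataFrame
        Samples x named radiomic features, complete cases only.
    y : array-like
        TILes response per sample, in [0, 1].

    ``fit()`` runs the full selection procedure (t filter, alias removal,
    VIF filter, cross-validated LASSO) and returns a `TilesLassoResults`.
    """

    def __init__(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=np.float64)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        self.X = X
        self.y = y

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str = "tiles") -> "TilesLasso":
        if response not in df.columns:
            raise KeyError(f"response column {response!r} not in frame")
        return cls(df.drop(columns=[response]), df[response].to_numpy())

    def fit(
        self,
        t_alpha: float = 0.005,
        vif_cutoff: float = 10.0,
        alpha: float = 1.0,
        cv_folds: int = 10,
        seed: int = 0,
        lambda_rule: str = "min",
        welch: bool = False,
    ) -> "TilesLassoResults":
        model, report = run_selection_pipeline(
            self.X,
            self.y,
            t_alpha=t_alpha,
            vif_cutoff=vif_cutoff,
            alpha=alpha,
            cv_folds=cv_folds,
            seed=seed,
            lambda_rule=lambda_rule,
            welch=welch,
        )
        return TilesLassoResults(self, model, report)


class TilesLassoResults:
    """Fit results: selected features, coefficients, and the filter audit."""

    def __init__(self, model_obj: TilesLasso, model: LassoModel | None, report: pd.DataFrame):
        self.model_obj = model_obj
        self.model = model
        self.filter_report = report

    @property
    def empty(self) -> bool:
        return self.model is None or not self.model.selected_features

    @property
    def params(self) -> pd.Series:
        if self.model is None:
            return pd.Series(dtype=float)
        out = {"intercept": self.model.intercept}
        out.update({f: self.model.coefficients[f] for f in self.model.selected_features})
        return pd.Series(out)

    def predict(self, X: pd.DataFrame | None = None) -> pd.Series:
        if self.model is None:
            raise ValueError("empty model: no features were selected")
        return self.model.predict(self.model_obj.X if X is None else X)

    def predicted_groups(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        if self.model is None:
            raise ValueError("empty model: no features were selected")
        return predict_tiles(self.model_obj.X if X is None else X, self.model)

    def stage_counts(self) -> pd.Series:
        return self.filter_report["stage"].value_counts()

    def log2_fold_changes(self) -> pd.DataFrame:
        """TILes log2 fold change (high vs low group) per selected feature.

        The group summary the published fold changes used is unstated, so
        both mean- and median-based values are reported.
        """
        rows = []
        y = self.model_obj.y
        for f in self.model.selected_features:
            high = median_split(self.model_obj.X[f].to_numpy())
            with np.errstate(divide="ignore"):
                rows.append(
                    {
                        "feature": f,
                        "log2fc_mean": float(
                            np.log2(y[high].mean() / y[~high].mean())
                        ),
                        "log2fc_median": float(
                            np.log2(np.median(y[high]) / np.median(y[~high]))
                        ),
                    }
                )
        return pd.DataFrame(rows).set_index("feature")

    def summary(self) -> str:
        lines = ["Predicted-TILes LASSO selection", "=" * 47]
        counts = self.stage_counts()
        lines.append(f"Input features: {len(self.filter_report)}")
        for stage in STAGES:
            if stage in counts.index:
                lines.append(f"  removed at {stage}: {counts[stage]}" if stage != "kept"
                             else f"  selected (non-zero): {counts[stage]}")
        if self.empty:
            lines.append("No features selected (empty model).")
            return "\n".join(lines)
        lines.append(f"lambda = {self.model.lambda_:.6g} (alpha = {self.model.alpha:g}, "
                     f"{self.model.diagnostics.get('lambda_rule', 'min')} rule, "
                     f"{self.model.diagnostics.get('cv_folds')}-fold CV)")
        lines.append(f"KKT residual = {self.model.diagnostics.get('kkt_residual', float('nan')):.3g}")
        rho = self.model.diagnostics.get("spearman_rho_fitted_vs_y")
        if rho is not None:
            lines.append(f"Spearman rho (fitted vs TILes) = {rho:.3f}")
        lines.append("")
        lines.append(f"{'feature':<42}{'coefficient':>15}")
        lines.append("-" * 57)
        lines.append(f"{'intercept':<42}{self.model.intercept:>15.6g}")
        for f in self.model.selected_features:
            lines.append(f"{f:<42}{self.model.coefficients[f]:>15.6g}")
        return "\n".join(lines)
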