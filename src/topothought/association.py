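"""Standardized regression of an outcome on topography features.

All continuous predictors and the outcome are z-scored (sample sd, n-1), so
coefficients are directly comparable across predictors; categorical
fixed-effect columns are expanded to indicator contrasts with the first level
in sorted order as the reference.  A ridge variant with cross-validated
penalty is provided as a multicollinearity robustness check, and
``decompose_speed_effect`` fits the speed model next to its decomposition
into minimum required speed and circuitousness (the two components whose logs
sum to log speed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg
from sklearn.model_selection import KFold

__all__ = [
    "RegressionResult",
    "RankDeficientDesign",
    "fit_standardized_ols",
    "fit_ridge",
    "decompose_speed_effect",
]


class RankDeficientDesign(ValueError):
    """Design matrix is singular; carries the aliased column names."""

    def __init__(self, aliased: list[str]):
        self.aliased = aliased
        super().__init__(
            "rank-deficient design; aliased columns: " + ", ".join(aliased)
        )


@dataclass
class RegressionResult:
    """Coefficient table plus fit statistics for one regression.

    ``params`` has one row per predictor with columns coef, se, t, p (se/t/p
    are NaN for ridge fits, which do not come with classical standard
    errors).  ``adj_r2`` satisfies 1 - (1-R^2)(n-1)/(n-p-1).
    """

    params: pd.DataFrame
    r2: float
    adj_r2: float
    n: int
    n_params: int
    method: str = "ols"
    extra: dict = field(default_factory=dict)

    def coef(self, name: str) -> float:
        return float(self.params.loc[name, "coef"])


def _standardize(series: pd.Series) -> pd.Series:
    sd = series.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"column {series.name!r} has zero variance; cannot standardize")
    return (series - series.mean()) / sd


def _build_design(
    table: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    fixed_effects: list[str],
    check_rank: bool = True,
) -> tuple[pd.Series, pd.DataFrame, int]:
    """Standardized outcome/predictors + expanded fixed-effect contrasts.

    Rows with any missing value in the used columns are dropped (count
    returned).  Raises :class:`RankDeficientDesign` on a singular design,
    naming the aliased columns instead of silently dropping them.
    """
    used = [outcome] + list(predictors) + list(fixed_effects)
    missing = [c for c in used if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    data = table[used].dropna()
    n_dropped = len(table) - len(data)
    y = _standardize(data[outcome].astype(float))
    cols: dict[str, pd.Series] = {}
    for p in predictors:
        cols[p] = _standardize(data[p].astype(float))
    for fe in fixed_effects:
        levels = sorted(data[fe].astype(str).unique())
        for level in levels[1:]:  # first sorted level is the reference
            cols[f"{fe}[{level}]"] = (data[fe].astype(str) == level).astype(float)
    X = pd.DataFrame(cols, index=data.index)
    # detect collinearity with a pivoted QR on the centered design
    Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
    if check_rank and Xc.shape[1] > 0:
        r = linalg.qr(Xc, mode="r", pivoting=True)
        R, piv = r[0], r[1]
        diag = np.abs(np.diag(R))
        tol = max(Xc.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
        rank = int(np.sum(diag > tol))
        if rank < X.shape[1]:
            aliased = [X.columns[i] for i in piv[rank:]]
            raise RankDeficientDesign(sorted(aliased))
    return y, X, n_dropped


def fit_standardized_ols(
    table: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    fixed_effects: list[str] | None = None,
) -> RegressionResult:
    """OLS of the z-scored outcome on z-scored predictors + fixed effects.

    Solved with statsmodels' QR-based least squares; p-values come from the
    t distribution with n - p - 1 degrees of freedom.
    """
    fixed_effects = fixed_effects or []
    y, X, n_dropped = _build_design(table, outcome, predictors, fixed_effects)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"n = {n} is too small for {p} parameters")
    model = sm.OLS(y.to_numpy(), sm.add_constant(X.to_numpy()), missing="raise")
    res = model.fit(method="qr")
    names = ["const"] + list(X.columns)
    params = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        },
        index=names,
    ).drop(index="const")
    return RegressionResult(
        params=params,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        n=n,
        n_params=p + 1,
        method="ols",
        extra={"n_dropped_rows": n_dropped, "intercept": float(res.params[0])},
    )


def fit_ridge(
    table: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    fixed_effects: list[str] | None = None,
    penalty_grid: np.ndarray | list[float] | None = None,
    k_folds: int = 10,
    seed: int = 0,
) -> RegressionResult:
    """Ridge regression with the penalty chosen by k-fold cross-validation.

    Columns and outcome are centered (continuous ones standardized), the
    intercept is unpenalized (absorbed by centering), and coefficients solve
    (X'X + lambda I) b = X'y.  ``penalty_grid`` defaults to a log-spaced grid
    including 0; lambda = 0 reproduces OLS.  Folds are shuffled with a fixed
    seed for reproducibility.
    """
    fixed_effects = fixed_effects or []
    # no rank check: handling collinear designs is what the penalty is for
    y, X, n_dropped = _build_design(table, outcome, predictors, fixed_effects,
                                    check_rank=False)
    if penalty_grid is None:
        penalty_grid = np.concatenate([[0.0], np.logspace(-3, 3, 13)])
    grid = np.asarray(penalty_grid, dtype=float)
    yv = y.to_numpy()
    Xv = X.to_numpy()
    Xc = Xv - Xv.mean(axis=0)
    yc = yv - yv.mean()
    n, p = Xc.shape

    def _solve(Xm: np.ndarray, ym: np.ndarray, lam: float) -> np.ndarray:
        return np.linalg.solve(Xm.T @ Xm + lam * np.eye(Xm.shape[1]), Xm.T @ ym)

    if grid.size > 1:
        kf = KFold(n_splits=min(k_folds, n), shuffle=True, random_state=seed)
        mse = np.zeros(grid.size)
        for train, test in kf.split(Xc):
            Xt, yt = Xc[train], yc[train]
            mu_x, mu_y = Xt.mean(axis=0), yt.mean()
            for gi, lam in enumerate(grid):
                b = _solve(Xt - mu_x, yt - mu_y, lam)
                pred = (Xc[test] - mu_x) @ b + mu_y
                mse[gi] += float(np.sum((yc[test] - pred) ** 2))
        best = int(np.argmin(mse))  # ties resolve to the smaller penalty
        lam = float(grid[best])
    else:
        lam = float(grid[0])
    beta = _solve(Xc, yc, lam)
    resid = yc - Xc @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(yc @ yc)
    r2 = 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    params = pd.DataFrame(
        {"coef": beta, "se": np.nan, "t": np.nan, "p": np.nan}, index=list(X.columns)
    )
    return RegressionResult(
        params=params,
        r2=r2,
        adj_r2=adj_r2,
        n=n,
        n_params=p + 1,
        method="ridge",
        extra={"penalty": lam, "n_dropped_rows": n_dropped},
    )


def decompose_speed_effect(
    table: pd.DataFrame,
    outcome: str,
    volume_col: str = "z_log_norm_volume",
    speed_col: str = "z_log_speed",
    min_speed_col: str = "z_log_min_required_speed",
    circuitousness_col: str = "z_log_circuitousness",
    covariates: list[str] | None = None,
    fixed_effects: list[str] | None = None,
) -> tuple[RegressionResult, RegressionResult]:
    """Fit the speed model and its decomposition side by side.

    Model 1 regresses the outcome on volume and speed; Model 2 replaces
    speed by its two components, minimum required speed and circuitousness
    (log speed = log min required speed + log circuitousness), separating
    what the text covers from how optimally it is ordered.
    """
    covariates = covariates or []
    m1 = fit_standardized_ols(
        table, outcome, [volume_col, speed_col] + covariates, fixed_effects
    )
    m2 = fit_standardized_ols(
        table, outcome, [volume_col, min_speed_col, circuitousness_col] + covariates,
        fixed_effects,
    )
    return m1, m2
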