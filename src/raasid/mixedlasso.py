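"""Lasso-penalized linear mixed model for residual biomarker variability.

Each log biomarker is regressed on 13 clinical covariates (fixed effects,
lasso-penalized) while the biomarker cluster assignment and the 8-level
treatment classification enter as crossed random intercepts. The random
terms absorb the systematic between-cluster / between-treatment differences,
so the penalized fixed effects capture residual clinical associations.

Fitting alternates (a) coordinate-descent lasso on the partial residual
after removing the current random-intercept predictions, with internally
standardized predictors and an unpenalized intercept, and (b) maximum-
likelihood estimation of the three variance components (cluster, treatment,
residual) on the fixed-effect residual via Woodbury identities, with BLUPs
as the ridge solution u = (Z'Z + sigma2_e G^-1)^-1 Z'r. The penalty weight
is tuned by stratified k-fold cross-validation minimizing validation MSE,
and inference for the retained predictors comes from an unpenalized
generalized-least-squares refit (naive post-selection Wald).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.model_selection import StratifiedKFold

#: Fixed-effect predictors in canonical order.
PREDICTORS = (
    "age",
    "sex_m",
    "bmi",
    "hba1c",
    "glucose",
    "cholesterol",
    "egfr",
    "sodium",
    "potassium",
    "cortisol",
    "sbp",
    "dbp",
    "dm",
)

_CONVERGENCE_TOL = 1e-6
_MAX_OUTER = 500


def soft_threshold(z: float, lam: float) -> float:
    """Lasso shrinkage operator sign(z) * max(|z| - lam, 0)."""
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    return float(np.sign(z) * max(abs(z) - lam, 0.0))


@dataclass
class MixedLassoSpec:
    """Settings for one penalized mixed-model fit."""

    response: str
    lam: float = 0.0
    cv_folds: int = 8
    seed: int = 0
    max_outer: int = _MAX_OUTER
    tol: float = _CONVERGENCE_TOL


@dataclass
class MixedLassoFit:
    """Penalized estimates with variance components and BLUPs."""

    response: str
    lam: float
    coefficients: dict[str, float]  # original predictor scale, zeros included
    intercept: float
    retained: tuple[str, ...]
    dropped: tuple[str, ...]
    sigma2_cluster: float
    sigma2_treatment: float
    sigma2_residual: float
    blups: dict[str, dict]  # factor -> {level: prediction}
    converged: bool
    n_iterations: int
    boundary: dict[str, bool] = field(default_factory=dict)
    objective_trace: list = field(default_factory=list)


@dataclass
class CVCurve:
    """Cross-validation MSE profile over the penalty grid."""

    lambdas: np.ndarray  # descending
    mean_mse: np.ndarray
    se_mse: np.ndarray
    lambda_min: float


def build_design(cohort: pd.DataFrame, response: str):
    """Assemble (X, y, cluster labels, treatment labels) from a cohort table.

    ``response`` is a biomarker column name; y is its natural log. The sex
    column may be either M/F strings or a 0/1 ``sex_m`` indicator.
    """
    if response not in cohort.columns:
        raise ValueError(f"response column {response!r} not in cohort")
    work = cohort.copy()
    if "sex_m" not in work.columns:
        work["sex_m"] = (work["sex"] == "M").astype(float)
    missing = [p for p in PREDICTORS if p not in work.columns]
    if missing:
        raise ValueError(f"cohort is missing predictor column(s) {missing!r}")
    X = work[list(PREDICTORS)].astype(float)
    y = np.log(work[response].to_numpy(dtype=float))
    return X, y


class _RandomStructure:
    """One-hot crossed random intercepts with level bookkeeping."""

    def __init__(self, clusters, treatments):
        self.cluster_levels = tuple(pd.unique(np.asarray(clusters)))
        self.treatment_levels = tuple(pd.unique(np.asarray(treatments)))
        if len(self.cluster_levels) < 2 or len(self.treatment_levels) < 2:
            raise ValueError("each random factor needs at least 2 levels")
        self.n_c = len(self.cluster_levels)
        self.n_t = len(self.treatment_levels)
        self.Z = self.encode(clusters, treatments)

    def encode(self, clusters, treatments) -> np.ndarray:
        clusters = np.asarray(clusters)
        treatments = np.asarray(treatments)
        n = clusters.shape[0]
        Z = np.zeros((n, self.n_c + self.n_t))
        c_index = {lv: i for i, lv in enumerate(self.cluster_levels)}
        t_index = {lv: i for i, lv in enumerate(self.treatment_levels)}
        for i, (c, t) in enumerate(zip(clusters, treatments)):
            if c not in c_index:
                raise ValueError(f"unseen cluster level {c!r}")
            if t not in t_index:
                raise ValueError(f"unseen treatment level {t!r}")
            Z[i, c_index[c]] = 1.0
            Z[i, self.n_c + t_index[t]] = 1.0
        return Z

    def g_diag(self, s2_c: float, s2_t: float) -> np.ndarray:
        return np.concatenate(
            [np.full(self.n_c, s2_c), np.full(self.n_t, s2_t)]
        )


def _nll_and_blups(theta, ZtZ, Ztr, rtr, n, rs: _RandomStructure):
    """Marginal negative log-likelihood of r ~ N(0, V) and the BLUPs.

    V = s2_e I + Z G Z'; everything is computed through the q x q
    (q = n_clusters + n_treatments) Woodbury core, so each evaluation is
    O(q^3) regardless of n.
    """
    s2_c, s2_t, s2_e = np.exp(theta)
    g = rs.g_diag(s2_c, s2_t)
    sqrt_g = np.sqrt(g)
    core = np.eye(g.size) + (sqrt_g[:, None] * ZtZ * sqrt_g[None, :]) / s2_e
    sign, logdet_core = np.linalg.slogdet(core)
    if sign <= 0:
        return np.inf, None
    A = ZtZ + s2_e * np.diag(1.0 / g)
    try:
        u = np.linalg.solve(A, Ztr)
    except np.linalg.LinAlgError:
        return np.inf, None
    quad = (rtr - Ztr @ u) / s2_e
    nll = 0.5 * (n * np.log(s2_e) + logdet_core + quad)
    return float(nll), u


def _estimate_variance_components(
    resid: np.ndarray, rs: _RandomStructure, theta0: np.ndarray | None = None
):
    """ML variance components on the fixed-effect residual, plus BLUPs."""
    n = resid.shape[0]
    ZtZ = rs.Z.T @ rs.Z
    Ztr = rs.Z.T @ resid
    rtr = float(resid @ resid)
    var_r = max(rtr / n, 1e-12)
    if theta0 is None:
        theta0 = np.log(np.array([0.1 * var_r, 0.1 * var_r, 0.8 * var_r]))

    def objective(theta):
        val, _ = _nll_and_blups(theta, ZtZ, Ztr, rtr, n, rs)
        return val

    bounds = [(np.log(1e-10 * var_r), np.log(1e4 * var_r))] * 3
    res = optimize.minimize(
        objective, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-12},
    )
    theta = res.x
    _, u = _nll_and_blups(theta, ZtZ, Ztr, rtr, n, rs)
    s2_c, s2_t, s2_e = np.exp(theta)
    lo = 1e-8 * var_r
    boundary = {"cluster": s2_c <= 10 * np.exp(bounds[0][0]),
                "treatment": s2_t <= 10 * np.exp(bounds[0][0])}
    # treat variances at the lower bound as zero
    if s2_c <= lo:
        s2_c = 0.0
    if s2_t <= lo:
        s2_t = 0.0
    return float(s2_c), float(s2_t), float(s2_e), u, theta, boundary


def _coordinate_descent(
    Xs: np.ndarray, r: np.ndarray, beta: np.ndarray, lam: float,
    max_sweeps: int = 2000, tol: float = 1e-10,
):
    """Cyclic coordinate descent for (1/2n)||r - b0 - Xs b||^2 + lam |b|_1.

    Columns of Xs are centered with unit population variance, so each
    coordinate update is an exact soft-thresholded univariate fit and the
    intercept is the residual mean.
    """
    n, p = Xs.shape
    b0 = float(r.mean())
    work = r - b0 - Xs @ beta
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            zj = beta[j] + (Xs[:, j] @ work) / n
            new = soft_threshold(zj, lam)
            delta = new - beta[j]
            if delta != 0.0:
                work -= delta * Xs[:, j]
                beta[j] = new
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    return b0, beta


def fit_lasso_lmm(
    X: pd.DataFrame,
    y: np.ndarray,
    clusters,
    treatments,
    lam: float,
    *,
    fix_variances: tuple[float, float] | None = None,
    max_outer: int = _MAX_OUTER,
    tol: float = _CONVERGENCE_TOL,
    response: str = "",
    _structure: _RandomStructure | None = None,
    _warm: dict | None = None,
) -> MixedLassoFit:
    """Alternating lasso / variance-component fit of the mixed model.

    ``fix_variances`` pins (sigma2_cluster, sigma2_treatment); passing
    ``(0.0, 0.0)`` reduces the model to a plain lasso (and to OLS at lam=0).
    Coefficients are reported on the original predictor scale; predictors
    with zero penalized coefficients form the ``dropped`` set.
    """
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    y = np.asarray(y, dtype=float)
    Xmat = X[list(PREDICTORS)].to_numpy(dtype=float)
    n, p = Xmat.shape
    means = Xmat.mean(axis=0)
    sds = Xmat.std(axis=0, ddof=0)
    if (sds == 0).any():
        bad = np.array(PREDICTORS)[sds == 0]
        raise ValueError(f"constant predictor column(s) after standardization: {bad!r}")
    Xs = (Xmat - means) / sds
    rs = _structure or _RandomStructure(clusters, treatments)

    beta = np.zeros(p)
    u = np.zeros(rs.Z.shape[1])
    theta = None
    if _warm:
        beta = _warm.get("beta", beta).copy()
        u = _warm.get("u", u).copy()
        theta = _warm.get("theta")
    s2_c = s2_t = 0.0
    s2_e = float(np.var(y))
    s2_e_frozen: float | None = None
    boundary = {"cluster": False, "treatment": False}
    b0 = float(y.mean())
    converged = False
    trace = []
    n_iter = 0
    for n_iter in range(1, max_outer + 1):
        beta_old = beta.copy()
        partial = y - rs.Z @ u
        b0, beta = _coordinate_descent(Xs, partial, beta, lam)
        resid = y - b0 - Xs @ beta
        if fix_variances is not None:
            s2_c, s2_t = fix_variances
            # freeze the ridge weight so the alternation is exact block
            # coordinate descent on one fixed objective
            if s2_e_frozen is None:
                s2_e_frozen = float(resid @ resid) / n
            s2_e = s2_e_frozen
            if s2_c == 0.0 and s2_t == 0.0:
                u = np.zeros(rs.Z.shape[1])
            else:
                g = rs.g_diag(max(s2_c, 1e-12), max(s2_t, 1e-12))
                A = rs.Z.T @ rs.Z + s2_e * np.diag(1.0 / g)
                u = np.linalg.solve(A, rs.Z.T @ resid)
        else:
            s2_c, s2_t, s2_e, u, theta, boundary = _estimate_variance_components(
                resid, rs, theta
            )
        fit_resid = resid - rs.Z @ u
        # joint penalized objective at the current variance components
        g = rs.g_diag(max(s2_c, 1e-12), max(s2_t, 1e-12))
        obj = (
            float(fit_resid @ fit_resid) / (2 * n)
            + s2_e * float((u**2 / g).sum()) / (2 * n)
            + lam * np.abs(beta).sum()
        )
        trace.append(obj)
        if np.max(np.abs(beta - beta_old)) < tol:
            converged = True
            break

    coef_orig = beta / sds
    intercept = b0 - float(coef_orig @ means)
    retained = tuple(p_ for p_, b in zip(PREDICTORS, beta) if b != 0.0)
    dropped = tuple(p_ for p_, b in zip(PREDICTORS, beta) if b == 0.0)
    blups = {
        "cluster": {
            lv: float(u[i]) for i, lv in enumerate(rs.cluster_levels)
        },
        "treatment": {
            lv: float(u[rs.n_c + i]) for i, lv in enumerate(rs.treatment_levels)
        },
    }
    return MixedLassoFit(
        response=response,
        lam=float(lam),
        coefficients={p_: float(c) for p_, c in zip(PREDICTORS, coef_orig)},
        intercept=float(intercept),
        retained=retained,
        dropped=dropped,
        sigma2_cluster=float(s2_c),
        sigma2_treatment=float(s2_t),
        sigma2_residual=float(s2_e),
        blups=blups,
        converged=converged,
        n_iterations=n_iter,
        boundary=boundary,
        objective_trace=trace,
    )


def lambda_grid(X: pd.DataFrame, y: np.ndarray, size: int = 50) -> np.ndarray:
    """Descending log-spaced penalty grid from lambda_max down 3 decades.

    lambda_max is the smallest penalty that zeroes every standardized
    coefficient in the no-random-effects model.
    """
    Xmat = X[list(PREDICTORS)].to_numpy(dtype=float)
    sds = Xmat.std(axis=0, ddof=0)
    Xs = (Xmat - Xmat.mean(axis=0)) / np.where(sds == 0, 1.0, sds)
    y = np.asarray(y, dtype=float)
    lam_max = float(np.abs(Xs.T @ (y - y.mean())).max() / y.shape[0])
    return np.geomspace(lam_max, lam_max * 1e-3, size)


def cv_lambda(
    X: pd.DataFrame,
    y: np.ndarray,
    clusters,
    treatments,
    *,
    n_folds: int = 8,
    grid: np.ndarray | None = None,
    grid_size: int = 50,
    seed: int = 0,
    max_outer: int = _MAX_OUTER,
) -> CVCurve:
    """Stratified k-fold cross-validation of the penalty weight.

    Folds are stratified by treatment group so every random-factor level is
    present in every training set (a fold missing a cluster or treatment
    level raises). Held-out predictions use the training fixed effects plus
    the training BLUPs; the curve reports mean and SE of validation MSE per
    penalty, and ``lambda_min`` is the grid argmin.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    y = np.asarray(y, dtype=float)
    clusters = np.asarray(clusters)
    treatments = np.asarray(treatments)
    if grid is None:
        grid = lambda_grid(X, y, size=grid_size)
    grid = np.asarray(sorted(grid, reverse=True), dtype=float)
    if grid.size == 0:
        raise ValueError("empty penalty grid")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_mse = np.empty((n_folds, grid.size))
    all_c = set(np.unique(clusters))
    all_t = set(np.unique(treatments))
    for f, (train, test) in enumerate(skf.split(np.zeros(y.size), treatments)):
        if set(clusters[train]) != all_c or set(treatments[train]) != all_t:
            raise ValueError(
                f"fold {f} training set is missing a random-factor level"
            )
        X_tr = X.iloc[train]
        rs = _RandomStructure(clusters[train], treatments[train])
        Z_te = rs.encode(clusters[test], treatments[test])
        X_te = X_tr_matrix = None
        warm: dict | None = None
        for j, lam in enumerate(grid):
            fit = fit_lasso_lmm(
                X_tr, y[train], clusters[train], treatments[train], lam,
                response="cv", _structure=rs, _warm=warm,
                max_outer=max_outer,
            )
            coef = np.array([fit.coefficients[p_] for p_ in PREDICTORS])
            u = np.concatenate(
                [
                    [fit.blups["cluster"][lv] for lv in rs.cluster_levels],
                    [fit.blups["treatment"][lv] for lv in rs.treatment_levels],
                ]
            )
            Xte = X.iloc[test][list(PREDICTORS)].to_numpy(dtype=float)
            pred = fit.intercept + Xte @ coef + Z_te @ u
            fold_mse[f, j] = float(np.mean((y[test] - pred) ** 2))
            sds = X_tr[list(PREDICTORS)].to_numpy(dtype=float).std(axis=0, ddof=0)
            warm = {
                "beta": coef * sds,
                "u": u,
                "theta": np.log(
                    np.maximum(
                        [fit.sigma2_cluster, fit.sigma2_treatment,
                         fit.sigma2_residual],
                        1e-12,
                    )
                ),
            }
    mean_mse = fold_mse.mean(axis=0)
    se_mse = fold_mse.std(axis=0, ddof=1) / np.sqrt(n_folds)
    lambda_min = float(grid[int(np.argmin(mean_mse))])
    return CVCurve(
        lambdas=grid, mean_mse=mean_mse, se_mse=se_mse, lambda_min=lambda_min
    )


def post_selection_inference(
    X: pd.DataFrame,
    y: np.ndarray,
    clusters,
    treatments,
    fit: MixedLassoFit,
    *,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Unpenalized mixed-model refit on the retained predictors.

    Iterates generalized least squares for the fixed effects with ML
    variance components until both stabilize; SEs come from (X'V^-1 X)^-1
    and p-values are Wald. Dropped predictors are reported as "removed"
    with no SE/p. The inference is naive post-selection (no selective
    correction) and should be read as approximate.
    """
    y = np.asarray(y, dtype=float)
    retained = list(fit.retained)
    rs = _RandomStructure(clusters, treatments)
    n = y.shape[0]
    Xr = np.column_stack(
        [np.ones(n)]
        + [X[p_].to_numpy(dtype=float) for p_ in retained]
    )
    beta = np.zeros(Xr.shape[1])
    beta[0] = y.mean()
    theta = None
    s2 = (fit.sigma2_cluster, fit.sigma2_treatment, fit.sigma2_residual)
    cov = None
    for _ in range(max_iter):
        resid = y - Xr @ beta
        s2_c, s2_t, s2_e, _, theta, _ = _estimate_variance_components(
            resid, rs, theta
        )
        # V^-1 M via Woodbury with the q x q core
        g = rs.g_diag(max(s2_c, 1e-12), max(s2_t, 1e-12))
        A = rs.Z.T @ rs.Z + s2_e * np.diag(1.0 / g)
        ZtX = rs.Z.T @ Xr
        Zty = rs.Z.T @ y
        XtVinvX = (Xr.T @ Xr - ZtX.T @ np.linalg.solve(A, ZtX)) / s2_e
        XtVinvy = (Xr.T @ y - ZtX.T @ np.linalg.solve(A, Zty)) / s2_e
        cov = np.linalg.inv(XtVinvX)
        beta_new = cov @ XtVinvy
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol and max(
            abs(s2_c - s2[0]), abs(s2_t - s2[1]), abs(s2_e - s2[2])
        ) < tol * max(s2_e, 1.0):
            s2 = (s2_c, s2_t, s2_e)
            break
        s2 = (s2_c, s2_t, s2_e)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    rows = [
        {
            "predictor": "(Intercept)",
            "estimate": float(beta[0]),
            "se": float(se[0]),
            "p_value": float(pvals[0]),
            "status": "retained",
        }
    ]
    idx = {p_: i + 1 for i, p_ in enumerate(retained)}
    for p_ in PREDICTORS:
        if p_ in idx:
            i = idx[p_]
            rows.append(
                {
                    "predictor": p_,
                    "estimate": float(beta[i]),
                    "se": float(se[i]),
                    "p_value": float(pvals[i]),
                    "status": "retained",
                }
            )
        else:
            rows.append(
                {
                    "predictor": p_,
                    "estimate": np.nan,
                    "se": np.nan,
                    "p_value": np.nan,
                    "status": "removed",
                }
            )
    return pd.DataFrame(rows)


def lasso_analysis(
    cohort: pd.DataFrame,
    cluster_labels,
    response: str,
    *,
    n_folds: int = 8,
    grid_size: int = 50,
    seed: int = 0,
) -> dict:
    """End-to-end penalized mixed-model analysis of one log biomarker.

    Cross-validates the penalty, refits on the full data at lambda_min, and
    returns the CV curve, the penalized fit and the post-selection
    coefficient table.
    """
    X, y = build_design(cohort, response)
    treatments = cohort["group"].to_numpy()
    curve = cv_lambda(
        X, y, cluster_labels, treatments,
        n_folds=n_folds, grid_size=grid_size, seed=seed,
    )
    fit = fit_lasso_lmm(
        X, y, cluster_labels, treatments, curve.lambda_min, response=response
    )
    table = post_selection_inference(X, y, cluster_labels, treatments, fit)
    return {"cv": curve, "fit": fit, "inference": table}
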