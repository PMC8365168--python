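"""Generation-trend fitting with linear mixed-effects models.

Every measure is modelled as a linear function of generation with a random
intercept per transmission chain, fitted by REML.  Fixed effects are tested
with t-tests whose degrees of freedom come from Satterthwaite's
approximation, computed from the curvature of the REML criterion in the
variance parameters.  Single-chain tables degrade to ordinary least squares
(flagged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


@dataclass
class TrendFit:
    """One fixed-effect trend: slope per generation with its uncertainty."""

    measure_name: str
    term: str
    slope: float
    sem: float
    df: float
    t: float
    p_value: float
    random_intercept_variance: float
    residual_variance: float
    n_obs: int
    n_groups: int
    method: str = "lmm"           # "lmm" or "ols" fallback
    degenerate: bool = False


@dataclass
class LMMResult:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float                  # residual variance
    tau2: float                    # random-intercept variance
    satterthwaite_df: np.ndarray
    n_obs: int
    n_groups: int
    column_names: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# REML machinery for the random-intercept model
# ---------------------------------------------------------------------------

def _group_indices(groups: np.ndarray) -> list[np.ndarray]:
    codes, _ = pd.factorize(groups, sort=True)
    return [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]


def _gls_pieces(X: np.ndarray, y: np.ndarray, idx: list[np.ndarray],
                sigma2: float, tau2: float):
    """X'V^-1 X, X'V^-1 y, and a V^-1-weighted quadratic form helper,
    using Woodbury per group: V_g^-1 = (I - w J)/sigma2, w = tau2/(sigma2 + n_g tau2)."""
    p = X.shape[1]
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    for g in idx:
        n_g = g.size
        w = tau2 / (sigma2 + n_g * tau2)
        Xg, yg = X[g], y[g]
        xs, ys = Xg.sum(axis=0), yg.sum()
        XtViX += (Xg.T @ Xg - w * np.outer(xs, xs)) / sigma2
        XtViy += (Xg.T @ yg - w * xs * ys) / sigma2
    return XtViX, XtViy


def _reml_nll(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
              idx: list[np.ndarray]) -> float:
    """-2/2 * restricted log-likelihood (up to a constant) at natural
    variance parameters theta = (sigma2, tau2)."""
    sigma2, tau2 = float(theta[0]), float(theta[1])
    if sigma2 <= 0 or tau2 < 0:
        return np.inf
    XtViX, XtViy = _gls_pieces(X, y, idx, sigma2, tau2)
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        return np.inf
    logdetV = 0.0
    quad = 0.0
    for g in idx:
        n_g = g.size
        w = tau2 / (sigma2 + n_g * tau2)
        logdetV += (n_g - 1) * np.log(sigma2) + np.log(sigma2 + n_g * tau2)
        rg = y[g] - X[g] @ beta
        quad += (rg @ rg - w * rg.sum() ** 2) / sigma2
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf
    return 0.5 * (logdetV + logdetXtViX + quad)


def _profile_fit(X: np.ndarray, y: np.ndarray, idx: list[np.ndarray]):
    """REML fit profiled over the variance ratio lambda = tau2/sigma2."""
    n, p = X.shape

    def crit(log_lam: float) -> float:
        lam = np.exp(log_lam)
        XtWiX, XtWiy = _gls_pieces(X, y, idx, 1.0, lam)  # W = I + lam ZZ'
        try:
            beta = np.linalg.solve(XtWiX, XtWiy)
        except np.linalg.LinAlgError:
            return np.inf
        quad = 0.0
        logdetW = 0.0
        for g in idx:
            n_g = g.size
            w = lam / (1.0 + n_g * lam)
            rg = y[g] - X[g] @ beta
            quad += rg @ rg - w * rg.sum() ** 2
            logdetW += np.log(1.0 + n_g * lam)
        if quad <= 0:
            return np.inf
        sign, logdetXtWiX = np.linalg.slogdet(XtWiX)
        if sign <= 0:
            return np.inf
        return (n - p) * np.log(quad / (n - p)) + logdetW + logdetXtWiX

    grid = np.linspace(-10.0, 8.0, 37)
    vals = [crit(g) for g in grid]
    best = int(np.argmin(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(crit, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    # boundary check: lambda -> 0 (no chain variance)
    if crit(-30.0) <= res.fun + 1e-10:
        lam = 0.0

    XtWiX, XtWiy = _gls_pieces(X, y, idx, 1.0, lam)
    beta = np.linalg.solve(XtWiX, XtWiy)
    quad = 0.0
    for g in idx:
        n_g = g.size
        w = lam / (1.0 + n_g * lam)
        rg = y[g] - X[g] @ beta
        quad += rg @ rg - w * rg.sum() ** 2
    sigma2 = float(quad / (n - p))
    tau2 = lam * sigma2
    cov_beta = np.linalg.inv(XtWiX) * sigma2
    return beta, cov_beta, sigma2, tau2


def _satterthwaite_df(X: np.ndarray, y: np.ndarray, idx: list[np.ndarray],
                      sigma2: float, tau2: float) -> np.ndarray:
    """Satterthwaite df for each coefficient: 2 f^2 / Var(f), where
    f(theta) = [ (X'V^-1 X)^-1 ]_jj and Var(f) uses the inverse curvature of
    the REML criterion at the variance estimates."""
    n, p = X.shape
    fallback = np.full(p, float(max(n - p, 1)))
    if tau2 <= 0:
        return fallback  # boundary estimate: curvature-based df undefined

    theta = np.array([sigma2, tau2])
    steps = 1e-4 * np.abs(theta) + 1e-12

    def f_vec(th: np.ndarray) -> np.ndarray:
        XtViX, _ = _gls_pieces(X, y, idx, th[0], th[1])
        return np.diag(np.linalg.inv(XtViX))

    # gradient of each f_j (central differences)
    grads = np.zeros((p, 2))
    for k in range(2):
        e = np.zeros(2)
        e[k] = steps[k]
        grads[:, k] = (f_vec(theta + e) - f_vec(theta - e)) / (2 * steps[k])

    # numeric Hessian of the REML negative log-likelihood
    H = np.zeros((2, 2))
    f0 = _reml_nll(theta, X, y, idx)
    for a in range(2):
        for b in range(a, 2):
            ea = np.zeros(2); ea[a] = steps[a]
            eb = np.zeros(2); eb[b] = steps[b]
            if a == b:
                H[a, a] = (_reml_nll(theta + ea, X, y, idx) - 2 * f0
                           + _reml_nll(theta - ea, X, y, idx)) / steps[a] ** 2
            else:
                H[a, b] = H[b, a] = (
                    _reml_nll(theta + ea + eb, X, y, idx)
                    - _reml_nll(theta + ea - eb, X, y, idx)
                    - _reml_nll(theta - ea + eb, X, y, idx)
                    + _reml_nll(theta - ea - eb, X, y, idx)
                ) / (4 * steps[a] * steps[b])
    try:
        A = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return fallback
    if np.any(np.diag(A) <= 0):
        return fallback

    f = f_vec(theta)
    df = np.empty(p)
    for j in range(p):
        var_f = grads[j] @ A @ grads[j]
        df[j] = 2 * f[j] ** 2 / var_f if var_f > 0 else fallback[j]
    return np.clip(df, 1.0, None)


def fit_random_intercept_lmm(X: np.ndarray, y: np.ndarray, groups,
                             column_names: list[str] | None = None) -> LMMResult:
    """REML fit of ``y = X beta + (1 | group) + noise`` with Satterthwaite df."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    idx = _group_indices(np.asarray(groups))
    beta, cov_beta, sigma2, tau2 = _profile_fit(X, y, idx)
    df = _satterthwaite_df(X, y, idx, sigma2, tau2)
    return LMMResult(beta=beta, cov_beta=cov_beta, sigma2=sigma2, tau2=tau2,
                     satterthwaite_df=df, n_obs=X.shape[0], n_groups=len(idx),
                     column_names=column_names or
                     [f"x{i}" for i in range(X.shape[1])])


# ---------------------------------------------------------------------------
# Public trend-fitting surface over tidy measure tables
# ---------------------------------------------------------------------------

def _prepare(table: pd.DataFrame, measure_name: str, value_col: str,
             gen_col: str, chain_col: str, measure_col: str) -> pd.DataFrame:
    if measure_col in table.columns:
        sub = table[table[measure_col] == measure_name]
        if sub.empty:
            raise KeyError(f"measure {measure_name!r} not found in table")
    else:
        sub = table
    sub = sub.dropna(subset=[value_col])
    return sub


def _ols_trend(measure_name: str, gen: np.ndarray, y: np.ndarray,
               n_groups: int) -> TrendFit:
    n = y.size
    X = np.column_stack([np.ones(n), gen])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(n - 2, 1)
    s2 = float(resid @ resid / dof)
    cov = s2 * np.linalg.inv(X.T @ X)
    sem = float(np.sqrt(cov[1, 1]))
    t = beta[1] / sem if sem > 0 else 0.0
    p = 2 * stats.t.sf(abs(t), dof)
    return TrendFit(measure_name=measure_name, term="generation",
                    slope=float(beta[1]), sem=sem, df=float(dof), t=float(t),
                    p_value=float(p), random_intercept_variance=0.0,
                    residual_variance=s2, n_obs=n, n_groups=n_groups,
                    method="ols", degenerate=False)


def fit_generation_trend(table: pd.DataFrame, measure_name: str,
                         value_col: str = "value", gen_col: str = "generation",
                         chain_col: str = "chain_id",
                         measure_col: str = "measure") -> TrendFit:
    """Fit ``value ~ generation + (1 | chain)`` for one measure.

    Single-chain tables fall back to ordinary least squares (flagged via
    ``method='ols'``); zero-variance responses return a degenerate fit with
    slope 0.
    """
    sub = _prepare(table, measure_name, value_col, gen_col, chain_col,
                   measure_col)
    y = sub[value_col].to_numpy(dtype=float)
    gen = sub[gen_col].to_numpy(dtype=float)
    chains = sub[chain_col].to_numpy()
    n_groups = len(np.unique(chains))
    if np.ptp(y) == 0 or y.size < 3:
        return TrendFit(measure_name=measure_name, term="generation",
                        slope=0.0, sem=float("nan"), df=float("nan"),
                        t=float("nan"), p_value=float("nan"),
                        random_intercept_variance=0.0, residual_variance=0.0,
                        n_obs=y.size, n_groups=n_groups, degenerate=True)
    if n_groups < 2:
        logger.warning("measure %s: single chain, falling back to OLS",
                       measure_name)
        return _ols_trend(measure_name, gen, y, n_groups)
    X = np.column_stack([np.ones(y.size), gen])
    res = fit_random_intercept_lmm(X, y, chains,
                                   column_names=["intercept", "generation"])
    sem = float(np.sqrt(res.cov_beta[1, 1]))
    df = float(res.satterthwaite_df[1])
    t = float(res.beta[1] / sem)
    p = float(2 * stats.t.sf(abs(t), df))
    return TrendFit(measure_name=measure_name, term="generation",
                    slope=float(res.beta[1]), sem=sem, df=df, t=t, p_value=p,
                    random_intercept_variance=res.tau2,
                    residual_variance=res.sigma2, n_obs=res.n_obs,
                    n_groups=res.n_groups)


def fit_interaction_trend(table: pd.DataFrame, measure_name: str,
                          value_col: str = "value",
                          gen_col: str = "generation",
                          chain_col: str = "chain_id",
                          dataset_col: str = "dataset",
                          measure_col: str = "measure") -> dict[str, TrendFit]:
    """Fit ``value ~ generation * dataset + (1 | chain)``.

    ``dataset`` is a binary column (e.g. actual vs. shuffled intervals),
    dummy-coded 0/1 by sorted level name.  Returns fits for the generation
    main effect, the dataset main effect, and their interaction.
    """
    sub = _prepare(table, measure_name, value_col, gen_col, chain_col,
                   measure_col)
    levels = sorted(sub[dataset_col].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"dataset column must be binary, got {levels}")
    y = sub[value_col].to_numpy(dtype=float)
    gen = sub[gen_col].to_numpy(dtype=float)
    dset = (sub[dataset_col] == levels[1]).to_numpy(dtype=float)
    chains = sub[chain_col].to_numpy()
    X = np.column_stack([np.ones(y.size), gen, dset, gen * dset])
    names = ["intercept", "generation", "dataset", "generation:dataset"]
    res = fit_random_intercept_lmm(X, y, chains, column_names=names)
    fits: dict[str, TrendFit] = {}
    for j, term in enumerate(names):
        if term == "intercept":
            continue
        sem = float(np.sqrt(res.cov_beta[j, j]))
        df = float(res.satterthwaite_df[j])
        t = float(res.beta[j] / sem)
        fits[term] = TrendFit(
            measure_name=measure_name, term=term, slope=float(res.beta[j]),
            sem=sem, df=df, t=t, p_value=float(2 * stats.t.sf(abs(t), df)),
            random_intercept_variance=res.tau2, residual_variance=res.sigma2,
            n_obs=res.n_obs, n_groups=res.n_groups)
    return fits


def fit_all_trends(table: pd.DataFrame, min_generations: int = 3,
                   interaction_measures: tuple[str, ...] = (),
                   ) -> pd.DataFrame:
    """One trend row per measure in a tidy MeasureTable.

    Measures listed in ``interaction_measures`` (tables carrying a binary
    ``dataset`` column) get the generation x dataset model; everything else
    gets the plain generation trend.  Measures observed in fewer than
    ``min_generations`` generations are skipped with a warning.
    """
    rows = []
    for measure in sorted(table["measure"].unique()):
        sub = table[table["measure"] == measure].dropna(subset=["value"])
        if sub["generation"].nunique() < min_generations:
            warnings.warn(f"measure {measure!r}: fewer than {min_generations} "
                          f"generations with data; skipped")
            continue
        try:
            if measure in interaction_measures:
                fits = list(fit_interaction_trend(table, measure).values())
            else:
                fits = [fit_generation_trend(table, measure)]
        except (ValueError, KeyError) as exc:
            warnings.warn(f"measure {measure!r}: {exc}; skipped")
            continue
        for f in fits:
            rows.append({"measure": f.measure_name, "term": f.term,
                         "b": f.slope, "sem": f.sem, "df": f.df, "t": f.t,
                         "p": f.p_value, "chain_var": f.random_intercept_variance,
                         "resid_var": f.residual_variance, "n_obs": f.n_obs,
                         "method": f.method, "degenerate": f.degenerate})
    return pd.DataFrame(rows)
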