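"""Per-CpG association models: OLS, random-intercept REML, and Cox PH.

Each fitter takes one probe's methylation vector plus a design built from
the sample sheet and returns a :class:`SiteFit`. The linear model reports
the exposure slope with classical (t-based) inference; the mixed model is
a random-intercept fit by profiled REML with a Wald z test on the fixed
exposure effect; the Cox model reports the log hazard ratio per unit
methylation with Efron handling of tied event times (via lifelines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import SampleSheet


@dataclass
class SiteFit:
    """Result of fitting one CpG site."""

    estimate: float
    se: float
    p: float
    n_used: int
    converged: bool = True
    reason: str = ""
    contrasts: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


def _failed(n_used: int, reason: str) -> SiteFit:
    return SiteFit(np.nan, np.nan, np.nan, n_used, converged=False, reason=reason)


def scale_exposure(x, mode: str = "unit") -> np.ndarray:
    """Scale a numeric exposure so the slope is 'per unit / per IQR / per SD'.

    ``iqr`` divides by the interquartile range (linear-interpolation
    quartiles); ``sd`` divides by the sample standard deviation (n − 1).
    """
    x = np.asarray(x, dtype=float)
    if mode == "unit":
        return x
    finite = x[np.isfinite(x)]
    if mode == "iqr":
        q1, q3 = np.percentile(finite, [25, 75])
        denom = q3 - q1
    elif mode == "sd":
        denom = np.std(finite, ddof=1)
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    if not np.isfinite(denom) or denom == 0:
        raise ValueError(f"exposure has zero {mode.upper()}; cannot scale")
    return x / denom


def adjust_pvalues(p, method: str) -> np.ndarray:
    """Multiple-testing adjustment: Bonferroni or Benjamini–Hochberg step-up.

    NaNs are excluded from the test count m and propagated.
    """
    p = np.asarray(p, dtype=float)
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return out
    if method == "bonferroni":
        out[valid] = np.minimum(1.0, m * pv)
    elif method == "bh":
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / (np.arange(m) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        res = np.empty(m)
        res[order] = np.minimum(adj, 1.0)
        out[valid] = res
    else:
        raise ValueError(f"unknown adjustment method {method!r} (use 'bonferroni' or 'bh')")
    return out


def build_design(
    sheet: SampleSheet, exposure: str | None, covariates: list[str]
) -> tuple[np.ndarray, list[str], list[int]]:
    """Build [intercept | exposure column(s) | covariates] from the sheet.

    A factor exposure with L levels contributes L−1 dummy columns
    (reference level omitted). Returns (design, column names, indices of
    the exposure columns). The reported contrast downstream is the last
    exposure column (last level vs reference for factors).
    """
    n = len(sheet)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["Intercept"]
    exposure_idx: list[int] = []

    def add_var(name: str, track: bool) -> None:
        col = sheet.column(name)
        if sheet.is_factor(name):
            ft = sheet.factors[name]
            for level in ft.levels:
                if level == ft.reference:
                    continue
                cols.append((col.astype(str) == level).to_numpy(float))
                names.append(f"{name}[{level}]")
                if track:
                    exposure_idx.append(len(cols) - 1)
        else:
            numeric = pd.to_numeric(col, errors="coerce")
            if numeric.isna().all() and col.notna().any():
                raise ValueError(
                    f"variable {name!r} is non-numeric; declare it a factor first"
                )
            cols.append(numeric.to_numpy(float))
            names.append(name)
            if track:
                exposure_idx.append(len(cols) - 1)

    if exposure is not None:
        add_var(exposure, track=True)
    for cov in covariates:
        add_var(cov, track=False)
    return np.column_stack(cols), names, exposure_idx


def fit_glm_site(
    y: np.ndarray, X: np.ndarray, exposure_idx: int, exposure_cols: list[int] | None = None
) -> SiteFit:
    """OLS fit of one CpG on the design; classical t inference on the slope.

    A constant outcome returns the degenerate convention estimate 0,
    p = 1 (keeps the record count stable across a matrix).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    mask = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[mask], X[mask]
    n, p = X.shape
    if n < p + 1:
        return _failed(n, "too few complete cases")
    if np.ptp(y) == 0:
        return SiteFit(0.0, np.nan, 1.0, n, converged=True, reason="constant outcome")
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        return _failed(n, "rank-deficient design")
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = n - p
    if df <= 0:
        return _failed(n, "zero residual df")
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(XtX)
    se_all = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se_all
    pvals = 2 * stats.t.sf(np.abs(tstat), df)
    contrasts = {}
    for j in exposure_cols or [exposure_idx]:
        contrasts[f"col{j}"] = (float(beta[j]), float(se_all[j]), float(pvals[j]))
    return SiteFit(
        float(beta[exposure_idx]),
        float(se_all[exposure_idx]),
        float(pvals[exposure_idx]),
        n,
        contrasts=contrasts,
        extra={"df_resid": df, "sigma2": float(sigma2)},
    )


# ---------------------------------------------------------------------------
# Random-intercept linear mixed model, profiled REML.
#
# V_i = sigma2 * (I + theta * J) per group, theta = var_u / var_e >= 0.
# Given theta, GLS and sigma2 have closed forms, so REML reduces to a 1-D
# optimization; theta = 0 reproduces OLS exactly (boundary case, e.g. one
# observation per group).
# ---------------------------------------------------------------------------


def _reml_profile(theta: float, y, X, starts, sizes):
    """Negative profiled REML log-likelihood and GLS pieces at a given theta."""
    n, p = X.shape
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    logdetV = 0.0
    for s, m in zip(starts, sizes):
        Xi, yi = X[s : s + m], y[s : s + m]
        c = theta / (1.0 + m * theta)
        XtVX += Xi.T @ Xi - c * np.outer(Xi.sum(0), Xi.sum(0))
        XtVy += Xi.T @ yi - c * Xi.sum(0) * yi.sum()
        logdetV += np.log1p(m * theta)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = 0.0
    for s, m in zip(starts, sizes):
        ri = y[s : s + m] - X[s : s + m] @ beta
        c = theta / (1.0 + m * theta)
        rss += ri @ ri - c * ri.sum() ** 2
    sigma2 = rss / (n - p)
    sign, logdetXtVX = np.linalg.slogdet(XtVX)
    nll = 0.5 * ((n - p) * np.log(sigma2) + logdetV + logdetXtVX + (n - p))
    return nll, beta, sigma2, XtVX


def fit_lmm_site(y: np.ndarray, X: np.ndarray, groups, exposure_idx: int) -> SiteFit:
    """Random-intercept mixed model fit by profiled REML; Wald z on exposure.

    With one observation per group the between-group variance is not
    identifiable and the profile optimum sits at the boundary θ = 0, where
    the fit equals OLS.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    mask = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X, groups = y[mask], X[mask], groups[mask]
    n, p = X.shape
    if n < p + 1:
        return _failed(n, "too few complete cases")
    codes, _ = pd.factorize(groups)
    if len(np.unique(codes)) < 2:
        return _failed(n, "fewer than 2 groups")
    if np.linalg.matrix_rank(X) < p:
        return _failed(n, "rank-deficient design")
    if np.ptp(y) == 0:
        return SiteFit(0.0, np.nan, 1.0, n, converged=True, reason="constant outcome")
    order = np.argsort(codes, kind="mergesort")
    y, X, codes = y[order], X[order], codes[order]
    sizes = np.bincount(codes)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])

    def objective(log_theta: float) -> float:
        return _reml_profile(np.exp(log_theta), y, X, starts, sizes)[0]

    # profile over log-theta with the exact boundary candidate theta = 0
    nll0 = _reml_profile(0.0, y, X, starts, sizes)[0]
    try:
        res = optimize.minimize_scalar(objective, bounds=(-12.0, 8.0), method="bounded")
        theta = float(np.exp(res.x)) if res.fun < nll0 - 1e-10 else 0.0
    except Exception:  # pragma: no cover - numerical safety net
        theta = 0.0
    nll, beta, sigma2, XtVX = _reml_profile(theta, y, X, starts, sizes)
    cov = sigma2 * np.linalg.inv(XtVX)
    se = float(np.sqrt(cov[exposure_idx, exposure_idx]))
    est = float(beta[exposure_idx])
    z = est / se if se > 0 else np.nan
    pval = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
    return SiteFit(
        est,
        se,
        float(pval),
        n,
        extra={
            "theta": theta,
            "var_resid": float(sigma2),
            "var_group": float(theta * sigma2),
            "n_groups": int(len(sizes)),
        },
    )


def fit_cox_site(
    time: np.ndarray,
    event: np.ndarray,
    cpg: np.ndarray,
    covariates: np.ndarray | None = None,
    cov_names: list[str] | None = None,
) -> SiteFit:
    """Cox proportional-hazards fit with the CpG as the tested covariate.

    Partial-likelihood maximization with Efron tie handling (lifelines).
    Returns the log hazard ratio per 1.0 methylation unit; HR and its 95%
    Wald CI are stored in ``extra``.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    time = np.asarray(time, float)
    event = np.asarray(event, float)
    cpg = np.asarray(cpg, float)
    cols = {"time": time, "event": event, "cpg": cpg}
    if covariates is not None and covariates.size:
        for j in range(covariates.shape[1]):
            name = cov_names[j] if cov_names else f"x{j}"
            cols[name] = covariates[:, j]
    df = pd.DataFrame(cols).dropna()
    n = len(df)
    if df["event"].sum() < 1:
        raise ValueError("no events observed; Cox model undefined")
    if df["cpg"].nunique() < 2:
        return _failed(n, "no variation in methylation")
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="time", event_col="event",
                       fit_options={"precision": 1e-9, "max_steps": 500})
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        return _failed(n, f"non-convergence: {exc}")
    est = float(fitter.params_["cpg"])
    se = float(fitter.standard_errors_["cpg"])
    if not np.isfinite(est) or not np.isfinite(se) or se > 1e4:
        return _failed(n, "monotone likelihood (separation)")
    z = est / se
    pval = 2 * stats.norm.sf(abs(z))
    hr = float(np.exp(est))
    return SiteFit(
        est,
        se,
        float(pval),
        n,
        extra={
            "hr": hr,
            "hr_low": float(np.exp(est - 1.959963984540054 * se)),
            "hr_high": float(np.exp(est + 1.959963984540054 * se)),
            "n_events": int(df["event"].sum()),
        },
    )
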