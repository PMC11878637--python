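"""Bootstrap internal validation of selected differentially methylated sites.

Nonparametric resampling over sampling units (subjects when a repeated-
measures grouping exists, otherwise samples) with full model refits per
replicate, and five two-sided confidence-interval constructions: first-order
normal approximation, basic, studentized, percentile, and BCa (adjusted
percentile), following the standard Davison & Hinkley definitions. A fit
whose interval excludes the null value (0 for regression coefficients, 1
for hazard ratios) is flagged robust.

Determinism: every probe draws from its own seed stream derived from the
master seed and the probe's index, so results are bit-reproducible and
independent of worker count.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from scipy import stats

from .core import MethylationMatrix, ModelSpec, SampleSheet
from .models import build_design, fit_cox_site, fit_glm_site, fit_lmm_site, scale_exposure

CI_TYPES = ("normal", "basic", "studentized", "percentile", "bca")

BOOT_COLUMNS = [
    "probe_id", "original_estimate", "ci_type", "level",
    "lower", "upper", "B", "n_failed", "robust_flag",
]

_CRITERION_RE = re.compile(r"^\s*(p|fdr|bonferroni)\s*<\s*([0-9.eE+-]+)\s*$")
_CRITERION_COLS = {"p": "P-value", "fdr": "FDR", "bonferroni": "Bonferroni"}


def select_sites(dmp_table: pd.DataFrame, criterion) -> list[str]:
    """Select probes for validation by threshold or explicit list.

    ``criterion`` is either a string like ``"bonferroni<0.05"`` (column one
    of p/fdr/bonferroni) or an explicit list of probe IDs (returned
    verbatim). An empty selection raises, advising an explicit list.
    """
    if isinstance(criterion, (list, tuple, pd.Index, np.ndarray)):
        return list(criterion)
    m = _CRITERION_RE.match(str(criterion))
    if not m:
        raise ValueError(
            f"criterion {criterion!r} not understood; use e.g. 'fdr<0.05' or a probe list"
        )
    col, cutoff = _CRITERION_COLS[m.group(1)], float(m.group(2))
    selected = dmp_table.loc[dmp_table[col] < cutoff, "Probe"].tolist()
    if not selected:
        raise ValueError(
            f"no probes satisfy {criterion!r}; pass an explicit probe list instead"
        )
    return selected


def _batched_ols(X: np.ndarray, y: np.ndarray, idx: np.ndarray, j: int):
    """OLS exposure estimate and SE for each row of a replicate index matrix."""
    Xb = X[idx]  # B × n × p
    yb = y[idx]  # B × n
    XtX = np.einsum("bni,bnj->bij", Xb, Xb)
    Xty = np.einsum("bni,bn->bi", Xb, yb)
    B, n, p = Xb.shape
    est = np.full(B, np.nan)
    se = np.full(B, np.nan)
    try:
        beta = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        inv = np.linalg.inv(XtX)
        singular = None
    except np.linalg.LinAlgError:
        beta = np.full((B, p), np.nan)
        inv = np.full((B, p, p), np.nan)
        singular = []
        for b in range(B):
            try:
                beta[b] = np.linalg.solve(XtX[b], Xty[b])
                inv[b] = np.linalg.inv(XtX[b])
            except np.linalg.LinAlgError:
                singular.append(b)
    resid = yb - np.einsum("bni,bi->bn", Xb, beta)
    df = n - p
    sigma2 = np.einsum("bn,bn->b", resid, resid) / df
    with np.errstate(invalid="ignore"):
        est = beta[:, j]
        se = np.sqrt(sigma2 * inv[:, j, j])
    ok = np.isfinite(est) & np.isfinite(se) & (se > 0)
    # constant-outcome replicates: slope 0 by convention, zero-width info
    const = np.ptp(yb, axis=1) == 0
    est[const], se[const] = 0.0, np.nan
    ok |= const
    return est, se, ok


def bootstrap_replicates(
    y: np.ndarray,
    sheet: SampleSheet,
    model_spec: ModelSpec,
    B: int,
    seed,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Draw B bootstrap replicates of one probe's model fit.

    Resampling is with replacement over subjects when ``model_spec`` has a
    grouping variable (preserving repeated-measures structure), otherwise
    over samples. Returns (estimates, per-replicate SEs, n_failed) with
    failed (non-converged / degenerate-design) replicates removed.

    ``seed`` may be an int or a numpy SeedSequence/Generator.
    """
    if B < 100:
        import logging

        logging.getLogger("ewaskit").warning(
            "B=%d is low for interval estimation; 999 recommended", B
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, float)

    if model_spec.model == "coxph":
        time = pd.to_numeric(sheet.column(model_spec.time_var), errors="coerce").to_numpy(float)
        event = pd.to_numeric(sheet.column(model_spec.event_var), errors="coerce").to_numpy(float)
        Xc, cnames, _ = build_design(sheet, None, model_spec.covariates)
        cov, cov_names = Xc[:, 1:], cnames[1:]
        mask = np.isfinite(y) & np.isfinite(time) & np.isfinite(event)
        if cov.size:
            mask &= np.isfinite(cov).all(axis=1)
        n = int(mask.sum())
        yv, tv, ev = y[mask], time[mask], event[mask]
        cv = cov[mask] if cov.size else None
        ests, ses = [], []
        n_failed = 0
        for _ in range(B):
            idx = rng.integers(0, n, n)
            if ev[idx].sum() < 1:
                n_failed += 1
                continue
            fit = fit_cox_site(tv[idx], ev[idx], yv[idx], cv[idx] if cv is not None else None,
                               cov_names)
            if fit.converged:
                ests.append(fit.estimate)
                ses.append(fit.se)
            else:
                n_failed += 1
        return np.asarray(ests), np.asarray(ses), n_failed

    X, _, exp_cols = build_design(sheet, model_spec.exposure, model_spec.covariates)
    if model_spec.scaling != "unit" and not sheet.is_factor(model_spec.exposure):
        for c in exp_cols:
            X[:, c] = scale_exposure(X[:, c], model_spec.scaling)
    j = exp_cols[-1]
    mask = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[mask], X[mask]
    n = y.size

    if model_spec.model == "lmm":
        groups = sheet.column(model_spec.random_group).to_numpy()[mask]
        codes, uniq = pd.factorize(groups)
        rows_of = [np.where(codes == g)[0] for g in range(len(uniq))]
        ests, ses = [], []
        n_failed = 0
        for _ in range(B):
            pick = rng.integers(0, len(uniq), len(uniq))
            idx = np.concatenate([rows_of[g] for g in pick])
            new_groups = np.repeat(np.arange(len(pick)), [rows_of[g].size for g in pick])
            fit = fit_lmm_site(y[idx], X[idx], new_groups, j)
            if fit.converged:
                ests.append(fit.estimate)
                ses.append(fit.se)
            else:
                n_failed += 1
        return np.asarray(ests), np.asarray(ses), n_failed

    idx = rng.integers(0, n, (B, n))
    est, se, ok = _batched_ols(X, y, idx, j)
    return est[ok], se[ok], int(B - ok.sum())


def _jackknife(y: np.ndarray, sheet: SampleSheet, model_spec: ModelSpec) -> np.ndarray:
    """Leave-one-unit-out estimates (for the BCa acceleration constant)."""
    if model_spec.model == "coxph":
        time = pd.to_numeric(sheet.column(model_spec.time_var), errors="coerce").to_numpy(float)
        event = pd.to_numeric(sheet.column(model_spec.event_var), errors="coerce").to_numpy(float)
        Xc, cnames, _ = build_design(sheet, None, model_spec.covariates)
        cov = Xc[:, 1:]
        mask = np.isfinite(y) & np.isfinite(time) & np.isfinite(event)
        n = int(mask.sum())
        yv, tv, ev = y[mask], time[mask], event[mask]
        cv = cov[mask] if cov.size else None
        out = []
        for i in range(n):
            keep = np.arange(n) != i
            fit = fit_cox_site(tv[keep], ev[keep], yv[keep],
                               cv[keep] if cv is not None else None, cnames[1:])
            if fit.converged:
                out.append(fit.estimate)
        return np.asarray(out)

    X, _, exp_cols = build_design(sheet, model_spec.exposure, model_spec.covariates)
    if model_spec.scaling != "unit" and not sheet.is_factor(model_spec.exposure):
        for c in exp_cols:
            X[:, c] = scale_exposure(X[:, c], model_spec.scaling)
    j = exp_cols[-1]
    mask = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[mask], X[mask]
    n = y.size
    if model_spec.model == "lmm":
        groups = sheet.column(model_spec.random_group).to_numpy()[mask]
        codes, uniq = pd.factorize(groups)
        out = []
        for g in range(len(uniq)):
            keep = codes != g
            fit = fit_lmm_site(y[keep], X[keep], codes[keep], j)
            if fit.converged:
                out.append(fit.estimate)
        return np.asarray(out)
    idx = np.stack([np.delete(np.arange(n), i) for i in range(n)])
    est, _, ok = _batched_ols(X, y, idx, j)
    return est[ok]


def compute_ci(
    replicates: np.ndarray,
    original: float,
    ci_type: str,
    level: float = 0.95,
    jackknife: np.ndarray | None = None,
    rep_ses: np.ndarray | None = None,
    se_hat: float | None = None,
) -> tuple[float, float]:
    """One two-sided bootstrap confidence interval.

    Quantiles use linear interpolation throughout. A constant replicate
    vector short-circuits to the degenerate interval [c, c] for every type.
    """
    if ci_type not in CI_TYPES:
        raise ValueError(f"unknown ci_type {ci_type!r}; valid: {list(CI_TYPES)}")
    reps = np.asarray(replicates, float)
    if reps.size == 0:
        raise ValueError("no replicates")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if np.ptp(reps) == 0:
        c = float(reps[0])
        return c, c
    alpha = 1.0 - level
    zq = stats.norm.ppf(1 - alpha / 2)

    if ci_type == "normal":
        center = 2 * original - reps.mean()  # bias-corrected
        sd = reps.std(ddof=1)
        return float(center - zq * sd), float(center + zq * sd)
    if ci_type == "basic":
        qlo, qhi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        return float(2 * original - qhi), float(2 * original - qlo)
    if ci_type == "percentile":
        qlo, qhi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        return float(qlo), float(qhi)
    if ci_type == "studentized":
        if rep_ses is None:
            raise ValueError("studentized interval needs per-replicate SEs")
        ses = np.asarray(rep_ses, float)
        ok = np.isfinite(ses) & (ses > 0)
        if not ok.any():
            raise ValueError("studentized interval undefined: degenerate replicate SEs")
        z = (reps[ok] - original) / ses[ok]
        if se_hat is None or not np.isfinite(se_hat):
            se_hat = reps.std(ddof=1)
        qlo, qhi = np.quantile(z, [alpha / 2, 1 - alpha / 2])
        return float(original - se_hat * qhi), float(original - se_hat * qlo)
    # bca
    prop = np.mean(reps < original)
    prop = min(max(prop, 1.0 / (reps.size + 1)), reps.size / (reps.size + 1.0))
    z0 = stats.norm.ppf(prop)
    a = 0.0
    if jackknife is not None and np.asarray(jackknife).size >= 3:
        jk = np.asarray(jackknife, float)
        d = jk.mean() - jk
        denom = np.sum(d**2) ** 1.5
        if denom > 0:
            a = np.sum(d**3) / (6.0 * denom)
    zlo, zhi = stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)
    a1 = stats.norm.cdf(z0 + (z0 + zlo) / (1 - a * (z0 + zlo)))
    a2 = stats.norm.cdf(z0 + (z0 + zhi) / (1 - a * (z0 + zhi)))
    qlo, qhi = np.quantile(reps, [a1, a2])
    return float(qlo), float(qhi)


def run_bootstrap_validation(
    matrix: MethylationMatrix,
    sheet: SampleSheet,
    model_spec: ModelSpec,
    probes: list[str],
    ci_types: list[str] = ("percentile",),
    B: int = 999,
    level: float = 0.95,
    seed: int = 0,
    max_failed_frac: float = 0.2,
) -> pd.DataFrame:
    """Bootstrap-validate selected probes; one record per (probe, CI type).

    For the Cox model the reported estimate and interval are on the hazard-
    ratio scale (log-HR interval endpoints exponentiated, order preserved).
    ``robust_flag`` marks intervals excluding the null (0, or 1 for HR).
    """
    for ct in ci_types:
        if ct not in CI_TYPES:
            raise ValueError(f"unknown ci_type {ct!r}; valid: {list(CI_TYPES)}")
    missing = [p for p in probes if p not in set(matrix.probe_ids)]
    if missing:
        raise KeyError(f"probes absent from matrix: {missing[:5]}")
    is_cox = model_spec.model == "coxph"
    null_value = 1.0 if is_cox else 0.0

    records = []
    probe_pos = {p: i for i, p in enumerate(matrix.probe_ids)}
    for probe in probes:
        y = matrix.values.loc[probe].to_numpy(float)
        fit = _original_fit(y, sheet, model_spec)
        if not fit.converged:
            raise ValueError(f"original fit failed for {probe}: {fit.reason}")
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), probe_pos[probe]]))
        reps, rep_ses, n_failed = bootstrap_replicates(y, sheet, model_spec, B, rng)
        if B and n_failed / B > max_failed_frac:
            raise ValueError(
                f"probe {probe}: {n_failed}/{B} replicates failed; fit is unstable"
            )
        jk = _jackknife(y, sheet, model_spec) if "bca" in ci_types else None
        for ct in ci_types:
            lo, hi = compute_ci(reps, fit.estimate, ct, level, jk, rep_ses, fit.se)
            if is_cox:
                lo, hi = float(np.exp(lo)), float(np.exp(hi))
                orig = float(np.exp(fit.estimate))
            else:
                orig = fit.estimate
            records.append(
                {
                    "probe_id": probe,
                    "original_estimate": orig,
                    "ci_type": ct,
                    "level": level,
                    "lower": lo,
                    "upper": hi,
                    "B": B,
                    "n_failed": n_failed,
                    "robust_flag": bool(lo > null_value or hi < null_value),
                }
            )
    return pd.DataFrame(records, columns=BOOT_COLUMNS)


def _original_fit(y, sheet, model_spec):
    from .models import SiteFit  # noqa: F401

    if model_spec.model == "coxph":
        time = pd.to_numeric(sheet.column(model_spec.time_var), errors="coerce").to_numpy(float)
        event = pd.to_numeric(sheet.column(model_spec.event_var), errors="coerce").to_numpy(float)
        Xc, cnames, _ = build_design(sheet, None, model_spec.covariates)
        cov = Xc[:, 1:]
        return fit_cox_site(time, event, y, cov if cov.size else None, cnames[1:])
    X, _, exp_cols = build_design(sheet, model_spec.exposure, model_spec.covariates)
    if model_spec.scaling != "unit" and not sheet.is_factor(model_spec.exposure):
        for c in exp_cols:
            X[:, c] = scale_exposure(X[:, c], model_spec.scaling)
    j = exp_cols[-1]
    if model_spec.model == "lmm":
        groups = sheet.column(model_spec.random_group).to_numpy()
        return fit_lmm_site(np.asarray(y, float), X, groups, j)
    return fit_glm_site(np.asarray(y, float), X, j, exp_cols)
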