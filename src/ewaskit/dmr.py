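"""Kernel-smoothed differentially methylated region (DMR) detection.

Pipeline (independent of the per-probe DMP step):

1. moderated per-site statistics — per-CpG OLS effect for the exposure with
   empirical-Bayes variance shrinkage toward a common prior (moment
   matching of the scaled-F distribution of sample variances on the log
   scale, i.e. the classic moderated-t construction);
2. Gaussian kernel smoothing of the squared moderated t along each
   chromosome (kernel SD = bandwidth λ / C);
3. per-site p-values from a scaled chi-square null whose scale and degrees
   of freedom come from Satterthwaite moment matching of the
   kernel-weighted sum of squared statistics, followed by BH-FDR;
4. grouping of consecutive significant sites into regions while the
   inter-site gap stays within λ, with Fisher and Stouffer combined
   p-values per region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import MethylationMatrix, SampleSheet
from .models import adjust_pvalues, build_design, scale_exposure

DMR_COLUMNS = [
    "chrom", "start", "end", "n_cpgs", "min_site_fdr",
    "fisher_p", "stouffer_p", "max_effect", "mean_effect",
]


@dataclass
class DMRParams:
    """Tuning knobs for region calling.

    bandwidth_lambda
        Gap/smoothing scale in base pairs (default 1000, the common
        recommendation for array EWAS); the Gaussian kernel SD is λ/C.
    """

    bandwidth_lambda: float = 1000.0
    scaling_C: float = 2.0
    site_fdr_threshold: float = 0.05
    min_cpgs: int = 2

    def __post_init__(self) -> None:
        if self.bandwidth_lambda <= 0:
            raise ValueError("bandwidth_lambda must be positive")
        if self.min_cpgs < 2:
            raise ValueError("min_cpgs must be >= 2")


def _trigamma_inverse(x: np.ndarray | float) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (vectorised)."""
    x = np.atleast_1d(np.asarray(x, float))
    y = 0.5 + 1.0 / x  # standard starting value
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) / np.maximum(y, 1e-12) < 1e-10):
            break
    return y


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-probe residual variances.

    Fits a scaled-F prior to the observed sample variances by matching the
    mean and variance of log s² (digamma/trigamma moments), then returns
    the posterior variances (d0·s0² + df·s²) / (d0 + df) along with the
    prior df d0 and prior variance s0².
    """
    s2 = np.asarray(s2, float)
    pos = s2 > 0
    if pos.sum() < 2:
        return s2.copy(), 0.0, float(np.nanmean(s2))
    z = np.log(s2[pos])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    n = e.size
    evar = np.sum((e - emean) ** 2) / (n - 1) - special.polygamma(1, df / 2)
    if evar > 0:
        d0 = float(2 * _trigamma_inverse(evar)[0])
        s02 = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
        post = (d0 * s02 + df * s2) / (d0 + df)
    else:
        # dispersion below chi-square sampling noise: shrink completely to
        # the geometric mean of the observed variances (fixed point when
        # all probes share one variance)
        d0 = np.inf
        s02 = float(np.exp(np.mean(z)))
        post = np.full_like(s2, s02)
    post = np.where(pos, post, s02)
    return post, d0, s02


def moderated_site_stats(
    matrix: MethylationMatrix,
    sheet: SampleSheet,
    exposure: str,
    covariates: list[str] | None = None,
    scaling: str = "unit",
    shrink: bool = True,
) -> pd.DataFrame:
    """Per-probe exposure effect with a moderated t statistic.

    Returns a DataFrame indexed by probe with columns ``effect``, ``se``
    (moderated), ``t`` (moderated), ``p``, ``df_total``.
    """
    covariates = list(covariates or [])
    X, names, exp_cols = build_design(sheet, exposure, covariates)
    if scaling != "unit" and not sheet.is_factor(exposure):
        for j in exp_cols:
            X[:, j] = scale_exposure(X[:, j], scaling)
    j = exp_cols[-1]
    Y = matrix.values.to_numpy(float)
    n, p = X.shape
    df = n - p
    if df < 2:
        raise ValueError(f"need >= 2 residual df, have {df}")

    XtX_inv = np.linalg.inv(X.T @ X)
    cjj = XtX_inv[j, j]
    if np.isfinite(Y).all():
        B = XtX_inv @ (X.T @ Y.T)  # p × G
        resid = Y.T - X @ B
        s2 = np.sum(resid**2, axis=0) / df
        effect = B[j]
        dfs = np.full(Y.shape[0], float(df))
        cjjs = np.full(Y.shape[0], cjj)
    else:  # per-probe complete-case fallback
        effect = np.full(Y.shape[0], np.nan)
        s2 = np.full(Y.shape[0], np.nan)
        dfs = np.full(Y.shape[0], np.nan)
        cjjs = np.full(Y.shape[0], np.nan)
        for g in range(Y.shape[0]):
            m = np.isfinite(Y[g])
            Xg, yg = X[m], Y[g, m]
            if m.sum() < p + 2 or np.linalg.matrix_rank(Xg) < p:
                continue
            XtXg = np.linalg.inv(Xg.T @ Xg)
            b = XtXg @ (Xg.T @ yg)
            r = yg - Xg @ b
            dfg = m.sum() - p
            effect[g] = b[j]
            s2[g] = r @ r / dfg
            dfs[g] = dfg
            cjjs[g] = XtXg[j, j]

    valid = np.isfinite(s2)
    df_common = float(np.nanmedian(dfs))
    if shrink and valid.sum() >= 2:
        post, d0, s02 = squeeze_variances(np.where(valid, s2, np.nan)[valid], df_common)
        s2_post = s2.copy()
        s2_post[valid] = post
    else:
        s2_post, d0, s02 = s2, 0.0, float(np.nanmean(s2))
    df_total = dfs + (d0 if np.isfinite(d0) else 1e12)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_post * cjjs)
        t = effect / se
    pvals = 2 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {"effect": effect, "se": se, "t": t, "p": pvals, "df_total": df_total},
        index=matrix.values.index,
    )
    out.attrs["d0"] = d0
    out.attrs["s02"] = s02
    return out


def gaussian_smooth(
    positions: np.ndarray, values: np.ndarray, params: DMRParams
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel-smooth per-site statistics along one chromosome.

    Weights ∝ exp(−Δ² / 2σ²) with σ = λ/C, renormalised to sum to one at
    each site; contributions beyond 5σ are truncated. Returns the smoothed
    values and the effective sum of squared weights per site (needed for
    the Satterthwaite null downstream).
    """
    positions = np.asarray(positions, float)
    values = np.asarray(values, float)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing within a chromosome")
    sigma = params.bandwidth_lambda / params.scaling_C
    cutoff = 5.0 * sigma
    smoothed = np.empty_like(values)
    w2 = np.empty_like(values)
    lo = np.searchsorted(positions, positions - cutoff, side="left")
    hi = np.searchsorted(positions, positions + cutoff, side="right")
    for i in range(positions.size):
        d = positions[lo[i]:hi[i]] - positions[i]
        w = np.exp(-(d**2) / (2 * sigma**2))
        w /= w.sum()
        smoothed[i] = w @ values[lo[i]:hi[i]]
        w2[i] = np.sum(w**2)
    return smoothed, w2


def site_significance(smoothed: np.ndarray, w2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site p and BH-FDR for kernel-smoothed squared statistics.

    Under the null each squared statistic is ≈ χ²₁, so the weighted mean
    S = Σ wⱼ tⱼ² has E[S] = 1 and Var[S] = 2 Σ wⱼ². Satterthwaite matching
    gives S ~ (1/k)·χ²ₖ with k = 1/Σ wⱼ²; a single isolated site (w² = 1)
    collapses to the plain χ²₁ tail of its own t².
    """
    smoothed = np.asarray(smoothed, float)
    if np.nanmin(smoothed) < 0:
        raise ValueError("smoothed squared statistics must be nonnegative")
    k = 1.0 / np.asarray(w2, float)
    p = stats.chi2.sf(smoothed * k, k)
    fdr = adjust_pvalues(p, "bh")
    return p, fdr


def group_regions(sites: pd.DataFrame, params: DMRParams) -> pd.DataFrame:
    """Merge significant sites into regions by the gap rule.

    ``sites`` needs columns chrom, pos, p, fdr, effect, sorted by
    (chrom, pos). Consecutive significant sites on one chromosome join the
    same region while the gap to the previous member is ≤ λ; regions with
    fewer than ``min_cpgs`` members are dropped. Fisher (−2Σlog p against
    χ²₂ₖ) and Stouffer (Σz/√k) combine the member-site p-values.

    Kernel leakage guard: smoothing correlates neighbouring sites, so a
    single strong null site can drag its neighbours over the FDR line and
    fabricate a 2-site region. When a ``raw_fdr`` column is present
    (BH-adjusted p of the *unsmoothed* per-site statistics), a region is
    kept only if at least ``min_cpgs`` of its members are also raw-
    significant at the same threshold — independent evidence that the
    signal is not one site's spillover.
    """
    sig = sites[sites["fdr"] < params.site_fdr_threshold]
    records = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        breaks = np.where(np.diff(pos) > params.bandwidth_lambda)[0]
        bounds = np.concatenate([[0], breaks + 1, [len(pos)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            member = grp.iloc[a:b]
            k = len(member)
            if k < params.min_cpgs:
                continue
            if "raw_fdr" in member.columns:
                n_raw = int((member["raw_fdr"] < params.site_fdr_threshold).sum())
                if n_raw < params.min_cpgs:
                    continue
            pv = np.clip(member["p"].to_numpy(), 1e-300, 1.0)
            fisher_stat = -2.0 * np.sum(np.log(pv))
            fisher_p = stats.chi2.sf(fisher_stat, 2 * k)
            z = stats.norm.isf(pv)  # large z for small p
            stouffer_p = stats.norm.sf(np.sum(z) / np.sqrt(k))
            eff = member["effect"].to_numpy()
            records.append(
                {
                    "chrom": chrom,
                    "start": int(member["pos"].iloc[0]),
                    "end": int(member["pos"].iloc[-1]),
                    "n_cpgs": k,
                    "min_site_fdr": float(member["fdr"].min()),
                    "fisher_p": float(fisher_p),
                    "stouffer_p": float(stouffer_p),
                    "max_effect": float(eff[np.argmax(np.abs(eff))]),
                    "mean_effect": float(eff.mean()),
                }
            )
    return pd.DataFrame(records, columns=DMR_COLUMNS)


def run_dmr(
    matrix: MethylationMatrix,
    sheet: SampleSheet,
    exposure: str,
    annotation: pd.DataFrame,
    covariates: list[str] | None = None,
    params: DMRParams | None = None,
    scaling: str = "unit",
) -> pd.DataFrame:
    """Full region-calling pipeline; returns regions sorted by Fisher p."""
    params = params or DMRParams()
    stats_df = moderated_site_stats(matrix, sheet, exposure, covariates, scaling=scaling)
    ann = annotation.loc[annotation.index.intersection(stats_df.index)]
    if ann.empty:
        raise ValueError("no probes have annotation coordinates; cannot call regions")
    merged = stats_df.join(ann[["chrom", "pos"]], how="inner").dropna(subset=["t", "pos"])
    merged = merged.sort_values(["chrom", "pos"], kind="mergesort")
    # duplicate-position probes: average their statistics before smoothing
    merged = (
        merged.groupby(["chrom", "pos"], sort=False, as_index=False)
        .agg(effect=("effect", "mean"), t=("t", "mean"), raw_p=("p", "mean"))
    )
    merged["raw_fdr"] = adjust_pvalues(merged["raw_p"].to_numpy(), "bh")
    parts = []
    for chrom, grp in merged.groupby("chrom", sort=True):
        smoothed, w2 = gaussian_smooth(grp["pos"].to_numpy(), grp["t"].to_numpy() ** 2, params)
        p, _ = site_significance(smoothed, w2)
        part = grp.copy()
        part["p"] = p
        parts.append(part)
    sites = pd.concat(parts, ignore_index=True)
    sites["fdr"] = adjust_pvalues(sites["p"].to_numpy(), "bh")  # BH across all sites
    sites = sites.sort_values(["chrom", "pos"], kind="mergesort")
    regions = group_regions(sites, params)
    regions = regions.sort_values("fisher_p", kind="mergesort").reset_index(drop=True)
    return regions
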