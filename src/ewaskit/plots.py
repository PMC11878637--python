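"""Manhattan, QQ (with genomic inflation λ) and CpG density plots.

λ uses the median-χ²₁ definition: the median of the observed association
χ² statistics (obtained from the p-values) divided by the χ²₁ median
(≈ 0.4549); λ ≈ 1 indicates a calibrated test statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("ewaskit")

_CHROM_ORDER = [str(i) for i in range(1, 23)] + ["X", "Y"]

#: −log10(p) display ceiling; avoids overflow for p underflowing to 0.
LOG10P_CAP = 300.0


@dataclass
class PlotConfig:
    layout: str = "rectangular"
    alpha: float = 0.05
    draw_bonferroni_line: bool = True
    draw_fdr_line: bool = False
    dpi: int = 150

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.layout not in ("rectangular", "circular"):
            raise ValueError("layout must be 'rectangular' or 'circular'")


def _neglog10(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        v = -np.log10(np.clip(p, 0, 1))
    return np.minimum(v, LOG10P_CAP)


def _chrom_sort_key(c: str) -> int:
    c = str(c)
    return _CHROM_ORDER.index(c) if c in _CHROM_ORDER else len(_CHROM_ORDER)


def genomic_lambda(p: np.ndarray) -> float:
    """Genomic inflation factor from a vector of p-values."""
    p = np.asarray(p, float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    if p.size < 100:
        logger.warning("genomic lambda from only %d p-values; estimate is unstable", p.size)
    chisq = stats.chi2.isf(p, 1)
    return float(np.median(chisq) / stats.chi2.ppf(0.5, 1))


def manhattan_plot(dmp_table: pd.DataFrame, path: str | Path,
                   config: PlotConfig | None = None) -> Path:
    """Manhattan plot of −log10(p) by genomic position (rect or circular)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    config = config or PlotConfig()
    df = dmp_table[["Probe", "P-value", "CHR", "Position"]].copy()
    n_total = len(df)
    df = df[df["P-value"].notna()]
    if df.empty:
        raise ValueError("no probes with p-values to plot")
    df = df[df["Position"].notna() & (df["CHR"].astype(str) != "/")]
    skipped = n_total - len(df)
    if skipped:
        logger.warning("manhattan_plot: skipped %d probe(s) without coordinates", skipped)
    if df.empty:
        raise ValueError("no probes with genomic coordinates to plot")
    df["CHR"] = df["CHR"].astype(str)
    df["key"] = df["CHR"].map(_chrom_sort_key)
    df = df.sort_values(["key", "Position"], kind="mergesort")
    df["logp"] = _neglog10(df["P-value"].to_numpy())
    m = df["P-value"].notna().sum()
    gw_line = -np.log10(config.alpha / m)

    chroms = df["CHR"].unique().tolist()
    offsets, ticks = {}, []
    cum = 0.0
    for c in chroms:
        span = df.loc[df["CHR"] == c, "Position"].max()
        offsets[c] = cum
        ticks.append(cum + span / 2)
        cum += span * 1.05
    x = df["Position"].to_numpy(float) + df["CHR"].map(offsets).to_numpy(float)

    if config.layout == "rectangular":
        fig, ax = plt.subplots(figsize=(10, 4))
        for i, c in enumerate(chroms):
            sel = df["CHR"] == c
            ax.scatter(x[sel.to_numpy()], df.loc[sel, "logp"], s=4,
                       color=["#4477aa", "#66ccee"][i % 2])
        if config.draw_bonferroni_line:
            ax.axhline(gw_line, color="red", ls="--", lw=0.8)
        ax.set_xticks(ticks)
        ax.set_xticklabels(chroms, fontsize=7)
        ax.set_xlabel("chromosome")
        ax.set_ylabel(r"$-\log_{10}(p)$")
    else:  # circular: chromosomes as arcs with 2-degree gaps
        fig = plt.figure(figsize=(6, 6))
        ax = fig.add_subplot(projection="polar")
        gap = np.deg2rad(2.0)
        total = cum
        avail = 2 * np.pi - gap * len(chroms)
        theta0 = 0.0
        for i, c in enumerate(chroms):
            span = df.loc[df["CHR"] == c, "Position"].max()
            width = avail * (span * 1.05) / total
            theta = theta0 + (df.loc[df["CHR"] == c, "Position"].to_numpy() / span) * width
            ax.scatter(theta, 1.0 + df.loc[df["CHR"] == c, "logp"], s=3,
                       color=["#4477aa", "#66ccee"][i % 2])
            theta0 += width + gap
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=config.dpi)
    plt.close(fig)
    return Path(path)


def qq_plot(dmp_table: pd.DataFrame, path: str | Path,
            config: PlotConfig | None = None) -> tuple[Path, float]:
    """Observed vs expected −log10(p) under the uniform null; returns λ."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    config = config or PlotConfig()
    p = dmp_table["P-value"].to_numpy(float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values to plot")
    lam = genomic_lambda(p)
    obs = np.sort(_neglog10(p))[::-1]
    exp = _neglog10((np.arange(1, p.size + 1) - 0.5) / p.size)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(exp, obs, s=4, color="#4477aa")
    lim = max(exp.max(), obs.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="grey", lw=0.8)
    ax.set_xlabel(r"expected $-\log_{10}(p)$")
    ax.set_ylabel(r"observed $-\log_{10}(p)$")
    ax.set_title(f"$\\lambda$ = {lam:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=config.dpi)
    plt.close(fig)
    return Path(path), lam


def density_bins(annotation: pd.DataFrame, window_bp: int = 1_000_000) -> pd.DataFrame:
    """Per-chromosome probe counts in fixed windows (pure helper)."""
    rows = []
    for chrom, grp in annotation.groupby("chrom"):
        pos = grp["pos"].to_numpy(float)
        n_bins = int(np.floor(pos.max() / window_bp)) + 1
        counts, _ = np.histogram(pos, bins=n_bins, range=(0, n_bins * window_bp))
        for b, cnt in enumerate(counts):
            rows.append({"chrom": str(chrom), "bin": b, "count": int(cnt)})
    return pd.DataFrame(rows)


def cpg_density_plot(annotation: pd.DataFrame, path: str | Path,
                     window_bp: int = 1_000_000, dpi: int = 150) -> Path:
    """Probe density per chromosome as a heat track."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if annotation.empty:
        raise ValueError("no annotated probes")
    bins = density_bins(annotation, window_bp)
    chroms = sorted(bins["chrom"].unique(), key=_chrom_sort_key)
    fig, ax = plt.subplots(figsize=(10, 0.4 * len(chroms) + 1.2))
    vmax = max(bins["count"].max(), 1)
    for i, c in enumerate(chroms):
        sub = bins[bins["chrom"] == c]
        ax.scatter(sub["bin"], np.full(len(sub), i), c=sub["count"], cmap="YlOrRd",
                   vmin=0, vmax=vmax, marker="s", s=28)
    ax.set_yticks(range(len(chroms)))
    ax.set_yticklabels(chroms, fontsize=7)
    ax.set_xlabel(f"window ({window_bp:,} bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return Path(path)
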