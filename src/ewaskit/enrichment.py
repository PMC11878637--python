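"""Gene-set over-representation analysis for differentially methylated genes.

Significant probes are mapped to their annotated genes and tested against
user-supplied GMT gene-set collections (GO- or KEGG-style) with the upper
hypergeometric tail, BH-adjusted across terms. The sampling frame is the
set of genes annotated on the analyzed array, not the whole genome.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import UNASSIGNED
from .bootstrap import select_sites
from .models import adjust_pvalues

logger = logging.getLogger("ewaskit")

ENRICH_COLUMNS = ["term_id", "term_name", "k", "K", "n", "N", "p", "adj_p", "hit_genes"]


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """Parse a GMT file: one set per line (id, description, member genes)."""
    sets: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = (parts[1], {g for g in parts[2:] if g})
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return sets


def map_sites_to_genes(dmp_table: pd.DataFrame, criterion) -> tuple[set[str], set[str]]:
    """Map selected probes and the whole array to gene sets.

    Returns (significant genes, universe genes); probes unassigned to any
    gene ("/") contribute nothing, and duplicates collapse.
    """
    probes = select_sites(dmp_table, criterion)
    sub = dmp_table[dmp_table["Probe"].isin(set(probes))]
    sig = {g for g in sub["Gene"].astype(str) if g and g != UNASSIGNED and g != "nan"}
    universe = {
        g for g in dmp_table["Gene"].astype(str) if g and g != UNASSIGNED and g != "nan"
    }
    if not sig:
        raise ValueError("selected probes map to no named genes")
    return sig, universe


def overrepresentation_test(
    sig_genes: set[str],
    universe: set[str],
    gene_sets: dict[str, tuple[str, set[str]]],
    min_size: int = 10,
    max_size: int = 500,
) -> pd.DataFrame:
    """Hypergeometric over-representation across a gene-set collection.

    For each term with K universe genes, of which k are among the n
    significant genes drawn from a universe of N, p = P(X ≥ k) under
    Hypergeometric(N, K, n). BH adjustment across tested terms; sorted by
    adjusted p.
    """
    if not gene_sets:
        raise ValueError("empty gene-set collection")
    stray = sig_genes - universe
    if stray:
        logger.warning("dropping %d significant gene(s) outside the universe", len(stray))
        sig_genes = sig_genes & universe
    N = len(universe)
    n = len(sig_genes)
    rows = []
    for term_id, (term_name, members) in gene_sets.items():
        in_universe = members & universe
        K = len(in_universe)
        if not min_size <= K <= max_size:
            continue
        hits = sorted(in_universe & sig_genes)
        k = len(hits)
        # upper tail P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term_id": term_id, "term_name": term_name, "k": k, "K": K,
             "n": n, "N": N, "p": p, "hit_genes": ";".join(hits)}
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    out["adj_p"] = adjust_pvalues(out["p"].to_numpy(), "bh")
    out = out.sort_values(["adj_p", "p", "term_id"], kind="mergesort").reset_index(drop=True)
    return out[ENRICH_COLUMNS]


def enrichment_plot(table: pd.DataFrame, path: str | Path, kind: str = "bubble",
                    top_n: int = 20):
    """Bubble or bar plot of the top enriched terms, written to ``path``.

    Bubble: x = gene ratio k/n, size = k, colour = adjusted p. Bar:
    −log10(adjusted p) per term.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if kind not in ("bubble", "bar"):
        raise ValueError(f"unknown plot kind {kind!r}; use 'bubble' or 'bar'")
    if table.empty:
        raise ValueError("cannot plot an empty enrichment table")
    top = table.nsmallest(min(top_n, len(table)), "adj_p").iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, max(2.5, 0.35 * len(top))))
    labels = top["term_name"].where(top["term_name"].astype(bool), top["term_id"])
    if kind == "bubble":
        ratio = top["k"] / top["n"]
        sc = ax.scatter(ratio, np.arange(len(top)), s=30 + 25 * top["k"],
                        c=top["adj_p"], cmap="viridis_r")
        fig.colorbar(sc, ax=ax, label="adjusted p")
        ax.set_xlabel("gene ratio (k / n)")
    else:
        ax.barh(np.arange(len(top)), -np.log10(np.clip(top["adj_p"], 1e-300, 1.0)),
                color="#4477aa")
        ax.set_xlabel("-log10 adjusted p")
    ax.set_yticks(np.arange(len(top)))
    ax.set_yticklabels(labels, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
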