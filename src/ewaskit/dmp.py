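"""Differentially methylated position (DMP) analysis across a matrix.

Fits the chosen per-site model at every probe, applies both Bonferroni and
Benjamini–Hochberg corrections, merges probe annotation, and returns one
record per probe in input order. Worker count never changes the output:
probes are partitioned into contiguous chunks and reassembled by index.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .core import UNASSIGNED, MethylationMatrix, ModelSpec, SampleSheet
from .models import (
    SiteFit,
    adjust_pvalues,
    build_design,
    fit_cox_site,
    fit_glm_site,
    fit_lmm_site,
    scale_exposure,
)

logger = logging.getLogger("ewaskit")

#: Result-table column names (annotation block mirrors standard EWAS output).
DMP_COLUMNS = [
    "Probe",
    "Coefficient",
    "SE",
    "P-value",
    "FDR",
    "Bonferroni",
    "N",
    "Converged",
    "CHR",
    "Position",
    "Relation to island",
    "Gene",
    "Location",
]
COX_COLUMNS = ["HR", "HR 95% CI lower", "HR 95% CI upper"]


def _prepare_glm_lmm(matrix: MethylationMatrix, sheet: SampleSheet, spec: ModelSpec):
    X, names, exp_cols = build_design(sheet, spec.exposure, spec.covariates)
    if spec.scaling != "unit" and not sheet.is_factor(spec.exposure):
        for j in exp_cols:
            X[:, j] = scale_exposure(X[:, j], spec.scaling)
    elif spec.scaling != "unit":
        logger.warning("scaling %r ignored for factor exposure %r", spec.scaling, spec.exposure)
    exposure_idx = exp_cols[-1]  # last level vs reference for factors
    groups = None
    if spec.model == "lmm":
        groups = sheet.column(spec.random_group).to_numpy()
    return X, names, exp_cols, exposure_idx, groups


def _fit_chunk(Y: np.ndarray, spec_model: str, X, exp_cols, exposure_idx, groups,
               time, event, cov, cov_names) -> list[SiteFit]:
    fits = []
    for row in Y:
        if spec_model == "glm":
            fits.append(fit_glm_site(row, X, exposure_idx, exp_cols))
        elif spec_model == "lmm":
            fits.append(fit_lmm_site(row, X, groups, exposure_idx))
        else:
            fits.append(fit_cox_site(time, event, row, cov, cov_names))
    return fits


def run_dmp(
    matrix: MethylationMatrix,
    sheet: SampleSheet,
    model_spec: ModelSpec,
    annotation: pd.DataFrame | None = None,
    n_workers: int = 1,
) -> pd.DataFrame:
    """Run per-CpG association tests for every probe in the matrix.

    Returns a DataFrame with one row per probe (input order), the exposure
    coefficient (log hazard ratio for ``coxph``) with SE and Wald p, FDR
    and Bonferroni columns, sample counts, and merged annotation. For the
    Cox model HR and its 95% CI are appended.
    """
    if list(matrix.sample_ids) != list(sheet.sample_ids):
        raise ValueError("matrix and sheet must be aligned before DMP analysis")
    Y = matrix.values.to_numpy(float)
    n_probes = Y.shape[0]

    time = event = cov = cov_names = None
    X = exp_cols = exposure_idx = groups = None
    if model_spec.model in ("glm", "lmm"):
        X, names, exp_cols, exposure_idx, groups = _prepare_glm_lmm(matrix, sheet, model_spec)
    else:
        time = pd.to_numeric(sheet.column(model_spec.time_var), errors="coerce").to_numpy(float)
        event = pd.to_numeric(sheet.column(model_spec.event_var), errors="coerce").to_numpy(float)
        if not set(np.unique(event[np.isfinite(event)])) <= {0.0, 1.0}:
            raise ValueError(f"event indicator {model_spec.event_var!r} must be 0/1")
        if np.nansum(event) < 1:
            raise ValueError("no events in the sample sheet; Cox analysis undefined")
        Xc, cnames, _ = build_design(sheet, None, model_spec.covariates)
        cov, cov_names = Xc[:, 1:], cnames[1:]
        if model_spec.scale_cpg:
            Y = np.apply_along_axis(
                lambda r: scale_exposure(r, "sd") if np.nanstd(r) > 0 else r, 1, Y
            )

    n_workers = max(1, int(n_workers))
    chunks = np.array_split(np.arange(n_probes), min(n_workers, max(n_probes, 1)) or 1)
    chunks = [c for c in chunks if c.size]
    if n_workers == 1 or len(chunks) <= 1:
        fit_lists = [
            _fit_chunk(Y[c], model_spec.model, X, exp_cols, exposure_idx, groups,
                       time, event, cov, cov_names)
            for c in chunks
        ]
    else:
        fit_lists = Parallel(n_jobs=n_workers)(
            delayed(_fit_chunk)(Y[c], model_spec.model, X, exp_cols, exposure_idx, groups,
                                time, event, cov, cov_names)
            for c in chunks
        )
    fits: list[SiteFit] = [f for sub in fit_lists for f in sub]

    n_bad = sum(not f.converged for f in fits)
    if n_probes and n_bad / n_probes > 0.5:
        reasons = pd.Series([f.reason for f in fits if not f.converged]).value_counts()
        logger.warning(
            "run_dmp: %d/%d probes failed to converge; reasons: %s",
            n_bad, n_probes, reasons.to_dict(),
        )

    table = pd.DataFrame(
        {
            "Probe": matrix.probe_ids,
            "Coefficient": [f.estimate for f in fits],
            "SE": [f.se for f in fits],
            "P-value": [f.p for f in fits],
            "N": [f.n_used for f in fits],
            "Converged": [f.converged for f in fits],
        }
    )
    table["FDR"] = adjust_pvalues(table["P-value"].to_numpy(), "bh")
    table["Bonferroni"] = adjust_pvalues(table["P-value"].to_numpy(), "bonferroni")

    if model_spec.model == "coxph":
        table["HR"] = [f.extra.get("hr", np.nan) for f in fits]
        table["HR 95% CI lower"] = [f.extra.get("hr_low", np.nan) for f in fits]
        table["HR 95% CI upper"] = [f.extra.get("hr_high", np.nan) for f in fits]

    # auxiliary per-level contrasts for multi-level factor exposures
    if exp_cols and len(exp_cols) > 1:
        _, names, _ = build_design(sheet, model_spec.exposure, model_spec.covariates)
        for j in exp_cols:
            key = f"col{j}"
            table[f"Coefficient {names[j]}"] = [f.contrasts.get(key, (np.nan,) * 3)[0] for f in fits]
            table[f"P-value {names[j]}"] = [f.contrasts.get(key, (np.nan,) * 3)[2] for f in fits]

    ann_cols = {"chrom": "CHR", "pos": "Position", "island_relation": "Relation to island",
                "gene": "Gene", "location": "Location"}
    if annotation is not None:
        ann = annotation.rename(columns=ann_cols)[list(ann_cols.values())]
        table = table.merge(ann, left_on="Probe", right_index=True, how="left")
        for col in ("Relation to island", "Gene", "Location", "CHR"):
            table[col] = table[col].fillna(UNASSIGNED)
    else:
        for col in ann_cols.values():
            table[col] = UNASSIGNED if col != "Position" else np.nan

    ordered = [c for c in DMP_COLUMNS if c in table.columns]
    rest = [c for c in table.columns if c not in ordered]
    table = table[ordered + rest]
    table.attrs["model"] = model_spec.model
    table.attrs["value_type"] = matrix.value_type
    table.attrs["scaling"] = model_spec.scaling
    return table
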