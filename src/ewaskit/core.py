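"""Core data model for methylation association analysis.

Containers for the probes × samples methylation matrix, the per-sample
phenotype sheet, probe annotation, and the model specification, together
with delimited-text readers/writers and the β ↔ M value transform.

β-values are bounded methylated-signal fractions in [0, 1]; M-values are
their logit2, M = log2(β / (1 − β)), which is unbounded and closer to
homoscedastic — most linear modelling is better behaved on the M scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ewaskit")

VALUE_TYPES = ("beta", "m")

#: Supported Illumina-style array platforms and their reference genome build.
PLATFORMS = {
    "27K": "hg19",
    "450K": "hg19",
    "EPICv1": "hg19",
    "EPICv2": "hg38",
    "MSA": "hg38",
}

#: Gene/location placeholder for probes not assigned to any gene.
UNASSIGNED = "/"

ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

# Manifest column synonyms, per platform family. Illumina manifests use
# slightly different headers across array generations; all map onto the
# same internal schema.
_MANIFEST_COLUMNS = {
    "probe_id": ("IlmnID", "Name", "probe_id", "Probe", "ID"),
    "chrom": ("CHR", "Chromosome", "chrom", "chr"),
    "pos": ("MAPINFO", "Position", "pos", "Coordinate"),
    "gene": ("UCSC_RefGene_Name", "Gene", "gene"),
    "location": ("UCSC_RefGene_Group", "Location", "location", "Feature"),
    "island_relation": (
        "Relation_to_UCSC_CpG_Island",
        "Relation_to_Island",
        "island_relation",
        "Relation to island",
    ),
}

# Clipping constant for β ∈ {0, 1} before the logit2 transform.
BETA_CLIP = 1e-6


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a delimited or columnar table by extension (.csv/.tsv/.txt/.parquet)."""
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, **kwargs)


def _write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    path = Path(path)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=index)
        return
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep, index=index)


@dataclass
class MethylationMatrix:
    """Probes × samples methylation matrix with a declared value scale.

    Parameters
    ----------
    values
        DataFrame indexed by probe ID with one column per sample ID.
    value_type
        Either ``"beta"`` (values in [0, 1]) or ``"m"`` (unbounded logit2).
    """

    values: pd.DataFrame
    value_type: str = "beta"

    def __post_init__(self) -> None:
        if self.value_type not in VALUE_TYPES:
            raise ValueError(f"value_type must be one of {VALUE_TYPES}, got {self.value_type!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe IDs: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        self.values = self.values.astype(float)
        if self.value_type == "beta":
            arr = self.values.to_numpy()
            bad = (arr < 0) | (arr > 1)
            bad &= np.isfinite(arr)
            if bad.any():
                probe = self.values.index[np.where(bad.any(axis=1))[0][0]]
                raise ValueError(
                    f"beta values must lie in [0, 1]; probe {probe!r} violates the bound"
                )

    @property
    def probe_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_mvalues(self) -> "MethylationMatrix":
        if self.value_type == "m":
            return self
        return MethylationMatrix(
            pd.DataFrame(
                beta_m_convert(self.values.to_numpy(), "beta_to_m"),
                index=self.values.index,
                columns=self.values.columns,
            ),
            value_type="m",
        )

    def to_betavalues(self) -> "MethylationMatrix":
        if self.value_type == "beta":
            return self
        return MethylationMatrix(
            pd.DataFrame(
                beta_m_convert(self.values.to_numpy(), "m_to_beta"),
                index=self.values.index,
                columns=self.values.columns,
            ),
            value_type="beta",
        )

    def save(self, path: str | Path) -> None:
        _write_table(self.values, path)


@dataclass
class FactorType:
    """Factor variable with an explicit level order and reference level."""

    levels: list[str]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.levels:
            raise ValueError(f"reference {self.reference!r} not among levels {self.levels}")


@dataclass
class SampleSheet:
    """Per-sample phenotype and covariate table keyed by sample ID.

    Columns are plain numeric/string as read; ``convert_variable_types``
    assigns explicit factor codings (level order = first appearance,
    reference = first level unless overridden).
    """

    data: pd.DataFrame
    factors: dict[str, FactorType] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def variables(self) -> list[str]:
        return self.data.columns.tolist()

    def __len__(self) -> int:
        return len(self.data)

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"variable {name!r} not in sample sheet (have {self.variables})")
        return self.data[name]

    def is_factor(self, name: str) -> bool:
        return name in self.factors

    def save(self, path: str | Path) -> None:
        _write_table(self.data, path)


@dataclass
class ModelSpec:
    """Specification of one per-CpG association model.

    model
        ``"glm"`` — ordinary least squares of methylation on exposure +
        covariates; ``"lmm"`` — adds a random intercept per subject
        (repeated measures); ``"coxph"`` — Cox proportional hazards with
        the CpG methylation itself as the tested hazard covariate.
    scaling
        Exposure scaling: ``unit`` (as is), ``iqr`` (per interquartile
        range), ``sd`` (per sample standard deviation).
    """

    model: str
    exposure: str | None = None
    covariates: list[str] = field(default_factory=list)
    scaling: str = "unit"
    random_group: str | None = None
    time_var: str | None = None
    event_var: str | None = None
    scale_cpg: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("glm", "lmm", "coxph"):
            raise ValueError(f"model must be glm, lmm or coxph, got {self.model!r}")
        if self.scaling not in ("unit", "iqr", "sd"):
            raise ValueError(f"scaling must be unit, iqr or sd, got {self.scaling!r}")
        if self.model == "lmm" and not self.random_group:
            raise ValueError("lmm requires random_group (subject identifier variable)")
        if self.model == "coxph":
            if not (self.time_var and self.event_var):
                raise ValueError("coxph requires time_var and event_var")
            if self.exposure is not None:
                raise ValueError(
                    "coxph takes the CpG itself as the tested covariate; do not set exposure"
                )
        elif self.exposure is None:
            raise ValueError(f"{self.model} requires an exposure variable")


def load_methylation_matrix(path: str | Path, value_type: str = "beta") -> MethylationMatrix:
    """Load a probes × samples matrix from CSV/TSV/parquet.

    The first column holds probe IDs; every remaining column is one
    sample. Non-numeric cells are parsed as missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_table(path, index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce")
    df.index = df.index.astype(str)
    return MethylationMatrix(df, value_type=value_type)


def load_sample_sheet(path: str | Path) -> SampleSheet:
    """Load a sample sheet; first column is the sample ID key.

    Columns are typed as read: numeric where fully parseable, string
    otherwise. Use :func:`convert_variable_types` afterwards to declare
    factors and force numeric conversions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = _read_table(path, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty sample sheet: {path}") from exc
    if df.empty and df.columns.empty:
        raise ValueError(f"empty sample sheet: {path}")
    df.index = df.index.astype(str)
    return SampleSheet(df)


def convert_variable_types(sheet: SampleSheet, spec: Mapping[str, str | dict]) -> SampleSheet:
    """Convert sample-sheet variables to declared types.

    ``spec`` maps variable name → ``"numeric"`` | ``"factor"`` | a dict
    ``{"type": "factor", "reference": level}``. Factor levels are recorded
    in first-appearance order; the reference level defaults to the first.
    """
    data = sheet.data.copy()
    factors = dict(sheet.factors)
    for name, ty in spec.items():
        if name not in data.columns:
            raise KeyError(f"variable {name!r} not in sample sheet")
        reference = None
        if isinstance(ty, dict):
            reference = ty.get("reference")
            ty = ty["type"]
        if ty == "numeric":
            converted = pd.to_numeric(data[name], errors="coerce")
            bad = converted.isna() & data[name].notna()
            if bad.any():
                offenders = data.loc[bad, name].unique().tolist()
                raise ValueError(
                    f"cannot convert {name!r} to numeric; offending values: {offenders[:5]}"
                )
            data[name] = converted
            factors.pop(name, None)
        elif ty == "factor":
            col = data[name].astype(str)
            levels = list(dict.fromkeys(col.tolist()))  # first-appearance order
            ref = reference if reference is not None else levels[0]
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not observed in {name!r}")
            data[name] = col
            factors[name] = FactorType(levels=levels, reference=ref)
        else:
            raise ValueError(f"unknown target type {ty!r} for {name!r}")
    return SampleSheet(data, factors)


def align_samples(
    matrix: MethylationMatrix, sheet: SampleSheet
) -> tuple[MethylationMatrix, SampleSheet]:
    """Restrict matrix and sheet to their common samples, in sheet order."""
    common = [s for s in sheet.sample_ids if s in set(matrix.sample_ids)]
    if not common:
        raise ValueError("no common sample IDs between matrix and sample sheet")
    dropped = sorted(set(matrix.sample_ids).symmetric_difference(sheet.sample_ids))
    if dropped:
        logger.warning("align_samples: dropping %d unmatched sample(s): %s", len(dropped), dropped)
    mat = MethylationMatrix(matrix.values[common], value_type=matrix.value_type)
    sh = SampleSheet(sheet.data.loc[common], dict(sheet.factors))
    return mat, sh


def beta_m_convert(x, direction: str):
    """Convert between β-values and M-values, elementwise.

    M = log2(β / (1 − β)); β = 2^M / (1 + 2^M). β values of exactly 0 or 1
    are clipped to [1e-6, 1 − 1e-6] so the logit stays finite.
    """
    arr = np.asarray(x, dtype=float)
    if direction == "beta_to_m":
        finite = np.isfinite(arr)
        if ((arr[finite] < 0) | (arr[finite] > 1)).any():
            raise ValueError("beta values must lie in [0, 1]")
        if ((arr[finite] <= 0) | (arr[finite] >= 1)).any():
            logger.warning("beta values at 0/1 clipped to [%g, %g] before M conversion",
                           BETA_CLIP, 1 - BETA_CLIP)
        clipped = np.clip(arr, BETA_CLIP, 1 - BETA_CLIP)
        out = np.log2(clipped / (1 - clipped))
    elif direction == "m_to_beta":
        out = 1.0 / (1.0 + np.power(2.0, -arr))
    else:
        raise ValueError("direction must be 'beta_to_m' or 'm_to_beta'")
    return out if np.ndim(x) else float(out)


def load_annotation(path: str | Path, platform: str) -> pd.DataFrame:
    """Load a probe annotation manifest into the internal schema.

    Returns a DataFrame indexed by probe ID with columns ``chrom``, ``pos``
    (1-based, Illumina convention), ``gene``, ``location``,
    ``island_relation`` and ``platform``. Probes without coordinates are
    dropped (count logged); empty gene/location entries are marked ``"/"``.
    """
    if platform not in PLATFORMS:
        raise ValueError(
            f"unknown platform {platform!r}; supported: {sorted(PLATFORMS)}"
        )
    raw = _read_table(path)
    resolved: dict[str, str] = {}
    for field_name, synonyms in _MANIFEST_COLUMNS.items():
        for cand in synonyms:
            if cand in raw.columns:
                resolved[field_name] = cand
                break
    missing = {"probe_id", "chrom", "pos"} - resolved.keys()
    if missing:
        raise ValueError(f"manifest lacks required columns for: {sorted(missing)}")
    ann = pd.DataFrame(index=raw[resolved["probe_id"]].astype(str))
    ann.index.name = "probe_id"
    ann["chrom"] = raw[resolved["chrom"]].astype(str).str.removeprefix("chr").to_numpy()
    ann["pos"] = pd.to_numeric(raw[resolved["pos"]], errors="coerce").to_numpy()
    for field_name in ("gene", "location", "island_relation"):
        if field_name in resolved:
            col = raw[resolved[field_name]].astype(str).to_numpy()
        else:
            col = np.full(len(raw), "", dtype=object)
        ann[field_name] = col
    for field_name in ("gene", "location"):
        # multi-gene annotations keep the first entry; empty → unassigned
        ann[field_name] = (
            ann[field_name]
            .replace({"nan": "", "None": ""})
            .str.split(";")
            .str[0]
            .replace("", UNASSIGNED)
        )
    ann["island_relation"] = ann["island_relation"].replace({"nan": "OpenSea", "": "OpenSea"})
    n_missing = int(ann["pos"].isna().sum() + (ann["chrom"] == "nan").sum())
    if n_missing:
        logger.warning("load_annotation: dropped %d probe(s) without coordinates", n_missing)
        ann = ann[ann["pos"].notna() & (ann["chrom"] != "nan")]
    ann = ann[~ann.index.duplicated(keep="first")]
    ann["pos"] = ann["pos"].astype(int)
    if (ann["pos"] < 1).any():
        raise ValueError("annotation positions must be 1-based (>= 1)")
    ann["platform"] = platform
    ann.attrs["genome_build"] = PLATFORMS[platform]
    return ann


def dmrs_to_bed(dmr_table: pd.DataFrame, path: str | Path) -> None:
    """Export DMR calls as BED (0-based half-open from 1-based inclusive)."""
    bed = pd.DataFrame(
        {
            "chrom": dmr_table["chrom"],
            "start": dmr_table["start"].astype(int) - 1,
            "end": dmr_table["end"].astype(int),
            "name": [f"DMR_{i + 1}" for i in range(len(dmr_table))],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
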