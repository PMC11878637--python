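"""Synthetic methylation datasets with known ground truth.

Emulates preprocessed Illumina-style array data: per-probe baselines are
drawn on the M (logit2) scale — μ_p ~ Normal(0, 2), residual SD
σ_p ~ |Normal(0.2, 0.05)| — association effects are planted additively on
M for causal probes, and β-values come back through the inverse logit, so
both analysis scales are exercised. Phenotypes include a standard-normal
continuous exposure, age ~ Normal(45, 10) and sex ~ Bernoulli(0.5)
covariates, optional batch shifts, repeated-measures structure, survival
outcomes, and spatially coherent differentially methylated regions.
All generators are deterministic functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MethylationMatrix, SampleSheet, FactorType, beta_m_convert

GENERATOR_VERSION = "1.0"


@dataclass
class SyntheticTruth:
    """Ground truth that fully determines a simulated dataset (given seed)."""

    seed: int
    effects: np.ndarray | None = None  # per-probe true effect on M scale
    causal_probes: list[str] = field(default_factory=list)
    batch_labels: list[str] | None = None
    batch_shift: float = 0.0
    regions: list[dict] = field(default_factory=list)  # chrom/start/end/probes
    true_log_hr: float | None = None
    subjects: list[str] | None = None
    version: str = GENERATOR_VERSION


def _annotation_frame(probe_ids, chroms, positions) -> pd.DataFrame:
    ann = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "gene": [f"GENE{int(i) % 97}" for i in range(len(probe_ids))],
            "location": "Body",
            "island_relation": "OpenSea",
            "platform": "450K",
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ann


def _baseline_m(rng, n_probes, n_samples):
    mu = rng.normal(0.0, 2.0, n_probes)
    sigma = np.abs(rng.normal(0.2, 0.05, n_probes))
    noise = rng.normal(0.0, 1.0, (n_probes, n_samples)) * sigma[:, None]
    return mu[:, None] + noise, mu, sigma


def simulate_ewas_dataset(
    n_samples: int = 100,
    n_probes: int = 5000,
    n_causal: int = 50,
    effect_size: float = 0.5,
    batch_spec: dict | None = None,
    seed: int = 0,
    value_type: str = "m",
    n_timepoints: int = 1,
    subject_sd: float = 0.0,
):
    """Cross-sectional (or repeated-measures) EWAS dataset with planted effects.

    ``effect_size`` is the M-scale slope per unit of the standard-normal
    exposure at each of the ``n_causal`` causal probes. ``batch_spec``
    (e.g. ``{"n_batches": 2, "shift": 0.1}``) adds a constant M shift to
    every probe of the non-reference batches. With ``n_timepoints > 1``
    each subject contributes that many rows sharing a random intercept of
    SD ``subject_sd`` (exercises the mixed model).

    Returns (matrix, sheet, annotation, truth).
    """
    if n_causal > n_probes:
        raise ValueError("n_causal cannot exceed n_probes")
    if n_samples < 4 or n_probes < 1:
        raise ValueError("invalid sizes")
    rng = np.random.default_rng(seed)
    n_subjects = n_samples
    n_rows = n_subjects * n_timepoints

    exposure_subj = rng.normal(0.0, 1.0, n_subjects)
    age = rng.normal(45.0, 10.0, n_subjects)
    sex = rng.integers(0, 2, n_subjects)
    exposure = np.repeat(exposure_subj, n_timepoints)

    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    M, mu, sigma = _baseline_m(rng, n_probes, n_rows)
    if subject_sd > 0 and n_timepoints > 1:
        subj_int = rng.normal(0.0, subject_sd, (n_probes, n_subjects))
        M += np.repeat(subj_int, n_timepoints, axis=1)

    effects = np.zeros(n_probes)
    causal_idx = rng.choice(n_probes, size=n_causal, replace=False) if n_causal else np.array([], int)
    effects[causal_idx] = effect_size
    M += effects[:, None] * exposure[None, :]

    batch_labels = None
    shift = 0.0
    if batch_spec:
        n_batches = int(batch_spec.get("n_batches", 2))
        shift = float(batch_spec.get("shift", 0.1))
        assign = rng.integers(0, n_batches, n_subjects)
        batch_labels = [f"B{b + 1}" for b in np.repeat(assign, n_timepoints)]
        M += shift * (np.repeat(assign, n_timepoints) > 0)[None, :]

    sample_ids = (
        [f"S{i:04d}" for i in range(n_subjects)]
        if n_timepoints == 1
        else [f"S{i:04d}_T{t}" for i in range(n_subjects) for t in range(n_timepoints)]
    )
    subjects = [f"S{i:04d}" for i in np.repeat(np.arange(n_subjects), n_timepoints)]

    values = pd.DataFrame(M, index=probe_ids, columns=sample_ids)
    if value_type == "beta":
        values = pd.DataFrame(
            beta_m_convert(M, "m_to_beta"), index=probe_ids, columns=sample_ids
        )
    matrix = MethylationMatrix(values, value_type=value_type)

    sheet_data = pd.DataFrame(
        {
            "exposure": exposure,
            "age": np.repeat(age, n_timepoints),
            "sex": np.where(np.repeat(sex, n_timepoints) == 1, "male", "female"),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    factors = {"sex": FactorType(levels=["female", "male"], reference="female")}
    sheet_data["sex"] = sheet_data["sex"].astype(str)
    if n_timepoints > 1:
        sheet_data["subject"] = subjects
    if batch_labels is not None:
        sheet_data["batch"] = batch_labels
        factors["batch"] = FactorType(
            levels=sorted(set(batch_labels)), reference=sorted(set(batch_labels))[0]
        )
    sheet = SampleSheet(sheet_data, factors)

    # positions spread uniformly over a small synthetic genome
    chrom_ids = rng.integers(1, 23, n_probes).astype(str)
    positions = rng.integers(1, 5_000_000, n_probes)
    ann = _annotation_frame(probe_ids, chrom_ids, positions)

    truth = SyntheticTruth(
        seed=seed,
        effects=effects,
        causal_probes=[probe_ids[i] for i in sorted(causal_idx)],
        batch_labels=batch_labels,
        batch_shift=shift,
        subjects=subjects if n_timepoints > 1 else None,
    )
    return matrix, sheet, ann, truth


def simulate_survival_dataset(
    n: int = 300,
    true_log_hr: float = 2.0,
    censor_frac: float = 0.3,
    n_probes: int = 1,
    h0: float = 0.1,
    seed: int = 0,
):
    """Survival dataset for the Cox model: exponential event times.

    Event times are exponential with rate h0·exp(log HR · β-methylation);
    independent uniform censoring is tuned so roughly ``censor_frac`` of
    subjects are censored (0 → no censoring). The first probe carries the
    planted hazard effect; remaining probes are null.

    Returns (matrix of β-values, sheet with time/event, truth).
    """
    rng = np.random.default_rng(seed)
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    beta_vals = 1.0 / (1.0 + np.exp(-rng.normal(0.0, 1.0, (n_probes, n)) * 0.8))
    cpg = beta_vals[0]
    rate = h0 * np.exp(true_log_hr * (cpg if n_probes else 0.0))
    if true_log_hr == 0:
        rate = np.full(n, h0)
    times = rng.exponential(1.0 / rate)
    if censor_frac > 0:
        # uniform censoring on (0, c]; bisect c to hit the target fraction
        lo_c, hi_c = 1e-6, np.quantile(times, 0.999) * 50
        cens_draw = rng.uniform(0.0, 1.0, n)
        for _ in range(60):
            mid = 0.5 * (lo_c + hi_c)
            frac = np.mean(cens_draw * mid < times)  # fraction censored at scale mid
            if frac > censor_frac:
                lo_c = mid  # too much censoring: lengthen the censoring window
            else:
                hi_c = mid
        ctimes = cens_draw * 0.5 * (lo_c + hi_c)
        event = (times <= ctimes).astype(int)
        obs_time = np.minimum(times, ctimes)
    else:
        event = np.ones(n, int)
        obs_time = times
    sample_ids = [f"S{i:04d}" for i in range(n)]
    matrix = MethylationMatrix(
        pd.DataFrame(beta_vals, index=probe_ids, columns=sample_ids), value_type="beta"
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {"time": obs_time, "event": event, "age": rng.normal(45, 10, n)},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = SyntheticTruth(seed=seed, true_log_hr=true_log_hr)
    return matrix, sheet, truth


def _spacing_draw(rng, size):
    """Inter-probe gaps: island-like 50–500 bp or open-sea 1–50 kb (bimodal)."""
    island = rng.random(size) < 0.5
    gaps = np.where(
        island,
        rng.integers(50, 501, size),
        rng.integers(1000, 50001, size),
    )
    return gaps


def simulate_dmr_dataset(
    n_samples: int = 80,
    n_null_probes: int = 5000,
    n_regions: int = 10,
    region_size_range: tuple[int, int] = (8, 20),
    effect_size: float = 0.08,
    seed: int = 0,
):
    """Dataset with spatially coherent planted regions for DMR calling.

    Null probes are placed with bimodal realistic spacing over synthetic
    chromosomes; each planted region inserts ``region_size``
    tightly spaced probes (50–300 bp gaps) sharing a same-sign M-scale
    effect of ``effect_size`` per unit exposure.

    Returns (matrix, sheet, annotation, truth).
    """
    rng = np.random.default_rng(seed)
    n_chroms = 10
    per_chrom = n_null_probes // n_chroms
    chroms, positions = [], []
    for c in range(1, n_chroms + 1):
        gaps = _spacing_draw(rng, per_chrom)
        pos = 10_000 + np.cumsum(gaps)
        chroms.extend([str(c)] * per_chrom)
        positions.extend(pos.tolist())

    region_meta = []
    sizes = rng.integers(region_size_range[0], region_size_range[1] + 1, n_regions)
    signs = rng.choice([-1.0, 1.0], n_regions)
    for r in range(n_regions):
        chrom = str((r % n_chroms) + 1)
        chrom_pos = [p for ch, p in zip(chroms, positions) if ch == chrom]
        anchor = max(chrom_pos) + 100_000 * (r // n_chroms + 1) + rng.integers(0, 10_000)
        gaps = rng.integers(50, 301, sizes[r])
        pos = anchor + np.cumsum(gaps)
        chroms.extend([chrom] * sizes[r])
        positions.extend(pos.tolist())
        region_meta.append(
            {"chrom": chrom, "start": int(pos[0]), "end": int(pos[-1]),
             "n_cpgs": int(sizes[r]), "sign": float(signs[r])}
        )

    n_probes = len(positions)
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]

    exposure = rng.normal(0.0, 1.0, n_samples)
    M, mu, sigma = _baseline_m(rng, n_probes, n_samples)
    effects = np.zeros(n_probes)
    idx = n_null_probes
    for r, meta in enumerate(region_meta):
        effects[idx : idx + meta["n_cpgs"]] = meta["sign"] * effect_size
        meta["probes"] = probe_ids[idx : idx + meta["n_cpgs"]]
        idx += meta["n_cpgs"]
    M += effects[:, None] * exposure[None, :]

    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    matrix = MethylationMatrix(
        pd.DataFrame(M, index=probe_ids, columns=sample_ids), value_type="m"
    )
    sheet = SampleSheet(
        pd.DataFrame({"exposure": exposure}, index=pd.Index(sample_ids, name="sample_id"))
    )
    ann = _annotation_frame(probe_ids, chroms, positions)
    truth = SyntheticTruth(seed=seed, effects=effects, regions=region_meta)
    return matrix, sheet, ann, truth
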