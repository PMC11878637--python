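# ewaskit

An epigenome-wide association study (EWAS) toolkit for preprocessed
Illumina-style DNA methylation matrices (β- or M-values). It is aimed at
epidemiologists and clinical researchers who have a probes × samples
methylation matrix and a sample sheet and want a complete, reproducible
association pipeline without assembling a dozen packages: per-CpG
differential methylation under several study designs, batch correction,
region calling, internal validation, annotation, enrichment, and
publication-grade figures.

## What it computes

**Differentially methylated positions (DMPs).** For each CpG site the
methylation level (β or M = log2 β/(1−β)) is the outcome of one of three
models:

- **GLM** — ordinary least squares,
  CpG = β₀ + β₁X₁ + … + βₙXₙ + ε, for cross-sectional or case–control
  designs; β₁ is reported per unit, per IQR, or per SD of the exposure X₁.
- **LMM** — adds a random intercept u per subject,
  CpG = β₀ + β₁X₁ + … + u + ε, for repeated-measures/longitudinal data;
  fitted by profiled REML with a Wald z test on β₁.
- **CoxPH** — the CpG enters the hazard,
  h(t|X) = h₀(t)·exp(β₁·CpG + β₂X₂ + …), fitted by partial likelihood
  (Efron ties); reported as the hazard ratio exp(β₁) with its 95% CI.

Every scan reports both Benjamini–Hochberg FDR and Bonferroni-adjusted
p-values and merges probe annotation (chromosome, position, gene,
genomic feature, relation to CpG island) for the 27K/450K/EPICv1/EPICv2/MSA
platforms.

**Batch correction** is the parametric empirical-Bayes location/scale
adjustment (ComBat): per-probe standardization against a model containing
any protected biological covariates, method-of-moments priors across
probes, EB shrinkage of per-batch means and variances, and
back-transformation.

**Differentially methylated regions (DMRs)** follow the kernel-smoothing
approach: moderated per-site t statistics (EB variance shrinkage),
Gaussian smoothing of t² along the chromosome (kernel SD = λ/C, defaults
λ = 1000 bp, C = 2), Satterthwaite chi-square site p-values, BH-FDR, and
gap-based grouping of significant sites (gap ≤ λ, ≥ 2 CpGs), with Fisher
and Stouffer combined region p-values.

**Bootstrap validation** recomputes selected DMP estimates under
subject-level resampling (B = 999 default) and reports five two-sided
interval types: first-order normal, basic, studentized, percentile, and
BCa. An interval excluding 0 (or 1 for hazard ratios) flags a robust hit.

**Enrichment** maps significant probes to genes and tests user-supplied
GMT gene sets with the hypergeometric upper tail, BH-adjusted, with
bubble/bar plots. **Visualization** covers rectangular/circular Manhattan
plots, QQ plots with the genomic inflation factor
λ = median(χ²_obs)/median(χ²₁), and CpG density tracks.

A `simulate` module generates full synthetic studies (planted effects,
batches, regions, survival structure) so every capability is testable
offline with known ground truth.

## Worked example

```bash
python examples/01_dmp_linear_model.py
```

```
probes tested:        2000
discoveries (FDR<5%): 52
  of which truly causal: 50 / 50 planted

top 3 sites (coefficient = M-value change per exposure unit):
     Probe  Coefficient       SE      P-value          FDR
cg00001720     0.491939 0.011021 5.229842e-66 1.045968e-62
cg00001537     0.515782 0.012412 3.596864e-63 3.596864e-60
cg00000294     0.513851 0.013812 7.925958e-59 5.283972e-56
```

The simulation plants a 0.5 M-unit effect per exposure SD at 50 of 2000
CpGs; the scan recovers all 50 at FDR < 0.05 with coefficients near 0.5,
plus two false discoveries — consistent with a 5% FDR. The other
`examples/*.py` scripts walk through batch correction, the mixed and Cox
models, region calling, bootstrap validation, enrichment, and plotting,
each printing the numbers it computes and what they mean.

The same pipeline is scriptable from the shell:

```bash
ewaskit init --workdir run1
ewaskit simulate --workdir run1 --preset glm --seed 7
ewaskit dmp --workdir run1 --model glm --exposure exposure --covariates age,sex
ewaskit dmr --workdir run1 --exposure exposure
ewaskit boot --workdir run1 --select "bonferroni<0.05" --ci-types percentile,bca --seed 7
ewaskit plot --workdir run1 --kind qq
```

Each stage writes its outputs (`dmp.csv`, `dmr.csv`, `boot.csv`, plots)
into the session directory and logs the parameters that produced them in
`session.json`; stages enforce their prerequisites (`dmr` is independent
of `dmp`).

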