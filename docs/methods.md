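# Methods

This note documents the statistical models, the numerical choices, and
the synthetic-data conditions under which the package is tested, in the
spirit of a model-description vignette.

## Data model and scales

Methylation arrives as a probes × samples matrix of β-values (bounded
fractions in [0, 1]) or M-values (M = log2 β/(1−β)). Analyses run on
whichever scale the user supplies; the choice is recorded in the result
table metadata. β values of exactly 0 or 1 are clipped to
[1e−6, 1−1e−6] before the logit so the transform stays finite (logged).
Missing cells are allowed and handled per probe by complete-case fitting,
with the per-probe sample count reported. Sample sheets are typed as
read; factor conversion records levels in first-appearance order with the
first level as reference unless overridden — deterministic and free of
locale-dependent sorting. Annotation coordinates are 1-based (Illumina
manifest convention); BED export converts to 0-based half-open. CSV/TSV
is the normative interchange format; parquet is accepted as a faster
columnar sidecar.

## Per-CpG models

**GLM.** OLS with classical SEs and a two-sided t test on the exposure
coefficient. Degenerate cases keep the record count stable rather than
failing the scan: a constant outcome returns estimate 0, p = 1; a
rank-deficient design returns a flagged non-converged record. A
multi-level factor exposure reports the last-level-vs-reference contrast
in the main columns and every level contrast in auxiliary columns.

**LMM.** Random-intercept model fit by profiled REML: with
V = σ²(I + θ·ZZᵀ) and θ = σ²_u/σ²_e, the GLS estimate and σ² have closed
forms given θ, so REML reduces to a 1-D optimization over log θ with the
boundary candidate θ = 0 evaluated exactly. At the boundary (e.g. one
observation per subject, where θ is not identifiable and the profile is
flat) the fit equals OLS exactly. Inference is a Wald z test on the fixed
exposure effect; Satterthwaite degrees of freedom are out of scope — the
normal reference is deterministic and library-independent. The fitter is
cross-checked against statsmodels MixedLM in the test suite.

**CoxPH.** The CpG itself is the tested hazard covariate (log HR per 1.0
methylation unit; an optional flag rescales it per SD because "per
β-unit" hazard ratios are often extreme). Partial-likelihood
maximization uses lifelines with Efron tie handling and a tightened
Newton precision (1e−9) so estimates agree with brute-force 1-D
maximization to better than 1e−4. Monotone-likelihood (separated) fits
are flagged non-converged rather than reported with absurd SEs.

**Multiple testing.** Both Bonferroni (min(1, m·p)) and BH step-up
adjusted values are always emitted; NaN p-values are excluded from m and
propagated. BH is the cumulative-minimum construction and is verified
against an independent step-up oracle and statsmodels.

**Exposure scaling.** `unit` leaves the exposure as is; `iqr`/`sd`
divide by the interquartile range (linear-interpolation quartiles) or
the n−1 sample SD, so the coefficient reads "methylation change per IQR
(SD) of exposure". Scaling applies to the exposure, not the outcome.

**Parallelism.** Probes are partitioned into contiguous chunks and
reassembled by original index, so the worker count never changes a byte
of output. The default is 1 worker; fits are deterministic.

## Batch correction

Parametric empirical-Bayes location/scale adjustment (the ComBat
algorithm): (1) per-probe regression on batch indicators plus protected
covariates; (2) standardization by the pooled residual SD (÷n
convention); (3) per-batch means γ̂ and variances δ̂ of the standardized
data; (4) EB shrinkage with a normal prior on γ (moments γ̄, τ² across
probes) and an inverse-gamma prior on δ (method-of-moments λ, θ), solved
by the standard fixed-point iteration; (5) adjustment and
back-transformation. Probes with zero within-batch variance pass through
uncorrected with a warning; missing entries are excluded from all moment
estimates. An internal `shrink=False` flag (the τ²→∞ limit) reduces the
adjustment to exact per-batch standardization and anchors the tests.
Non-parametric priors and reference-batch variants are out of scope.

Because EB shrinkage is partial, per-probe batch differences retain a
noise-level residual; what the correction removes essentially completely
(≈96% in the test conditions) is the *systematic* shift — the
across-probe mean between-batch difference — which is how the batch
tests measure it. A planted biological effect passed as a protected
covariate survives within a few percent.

## Region calling

Per-site moderated statistics use EB variance shrinkage: a scaled-F
prior is fitted to the per-probe residual variances by matching the mean
and variance of log s² (digamma/trigamma moments; the trigamma equation
is inverted by Newton iteration), giving prior df d₀ and prior variance
s₀²; posterior variances are (d₀s₀² + d·s²)/(d₀ + d) and the moderated t
uses d + d₀ df. If the observed dispersion of variances is below
chi-square sampling noise the prior df is infinite and all variances
shrink to the geometric mean of the observed values (exact fixed point
when all probes share one variance).

Squared moderated t values are smoothed along each chromosome with a
Gaussian kernel of SD σ = λ/C (defaults λ = 1000 bp — the common
array-EWAS window — and C = 2), weights renormalized to 1 per site and
truncated at 5σ; smoothing never crosses chromosomes, and
duplicate-position probes are averaged first. Under the null each
squared statistic is ≈χ²₁, so the smoothed value S with weight vector w
satisfies E[S] = 1, Var[S] = 2Σw²; Satterthwaite matching gives
S ~ (1/k)χ²ₖ with k = 1/Σw², collapsing to the plain χ²₁ tail for an
isolated site. Site p-values are BH-adjusted across all sites.

Significant sites (FDR < 0.05 by default) merge into regions while the
inter-site gap stays ≤ λ; regions need ≥ 2 CpGs. **Kernel-leakage
guard:** smoothing makes neighbouring sites' statistics correlated, so
false discoveries arrive in clumps — a single strong null site can drag
its neighbour over the FDR line and fabricate a 2-site region. A region
is therefore kept only if at least `min_cpgs` of its members are also
significant on the raw (unsmoothed) statistics at the same BH threshold.
This removes single-spike artifacts while leaving genuine regions, whose
member sites are individually strong, untouched; the cost is reduced
sensitivity to regions whose signal is only detectable after smoothing.
Regions report Fisher (−2Σlog p vs χ²₂ₖ) and Stouffer (Σz/√k) combined
p-values — both are emitted because no single region-level FDR
definition is canonical — plus min site FDR and the mean/absolute-max
per-site effect, sorted by Fisher p.

## Bootstrap validation

Resampling is with replacement over sampling units: subjects when the
model has a grouping variable (preserving repeated-measures structure),
otherwise samples. Covariates are refit in every replicate. Replicates
that lose all factor levels, all events, or design rank are counted as
failed and excluded; a probe with > 20% failures errors as unstable.
B defaults to 999 (the asthma-style worked examples in the field often
use 500; 999 gives more stable interval endpoints) and the level to
0.95. Quantiles use linear interpolation throughout.

Interval constructions (Davison & Hinkley): normal = bias-corrected
center 2θ̂ − mean(θ*) ± z·sd(θ*); basic = [2θ̂ − q₁₋α/₂, 2θ̂ − qα/₂];
studentized pivots (θ* − θ̂)/se* against the original-fit SE;
percentile = empirical quantiles; BCa = percentile with bias term
z₀ = Φ⁻¹(#{θ* < θ̂}/B) (proportion clipped to (1/(B+1), B/(B+1))) and
jackknife acceleration a. A constant replicate vector short-circuits
every type to the degenerate [c, c]; the studentized error for
degenerate SEs fires only when the estimates themselves vary. Cox
intervals are computed on the log-HR scale and exponentiated. Each probe
draws from a seed stream derived from (master seed, probe index), so
tables are bit-reproducible and independent of worker count. GLM
replicates are fit by batched normal equations (vectorized over
replicates — the same estimator as the single fit); LMM/Cox replicates
loop over full refits.

## Enrichment and plots

Over-representation is the hypergeometric upper tail P(X ≥ k) for k hits
among n significant genes against a term with K genes in an N-gene
universe, where the universe is the set of genes annotated on the
analyzed array (the array is the sampling frame, not the genome). Terms
are filtered to 10–500 universe genes by default; BH across tested
terms. Gene sets come from offline GMT files; probe-density/gene-length
bias is not corrected. Genomic inflation is
λ = median(χ²₁ quantile of p) / χ²₁ median, computed exactly (all
p = 0.5 gives λ = 1). −log10(p) is capped at 300 for display. Circular
Manhattan layouts draw chromosomes as polar arcs with 2° gaps — purely
presentational.

## Synthetic data

The generators emulate preprocessed array data, not raw intensities:
per-probe baselines on the M scale with μ_p ~ N(0, 2) and residual SD
σ_p ~ |N(0.2, 0.05)|, a standard-normal continuous exposure, age
~ N(45, 10) and sex ~ Bernoulli(0.5) covariates, additive M-scale
effects at causal probes (β output via the inverse logit so both scales
are exercised), optional constant batch shifts, subject random
intercepts for repeated measures, exponential survival times with
uniform censoring bisected to the target censored fraction, and region
datasets with bimodal inter-probe spacing (50–500 bp island-like, 1–50
kb open-sea) and same-sign region effects. Not emulated: probe-type
chemistry differences, dye bias, cell-type mixture, spatially varying
baselines, or p-value dependence from co-methylation outside planted
regions — so passing tests demonstrate statistical correctness of the
methods under clean conditions, not robustness to every array artifact.

## Problem sizes and defaults used in validation

The standard validation conditions (also used by `scripts/acceptance.py`)
are: 100 random OLS instances (n ≤ 50, p ≤ 5); 1000 random p-vectors;
50 Cox and 50 LMM-boundary instances; a pooled null of 20 × 2000 probes
at n = 100; bootstrap coverage over 200 datasets (n = 150, B = 499);
batch recovery on 500 probes at n = 50/batch; region recovery over 50
replicates of 5000 null probes + 10 planted regions (8–20 CpGs, 0.08
M-units, n = 80); and the full hypergeometric grid for N ≤ 25. These
sizes give tight Monte-Carlo error (e.g. binomial SE ≈ 0.001 on the
pooled type-I rate) while keeping the whole validation run around half a
minute.

## Known limitations

Raw IDAT processing, normalization, probe QC, surrogate-variable/latent
batch discovery, WGBS data, robust/sandwich SEs, interaction terms,
GSEA-style ranked enrichment, and external-cohort replication are out of
scope. The mixed model supports a single random intercept (no random
slopes or crossed designs). Region calls are not calibrated to any
particular reference implementation's output — planted-region recovery
under the synthetic conditions above is the stated contract.
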