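# metafrail

Metabolite–frailty association and two-sample Mendelian randomization (MR)
pipeline.

`metafrail` implements, as a tested and reusable library, the full analytic
workflow used to ask whether circulating metabolic biomarkers (NMR
metabolomics panels, clinical chemistry) are causally related to frailty in
ageing cohorts:

1. **Frailty measurement** — the deficit-accumulation frailty index
   (FI, % of accumulated deficits over a fixed item set, with a >20%
   missingness exclusion rule), the Fried frailty phenotype score
   (FP, 0–5), and 11 *category-stripped* FIs that remove one deficit domain
   (e.g. cardiometabolic) at a time.
2. **Discovery screening** — within-sample biomarker standardization,
   covariate-adjusted linear models of FI (or FP) per biomarker
   (β = FI % per SD of biomarker), Bonferroni control, median ± 5·IQR
   outlier exclusion, age/sex subgroup reruns, cluster-robust errors for
   twin data.
3. **LASSO selection** — 10-fold cross-validated L1 regression with
   unpenalized age/sex and the 1-SE λ rule, keeping biomarkers that are
   *independently* informative for the FI.
4. **Replication** — DerSimonian–Laird random-effects meta-analysis across
   replication cohorts; pooled p < 0.05 = replicated.
5. **Two-sample MR** — instrument selection (p < 5×10⁻⁸, LD clumping at
   r² < 0.001 within 10,000 kb), allele harmonization (palindromic SNPs
   dropped at MAF > 0.42), instrument-strength F-statistics, and a full
   estimator suite: multiplicative random-effects IVW (primary), MR-Egger,
   weighted median, weighted mode, MR-PRESSO outlier correction, Cochran's
   Q, Benjamini–Hochberg FDR over the primary IVW family, pleiotropy-pruned
   instrument sensitivity, and stripped-FI outcome reruns.
6. **Co-twin control** — population vs within-twin-pair estimates by
   zygosity, with explicit interpretation rules (causal-consistent /
   genetic-confounding / shared-environment / inconclusive).

Because the cohort and GWAS data such analyses run on are access-restricted,
the package ships a first-class **synthetic-data module** that generates
cohorts, MZ/DZ twin samples, and paired exposure/outcome GWAS summary
statistics with known ground truth (stored alongside every draw), so every
stage is testable offline and end to end.

## The core model

For harmonized instruments *j* = 1…J with exposure effects β̂_Xj (SE σ_Xj)
and outcome effects β̂_Yj (SE σ_Yj), the per-SNP Wald ratio is
β̂_j = β̂_Yj / β̂_Xj with first-order SE σ_j = σ_Yj / |β̂_Xj|. The primary
IVW estimator is the weighted regression of β̂_Y on β̂_X through the origin:

    θ̂ = Σ β̂_Xj β̂_Yj σ_Yj⁻² / Σ β̂_Xj² σ_Yj⁻²

with multiplicative random-effects SE = (Σ β̂_Xj² σ_Yj⁻²)^(−1/2) ·
max(1, √(Q/(J−1))), where Q = Σ σ_Yj⁻² (β̂_Yj − θ̂ β̂_Xj)² is Cochran's
heterogeneity statistic. MR-Egger adds an intercept α estimating average
directional pleiotropy; the weighted median and mode relax validity to a
majority / plurality of instruments; MR-PRESSO detects per-SNP pleiotropic
outliers by simulation and re-estimates without them.

## Worked example

```python
from metafrail.synthetic import GwasSimConfig, simulate_gwas_pair
from metafrail.mr import select_instruments, harmonize, ivw, mr_egger

exposure, outcome, truth = simulate_gwas_pair(
    GwasSimConfig(n_snps=100, n_exposure=200_000, n_outcome=200_000,
                  theta=0.3, exposure_h2=0.1, seed=6,
                  pleiotropy_mode="directional",
                  pleiotropy_mean=0.05, pleiotropy_sd=0.01)
)
instruments = select_instruments(exposure, truth.ld)   # p < 5e-8, clumped
hset = harmonize(exposure, outcome, instruments)
est, egger = ivw(hset), mr_egger(hset)
print(f"IVW theta = {est.beta:.3f} (SE {est.se:.3f}), Q = {est.Q:.1f}")
print(f"Egger slope = {egger.beta:.3f} (SE {egger.se:.3f}), "
      f"intercept = {egger.egger_intercept:.4f} (p = {egger.intercept_p:.3f})")
```

Output:

```
IVW theta = 1.047 (SE 0.044), Q = 2686.3
Egger slope = 0.353 (SE 0.050), intercept = 0.0463 (p = 0.000)
```

The IVW estimate (1.05) is badly biased away from the planted θ = 0.3
because every instrument carries directional pleiotropy of mean 0.05 on
the outcome, and the heterogeneity statistic Q flags it. MR-Egger
separates the two: its intercept recovers the average pleiotropic effect
(0.046, within 2 SE of 0.05) and its slope (0.35 ± 0.05) recovers the
causal effect. With `pleiotropy_mode="none"` the IVW estimate falls within
2 SE of θ and the intercept is consistent with zero.

The full workflow runs from one config:

```bash
metafrail run-all --seed 1 --out results/run1
```

which writes `discovery_screen.tsv`, `lasso_selected.txt`,
`replication_meta.tsv`, `mr_results.tsv`, `cotwin_results.tsv`, a
forest-table style `summary_table.tsv` (observational, meta-analyzed, and
IVW estimates side by side), and `run_log.json` recording every threshold,
family size, and seed so a second machine reproduces the outputs exactly.

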