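# Methods

This note documents the statistical models implemented in `metafrail`, the
parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Frailty measures

**Frailty index (FI).** For an individual with deficit values d_i ∈ [0, 1]
over m items (graded codings such as 0.5 are accepted), the FI is
100 · Σ d_i / m_obs, where m_obs counts the non-missing items. Individuals
with a missing fraction *strictly greater than* 0.20 are excluded rather
than scored — the rule is ">20%", so an individual at exactly 20% is
retained. `max_missing_fraction` is exposed (default 0.20). Values outside
[0, 1] are a data error reported with the individual and item.

**Frailty phenotype (FP).** The count (0–5) of Fried criteria present
(weight loss, exhaustion, slowness, low activity, weakness). An individual
missing any criterion gets a missing score; we do not rescale to fewer
criteria because partial scoring changes the score's meaning and no
convention for it is established here.

**Stripped FIs.** For each of the 11 deficit categories, the FI is
recomputed on the item set excluding that category, with the same
missingness rule applied to the reduced denominator. With the default
49-item map, stripping the 8 cardiometabolic items yields a 41-item FI.
These serve as alternative MR outcomes: if an exposure acts on frailty
only through, say, cardiometabolic disease, its estimate on the
cardiometabolic-stripped FI attenuates to null.

## Discovery screening

Biomarkers are standardized to mean 0, sample SD 1 (ddof = 1) *within each
cohort*, so all effects are FI % per SD. Each biomarker is fit by OLS with
an intercept and the configured covariates; categorical covariates enter as
reference-coded indicators (first observed level as reference). Analyses
are complete-case per model (dropped counts are logged); confidence
intervals use the normal 1.96 multiplier, appropriate for the cohort sizes
this design targets. Twin cohorts use cluster-robust sandwich SEs with the
CR1 small-sample correction; with all clusters of size 1 this reduces
exactly to HC1, which the tests assert. Extreme biomarker values can be
excluded with the median ± k·IQR rule (default k = 5); a zero IQR keeps
everything and warns. Family-wise control is Bonferroni at α/m where m is
the configured family size (200 for the full biomarker panel, giving the
0.00025 threshold); strata reruns reuse the same per-test threshold rather
than resizing the family.

## LASSO selection

The selection objective is

    min_(b, g)  (1/2n) ||y − X b − C g||² + λ ||b||₁

with the biomarker panel X penalized and the mandatory covariates C (age,
sex, plus an intercept) unpenalized — they are adjustment terms, not
selection candidates. Because C is unpenalized, the solution is obtained
exactly by Frisch–Waugh–Lovell residualization: project y and X off C, run
coordinate descent (scikit-learn's `lasso_path`) on the residuals, then
recover g by least squares. λ is tuned by k-fold cross-validation
(default 10 folds, seeded shuffle) on a 100-point geometric grid from
λ_max = max_j |X̃ⱼᵀỹ|/n down to 10⁻³ λ_max. The CV criterion is mean
squared error; its SE is the across-fold SD divided by √k. λ_1SE is the
*largest* λ whose CV MSE is within one SE of the minimum (maximal
sparsity, the rule's intent); ties along a flat curve therefore resolve
toward sparser models. The response is the raw FI in percent, matching the
regression screen. Two separate fits (metabolomic and clinical panels) are
run when both panels are configured.

## Replication meta-analysis

Per-cohort estimates are pooled with the moment-based DerSimonian–Laird
random-effects estimator: fixed-effect weights w = se⁻², heterogeneity
Q = Σ w (β − β_FE)², τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)),
random-effects weights 1/(se² + τ²). When Q ≤ k−1 this reduces exactly to
fixed-effect inverse-variance pooling. The pooled p is two-sided normal.
A biomarker is "replicated" when pooled p < 0.05 (strict); an optional
direction-consistency check against the discovery sign exists but is off
by default because the replication criterion is the p-value alone.

## Two-sample MR

**Instruments.** SNPs associated with the exposure at p < 5×10⁻⁸ are
greedily clumped: sort by ascending p, keep the best remaining SNP,
discard SNPs within 10,000 kb on the same chromosome with r² ≥ 0.001
against a kept SNP. The LD source is an abstraction — a pairwise r² table
or synthetic block labels — because a reference-panel reader is out of
scope here.

**Harmonization.** Outcome records are aligned to the exposure's
effect-allele coding, trying direct match, allele swap, strand complement,
and swapped complement; swaps flip the outcome beta sign and complement the
EAF. Strand-ambiguous (A/T, C/G) SNPs are dropped when the exposure-study
MAF exceeds 0.42 (frequency alignment is unreliable near 0.5); retained
palindromic SNPs are aligned by allele frequency. SNPs absent from the
outcome study or with irreconcilable alleles are dropped with a logged
reason. Harmonization is involutive and invariant to flipping both
studies' coding, which the tests assert.

**Estimators.** The per-SNP Wald ratio is β_Y/β_X with first-order SE
se_Y/|β_X| (first-order weights; second-order weights were considered and
not adopted since the first-order form is the common default and the two
agree closely for the strong instruments that survive selection).

* *IVW (primary)*: origin regression of β_Y on β_X with weights se_Y⁻²;
  the fixed-effect SE is inflated by max(1, √(Q/(J−1))) — multiplicative
  random effects, floored at 1 so underdispersion never shrinks the SE.
* *MR-Egger*: each SNP oriented so β_X ≥ 0 (Egger is not orientation
  invariant), then weighted regression with intercept; SEs carry
  max(1, √(Q_E/(J−2))). The intercept estimates average directional
  pleiotropy under InSIDE. Requires J ≥ 3.
* *Weighted median*: sorted ratios against percentiles p_j = cumulative
  weight − w_j/2, linear interpolation at 0.5, weights σ_j⁻². Requires
  J ≥ 3; SE by seeded parametric bootstrap (default 1000 draws) of the
  summary statistics.
* *Weighted mode*: argmax of a normal-kernel weighted density of the
  ratios on a 512-point grid spanning the ratio range; bandwidth
  φ·0.9·min(weighted SD, weighted IQR/1.34)·J^(−1/5) with φ = 1 by
  default. Identical ratios (zero bandwidth) return the common ratio.
* *MR-PRESSO*: per-SNP weighted squared residuals against leave-one-out
  IVW fits; the observed global RSS is compared with seeded simulations
  (default 1000) from the per-SNP sampling distributions under no
  pleiotropy (global p), and each SNP's residual against its own simulated
  distribution with Bonferroni correction by J (outlier p, flag at 0.05).
  The corrected estimate is IVW on the unflagged SNPs. Requires J ≥ 4.
  The distortion test is not implemented; the raw-vs-corrected difference
  is reported descriptively instead.

Bootstrap and simulation draws attach to a canonical (sorted-ID) SNP
ordering, making every estimator — including the bootstrapped SEs —
invariant to input row order.

Single-instrument exposures (common after pleiotropy pruning) fall back to
the Wald ratio with delta-method SE, labelled `wald_ratio`.

**Inference bookkeeping.** Cochran's Q on the ratios (algebraically equal
to the IVW regression Q) tests heterogeneity. The battery runner applies
Benjamini–Hochberg FDR across the primary IVW family — exposures × the two
frailty outcomes (FI, FP) — and records the family size in the run log;
with the full 49-biomarker exposure set this family is 98 tests. The BH
routine also reports the largest rejected raw p, the data-dependent
per-test threshold. Pleiotropy pruning removes any instrument that is
genome-wide significant for another configured exposure, warning when the
instrument set empties.

## Co-twin control

The within-pair (conditional) estimator regresses within-pair mean-centered
outcome on centered exposure and covariates; for a linear outcome this is
algebraically the fixed-pair estimator and equals OLS on twin differences
exactly (asserted to 1e-10). Pair-constant covariates are absorbed by the
pair effects and dropped from the centered design; residual degrees of
freedom subtract the absorbed pair means. Interpretation of the population
vs DZ vs MZ pattern uses explicit, configurable rules (`CotwinPolicy`):

* causal-consistent — both within-pair CIs cover the population point
  estimate;
* genetic-confounding — |pop| > |DZ| > |MZ| with the MZ CI covering 0
  (MZ pairs share all segregating genes, DZ about half);
* shared-environment — DZ and MZ attenuate similarly (difference within
  25% of |pop| by default);
* inconclusive — anything else, *including* within-pair CIs wider than
  `max_relative_halfwidth` (default 1.0) times |pop|: wide intervals would
  otherwise trivially "cover" the population estimate while carrying no
  discriminating information.

## Synthetic data

The generators define the conditions every test and calibration study runs
under. Seeds are mandatory and identical seeds give byte-identical output.

**Cohorts.** Biomarkers are standard normal with block-equicorrelation
(configurable (size, ρ) blocks) mimicking correlated lipoprotein panels.
Each of the 49 deficit items (11 labelled categories; 8 cardiometabolic
items so the stripped FI has 41) is Bernoulli with a logistic link on a
single latent frailty liability L = b_age·z_age + Σ c_j z_j + u. Baseline
item prevalences are log-spaced (0.02–0.35) and scaled so the FI mean hits
its target (12.29% by default, with age 56.77 ± 8.03 y); item intercepts
are Newton-calibrated against the realized liability distribution to
remove the Jensen bias of the logistic link. Biomarker loadings are the
configured FI%-per-SD effects divided by the mean logistic slope
100·mean(p(1−p)), so OLS of FI% on a biomarker z-score recovers the
configured effect (to first order; verified within 3 SE at n = 20,000).
The liability noise SD (0.55) sets the FI overdispersion relative to the
binomial floor, giving SD ≈ 7.4% and right skew. FP criteria are five
Bernoulli draws from the same liability. What this does *not* emulate:
item-specific age profiles, informative missingness, measurement error in
biomarkers, or non-linear biomarker–frailty dose-response — passing tests
therefore show correctness of the estimators under the linear model, not
robustness to those features of real data.

**Twins.** An additive-genetic factor correlated 1.0 within MZ and 0.5
within DZ pairs and a fully shared environment factor jointly drive the
biomarker and a continuous FI according to the confounding mode
(`none` / `genetic` / `shared_env`); the confounder effect is in FI % per
SD of the factor. This is a direct mechanism for the co-twin patterns, not
a full variance-component (ACE) model.

**GWAS pairs.** Per-allele exposure effects γ_j are normal, scaled so the
instruments jointly explain `exposure_h2` of a standardized exposure;
SEs follow se = 1/√(2·EAF·(1−EAF)·n) and p-values satisfy the Wald
relation exactly. Outcome effects are θ·γ_j + α_j with α per pleiotropy
regime: balanced (zero-mean normal), directional (mean `pleiotropy_mean`,
defined relative to the exposure-increasing allele — the orientation
MR-Egger fits under), or outlier (n_outliers SNPs with large |α|).
`inside_violated` correlates α with γ. A configurable fraction of SNPs
gets palindromic alleles; LD blocks are block-constant r² with block
members placed within the clumping window and all other SNPs far apart.
The truth record (θ, γ, α, outlier IDs, LD) always accompanies the data.
For stripped-FI outcomes, the causal effect decomposes into a direct
channel plus per-category channels θ_c = θ·mediation_c; the outcome for
the FI stripped of category c has effect θ − θ_c, and all outcomes share
one per-SNP noise draw so non-mediated stripped FIs track the full-FI
estimate closely. MAFs are uniform on (0.05, 0.95) — no realistic allele
frequency spectrum — and LD beyond block-constant r² is not modelled.

## Problem sizes and numerical choices

Calibration studies use 500 replicates for IVW type-I error and coverage
(J = 50, θ = 0) and 100 replicates for the MR-PRESSO null and the LASSO
selection-rate studies; the LASSO studies use n = 2000 (power, effect 1.0
per SD among 49 nulls, unit noise) and n = 500 × 50 nulls (selection
under the null). These sizes give Monte-Carlo SEs of about 1% on the
reported rates while keeping the full suite quick on one CPU. The
acceptance script simulates 10,000 SNPs at a metabolomics-GWAS-like sample
size (n = 115,078, h² = 0.3), where the genome-wide threshold maps to a
minimum instrument F of χ²₁(5×10⁻⁸) ≈ 29.72.

Degenerate inputs are handled explicitly rather than numerically: constant
biomarkers, zero IQR, rank-deficient designs (offending columns named),
zero within-pair exposure variance, empty strata, and empty instrument
sets all raise or warn with actionable messages.

## Known limitations

* The conditional twin estimator covers linear outcomes only; binary
  outcomes would need a genuine conditional-likelihood fit.
* MR-PRESSO outlier detection is single-pass; a gross outlier leaks into
  the other SNPs' leave-one-out fits and can drag neighbours over the
  flagging threshold (the planted outlier itself is always the strongest
  signal). Iterative re-testing was left out to keep the procedure simple
  and seeded.
* Clumping assumes the LD source covers all relevant pairs; absent pairs
  are treated as r² = 0.
* The pipeline's synthetic replication cohorts re-draw from the same
  effect configuration as discovery; between-cohort effect heterogeneity
  beyond sampling noise is not modelled.
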