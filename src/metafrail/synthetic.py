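"""Synthetic cohorts, twin samples, and paired GWAS summary statistics.

This module emulates the statistical structure that the downstream stages
assume, so the full discovery -> replication -> MR -> co-twin workflow is
testable without any restricted data:

* ``simulate_cohort`` draws block-correlated standardized biomarkers, a
  49-item deficit matrix in 11 labelled categories (deficit probabilities
  follow a logistic function of age, a latent frailty liability, and the
  configured biomarker effects), and 5 frailty-phenotype criteria from the
  same liability. Defaults reproduce discovery-cohort-like marginals
  (age 56.77 +/- 8.03 y, FI mean ~12%, right-skewed).
* ``simulate_twin_cohort`` draws MZ/DZ pairs sharing an additive-genetic
  factor (correlated 1.0 within MZ, 0.5 within DZ) and a fully shared
  environment factor, with configurable confounding channels.
* ``simulate_gwas_pair`` draws two-sample GWAS summary statistics: per-SNP
  exposure effects scaled to a target instrument heritability, outcome
  effects theta * gamma + pleiotropy, standard errors from sample size and
  allele frequency, and Wald-consistent p-values. A truth record always
  accompanies the data for parameter-recovery tests.

Seeds are mandatory; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._utils import derive_rng, wald_p
from .frailty import DeficitMatrix

__all__ = [
    "CohortConfig",
    "GwasSimConfig",
    "SimulatedCohort",
    "GwasTruth",
    "BlockLD",
    "default_category_map",
    "simulate_cohort",
    "simulate_twin_cohort",
    "simulate_gwas_pair",
    "simulate_outcome_battery",
]

#: 11 deficit categories with item counts summing to 49, echoing the
#: domain structure of a self-report deficit inventory (cardiometabolic
#: has 8 items so that stripping it leaves a 41-item FI).
_DEFAULT_CATEGORY_SIZES: dict[str, int] = {
    "cardiometabolic": 8,
    "cancer": 3,
    "immunological": 4,
    "musculoskeletal": 6,
    "mental": 6,
    "sensory": 4,
    "gastrointestinal": 4,
    "respiratory": 4,
    "genitourinary": 3,
    "pain": 4,
    "general": 3,
}

_FP_CRITERIA = ["weight_loss", "exhaustion", "slowness", "low_activity", "weakness"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def default_category_map(n_items: int = 49) -> dict[str, str]:
    """item -> category labels; 49 items spread over the 11 categories.

    For other item counts the category proportions are preserved as closely
    as possible while keeping all 11 categories non-empty (requires
    ``n_items >= 11``).
    """
    cats = list(_DEFAULT_CATEGORY_SIZES)
    if n_items < len(cats):
        raise ValueError(f"need at least {len(cats)} items to cover all categories")
    sizes = np.array([_DEFAULT_CATEGORY_SIZES[c] for c in cats], dtype=float)
    alloc = np.maximum(1, np.floor(sizes / sizes.sum() * n_items).astype(int))
    # distribute the remainder deterministically, largest categories first
    order = np.argsort(-sizes)
    i = 0
    while alloc.sum() < n_items:
        alloc[order[i % len(cats)]] += 1
        i += 1
    while alloc.sum() > n_items:
        j = order[i % len(cats)]
        if alloc[j] > 1:
            alloc[j] -= 1
        i += 1
    mapping: dict[str, str] = {}
    k = 1
    for cat, size in zip(cats, alloc):
        for _ in range(size):
            mapping[f"d{k:02d}"] = cat
            k += 1
    return mapping


@dataclass
class CohortConfig:
    """Conditions for one simulated cross-sectional cohort.

    ``true_effects`` maps biomarker names to effects on the FI scale
    (FI % per SD of the biomarker); ``covariate_effects`` likewise for
    covariates ("age" is per SD of age). ``biomarker_block_structure`` is a
    list of (block size, within-block correlation) pairs; unlisted
    biomarkers are independent.
    """

    n_individuals: int
    n_biomarkers: int
    seed: int
    biomarker_block_structure: Sequence[tuple[int, float]] = ()
    true_effects: Mapping[str, float] = field(default_factory=dict)
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    n_deficit_items: int = 49
    category_map: Mapping[str, str] | None = None
    age_mean_sd: tuple[float, float] = (56.77, 8.03)
    fi_target_mean_pct: float = 12.29
    liability_sd: float = 0.55
    deficit_missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_biomarkers <= 0:
            raise ValueError("cohort dimensions must be positive")
        if self.n_deficit_items < 11:
            raise ValueError("need at least as many deficit items as categories")
        for size, rho in self.biomarker_block_structure:
            if not (0.0 <= rho < 1.0):
                raise ValueError(f"within-block correlation {rho} not in [0, 1)")
            if size < 1:
                raise ValueError("block size must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.0 <= self.deficit_missing_rate < 1.0):
            raise ValueError("deficit_missing_rate must be in [0, 1)")

    def biomarker_names(self) -> list[str]:
        return [f"bm{j + 1:03d}" for j in range(self.n_biomarkers)]

    def resolved_category_map(self) -> dict[str, str]:
        if self.category_map is not None:
            return dict(self.category_map)
        return default_category_map(self.n_deficit_items)


@dataclass
class SimulatedCohort:
    """Phenotype table + deficit matrix + FP criteria + generating truth."""

    phenotypes: pd.DataFrame
    deficits: DeficitMatrix
    fp_criteria: pd.DataFrame
    truth: dict

    def table(self) -> pd.DataFrame:
        """Single flat table (phenotypes, deficit items, FP criteria)."""
        return pd.concat(
            [self.phenotypes, self.deficits.values, self.fp_criteria], axis=1
        )


def _draw_block_biomarkers(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Standard-normal biomarkers with the configured block-equicorrelation."""
    n, p = config.n_individuals, config.n_biomarkers
    out = np.empty((n, p))
    j = 0
    for size, rho in config.biomarker_block_structure:
        if j + size > p:
            raise ValueError("block structure exceeds n_biomarkers")
        shared = rng.standard_normal(n)[:, None]
        own = rng.standard_normal((n, size))
        out[:, j : j + size] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
        j += size
    if j < p:
        out[:, j:] = rng.standard_normal((n, p - j))
    return out


def _item_prevalences(config: CohortConfig) -> np.ndarray:
    """Per-item baseline prevalences, log-spaced and scaled to the FI target."""
    m = config.n_deficit_items
    raw = np.geomspace(0.02, 0.35, m)
    return raw * (config.fi_target_mean_pct / 100.0) / raw.mean()


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Draw a cohort with biomarkers, deficits, FP criteria and covariates.

    Each deficit item is Bernoulli with probability
    ``expit(logit(prevalence_i) + L)`` where the latent liability
    ``L = b_age * z_age + sum_j c_j * z_j + u``. The biomarker loadings
    ``c_j`` are the configured FI%-per-SD effects divided by the mean
    logistic slope ``100 * mean(p_i (1 - p_i))``, so that the regression of
    FI% on a biomarker z-score recovers the configured effect.
    """
    rng = derive_rng(config.seed, "cohort")
    n = config.n_individuals
    names = config.biomarker_names()

    age_mu, age_sd = config.age_mean_sd
    age = rng.normal(age_mu, age_sd, n)
    sex = rng.binomial(1, 0.545, n)  # 1 = female
    bmi = rng.normal(27.3, 4.7, n)
    smoking = rng.choice(["never", "previous", "current"], n, p=[0.55, 0.35, 0.10])
    alcohol = rng.choice(
        ["less_than_monthly", "weekly", "daily"], n, p=[0.285, 0.515, 0.20]
    )
    education = rng.choice(["low", "intermediate", "high"], n, p=[0.175, 0.50, 0.325])
    deprivation = rng.normal(-1.48, 3.00, n)

    z = _draw_block_biomarkers(config, rng)

    prev = _item_prevalences(config)
    slope = 100.0 * np.mean(prev * (1 - prev))  # d E[FI%] / d L at baseline
    z_age = (age - age_mu) / age_sd
    liability = config.covariate_effects.get("age", 2.0) / slope * z_age
    for cov_name, eff in config.covariate_effects.items():
        if cov_name == "age":
            continue
        if cov_name == "sex":
            liability = liability + eff / slope * (sex - sex.mean())
    for j, name in enumerate(names):
        eff = config.true_effects.get(name, 0.0)
        if eff != 0.0:
            liability = liability + eff / slope * z[:, j]
    liability = liability + rng.normal(0.0, config.liability_sd, n)

    # calibrate item intercepts so marginal prevalences hit their targets
    # despite the Jensen bias of the logistic link (Newton in the intercept)
    alpha = logit(prev)
    for _ in range(8):
        p_mat = expit(alpha[None, :] + liability[:, None])
        mean_p = p_mat.mean(axis=0)
        grad = (p_mat * (1 - p_mat)).mean(axis=0)
        alpha = alpha - (mean_p - prev) / np.maximum(grad, 1e-8)
    item_p = expit(alpha[None, :] + liability[:, None])
    items = (rng.random((n, config.n_deficit_items)) < item_p).astype(float)
    if config.deficit_missing_rate > 0:
        miss = rng.random(items.shape) < config.deficit_missing_rate
        items[miss] = np.nan

    fp_p = expit(logit(0.105) + liability[:, None])
    fp = (rng.random((n, 5)) < fp_p).astype(float)

    ids = pd.Index([f"id{i + 1:06d}" for i in range(n)], name="individual_id")
    cat_map = config.resolved_category_map()
    item_cols = list(cat_map)

    phenotypes = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "smoking": smoking,
            "alcohol": alcohol,
            "education": education,
            "deprivation": deprivation,
            **{name: z[:, j] for j, name in enumerate(names)},
        },
        index=ids,
    )
    deficits = DeficitMatrix(
        pd.DataFrame(items, index=ids, columns=item_cols), cat_map
    )
    fp_criteria = pd.DataFrame(fp, index=ids, columns=_FP_CRITERIA)
    truth = {
        "true_effects": dict(config.true_effects),
        "liability_slope": slope,
        "item_prevalences": prev,
    }
    return SimulatedCohort(phenotypes, deficits, fp_criteria, truth)


_TWIN_CONFOUNDING_MODES = ("none", "genetic", "shared_env")


def simulate_twin_cohort(
    config: CohortConfig,
    n_mz_pairs: int,
    n_dz_pairs: int,
    confounding: str = "none",
    confounder_effect: float = 0.0,
) -> pd.DataFrame:
    """Twin-pair table with a biomarker and FI% jointly driven by familial factors.

    A latent additive-genetic factor A is correlated 1.0 within MZ and 0.5
    within DZ pairs; a shared-environment factor C is correlated 1.0 within
    all pairs. Under ``confounding="genetic"`` (resp. ``"shared_env"``) the
    biomarker loads on A (resp. C) and the confounder also affects the FI
    with coefficient ``confounder_effect`` (FI % per SD of the factor).
    The direct biomarker -> FI effect is ``config.true_effects`` for the
    single generated biomarker column ``"biomarker"`` (0 if unset).

    Returns a long table: one row per twin with ``pair_id``, ``zygosity``,
    ``twin``, ``biomarker``, ``fi_pct`` and covariates.
    """
    if confounding not in _TWIN_CONFOUNDING_MODES:
        raise ValueError(
            f"unknown confounding mode {confounding!r}; "
            f"expected one of {_TWIN_CONFOUNDING_MODES}"
        )
    if n_mz_pairs < 0 or n_dz_pairs < 0:
        raise ValueError("pair counts must be non-negative")

    rng = derive_rng(config.seed, "twins", confounding)
    direct = config.true_effects.get("biomarker", 0.0)
    if direct == 0.0 and config.true_effects:
        direct = next(iter(config.true_effects.values()))

    frames = []
    for zyg, n_pairs, r_a in (("MZ", n_mz_pairs, 1.0), ("DZ", n_dz_pairs, 0.5)):
        if n_pairs == 0:
            continue
        shared_a = rng.standard_normal(n_pairs)
        own_a = rng.standard_normal((n_pairs, 2))
        a = np.sqrt(r_a) * shared_a[:, None] + np.sqrt(1 - r_a) * own_a
        c = np.repeat(rng.standard_normal(n_pairs)[:, None], 2, axis=1)

        e_x = rng.standard_normal((n_pairs, 2))
        if confounding == "genetic":
            x = np.sqrt(0.5) * a + np.sqrt(0.5) * e_x
            familial = a
        elif confounding == "shared_env":
            x = np.sqrt(0.5) * c + np.sqrt(0.5) * e_x
            familial = c
        else:
            x = e_x
            familial = np.zeros_like(e_x)

        age = np.repeat(rng.normal(58.3, 7.9, n_pairs)[:, None], 2, axis=1)
        sex = np.repeat(rng.binomial(1, 0.55, n_pairs)[:, None], 2, axis=1)
        bmi = rng.normal(25.0, 3.3, (n_pairs, 2))
        edu_years = np.repeat(rng.normal(11.5, 3.0, n_pairs)[:, None], 2, axis=1)

        fi = (
            12.0
            + 2.0 * (age - 58.3) / 7.9
            + direct * x
            + confounder_effect * familial
            + rng.normal(0.0, 6.0, (n_pairs, 2))
        )
        fi = np.clip(fi, 0.0, 100.0)

        pair_ids = [f"{zyg}{i + 1:05d}" for i in range(n_pairs)]
        frames.append(
            pd.DataFrame(
                {
                    "pair_id": np.repeat(pair_ids, 2),
                    "zygosity": zyg,
                    "twin": np.tile([1, 2], n_pairs),
                    "biomarker": x.ravel(),
                    "fi_pct": fi.ravel(),
                    "age": age.ravel(),
                    "sex": sex.ravel(),
                    "bmi": bmi.ravel(),
                    "education_years": edu_years.ravel(),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "pair_id", "zygosity", "twin", "biomarker", "fi_pct",
                "age", "sex", "bmi", "education_years",
            ]
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class GwasSimConfig:
    """Conditions for one paired exposure/outcome summary-statistic draw."""

    n_snps: int
    n_exposure: int
    n_outcome: int
    theta: float
    seed: int
    exposure_h2: float = 0.1
    pleiotropy_mode: str = "none"  # none | balanced | directional | outlier
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_outliers: int = 0
    outlier_scale: float | None = None
    inside_violated: bool = False
    palindromic_fraction: float = 0.0
    ld_blocks: Sequence[tuple[int, float]] = ()
    category_mediation: Mapping[str, float] = field(default_factory=dict)
    theta_fp: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.theta):
            raise ValueError("theta must be finite")
        if not (0.0 < self.exposure_h2 < 1.0):
            raise ValueError("exposure_h2 must be in (0, 1)")
        if not (0.0 <= self.palindromic_fraction <= 1.0):
            raise ValueError("palindromic_fraction must be in [0, 1]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "outlier"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.n_outliers > self.n_snps:
            raise ValueError("n_outliers cannot exceed n_snps")
        for frac in self.category_mediation.values():
            if not (0.0 <= frac <= 1.0):
                raise ValueError("mediation fractions must be in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class GwasTruth:
    """Generating truth stored alongside simulated summary statistics."""

    theta: float
    gamma: np.ndarray  # true per-allele exposure effects (aligned to snp ids)
    alpha: np.ndarray  # per-SNP direct (pleiotropic) outcome effects
    outlier_ids: list[str]
    snp_ids: list[str]
    ld: "BlockLD"
    category_mediation: dict[str, float]
    theta_fp: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.snp_ids,
                "gamma": self.gamma,
                "alpha": self.alpha,
                "is_outlier": [s in set(self.outlier_ids) for s in self.snp_ids],
            }
        )


class BlockLD:
    """Pairwise r^2 source defined by block labels (block-constant r^2).

    SNPs sharing a block label have the block's r^2; all other pairs have
    r^2 = 0. This stands in for a reference-panel LD lookup.
    """

    def __init__(self, blocks: Mapping[str, int], r2_by_block: Mapping[int, float]):
        self._blocks = dict(blocks)
        self._r2 = dict(r2_by_block)

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        ba = self._blocks.get(snp_a)
        bb = self._blocks.get(snp_b)
        if ba is None or bb is None or ba != bb:
            return 0.0
        return self._r2.get(ba, 0.0)


def _assign_alleles(
    n: int, palindromic_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n_pal = int(round(palindromic_fraction * n))
    ea = np.empty(n, dtype="<U1")
    oa = np.empty(n, dtype="<U1")
    pal_pairs = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
    nonpal = [
        (a, b)
        for a in "ACGT"
        for b in "ACGT"
        if a != b and _COMPLEMENT[a] != b
    ]
    idx = rng.permutation(n)
    for k, i in enumerate(idx):
        pair = pal_pairs[rng.integers(4)] if k < n_pal else nonpal[rng.integers(len(nonpal))]
        ea[i], oa[i] = pair
    return ea, oa


def _positions(config: GwasSimConfig, blocks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Chromosome/position layout: LD blocks are contiguous within 50 kb;
    independent SNPs sit > 10 Mb apart."""
    chrom = np.empty(config.n_snps, dtype=int)
    pos = np.empty(config.n_snps, dtype=int)
    cur_chrom, cur_pos = 1, 1_000_000
    prev_block = None
    for j in range(config.n_snps):
        if blocks[j] >= 0 and blocks[j] == prev_block:
            cur_pos += 5_000  # stay inside the clumping window
        else:
            cur_pos += 20_000_000
            if cur_pos > 240_000_000:
                cur_chrom = cur_chrom % 22 + 1
                cur_pos = 1_000_000
        chrom[j] = cur_chrom
        pos[j] = cur_pos
        prev_block = blocks[j]
    return chrom, pos


def _truth_outcome_effects(
    config: GwasSimConfig, gamma: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, list[int]]:
    """Per-SNP pleiotropic effects alpha and outlier indices."""
    n = config.n_snps
    alpha = np.zeros(n)
    outlier_idx: list[int] = []
    if config.pleiotropy_mode == "balanced":
        sd = config.pleiotropy_sd or abs(config.pleiotropy_mean) or 0.02
        alpha = rng.normal(0.0, sd, n)
    elif config.pleiotropy_mode == "directional":
        # directional relative to the exposure-increasing allele (the
        # orientation MR-Egger fits under), hence the sign(gamma) factor
        alpha = np.sign(gamma) * rng.normal(
            config.pleiotropy_mean, config.pleiotropy_sd, n
        )
    elif config.pleiotropy_mode == "outlier":
        if config.n_outliers < 1:
            raise ValueError("outlier mode requires n_outliers >= 1")
        outlier_idx = list(rng.choice(n, size=config.n_outliers, replace=False))
        scale = config.outlier_scale
        if scale is None:
            base = abs(config.theta) * np.mean(np.abs(gamma))
            scale = 10.0 * base if base > 0 else 0.1
        signs = rng.choice([-1.0, 1.0], size=config.n_outliers)
        alpha[outlier_idx] = signs * scale
    if config.inside_violated and config.pleiotropy_mode != "none":
        # correlate alpha with instrument strength (violates InSIDE)
        alpha = alpha + 0.5 * np.std(alpha) / max(np.std(gamma), 1e-12) * gamma
    return alpha, outlier_idx


def simulate_gwas_pair(
    config: GwasSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GwasTruth]:
    """Two-sample GWAS summary statistics for an exposure and an outcome.

    Exposure effects gamma_j are scaled so instruments jointly explain
    ``exposure_h2`` of the (standardized) exposure variance; outcome effects
    are ``theta * gamma_j + alpha_j`` with alpha per the pleiotropy regime.
    Standard errors follow se = 1/sqrt(2 f (1-f) n) for standardized traits
    and p-values satisfy the Wald relation exactly.
    """
    rng = derive_rng(config.seed, "gwas")
    n = config.n_snps

    eaf = rng.uniform(0.05, 0.95, n)
    gamma = rng.standard_normal(n)
    var_j = 2.0 * eaf * (1 - eaf)
    gamma *= np.sqrt(config.exposure_h2 / np.sum(var_j * gamma**2))

    alpha, outlier_idx = _truth_outcome_effects(config, gamma, rng)

    se_x = 1.0 / np.sqrt(var_j * config.n_exposure)
    se_y = 1.0 / np.sqrt(var_j * config.n_outcome)
    beta_x = gamma + rng.normal(0.0, se_x)
    beta_y_true = config.theta * gamma + alpha
    beta_y = beta_y_true + rng.normal(0.0, se_y)

    ea, oa = _assign_alleles(n, config.palindromic_fraction, rng)

    # LD blocks: consecutive SNPs grouped per (size, r2); -1 = independent
    blocks = np.full(n, -1)
    r2_by_block: dict[int, float] = {}
    j = 0
    for b, (size, r2) in enumerate(config.ld_blocks):
        if j + size > n:
            raise ValueError("ld_blocks exceed n_snps")
        blocks[j : j + size] = b
        r2_by_block[b] = r2
        j += size
    chrom, pos = _positions(config, blocks)

    snp_ids = [f"rs{j + 1:07d}" for j in range(n)]

    def _frame(beta, se, n_sample):
        return pd.DataFrame(
            {
                "variant_id": snp_ids,
                "chromosome": chrom,
                "base_pair_location": pos,
                "effect_allele": ea,
                "other_allele": oa,
                "effect_allele_frequency": eaf,
                "beta": beta,
                "standard_error": se,
                "p_value": wald_p(beta, se),
                "n": n_sample,
            }
        )

    exposure = _frame(beta_x, se_x, config.n_exposure)
    outcome = _frame(beta_y, se_y, config.n_outcome)
    truth = GwasTruth(
        theta=config.theta,
        gamma=gamma,
        alpha=alpha,
        outlier_ids=[snp_ids[i] for i in outlier_idx],
        snp_ids=snp_ids,
        ld=BlockLD({snp_ids[j]: blocks[j] for j in range(n) if blocks[j] >= 0},
                   r2_by_block),
        category_mediation=dict(config.category_mediation),
        theta_fp=config.theta_fp,
    )
    return exposure, outcome, truth


def simulate_outcome_battery(
    config: GwasSimConfig,
    categories: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], GwasTruth]:
    """Exposure stats plus outcome stats for the FI, the FP, and stripped FIs.

    The total causal effect on the full FI decomposes into a direct channel
    plus per-category channels: theta_c = theta * category_mediation[c].
    The outcome for the FI stripped of category c has causal effect
    theta - theta_c. All outcomes share the same per-SNP sampling-noise
    draw (scaled by se), so estimates on non-mediated stripped FIs track the
    full-FI estimate closely.
    """
    if categories is None:
        categories = list(_DEFAULT_CATEGORY_SIZES)
    med = dict(config.category_mediation)
    unknown = set(med) - set(categories)
    if unknown:
        raise ValueError(f"mediation categories not in outcome set: {sorted(unknown)}")
    if sum(med.values()) > 1.0 + 1e-12:
        raise ValueError("mediation fractions sum to more than 1")

    exposure, outcome_fi, truth = simulate_gwas_pair(config)
    rng = derive_rng(config.seed, "gwas-outcomes")
    se_y = outcome_fi["standard_error"].to_numpy()
    shared_noise = rng.standard_normal(config.n_snps)

    outcomes: dict[str, pd.DataFrame] = {"fi": outcome_fi}

    def _with_effect(theta_eff: float) -> pd.DataFrame:
        beta = theta_eff * truth.gamma + truth.alpha + shared_noise * se_y
        df = outcome_fi.copy()
        df["beta"] = beta
        df["p_value"] = wald_p(beta, se_y)
        return df

    fp_df = _with_effect(config.theta_fp)
    # FP is on its own score scale; alpha still applies as generic pleiotropy
    outcomes["fp"] = fp_df
    for cat in categories:
        theta_stripped = config.theta * (1.0 - med.get(cat, 0.0))
        outcomes[f"fi_stripped_{cat}"] = _with_effect(theta_stripped)
    return exposure, outcomes, truth
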