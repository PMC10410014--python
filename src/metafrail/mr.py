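"""Two-sample Mendelian randomization engine.

Implements the full estimator suite used for biomarker -> frailty causal
inference from GWAS summary statistics:

* instrument selection (genome-wide significance + greedy LD clumping),
* allele harmonization across the exposure and outcome studies (strand
  flips, palindromic-SNP handling, frequency alignment),
* instrument-strength F-statistics,
* IVW with multiplicative random effects (the primary estimator),
* MR-Egger (directional-pleiotropy intercept under InSIDE),
* weighted median (valid if >50% of weight is on valid instruments),
* weighted mode (valid under a plurality of valid instruments),
* MR-PRESSO (simulation-based global pleiotropy test and per-SNP outlier
  detection with outlier-corrected re-estimation),
* Cochran's Q heterogeneity, Benjamini-Hochberg FDR, pleiotropy pruning,
  and a battery runner over exposures x outcomes x methods.

All estimators consume a :class:`HarmonizedInstruments` set holding
allele-aligned per-SNP effect pairs (beta_x, se_x, beta_y, se_y) and the
per-SNP Wald ratios beta_j = beta_y/beta_x with sigma_j = se_y/|beta_x|
(first-order weights).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import derive_rng

logger = logging.getLogger(__name__)

__all__ = [
    "LDSource",
    "TableLD",
    "HarmonizedInstruments",
    "MREstimate",
    "select_instruments",
    "harmonize",
    "f_statistic",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "weighted_mode",
    "mr_presso",
    "cochran_q",
    "bh_fdr",
    "prune_pleiotropic",
    "run_mr_battery",
]

_Z95 = 1.959963984540054
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

SUMMARY_COLUMNS = [
    "variant_id",
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "effect_allele_frequency",
    "beta",
    "standard_error",
    "p_value",
    "n",
]


class LDSource(Protocol):
    """Pairwise linkage-disequilibrium lookup."""

    def r2(self, snp_a: str, snp_b: str) -> float: ...


class TableLD:
    """LD source backed by a (snp_a, snp_b, r2) table; symmetric lookup."""

    def __init__(self, pairs: pd.DataFrame):
        required = {"snp_a", "snp_b", "r2"}
        if not required.issubset(pairs.columns):
            raise ValueError(f"LD table needs columns {sorted(required)}")
        self._r2: dict[tuple[str, str], float] = {}
        for a, b, r in pairs[["snp_a", "snp_b", "r2"]].itertuples(index=False):
            self._r2[(a, b)] = float(r)
            self._r2[(b, a)] = float(r)

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        return self._r2.get((snp_a, snp_b), 0.0)


@dataclass
class HarmonizedInstruments:
    """Allele-aligned per-SNP exposure/outcome effect pairs."""

    table: pd.DataFrame  # variant_id, beta_x, se_x, beta_y, se_y, ratio, ratio_se, flipped
    dropped: pd.DataFrame  # variant_id, reason

    @property
    def n_snp(self) -> int:
        return len(self.table)

    def __post_init__(self) -> None:
        t = self.table
        if len(t) and np.any(t["se_x"].to_numpy() <= 0):
            raise ValueError("se_x must be positive")
        if len(t) and np.any(t["se_y"].to_numpy() <= 0):
            raise ValueError("se_y must be positive")

    def arrays(self):
        t = self.table
        return (
            t["beta_x"].to_numpy(float),
            t["se_x"].to_numpy(float),
            t["beta_y"].to_numpy(float),
            t["se_y"].to_numpy(float),
        )


@dataclass
class MREstimate:
    """One method's causal estimate with inference and diagnostics."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_snp: int
    Q: float | None = None
    Q_df: int | None = None
    Q_p: float | None = None
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    outlier_ids: list[str] = field(default_factory=list)
    fdr_q: float | None = None

    @classmethod
    def build(cls, method, beta, se, n_snp, **kw):
        beta, se = float(beta), float(se)
        return cls(
            method=method,
            beta=beta,
            se=se,
            ci_low=beta - _Z95 * se,
            ci_high=beta + _Z95 * se,
            p=float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else np.nan,
            n_snp=int(n_snp),
            **kw,
        )


# ---------------------------------------------------------------------------
# instrument selection and harmonization


def select_instruments(
    exposure: pd.DataFrame,
    ld: LDSource,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> list[str]:
    """Genome-wide significant, LD-clumped instrument list.

    Greedy clumping: sort SNPs passing ``p_threshold`` by ascending p;
    repeatedly keep the best remaining SNP and discard all others within
    ``window_kb`` on the same chromosome with r^2 >= ``r2_threshold``.
    """
    passing = exposure.loc[exposure["p_value"] < p_threshold]
    if passing.empty:
        warnings.warn("no SNP passes the significance threshold", stacklevel=2)
        return []
    passing = passing.sort_values(["p_value", "variant_id"], kind="mergesort")
    window_bp = window_kb * 1_000
    kept: list[str] = []
    kept_rows: list[tuple[str, int, int]] = []
    for row in passing.itertuples(index=False):
        snp = row.variant_id
        ok = True
        for ksnp, kchrom, kpos in kept_rows:
            if (
                row.chromosome == kchrom
                and abs(row.base_pair_location - kpos) <= window_bp
                and ld.r2(snp, ksnp) >= r2_threshold
            ):
                ok = False
                break
        if ok:
            kept.append(snp)
            kept_rows.append((snp, row.chromosome, row.base_pair_location))
    return kept


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    instruments: Sequence[str],
    palindromic_maf: float = 0.42,
) -> HarmonizedInstruments:
    """Align outcome records to the exposure's effect-allele coding.

    Rules, per instrument SNP:

    * absent from the outcome study -> dropped (``missing_in_outcome``);
    * outcome alleles equal to the exposure's (directly or after strand
      complement) -> pass-through; swapped -> outcome beta sign flipped and
      EAF complemented;
    * strand-ambiguous (A/T, C/G) SNPs with exposure-study
      min(EAF, 1-EAF) > ``palindromic_maf`` -> dropped
      (``palindromic_high_maf``); remaining palindromic SNPs are aligned by
      allele frequency (flip when EAFs sit on opposite sides of 0.5);
    * irreconcilable allele pairs -> dropped (``allele_mismatch``).

    Wald ratios ``beta_y/beta_x`` and first-order SEs ``se_y/|beta_x|`` are
    attached to every retained SNP.
    """
    exp = exposure.set_index("variant_id")
    out = outcome.set_index("variant_id")

    rows, dropped = [], []
    for snp in instruments:
        if snp not in exp.index:
            raise KeyError(f"instrument {snp!r} missing from exposure stats")
        if snp not in out.index:
            dropped.append({"variant_id": snp, "reason": "missing_in_outcome"})
            continue
        e = exp.loc[snp]
        o = out.loc[snp]
        ea, oa = e["effect_allele"], e["other_allele"]
        oea, ooa = o["effect_allele"], o["other_allele"]
        beta_y = float(o["beta"])
        eaf_y = float(o["effect_allele_frequency"])

        if _is_palindromic(ea, oa):
            eaf_x = float(e["effect_allele_frequency"])
            maf = min(eaf_x, 1 - eaf_x)
            if maf > palindromic_maf:
                dropped.append({"variant_id": snp, "reason": "palindromic_high_maf"})
                continue
            if {oea, ooa} != {ea, oa}:
                dropped.append({"variant_id": snp, "reason": "allele_mismatch"})
                continue
            # nominal alignment by allele label, then frequency check
            flipped = oea != ea
            if flipped:
                beta_y, eaf_y = -beta_y, 1 - eaf_y
            if (eaf_x - 0.5) * (eaf_y - 0.5) < 0:
                beta_y, eaf_y = -beta_y, 1 - eaf_y
                flipped = not flipped
        else:
            if (oea, ooa) == (ea, oa):
                flipped = False
            elif (oea, ooa) == (oa, ea):
                flipped = True
            elif (_COMPLEMENT.get(oea), _COMPLEMENT.get(ooa)) == (ea, oa):
                flipped = False
            elif (_COMPLEMENT.get(oea), _COMPLEMENT.get(ooa)) == (oa, ea):
                flipped = True
            else:
                dropped.append({"variant_id": snp, "reason": "allele_mismatch"})
                continue
            if flipped:
                beta_y, eaf_y = -beta_y, 1 - eaf_y

        beta_x = float(e["beta"])
        se_x = float(e["standard_error"])
        se_y = float(o["standard_error"])
        rows.append(
            {
                "variant_id": snp,
                "beta_x": beta_x,
                "se_x": se_x,
                "beta_y": beta_y,
                "se_y": se_y,
                "eaf_x": float(e["effect_allele_frequency"]),
                "eaf_y": eaf_y,
                "ratio": beta_y / beta_x,
                "ratio_se": se_y / abs(beta_x),
                "flipped": flipped,
            }
        )
    return HarmonizedInstruments(
        table=pd.DataFrame(
            rows,
            columns=[
                "variant_id", "beta_x", "se_x", "beta_y", "se_y",
                "eaf_x", "eaf_y", "ratio", "ratio_se", "flipped",
            ],
        ),
        dropped=pd.DataFrame(dropped, columns=["variant_id", "reason"]),
    )


def f_statistic(hset: HarmonizedInstruments) -> tuple[pd.Series, float]:
    """Per-SNP instrument strength F_j = (beta_x / se_x)^2, and the mean F."""
    bx, sx, _, _ = hset.arrays()
    f = (bx / sx) ** 2
    series = pd.Series(f, index=hset.table["variant_id"].to_numpy(), name="F")
    return series, float(f.mean()) if len(f) else float("nan")


# ---------------------------------------------------------------------------
# estimators


def wald_ratio(hset: HarmonizedInstruments) -> MREstimate:
    """Single-instrument fallback: Wald ratio with delta-method SE."""
    if hset.n_snp != 1:
        raise ValueError("wald_ratio requires exactly one SNP")
    bx, _, by, sy = hset.arrays()
    return MREstimate.build(
        "wald_ratio", by[0] / bx[0], sy[0] / abs(bx[0]), 1
    )


def _ivw_core(bx, by, sy):
    w = sy**-2.0
    theta = np.sum(w * bx * by) / np.sum(w * bx**2)
    se_fixed = np.sum(w * bx**2) ** -0.5
    Q = float(np.sum(w * (by - theta * bx) ** 2))
    return float(theta), float(se_fixed), Q


def ivw(hset: HarmonizedInstruments) -> MREstimate:
    """Multiplicative random-effects IVW: weighted regression of beta_y on
    beta_x through the origin with weights se_y^-2; the fixed-effect SE is
    inflated by max(1, sqrt(Q/(J-1)))."""
    if hset.n_snp < 2:
        raise ValueError("IVW needs >= 2 SNPs (use wald_ratio for one)")
    bx, _, by, sy = hset.arrays()
    theta, se_fixed, Q = _ivw_core(bx, by, sy)
    J = hset.n_snp
    scale = max(1.0, np.sqrt(Q / (J - 1)))
    q_p = float(stats.chi2.sf(Q, J - 1))
    return MREstimate.build(
        "IVW", theta, se_fixed * scale, J, Q=Q, Q_df=J - 1, Q_p=q_p
    )


def mr_egger(hset: HarmonizedInstruments) -> MREstimate:
    """Weighted regression beta_y = alpha + theta * beta_x (weights se_y^-2),
    after orienting every SNP so beta_x >= 0. The intercept estimates the
    average directional pleiotropic effect; SEs carry the multiplicative
    overdispersion factor max(1, sqrt(Q_egger/(J-2)))."""
    if hset.n_snp < 3:
        raise ValueError("MR-Egger needs >= 3 SNPs")
    bx, _, by, sy = hset.arrays()
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = sy**-2.0
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtx = X.T @ WX
    xty = WX.T @ by
    coef = np.linalg.solve(xtx, xty)
    resid = by - X @ coef
    J = hset.n_snp
    Q = float(np.sum(w * resid**2))
    scale2 = max(1.0, Q / (J - 2))
    cov = np.linalg.inv(xtx) * scale2
    alpha, theta = coef
    se_a, se_t = np.sqrt(np.diag(cov))
    return MREstimate.build(
        "Egger",
        theta,
        se_t,
        J,
        Q=Q,
        Q_df=J - 2,
        Q_p=float(stats.chi2.sf(Q, J - 2)),
        egger_intercept=float(alpha),
        intercept_se=float(se_a),
        intercept_p=float(2 * stats.norm.sf(abs(alpha / se_a))),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    # percentile of each sorted ratio: cumulative weight minus half its own
    p = np.cumsum(w) - w / 2
    return float(np.interp(0.5, p, r))


def _bootstrap_se(hset, point_fn, n_boot, seed, tag):
    # canonical SNP order so the draw (and hence the SE) does not depend
    # on input row order
    order = np.argsort(hset.table["variant_id"].to_numpy(), kind="mergesort")
    bx, sx, by, sy = (a[order] for a in hset.arrays())
    rng = derive_rng(seed, "mr-bootstrap", tag)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + rng.normal(0.0, sx)
        byb = by + rng.normal(0.0, sy)
        ests[b] = point_fn(byb / bxb, np.abs(bxb) / sy)
    return float(ests.std(ddof=1))


def weighted_median(
    hset: HarmonizedInstruments, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of the per-SNP Wald ratios (weights sigma_j^-2);
    consistent when valid instruments carry >50% of the weight. SE by
    seeded parametric bootstrap of the summary statistics."""
    if hset.n_snp < 3:
        raise ValueError("weighted median needs >= 3 SNPs")
    t = hset.table
    ratios = t["ratio"].to_numpy(float)
    weights = t["ratio_se"].to_numpy(float) ** -2.0
    point = _weighted_median_point(ratios, weights)
    se = _bootstrap_se(
        hset,
        lambda r, inv_sigma: _weighted_median_point(r, inv_sigma**2),
        n_boot,
        seed,
        "median",
    )
    return MREstimate.build("weighted_median", point, se, hset.n_snp)


def _weighted_mode_point(
    ratios: np.ndarray, weights: np.ndarray, phi: float = 1.0, n_grid: int = 512
) -> float:
    w = weights / weights.sum()
    mu = np.sum(w * ratios)
    sd = np.sqrt(np.sum(w * (ratios - mu) ** 2))
    order = np.argsort(ratios)
    cw = np.cumsum(w[order])
    q25 = np.interp(0.25, cw, ratios[order])
    q75 = np.interp(0.75, cw, ratios[order])
    spread = min(sd, (q75 - q25) / 1.34)
    h = phi * 0.9 * spread * len(ratios) ** (-1 / 5)
    if h <= 0 or not np.isfinite(h):
        return float(ratios[0])  # all ratios identical
    grid = np.linspace(ratios.min(), ratios.max(), n_grid)
    dens = np.sum(
        w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2),
        axis=1,
    )
    return float(grid[np.argmax(dens)])


def weighted_mode(
    hset: HarmonizedInstruments,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode of the normal-kernel weighted density of the Wald ratios
    (modified Silverman bandwidth scaled by ``phi``); consistent when the
    largest group of instruments sharing a ratio is valid (plurality)."""
    if hset.n_snp < 3:
        raise ValueError("weighted mode needs >= 3 SNPs")
    t = hset.table
    ratios = t["ratio"].to_numpy(float)
    weights = t["ratio_se"].to_numpy(float) ** -2.0
    point = _weighted_mode_point(ratios, weights, phi=phi)
    se = _bootstrap_se(
        hset,
        lambda r, inv_sigma: _weighted_mode_point(r, inv_sigma**2, phi=phi),
        n_boot,
        seed,
        "mode",
    )
    return MREstimate.build("weighted_mode", point, se, hset.n_snp)


def cochran_q(hset: HarmonizedInstruments, theta: float) -> tuple[float, int, float]:
    """Heterogeneity across instruments: Q = sum sigma_j^-2 (ratio_j - theta)^2."""
    if hset.n_snp < 2:
        raise ValueError("Cochran's Q needs >= 2 SNPs")
    t = hset.table
    w = t["ratio_se"].to_numpy(float) ** -2.0
    Q = float(np.sum(w * (t["ratio"].to_numpy(float) - theta) ** 2))
    df = hset.n_snp - 1
    return Q, df, float(stats.chi2.sf(Q, df))


def mr_presso(
    hset: HarmonizedInstruments,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> tuple[MREstimate, MREstimate, float, list[str]]:
    """Pleiotropy residual-sum-and-outlier test.

    Each SNP's weighted squared residual is computed against the IVW fit
    that excludes it (leave-one-out). The observed global RSS is compared
    with ``n_sim`` simulated RSS values drawn under no pleiotropy from the
    per-SNP sampling distributions (global p); each SNP's residual is
    compared with its own simulated distribution and Bonferroni-corrected
    by J (outlier p). Flagged SNPs are removed and IVW re-estimated.

    Returns ``(raw, corrected, global_p, outlier_ids)``; with no outliers
    the corrected estimate equals the raw one.
    """
    J = hset.n_snp
    if J < 4:
        raise ValueError("MR-PRESSO needs >= 4 SNPs")
    order = np.argsort(hset.table["variant_id"].to_numpy(), kind="mergesort")
    bx, sx, by, sy = (a[order] for a in hset.arrays())
    w = sy**-2.0

    # leave-one-out IVW slopes
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx**2)
    theta_loo = (sxy - w * bx * by) / (sxx - w * bx**2)

    resid_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(resid_obs.sum())

    rng = derive_rng(seed, "mr-presso")
    exceed_global = 0
    exceed_snp = np.zeros(J)
    for _ in range(n_sim):
        bx_s = bx + rng.normal(0.0, sx)
        by_s = theta_loo * bx + rng.normal(0.0, sy)
        r_s = w * (by_s - theta_loo * bx_s) ** 2
        exceed_global += r_s.sum() >= rss_obs
        exceed_snp += r_s >= resid_obs
    global_p = exceed_global / n_sim
    p_snp = np.minimum(1.0, exceed_snp / n_sim * J)  # Bonferroni by J

    snp_ids = hset.table["variant_id"].to_numpy()[order]
    outliers = [snp_ids[j] for j in range(J) if p_snp[j] < outlier_alpha]

    raw = ivw(hset)
    raw.method = "PRESSO_raw"
    raw.outlier_ids = list(outliers)
    if outliers and J - len(outliers) >= 2:
        keep = ~hset.table["variant_id"].isin(outliers)
        sub = HarmonizedInstruments(
            hset.table.loc[keep].reset_index(drop=True), hset.dropped
        )
        corrected = ivw(sub)
    else:
        corrected = ivw(hset)
    corrected.method = "PRESSO_corrected"
    corrected.outlier_ids = list(outliers)
    return raw, corrected, float(global_p), outliers


# ---------------------------------------------------------------------------
# multiple testing and sensitivity utilities


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Benjamini-Hochberg step-up.

    Returns (adjusted p-values, rejection flags, largest rejected raw p).
    The last value is the data-dependent per-test threshold; ``None`` when
    nothing is rejected.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj, 1.0)

    below = np.flatnonzero(ranked <= np.arange(1, m + 1) * q / m)
    reject = np.zeros(m, dtype=bool)
    threshold: float | None = None
    if below.size:
        k = below[-1]
        reject[order[: k + 1]] = True
        threshold = float(ranked[k])
    return adjusted, reject, threshold


def prune_pleiotropic(
    instruments: Sequence[str],
    other_exposures: Mapping[str, pd.DataFrame],
    p_threshold: float = 5e-8,
) -> tuple[list[str], pd.DataFrame]:
    """Drop instruments genome-wide significant for any other exposure.

    Returns the reduced list and a removal log (variant_id, exposure, p).
    """
    removals = []
    removed: set[str] = set()
    for name, stats_df in other_exposures.items():
        sub = stats_df.set_index("variant_id")["p_value"]
        for snp in instruments:
            if snp in sub.index and float(sub.loc[snp]) < p_threshold:
                removals.append(
                    {"variant_id": snp, "exposure": name, "p_value": float(sub.loc[snp])}
                )
                removed.add(snp)
    kept = [s for s in instruments if s not in removed]
    if not kept:
        warnings.warn(
            "pleiotropy pruning removed every instrument "
            "(highly reduced number of genetic instruments)",
            stacklevel=2,
        )
    return kept, pd.DataFrame(removals, columns=["variant_id", "exposure", "p_value"])


# ---------------------------------------------------------------------------
# battery


@dataclass
class MRBatteryConfig:
    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: float = 10_000
    palindromic_maf: float = 0.42
    fdr_q: float = 0.05
    n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    seed: int = 0
    primary_outcomes: tuple[str, ...] = ("fi", "fp")


def _estimate_rows(name_exp, name_out, hset, cfg: MRBatteryConfig) -> list[MREstimate]:
    ests: list[MREstimate] = []
    if hset.n_snp == 0:
        return ests
    if hset.n_snp == 1:
        ests.append(wald_ratio(hset))
        return ests
    ests.append(ivw(hset))
    if hset.n_snp >= 3:
        ests.append(mr_egger(hset))
        seed = derive_seed_pair(cfg.seed, name_exp, name_out)
        ests.append(weighted_median(hset, n_boot=cfg.n_boot, seed=seed))
        ests.append(weighted_mode(hset, n_boot=cfg.n_boot, seed=seed))
    if hset.n_snp >= 4:
        raw, corrected, global_p, _ = mr_presso(
            hset,
            n_sim=cfg.presso_n_sim,
            outlier_alpha=cfg.presso_outlier_alpha,
            seed=derive_seed_pair(cfg.seed, name_exp, name_out),
        )
        raw.Q_p = global_p  # global pleiotropy p reported alongside
        ests.extend([raw, corrected])
    return ests


def derive_seed_pair(seed: int, *keys: object) -> int:
    from ._utils import derive_seed

    return derive_seed(seed, *keys)


def run_mr_battery(
    exposures: Mapping[str, pd.DataFrame],
    outcomes: Mapping[str, pd.DataFrame],
    ld: LDSource,
    config: MRBatteryConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full estimator battery across exposures x outcomes.

    Instruments are selected per exposure, harmonized against each outcome,
    and every applicable estimator is run. BH-FDR is applied across the
    primary IVW family (exposures x primary outcomes, FI and FP by
    default). Per-pair failures are logged and the battery continues.

    Returns a tidy results frame and a run log recording thresholds, the
    FDR family size, mean instrument strength, and any failures.
    """
    cfg = config or MRBatteryConfig()
    rows = []
    failures = []
    for name_exp, exp_stats in exposures.items():
        instruments = select_instruments(
            exp_stats, ld, cfg.p_threshold, cfg.r2_threshold, cfg.window_kb
        )
        for name_out, out_stats in outcomes.items():
            try:
                hset = harmonize(
                    exp_stats, out_stats, instruments, cfg.palindromic_maf
                )
                _, mean_f = f_statistic(hset)
                for est in _estimate_rows(name_exp, name_out, hset, cfg):
                    rows.append(
                        {
                            "exposure": name_exp,
                            "outcome": name_out,
                            "method": est.method,
                            "beta": est.beta,
                            "se": est.se,
                            "ci_low": est.ci_low,
                            "ci_high": est.ci_high,
                            "p": est.p,
                            "n_snp": est.n_snp,
                            "Q": est.Q,
                            "Q_p": est.Q_p,
                            "egger_intercept": est.egger_intercept,
                            "intercept_p": est.intercept_p,
                            "outlier_ids": ";".join(est.outlier_ids),
                            "mean_f": mean_f,
                        }
                    )
            except Exception as exc:  # battery continues past per-pair failures
                logger.warning("MR failed for %s -> %s: %s", name_exp, name_out, exc)
                failures.append(
                    {"exposure": name_exp, "outcome": name_out, "error": str(exc)}
                )
    results = pd.DataFrame(rows)

    fdr_family = 0
    if not results.empty:
        primary = results[
            results["method"].isin(["IVW", "wald_ratio"])
            & results["outcome"].isin(cfg.primary_outcomes)
        ]
        fdr_family = len(primary)
        if fdr_family:
            adjusted, reject, threshold = bh_fdr(primary["p"].to_numpy(), cfg.fdr_q)
            results.loc[primary.index, "fdr_q"] = adjusted
            results.loc[primary.index, "fdr_significant"] = reject
    run_log = {
        "p_threshold": cfg.p_threshold,
        "r2_threshold": cfg.r2_threshold,
        "window_kb": cfg.window_kb,
        "palindromic_maf": cfg.palindromic_maf,
        "fdr_q": cfg.fdr_q,
        "fdr_family_size": fdr_family,
        "n_exposures": len(exposures),
        "n_outcomes": len(outcomes),
        "seed": cfg.seed,
        "failures": failures,
    }
    return results, run_log
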