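"""Co-twin control analysis of biomarker-FI associations.

Comparing population-level estimates with within-twin-pair estimates
separates a direct association from familial confounding: MZ co-twins share
all segregating genes and the rearing environment, DZ co-twins share about
half their genes and the rearing environment. A causal (non-familial)
association keeps its size within pairs; genetic confounding attenuates the
MZ within-pair estimate toward null with the DZ estimate in between;
shared-environment confounding attenuates MZ and DZ alike.

The within-pair (conditional) estimator for a linear outcome is computed by
within-pair mean-centering of outcome, exposure, and covariates, which
equals OLS on twin-difference data exactly; the residual degrees of freedom
account for the absorbed pair means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "WithinPairEstimate",
    "CotwinPolicy",
    "CotwinResult",
    "within_pair_estimate",
    "cotwin_compare",
]

_Z95 = 1.959963984540054

COTWIN_LABELS = (
    "causal-consistent",
    "genetic-confounding-pattern",
    "shared-environment-pattern",
    "inconclusive",
)


@dataclass
class WithinPairEstimate:
    beta: float
    se: float
    n_pairs: int
    zygosity: str | None = None

    @property
    def ci_low(self) -> float:
        return self.beta - _Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + _Z95 * self.se


def within_pair_estimate(
    pairs: pd.DataFrame,
    zygosity: str | None = None,
    exposure: str = "biomarker",
    outcome: str = "fi_pct",
    covariates: Sequence[str] = (),
) -> WithinPairEstimate:
    """Conditional (fixed-pair) estimate of outcome on exposure.

    ``pairs`` is a long table with ``pair_id`` (2 rows per retained pair)
    and optionally ``zygosity`` to filter on. Pairs with a missing value on
    any model variable in either twin are dropped (count logged). Raises
    when fewer than 2 complete pairs remain or the within-pair exposure
    variance is zero.
    """
    df = pairs
    if zygosity is not None:
        df = df[df["zygosity"] == zygosity]
    cols = [exposure, outcome, *covariates]
    df = df[["pair_id", *cols]].dropna()
    counts = df.groupby("pair_id").size()
    complete = counts[counts == 2].index
    n_dropped = counts.size - complete.size
    if n_dropped:
        logger.info("within_pair_estimate: dropped %d incomplete pairs", n_dropped)
    df = df[df["pair_id"].isin(complete)]
    n_pairs = complete.size
    if n_pairs < 2:
        raise ValueError(
            f"need >= 2 complete pairs (got {n_pairs}) for zygosity={zygosity!r}"
        )

    centered = df[cols] - df.groupby("pair_id")[cols].transform("mean")
    x_c = centered[exposure].to_numpy(float)
    if np.allclose(x_c, 0.0):
        raise ValueError("within-pair exposure variance is zero")
    # pair-constant covariates (e.g. shared age) are absorbed by the pair
    # effects; their centered columns are identically zero and are dropped
    kept_covs = [
        c for c in covariates if not np.allclose(centered[c].to_numpy(float), 0.0)
    ]
    X = np.column_stack([x_c] + [centered[c].to_numpy(float) for c in kept_covs])
    y = centered[outcome].to_numpy(float)

    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    # df: n obs minus absorbed pair means minus slope parameters
    dof = len(df) - n_pairs - X.shape[1]
    if dof <= 0:
        raise ValueError("not enough pairs for the number of covariates")
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[0, 0]))
    return WithinPairEstimate(float(coef[0]), se, int(n_pairs), zygosity)


@dataclass
class CotwinPolicy:
    """Explicit thresholds for the qualitative interpretation rules."""

    #: within-pair CI half-width above this multiple of |population beta|
    #: makes the comparison inconclusive (imprecise estimates carry no signal)
    max_relative_halfwidth: float = 1.0
    #: |DZ - MZ| below this multiple of |population beta| counts as
    #: "similar attenuation" for the shared-environment pattern
    similar_attenuation_tol: float = 0.25


@dataclass
class CotwinResult:
    population_beta: float
    population_se: float
    dz: WithinPairEstimate
    mz: WithinPairEstimate
    attenuation_dz: float
    attenuation_mz: float
    label: str


def _covers(est: WithinPairEstimate, value: float) -> bool:
    return est.ci_low <= value <= est.ci_high


def cotwin_compare(
    population_beta: float,
    population_se: float,
    dz: WithinPairEstimate,
    mz: WithinPairEstimate,
    policy: CotwinPolicy | None = None,
) -> CotwinResult:
    """Interpret population vs within-pair estimates.

    * ``causal-consistent``: both within-pair CIs cover the population
      point estimate (and are precise enough to be informative);
    * ``genetic-confounding-pattern``: |pop| > |DZ| > |MZ| with the MZ CI
      covering 0;
    * ``shared-environment-pattern``: DZ and MZ attenuate similarly (both
      below the population estimate, difference within tolerance);
    * ``inconclusive``: anything else, including within-pair CIs too wide
      relative to the population effect to discriminate the patterns.
    """
    pol = policy or CotwinPolicy()
    pop = population_beta
    att_dz = dz.beta / pop if pop != 0 else np.nan
    att_mz = mz.beta / pop if pop != 0 else np.nan

    scale = abs(pop)
    informative = scale > 0 and all(
        _Z95 * est.se <= pol.max_relative_halfwidth * scale for est in (dz, mz)
    )
    if not informative:
        label = "inconclusive"
    elif _covers(dz, pop) and _covers(mz, pop):
        label = "causal-consistent"
    elif abs(pop) > abs(dz.beta) > abs(mz.beta) and _covers(mz, 0.0):
        label = "genetic-confounding-pattern"
    elif (
        abs(dz.beta) < abs(pop)
        and abs(mz.beta) < abs(pop)
        and abs(dz.beta - mz.beta) <= pol.similar_attenuation_tol * scale
    ):
        label = "shared-environment-pattern"
    else:
        label = "inconclusive"

    return CotwinResult(
        population_beta=pop,
        population_se=population_se,
        dz=dz,
        mz=mz,
        attenuation_dz=float(att_dz),
        attenuation_mz=float(att_mz),
        label=label,
    )


def cotwin_tsv_row(name: str, result: CotwinResult) -> dict:
    """Flatten a CotwinResult for tabular output."""
    return {
        "biomarker": name,
        "population_beta": result.population_beta,
        "population_se": result.population_se,
        "dz_beta": result.dz.beta,
        "dz_se": result.dz.se,
        "dz_pairs": result.dz.n_pairs,
        "mz_beta": result.mz.beta,
        "mz_se": result.mz.se,
        "mz_pairs": result.mz.n_pairs,
        "attenuation_dz": result.attenuation_dz,
        "attenuation_mz": result.attenuation_mz,
        "label": result.label,
    }
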