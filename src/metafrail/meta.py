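"""DerSimonian-Laird random-effects meta-analysis for replication.

Discovery hits are re-estimated in each replication cohort; the per-cohort
betas and standard errors are pooled with the moment-based DL estimator of
the between-study variance tau^2:

    w_i   = se_i^-2                       (fixed-effect weights)
    Q     = sum w_i (b_i - b_FE)^2
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))
    w*_i  = 1 / (se_i^2 + tau^2)
    pooled = sum w* b / sum w*,  SE = (sum w*)^(-1/2)

A biomarker is "replicated" when the pooled two-sided normal p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["MetaResult", "dl_meta", "replication_flag"]

_Z95 = 1.959963984540054


@dataclass
class MetaResult:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    tau2: float
    Q: float
    df: int
    k: int
    replicated: bool


def dl_meta(betas, ses) -> MetaResult:
    """Pool per-study estimates with DerSimonian-Laird random effects.

    ``k = 1`` degenerates to the single study (tau^2 = 0, Q = 0).
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.ndim != 1 or b.shape != s.shape:
        raise ValueError("betas and ses must be 1-d and equal length")
    k = b.size
    if k == 0:
        raise ValueError("need at least one study")
    if np.any(s <= 0):
        raise ValueError("all standard errors must be positive")

    w = s**-2.0
    b_fe = np.sum(w * b) / np.sum(w)
    Q = float(np.sum(w * (b - b_fe) ** 2))
    if k > 1:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - (k - 1)) / denom)
    else:
        tau2 = 0.0
    w_star = 1.0 / (s**2 + tau2)
    pooled = float(np.sum(w_star * b) / np.sum(w_star))
    se = float(np.sum(w_star) ** -0.5)
    p = float(2 * stats.norm.sf(abs(pooled / se)))
    return MetaResult(
        beta=pooled,
        se=se,
        ci_low=pooled - _Z95 * se,
        ci_high=pooled + _Z95 * se,
        p=p,
        tau2=float(tau2),
        Q=Q,
        df=k - 1,
        k=k,
        replicated=p < 0.05,
    )


def replication_flag(
    meta: MetaResult,
    discovery_beta: float | None = None,
    require_direction: bool = False,
    alpha: float = 0.05,
) -> bool:
    """Replication rule: pooled p < alpha (strict inequality).

    Optionally also require sign agreement with the discovery estimate
    (off by default; the stated criterion is the p-value alone).
    """
    flag = meta.p < alpha
    if flag and require_direction and discovery_beta is not None:
        flag = np.sign(meta.beta) == np.sign(discovery_beta)
    return bool(flag)
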