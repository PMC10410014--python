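"""Discovery-phase association scan of biomarkers against frailty scores.

Each biomarker is standardized within cohort (mean 0, sample SD 1), then the
frailty outcome (FI % or FP score) is regressed on the biomarker z-score with
covariate adjustment. Estimates are beta-coefficients per SD of biomarker.
Family-wise error is controlled with a Bonferroni threshold; extreme
biomarker values can be excluded with a median +/- k*IQR rule; twin cohorts
use cluster-robust (CR1) standard errors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "standardize",
    "filter_outliers",
    "fit_linear_assoc",
    "bonferroni_threshold",
    "run_screen",
]

_Z95 = 1.959963984540054  # normal 97.5% quantile


@dataclass
class AssociationResult:
    """One biomarker-outcome linear association."""

    biomarker: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    model: str = "base"
    cluster_robust: bool = False

    @classmethod
    def from_fit(cls, biomarker, beta, se, p, n, model, cluster_robust=False):
        return cls(
            biomarker=biomarker,
            beta=float(beta),
            se=float(se),
            ci_low=float(beta - _Z95 * se),
            ci_high=float(beta + _Z95 * se),
            p=float(p),
            n=int(n),
            model=model,
            cluster_robust=cluster_robust,
        )


def standardize(values: pd.Series | np.ndarray) -> pd.Series:
    """Z-score with sample SD (ddof=1), computed within the supplied sample."""
    s = pd.Series(values, copy=False).astype(float)
    finite = s.dropna()
    if finite.nunique() < 2:
        name = s.name or "biomarker"
        raise ValueError(f"cannot standardize constant biomarker {name!r}")
    return (s - finite.mean()) / finite.std(ddof=1)


def filter_outliers(values: pd.Series | np.ndarray, k: float = 5.0) -> np.ndarray:
    """Keep mask: |value - median| <= k * IQR. NaNs are kept (not judged).

    With IQR = 0 every value is kept and a warning is emitted.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    med = np.median(finite)
    q1, q3 = np.percentile(finite, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        warnings.warn("IQR is zero; outlier filter keeps all values", stacklevel=2)
        return np.ones_like(arr, dtype=bool)
    keep = np.abs(arr - med) <= k * iqr
    keep |= np.isnan(arr)
    return keep


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Per-test significance threshold alpha/m for a family of m tests."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return alpha / m


def _design_matrix(
    biomarker_z: pd.Series, covariates: pd.DataFrame | None
) -> pd.DataFrame:
    parts = [pd.Series(1.0, index=biomarker_z.index, name="const"), biomarker_z]
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.copy()
        cat_cols = [
            c for c in cov.columns
            if cov[c].dtype == object or isinstance(cov[c].dtype, pd.CategoricalDtype)
        ]
        if cat_cols:
            # reference coding, first observed level as reference
            cov = pd.get_dummies(cov, columns=cat_cols, drop_first=True, dtype=float)
        parts.append(cov.astype(float))
    return pd.concat(parts, axis=1)


def fit_linear_assoc(
    outcome: pd.Series,
    biomarker_z: pd.Series,
    covariates: pd.DataFrame | None = None,
    cluster_ids: pd.Series | None = None,
    model_tag: str = "base",
) -> AssociationResult:
    """OLS of a frailty outcome on one biomarker z-score plus covariates.

    Complete cases only (rows missing any model variable are dropped and the
    count logged). Classical SEs by default; cluster-robust sandwich SEs
    with the CR1 small-sample correction when ``cluster_ids`` is supplied.
    """
    name = biomarker_z.name or "biomarker"
    X = _design_matrix(biomarker_z, covariates)
    frame = pd.concat([outcome.rename("_y"), X], axis=1)
    if cluster_ids is not None:
        frame["_cluster"] = cluster_ids
    complete = frame.dropna()
    n_dropped = len(frame) - len(complete)
    if n_dropped:
        logger.info("fit_linear_assoc[%s]: dropped %d incomplete rows", name, n_dropped)
    if len(complete) <= X.shape[1] + 1:
        raise ValueError(f"too few complete cases ({len(complete)}) for {name!r}")

    Xc = complete.drop(columns=["_y"] + (["_cluster"] if cluster_ids is not None else []))
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # locate offending columns by greedy rank growth
        bad = []
        kept: list[str] = []
        for col in Xc.columns:
            trial = Xc[kept + [col]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(col)
            else:
                bad.append(col)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    fit = sm.OLS(complete["_y"].to_numpy(), Xc.to_numpy()).fit()
    if cluster_ids is not None:
        res = fit.get_robustcov_results(
            cov_type="cluster",
            groups=complete["_cluster"].to_numpy(),
            use_correction=True,
        )
    else:
        res = fit
    j = list(Xc.columns).index(name)
    # normal-approximation p (large-n cohorts)
    from scipy import stats

    beta = res.params[j]
    se = res.bse[j]
    p = 2 * stats.norm.sf(abs(beta / se))
    return AssociationResult.from_fit(
        name, beta, se, p, len(complete), model_tag,
        cluster_robust=cluster_ids is not None,
    )


def run_screen(
    cohort: pd.DataFrame,
    outcome: str,
    biomarkers: Sequence[str],
    covariates: Sequence[str] = (),
    strata: Mapping[str, pd.Series] | None = None,
    family_size: int | None = None,
    alpha: float = 0.05,
    cluster_col: str | None = None,
    outlier_k: float | None = None,
    model_tag: str = "base",
) -> pd.DataFrame:
    """One association fit per biomarker (x stratum), with Bonferroni flags.

    ``family_size`` defaults to the number of biomarkers tested; the same
    per-test threshold applies within every stratum. ``outlier_k`` switches
    on the median +/- k*IQR exclusion of extreme raw biomarker values
    before standardization.
    """
    if outcome not in cohort.columns:
        raise KeyError(f"outcome column {outcome!r} not in cohort")
    m = family_size if family_size is not None else len(biomarkers)
    threshold = bonferroni_threshold(m, alpha)

    strata_items: list[tuple[str, pd.Series | None]] = [("all", None)]
    if strata:
        strata_items = list(strata.items())

    rows = []
    for label, mask in strata_items:
        sub = cohort if mask is None else cohort.loc[mask.reindex(cohort.index, fill_value=False)]
        if len(sub) == 0:
            warnings.warn(f"stratum {label!r} is empty; skipped", stacklevel=2)
            continue
        cov = sub[list(covariates)] if covariates else None
        cluster = sub[cluster_col] if cluster_col else None
        for bm in biomarkers:
            raw = sub[bm]
            if outlier_k is not None:
                keep = filter_outliers(raw, k=outlier_k)
                raw = raw.where(keep)
            z = standardize(raw).rename(bm)
            res = fit_linear_assoc(
                sub[outcome], z, cov, cluster_ids=cluster,
                model_tag=model_tag if mask is None else label,
            )
            rows.append(
                {
                    "biomarker": res.biomarker,
                    "stratum": label,
                    "beta": res.beta,
                    "se": res.se,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                    "n": res.n,
                    "model": res.model,
                    "cluster_robust": res.cluster_robust,
                    "significant": res.p < threshold,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "biomarker", "stratum", "beta", "se", "ci_low", "ci_high",
            "p", "n", "model", "cluster_robust", "significant",
        ],
    )
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["family_size"] = m
    return out
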