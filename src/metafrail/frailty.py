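"""Frailty index (FI), frailty phenotype (FP), and category-stripped FIs.

The FI follows the deficit-accumulation model: for each individual, the sum
of deficit values (each coded in [0, 1]) divided by the number of non-missing
items, multiplied by 100 and read as a percentage (0-100%). Individuals with
more than ``max_missing_fraction`` of items missing are excluded rather than
scored. The FP is the count (0-5) of Fried-model criteria present (weight
loss, exhaustion, slowness, low activity, weakness) and is treated as a
continuous score downstream.

Stripped FIs remove all items belonging to one labelled category and rescore
on the reduced item set; they are used as alternative outcomes to test
whether an exposure acts through deficits of a particular domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["DeficitMatrix", "compute_fi", "compute_fp", "strip_fi", "strip_all"]


class DeficitDataError(ValueError):
    """Raised when deficit values fall outside [0, 1]."""


@dataclass
class DeficitMatrix:
    """Individuals x deficit items, with an item -> category label map.

    ``values`` holds one column per item; entries are deficit codings in
    [0, 1] (graded responses such as 0.5 allowed) or NaN for missing.
    Every column must have exactly one category label.
    """

    values: pd.DataFrame
    categories: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape[1] < 1:
            raise ValueError("deficit matrix needs at least one item")
        missing_cat = [c for c in self.values.columns if c not in self.categories]
        if self.categories and missing_cat:
            raise ValueError(f"items without a category label: {missing_cat}")
        arr = self.values.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise DeficitDataError(
                f"deficit value out of [0, 1] for individual "
                f"{self.values.index[i]!r}, item {self.values.columns[j]!r}"
            )

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def category_labels(self) -> list[str]:
        return sorted(set(self.categories.values()))

    def items_in_category(self, category: str) -> list[str]:
        return [c for c in self.values.columns if self.categories.get(c) == category]


def compute_fi(
    deficits: DeficitMatrix, max_missing_fraction: float = 0.20
) -> pd.DataFrame:
    """Score the FI (%) per individual.

    Returns a frame indexed like ``deficits.values`` with columns
    ``fi_pct`` (NaN when excluded), ``n_items_used``, ``excluded`` and
    ``reason``. Exclusion uses strictly-greater-than ``max_missing_fraction``
    missingness, so individuals at exactly the threshold are retained.
    """
    vals = deficits.values.to_numpy(dtype=float)
    n_items = vals.shape[1]
    n_missing = np.isnan(vals).sum(axis=1)
    frac_missing = n_missing / n_items
    excluded = frac_missing > max_missing_fraction

    n_used = n_items - n_missing
    with np.errstate(invalid="ignore", divide="ignore"):
        fi = 100.0 * np.nansum(vals, axis=1) / np.where(n_used > 0, n_used, np.nan)
    fi = np.where(excluded, np.nan, fi)

    reason = np.where(
        excluded,
        f"missing fraction > {max_missing_fraction:g}",
        "",
    )
    return pd.DataFrame(
        {
            "fi_pct": fi,
            "n_items_used": n_used,
            "excluded": excluded,
            "reason": reason,
        },
        index=deficits.values.index,
    )


def compute_fp(criteria: pd.DataFrame) -> pd.Series:
    """FP score = number of the 5 frailty criteria present.

    ``criteria`` must have exactly 5 columns of booleans (NaN = missing).
    Individuals with any missing criterion get a missing score (the model
    does not rescale to fewer criteria).
    """
    if criteria.shape[1] != 5:
        raise ValueError(
            f"frailty phenotype needs exactly 5 criteria, got {criteria.shape[1]}"
        )
    arr = criteria.to_numpy(dtype=float)
    any_missing = np.isnan(arr).any(axis=1)
    score = arr.sum(axis=1)
    score[any_missing] = np.nan
    return pd.Series(score, index=criteria.index, name="fp_score").astype("Float64")


def strip_fi(
    deficits: DeficitMatrix,
    category: str,
    max_missing_fraction: float = 0.20,
) -> pd.DataFrame:
    """FI recomputed after removing every item of ``category``.

    The same missingness rule applies against the reduced denominator.
    """
    labels = deficits.category_labels
    if category not in labels:
        raise KeyError(f"unknown category {category!r}; valid categories: {labels}")
    keep = [c for c in deficits.values.columns if deficits.categories[c] != category]
    if not keep:
        raise ValueError(f"stripping {category!r} would remove every item")
    reduced = DeficitMatrix(
        deficits.values[keep],
        {c: deficits.categories[c] for c in keep},
    )
    return compute_fi(reduced, max_missing_fraction=max_missing_fraction)


def strip_all(
    deficits: DeficitMatrix, max_missing_fraction: float = 0.20
) -> dict[str, pd.DataFrame]:
    """One stripped-FI score frame per category (11 for the default map)."""
    return {
        cat: strip_fi(deficits, cat, max_missing_fraction=max_missing_fraction)
        for cat in deficits.category_labels
    }
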