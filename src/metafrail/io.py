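"""Tabular I/O: phenotype CSV, GWAS summary-stats TSV, LD TSV, results TSV.

Summary statistics follow a GWAS-SSF-aligned header with 1-based positions:
variant_id, chromosome, base_pair_location, effect_allele, other_allele,
effect_allele_frequency, beta, standard_error, p_value, n. Malformed files
are rejected with the offending column or line named. All writers use fixed
column orders so outputs are diff-able.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .mr import SUMMARY_COLUMNS, TableLD

__all__ = [
    "read_summary_stats",
    "write_summary_stats",
    "read_phenotypes",
    "write_phenotypes",
    "read_ld_table",
    "write_ld_table",
    "write_results",
]


class ParseError(ValueError):
    """Raised for malformed tabular inputs."""


_INT_COLUMNS = ("chromosome", "base_pair_location", "n")
_FLOAT_COLUMNS = ("effect_allele_frequency", "beta", "standard_error", "p_value")


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a summary-stats TSV, validating header and column types."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing required column(s) {missing}")
    df = df[SUMMARY_COLUMNS].copy()
    for col in _INT_COLUMNS:
        try:
            df[col] = df[col].astype(int)
        except (TypeError, ValueError):
            bad = pd.to_numeric(df[col], errors="coerce")
            line = int(bad[bad.isna() | (bad % 1 != 0)].index[0]) + 2  # header + 1-based
            raise ParseError(
                f"{path.name}: column {col!r} not integer at line {line}"
            ) from None
    for col in _FLOAT_COLUMNS:
        try:
            df[col] = df[col].astype(float)
        except (TypeError, ValueError):
            bad = pd.to_numeric(df[col], errors="coerce")
            line = int(bad[bad.isna()].index[0]) + 2
            raise ParseError(
                f"{path.name}: column {col!r} not numeric at line {line}"
            ) from None
    return df


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"cannot write summary stats; missing column(s) {missing}")
    df[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path, index_col: str = "individual_id") -> pd.DataFrame:
    df = pd.read_csv(path)
    if index_col in df.columns:
        df = df.set_index(index_col)
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=df.index.name is not None)


def read_ld_table(path: str | Path) -> TableLD:
    """Read a pairwise (snp_a, snp_b, r2) TSV into an LD source."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ["snp_a", "snp_b", "r2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing required column(s) {missing}")
    return TableLD(df)


def write_ld_table(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs[["snp_a", "snp_b", "r2"]].to_csv(path, sep="\t", index=False)


def write_results(df: pd.DataFrame, path: str | Path) -> None:
    """Write a results frame as TSV with a stable column order."""
    df.to_csv(path, sep="\t", index=False)
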