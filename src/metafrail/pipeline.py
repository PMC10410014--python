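"""End-to-end orchestration: discovery -> selection -> replication -> MR -> co-twin.

``run_all`` drives the whole workflow from a single :class:`PipelineConfig`
(loadable from YAML). In synthetic mode every input is generated by the
``synthetic`` module with per-stage seeds derived from ``config.seed``, so a
rerun with the same config is byte-identical. Forwarding rules follow the
study design: only biomarkers that pass the Bonferroni screen AND carry a
nonzero LASSO coefficient go to replication; only replicated-or-unavailable
biomarkers go to MR.

Outputs (all TSV/CSV/JSON text): per-stage results tables, a Figure-3-style
summary (observational beta, meta beta, IVW beta, flags per biomarker), and
a run log recording every threshold, family size, and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import derive_seed
from . import io as mio
from .cotwin import cotwin_compare, cotwin_tsv_row, within_pair_estimate
from .frailty import compute_fi, compute_fp
from .meta import dl_meta
from .mr import MRBatteryConfig, run_mr_battery
from .screening import fit_linear_assoc, run_screen, standardize
from .selection import lasso_select
from .synthetic import (
    CohortConfig,
    GwasSimConfig,
    simulate_cohort,
    simulate_outcome_battery,
    simulate_twin_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Thresholds, sizes, and seeds for a full synthetic-mode run."""

    seed: int = 1
    # discovery cohort
    n_discovery: int = 8000
    n_biomarkers: int = 30
    true_effects: dict = field(default_factory=lambda: {
        "bm001": 2.0, "bm002": 1.2, "bm003": 0.8,
    })
    block_structure: list = field(default_factory=lambda: [[5, 0.6], [5, 0.3]])
    # replication cohorts
    n_replication_twin: int = 4000
    n_replication_survey: int = 3000
    unavailable_biomarkers: list = field(default_factory=list)
    # multiple testing
    bonferroni_alpha: float = 0.05
    bonferroni_family: int = 200
    replication_alpha: float = 0.05
    fdr_q: float = 0.05
    # MR
    gwas_p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000
    palindromic_maf: float = 0.42
    mr_n_snps: int = 60
    mr_n_exposure: int = 115_078
    mr_n_outcome: int = 164_610
    mr_theta_scale: float = 0.25  # causal fraction of the observational effect
    n_boot: int = 1000
    presso_n_sim: int = 1000
    # co-twin
    n_mz_pairs: int = 1132
    n_dz_pairs: int = 2762
    # covariates used in adjusted models
    covariates: list = field(default_factory=lambda: [
        "age", "sex", "bmi", "smoking", "alcohol", "education", "deprivation",
    ])
    lasso_n_folds: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _discovery_stage(cfg: PipelineConfig, outdir: Path) -> tuple[pd.DataFrame, list[str]]:
    cohort_cfg = CohortConfig(
        n_individuals=cfg.n_discovery,
        n_biomarkers=cfg.n_biomarkers,
        seed=derive_seed(cfg.seed, "discovery"),
        biomarker_block_structure=[tuple(b) for b in cfg.block_structure],
        true_effects=cfg.true_effects,
    )
    sim = simulate_cohort(cohort_cfg)
    table = sim.phenotypes.copy()
    fi = compute_fi(sim.deficits)
    table["fi_pct"] = fi["fi_pct"]
    table["fp_score"] = compute_fp(sim.fp_criteria).astype(float)
    biomarkers = cohort_cfg.biomarker_names()

    screen = run_screen(
        table,
        outcome="fi_pct",
        biomarkers=biomarkers,
        covariates=cfg.covariates,
        family_size=cfg.bonferroni_family,
        alpha=cfg.bonferroni_alpha,
        model_tag="fully_adjusted",
    )
    mio.write_results(screen, outdir / "discovery_screen.tsv")

    z = pd.DataFrame({b: standardize(table[b]) for b in biomarkers})
    mand = pd.DataFrame({"age": table["age"], "sex": table["sex"].astype(float)})
    lres = lasso_select(
        z, table["fi_pct"], mand,
        n_folds=cfg.lasso_n_folds,
        seed=derive_seed(cfg.seed, "lasso"),
    )
    mio.write_results(lres.to_frame(), outdir / "lasso_cv_path.tsv")
    (outdir / "lasso_selected.txt").write_text("\n".join(lres.selected) + "\n")

    bonf_hits = set(screen.loc[screen["significant"], "biomarker"])
    forwarded = sorted(bonf_hits & set(lres.selected))
    return screen, forwarded


def _replication_stage(
    cfg: PipelineConfig, forwarded: list[str], outdir: Path
) -> pd.DataFrame:
    rows = []
    rep_specs = [
        ("twin_cohort", cfg.n_replication_twin, True),
        ("survey_cohort", cfg.n_replication_survey, False),
    ]
    per_cohort: dict[str, pd.DataFrame] = {}
    for name, n, twins in rep_specs:
        sim = simulate_cohort(
            CohortConfig(
                n_individuals=n,
                n_biomarkers=cfg.n_biomarkers,
                seed=derive_seed(cfg.seed, "replication", name),
                biomarker_block_structure=[tuple(b) for b in cfg.block_structure],
                true_effects=cfg.true_effects,
            )
        )
        table = sim.phenotypes.copy()
        table["fi_pct"] = compute_fi(sim.deficits)["fi_pct"]
        if twins:  # pair consecutive individuals as pseudo-twin clusters
            table["pair_id"] = np.arange(len(table)) // 2
        screen = run_screen(
            table,
            outcome="fi_pct",
            biomarkers=[b for b in forwarded if b not in cfg.unavailable_biomarkers],
            covariates=[c for c in cfg.covariates if c != "deprivation"],
            family_size=cfg.bonferroni_family,
            alpha=cfg.bonferroni_alpha,
            cluster_col="pair_id" if twins else None,
            model_tag=name,
        )
        per_cohort[name] = screen.set_index("biomarker")

    for bm in forwarded:
        if bm in cfg.unavailable_biomarkers or any(
            bm not in per_cohort[name].index for name, _, _ in rep_specs
        ):
            rows.append({"biomarker": bm, "status": "unavailable"})
            continue
        betas = [per_cohort[name].loc[bm, "beta"] for name, _, _ in rep_specs]
        ses = [per_cohort[name].loc[bm, "se"] for name, _, _ in rep_specs]
        m = dl_meta(betas, ses)
        rows.append(
            {
                "biomarker": bm,
                "status": "replicated" if m.p < cfg.replication_alpha else "not_replicated",
                "meta_beta": m.beta,
                "meta_se": m.se,
                "meta_p": m.p,
                "tau2": m.tau2,
                "Q": m.Q,
                "k": m.k,
            }
        )
    meta_df = pd.DataFrame(
        rows,
        columns=["biomarker", "status", "meta_beta", "meta_se", "meta_p",
                 "tau2", "Q", "k"],
    )
    mio.write_results(meta_df, outdir / "replication_meta.tsv")
    return meta_df


def _mr_stage(
    cfg: PipelineConfig,
    mr_biomarkers: list[str],
    discovery: pd.DataFrame,
    outdir: Path,
) -> tuple[pd.DataFrame, dict]:
    disc = discovery.set_index("biomarker")
    battery_cfg = MRBatteryConfig(
        p_threshold=cfg.gwas_p_threshold,
        r2_threshold=cfg.clump_r2,
        window_kb=cfg.clump_window_kb,
        palindromic_maf=cfg.palindromic_maf,
        fdr_q=cfg.fdr_q,
        n_boot=cfg.n_boot,
        presso_n_sim=cfg.presso_n_sim,
        seed=derive_seed(cfg.seed, "mr"),
    )
    all_results = []
    for bm in mr_biomarkers:
        theta = cfg.mr_theta_scale * float(disc.loc[bm, "beta"])
        exp_stats, outs, truth = simulate_outcome_battery(
            GwasSimConfig(
                n_snps=cfg.mr_n_snps,
                n_exposure=cfg.mr_n_exposure,
                n_outcome=cfg.mr_n_outcome,
                theta=theta,
                exposure_h2=0.04,
                palindromic_fraction=0.1,
                seed=derive_seed(cfg.seed, "gwas", bm),
            )
        )
        res, _ = run_mr_battery(
            {bm: exp_stats},
            {"fi": outs["fi"], "fp": outs["fp"]},
            truth.ld,
            battery_cfg,
        )
        all_results.append(res)
    results = pd.concat(all_results, ignore_index=True) if all_results else pd.DataFrame()

    # FDR across the primary IVW family (all exposures x {fi, fp})
    fdr_family = 0
    if not results.empty:
        from .mr import bh_fdr

        primary = results[
            results["method"].isin(["IVW", "wald_ratio"])
            & results["outcome"].isin(["fi", "fp"])
        ]
        fdr_family = len(primary)
        adjusted, reject, _ = bh_fdr(primary["p"].to_numpy(), cfg.fdr_q)
        results.loc[primary.index, "fdr_q"] = adjusted
        results.loc[primary.index, "fdr_significant"] = reject
    mio.write_results(results, outdir / "mr_results.tsv")
    return results, {"fdr_family_size": fdr_family}


def _cotwin_stage(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    twin_effect = next(iter(cfg.true_effects.values()), 0.0)
    pairs = simulate_twin_cohort(
        CohortConfig(
            n_individuals=1,
            n_biomarkers=1,
            seed=derive_seed(cfg.seed, "cotwin"),
            true_effects={"biomarker": twin_effect},
        ),
        n_mz_pairs=cfg.n_mz_pairs,
        n_dz_pairs=cfg.n_dz_pairs,
        confounding="none",
    )
    covs = ["age", "sex", "bmi", "education_years"]
    pop = fit_linear_assoc(
        pairs["fi_pct"],
        pairs["biomarker"].rename("biomarker"),
        pairs[covs],
        cluster_ids=pairs["pair_id"],
        model_tag="population",
    )
    dz = within_pair_estimate(pairs, "DZ", covariates=covs[:1])
    mz = within_pair_estimate(pairs, "MZ", covariates=covs[:1])
    result = cotwin_compare(pop.beta, pop.se, dz, mz)
    out = pd.DataFrame([cotwin_tsv_row("biomarker", result)])
    mio.write_results(out, outdir / "cotwin_results.tsv")
    return out


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline; returns the run log (also written to disk).

    Stage failures abort with a stage-labelled error; partial outputs from
    completed stages are left in place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": config.to_dict(), "stages": {}}

    def _stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    screen, forwarded = _stage("discovery", _discovery_stage, config, outdir)
    log["stages"]["discovery"] = {
        "bonferroni_threshold": config.bonferroni_alpha / config.bonferroni_family,
        "bonferroni_family": config.bonferroni_family,
        "n_tested": int(screen["biomarker"].nunique()),
        "forwarded": forwarded,
    }

    meta_df = _stage("replication", _replication_stage, config, forwarded, outdir)
    replicated = meta_df.loc[
        meta_df["status"].isin(["replicated", "unavailable"]), "biomarker"
    ].tolist()
    log["stages"]["replication"] = {
        "replication_alpha": config.replication_alpha,
        "n_forwarded": len(forwarded),
        "mr_set": replicated,
    }

    mr_results, mr_log = _stage("mr", _mr_stage, config, replicated, screen, outdir)
    log["stages"]["mr"] = {
        "p_threshold": config.gwas_p_threshold,
        "clump_r2": config.clump_r2,
        "clump_window_kb": config.clump_window_kb,
        "palindromic_maf": config.palindromic_maf,
        "fdr_q": config.fdr_q,
        **mr_log,
    }

    cotwin_df = _stage("cotwin", _cotwin_stage, config, outdir)
    log["stages"]["cotwin"] = {
        "n_mz_pairs": config.n_mz_pairs,
        "n_dz_pairs": config.n_dz_pairs,
        "label": cotwin_df["label"].iloc[0],
    }

    # Figure-3-style summary: observational, meta, and IVW estimates side by side
    summary_rows = []
    disc = screen.set_index("biomarker")
    meta_idx = meta_df.set_index("biomarker") if not meta_df.empty else None
    ivw_idx = (
        mr_results[
            (mr_results["method"].isin(["IVW", "wald_ratio"]))
            & (mr_results["outcome"] == "fi")
        ].set_index("exposure")
        if not mr_results.empty
        else None
    )
    for bm in forwarded:
        row = {
            "biomarker": bm,
            "observational_beta": float(disc.loc[bm, "beta"]),
            "observational_p": float(disc.loc[bm, "p"]),
        }
        if meta_idx is not None and bm in meta_idx.index:
            row["status"] = meta_idx.loc[bm, "status"]
            row["meta_beta"] = meta_idx.loc[bm].get("meta_beta", np.nan)
        if ivw_idx is not None and bm in ivw_idx.index:
            row["ivw_beta"] = float(ivw_idx.loc[bm, "beta"])
            row["ivw_p"] = float(ivw_idx.loc[bm, "p"])
            row["ivw_fdr_significant"] = bool(
                ivw_idx.loc[bm].get("fdr_significant", False)
            )
        summary_rows.append(row)
    summary = pd.DataFrame(
        summary_rows,
        columns=["biomarker", "observational_beta", "observational_p",
                 "status", "meta_beta", "ivw_beta", "ivw_p",
                 "ivw_fdr_significant"],
    )
    mio.write_results(summary, outdir / "summary_table.tsv")

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    return log
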