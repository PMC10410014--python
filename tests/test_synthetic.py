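"""Contracts and statistical structure of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metafrail.frailty import compute_fi
from metafrail.screening import fit_linear_assoc, standardize
from metafrail.synthetic import (
    CohortConfig,
    GwasSimConfig,
    default_category_map,
    simulate_cohort,
    simulate_gwas_pair,
    simulate_outcome_battery,
    simulate_twin_cohort,
)


class TestCohortConfig:
    def test_dimension_contract(self):
        sim = simulate_cohort(CohortConfig(n_individuals=1000, n_biomarkers=10, seed=1))
        assert sim.phenotypes.shape[0] == 1000
        import re

        assert sum(bool(re.match(r"bm\d", c)) for c in sim.phenotypes.columns) == 10
        assert sim.deficits.values.shape == (1000, 49)
        assert sim.fp_criteria.shape == (1000, 5)

    def test_default_category_map_has_11_categories_49_items(self):
        cm = default_category_map()
        assert len(cm) == 49
        assert len(set(cm.values())) == 11
        assert sum(v == "cardiometabolic" for v in cm.values()) == 8

    @pytest.mark.parametrize(
        "kw",
        [
            {"n_individuals": 0},
            {"n_biomarkers": -1},
            {"n_deficit_items": 5},
            {"biomarker_block_structure": [(3, 1.0)]},
            {"deficit_missing_rate": 1.5},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        base = dict(n_individuals=100, n_biomarkers=5, seed=1)
        base.update(kw)
        with pytest.raises(ValueError):
            CohortConfig(**base)

    def test_seeded_determinism(self):
        a = simulate_cohort(CohortConfig(n_individuals=200, n_biomarkers=4, seed=9))
        b = simulate_cohort(CohortConfig(n_individuals=200, n_biomarkers=4, seed=9))
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        pd.testing.assert_frame_equal(a.deficits.values, b.deficits.values)
        c = simulate_cohort(CohortConfig(n_individuals=200, n_biomarkers=4, seed=10))
        assert not a.phenotypes["age"].equals(c.phenotypes["age"])

    def test_table_one_like_marginals(self):
        sim = simulate_cohort(CohortConfig(n_individuals=8000, n_biomarkers=3, seed=2))
        fi = compute_fi(sim.deficits)["fi_pct"]
        assert sim.phenotypes["age"].mean() == pytest.approx(56.77, abs=0.5)
        assert sim.phenotypes["age"].std() == pytest.approx(8.03, abs=0.5)
        assert fi.mean() == pytest.approx(12.29, abs=1.0)
        assert 5.0 < fi.std() < 10.0
        assert stats.skew(fi) > 0.3  # right-skewed deficit accumulation

    def test_block_correlation_structure(self):
        sim = simulate_cohort(
            CohortConfig(
                n_individuals=6000, n_biomarkers=6, seed=3,
                biomarker_block_structure=[(3, 0.6)],
            )
        )
        z = sim.phenotypes[[f"bm{j:03d}" for j in range(1, 7)]]
        corr = z.corr().to_numpy()
        assert corr[0, 1] == pytest.approx(0.6, abs=0.05)
        assert abs(corr[0, 4]) < 0.05

    def test_effect_recovery_oracle(self):
        sim = simulate_cohort(
            CohortConfig(
                n_individuals=20_000, n_biomarkers=3, seed=4,
                true_effects={"bm001": 1.5},
            )
        )
        fi = compute_fi(sim.deficits)["fi_pct"]
        res = fit_linear_assoc(
            fi, standardize(sim.phenotypes["bm001"]).rename("bm001"),
            sim.phenotypes[["age", "sex"]],
        )
        assert abs(res.beta - 1.5) < 3 * res.se

    def test_null_effects_pass_no_bonferroni_screen(self):
        from metafrail.screening import run_screen

        flagged = 0
        reps = 25
        for rep in range(reps):
            sim = simulate_cohort(
                CohortConfig(n_individuals=2000, n_biomarkers=8, seed=500 + rep)
            )
            table = sim.phenotypes.copy()
            table["fi_pct"] = compute_fi(sim.deficits)["fi_pct"]
            res = run_screen(table, "fi_pct", [f"bm{j:03d}" for j in range(1, 9)],
                             covariates=["age", "sex"], family_size=200)
            flagged += res["significant"].any()
        assert flagged / reps <= 0.05


class TestTwinCohort:
    def test_zygosity_correlation_structure(self):
        pairs = simulate_twin_cohort(
            CohortConfig(n_individuals=1, n_biomarkers=1, seed=5),
            4000, 4000, confounding="genetic",
        )
        # x = sqrt(.5) A + sqrt(.5) e: within-pair corr = 0.5 (MZ), 0.25 (DZ)
        def within_corr(zyg):
            wide = pairs[pairs["zygosity"] == zyg].pivot(
                index="pair_id", columns="twin", values="biomarker"
            )
            return wide[1].corr(wide[2])

        assert within_corr("MZ") == pytest.approx(0.5, abs=0.05)
        assert within_corr("DZ") == pytest.approx(0.25, abs=0.05)

    def test_unknown_confounding_mode_rejected(self):
        with pytest.raises(ValueError, match="confounding"):
            simulate_twin_cohort(
                CohortConfig(n_individuals=1, n_biomarkers=1, seed=6),
                10, 10, confounding="epigenetic",
            )

    def test_zero_pairs_gives_empty_stratum(self):
        pairs = simulate_twin_cohort(
            CohortConfig(n_individuals=1, n_biomarkers=1, seed=7), 0, 50
        )
        assert (pairs["zygosity"] == "MZ").sum() == 0
        assert (pairs["zygosity"] == "DZ").sum() == 100


class TestGwasPair:
    def test_internal_consistency(self):
        exp, out, truth = simulate_gwas_pair(
            GwasSimConfig(n_snps=300, n_exposure=50_000, n_outcome=60_000,
                          theta=0.2, seed=8, palindromic_fraction=0.2)
        )
        for df in (exp, out):
            eaf = df["effect_allele_frequency"]
            assert ((eaf > 0) & (eaf < 1)).all()
            z = (df["beta"] / df["standard_error"]).abs()
            np.testing.assert_allclose(
                df["p_value"], 2 * stats.norm.sf(z), atol=1e-10
            )
        # requested palindromic fraction honored
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        pal = sum(comp[a] == b for a, b in zip(exp["effect_allele"],
                                               exp["other_allele"]))
        assert pal == 60

    def test_seeded_determinism(self):
        cfg = dict(n_snps=50, n_exposure=10_000, n_outcome=10_000, theta=0.1)
        a = simulate_gwas_pair(GwasSimConfig(**cfg, seed=11))
        b = simulate_gwas_pair(GwasSimConfig(**cfg, seed=11))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_exposure_h2_reproduced(self):
        cfg = GwasSimConfig(n_snps=150, n_exposure=500_000, n_outcome=100_000,
                            theta=0.0, exposure_h2=0.25, seed=12)
        exp, _, truth = simulate_gwas_pair(cfg)
        var_j = 2 * exp["effect_allele_frequency"] * (1 - exp["effect_allele_frequency"])
        # from the estimated betas, debiased by the sampling variance
        h2_hat = np.sum(var_j * (exp["beta"] ** 2 - exp["standard_error"] ** 2))
        assert h2_hat == pytest.approx(0.25, rel=0.10)

    def test_truth_record_stores_generating_state(self):
        cfg = GwasSimConfig(n_snps=40, n_exposure=10_000, n_outcome=10_000,
                            theta=0.3, seed=13, pleiotropy_mode="outlier",
                            n_outliers=3)
        _, _, truth = simulate_gwas_pair(cfg)
        assert truth.theta == 0.3
        assert len(truth.outlier_ids) == 3
        assert truth.to_frame()["is_outlier"].sum() == 3

    @pytest.mark.parametrize(
        "kw",
        [
            {"theta": np.inf},
            {"exposure_h2": 0.0},
            {"palindromic_fraction": 1.2},
            {"n_outliers": 100},
            {"pleiotropy_mode": "weird"},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        base = dict(n_snps=50, n_exposure=1000, n_outcome=1000, theta=0.1, seed=1)
        base.update(kw)
        with pytest.raises(ValueError):
            GwasSimConfig(**base)

    def test_outcome_battery_mediation_channels(self):
        from metafrail.mr import harmonize, ivw, select_instruments

        cfg = GwasSimConfig(
            n_snps=80, n_exposure=200_000, n_outcome=200_000, theta=0.4,
            exposure_h2=0.1, seed=14,
            category_mediation={"cardiometabolic": 1.0},
        )
        exp, outcomes, truth = simulate_outcome_battery(cfg)
        assert set(outcomes) >= {"fi", "fp", "fi_stripped_cardiometabolic"}
        ins = select_instruments(exp, truth.ld)
        est_full = ivw(harmonize(exp, outcomes["fi"], ins))
        est_strip = ivw(harmonize(exp, outcomes["fi_stripped_cardiometabolic"], ins))
        assert abs(est_full.beta - 0.4) < 2 * est_full.se
        assert abs(est_strip.beta) < 2 * est_strip.se  # attenuated to null
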