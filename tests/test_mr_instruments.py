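"""Instrument selection, harmonization, instrument strength, FDR, pruning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metafrail.mr import (
    TableLD,
    bh_fdr,
    f_statistic,
    harmonize,
    prune_pleiotropic,
    select_instruments,
)


def summary_frame(rows):
    cols = [
        "variant_id", "chromosome", "base_pair_location", "effect_allele",
        "other_allele", "effect_allele_frequency", "beta", "standard_error",
        "p_value", "n",
    ]
    return pd.DataFrame(rows, columns=cols)


NO_LD = TableLD(pd.DataFrame(columns=["snp_a", "snp_b", "r2"]))


class TestSelectInstruments:
    def test_significance_filter(self):
        exp = summary_frame([
            ("s1", 1, 1_000, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1000),
            ("s2", 1, 50_000_000, "A", "G", 0.3, 0.1, 0.01, 1e-7, 1000),
            ("s3", 2, 1_000, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000),
        ])
        assert set(select_instruments(exp, NO_LD)) == {"s1", "s3"}

    def test_clumping_keeps_lower_p(self):
        exp = summary_frame([
            ("lead", 1, 100_000, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000),
            ("tag", 1, 105_000, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1000),
        ])
        ld = TableLD(pd.DataFrame({"snp_a": ["lead"], "snp_b": ["tag"], "r2": [0.5]}))
        assert select_instruments(exp, ld) == ["lead"]

    def test_independent_snps_all_kept(self):
        exp = summary_frame([
            (f"s{j}", 1, 100_000 + j * 1000, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1000)
            for j in range(5)
        ])
        assert len(select_instruments(exp, NO_LD)) == 5

    def test_no_passing_snps_warns_empty(self):
        exp = summary_frame([("s1", 1, 1000, "A", "G", 0.3, 0.01, 0.01, 0.5, 1000)])
        with pytest.warns(UserWarning, match="no SNP"):
            assert select_instruments(exp, NO_LD) == []


def exposure_outcome_pair():
    exp = summary_frame([
        ("s1", 1, 1000, "A", "G", 0.30, 0.10, 0.01, 1e-20, 1000),
        ("s2", 1, 2_000_000, "C", "T", 0.40, -0.08, 0.01, 1e-15, 1000),
    ])
    out = summary_frame([
        ("s1", 1, 1000, "A", "G", 0.30, 0.05, 0.02, 1e-5, 2000),
        ("s2", 1, 2_000_000, "C", "T", 0.40, -0.03, 0.02, 1e-3, 2000),
    ])
    return exp, out


class TestHarmonize:
    def test_identity_pass_through(self):
        exp, out = exposure_outcome_pair()
        h = harmonize(exp, out, ["s1", "s2"])
        assert h.n_snp == 2
        assert not h.table["flipped"].any()
        np.testing.assert_allclose(h.table["beta_y"], [0.05, -0.03])
        np.testing.assert_allclose(h.table["ratio"], [0.5, 0.375])

    def test_swapped_alleles_flip_sign(self):
        exp, out = exposure_outcome_pair()
        out.loc[0, ["effect_allele", "other_allele"]] = ["G", "A"]
        out.loc[0, "effect_allele_frequency"] = 0.70
        h = harmonize(exp, out, ["s1"])
        assert h.table["beta_y"].iloc[0] == pytest.approx(-0.05)
        assert bool(h.table["flipped"].iloc[0])
        assert h.table["eaf_y"].iloc[0] == pytest.approx(0.30)

    def test_strand_complement_resolved(self):
        exp, out = exposure_outcome_pair()
        out.loc[0, ["effect_allele", "other_allele"]] = ["T", "C"]  # comp of A/G
        h = harmonize(exp, out, ["s1"])
        assert h.table["beta_y"].iloc[0] == pytest.approx(0.05)
        assert not bool(h.table["flipped"].iloc[0])

    def test_palindromic_high_maf_dropped(self):
        exp, out = exposure_outcome_pair()
        for df in (exp, out):
            df.loc[0, ["effect_allele", "other_allele"]] = ["A", "T"]
            df.loc[0, "effect_allele_frequency"] = 0.45
        h = harmonize(exp, out, ["s1"])
        assert h.n_snp == 0
        assert h.dropped["reason"].tolist() == ["palindromic_high_maf"]

    def test_palindromic_low_maf_frequency_aligned(self):
        exp, out = exposure_outcome_pair()
        for df in (exp, out):
            df.loc[0, ["effect_allele", "other_allele"]] = ["A", "T"]
        exp.loc[0, "effect_allele_frequency"] = 0.10
        out.loc[0, "effect_allele_frequency"] = 0.90  # opposite strand report
        h = harmonize(exp, out, ["s1"])
        assert h.table["beta_y"].iloc[0] == pytest.approx(-0.05)

    def test_missing_in_outcome_dropped(self):
        exp, out = exposure_outcome_pair()
        h = harmonize(exp, out.iloc[:1], ["s1", "s2"])
        assert h.n_snp == 1
        assert h.dropped["reason"].tolist() == ["missing_in_outcome"]

    def test_irreconcilable_alleles_dropped(self):
        exp, out = exposure_outcome_pair()
        out.loc[0, ["effect_allele", "other_allele"]] = ["A", "C"]
        h = harmonize(exp, out, ["s1"])
        assert h.dropped["reason"].tolist() == ["allele_mismatch"]

    def test_involution_and_coding_flip_invariance(self):
        from metafrail.mr import ivw

        exp, out = exposure_outcome_pair()
        h1 = harmonize(exp, out, ["s1", "s2"])
        est1 = ivw(h1)
        # flip BOTH studies' allele coding for s1: estimates unchanged
        for df in (exp, out):
            ea, oa = df.loc[0, "effect_allele"], df.loc[0, "other_allele"]
            df.loc[0, ["effect_allele", "other_allele"]] = [oa, ea]
            df.loc[0, "effect_allele_frequency"] = 1 - df.loc[0, "effect_allele_frequency"]
            df.loc[0, "beta"] = -df.loc[0, "beta"]
        h2 = harmonize(exp, out, ["s1", "s2"])
        est2 = ivw(h2)
        assert est2.beta == pytest.approx(est1.beta, abs=1e-12)
        assert est2.se == pytest.approx(est1.se, abs=1e-12)
        # harmonizing the already-aligned pair again changes nothing
        np.testing.assert_allclose(
            np.abs(h2.table["ratio"]), np.abs(h1.table["ratio"]), atol=1e-12
        )


class TestFStatistic:
    def test_simple_ratio(self, two_snp_hset):
        f, mean_f = f_statistic(two_snp_hset)
        np.testing.assert_allclose(f, [10_000.0, 10_000.0])
        assert mean_f == 10_000.0

    def test_threshold_snp_f_equals_chi2_quantile(self):
        # a SNP exactly at Wald p = 5e-8 has F = chi2_1 quantile = 29.72
        z = stats.norm.isf(2.5e-8)
        assert z**2 == pytest.approx(stats.chi2.isf(5e-8, 1), rel=1e-10)
        assert z**2 == pytest.approx(29.72, abs=0.01)


class TestBHFDR:
    def test_step_up_example(self):
        adj, reject, thr = bh_fdr([0.001, 0.01, 0.03, 0.04, 0.2], q=0.05)
        assert reject.sum() == 4
        assert thr == pytest.approx(0.04)

    def test_all_tiny_all_rejected(self):
        adj, reject, thr = bh_fdr([0.001] * 98, q=0.05)
        assert reject.all()

    def test_all_ones_none_rejected(self):
        adj, reject, thr = bh_fdr([1.0, 1.0, 1.0], q=0.05)
        assert not reject.any() and thr is None

    def test_matches_brute_force_for_small_m(self):
        def brute(p, q):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p)
            k_star = 0
            for k in range(1, m + 1):
                if p[order[k - 1]] <= k * q / m:
                    k_star = k
            reject = np.zeros(m, dtype=bool)
            reject[order[:k_star]] = True
            return reject

        rng = np.random.default_rng(4)
        for m in range(1, 6):
            for _ in range(40):
                p = np.round(rng.random(m), 3)
                _, reject, _ = bh_fdr(p, q=0.05)
                np.testing.assert_array_equal(reject, brute(p, 0.05))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.random(50)
        adj, reject, _ = bh_fdr(p, q=0.05)
        ref_reject, ref_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adj, ref_adj, atol=1e-12)
        np.testing.assert_array_equal(reject, ref_reject)


class TestPrunePleiotropic:
    def _other(self, pvals):
        return summary_frame([
            (f"s{j + 1}", 1, 1000 * (j + 1), "A", "G", 0.3, 0.1, 0.01, p, 1000)
            for j, p in enumerate(pvals)
        ])

    def test_cross_associated_removed(self):
        kept, log = prune_pleiotropic(
            ["s1", "s2"], {"ldl": self._other([1e-9, 0.5])}
        )
        assert kept == ["s2"]
        assert log["variant_id"].tolist() == ["s1"]

    def test_no_cross_association_identity(self):
        kept, log = prune_pleiotropic(
            ["s1", "s2"], {"ldl": self._other([0.1, 0.9])}
        )
        assert kept == ["s1", "s2"] and log.empty

    def test_all_removed_warns(self):
        with pytest.warns(UserWarning, match="reduced"):
            kept, _ = prune_pleiotropic(
                ["s1", "s2"], {"ldl": self._other([1e-9, 1e-12])}
            )
        assert kept == []
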