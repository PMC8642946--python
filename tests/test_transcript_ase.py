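"""Binomial ASE test, transcript-level classification, cross-level comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pasekit import transcript_ase as ta
from pasekit.pase import classify_regulation
from pasekit.synthetic import simulate_allele_counts


def counts_frame(rows):
    frame = pd.DataFrame(rows, columns=["hyb1_B", "hyb1_D"])
    frame.index = pd.Index([f"g{i}" for i in range(len(frame))], name="gene")
    return frame


def brute_force_binomial_p(k, n, p0=0.5):
    """Minimum-likelihood two-sided p: sum of P(X=j) <= P(X=k)."""
    probs = stats.binom.pmf(np.arange(n + 1), n, p0)
    return float(probs[probs <= probs[k] * (1 + 1e-7)].sum())


class TestBinomialTest:
    def test_balanced_counts_give_p_one(self):
        res = ta.binomial_ase_test(counts_frame([[10, 10]]))
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_extreme_counts_closed_form(self):
        # 0 vs 20: two-sided p = 2 * 0.5^20
        res = ta.binomial_ase_test(counts_frame([[0, 20]]))
        assert res["p_value"].iloc[0] == pytest.approx(2 * 0.5**20, rel=1e-9)

    def test_low_depth_genes_skipped_with_reason(self):
        res = ta.binomial_ase_test(counts_frame([[2, 3], [30, 30]]))
        assert not res["tested"].iloc[0] and res["reason"].iloc[0] == "low_depth"
        assert res["tested"].iloc[1]

    def test_matches_enumeration_for_moderate_totals(self):
        for n in (10, 17, 25):
            for k in range(n + 1):
                got = ta.binomial_ase_test(
                    counts_frame([[k, n - k]]))["p_value"].iloc[0]
                assert got == pytest.approx(brute_force_binomial_p(k, n), rel=1e-9)

    def test_counts_pooled_across_hybrid_samples(self):
        frame = pd.DataFrame([[5, 10, 5, 10]],
                             columns=["hyb1_B", "hyb1_D", "hyb2_B", "hyb2_D"],
                             index=pd.Index(["g0"], name="gene"))
        res = ta.binomial_ase_test(frame)
        assert res["b_count"].iloc[0] == 10 and res["total"].iloc[0] == 30
        assert res["p_value"].iloc[0] == pytest.approx(
            brute_force_binomial_p(10, 30), rel=1e-9)

    def test_null_simulation_calibrated(self):
        counts, _, _ = simulate_allele_counts(
            2000, 100, {"conserved": 1.0}, 0.0, seed=19)
        res = ta.binomial_ase_test(counts)
        assert (res["p_adjusted"].dropna() < 0.05).mean() <= 0.05


class TestTranscriptClassification:
    def test_balanced_gene_is_conserved(self):
        counts = counts_frame([[50, 50]])
        parental = pd.DataFrame({"B6_1": [100.0], "D2_1": [100.0]},
                                index=counts.index)
        res = ta.classify_transcript_regulation(counts, parental)
        assert res["category"].iloc[0] == "conserved"

    def test_concordant_imbalance_is_cis(self):
        counts = counts_frame([[80, 20]])  # rF1 ~ 2
        parental = pd.DataFrame({"B6_1": [400.0], "D2_1": [100.0]},  # rP = 2
                                index=counts.index)
        res = ta.classify_transcript_regulation(counts, parental)
        assert res["category"].iloc[0] == "cis"

    def test_planted_categories_recovered_at_high_depth(self):
        counts, parental, truth = simulate_allele_counts(
            400, 500, (0.2,) * 5, effect=2.0, seed=20)
        res = ta.classify_transcript_regulation(counts, parental)
        assert (truth.genes["category"] == res["category"]).mean() >= 0.95

    def test_shared_classifier_with_protein_level(self):
        counts = counts_frame([[80, 20]])
        parental = pd.DataFrame({"B6_1": [400.0], "D2_1": [100.0]},
                                index=counts.index)
        res = ta.classify_transcript_regulation(counts, parental)
        r = ta.transcript_ratios(counts, parental).iloc[0]
        assert res["category"].iloc[0] == classify_regulation(r["r_parental"],
                                                              r["r_f1"])

    def test_pseudocount_insensitive_at_depth(self):
        counts = counts_frame([[120, 60]])
        parental = pd.DataFrame({"B6_1": [1.0], "D2_1": [1.0]}, index=counts.index)
        r_half = ta.transcript_ratios(counts, parental, pseudocount=0.5)
        r_one = ta.transcript_ratios(counts, parental, pseudocount=1.0)
        assert abs(r_half["r_f1"].iloc[0] - r_one["r_f1"].iloc[0]) < 0.05


class TestCompareLevels:
    @staticmethod
    def brute_force_fisher(table):
        """Enumerate all tables with the observed margins (hypergeometric)."""
        a, b = table[0]
        c, d = table[1]
        row1, col1, n = a + b, a + c, a + b + c + d
        obs = stats.hypergeom.pmf(a, n, row1, col1)
        total = 0.0
        for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
            p = stats.hypergeom.pmf(k, n, row1, col1)
            if p <= obs * (1 + 1e-7):
                total += p
        return total

    def test_hand_built_table_matches_enumeration(self):
        table = [[4, 1], [1, 4]]
        _, p = stats.fisher_exact(table)
        assert p == pytest.approx(self.brute_force_fisher(table), rel=1e-9)
        genes = [f"g{i}" for i in range(10)]
        prot = pd.DataFrame({"gene": genes,
                             "ase": [True] * 5 + [False] * 5,
                             "category": ["cis"] * 10})
        trans = pd.DataFrame({"ase": [True] * 4 + [False] + [True] + [False] * 4,
                              "category": ["cis"] * 10}, index=genes)
        result = ta.compare_levels(prot, trans)
        np.testing.assert_array_equal(result["table"], [[4, 1], [1, 4]])
        assert result["p_value"] == pytest.approx(self.brute_force_fisher(table),
                                                  rel=1e-9)

    def test_identical_call_sets_maximally_significant(self):
        genes = [f"g{i}" for i in range(40)]
        ase = [i % 2 == 0 for i in range(40)]
        prot = pd.DataFrame({"gene": genes, "ase": ase, "category": ["cis"] * 40})
        trans = pd.DataFrame({"ase": ase, "category": ["cis"] * 40}, index=genes)
        result = ta.compare_levels(prot, trans)
        assert result["odds_ratio"] == np.inf
        assert result["p_value"] < 1e-9

    def test_independent_random_calls_near_uniform_p(self, rng):
        pvals = []
        genes = [f"g{i}" for i in range(60)]
        for _ in range(200):
            prot = pd.DataFrame({"gene": genes, "ase": rng.random(60) < 0.4,
                                 "category": ["cis"] * 60})
            trans = pd.DataFrame({"ase": rng.random(60) < 0.4,
                                  "category": ["cis"] * 60}, index=genes)
            pvals.append(ta.compare_levels(prot, trans)["p_value"])
        # exact-test p-values are conservative/discrete; just check no excess
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.07

    def test_disjoint_universes_rejected(self):
        prot = pd.DataFrame({"gene": ["a"], "ase": [True], "category": ["cis"]})
        trans = pd.DataFrame({"ase": [True], "category": ["cis"]}, index=["b"])
        with pytest.raises(ValueError, match="intersect"):
            ta.compare_levels(prot, trans)

    def test_category_crosstab_margins(self):
        genes = [f"g{i}" for i in range(30)]
        cats = (["cis"] * 10 + ["trans"] * 10 + ["conserved"] * 10)
        prot = pd.DataFrame({"gene": genes, "ase": [True] * 30, "category": cats})
        trans = pd.DataFrame({"ase": [True] * 30, "category": cats}, index=genes)
        result = ta.compare_levels(prot, trans)
        assert result["category_crosstab"].to_numpy().sum() == 30
        assert result["category_crosstab"].loc["cis", "cis"] == 10
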