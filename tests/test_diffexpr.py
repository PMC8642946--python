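"""Moderated t-test, BH correction, DEP/SPE/hybrid screens, power simulation."""

import subprocess
import sys
import textwrap
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from pasekit import diffexpr
from pasekit.design import StrainDesign


def brute_force_bh(p):
    """Step-up definition applied literally: independent oracle."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


class TestBHAdjust:
    def test_forced_arithmetic(self):
        np.testing.assert_allclose(diffexpr.bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(diffexpr.bh_adjust([0.2]), [0.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=100))
    def test_matches_brute_force_definition(self, pvals):
        np.testing.assert_allclose(diffexpr.bh_adjust(pvals),
                                   brute_force_bh(pvals), atol=1e-12)

    def test_nan_rejected_with_indices(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            diffexpr.bh_adjust([0.1, np.nan, 0.5])


def two_group_matrix(rng, n_features=100, n_per_group=3, sd=1.0):
    cols = [f"a{i}" for i in range(n_per_group)] + [f"b{i}" for i in range(n_per_group)]
    return pd.DataFrame(rng.normal(0, sd, (n_features, 2 * n_per_group)),
                        columns=cols), cols[:n_per_group], cols[n_per_group:]


class TestModeratedTTest:
    def test_identical_group_means_give_t_zero(self):
        mat = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], columns=list("abcd"))
        res = diffexpr.moderated_ttest(
            pd.concat([mat] * 30, ignore_index=True), ["a", "b"], ["c", "d"])
        assert np.allclose(res["t"], 0.0)
        assert np.allclose(res["p_value"], 1.0)

    def test_forced_infinite_prior_uses_prior_variance(self, rng):
        mat, ga, gb = two_group_matrix(rng, 50)
        res = diffexpr.moderated_ttest(mat, ga, gb, d0_override=np.inf)
        s0 = res.attrs["s0_sq"]
        expected_t = ((mat[ga].mean(axis=1) - mat[gb].mean(axis=1))
                      / np.sqrt(s0 * (2 / 3)))
        np.testing.assert_allclose(res["t"], expected_t, rtol=1e-6)

    def test_zero_prior_df_equals_ordinary_pooled_t(self, rng):
        mat, ga, gb = two_group_matrix(rng, 50)
        res = diffexpr.moderated_ttest(mat, ga, gb, d0_override=0.0)
        ref = stats.ttest_ind(mat[ga], mat[gb], axis=1, equal_var=True)
        np.testing.assert_allclose(res["t"], ref.statistic, atol=1e-10)
        np.testing.assert_allclose(res["p_value"], ref.pvalue, atol=1e-10)

    def test_null_pvalues_approximately_uniform(self, rng):
        mat, ga, gb = two_group_matrix(rng, 200)
        res = diffexpr.moderated_ttest(mat, ga, gb)
        ks = stats.kstest(res["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_matches_limma_ebayes_on_fixture(self, tmp_path):
        """Independent oracle: Bioconductor limma on a heteroscedastic fixture."""
        rng = np.random.default_rng(7)
        sd = np.sqrt(0.1 * 4 / rng.chisquare(4, size=60))
        data = rng.normal(0, 1, (60, 6)) * sd[:, None]
        mat = pd.DataFrame(data, index=[f"f{i}" for i in range(60)],
                           columns=["a0", "a1", "a2", "b0", "b1", "b2"])
        res = diffexpr.moderated_ttest(mat, ["a0", "a1", "a2"], ["b0", "b1", "b2"])
        mat_path = tmp_path / "mat.tsv"
        mat.to_csv(mat_path, sep="\t")
        rcode = textwrap.dedent(f"""
            suppressMessages(library(limma))
            mat <- as.matrix(read.delim("{mat_path}", row.names=1))
            fit <- eBayes(lmFit(mat, cbind(Intercept=1, groupA=c(1,1,1,0,0,0))))
            cat(fit$df.prior, fit$s2.prior, "\\n")
            write.table(data.frame(t=fit$t[,"groupA"], p=fit$p.value[,"groupA"]),
                        "{tmp_path}/limma.tsv", sep="\\t", quote=FALSE)
        """)
        proc = subprocess.run(["Rscript", "-"], input=rcode, text=True,
                              capture_output=True)
        assert proc.returncode == 0, proc.stderr
        d0_r, s0_r = map(float, proc.stdout.split()[:2])
        assert res.attrs["d0"] == pytest.approx(d0_r, rel=1e-5)
        assert res.attrs["s0_sq"] == pytest.approx(s0_r, rel=1e-5)
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t", index_col=0)
        np.testing.assert_allclose(res["t"], ref["t"], atol=1e-8)
        np.testing.assert_allclose(res["p_value"], ref["p"], atol=1e-8)

    def test_group_overlap_rejected(self, rng):
        mat, ga, gb = two_group_matrix(rng, 10)
        with pytest.raises(ValueError, match="overlap"):
            diffexpr.moderated_ttest(mat, ga, [ga[0], gb[0]])

    def test_dep_calls_invariant_under_sample_relabeling(self, rng):
        mat, ga, gb = two_group_matrix(rng, 100)
        mat.iloc[:10, :3] += 3.0
        res1 = diffexpr.call_deps(diffexpr.moderated_ttest(mat, ga, gb))
        shuffled = mat[[ga[2], ga[0], ga[1], gb[1], gb[2], gb[0]]]
        res2 = diffexpr.call_deps(diffexpr.moderated_ttest(
            shuffled, [ga[2], ga[0], ga[1]], [gb[1], gb[2], gb[0]]))
        pd.testing.assert_series_equal(res1["dep"], res2["dep"])


class TestCallDeps:
    @pytest.mark.parametrize(
        "p_adj, fc, is_dep",
        [(0.04, 1.6, True), (0.04, 1.4, False), (0.06, 3.0, False)])
    def test_threshold_boundaries(self, p_adj, fc, is_dep):
        res = pd.DataFrame({"p_adjusted": [p_adj], "log2_fc": [fc]})
        assert diffexpr.call_deps(res)["dep"].iloc[0] == is_dep

    def test_null_data_dep_rate_controlled(self, rng):
        mat, ga, gb = two_group_matrix(rng, 2000, sd=0.3)
        res = diffexpr.call_deps(diffexpr.moderated_ttest(mat, ga, gb))
        assert res["dep"].mean() <= 0.05


class TestCV:
    def test_constant_protein_not_flagged(self):
        mat = pd.DataFrame(np.zeros((30, 4)) + np.arange(30)[:, None])
        out = diffexpr.compute_cv_and_high_variation(mat)
        assert np.allclose(out["cv"], 0.0)
        assert not out["high_variation"].any()

    def test_two_point_cv_arithmetic(self):
        # linear values (5, 15): sd = sqrt(50) = 7.071, mean = 10, CV = 0.707
        mat = pd.DataFrame([[np.log2(5), np.log2(15)]] * 25)
        out = diffexpr.compute_cv_and_high_variation(mat)
        assert out["cv"].iloc[0] == pytest.approx(0.7071, abs=1e-4)

    def test_inflated_variance_proteins_enriched(self, rng):
        base = rng.normal(0, 0.1, size=(1000, 8))
        base[:50] = rng.normal(0, 1.5, size=(50, 8))
        out = diffexpr.compute_cv_and_high_variation(pd.DataFrame(base))
        flagged = set(out.index[out["high_variation"]])
        hits = len(flagged & set(range(50)))
        assert hits >= 0.8 * len(flagged) and hits >= 25


class TestSPE:
    def test_planted_on_off_proteins_flagged_exactly(self, design, rng):
        # non-planted proteins share one value across strains (correlated
        # parents); 10 planted proteins are expressed in B6, silent in D2
        n = 250
        common = rng.normal(10, 1, size=n)
        mat = pd.DataFrame(
            {s: common + rng.normal(0, 0.02, n) for s in design.sample_ids},
            index=[f"p{i}" for i in range(n)])
        planted = [f"p{i}" for i in range(10)]
        mat.loc[planted, design.samples_of("B6")] = 11.0
        mat.loc[planted, design.samples_of("D2")] = -8.0
        out = diffexpr.call_spe(mat, design)
        assert set(out.index[out["spe"]]) == set(planted)
        assert (out.loc[planted, "silent_parent"] == "D2").all()

    def test_median_protein_not_spe(self, design, rng):
        mat = pd.DataFrame(rng.normal(10, 1, size=(100, 8)),
                           columns=design.sample_ids)
        mid = mat.median()
        mat.iloc[0] = mid
        assert not diffexpr.call_spe(mat, design)["spe"].iloc[0]

    def test_few_proteins_warns(self, design, rng):
        mat = pd.DataFrame(rng.normal(0, 1, size=(10, 8)),
                           columns=design.sample_ids)
        with pytest.warns(UserWarning, match="20 proteins"):
            diffexpr.call_spe(mat, design)


class TestReciprocalHybrids:
    def test_identical_hybrid_groups_give_empty_set(self, design, rng):
        mat = pd.DataFrame(rng.normal(0, 1, size=(50, 8)),
                           columns=design.sample_ids)
        f1a, f1b = design.samples_of("B6D2F1"), design.samples_of("D2B6F1")
        mat[f1b] = mat[f1a].to_numpy()
        res = diffexpr.compare_reciprocal_hybrids(mat, design)
        assert not res["candidate"].any()

    def test_planted_parent_of_origin_effect_recovered(self, design, rng):
        mat = pd.DataFrame(rng.normal(0, 0.05, size=(200, 8)),
                           columns=design.sample_ids)
        mat.iloc[:5, mat.columns.get_indexer(design.samples_of("B6D2F1"))] += 1.0
        res = diffexpr.compare_reciprocal_hybrids(mat, design)
        assert res["candidate"].iloc[:5].all()
        assert (res["direction"].iloc[:5] == "maternal_B6_higher").all()

    def test_small_fold_change_excluded(self, design, rng):
        mat = pd.DataFrame(rng.normal(0, 0.01, size=(100, 8)),
                           columns=design.sample_ids)
        mat.iloc[0, mat.columns.get_indexer(design.samples_of("B6D2F1"))] += 0.2
        res = diffexpr.compare_reciprocal_hybrids(mat, design)
        # p may be tiny but |log2FC| = 0.2 < 0.3
        assert not res["candidate"].iloc[0]


class TestPowerSimulation:
    def test_power_monotone_and_saturating(self):
        table = diffexpr.simulate_power(3, [0.0, 0.5, 1.0, 3.0], n_features=400,
                                        n_reps=3, seed=11)
        power = table["power"].to_numpy()
        assert power[-1] > 0.95
        assert np.all(np.diff(power) > -0.05)

    def test_null_effect_controls_fdp(self):
        table = diffexpr.simulate_power(3, [0.0], n_features=1000, n_reps=3,
                                        seed=12)
        assert table["power"].iloc[0] <= 0.05
        assert table["observed_fdp"].iloc[0] <= 0.1
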