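"""TMT quantification chain: impurity correction, filters, normalization, roll-up."""

import numpy as np
import pandas as pd
import pytest

from pasekit import tmt
from pasekit.synthetic import SimParams, default_impurity_matrix, simulate_proteome


def make_psms(values, proteins=None, prefix="psm"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, k = values.shape
    frame = pd.DataFrame(values, columns=[f"s{j}" for j in range(k)])
    frame.insert(0, "peptide", [f"PEP{i}" for i in range(n)])
    frame.insert(1, "protein", proteins or ["P1"] * n)
    frame.index = pd.Index([f"{prefix}_{i}" for i in range(n)], name="psm_id")
    return frame


class TestIsotopeCorrection:
    def test_identity_matrix_is_noop(self):
        psms = make_psms([[1000, 2000, 500]])
        out = tmt.correct_isotope_impurity(psms, np.eye(3))
        np.testing.assert_allclose(out[["s0", "s1", "s2"]], psms[["s0", "s1", "s2"]])
        assert not out["flag_isotope_clipped"].any()

    def test_two_channel_system_solved_exactly(self):
        # [[0.9, 0.1], [0.1, 0.9]] x = [1000, 500]:
        # x1 = (0.9*1000 - 0.1*500) / 0.8 = 1062.5, x2 = 437.5 (hand-solved)
        psms = make_psms([[1000, 500]])
        m = np.array([[0.9, 0.1], [0.1, 0.9]])
        out = tmt.correct_isotope_impurity(psms, m)
        np.testing.assert_allclose(out[["s0", "s1"]].to_numpy(), [[1062.5, 437.5]])

    def test_all_zero_stays_zero(self):
        psms = make_psms([[0.0, 0.0]])
        out = tmt.correct_isotope_impurity(psms, np.array([[0.9, 0.1], [0.1, 0.9]]))
        np.testing.assert_allclose(out[["s0", "s1"]].to_numpy(), 0.0)

    def test_negative_solutions_clipped_and_flagged(self):
        psms = make_psms([[100, 10000]])
        m = np.array([[0.8, 0.3], [0.2, 0.7]])
        out = tmt.correct_isotope_impurity(psms, m)
        assert (out[["s0", "s1"]].to_numpy() >= 0).all()
        assert out["flag_isotope_clipped"].iloc[0]

    def test_singular_matrix_raises(self):
        psms = make_psms([[100, 100]])
        with pytest.raises(ValueError, match="singular"):
            tmt.correct_isotope_impurity(psms, np.ones((2, 2)))


class TestLowIntensityFilter:
    @pytest.mark.parametrize(
        "row, kept",
        [
            ([800, 5000, 6000], False),   # min 800 below 1000
            ([1200, 4000, 4500], False),  # median 4000 below 5000
            ([1500, 6000, 7000], True),
        ],
    )
    def test_min_and_median_rules(self, row, kept):
        out = tmt.filter_low_intensity(make_psms([row]))
        assert (len(out) == 1) is kept

    def test_empty_table_warns_and_passes_through(self, caplog):
        empty = make_psms(np.empty((0, 3)))
        with caplog.at_level("WARNING"):
            out = tmt.filter_low_intensity(empty)
        assert out.empty
        assert any("empty" in r.message for r in caplog.records)

    def test_mostly_missing_psm_dropped(self):
        psms = make_psms([[6000, np.nan, np.nan, np.nan]])
        assert tmt.filter_low_intensity(psms).empty


class TestLoadingNormalization:
    def test_identical_channels_get_equal_factors(self):
        psms = make_psms(np.tile([[1000.0], [2000.0], [4000.0]], (1, 3)))
        out = tmt.normalize_loading(psms)
        factors = out.attrs["loading_factors_log2"]
        assert np.allclose(list(factors.values()), 0.0, atol=1e-12)

    def test_twofold_bias_removed(self, rng):
        base = rng.lognormal(10, 1, size=200)
        psms = make_psms(np.column_stack([base, 2.0 * base]))
        out = tmt.normalize_loading(psms)
        logv = np.log2(out[["s0", "s1"]].to_numpy())
        med = np.median(logv, axis=0)
        assert abs(med[0] - med[1]) < 1e-9

    def test_random_table_trimmed_medians_align(self, rng):
        vals = rng.lognormal(12, 1.5, size=(500, 6)) * rng.uniform(0.3, 3.0, 6)
        out = tmt.normalize_loading(make_psms(vals), trim_fraction=0.1)
        logv = np.log2(out[[f"s{j}" for j in range(6)]].to_numpy())
        meds = [tmt._trimmed_median(logv[:, j], 0.1) for j in range(6)]
        assert max(meds) - min(meds) < 1e-9

    def test_normalization_is_idempotent(self, rng):
        vals = rng.lognormal(12, 1, size=(300, 4))
        once = tmt.normalize_loading(make_psms(vals))
        twice = tmt.normalize_loading(once)
        assert np.allclose(list(twice.attrs["loading_factors_log2"].values()),
                           0.0, atol=1e-9)

    def test_all_missing_channel_raises(self):
        psms = make_psms([[1000, np.nan], [2000, np.nan]])
        with pytest.raises(ValueError, match="s1"):
            tmt.normalize_loading(psms)


class TestSummarizeProteins:
    def test_single_psm_profile_is_its_centered_profile(self):
        psms = make_psms([[1000, 4000]])
        quant = tmt.summarize_proteins(psms)
        expected = np.log2([1000, 4000]) - np.mean(np.log2([1000, 4000]))
        np.testing.assert_allclose(quant.log2_rel.loc["P1"], expected)

    def test_opposite_profiles_cancel(self):
        psms = make_psms([[1000, 4000], [4000, 1000]])
        quant = tmt.summarize_proteins(psms)
        np.testing.assert_allclose(quant.log2_rel.loc["P1"], 0.0, atol=1e-12)

    def test_top3_grand_mean_hand_computed(self):
        # totals: psm_0 400, psm_1 400 (tie -> psm_0 wins lexicographically),
        # psm_2 2000, psm_3 100, psm_4 1000; top3 = psm_2, psm_4, psm_0;
        # grand mean = mean(1000,1000,400,600,100,300) = 3400/6
        psms = make_psms([[100, 300], [200, 200], [1000, 1000],
                          [50, 50], [400, 600]])
        quant = tmt.summarize_proteins(psms)
        assert quant.absolute.loc["P1"] == pytest.approx(3400 / 6)

    def test_mean_centering_conservation(self, rng):
        vals = rng.lognormal(12, 1, size=(60, 8))
        proteins = [f"P{i % 7}" for i in range(60)]
        quant = tmt.summarize_proteins(make_psms(vals, proteins=proteins))
        assert np.abs(quant.log2_rel.sum(axis=1)).max() < 1e-9


class TestFullChain:
    def test_zero_noise_recovery_of_generated_profiles(self, design):
        # no loading bias, identity impurity, no PSM noise: the roll-up must
        # reproduce the generated mean-centered profiles to float precision
        # (loading normalization is skipped - with finite proteomes it trades
        # channel medians of real biology against the equal-loading assumption)
        params = SimParams(n_proteins=25, psm_cv=0.0, psm_log2_sd=0.0,
                           loading_bias=np.ones(8), impurity=np.eye(8),
                           baseline_mean=16.0, seed=9)
        psms, matrix, _ = simulate_proteome(design, params)
        corrected = tmt.correct_isotope_impurity(psms, np.eye(8))
        quant = tmt.summarize_proteins(tmt.filter_low_intensity(corrected))
        centered = matrix.sub(matrix.mean(axis=1), axis=0)
        shared = quant.log2_rel.index.intersection(centered.index)
        assert len(shared) >= 20
        diff = (quant.log2_rel.loc[shared, design.sample_ids]
                - centered.loc[shared]).to_numpy()
        assert np.abs(diff).max() < 1e-9

    def test_quantify_removes_loading_bias_approximately(self, design):
        params = SimParams(n_proteins=400, sigma_additive=0.3, fraction_null=0.5,
                           psm_cv=0.05, seed=10)
        psms, matrix, _ = simulate_proteome(design, params)
        quant = tmt.quantify(psms, default_impurity_matrix(8))
        centered = matrix.sub(matrix.mean(axis=1), axis=0)
        shared = quant.log2_rel.index.intersection(centered.index)
        resid = (quant.log2_rel.loc[shared, design.sample_ids]
                 - centered.loc[shared]).to_numpy()
        # per-protein profiles track truth up to small normalization shifts
        assert np.median(np.abs(resid)) < 0.2
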