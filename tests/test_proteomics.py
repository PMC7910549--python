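"""Perseus-style filtering, imputation, enrichment testing, SILAC and iBAQ."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pausekit.proteomics import (
    GroupDesign,
    IntensityMatrix,
    clean_and_log2,
    filter_min_valid,
    group_ttest_volcano,
    ibaq_stoichiometry,
    impute_downshift,
    read_protein_groups,
    silac_enrichment,
)

SAMPLES = ["UV_1", "UV_2", "UV_3", "UV_4", "mock_1", "mock_2", "mock_3", "mock_4"]
DESIGN = GroupDesign({s: s.split("_")[0] for s in SAMPLES})


def linear_matrix(values, flags=None):
    df = pd.DataFrame(values, columns=SAMPLES[: np.shape(values)[1]])
    df.index = [f"P{i}" for i in range(len(df))]
    fl = None
    if flags is not None:
        fl = pd.DataFrame(
            {"Reverse": flags, "Potential contaminant": False, "Only identified by site": False},
            index=df.index,
        )
    return IntensityMatrix(values=df, flags=fl, state="linear")


class TestCleanAndLog2:
    def test_flagged_protein_dropped(self):
        m = linear_matrix(np.full((2, 8), 8.0), flags=[True, False])
        out = clean_and_log2(m)
        assert list(out.values.index) == ["P1"]

    def test_log2_of_eight_is_three(self):
        out = clean_and_log2(linear_matrix(np.full((1, 8), 8.0)))
        assert (out.values.to_numpy() == 3.0).all()
        assert out.state == "log2"

    def test_zero_becomes_missing(self):
        vals = np.full((1, 8), 4.0)
        vals[0, 0] = 0.0
        out = clean_and_log2(linear_matrix(vals))
        assert np.isnan(out.values.iloc[0, 0])

    def test_requires_linear_state(self):
        m = clean_and_log2(linear_matrix(np.full((1, 8), 8.0)))
        with pytest.raises(ValueError):
            clean_and_log2(m)


class TestFilterMinValid:
    def _log2(self, vals):
        df = pd.DataFrame(vals, columns=SAMPLES)
        df.index = [f"P{i}" for i in range(len(df))]
        return IntensityMatrix(values=df, state="log2")

    def test_full_in_one_group_kept(self):
        vals = np.full((1, 8), 20.0)
        vals[0, 4:] = np.nan  # 4/4 in UV, 0/4 in mock
        assert filter_min_valid(self._log2(vals), DESIGN, 4).n_proteins == 1

    def test_three_of_four_everywhere_removed(self):
        vals = np.full((1, 8), 20.0)
        vals[0, 0] = np.nan
        vals[0, 4] = np.nan
        assert filter_min_valid(self._log2(vals), DESIGN, 4).n_proteins == 0

    def test_min_valid_zero_is_identity(self):
        vals = np.full((3, 8), np.nan)
        assert filter_min_valid(self._log2(vals), DESIGN, 0).n_proteins == 3

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(20, 2, (50, 8))
        vals[rng.uniform(size=vals.shape) < 0.4] = np.nan
        m = self._log2(vals)
        kept = [set(filter_min_valid(m, DESIGN, k).values.index) for k in range(5)]
        for a, b in zip(kept, kept[1:]):
            assert b <= a


class TestImputeDownshift:
    def _matrix(self, n_obs=400, n_missing=100, mu=20.0, sigma=2.0, seed=1):
        rng = np.random.default_rng(seed)
        vals = rng.normal(mu, sigma, size=(n_obs + n_missing) // 4 * 4).reshape(-1, 4)
        flat = vals.ravel()
        flat[:n_missing] = np.nan
        df = pd.DataFrame(flat.reshape(-1, 4), columns=SAMPLES[:4])
        df.index = [f"P{i}" for i in range(len(df))]
        return IntensityMatrix(values=df, state="log2")

    def test_draws_from_downshifted_normal(self):
        m = self._matrix()
        obs = m.values.to_numpy()
        mu, sigma = np.nanmean(obs), np.nanstd(obs)
        out = impute_downshift(m, seed=7)
        imputed = out.values.to_numpy()[~np.isfinite(m.values.to_numpy())]
        assert imputed.mean() == pytest.approx(mu - 1.8 * sigma, abs=0.2 * sigma)

    def test_same_seed_identical(self):
        m = self._matrix()
        a = impute_downshift(m, seed=3).values
        b = impute_downshift(m, seed=3).values
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs_only_at_missing(self):
        m = self._matrix()
        a = impute_downshift(m, seed=3).values.to_numpy()
        b = impute_downshift(m, seed=4).values.to_numpy()
        observed = np.isfinite(m.values.to_numpy())
        np.testing.assert_array_equal(a[observed], b[observed])
        assert (a[~observed] != b[~observed]).any()

    def test_no_finite_values_rejected(self):
        df = pd.DataFrame(np.full((2, 4), np.nan), columns=SAMPLES[:4])
        with pytest.raises(ValueError):
            impute_downshift(IntensityMatrix(values=df, state="log2"))


class TestGroupTtest:
    def _complete(self, vals):
        df = pd.DataFrame(vals, columns=SAMPLES)
        df.index = [f"P{i}" for i in range(len(df))]
        return IntensityMatrix(values=df, state="log2")

    def test_identical_groups_null(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], (1, 2))
        res = group_ttest_volcano(self._complete(vals), DESIGN, ("UV", "mock"))
        assert res["log2_fc"].item() == 0.0
        assert res["p_value"].item() == pytest.approx(1.0)

    def test_closed_form_two_df_case(self):
        """a={5,6}, b={1,2}: fold-change 4, t = 4/sqrt(0.5), df = 2."""
        design = GroupDesign({"a1": "a", "a2": "a", "b1": "b", "b2": "b"})
        df = pd.DataFrame([[5.0, 6.0, 1.0, 2.0]], columns=["a1", "a2", "b1", "b2"], index=["P0"])
        res = group_ttest_volcano(IntensityMatrix(values=df, state="log2"), design, ("a", "b"))
        assert res["log2_fc"].item() == pytest.approx(4.0)
        t = 4.0 / np.sqrt(0.5)
        assert res["p_value"].item() == pytest.approx(2 * stats.t.sf(t, df=2))

    def test_label_swap_negates_fc_keeps_p(self):
        rng = np.random.default_rng(5)
        m = self._complete(rng.normal(20, 1, (20, 8)))
        ab = group_ttest_volcano(m, DESIGN, ("UV", "mock"))
        ba = group_ttest_volcano(m, DESIGN, ("mock", "UV"))
        np.testing.assert_allclose(ab["log2_fc"], -ba["log2_fc"])
        np.testing.assert_allclose(ab["p_value"], ba["p_value"])

    def test_missing_values_rejected(self):
        vals = np.full((1, 8), 20.0)
        vals[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            group_ttest_volcano(self._complete(vals), DESIGN, ("UV", "mock"))


class TestSilac:
    def test_threshold_inclusive(self):
        ratios = pd.Series({"A": 2.0, "B": 1.99, "C": 5.0})
        out = silac_enrichment(ratios, 2.0)
        assert out.to_dict() == {"A": True, "B": False, "C": True}

    def test_label_swap_inverts(self):
        ratios = pd.Series({"A": 4.0, "B": 0.5})
        swapped = 1.0 / ratios
        assert silac_enrichment(ratios, 2.0)["A"]
        assert not silac_enrichment(swapped, 2.0)["A"]
        assert silac_enrichment(swapped, 2.0)["B"]

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            silac_enrichment(pd.Series({"A": 0.0}))


class TestIbaqStoichiometry:
    def _ibaq(self):
        return pd.DataFrame(
            {"UV": [10.0, 6.0, 0.02], "mock": [10.0, 6.0, 0.002]},
            index=["CSB", "PAF1", "weak"],
        )

    def test_bound_fraction(self):
        res = ibaq_stoichiometry(self._ibaq(), "CSB", ["PAF1"], ("UV", "mock"))
        assert res.loc["PAF1", "fraction_UV"] == pytest.approx(0.6)

    def test_equal_conditions_fold_one(self):
        res = ibaq_stoichiometry(self._ibaq(), "CSB", ["PAF1"], ("UV", "mock"))
        assert res.loc["PAF1", "fold_change"] == pytest.approx(1.0)

    def test_fold_change_ratio(self):
        res = ibaq_stoichiometry(self._ibaq(), "CSB", ["weak"], ("UV", "mock"))
        assert res.loc["weak", "fold_change"] == pytest.approx(10.0)

    def test_zero_bait_rejected(self):
        ibaq = self._ibaq()
        ibaq.loc["CSB", "UV"] = 0.0
        with pytest.raises(ValueError, match="bait"):
            ibaq_stoichiometry(ibaq, "CSB", ["PAF1"], ("UV", "mock"))


def test_protein_groups_tsv_roundtrip(tmp_path):
    p = tmp_path / "proteinGroups.txt"
    p.write_text(
        "Protein IDs\tLFQ intensity UV_1\tLFQ intensity mock_1\tiBAQ UV_1\tReverse\tPotential contaminant\n"
        "P1\t100\t50\t10\t\t\n"
        "P2\t0\t80\t5\t+\t\n"
    )
    m = read_protein_groups(p)
    assert m.values.loc["P1", "UV_1"] == 100.0
    assert m.flags.loc["P2", "Reverse"]
    assert m.ibaq.loc["P1", "UV_1"] == 10.0
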