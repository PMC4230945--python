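import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import refstab as r
from conftest import random_quantities

from _oracles import genorm_full


class TestCtToQuantity:
    def test_powers_of_two(self, design):
        wells = pd.MultiIndex.from_tuples(
            [(s, 1) for s in design.samples[:3]], names=["sample_id", "replicate"]
        )
        ct = r.CtTable(
            pd.DataFrame([[20.0, 21.0, 23.0]], index=["a"], columns=wells),
            design=design,
        )
        q = r.ct_to_quantity(ct)
        assert q.loc["a"].tolist() == pytest.approx([1.0, 0.5, 0.125])

    def test_efficiency_below_two(self, design):
        wells = pd.MultiIndex.from_tuples(
            [(s, 1) for s in design.samples[:2]], names=["sample_id", "replicate"]
        )
        ct = r.CtTable(
            pd.DataFrame([[20.0, 21.0]], index=["a"], columns=wells),
            efficiency=pd.Series({"a": 1.9}),
            design=design,
        )
        assert r.ct_to_quantity(ct).loc["a"].tolist() == pytest.approx(
            [1.0, 1 / 1.9]
        )

    def test_constant_row_and_missing_handling(self, design):
        wells = pd.MultiIndex.from_tuples(
            [(s, 1) for s in design.samples[:3]], names=["sample_id", "replicate"]
        )
        frame = pd.DataFrame(
            [[21.0, 21.0, 21.0], [20.0, np.nan, 22.0]],
            index=["const", "holey"], columns=wells,
        )
        q = r.ct_to_quantity(r.CtTable(frame, design=design))
        assert (q.loc["const"] == 1.0).all()
        assert "holey" not in q.index  # dropped with a warning

    def test_all_missing_gene_raises(self, design):
        wells = pd.MultiIndex.from_tuples(
            [(s, 1) for s in design.samples[:2]], names=["sample_id", "replicate"]
        )
        frame = pd.DataFrame(
            [[np.nan, np.nan], [20.0, 21.0]], index=["gone", "ok"], columns=wells
        )
        with pytest.raises(ValueError, match="all-missing"):
            r.ct_to_quantity(r.CtTable(frame, design=design))


class TestPairwiseAndM:
    def test_hand_worked_three_genes(self, hand_quantities):
        v = r.pairwise_stability(hand_quantities)
        assert v.loc["g1", "g2"] == pytest.approx(0.0)  # proportional genes
        assert v.loc["g1", "g3"] == pytest.approx(1.0)  # SD of (0, 1, 2)
        assert np.allclose(v, v.T) and np.allclose(np.diag(v), 0)
        m = r.m_values(hand_quantities)
        assert m.tolist() == pytest.approx([0.5, 0.5, 1.0])

    def test_duplicated_gene_pair_m_zero(self):
        q = pd.DataFrame([[1.0, 0.5, 0.25]] * 2, index=["a", "b"],
                         columns=["s1", "s2", "s3"])
        assert r.m_values(q).tolist() == pytest.approx([0.0, 0.0])

    def test_rescaling_one_gene_leaves_m_unchanged(self, hand_quantities):
        before = r.m_values(hand_quantities)
        scaled = hand_quantities.copy()
        scaled.loc["g1"] *= 7.3
        after = r.m_values(scaled)
        assert after.tolist() == pytest.approx(before.tolist())

    def test_singleton_active_set_rejected(self, hand_quantities):
        with pytest.raises(ValueError, match=">=2"):
            r.m_values(hand_quantities, active=["g1"])


class TestStepwiseRanking:
    def test_noisy_gene_excluded_first(self):
        rng = np.random.default_rng(5)
        base = 2.0 ** rng.uniform(-4, 0, size=10)
        q = pd.DataFrame(
            {
                "g1": base,
                "g2": base * 0.5,
                "g3": base * 2.0,
                "g4": base * 2.0 ** rng.normal(0, 1.0, size=10),
            }
        ).T
        q = q.div(q.max(axis=1), axis=0)
        model = r.stepwise_ranking(q)
        assert model.exclusion_order_[0][0] == "g4"
        assert set(model.most_stable_pair_) <= {"g1", "g2", "g3"}

    def test_proportional_genes_tie_break_by_input_order(self):
        q = pd.DataFrame(
            [[1.0, 0.5], [2.0, 1.0], [4.0, 2.0]],
            index=["a", "b", "c"], columns=["s1", "s2"],
        )
        model = r.stepwise_ranking(q)
        assert model.exclusion_order_ == [("c", 0.0)]  # later gene excluded on tie
        assert model.most_stable_pair_ == ("a", "b")
        assert model.m_final_.tolist() == pytest.approx([0.0, 0.0, 0.0])

    def test_final_pair_shares_rank_one(self, panel_ct):
        q = r.ct_to_quantity(r.collapse_replicates(panel_ct))
        model = r.GeNorm().fit(q.T)
        pair = model.most_stable_pair_
        assert [model.ranking_[g] for g in pair] == [1, 1]
        assert sorted(model.ranking_) == [1, 1] + list(range(3, len(q.index) + 1))
        assert sorted(model.stability_order_) == sorted(q.index)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_shift_invariance_in_ct_space(self, seed):
        """Adding a constant to one gene's Ct changes no M and no V."""
        rng = np.random.default_rng(seed)
        ct = rng.uniform(18, 28, size=(4, 6))
        shifted = ct.copy()
        shifted[2] += 3.7
        results = []
        for mat in (ct, shifted):
            q = 2.0 ** (mat.min(axis=1, keepdims=True) - mat)
            q = pd.DataFrame(q, index=list("abcd"))
            model = r.stepwise_ranking(q)
            results.append((model.m_final_.to_numpy(), model.v_series_["v"].to_numpy()))
        np.testing.assert_allclose(results[0][0], results[1][0], atol=1e-10)
        np.testing.assert_allclose(results[0][1], results[1][1], atol=1e-10)


class TestNormalizationFactorAndVSeries:
    def test_nf_identities(self, hand_quantities):
        single = r.normalization_factor(hand_quantities, ["g1"])
        pd.testing.assert_series_equal(
            single, hand_quantities.loc["g1"].rename("NF"), check_names=True
        )
        pair = r.normalization_factor(
            pd.DataFrame([[1.0, 1.0], [4.0, 1.0]], index=["a", "b"]), ["a", "b"]
        )
        assert pair.iloc[0] == pytest.approx(2.0)  # geometric mean of (1, 4)
        dup = r.normalization_factor(hand_quantities, ["g1", "g1"])
        pd.testing.assert_series_equal(dup, single)

    def test_v_zero_when_third_gene_proportional_to_nf2(self):
        rng = np.random.default_rng(2)
        g1 = 2.0 ** rng.uniform(-3, 0, 8)
        g2 = 2.0 ** rng.uniform(-3, 0, 8)
        nf2 = np.sqrt(g1 * g2)
        q = pd.DataFrame([g1, g2, nf2 * 0.5], index=["a", "b", "c"])
        series, _ = r.v_series(q, ["a", "b", "c"])
        assert series.loc[series["n"] == 2, "v"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_recommended_n_thresholding(self, hand_quantities):
        # V2/3 just under vs just over the cutoff flips the recommendation
        q = hand_quantities
        model = r.GeNorm(cutoff=10.0).fit(q.T)
        assert model.recommended_n_ == 2
        model = r.GeNorm(cutoff=1e-12).fit(q.T)
        assert model.recommended_n_ is None


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(3, 7))
        n_samples = int(rng.integers(3, 9))
        q = random_quantities(rng, n_genes, n_samples)
        expected = genorm_full({g: q.loc[g].tolist() for g in q.index})
        model = r.GeNorm().fit(q.T)
        assert model.stability_order_ == expected["order"]
        for gene, m in expected["m"].items():
            assert model.m_final_[gene] == pytest.approx(m, abs=1e-10)
        got_v = dict(zip(model.v_series_["n"], model.v_series_["v"]))
        for n, v in expected["v_series"]:
            assert got_v[n] == pytest.approx(v, abs=1e-10)
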