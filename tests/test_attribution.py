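"""Connection-weight decision weights, category totals and characters."""

import numpy as np
import pandas as pd
import pytest

import speceffect as se
from speceffect.datasets import rhubarb_category_contributions
from speceffect.exceptions import DegenerateDataError


def _loop_decision_weights(Ws):
    """Independent brute-force oracle: literal nested-loop path enumeration
    over the normalized share matrices."""
    shares = [np.abs(W) / np.abs(W).sum() for W in Ws]
    n_in = shares[0].shape[0]
    n_out = shares[-1].shape[1]
    F = np.zeros((n_in, n_out))
    if len(shares) == 2:
        F1, F2 = shares
        for i in range(n_in):
            for j in range(F1.shape[1]):
                for k in range(n_out):
                    F[i, k] += F1[i, j] * F2[j, k]
    elif len(shares) == 3:
        F1, F2, F3 = shares
        for i in range(n_in):
            for j in range(F1.shape[1]):
                for o in range(F2.shape[1]):
                    for k in range(n_out):
                        F[i, k] += F1[i, j] * F2[j, o] * F3[o, k]
    else:
        F1, F2, F3, F4 = shares
        for i in range(n_in):
            for j in range(F1.shape[1]):
                for o in range(F2.shape[1]):
                    for q in range(F3.shape[1]):
                        for k in range(n_out):
                            F[i, k] += F1[i, j] * F2[j, o] * F3[o, q] * F4[q, k]
    s = F.sum(axis=1)
    return s / s.sum()


def _garson_grand_sum(W1, W2):
    """Connection-weights importance for one hidden layer, written from the
    definition with explicit loops: importance_i ~ sum_j |w_ij| * |v_j|."""
    imp = []
    for i in range(W1.shape[0]):
        tot = 0.0
        for j in range(W1.shape[1]):
            for k in range(W2.shape[1]):
                tot += abs(W1[i, j]) * abs(W2[j, k])
        imp.append(tot)
    imp = np.asarray(imp)
    return imp / imp.sum()


def _random_net(rng, sizes):
    return [rng.normal(0.0, 1.0, (a, b)) for a, b in zip(sizes[:-1], sizes[1:])]


class TestLayerShare:
    def test_direct_evaluation(self):
        W = np.array([[1.0, -1.0], [2.0, 0.0]])
        assert np.allclose(se.layer_share(W), [[0.25, 0.25], [0.5, 0.0]])

    def test_sign_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(4, 3))
        assert np.allclose(se.layer_share(W), se.layer_share(-W))
        assert np.allclose(se.layer_share(W), se.layer_share(3.7 * W))

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateDataError):
            se.layer_share(np.zeros((3, 3)))


class TestDecisionWeights:
    def test_uniform_weights_give_uniform_importance(self):
        Ws = [np.ones((6, 4)), np.ones((4, 3)), np.ones((3, 1))]
        dw = se.decision_weights(Ws)
        assert np.allclose(dw.s.to_numpy(), 1.0 / 6.0)

    def test_path_dominance(self):
        """If only input 1 reaches the first hidden layer, it takes all the
        importance."""
        W1 = np.zeros((5, 4))
        W1[0] = [1.0, -2.0, 0.5, 1.5]
        Ws = [W1, np.ones((4, 1))]
        dw = se.decision_weights(Ws)
        assert dw.s.iloc[0] == pytest.approx(1.0)
        assert np.allclose(dw.s.iloc[1:], 0.0)

    @pytest.mark.parametrize("sizes", [(4, 5, 3, 1), (6, 4, 1), (5, 4, 3, 2, 1)])
    def test_matches_loop_oracle(self, sizes):
        rng = np.random.default_rng(hash(sizes) % 2**31)
        for _ in range(10):
            Ws = _random_net(rng, sizes)
            dw = se.decision_weights(Ws)
            assert np.abs(dw.s.to_numpy() - _loop_decision_weights(Ws)).max() < 1e-13

    def test_one_hidden_layer_equals_garson_connection_weights(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            Ws = _random_net(rng, (6, 4, 1))
            dw = se.decision_weights(Ws)
            assert np.allclose(dw.s.to_numpy(), _garson_grand_sum(*Ws), atol=1e-13)

    def test_sums_to_one_and_nonnegative_for_trained_nets(self, linear_training_data):
        X, y = linear_training_data
        for depth, hl in enumerate([(6,), (6, 5), (6, 5, 4)], start=1):
            net = se.QuantityEffectRegressor(hidden_layer_sizes=hl, max_epochs=40,
                                             random_state=depth).fit(X, y)
            dw = se.decision_weights(net)
            assert abs(dw.s.sum() - 1.0) < 1e-12
            assert (dw.s >= 0).all()

    def test_per_layer_transformations_leave_s_unchanged(self):
        rng = np.random.default_rng(9)
        Ws = _random_net(rng, (5, 4, 3, 1))
        base = se.decision_weights(Ws).s
        flipped = se.decision_weights([-Ws[0], Ws[1], -Ws[2]]).s
        scaled = se.decision_weights([2.0 * Ws[0], 0.1 * Ws[1], 5.0 * Ws[2]]).s
        assert np.allclose(base, flipped) and np.allclose(base, scaled)


class TestAveragedDecisionWeights:
    def test_single_seed_equals_single_run(self, linear_training_data):
        X, y = linear_training_data
        seed0 = int(np.random.SeedSequence(5).generate_state(1)[0] % 2**31)
        net = se.QuantityEffectRegressor(max_epochs=30, random_state=seed0).fit(X, y)
        single = se.decision_weights(net).s
        avg = se.averaged_decision_weights(X, y, n_seeds=1, seed=5, max_epochs=30)
        assert np.allclose(avg.s.to_numpy(), single.to_numpy())
        assert avg.n_seeds == 1

    def test_mean_sums_to_one(self, linear_training_data):
        X, y = linear_training_data
        avg = se.averaged_decision_weights(X, y, n_seeds=4, seed=0, max_epochs=30)
        assert avg.s.sum() == pytest.approx(1.0, abs=1e-12)
        assert avg.sd is not None


class TestSelection:
    def test_threshold_zero_keeps_positive_weights(self):
        s = pd.Series([0.5, 0.3, 0.2, 0.0], index=list("abcd"))
        sel = se.select_contributors(s, threshold=0.0)
        assert list(sel.index) == ["a", "b", "c"]

    def test_threshold_one_empty(self):
        s = pd.Series([0.6, 0.4], index=list("ab"))
        assert len(se.select_contributors(s, threshold=1.0)) == 0

    def test_ties_broken_by_id(self):
        s = pd.Series([0.25, 0.25, 0.5], index=["b", "a", "c"])
        assert list(se.select_contributors(s, threshold=0.1).index) == ["c", "a", "b"]


class TestCategoryTotals:
    def test_published_grand_totals(self):
        """Summing the published per-efficacy category contributions
        reproduces the printed grand totals."""
        table = se.aggregate_contribution_table(rhubarb_category_contributions())
        expected = {"Rh-02": 0.43665, "Rh-04": 0.26658, "Rh-06": 0.14023,
                    "Rh-03": 0.12093, "Rh-01": 0.12049, "Rh-09": 0.11804,
                    "Rh-05": 0.11295, "Rh-08": 0.11183, "Rh-07": 0.07986,
                    "Rh-10": 0.03178}
        for cat, tot in expected.items():
            assert table.total[cat] == pytest.approx(tot, abs=1e-9)

    def test_published_ranks(self):
        """Recomputed per-efficacy ranks match the published ordinal
        annotations (e.g. Rh-02 ranks first in E1, E3, E4, E5 and second in
        E2)."""
        table = se.aggregate_contribution_table(rhubarb_category_contributions())
        assert list(table.ranks.loc["Rh-02"]) == [1, 2, 1, 1, 1]
        assert list(table.ranks.loc["Rh-04"]) == [2, 1, 3, 2, 2]
        assert list(table.ranks.loc["Rh-10"]) == [10, 10, 9, 10, 10]

    def test_conservation(self, linear_training_data):
        """Per-effect category totals sum to the total above-threshold
        decision weight of that effect."""
        X, y = linear_training_data
        dw = se.averaged_decision_weights(X, y, n_seeds=2, seed=1, max_epochs=30,
                                          feature_names=[f"C{i:02d}" for i in range(10)])
        assignments = pd.DataFrame({
            "component_id": dw.s.index,
            "category": ["Rh-01", "Rh-02"] * 5,
        })
        cct = se.category_totals({"E1": dw}, assignments, threshold=0.01)
        expected = dw.s[dw.s > 0.01].sum()
        assert cct.contributions["E1"].sum() == pytest.approx(expected, abs=1e-12)

    def test_single_category_takes_everything(self):
        s = pd.Series([0.6, 0.3, 0.1], index=["c1", "c2", "c3"])
        assignments = pd.DataFrame({"component_id": ["c1", "c2", "c3"],
                                    "category": ["Rh-05"] * 3})
        cct = se.category_totals({"E1": s}, assignments, threshold=0.0)
        assert cct.contributions.loc["Rh-05", "E1"] == pytest.approx(1.0)

    def test_unassigned_component_rejected(self):
        s = pd.Series([1.0], index=["cX"])
        assignments = pd.DataFrame({"component_id": ["other"], "category": ["Rh-01"]})
        with pytest.raises(ValueError):
            se.category_totals({"E1": s}, assignments)


class TestUniversalIndividual:
    def test_published_universal_pair(self):
        """The top-3 intersection across the five efficacies is exactly the
        combined-anthraquinone and flavanol categories."""
        table = se.aggregate_contribution_table(rhubarb_category_contributions())
        chars = se.universal_individual(table, top_m=3)
        assert chars.universal == {"Rh-02", "Rh-04"}
        assert "Rh-05" in chars.individual["E3"]  # gallotannins rank 2 in E3 only

    def test_top_m_equal_n_categories_makes_all_universal(self):
        table = se.aggregate_contribution_table(rhubarb_category_contributions())
        chars = se.universal_individual(table, top_m=10)
        assert chars.universal == set(table.contributions.index)

    def test_single_effect_table(self):
        df = pd.DataFrame({"E1": [0.5, 0.3, 0.2]}, index=["a", "b", "c"])
        chars = se.universal_individual(se.aggregate_contribution_table(df), top_m=2)
        assert chars.universal == {"a", "b"}

    def test_top_m_out_of_range(self):
        table = se.aggregate_contribution_table(rhubarb_category_contributions())
        with pytest.raises(ValueError):
            se.universal_individual(table, top_m=11)
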