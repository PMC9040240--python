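"""Quantity-effect network: normalization, splits, training contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import speceffect as se
from speceffect.exceptions import DivergenceError
from speceffect.network import summarize_sweep, sweep


class TestMinMax:
    def test_fit_records_extremes(self):
        p = se.minmax_fit(np.array([[2.0], [4.0], [6.0]]))
        assert p.min_[0] == 2.0 and p.max_[0] == 6.0

    def test_endpoints_and_midpoint(self):
        p = se.minmax_fit(np.array([[2.0], [6.0]]))
        assert se.minmax_apply(np.array([[2.0]]), p)[0, 0] == 0.0
        assert se.minmax_apply(np.array([[6.0]]), p)[0, 0] == 1.0
        assert se.minmax_apply(np.array([[4.0]]), p)[0, 0] == 0.5

    def test_degenerate_feature_maps_to_half(self):
        p = se.minmax_fit(np.array([[3.0, 1.0], [3.0, 2.0]]))
        assert p.degenerate[0] and not p.degenerate[1]
        assert se.minmax_apply(np.array([[3.0, 1.5]]), p)[0, 0] == 0.5

    def test_idempotence_on_normalized_data(self):
        X = np.random.default_rng(0).uniform(-5, 5, (20, 3))
        p = se.minmax_fit(X)
        p2 = se.minmax_fit(se.minmax_apply(X, p))
        assert np.allclose(p2.min_, 0.0) and np.allclose(p2.max_, 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(arrays(np.float64, (7, 3), elements=st.floats(-1e6, 1e6)))
    def test_roundtrip_property(self, X):
        p = se.minmax_fit(X)
        back = se.minmax_invert(se.minmax_apply(X, p), p)
        keep = ~p.degenerate
        assert np.allclose(back[:, keep], X[:, keep], atol=1e-6)


class TestSplit:
    def test_study_mode_trains_on_all_groups(self):
        groups = [f"g{i}" for i in range(18)]
        sp = se.split_train_test(groups, ["g15", "g16", "g17"])
        assert len(sp.train_labels) == 18 and len(sp.test_labels) == 3

    def test_strict_mode_excludes_test_groups(self):
        groups = [f"g{i}" for i in range(18)]
        sp = se.split_train_test(groups, ["g15", "g16", "g17"], strict=True)
        assert len(sp.train_labels) == 15
        assert set(sp.train_labels).isdisjoint(sp.test_labels)

    def test_empty_test_list(self):
        sp = se.split_train_test(["a", "b"], [])
        assert sp.train_labels == ("a", "b") and sp.test_labels == ()

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            se.split_train_test(["a"], ["zzz"])


class TestTraining:
    def test_linear_target_converges(self, linear_training_data):
        X, y = linear_training_data
        net = se.QuantityEffectRegressor(random_state=0).fit(X, y)
        assert min(net.loss_curve_) < 1e-3
        assert net.n_epochs_ <= 1000

    def test_goal_met_stops_immediately(self, linear_training_data):
        X, y = linear_training_data
        net = se.QuantityEffectRegressor(mse_goal=10.0, random_state=0).fit(X, y)
        assert net.stop_reason_ == "goal"
        assert net.n_epochs_ == 1
        assert len(net.loss_curve_) >= 1

    def test_seeded_determinism_bitwise(self, linear_training_data):
        X, y = linear_training_data
        a = se.QuantityEffectRegressor(max_epochs=50, random_state=42).fit(X, y)
        b = se.QuantityEffectRegressor(max_epochs=50, random_state=42).fit(X, y)
        assert all((Wa == Wb).all() for Wa, Wb in zip(a.weights_, b.weights_))
        assert a.loss_curve_ == b.loss_curve_

    def test_small_lr_plain_descent_monotone(self, linear_training_data):
        """In the small-learning-rate regime, plain gradient descent has a
        non-increasing training MSE on a linear target."""
        X, y = linear_training_data
        net = se.QuantityEffectRegressor(learning_rate=0.001, momentum=0.0,
                                         adaptive_lr=False, max_epochs=300,
                                         validation_fraction=0.0,
                                         random_state=1).fit(X, y)
        diffs = np.diff(net.loss_curve_)
        assert (diffs <= 1e-15).all()

    def test_same_architecture_recovery(self):
        """Noiseless data generated by a network of the same shape is fit to
        MSE < 1e-4 (approximation sanity)."""
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, (200, 6))
        teacher = se.QuantityEffectRegressor(hidden_layer_sizes=(8,), max_epochs=1,
                                             validation_fraction=0.0,
                                             random_state=3).fit(X, rng.uniform(0, 1, 200))
        y = teacher.predict(X)
        student = se.QuantityEffectRegressor(hidden_layer_sizes=(8,),
                                             validation_fraction=0.0,
                                             random_state=11).fit(X, y)
        assert min(student.loss_curve_) < 1e-4

    def test_sample_order_invariance(self, linear_training_data):
        """Full-batch training gives identical predictions whatever the
        order of the training rows (validation split disabled so the row
        subset is unchanged)."""
        X, y = linear_training_data
        perm = np.random.default_rng(3).permutation(len(y))
        a = se.QuantityEffectRegressor(max_epochs=60, validation_fraction=0.0,
                                       random_state=5).fit(X, y)
        b = se.QuantityEffectRegressor(max_epochs=60, validation_fraction=0.0,
                                       random_state=5).fit(X[perm], y[perm])
        assert np.allclose(a.predict(X), b.predict(X), atol=1e-10)

    def test_validation_stop_on_noise_target(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (40, 8))
        y = rng.uniform(0, 1, 40)
        net = se.QuantityEffectRegressor(random_state=2).fit(X, y)
        assert net.stop_reason_ == "validation"

    def test_gradient_stop(self, linear_training_data):
        X, y = linear_training_data
        net = se.QuantityEffectRegressor(gradient_tol=1e6, random_state=0).fit(X, y)
        assert net.stop_reason_ == "gradient"

    def test_divergence_raises(self, linear_training_data):
        X, y = linear_training_data
        with pytest.raises(DivergenceError):
            se.QuantityEffectRegressor(learning_rate=1e6, momentum=0.0,
                                       adaptive_lr=False, validation_fraction=0.0,
                                       random_state=0).fit(X, y)

    def test_architecture_validation(self, linear_training_data):
        X, y = linear_training_data
        with pytest.raises(ValueError):
            se.QuantityEffectRegressor(hidden_layer_sizes=()).fit(X, y)
        with pytest.raises(ValueError):
            se.QuantityEffectRegressor(hidden_layer_sizes=(5, 5, 5, 5)).fit(X, y)


class TestPrediction:
    def test_relative_error_definition(self):
        class Fake:
            def predict(self, X):
                return np.array([1.1, 2.0, 3.0])

        rel = se.relative_errors(Fake(), None, np.array([1.0, 2.0, 0.0]))
        assert rel[0] == pytest.approx(0.1)
        assert rel[1] == 0.0
        assert np.isnan(rel[2])

    def test_trained_net_small_relative_errors(self, linear_training_data):
        """A net trained to MSE < 2e-6 on noiseless linear data predicts all
        training rows with |true| > 0.1 to within 5% relative error."""
        X, y = linear_training_data
        net = se.QuantityEffectRegressor(validation_fraction=0.0, max_epochs=20000,
                                         random_state=0).fit(X, y)
        assert min(net.loss_curve_) < 2e-6
        rel = se.relative_errors(net, X, y)
        mask = np.abs(y) > 0.1
        assert np.nanmax(np.abs(rel[mask])) < 0.05


class TestSweep:
    def test_bookkeeping(self, linear_training_data):
        X, y = linear_training_data
        res = sweep(X[:40], y[:40], [{"hidden_layer_sizes": (5,)}], repeats=3,
                    seed=0, test_index=[0, 1], max_epochs=20)
        assert len(res) == 3 * 2
        assert set(res["repeat"]) == {0, 1, 2}

    def test_depth_comparison_on_realizable_data(self, linear_training_data):
        """On noiseless realizable data every depth converges to a small
        training MSE and deeper networks stay within an order of magnitude
        of the shallow optimum (depth does not break achievability)."""
        X, y = linear_training_data
        grid = [{"hidden_layer_sizes": (10,) * d} for d in (1, 2, 3)]
        res = sweep(X, y, grid, repeats=2, seed=1, max_epochs=3000,
                    validation_fraction=0.0)
        best = res.groupby("n_hidden_layers")["final_mse"].min()
        assert (best < 1e-3).all()
        assert best.loc[2] < 20 * best.loc[1] and best.loc[3] < 20 * best.loc[1]
        summary = summarize_sweep(res)
        assert len(summary) == 3

    def test_zero_hidden_layers_rejected(self, linear_training_data):
        X, y = linear_training_data
        with pytest.raises(ValueError):
            sweep(X, y, [{"hidden_layer_sizes": ()}], repeats=1)

    def test_empty_grid_rejected(self, linear_training_data):
        X, y = linear_training_data
        with pytest.raises(ValueError):
            sweep(X, y, [], repeats=1)
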