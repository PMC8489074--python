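import numpy as np
import pytest
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from lpiboost.deep import DeepGBDTClassifier, binary_cross_entropy

from conftest import tiny_classifier


class TestInitialization:
    def test_layer_output_widths_match_architecture(self, two_cluster_data):
        X, y = two_cluster_data
        model = tiny_classifier(hidden_dims=(16, 16), n_epochs=0).fit(X, y)
        assert [l.output.shape[1] for l in model.layers_] == [16, 16]
        assert model.layers_[0].inverse is None
        assert model.layers_[1].inverse is not None

    def test_zero_epsilon_gives_zero_initial_outputs(self, two_cluster_data):
        X, y = two_cluster_data
        model = tiny_classifier(epsilon=0.0, n_epochs=0).fit(X, y)
        for layer in model.layers_:
            np.testing.assert_allclose(layer.output, 0.0, atol=1e-12)

    def test_same_seed_identical_training_log(self, two_cluster_data):
        X, y = two_cluster_data
        h1 = tiny_classifier(n_epochs=3).fit(X, y).history_
        h2 = tiny_classifier(n_epochs=3).fit(X, y).history_
        assert h1 == h2  # bit-identical logs

    def test_single_class_errors(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="class"):
            tiny_classifier().fit(X, np.ones(10))


class TestTopPseudoLabel:
    def test_literal_mode_alpha_one_returns_label(self, two_cluster_data):
        """With squared loss between output and label and a unit step, the
        pseudo-label collapses exactly onto the label."""
        X, y = two_cluster_data
        model = tiny_classifier(pseudo_label_mode="literal", target_lr=1.0,
                                n_epochs=0).fit(X, y)
        p = model.top_pseudo_label(y.astype(float))
        np.testing.assert_allclose(p, np.tile(y[:, None],
                                              (1, p.shape[1])))

    def test_zero_target_lr_means_no_movement(self, two_cluster_data):
        X, y = two_cluster_data
        model = tiny_classifier(n_epochs=0).fit(X, y)
        model.target_lr = 0.0  # pragmatic: alpha=0 is the no-movement limit
        with pytest.raises(ValueError):
            model._validate_params_()
        model.target_lr = 1e-12
        p = model.top_pseudo_label(y.astype(float))
        np.testing.assert_allclose(p, model.layers_[-1].output, atol=1e-9)

    def test_head_gradient_matches_finite_differences(self, two_cluster_data):
        """p - o must equal -alpha * d(per-sample BCE)/do through the
        sigmoid head, checked against central differences."""
        X, y = two_cluster_data
        model = tiny_classifier(n_epochs=1, target_lr=1.0).fit(X, y)
        y01 = y.astype(float)
        o = model.layers_[-1].output
        p = model.top_pseudo_label(y01)
        W = model.head_.coef_[0]
        b = model.head_.intercept_[0]
        h = 1e-6
        for i in (0, 5, 17):
            for j in range(o.shape[1]):
                op, om = o[i].copy(), o[i].copy()
                op[j] += h
                om[j] -= h
                lp = binary_cross_entropy(
                    expit(np.array([op @ W + b])), np.array([y01[i]]))
                lm = binary_cross_entropy(
                    expit(np.array([om @ W + b])), np.array([y01[i]]))
                num_grad = (lp - lm) / (2 * h)
                assert p[i, j] - o[i, j] == pytest.approx(-num_grad,
                                                          abs=1e-6)

    def test_head_gradient_closed_form(self, two_cluster_data):
        X, y = two_cluster_data
        model = tiny_classifier(n_epochs=1, target_lr=0.5).fit(X, y)
        o = model.layers_[-1].output
        s = expit(o @ model.head_.coef_[0] + model.head_.intercept_[0])
        expected = o - 0.5 * (s - y)[:, None] * model.head_.coef_[0]
        np.testing.assert_allclose(model.top_pseudo_label(y.astype(float)),
                                   expected)


class TestMappingUpdates:
    def test_forward_fixed_point_leaves_mapping_unchanged(self,
                                                          two_cluster_data):
        """If the pseudo-label already equals the mapping's output, the
        residuals are zero and boosting adds only zero-valued trees."""
        X, y = two_cluster_data
        model = tiny_classifier(n_epochs=0).fit(X, y)
        o_before = model.layers_[0].output.copy()
        model._epoch_forw_losses = {}
        o_after = model.update_forward(1, o_before.copy())
        np.testing.assert_allclose(o_after, o_before, atol=1e-12)

    def test_forward_reconstruction_loss_non_increasing(self,
                                                        two_cluster_data):
        X, y = two_cluster_data
        model = tiny_classifier(n_epochs=3).fit(X, y)
        for entry in model.history_[1:]:
            for trace in entry["forward_losses"].values():
                assert all(a >= b - 1e-9 for a, b in
                           zip(trace, trace[1:]))

    def test_inverse_losses_finite_nonnegative(self, two_cluster_data):
        X, y = two_cluster_data
        model = tiny_classifier(n_epochs=2).fit(X, y)
        for entry in model.history_[1:]:
            for trace in entry["inverse_losses"].values():
                assert all(np.isfinite(v) and v >= 0 for v in trace)

    def test_inverse_update_reduces_reconstruction_loss(self,
                                                        two_cluster_data):
        X, y = two_cluster_data
        model = tiny_classifier(n_epochs=0, epsilon=0.0).fit(X, y)
        model._epoch_inv_losses = {}
        layer = model.layers_[1]
        below = model.layers_[0].output
        before = float(((layer.inverse.predict(layer.forward.predict(below))
                         - below) ** 2).sum())
        model.update_inverse(2, layer.output)
        after = model._epoch_inv_losses[2][-1] * below.shape[0]
        assert after <= before + 1e-9

    def test_tree_budget_per_epoch(self, two_cluster_data):
        """Each mapping gains exactly n_rounds * num_boost_round trees per
        epoch on top of its single initialisation round."""
        X, y = two_cluster_data
        n_epochs, n_rounds, nbr = 3, 3, 5
        model = tiny_classifier(n_epochs=n_epochs, n_rounds=n_rounds,
                                num_boost_round=nbr).fit(X, y)
        for layer in model.layers_:
            assert layer.forward.n_trees == 1 + n_epochs * n_rounds * nbr
        assert model.layers_[1].inverse.n_trees == \
            1 + n_epochs * n_rounds * nbr

    def test_layer_one_has_no_inverse(self, two_cluster_data):
        X, y = two_cluster_data
        model = tiny_classifier(n_epochs=0).fit(X, y)
        with pytest.raises(ValueError, match="inverse"):
            model.update_inverse(1, model.layers_[0].output)


class TestTraining:
    def test_zero_epochs_is_head_on_initial_features(self, two_cluster_data):
        X, y = two_cluster_data
        model = tiny_classifier(n_epochs=0).fit(X, y)
        assert len(model.history_) == 1
        head = LogisticRegression(C=1.0, tol=1e-8, max_iter=1000)
        head.fit(model.layers_[-1].output, y)
        np.testing.assert_allclose(model.head_.coef_, head.coef_,
                                   atol=1e-6)

    def test_loss_decreases_on_separable_data(self, two_cluster_data):
        X, y = two_cluster_data
        model = tiny_classifier(n_epochs=5).fit(X, y)
        assert model.history_[-1]["global_loss"] < \
            model.history_[0]["global_loss"]

    def test_epoch_count_honoured(self, two_cluster_data):
        X, y = two_cluster_data
        model = tiny_classifier(n_epochs=4).fit(X, y)
        assert model.history_[-1]["epoch"] == 4
        assert len(model.history_) == 5

    def test_diagnostic_identity_reduces_to_logistic_head(self,
                                                          two_cluster_data):
        X, y = two_cluster_data
        model = tiny_classifier(diagnostic_identity=True).fit(X, y)
        ref = LogisticRegression(C=1.0, tol=1e-8, max_iter=1000).fit(X, y)
        np.testing.assert_allclose(model.predict_proba(X),
                                   ref.predict_proba(X), atol=1e-8)


class TestPrediction:
    def test_scores_in_open_unit_interval(self, two_cluster_data, rng):
        X, y = two_cluster_data
        model = tiny_classifier(n_epochs=1).fit(X, y)
        s = model.predict_proba(rng.normal(size=(30, X.shape[1])))[:, 1]
        assert ((s > 0) & (s < 1)).all()

    def test_prediction_deterministic(self, two_cluster_data):
        X, y = two_cluster_data
        model = tiny_classifier(n_epochs=1).fit(X, y)
        np.testing.assert_array_equal(model.predict_proba(X),
                                      model.predict_proba(X))

    def test_width_mismatch_errors(self, two_cluster_data, rng):
        X, y = two_cluster_data
        model = tiny_classifier(n_epochs=0).fit(X, y)
        with pytest.raises(ValueError):
            model.predict_proba(rng.normal(size=(3, X.shape[1] + 1)))

    def test_labels_threshold_at_half(self, two_cluster_data):
        X, y = two_cluster_data
        model = tiny_classifier(n_epochs=3).fit(X, y)
        proba = model.predict_proba(X)[:, 1]
        np.testing.assert_array_equal(model.predict(X),
                                      (proba >= 0.5).astype(int))
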