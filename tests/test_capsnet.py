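"""Capsule network: shape arithmetic, squash, routing, margin loss, training."""

import numpy as np
import pytest

from gwoscreen.autograd import Tensor
from gwoscreen.capsnet import (CapsNet, CapsNetClassifier, CapsNetSpec,
                               build_capsnet, class_norms, conv_output_side,
                               dynamic_routing, margin_loss, squash,
                               train_capsnet)


def desk_spec(**kw):
    base = dict(input_side=24, conv_filters=16, primary_caps_types=2)
    base.update(kw)
    return CapsNetSpec(**base)


class TestConvArithmetic:
    @pytest.mark.parametrize("in_side,kernel,stride,expected", [
        (64, 9, 1, 56),
        (56, 9, 2, 24),
        (7, 7, 1, 1),
        (13, 13, 1, 1),
    ])
    def test_valid_convolution_sides(self, in_side, kernel, stride, expected):
        assert conv_output_side(in_side, kernel, stride) == expected

    def test_kernel_larger_than_input_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            conv_output_side(8, 9, 1)

    def test_default_spec_shape_chain(self):
        spec = CapsNetSpec()
        spec.validate_printed_shapes()
        assert spec.conv_side == 56
        assert spec.primary_side == 24
        assert spec.primary_channels == 32 * 8 == 256
        assert spec.num_primary_caps == 24 * 24 * 32 == 18432

    def test_routing_iterations_must_be_positive(self):
        with pytest.raises(ValueError, match="routing"):
            CapsNetSpec(routing_iters=0)


class TestSquash:
    def test_zero_vector_fixed_point(self):
        np.testing.assert_allclose(squash(np.zeros(8)), np.zeros(8))

    def test_unit_vector_halves(self):
        v = np.zeros(4)
        v[0] = 1.0
        out = squash(v)
        assert np.linalg.norm(out) == pytest.approx(0.5, abs=1e-6)

    def test_large_vector_approaches_one(self):
        v = np.zeros(4)
        v[1] = 100.0
        out = squash(v)
        assert np.linalg.norm(out) == pytest.approx(10000 / 10001, abs=1e-6)

    def test_norm_bound_and_direction_preserved(self):
        rng = np.random.default_rng(0)
        for dim in (8, 16):
            v = rng.normal(size=(10_000, dim))
            v *= (10.0 ** rng.uniform(-6, 3, (10_000, 1))) / \
                np.linalg.norm(v, axis=1, keepdims=True)
            out = squash(v)
            norms = np.linalg.norm(out, axis=1)
            assert np.all(norms < 1.0) and np.all(norms > 0.0)
            cos = (v * out).sum(1) / (np.linalg.norm(v, axis=1) * norms)
            assert np.all(np.abs(cos - 1.0) < 1e-6)


class TestDynamicRouting:
    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError):
            dynamic_routing(np.zeros((2, 2, 2)), 0)

    def test_single_iteration_uniform_couplings(self):
        u = np.random.default_rng(1).normal(size=(5, 3, 4))
        _, c = dynamic_routing(u, 1)
        np.testing.assert_allclose(c, 1 / 3)

    def test_symmetric_votes_stay_uniform(self):
        # identical predictions for every class: agreement is symmetric
        u_single = np.random.default_rng(2).normal(size=(4, 1, 6))
        u = np.repeat(u_single, 2, axis=1)
        _, c = dynamic_routing(u, 5)
        np.testing.assert_allclose(c, 0.5, atol=1e-12)

    def test_couplings_normalized_every_iteration(self):
        u = np.random.default_rng(3).normal(size=(6, 2, 3))
        _, _, hist = dynamic_routing(u, 4, return_history=True)
        assert len(hist) == 4
        for c in hist:
            np.testing.assert_allclose(c.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_step_by_step_hand_computation(self):
        """2 input capsules, 2 classes, 2-D votes, 3 iterations."""
        u = np.array([[[1.0, 0.0], [0.0, 1.0]],
                      [[0.8, 0.2], [-0.3, 0.5]]])
        v, c = dynamic_routing(u, 3)
        # independent re-derivation with explicit formulas
        b = np.zeros((2, 2))
        for _ in range(3):
            e = np.exp(b)
            cc = e / e.sum(axis=1, keepdims=True)
            s = (cc[:, :, None] * u).sum(axis=0)
            n2 = (s ** 2).sum(axis=1, keepdims=True)
            vv = (n2 / (1 + n2)) * s / np.sqrt(n2 + 1e-9)
            b = b + (u * vv[None]).sum(axis=-1)
        np.testing.assert_allclose(v, vv, atol=1e-10)
        np.testing.assert_allclose(c, cc, atol=1e-10)


class TestMarginLoss:
    def norms_tensor(self, true_norm, other_norm):
        return Tensor(np.array([[true_norm, other_norm]], dtype=np.float32))

    def test_confident_correct_is_zero(self):
        loss = margin_loss(self.norms_tensor(0.9, 0.1),
                           np.array([[1.0, 0.0]]))
        assert float(loss.data) == pytest.approx(0.0, abs=1e-7)

    def test_all_zero_norms(self):
        loss = margin_loss(self.norms_tensor(0.0, 0.0),
                           np.array([[1.0, 0.0]]))
        assert float(loss.data) == pytest.approx(0.81, abs=1e-6)

    def test_half_half(self):
        loss = margin_loss(self.norms_tensor(0.5, 0.5),
                           np.array([[1.0, 0.0]]))
        assert float(loss.data) == pytest.approx(0.16 + 0.5 * 0.16, abs=1e-6)


class TestModel:
    def test_forward_probabilities_bounded(self):
        model = build_capsnet(desk_spec(), seed=0)
        x = np.random.default_rng(0).random((2, 3, 24, 24)).astype(np.float32)
        v = model(Tensor(x))
        norms = class_norms(v).data
        assert v.shape == (2, 2, 16)
        assert np.all(norms >= 0.0) and np.all(norms < 1.0)

    def test_seeded_determinism(self):
        x = np.random.default_rng(1).random((1, 3, 24, 24)).astype(np.float32)
        outs = [class_norms(build_capsnet(desk_spec(), seed=4)(Tensor(x))).data
                for _ in range(2)]
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_wrong_input_shape_names_expectation(self):
        model = build_capsnet(desk_spec(), seed=0)
        with pytest.raises(ValueError, match="expected input"):
            model(Tensor(np.zeros((1, 3, 32, 32), np.float32)))

    def test_primary_capsule_count_matches_spec_product(self):
        spec = desk_spec()
        model = build_capsnet(spec, seed=0)
        assert model.W.shape[0] == spec.num_primary_caps
        assert spec.num_primary_caps == spec.primary_side ** 2 * spec.primary_caps_types


class TestTraining:
    def tiny_data(self, n=16, side=24):
        """Linearly separable blobs: bright-center vs dark-center images."""
        rng = np.random.default_rng(0)
        x = rng.random((n, side, side, 3)).astype(np.float32) * 0.2
        labels = np.array(["a", "b"] * (n // 2))
        for i in range(n):
            if labels[i] == "a":
                x[i, 8:16, 8:16] += 0.7
        return np.clip(x, 0, 1), labels

    def test_zero_epochs_leaves_model_unchanged(self):
        x, labels = self.tiny_data()
        model = build_capsnet(desk_spec(), seed=0)
        before = model.checksum()
        trace = train_capsnet(model, x, labels, epochs=0)
        assert trace == []
        assert model.checksum() == before

    def test_single_class_rejected(self):
        x, labels = self.tiny_data()
        model = build_capsnet(desk_spec(), seed=0)
        with pytest.raises(ValueError, match="both classes"):
            train_capsnet(model, x, np.array(["a"] * len(x)), epochs=1)

    def test_identical_seeds_identical_traces(self):
        x, labels = self.tiny_data()
        traces = []
        for _ in range(2):
            model = build_capsnet(desk_spec(), seed=2)
            traces.append(train_capsnet(model, x, labels, epochs=2,
                                        learning_rate=1e-3, seed=2))
        assert traces[0] == traces[1]

    def test_margin_loss_collapses_on_separable_inputs(self):
        x, labels = self.tiny_data(n=20)
        model = build_capsnet(desk_spec(), seed=0)
        trace = train_capsnet(model, x, labels, epochs=15,
                              learning_rate=1e-3, seed=0, patience=15,
                              augment=False)
        assert trace[-1]["train_loss"] < 0.1 * trace[0]["train_loss"]


class TestClassifier:
    def test_sklearn_interface(self):
        clf = CapsNetClassifier(conv_filters=16, primary_caps_types=2,
                                input_side=24, epochs=1)
        assert clf.get_params()["conv_filters"] == 16

    def test_two_classes_required(self):
        clf = CapsNetClassifier(conv_filters=16, primary_caps_types=2,
                                input_side=24, epochs=1)
        x = np.zeros((4, 24, 24, 3), np.float32)
        with pytest.raises(ValueError, match="two classes"):
            clf.fit(x, np.array(["a"] * 4))

    def test_predict_proba_sums_to_one(self):
        rng = np.random.default_rng(5)
        x = rng.random((8, 24, 24, 3)).astype(np.float32)
        y = np.array(["a", "b"] * 4)
        clf = CapsNetClassifier(conv_filters=16, primary_caps_types=2,
                                input_side=24, epochs=1,
                                learning_rate=1e-3).fit(x, y)
        proba = clf.predict_proba(x)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        outs = clf.output(x[:2])
        assert outs[0].class_vectors.shape == (2, 16)
        assert outs[0].predicted_label in ("a", "b")
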