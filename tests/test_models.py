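"""Unit tests for the MIL forward math: attention scoring, pooling heads,
bounded contributions, and checkpointing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from slidemil.bags import Bag
from slidemil.models import (
    AttentionParams,
    ConfigurationError,
    admil_forward,
    amil_forward,
    attention_logits,
    attention_normalize,
    bound_contributions,
    build_model,
    forward,
    load_checkpoint,
    save_checkpoint,
    softmax,
)

from .conftest import make_model
from .oracles import mean_pool_forward


class TestAttentionLogits:
    def test_zero_weight_vector_gives_zero_logits(self):
        params = AttentionParams(V=np.ones((3, 4)), w=np.zeros(3))
        H = np.random.default_rng(0).normal(size=(5, 4))
        assert np.all(attention_logits(H, params) == 0.0)

    @pytest.mark.parametrize(
        "activation,h,expected",
        [
            ("tanh", [0.5, 9.0], math.tanh(0.5)),  # w^T tanh(V h) by hand
            ("leaky_relu", [-1.0, 0.0], -0.01),  # slope 0.01 on the negative side
        ],
    )
    def test_single_unit_scorer_closed_form(self, activation, h, expected):
        params = AttentionParams(V=[[1.0, 0.0]], w=[1.0], activation=activation)
        logit = attention_logits(np.array([h]), params)
        assert logit == pytest.approx(expected, abs=1e-6)

    def test_dimension_mismatch_names_shapes(self):
        params = AttentionParams(V=np.ones((3, 4)), w=np.ones(3))
        with pytest.raises(ValueError, match=r"\(3, 4\)"):
            attention_logits(np.ones((2, 5)), params)


class TestAttentionNormalize:
    @pytest.mark.parametrize(
        "logits,expected",
        [
            ([0, 0, 0, 0], [0.25] * 4),
            ([7.3], [1.0]),
            ([math.log(2), 0.0], [2 / 3, 1 / 3]),
        ],
    )
    def test_softmax_closed_forms(self, logits, expected):
        np.testing.assert_allclose(
            attention_normalize(np.array(logits, dtype=float)),
            expected,
            atol=1e-7,
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            attention_normalize(np.array([]))

    @settings(derandomize=True, max_examples=50)
    @given(
        logits=arrays(
            np.float64, st.integers(1, 40),
            elements=st.floats(-30, 30),
        ),
        shift=st.floats(-10, 10),
    )
    def test_softmax_is_shift_invariant_and_on_simplex(self, logits, shift):
        a = attention_normalize(logits)
        assert np.all(a >= 0) and abs(a.sum() - 1.0) < 1e-9
        np.testing.assert_allclose(
            a, attention_normalize(logits + shift), atol=1e-9
        )

    def test_simplex_invariant_on_random_logits(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = attention_normalize(rng.normal(scale=5, size=rng.integers(1, 40)))
            assert np.all(a >= 0)
            assert abs(a.sum() - 1.0) < 1e-9


class TestAmilForward:
    def test_singleton_bag_pools_to_the_instance(self):
        model = make_model("amil", d=6)
        h = np.random.default_rng(3).normal(size=(1, 6)).astype(np.float32)
        pred = amil_forward(Bag(instances=h, label=1), model)
        expected_logits = model.W @ h[0] + model.b
        np.testing.assert_allclose(pred.bag_logits, expected_logits, atol=1e-6)
        assert pred.attention[0] == pytest.approx(1.0)
        assert pred.patch_logits is None

    def test_duplicating_instances_preserves_probabilities(self):
        model = make_model("amil", d=5)
        rng = np.random.default_rng(4)
        H = rng.normal(size=(7, 5)).astype(np.float32)
        p1 = amil_forward(Bag(instances=H, label=0), model).class_probabilities
        p2 = amil_forward(
            Bag(instances=np.vstack([H, H]), label=0), model
        ).class_probabilities
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_variant_mismatch_is_configuration_error(self):
        model = make_model("admil")
        with pytest.raises(ConfigurationError):
            amil_forward(Bag(instances=np.ones((2, 8)), label=0), model)


class TestAdmilForward:
    def test_sum_then_softmax_closed_form(self):
        # patch logits (+2, -1, +0.5) vs all-zero: p_pos = e^1.5/(1+e^1.5)
        patch = np.array([[0.0, 2.0], [0.0, -1.0], [0.0, 0.5]])
        probs = softmax(patch.sum(axis=0))
        assert probs[1] == pytest.approx(math.exp(1.5) / (1 + math.exp(1.5)), abs=1e-4)

    def test_zero_patch_logits_give_uniform_probabilities(self):
        model = make_model("admil", d=4)
        model.W[:] = 0.0
        model.b[:] = 0.0
        pred = admil_forward(Bag(instances=np.ones((3, 4)), label=1), model)
        np.testing.assert_allclose(pred.class_probabilities, [0.5, 0.5], atol=1e-7)

    def test_bag_logits_equal_patch_logit_column_sum(self, random_bags):
        for bag in random_bags[:20]:
            model = make_model("admil_tanh", d=bag.d)
            pred = admil_forward(bag, model)
            np.testing.assert_allclose(
                pred.bag_logits, pred.patch_logits.sum(axis=0), atol=1e-6
            )

    def test_variant_mismatch_is_configuration_error(self):
        model = make_model("amil")
        with pytest.raises(ConfigurationError):
            admil_forward(Bag(instances=np.ones((2, 8)), label=0), model)


class TestBoundContributions:
    @pytest.mark.parametrize(
        "logit,value,polarity",
        [
            (0.0, 0.5, "inhibitory"),  # 0.5 ties break inhibitory
            (-2.0, 1 / (1 + math.e**2), "inhibitory"),
            (2.0, 1 / (1 + math.e**-2), "excitatory"),
        ],
    )
    def test_logistic_bounds_and_polarity(self, logit, value, polarity):
        res = bound_contributions(np.array([[0.0, logit]]))
        assert res.values[0, 1] == pytest.approx(value, abs=1e-4)
        assert res.polarity[0].value == polarity

    def test_nonfinite_logits_rejected(self):
        with pytest.raises(ValueError):
            bound_contributions(np.array([[np.inf, 0.0]]))


class TestPermutationInvariance:
    def test_forward_invariant_under_instance_permutation(self, random_bags, variant):
        rng = np.random.default_rng(9)
        for bag in random_bags[:30]:
            model = make_model(variant, d=bag.d)
            perm = rng.permutation(bag.n)
            pred = forward(bag, model)
            pred_p = forward(Bag(instances=bag.instances[perm], label=bag.label), model)
            np.testing.assert_allclose(
                pred.class_probabilities, pred_p.class_probabilities, atol=1e-6
            )
            np.testing.assert_allclose(
                pred.attention[perm], pred_p.attention, atol=1e-6
            )


class TestZeroAttentionDegeneracy:
    def test_zero_w_reduces_amil_to_mean_pooling(self, variant):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n, d = int(rng.integers(1, 20)), 6
            model = make_model(variant, d=d)
            model.attention.w[:] = 0.0
            H = rng.normal(size=(n, d)).astype(np.float32)
            pred = forward(Bag(instances=H, label=0), model)
            np.testing.assert_array_equal(pred.attention, np.full(n, 1.0 / n))
            if variant == "amil":
                expected = mean_pool_forward(H, model.W, model.b)
                np.testing.assert_allclose(
                    pred.class_probabilities, expected, atol=1e-6
                )


class TestBuildModel:
    def test_same_seed_yields_identical_parameters(self, variant):
        m1 = build_model(variant, d=12, seed=5)
        m2 = build_model(variant, d=12, seed=5)
        for k, v in m1.parameters().items():
            np.testing.assert_array_equal(v, m2.parameters()[k])

    def test_variants_differ_in_head_structure(self):
        amil = build_model("amil", d=8, seed=0)
        admil = build_model("admil", d=8, seed=0)
        assert not amil.is_additive and admil.is_additive
        assert amil.attention.activation == "tanh"
        assert admil.attention.activation == "leaky_relu"

    def test_default_embedding_length_accepted(self):
        model = build_model("amil", d=1024, seed=0)
        assert model.attention.V.shape == (128, 1024)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError):
            build_model("gated", d=8, seed=0)


class TestCheckpoint:
    def test_round_trip_preserves_parameters_and_metadata(self, tmp_path, variant):
        model = build_model(variant, d=10, seed=3, D=7, C=2)
        save_checkpoint(model, tmp_path / "ckpt")
        loaded = load_checkpoint(tmp_path / "ckpt")
        assert loaded.variant == variant
        assert (loaded.d, loaded.D, loaded.C, loaded.seed) == (10, 7, 2, 3)
        for k, v in model.parameters().items():
            np.testing.assert_array_equal(v, loaded.parameters()[k])
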