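"""Fusion arithmetic, weight simplex, classifier head and loss checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mvfusion.nn as nn
from mvfusion import (
    ClassifierHead,
    EncoderConfig,
    FusionStrategy,
    Prediction,
    ViewEmbedding,
    ViewScoreNet,
    ViewWeights,
    classify,
    compute_view_weights,
    cross_entropy,
    fuse_concat,
    fuse_label_average,
    fuse_label_weighted,
    fuse_weighted,
)
from mvfusion.fusion import MultiViewClassifier, _softmax_rows


def _emb(vec, vid="v"):
    return ViewEmbedding(vector=np.asarray(vec, dtype=np.float32), view_id=vid)


def _fixed_logit_scorer(logits):
    """A hand-set scorer mapping one-hot embedding e_i to ``logits[i]``.

    Lets softmax targets be chosen exactly: lin1 copies the one-hot input
    to the hidden layer, lin2 reads off the requested logit.
    """
    n = len(logits)
    dim = max(n, 2)
    net = ViewScoreNet(dim, hidden=n, rng=np.random.default_rng(0))
    lin1, _, lin2 = net.net.layers
    lin1.weight.value[...] = 0
    lin1.bias.value[...] = 0
    lin2.weight.value[...] = 0
    lin2.bias.value[...] = 0
    for j, logit in enumerate(logits):
        lin1.weight.value[j, j] = 1.0
        lin2.weight.value[0, j] = float(logit)
    embs = [_emb(np.eye(dim)[i], f"v{i}") for i in range(n)]
    return net, embs


class TestViewWeights:
    def test_identical_embeddings_give_uniform_weights(self, rng):
        net = ViewScoreNet(8, rng=rng)
        e = _emb(rng.normal(size=8))
        w = compute_view_weights([e, e, e], net)
        assert w.weights == pytest.approx([1 / 3] * 3, abs=1e-9)

    def test_single_view_weight_is_one(self, rng):
        net = ViewScoreNet(8, rng=rng)
        w = compute_view_weights([_emb(rng.normal(size=8))], net)
        assert w.weights == pytest.approx([1.0], abs=1e-12)

    def test_softmax_of_zero_and_ln2(self):
        net, embs = _fixed_logit_scorer([0.0, math.log(2.0)])
        w = compute_view_weights(embs, net)
        assert w.weights == pytest.approx([1 / 3, 2 / 3], abs=1e-6)

    def test_embedding_length_mismatch_errors(self, rng):
        net = ViewScoreNet(8, rng=rng)
        with pytest.raises(ValueError, match="mismatch"):
            compute_view_weights([_emb(np.zeros(8)), _emb(np.zeros(9))], net)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n=st.integers(1, 6),
    )
    def test_weights_on_probability_simplex(self, seed, n):
        """Any scorer parameterisation yields nonnegative weights summing to 1."""
        r = np.random.default_rng(seed)
        net = ViewScoreNet(8, hidden=8, rng=r)
        embs = [_emb(r.normal(size=8) * 10, f"v{i}") for i in range(n)]
        w = compute_view_weights(embs, net)
        assert np.all(w.weights >= 0)
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-6)

    def test_simplex_enforced_on_construction(self):
        with pytest.raises(ValueError):
            ViewWeights(np.array([0.5, 0.6]))
        with pytest.raises(ValueError):
            ViewWeights(np.array([-0.1, 1.1]))


class TestFeatureFusion:
    def test_zero_weight_zeroes_block(self):
        embs = [_emb([1, 2]), _emb([3, 4])]
        fused = fuse_weighted(embs, ViewWeights([1.0, 0.0]))
        assert fused.vector == pytest.approx([1, 2, 0, 0])

    def test_uniform_weights_scale_basis(self):
        embs = [_emb([1, 0]), _emb([0, 1])]
        fused = fuse_weighted(embs, ViewWeights([0.5, 0.5]))
        assert fused.vector == pytest.approx([0.5, 0, 0, 0.5])

    def test_fused_length_n_times_512(self, rng):
        embs = [_emb(rng.normal(size=512), f"v{i}") for i in range(3)]
        w = ViewWeights(np.full(3, 1 / 3))
        assert fuse_weighted(embs, w).vector.size == 3 * 512
        assert fuse_concat(embs).vector.size == 1536

    def test_concat_equals_weighted_scaled_by_n(self, rng):
        embs = [_emb(rng.normal(size=8), f"v{i}") for i in range(4)]
        w = ViewWeights(np.full(4, 0.25))
        assert fuse_concat(embs).vector == pytest.approx(
            4 * fuse_weighted(embs, w).vector, rel=1e-6
        )

    def test_single_view_concat_is_identity(self, rng):
        e = _emb(rng.normal(size=16))
        assert np.array_equal(fuse_concat([e]).vector, e.vector)

    def test_permuting_views_permutes_blocks(self, rng):
        embs = [_emb(rng.normal(size=4), f"v{i}") for i in range(3)]
        w = ViewWeights([0.2, 0.3, 0.5])
        perm = [2, 0, 1]
        fused = fuse_weighted(embs, w).vector.reshape(3, 4)
        fused_p = fuse_weighted(
            [embs[i] for i in perm], ViewWeights(w.weights[perm])
        ).vector.reshape(3, 4)
        assert np.allclose(fused_p, fused[perm])

    def test_count_mismatch_errors(self, rng):
        embs = [_emb(rng.normal(size=4)) for _ in range(2)]
        with pytest.raises(ValueError, match="weights"):
            fuse_weighted(embs, ViewWeights([1.0]))


class TestClassifierHead:
    def test_zero_head_gives_half(self, rng):
        head = ClassifierHead(8, hidden=4, rng=rng)
        for layer in head.net.layers:
            for p in layer.params():
                p.value[...] = 0
        from mvfusion.fusion import FusedFeature

        pred = classify(FusedFeature(np.ones(8)), head)
        assert pred.probability == pytest.approx(0.5, abs=1e-12)

    def test_toy_head_matches_hand_arithmetic(self, rng):
        head = ClassifierHead(1, hidden=1, rng=rng)
        lin1, _, lin2 = head.net.layers
        lin1.weight.value[...] = 2.0
        lin1.bias.value[...] = -1.0
        lin2.weight.value[...] = 3.0
        lin2.bias.value[...] = 0.5
        from mvfusion.fusion import FusedFeature

        # x=2: relu(2*2-1)=3 -> 3*3+0.5=9.5 -> sigmoid
        pred = classify(FusedFeature(np.array([2.0])), head)
        assert pred.probability == pytest.approx(1 / (1 + math.exp(-9.5)), rel=1e-6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_probability_bounded(self, seed):
        r = np.random.default_rng(seed)
        head = ClassifierHead(6, hidden=4, rng=r)
        from mvfusion.fusion import FusedFeature

        pred = classify(FusedFeature(r.normal(size=6) * 100), head)
        assert 0.0 <= pred.probability <= 1.0

    def test_dimension_mismatch_errors(self, rng):
        head = ClassifierHead(8, hidden=4, rng=rng)
        from mvfusion.fusion import FusedFeature

        with pytest.raises(ValueError, match="head expects"):
            classify(FusedFeature(np.zeros(9)), head)


class TestLabelFusion:
    def test_average(self):
        pred = fuse_label_average([Prediction(0.2), Prediction(0.4), Prediction(0.6)])
        assert pred.probability == pytest.approx(0.4)

    def test_average_of_equal_is_identity(self):
        assert fuse_label_average([Prediction(0.7)] * 5).probability == pytest.approx(0.7)

    def test_single_view(self):
        assert fuse_label_average([Prediction(0.9)]).probability == pytest.approx(0.9)

    def test_weighted_selects(self):
        p = fuse_label_weighted(
            [Prediction(0.9), Prediction(0.1)], ViewWeights([1.0, 0.0])
        )
        assert p.probability == pytest.approx(0.9)

    def test_weighted_third_two_thirds(self):
        p = fuse_label_weighted(
            [Prediction(0.3), Prediction(0.6)], ViewWeights([1 / 3, 2 / 3])
        )
        assert p.probability == pytest.approx(0.5)

    def test_uniform_weighted_equals_average(self, rng):
        preds = [Prediction(p) for p in rng.uniform(0, 1, 5)]
        w = ViewWeights(np.full(5, 0.2))
        assert fuse_label_weighted(preds, w).probability == pytest.approx(
            fuse_label_average(preds).probability
        )

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fuse_label_average([])


class TestCrossEntropy:
    def test_ln2_at_half(self):
        assert cross_entropy(1, 0.5) == pytest.approx(math.log(2), abs=1e-9)

    def test_symmetry_at_half(self):
        assert cross_entropy(0, 0.5) == cross_entropy(1, 0.5)

    def test_perfect_prediction_limit(self):
        assert cross_entropy(1, 1.0 - 1e-9) < 1e-6
        assert cross_entropy(0, 1e-9) < 1e-6

    def test_positive_away_from_truth(self):
        for y, p in [(1, 0.3), (0, 0.8), (1, 0.99), (0, 0.01)]:
            assert cross_entropy(y, p) > 0

    def test_invalid_label_errors(self):
        with pytest.raises(ValueError, match="label"):
            cross_entropy(2, 0.5)

    def test_clamp_keeps_loss_finite(self):
        assert np.isfinite(cross_entropy(1, 0.0))
        assert np.isfinite(cross_entropy(0, 1.0))


class TestMultiViewClassifier:
    def test_reduction_identity_single_view(self, rng, tiny_encoder_config):
        """With one view, all four strategies give the same prediction."""
        x = rng.normal(size=(6, 1, 8, 16, 16)).astype(np.float32)
        probs = {
            strat: MultiViewClassifier(
                tiny_encoder_config, 1, strat, head_hidden=8, score_hidden=8,
                rng=np.random.default_rng(3),
            ).predict_proba(x)
            for strat in FusionStrategy
        }
        base = probs[FusionStrategy.WEIGHTED_FEATURE]
        for strat in FusionStrategy:
            assert np.allclose(probs[strat], base, atol=1e-7), strat

    def test_gradients_match_finite_differences(self, rng, tiny_encoder_config):
        """End-to-end backward agrees with a directional finite difference."""
        old = nn.DTYPE
        nn.DTYPE = np.float64
        try:
            from mvfusion.fusion import LOSS_EPS

            for strat in FusionStrategy:
                m = MultiViewClassifier(
                    tiny_encoder_config, 2, strat, head_hidden=8, score_hidden=8,
                    rng=np.random.default_rng(1),
                )
                x = rng.normal(size=(4, 2, 8, 8, 8))
                y = np.array([0.0, 1.0, 1.0, 0.0])

                def loss():
                    p = m.forward(x, True)
                    m._cache = None
                    pc = np.clip(p, LOSS_EPS, 1 - LOSS_EPS)
                    return float(-(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean())

                m.zero_grad()
                m.forward(x, True)
                m.backward_from_labels(y)
                params = m.params()
                drng = np.random.default_rng(3)
                dirs = [drng.normal(size=p.value.shape) for p in params]
                norm = math.sqrt(sum(float((d * d).sum()) for d in dirs))
                dirs = [d / norm for d in dirs]
                analytic = sum(float((p.grad * d).sum()) for p, d in zip(params, dirs))
                eps = 1e-3
                for p, d in zip(params, dirs):
                    p.value += eps * d
                lp = loss()
                for p, d in zip(params, dirs):
                    p.value -= 2 * eps * d
                lm = loss()
                for p, d in zip(params, dirs):
                    p.value += eps * d
                numeric = (lp - lm) / (2 * eps)
                assert analytic == pytest.approx(numeric, rel=5e-2, abs=1e-7), strat
        finally:
            nn.DTYPE = old

    def test_wrong_view_count_errors(self, rng, tiny_encoder_config):
        m = MultiViewClassifier(
            tiny_encoder_config, 3, rng=np.random.default_rng(0), head_hidden=8
        )
        with pytest.raises(ValueError, match="expected"):
            m.forward(rng.normal(size=(2, 2, 8, 8, 8)).astype(np.float32), False)

    def test_view_weights_rows_sum_to_one(self, rng, tiny_encoder_config):
        m = MultiViewClassifier(
            tiny_encoder_config, 3, rng=np.random.default_rng(0), head_hidden=8
        )
        x = rng.normal(size=(5, 3, 8, 8, 8)).astype(np.float32)
        w = m.view_weights(x)
        assert w.shape == (5, 3)
        assert np.all(w >= 0)
        assert w.sum(axis=1) == pytest.approx(np.ones(5), abs=1e-9)


def test_softmax_rows_is_stable():
    s = np.array([[1000.0, 1000.0], [-1000.0, -999.0]])
    out = _softmax_rows(s)
    assert np.all(np.isfinite(out))
    assert out.sum(axis=1) == pytest.approx([1, 1])
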