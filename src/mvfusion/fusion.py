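"""View-weight computation, feature/label fusion strategies, and the classifier head.

The weighted feature fusion works as follows: every per-view embedding
``h_i`` is scored by one shared two-layer perceptron to a scalar logit,
the logits are softmax-normalised across the views of a case into weights
``w_i`` (nonnegative, summing to 1), and the weighted embeddings
``w_i * h_i`` are concatenated in canonical view order into a single
``n x embedding_dim`` feature.  A two-layer classifier head (hidden width
512 in the full-size configuration) maps the fused feature to a tear
probability.

Three comparison strategies are provided for ablation: plain concatenation
(all weights 1), label averaging (mean of per-view probabilities), and
weighted label fusion (softmax-weighted mean of per-view probabilities).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .encoder3d import Encoder3D, EncoderConfig, ViewEmbedding

__all__ = [
    "FusionStrategy",
    "ViewWeights",
    "FusedFeature",
    "Prediction",
    "ViewScoreNet",
    "ClassifierHead",
    "MultiViewClassifier",
    "compute_view_weights",
    "fuse_weighted",
    "fuse_concat",
    "classify",
    "fuse_label_average",
    "fuse_label_weighted",
    "cross_entropy",
]

#: clamp applied to probabilities inside the cross-entropy loss
LOSS_EPS = 1e-7


class FusionStrategy(str, enum.Enum):
    """How per-view information is combined into one decision."""

    WEIGHTED_FEATURE = "weighted_feature"
    CONCAT_FEATURE = "concat_feature"
    LABEL_AVERAGE = "label_average"
    LABEL_WEIGHTED = "label_weighted"

    @property
    def is_feature_fusion(self) -> bool:
        return self in (FusionStrategy.WEIGHTED_FEATURE, FusionStrategy.CONCAT_FEATURE)

    @property
    def uses_weights(self) -> bool:
        return self in (FusionStrategy.WEIGHTED_FEATURE, FusionStrategy.LABEL_WEIGHTED)


@dataclass
class ViewWeights:
    """Softmax-normalised per-view weights: nonnegative, summing to 1."""

    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        if self.weights.size < 1:
            raise ValueError("at least one view weight required")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("weights must be nonnegative and sum to 1")

    def __len__(self) -> int:
        return self.weights.size


@dataclass
class FusedFeature:
    """Concatenation of (weighted) per-view embeddings, length n x embedding_dim."""

    vector: np.ndarray

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float32).ravel()


@dataclass
class Prediction:
    """A tear probability in [0, 1]."""

    probability: float

    def __post_init__(self):
        p = float(self.probability)
        if not (0.0 <= p <= 1.0) or math.isnan(p):
            raise ValueError(f"probability outside [0,1]: {p}")
        self.probability = p


def _softmax_rows(s: np.ndarray) -> np.ndarray:
    s = s - s.max(axis=1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class ViewScoreNet(nn.Module):
    """Shared two-layer scorer mapping one embedding to one scalar logit.

    The same parameters score every view; softmax across a case's views
    turns the scalar logits into fusion weights.
    """

    def __init__(self, embedding_dim: int, hidden: int = 64, *, rng: np.random.Generator):
        self.hidden = hidden
        out = nn.Linear(hidden, 1, rng=rng)
        # near-zero output init: fusion weights start uniform (softmax of ~0
        # logits) and specialise gradually instead of collapsing early
        out.weight.value *= 0.01
        self.net = nn.Sequential(
            nn.Linear(embedding_dim, hidden, rng=rng),
            nn.ReLU(),
            out,
        )

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.net.forward(x, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)


class ClassifierHead(nn.Module):
    """Two-layer MLP: fused feature -> hidden (ReLU) -> one logit."""

    def __init__(self, in_features: int, hidden: int = 512, *, rng: np.random.Generator):
        self.in_features = in_features
        self.hidden = hidden
        self.net = nn.Sequential(
            nn.Linear(in_features, hidden, rng=rng),
            nn.ReLU(),
            nn.Linear(hidden, 1, rng=rng),
        )

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.net.forward(x, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)


# ---------------------------------------------------------------------------
# functional surface over single cases


def compute_view_weights(
    embeddings: Sequence[ViewEmbedding], score_net: ViewScoreNet
) -> ViewWeights:
    """Score each embedding with the shared MLP and softmax across views."""
    if len(embeddings) < 1:
        raise ValueError("need at least one embedding")
    dims = {e.vector.size for e in embeddings}
    if len(dims) != 1:
        raise ValueError(f"embedding length mismatch: {sorted(dims)}")
    h = np.stack([e.vector for e in embeddings])
    logits = score_net.forward(h.astype(nn.DTYPE), train=False)[:, 0]
    return ViewWeights(_softmax_rows(logits[None, :].astype(np.float64))[0])


def fuse_weighted(
    embeddings: Sequence[ViewEmbedding], w: ViewWeights
) -> FusedFeature:
    """Scale each embedding by its weight and concatenate in view order."""
    if len(embeddings) != len(w):
        raise ValueError(
            f"{len(embeddings)} embeddings but {len(w)} weights"
        )
    parts = [wi * e.vector for wi, e in zip(w.weights, embeddings)]
    return FusedFeature(np.concatenate(parts))


def fuse_concat(embeddings: Sequence[ViewEmbedding]) -> FusedFeature:
    """Unweighted concatenation of embeddings in view order."""
    if len(embeddings) < 1:
        raise ValueError("need at least one embedding")
    return FusedFeature(np.concatenate([e.vector for e in embeddings]))


def classify(fused: FusedFeature, head: ClassifierHead) -> Prediction:
    """Map a fused feature to a tear probability via the two-layer head."""
    if fused.vector.size != head.in_features:
        raise ValueError(
            f"fused feature has length {fused.vector.size}, head expects {head.in_features}"
        )
    logit = head.forward(fused.vector[None], train=False)[0, 0]
    return Prediction(float(_sigmoid(np.asarray([logit]))[0]))


def fuse_label_average(predictions: Sequence[Prediction]) -> Prediction:
    """Class-average label fusion: arithmetic mean of per-view probabilities."""
    if len(predictions) < 1:
        raise ValueError("need at least one prediction")
    return Prediction(float(np.mean([p.probability for p in predictions])))


def fuse_label_weighted(
    predictions: Sequence[Prediction], w: ViewWeights
) -> Prediction:
    """Class-probability-weighted label fusion: sum of w_i * p_i."""
    if len(predictions) != len(w):
        raise ValueError(f"{len(predictions)} predictions but {len(w)} weights")
    probs = np.array([p.probability for p in predictions])
    return Prediction(float(np.dot(w.weights, probs)))


def cross_entropy(y: int, y_hat: float) -> float:
    """Binary cross-entropy −[y·ln(ŷ) + (1−y)·ln(1−ŷ)] with natural log.

    ``y_hat`` is clamped to [LOSS_EPS, 1−LOSS_EPS] before taking logs.
    """
    if y not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {y!r}")
    p = min(max(float(y_hat), LOSS_EPS), 1.0 - LOSS_EPS)
    return -(y * math.log(p) + (1 - y) * math.log(1.0 - p))


# ---------------------------------------------------------------------------
# batched end-to-end model


class MultiViewClassifier(nn.Module):
    """Shared 3-D encoder + view fusion + classifier head, trained end to end.

    Parameters
    ----------
    encoder_config
        Architecture of the shared per-view encoder.
    n_views
        Number of views per case (fixed for one model).
    strategy
        One of the four :class:`FusionStrategy` members.
    head_hidden
        Hidden width of the classifier head (512 in the full-size model).
    score_hidden
        Hidden width of the shared view-scoring MLP.
    """

    def __init__(
        self,
        encoder_config: EncoderConfig,
        n_views: int,
        strategy: FusionStrategy = FusionStrategy.WEIGHTED_FEATURE,
        *,
        head_hidden: int = 512,
        score_hidden: int = 64,
        rng: np.random.Generator,
    ):
        if n_views < 1:
            raise ValueError("n_views must be >= 1")
        self.n_views = n_views
        self.strategy = FusionStrategy(strategy)
        self.encoder = Encoder3D(encoder_config, rng=rng)
        e = encoder_config.embedding_dim
        # head before score net: strategies sharing a seed then share the
        # encoder and (shape permitting) head initialisation exactly
        head_in = n_views * e if self.strategy.is_feature_fusion else e
        self.head = ClassifierHead(head_in, head_hidden, rng=rng)
        self.score_net = (
            ViewScoreNet(e, score_hidden, rng=rng) if self.strategy.uses_weights else None
        )
        self._cache = None

    @property
    def embedding_dim(self) -> int:
        return self.encoder.config.embedding_dim

    # -- forward ----------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        """Map ``(B, n_views, D, H, W)`` volumes to ``(B,)`` probabilities."""
        if x.ndim != 5 or x.shape[1] != self.n_views:
            raise ValueError(
                f"expected (B,{self.n_views},D,H,W), got {x.shape}"
            )
        b, n = x.shape[:2]
        e = self.embedding_dim
        flat = np.ascontiguousarray(x, dtype=nn.DTYPE).reshape(
            (b * n, 1) + x.shape[2:]
        )
        h_flat = self.encoder.forward(flat, train)  # (B*n, E)
        hv = h_flat.reshape(b, n, e)

        w = None
        if self.score_net is not None:
            s = self.score_net.forward(h_flat, train).reshape(b, n)
            w = _softmax_rows(s.astype(np.float64)).astype(nn.DTYPE)

        if self.strategy.is_feature_fusion:
            if self.strategy is FusionStrategy.WEIGHTED_FEATURE:
                fused = (w[..., None] * hv).reshape(b, n * e)
            else:
                fused = hv.reshape(b, n * e)
            logit = self.head.forward(fused, train)[:, 0]
            p = _sigmoid(logit.astype(np.float64))
            self._cache = ("feature", hv, w, p)
        else:
            logits_v = self.head.forward(h_flat, train).reshape(b, n)
            pv = _sigmoid(logits_v.astype(np.float64))
            if self.strategy is FusionStrategy.LABEL_AVERAGE:
                p = pv.mean(axis=1)
            else:
                p = (w * pv).sum(axis=1)
            self._cache = ("label", hv, w, pv, p)
        return p

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode probabilities (deterministic, running BN stats)."""
        p = self.forward(x, train=False)
        self._cache = None
        return p

    def view_weights(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode softmax view weights, shape (B, n_views)."""
        if self.score_net is None:
            raise ValueError(f"strategy {self.strategy.value} does not use view weights")
        b, n = x.shape[:2]
        flat = np.ascontiguousarray(x, dtype=nn.DTYPE).reshape(
            (b * n, 1) + x.shape[2:]
        )
        h_flat = self.encoder.forward(flat, False)
        s = self.score_net.forward(h_flat, False).reshape(b, n)
        return _softmax_rows(s.astype(np.float64))

    # -- backward ---------------------------------------------------------

    def backward_from_labels(self, y: np.ndarray, sample_weight=None) -> float:
        """Backpropagate the mean cross-entropy of the cached forward pass.

        ``sample_weight`` optionally scales each case's loss term (e.g. to
        up-weight the positive class).  Returns the loss value.  Must
        follow a ``train=True`` forward.
        """
        assert self._cache is not None, "backward before forward"
        cache, self._cache = self._cache, None
        y = np.asarray(y, dtype=np.float64)
        b = y.size
        sw = (
            np.ones(b) if sample_weight is None else np.asarray(sample_weight, float)
        )
        if cache[0] == "feature":
            _, hv, w, p = cache
            pc = np.clip(p, LOSS_EPS, 1 - LOSS_EPS)
            loss = float(-(sw * (y * np.log(pc) + (1 - y) * np.log(1 - pc))).mean())
            dlogit = (sw * (p - y) / b).astype(nn.DTYPE)  # sigmoid+CE shortcut
            dfused = self.head.backward(dlogit[:, None])
            n, e = self.n_views, self.embedding_dim
            df = dfused.reshape(b, n, e)
            if self.strategy is FusionStrategy.WEIGHTED_FEATURE:
                dh = w[..., None] * df
                dw = (df * hv).sum(axis=2)
                ds = w * (dw - (dw * w).sum(axis=1, keepdims=True))
                dh += self.score_net.backward(
                    ds.reshape(b * n, 1).astype(nn.DTYPE)
                ).reshape(b, n, e)
            else:
                dh = df
            self.encoder.backward(dh.reshape(b * n, e).astype(nn.DTYPE))
        else:
            _, hv, w, pv, p = cache
            pc = np.clip(p, LOSS_EPS, 1 - LOSS_EPS)
            loss = float(-(sw * (y * np.log(pc) + (1 - y) * np.log(1 - pc))).mean())
            dp = sw * (pc - y) / (pc * (1 - pc)) / b
            n, e = self.n_views, self.embedding_dim
            if self.strategy is FusionStrategy.LABEL_AVERAGE:
                dpv = np.repeat(dp[:, None] / n, n, axis=1)
                dh = np.zeros_like(hv)
            else:
                dpv = dp[:, None] * w
                dw = dp[:, None] * pv
                ds = w * (dw - (dw * w).sum(axis=1, keepdims=True))
                dh = self.score_net.backward(
                    ds.reshape(b * n, 1).astype(nn.DTYPE)
                ).reshape(b, n, e)
            dlogit_v = (dpv * pv * (1 - pv)).astype(nn.DTYPE)
            dh += self.head.backward(dlogit_v.reshape(b * n, 1)).reshape(b, n, e)
            self.encoder.backward(dh.reshape(b * n, e).astype(nn.DTYPE))
        return loss
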