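"""Training loop, model selection on validation AUC, and ROC evaluation.

The training protocol follows the standard recipe for this architecture:
Adam with first-moment coefficient 0.9, L2 weight decay 1e-4, initial
learning rate 1e-4, mini-batches of 32 cases, 100 epochs, and selection of
the parameter snapshot with the best validation AUC (earlier epoch wins
ties).  :meth:`TrainConfig.phantom` is a scaled-down preset for the 100-case
synthetic benchmark.

Evaluation reports the area under the ROC curve plus the operating point
maximising Youden's J = sensitivity + specificity - 1 (a case is called
positive when its probability is >= the threshold; ties in J resolve to
the lower threshold).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from . import nn
from .encoder3d import EncoderConfig
from .fusion import FusionStrategy, MultiViewClassifier
from .volume_io import Case, DatasetSplit

logger = logging.getLogger("mvfusion")

__all__ = [
    "TrainConfig",
    "TrainResult",
    "EvalReport",
    "build_model",
    "train",
    "evaluate",
    "evaluate_auc",
    "optimal_operating_point",
    "run_view_ablation",
    "run_fusion_ablation",
    "subset_views",
    "cases_to_arrays",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyper-parameters.

    ``beta1`` is Adam's first-moment (momentum) coefficient.  ``pos_weight``
    optionally up-weights the positive-class loss for imbalanced data
    (1.0 = off).  ``clip_norm`` caps the global gradient norm per step
    (None disables clipping).
    """

    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 32
    beta1: float = 0.9
    weight_decay: float = 1e-4
    seed: int = 0
    pos_weight: float = 1.0
    clip_norm: float | None = 5.0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.weight_decay < 0 or self.pos_weight <= 0:
            raise ValueError("rates must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")

    @classmethod
    def phantom(cls, seed: int = 0, epochs: int = 20) -> "TrainConfig":
        """Desk-scale preset for the 100-case phantom benchmark.

        The higher learning rate and smaller batches compensate for the
        short schedule (a 70-case epoch is only a handful of updates).
        """
        return cls(
            learning_rate=5e-4, epochs=epochs, batch_size=8, seed=seed
        )

    @classmethod
    def phantom_ablation(cls, seed: int = 0, epochs: int = 30) -> "TrainConfig":
        """Preset for the phantom ablation studies.

        A gentler learning rate than :meth:`phantom` so that all fusion
        strategies — whose effective step sizes differ with the scale of
        the fused feature — stay in a stable training regime under one
        shared config.
        """
        return cls(
            learning_rate=3e-4, epochs=epochs, batch_size=8, seed=seed
        )


@dataclass
class TrainResult:
    """Trained model plus the per-epoch log and the selected snapshot."""

    model: MultiViewClassifier
    log: list[dict]
    best_epoch: int
    best_val_auc: float


@dataclass
class EvalReport:
    """Per-case probabilities and ROC summary on one evaluation set."""

    probabilities: np.ndarray
    labels: np.ndarray
    auc: float
    optimal_threshold: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


# ---------------------------------------------------------------------------
# data plumbing


def cases_to_arrays(cases: list[Case]) -> tuple[np.ndarray, np.ndarray]:
    """Stack cases into ``(N, n_views, D, H, W)`` volumes and ``(N,)`` labels.

    All cases must share one view order and one volume shape.
    """
    if not cases:
        raise ValueError("empty case list")
    order = cases[0].view_ids
    for c in cases:
        if c.view_ids != order:
            raise ValueError(
                f"case {c.case_id!r} view order {c.view_ids} != canonical {order}"
            )
    x = np.stack([np.stack([v.data for v in c.views]) for c in cases])
    y = np.array([c.label for c in cases], dtype=np.float64)
    return x.astype(np.float32), y


def subset_views(split: DatasetSplit, view_ids: list[str]) -> DatasetSplit:
    """Restrict every case of a split to the given views (canonical order kept).

    Raises on an empty subset, duplicates, or unknown view ids.
    """
    if not view_ids:
        raise ValueError("view subset must not be empty")
    if len(set(view_ids)) != len(view_ids):
        raise ValueError(f"duplicate views in subset: {view_ids}")
    canon = split.train[0].view_ids if split.train else []
    unknown = [v for v in view_ids if v not in canon]
    if unknown:
        raise ValueError(f"unknown view ids {unknown}; canonical list is {canon}")
    keep = [v for v in canon if v in view_ids]  # keep canonical ordering

    def _sub(cases: list[Case]) -> list[Case]:
        return [
            Case(
                case_id=c.case_id,
                views=[v for v in c.views if v.view_id in keep],
                label=c.label,
            )
            for c in cases
        ]

    return DatasetSplit(
        train=_sub(split.train),
        validation=_sub(split.validation),
        test=_sub(split.test),
    )


def build_model(
    encoder_config: EncoderConfig,
    n_views: int,
    strategy: FusionStrategy = FusionStrategy.WEIGHTED_FEATURE,
    *,
    head_hidden: int = 512,
    score_hidden: int = 64,
    seed: int = 0,
) -> MultiViewClassifier:
    """Construct a multi-view classifier with seeded initialisation."""
    rng = np.random.default_rng(seed)
    return MultiViewClassifier(
        encoder_config,
        n_views,
        strategy,
        head_hidden=head_hidden,
        score_hidden=score_hidden,
        rng=rng,
    )


# ---------------------------------------------------------------------------
# metrics


def evaluate_auc(probabilities, labels) -> float:
    """Area under the ROC curve (probability a positive outscores a negative,
    ties counted one half)."""
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities, dtype=np.float64)
    if probabilities.shape != labels.shape:
        raise ValueError("probabilities and labels must have equal length")
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(
            f"AUC needs both classes present, got labels {classes.tolist()}"
        )
    return float(roc_auc_score(labels, probabilities))


def optimal_operating_point(probabilities, labels) -> tuple[float, float, float]:
    """Threshold maximising Youden's J, with its sensitivity and specificity.

    A case is predicted positive when probability >= threshold.  Ties in J
    resolve to the lowest threshold.
    """
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities, dtype=np.float64)
    evaluate_auc(probabilities, labels)  # validates both classes present
    fpr, tpr, thresholds = roc_curve(labels, probabilities)
    # drop scikit-learn's synthetic +inf first threshold
    finite = np.isfinite(thresholds)
    fpr, tpr, thresholds = fpr[finite], tpr[finite], thresholds[finite]
    j = tpr - fpr
    best_j = j.max()
    # thresholds are sorted decreasing: the last maximiser is the lowest
    idx = np.flatnonzero(j >= best_j - 1e-12)[-1]
    sensitivity = float(tpr[idx])
    specificity = float(1.0 - fpr[idx])
    return float(thresholds[idx]), sensitivity, specificity


def _predict_in_batches(
    model: MultiViewClassifier, x: np.ndarray, batch_size: int = 32
) -> np.ndarray:
    out = [
        model.predict_proba(x[i : i + batch_size])
        for i in range(0, len(x), batch_size)
    ]
    return np.concatenate(out)


def evaluate(model: MultiViewClassifier, cases: list[Case]) -> EvalReport:
    """Probabilities, AUC and Youden-optimal operating point on a case list."""
    x, y = cases_to_arrays(cases)
    probs = _predict_in_batches(model, x)
    auc = evaluate_auc(probs, y)
    thr, sens, spec = optimal_operating_point(probs, y)
    return EvalReport(
        probabilities=probs,
        labels=y.astype(int),
        auc=auc,
        optimal_threshold=thr,
        sensitivity=sens,
        specificity=spec,
    )


# ---------------------------------------------------------------------------
# training


def _snapshot(model: MultiViewClassifier):
    return (model.state(), nn.collect_batchnorm_stats(model))


def _restore(model: MultiViewClassifier, snap) -> None:
    values, bn_stats = snap
    model.load_state(values)
    nn.load_batchnorm_stats(model, bn_stats)


def train(
    split: DatasetSplit, model: MultiViewClassifier, cfg: TrainConfig
) -> TrainResult:
    """Mini-batch cross-entropy training with best-on-validation selection.

    After every epoch the validation AUC is computed in evaluation mode;
    the returned model carries the snapshot with the highest validation
    AUC (the earlier epoch wins ties).  The log records one entry per
    epoch: ``{"epoch", "train_loss", "val_auc"}``.

    Raises
    ------
    ValueError
        on empty partitions or a single-class training set.
    RuntimeError
        if the training loss becomes non-finite.
    """
    if not split.train or not split.validation:
        raise ValueError("train and validation partitions must be non-empty")
    x_train, y_train = cases_to_arrays(split.train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    x_val, y_val = cases_to_arrays(split.validation)

    rng = np.random.default_rng(cfg.seed)
    optimizer = nn.Adam(
        model.params(),
        lr=cfg.learning_rate,
        beta1=cfg.beta1,
        weight_decay=cfg.weight_decay,
    )
    sample_weight = None
    if cfg.pos_weight != 1.0:
        sample_weight = np.where(y_train == 1, cfg.pos_weight, 1.0)

    log: list[dict] = []
    best_auc = -np.inf
    best_epoch = -1
    best_snap = None
    n = len(x_train)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, sizes = [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            model.zero_grad()
            model.forward(x_train[idx], train=True)
            sw = sample_weight[idx] if sample_weight is not None else None
            loss = model.backward_from_labels(y_train[idx], sample_weight=sw)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch "
                    f"{start // cfg.batch_size}: {loss}"
                )
            if cfg.clip_norm is not None:
                gnorm = np.sqrt(
                    sum(float((p.grad ** 2).sum()) for p in model.params())
                )
                if gnorm > cfg.clip_norm:
                    scale = cfg.clip_norm / gnorm
                    for p in model.params():
                        p.grad *= scale
            optimizer.step()
            losses.append(loss)
            sizes.append(len(idx))
        train_loss = float(np.average(losses, weights=sizes))
        val_probs = _predict_in_batches(model, x_val, cfg.batch_size)
        val_auc = evaluate_auc(val_probs, y_val)
        log.append({"epoch": epoch, "train_loss": train_loss, "val_auc": val_auc})
        if val_auc > best_auc:
            best_auc = val_auc
            best_epoch = epoch
            best_snap = _snapshot(model)
        logger.debug("epoch %d: loss %.4f val_auc %.4f", epoch, train_loss, val_auc)

    _restore(model, best_snap)
    return TrainResult(
        model=model, log=log, best_epoch=best_epoch, best_val_auc=float(best_auc)
    )


# ---------------------------------------------------------------------------
# ablation harnesses


def run_view_ablation(
    split: DatasetSplit,
    encoder_config: EncoderConfig,
    cfg: TrainConfig,
    view_subsets: list[list[str]],
    *,
    strategy: FusionStrategy = FusionStrategy.WEIGHTED_FEATURE,
    head_hidden: int = 512,
) -> pd.DataFrame:
    """Train one model per view subset under identical seeds and config.

    Returns a tidy table with columns ``views``, ``n_views``, ``val_auc``,
    ``test_auc``.
    """
    rows = []
    for subset in view_subsets:
        sub = subset_views(split, subset)
        model = build_model(
            encoder_config,
            len(subset),
            strategy,
            head_hidden=head_hidden,
            seed=cfg.seed,
        )
        result = train(sub, model, cfg)
        report = evaluate(result.model, sub.test)
        rows.append(
            {
                "views": "+".join(subset),
                "n_views": len(subset),
                "val_auc": result.best_val_auc,
                "test_auc": report.auc,
            }
        )
    return pd.DataFrame(rows)


def run_fusion_ablation(
    split: DatasetSplit,
    encoder_config: EncoderConfig,
    cfg: TrainConfig,
    *,
    strategies: list[FusionStrategy] | None = None,
    head_hidden: int = 512,
) -> pd.DataFrame:
    """Train the fusion strategies under identical seeds/config.

    Returns a table with columns ``strategy``, ``val_auc``, ``test_auc``.
    """
    if strategies is None:
        strategies = list(FusionStrategy)
    n_views = split.train[0].n_views if split.train else 0
    rows = []
    for strat in strategies:
        model = build_model(
            encoder_config, n_views, strat, head_hidden=head_hidden, seed=cfg.seed
        )
        result = train(split, model, cfg)
        report = evaluate(result.model, split.test)
        rows.append(
            {
                "strategy": FusionStrategy(strat).value,
                "val_auc": result.best_val_auc,
                "test_auc": report.auc,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model checkpointing


def save_model(path, model: MultiViewClassifier) -> None:
    """Serialize a full model (weights, BN stats, architecture) to one file."""
    meta = {
        "encoder_config": asdict(model.encoder.config),
        "encoder_digest": model.encoder.config.digest(),
        "n_views": model.n_views,
        "strategy": model.strategy.value,
        "head_hidden": model.head.hidden,
        "score_hidden": model.score_net.hidden if model.score_net else None,
    }
    arrays = {f"p{i}": v for i, v in enumerate(model.state())}
    arrays.update(
        {f"bn{i}": v for i, v in enumerate(nn.collect_batchnorm_stats(model))}
    )
    payload = json.dumps(meta).encode()
    np.savez(path, __meta__=np.frombuffer(payload, dtype=np.uint8), **arrays)


def load_model(path) -> MultiViewClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = EncoderConfig(
            stem_channels=meta["encoder_config"]["stem_channels"],
            block_channels=tuple(meta["encoder_config"]["block_channels"]),
            blocks_per_stage=tuple(meta["encoder_config"]["blocks_per_stage"]),
            embedding_dim=meta["encoder_config"]["embedding_dim"],
        )
        if config.digest() != meta["encoder_digest"]:
            raise ValueError("checkpoint config digest mismatch")
        model = build_model(
            config,
            meta["n_views"],
            FusionStrategy(meta["strategy"]),
            head_hidden=meta["head_hidden"],
            score_hidden=meta.get("score_hidden") or 64,
        )
        n = len(model.state())
        model.load_state([data[f"p{i}"] for i in range(n)])
        stats = [
            data[f"bn{i}"]
            for i in range(len(nn.collect_batchnorm_stats(model)))
        ]
        nn.load_batchnorm_stats(model, stats)
    return model
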