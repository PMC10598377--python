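"""Shared-weight 3-D residual encoder mapping a volume to a fixed-length embedding.

The encoder is a 3D-ResNet-10-style network: a convolutional stem
(Conv3D -> BN3D -> ReLU -> MaxPool3D), four stages of one basic residual
block each, and global adaptive average pooling to a single spatial cell,
yielding one ``embedding_dim`` vector per view.  Each residual block
computes ``z = F(v, W) + v`` where the residual branch ``F`` is
conv -> BN -> ReLU -> conv -> BN, followed by a ReLU on the sum; when the
block changes channel count or stride, a 1x1x1 projection shortcut keeps
the addition shape-legal.

One encoder instance is shared across every view of every case: all views
are embedded by the same parameter set, which is the multi-view analogue of
weight sharing across inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn

__all__ = [
    "EncoderConfig",
    "ViewEmbedding",
    "ResidualBlockSpec",
    "ResidualBlock",
    "Encoder3D",
    "residual_block",
    "encode_view",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyper-parameters of the shared 3-D residual encoder.

    The default configuration is the full-size network whose per-view
    embedding has 512 dimensions; :meth:`small` returns a reduced variant
    (channels 8/16/32/64, 64-dim embedding) sized for CPU-scale phantom
    experiments.
    """

    stem_channels: int = 64
    block_channels: tuple[int, ...] = (64, 128, 256, 512)
    blocks_per_stage: tuple[int, ...] = (1, 1, 1, 1)
    embedding_dim: int = 512

    def __post_init__(self):
        if len(self.block_channels) != len(self.blocks_per_stage):
            raise ValueError(
                "block_channels and blocks_per_stage must have equal length"
            )
        if self.block_channels and self.block_channels[-1] != self.embedding_dim:
            raise ValueError(
                "embedding_dim must equal the last stage's channel width "
                f"({self.block_channels[-1]} != {self.embedding_dim})"
            )
        if not self.block_channels and self.stem_channels != self.embedding_dim:
            raise ValueError("with no stages, embedding_dim must equal stem_channels")

    @classmethod
    def small(cls) -> "EncoderConfig":
        """Reduced encoder for desk-scale CPU training on phantoms."""
        return cls(
            stem_channels=8,
            block_channels=(8, 16, 32, 64),
            blocks_per_stage=(1, 1, 1, 1),
            embedding_dim=64,
        )

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class ViewEmbedding:
    """Per-view feature vector produced by the shared encoder."""

    vector: np.ndarray
    view_id: str

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float32).ravel()
        if not np.all(np.isfinite(self.vector)):
            raise ValueError(f"non-finite embedding for view {self.view_id!r}")


@dataclass(frozen=True)
class ResidualBlockSpec:
    in_channels: int
    out_channels: int
    stride: int = 1

    @property
    def needs_projection(self) -> bool:
        return self.in_channels != self.out_channels or self.stride != 1


class ResidualBlock(nn.Module):
    """Basic 3-D residual block: (conv-BN-ReLU-conv-BN) + shortcut, then ReLU."""

    def __init__(self, spec: ResidualBlockSpec, *, rng: np.random.Generator):
        self.spec = spec
        self.conv1 = nn.Conv3d(
            spec.in_channels, spec.out_channels, 3, stride=spec.stride, padding=1, rng=rng
        )
        self.bn1 = nn.BatchNorm3d(spec.out_channels)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv3d(spec.out_channels, spec.out_channels, 3, 1, 1, rng=rng)
        self.bn2 = nn.BatchNorm3d(spec.out_channels)
        if spec.needs_projection:
            self.proj_conv = nn.Conv3d(
                spec.in_channels, spec.out_channels, 1, stride=spec.stride, padding=0, rng=rng
            )
            self.proj_bn = nn.BatchNorm3d(spec.out_channels)
        else:
            self.proj_conv = None
            self.proj_bn = None
        self._out_mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite input to residual block")
        branch = self.bn2.forward(
            self.conv2.forward(
                self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train),
                train,
            ),
            train,
        )
        if self.proj_conv is not None:
            shortcut = self.proj_bn.forward(self.proj_conv.forward(x, train), train)
        else:
            shortcut = x
        z = branch + shortcut
        self._out_mask = z > 0
        return np.where(self._out_mask, z, 0.0).astype(nn.DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask, self._out_mask = self._out_mask, None
        dz = np.where(mask, dout, 0.0).astype(nn.DTYPE)
        dbranch = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(dz))))
        )
        if self.proj_conv is not None:
            dshort = self.proj_conv.backward(self.proj_bn.backward(dz))
        else:
            dshort = dz
        return dbranch + dshort


class Encoder3D(nn.Module):
    """The shared feature-extraction network ``h = f(x)``.

    Input: ``(N, 1, D, H, W)`` single-channel volumes (grayscale MR).
    Output: ``(N, embedding_dim)`` embeddings.
    """

    def __init__(self, config: EncoderConfig, *, rng: np.random.Generator):
        self.config = config
        self.stem_conv = nn.Conv3d(1, config.stem_channels, 3, stride=2, padding=1, rng=rng)
        self.stem_bn = nn.BatchNorm3d(config.stem_channels)
        self.stem_relu = nn.ReLU()
        self.stem_pool = nn.MaxPool3d()
        blocks: list[ResidualBlock] = []
        in_ch = config.stem_channels
        for stage, (out_ch, n_blocks) in enumerate(
            zip(config.block_channels, config.blocks_per_stage)
        ):
            for b in range(n_blocks):
                stride = 2 if (stage > 0 and b == 0) else 1
                blocks.append(
                    ResidualBlock(ResidualBlockSpec(in_ch, out_ch, stride), rng=rng)
                )
                in_ch = out_ch
        self.blocks = blocks
        self.pool = nn.AdaptiveAvgPool3d()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x = self.stem_pool.forward(
            self.stem_relu.forward(self.stem_bn.forward(self.stem_conv.forward(x, train), train), train),
            train,
        )
        for block in self.blocks:
            x = block.forward(x, train)
        return self.pool.forward(x, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = self.pool.backward(dout)
        for block in reversed(self.blocks):
            dx = block.backward(dx)
        return self.stem_conv.backward(
            self.stem_bn.backward(self.stem_relu.backward(self.stem_pool.backward(dx)))
        )


def residual_block(
    x: np.ndarray, spec: ResidualBlockSpec, block: ResidualBlock
) -> np.ndarray:
    """Apply one residual block to a single ``(C, D, H, W)`` feature map.

    Thin functional wrapper over :class:`ResidualBlock` (evaluation mode).
    """
    x = np.asarray(x, dtype=nn.DTYPE)
    if x.ndim != 4:
        raise ValueError(f"expected (C,D,H,W), got shape {x.shape}")
    if block.spec != spec:
        raise ValueError("block was built for a different spec")
    return block.forward(x[None], train=False)[0]


def encode_view(volume, encoder: Encoder3D) -> ViewEmbedding:
    """Embed one preprocessed view volume with the shared encoder (eval mode)."""
    data = np.asarray(volume.data, dtype=nn.DTYPE)
    vec = encoder.forward(data[None, None], train=False)[0]
    return ViewEmbedding(vector=vec, view_id=volume.view_id)


def count_parameters(config: EncoderConfig) -> int:
    """Exact trainable-parameter count of the encoder built from ``config``."""
    rng = np.random.default_rng(0)
    return Encoder3D(config, rng=rng).n_parameters()


def save_checkpoint(path, encoder: Encoder3D, extra_state: dict | None = None) -> None:
    """Serialize encoder weights (and optional extra arrays) with the config.

    The config is embedded as JSON; :func:`load_checkpoint` refuses a file
    whose config digest does not match the requested architecture.
    """
    arrays = {f"p{i}": v for i, v in enumerate(encoder.state())}
    bn_stats = nn.collect_batchnorm_stats(encoder)
    arrays.update({f"bn{i}": v for i, v in enumerate(bn_stats)})
    if extra_state:
        arrays.update(extra_state)
    meta = json.dumps(
        {"config": asdict(encoder.config), "digest": encoder.config.digest()}
    )
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, config: EncoderConfig, *, rng=None) -> Encoder3D:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["digest"] != config.digest():
            raise ValueError(
                "checkpoint was written for a different encoder configuration"
            )
        enc = Encoder3D(config, rng=rng or np.random.default_rng(0))
        n = len(enc.state())
        enc.load_state([data[f"p{i}"] for i in range(n)])
        stats = [data[f"bn{i}"] for i in range(len(nn.collect_batchnorm_stats(enc)))]
        nn.load_batchnorm_stats(enc, stats)
    return enc


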