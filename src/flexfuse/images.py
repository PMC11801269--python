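"""Convolutional image branch: tile encoder with tile-level pooling.

Each pathology tile passes through a small convolutional backbone; the
spatial feature map at the tap point (the last convolutional stage) is
averaged over space to a per-tile embedding, tile embeddings are pooled
across the patient's tiles (unweighted mean by default, attention
optionally) and projected to the shared modality-representation width.
The tap-point feature map itself is exposed for SCDA heatmaps.

Backbones are registered by name. ``tiny_cnn`` (4 conv layers) is the
CPU-scale default used throughout the tests; ``small_cnn`` is a deeper
variant for architecture-swap checks. Large pretrained architectures
(ResNet/VGG families) are not bundled; requesting one raises
:class:`BackboneUnavailableError` so callers can plug in their own via
:func:`register_backbone`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .data import ImageSet
from .errors import BackboneUnavailableError, ConfigError
from .nn import Conv2d, Linear, Module, Tensor

__all__ = [
    "BackboneConfig",
    "ConvBackbone",
    "ImageBranch",
    "build_backbone",
    "register_backbone",
    "encode_tiles",
    "feature_map",
    "normalize_tiles",
]


@dataclass
class BackboneConfig:
    architecture: str = "tiny_cnn"
    pooling: str = "mean"  # or "attention"
    d_rep: int = 32

    def validate(self) -> None:
        if self.pooling not in ("mean", "attention"):
            raise ConfigError(f"unknown pooling mode {self.pooling!r}")


class ConvBackbone(Module):
    """Stack of valid 3x3 convolutions with ReLU; last stage is the tap point."""

    def __init__(self, stages: list[tuple[int, int, int]], rng: np.random.Generator, bias: bool = True):
        # stages: (c_in, c_out, stride)
        super().__init__()
        self.convs = [Conv2d(ci, co, 3, s, rng, bias=bias) for ci, co, s in stages]
        self.out_channels = stages[-1][1]

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, 3, H, W) -> tap-point feature map (B, C, h, w)."""
        need = self.min_input()
        if x.shape[2] < need or x.shape[3] < need:
            raise ConfigError(
                f"tile of size {x.shape[2]}x{x.shape[3]} too small for this backbone "
                f"(needs >= {need}px for a spatial tap point)"
            )
        for conv in self.convs:
            x = conv(x).relu()
        return x

    def min_input(self) -> int:
        size = 1
        for conv in reversed(self.convs):
            size = (size - 1) * conv.stride + 3
        return size


_REGISTRY: dict[str, Callable[[np.random.Generator, bool], ConvBackbone]] = {}


def register_backbone(name: str, factory: Callable[[np.random.Generator, bool], ConvBackbone]) -> None:
    _REGISTRY[name] = factory


# stride layout keeps the tap receptive field small (17 px) so SCDA
# localization stays sharper than the lesions it is asked to find
register_backbone("tiny_cnn", lambda rng, bias: ConvBackbone(
    [(3, 8, 1), (8, 16, 2), (16, 32, 2), (32, 32, 1)], rng, bias=bias))
register_backbone("small_cnn", lambda rng, bias: ConvBackbone(
    [(3, 8, 2), (8, 16, 2), (16, 32, 2), (32, 32, 1), (32, 32, 1)], rng, bias=bias))

_UNAVAILABLE = ("resnet18", "resnet34", "resnet50", "vgg16")


def build_backbone(name: str, rng: np.random.Generator, bias: bool = True) -> ConvBackbone:
    if name in _REGISTRY:
        return _REGISTRY[name](rng, bias)
    if name in _UNAVAILABLE:
        raise BackboneUnavailableError(
            f"backbone {name!r} is not bundled with this package; register a custom "
            f"factory with register_backbone() or use one of {sorted(_REGISTRY)}"
        )
    raise ConfigError(f"unknown backbone {name!r}; available: {sorted(_REGISTRY)}")


class ImageBranch(Module):
    """Backbone + spatial mean + tile pooling + projection to d_rep."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        config.validate()
        self.config = config
        self.backbone = build_backbone(config.architecture, rng, bias=bias)
        self.proj = Linear(self.backbone.out_channels, config.d_rep, rng)
        if config.pooling == "attention":
            self.att = Linear(self.backbone.out_channels, 1, rng)

    def tile_embeddings(self, tiles: Tensor) -> Tensor:
        """tiles: (N, 3, H, W) -> (N, C) spatial-mean embeddings."""
        fmap = self.backbone(tiles)
        if fmap.shape[2] < 1 or fmap.shape[3] < 1:
            raise ConfigError("tile too small for this backbone's tap point")
        return fmap.mean(axis=(2, 3))

    def __call__(self, tiles: Tensor, n_patients: int, tiles_per_patient: int) -> Tensor:
        """tiles: (B*T, 3, H, W) -> (B, d_rep) patient representations."""
        emb = self.tile_embeddings(tiles)  # (B*T, C)
        c = emb.shape[1]
        emb = emb.reshape(n_patients, tiles_per_patient, c)
        if self.config.pooling == "attention":
            scores = self.att(emb)  # (B, T, 1)
            shift = Tensor(scores.data.max(axis=1, keepdims=True))  # constant shift
            e = (scores - shift).exp()
            weights = e / e.sum(axis=1, keepdims=True)
            pooled = (emb * weights).sum(axis=1)
        else:
            pooled = emb.mean(axis=1)
        return self.proj(pooled).relu()

    def feature_map(self, tile: Tensor) -> Tensor:
        """Single tile (3, H, W) or batch (B, 3, H, W) -> tap-point activations."""
        x = tile if tile.ndim == 4 else tile.reshape((1,) + tile.shape)
        fmap = self.backbone(x)
        if fmap.shape[2] < 1 or fmap.shape[3] < 1:
            raise ConfigError("tap point has no spatial extent for this tile size")
        return fmap


# ----------------------------------------------------------------- utilities
def normalize_tiles(tiles: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    """uint8 HWC tiles -> float CHW, per-channel standardized."""
    x = tiles.astype(np.float64) / 255.0
    x = (x - mean.reshape(1, 1, 1, 3)) / std.reshape(1, 1, 1, 3)
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def tile_normalization_stats(image_sets: list[ImageSet]) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/std over all tiles of the training fold."""
    if not image_sets:
        return np.zeros(3), np.ones(3)
    stacked = np.concatenate([np.stack(s.tiles) for s in image_sets]).astype(np.float64) / 255.0
    mean = stacked.mean(axis=(0, 1, 2))
    std = stacked.std(axis=(0, 1, 2))
    std = np.where(std < 1e-6, 1.0, std)
    return mean, std


def encode_tiles(image_set: ImageSet | None, branch: ImageBranch, mean: np.ndarray, std: np.ndarray) -> np.ndarray | None:
    """Representation for one patient's tiles; None signals a missing modality."""
    if image_set is None or not image_set.tiles:
        return None
    branch.eval()
    x = normalize_tiles(np.stack(image_set.tiles), mean, std)
    rep = branch(Tensor(x), 1, len(image_set.tiles))
    return rep.data[0]


def feature_map(tile: np.ndarray, branch: ImageBranch, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    """Tap-point activation map (C, h, w) for one uint8 HWC tile."""
    branch.eval()
    x = normalize_tiles(tile[None], mean, std)
    return branch.feature_map(Tensor(x)).data[0]
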