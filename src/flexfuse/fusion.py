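"""Fusion operators, the two-layer classifier head, and the Meta module.

Four fusion rules combine per-modality representations h_m (all of width
d_rep except under concatenation, which merely stacks them):

* summation        fused = sum_m h_m
* multiplication   fused = prod_m h_m   (elementwise)
* gating           g_m = sigmoid(A_m [h_C; h_P; ...]),  fused = sum_m g_m * h_m
* concatenation    fused = [h_C; h_P; h_M; h_I]  (fixed modality order)

The classifier is two fully-connected layers (hidden ReLU, scalar logit;
sigmoid applied at the probability interface). The Meta module synthesizes
a replacement representation for a single missing modality from the
concatenation of the remaining active modalities' representations; more
than one missing active modality is explicitly unsupported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MODALITIES
from .errors import ConfigError, UnsupportedCaseError
from .nn import MLP, Linear, Module, Tensor, concat

__all__ = ["FusionConfig", "FusionLayer", "ClassifierHead", "MetaModule", "fuse", "impute_modality"]

FUSION_METHODS = ("summation", "multiplication", "gating", "concatenation")


@dataclass
class FusionConfig:
    method: str = "concatenation"
    modalities: tuple[str, ...] = ("C", "P", "M", "I")
    hidden: int = 64  # classifier hidden width
    dropout: float = 0.0

    def __post_init__(self) -> None:
        # keep canonical modality order regardless of caller order
        self.modalities = tuple(m for m in MODALITIES if m in self.modalities)

    def validate(self) -> None:
        if self.method not in FUSION_METHODS:
            raise ConfigError(f"fusion method must be one of {FUSION_METHODS}")
        if not self.modalities:
            raise ConfigError("at least one active modality required")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("dropout must lie in [0, 1)")

    def fused_width(self, d_rep: int) -> int:
        return d_rep * len(self.modalities) if self.method == "concatenation" else d_rep


class FusionLayer(Module):
    """Applies the configured fusion rule; owns gate parameters for gating."""

    def __init__(self, config: FusionConfig, d_rep: int, rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        self.d_rep = d_rep
        if config.method == "gating":
            total = d_rep * len(config.modalities)
            self.gates = {m: Linear(total, d_rep, rng) for m in config.modalities}

    def __call__(self, reps: dict[str, Tensor]) -> Tensor:
        cfg = self.config
        missing = [m for m in cfg.modalities if m not in reps]
        if missing:
            raise ConfigError(f"representations missing for active modalities: {missing}")
        ordered = [reps[m] for m in cfg.modalities]
        widths = {t.shape[-1] for t in ordered}
        if cfg.method != "concatenation" and widths != {self.d_rep}:
            raise ConfigError(f"{cfg.method} fusion requires equal d_rep, got widths {sorted(widths)}")
        if cfg.method == "summation":
            out = ordered[0]
            for t in ordered[1:]:
                out = out + t
            return out
        if cfg.method == "multiplication":
            out = ordered[0]
            for t in ordered[1:]:
                out = out * t
            return out
        if cfg.method == "gating":
            stacked = concat(ordered, axis=-1)
            out = None
            for m in cfg.modalities:
                g = self.gates[m](stacked).sigmoid()
                term = g * reps[m]
                out = term if out is None else out + term
            return out
        return concat(ordered, axis=-1)

    def gate_values(self, reps: dict[str, Tensor]) -> dict[str, np.ndarray]:
        if self.config.method != "gating":
            raise ConfigError("gate_values only defined for gating fusion")
        stacked = concat([reps[m] for m in self.config.modalities], axis=-1)
        return {m: self.gates[m](stacked).sigmoid().data for m in self.config.modalities}


class ClassifierHead(Module):
    """Two fully-connected layers: hidden ReLU then a single logit."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator, zero_init_out: bool = False):
        super().__init__()
        self.d_in = d_in
        self.fc1 = Linear(d_in, hidden, rng)
        self.fc2 = Linear(hidden, 1, rng, zero_init=zero_init_out)

    def logits(self, fused: Tensor) -> Tensor:
        if fused.shape[-1] != self.d_in:
            raise ConfigError(f"classifier expects width {self.d_in}, got {fused.shape[-1]}")
        return self.fc2(self.fc1(fused).relu())

    def __call__(self, fused: Tensor) -> Tensor:
        """Probability of progression, in (0, 1) for finite inputs."""
        return self.logits(fused).sigmoid()


class MetaModule(Module):
    """One feedforward synthesizer per target modality.

    meta_m maps the concatenation of the other active modalities'
    representations (in canonical order) to a d_rep replacement vector.
    """

    def __init__(self, modalities: tuple[str, ...], d_rep: int, rng: np.random.Generator, hidden: int = 64):
        super().__init__()
        self.modalities = tuple(m for m in MODALITIES if m in modalities)
        self.d_rep = d_rep
        if len(self.modalities) >= 2:
            self.nets = {
                m: MLP([(len(self.modalities) - 1) * d_rep, hidden, d_rep], rng, final_relu=True)
                for m in self.modalities
            }
        else:
            self.nets = {}

    def sources(self, target: str) -> list[str]:
        return [m for m in self.modalities if m != target]

    def __call__(self, available: dict[str, Tensor], target: str) -> Tensor:
        if target not in self.nets:
            raise ConfigError(f"no Meta synthesizer for modality {target!r}")
        srcs = self.sources(target)
        absent = [m for m in srcs if m not in available]
        if absent:
            raise UnsupportedCaseError(
                f"Meta module handles a single missing modality; also missing: {absent}"
            )
        return self.nets[target](concat([available[m] for m in srcs], axis=-1))


# ---------------------------------------------------- operation-style facade
def fuse(reps: dict[str, np.ndarray], config: FusionConfig, layer: FusionLayer | None = None) -> np.ndarray:
    """Fuse per-modality representation vectors/matrices into one array."""
    if layer is None:
        if config.method == "gating":
            raise ConfigError("gating fusion needs a FusionLayer carrying gate parameters")
        layer = FusionLayer(config, d_rep=next(iter(reps.values())).shape[-1], rng=np.random.default_rng(0))
    tens = {m: Tensor(np.atleast_2d(v)) for m, v in reps.items()}
    out = layer(tens).data
    return out[0] if np.ndim(next(iter(reps.values()))) == 1 else out


def impute_modality(available: dict[str, np.ndarray], target: str, meta: MetaModule) -> np.ndarray:
    """Synthesize the missing modality's representation from the others."""
    tens = {m: Tensor(np.atleast_2d(v)) for m, v in available.items()}
    out = meta(tens, target).data
    return out[0] if np.ndim(next(iter(available.values()))) == 1 else out
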