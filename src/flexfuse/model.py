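"""End-to-end model: per-modality encoders -> fusion -> two-layer classifier.

The model owns one encoder per active modality (an EncodingBank for the
encoding-training pathway or a plain feedforward encoder for the raw /
hashed-only ablations; a convolutional branch for images), a fusion layer,
a classifier head and optionally a Meta module. A single forward pass maps
a :class:`ModelInputs` batch to logits; missing modalities are routed
through the Meta module (or a zero vector) by presence masks, so batches
with heterogeneous missingness run in one graph.

All parameters live in one module tree, so one Adam instance trains
encodings, backbone, gates, Meta and classifier jointly — the model is
end-to-end by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import MODALITIES
from .errors import ConfigError, UnsupportedCaseError
from .fet import D_ENC_DEFAULT, EncodingBank, PlainTabularEncoder
from .fusion import ClassifierHead, FusionConfig, FusionLayer, MetaModule
from .images import BackboneConfig, ImageBranch
from .nn import Module, Tensor

__all__ = ["ModelSpec", "ModelInputs", "FlexModel"]

PATHWAYS = ("raw", "hashed", "encoded")


@dataclass
class ModelSpec:
    """Architecture hyperparameters shared by training and inference."""

    modalities: tuple[str, ...] = ("C", "P", "M", "I")
    feature_names: dict[str, list[str]] = field(default_factory=dict)
    pathway: str = "encoded"
    d_rep: int = 32
    d_enc: int = D_ENC_DEFAULT
    fusion: str = "concatenation"
    classifier_hidden: int = 64
    backbone: str = "tiny_cnn"
    pooling: str = "mean"
    use_meta: bool = True
    shared_affine: bool = False
    dropout: float = 0.0  # on the fused vector, training mode only

    def __post_init__(self) -> None:
        self.modalities = tuple(m for m in MODALITIES if m in self.modalities)

    def validate(self) -> None:
        if self.pathway not in PATHWAYS:
            raise ConfigError(f"pathway must be one of {PATHWAYS}")
        for m in self.modalities:
            if m != "I" and m not in self.feature_names:
                raise ConfigError(f"feature_names missing for modality {m}")
        if self.d_rep <= 0 or self.d_enc <= 0:
            raise ConfigError("d_rep and d_enc must be positive")


@dataclass
class ModelInputs:
    """Numeric batch: per-modality arrays aligned on the same patients.

    For each tabular modality m: values[m] is (B, F_m) — bucket midpoints
    (encoded/hashed pathways) or standardized raw values (raw pathway) —
    and present[m] is the matching (B, F_m) cell-presence mask (all-zero
    row == modality absent for that patient). For images: tiles is
    (B, T, 3, H, W) normalized floats and image_present is (B,).
    """

    patient_ids: list[str]
    values: dict[str, np.ndarray]
    present: dict[str, np.ndarray]
    tiles: np.ndarray | None = None
    image_present: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    def modality_present(self, m: str) -> np.ndarray:
        if m == "I":
            if self.image_present is None:
                return np.zeros(self.n, dtype=bool)
            return self.image_present.astype(bool)
        return self.present[m].any(axis=1)

    def select(self, idx: np.ndarray) -> "ModelInputs":
        return ModelInputs(
            patient_ids=[self.patient_ids[i] for i in idx],
            values={m: v[idx] for m, v in self.values.items()},
            present={m: p[idx] for m, p in self.present.items()},
            tiles=None if self.tiles is None else self.tiles[idx],
            image_present=None if self.image_present is None else self.image_present[idx],
        )


class FlexModel(Module):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__()
        spec.validate()
        self.spec = spec
        encoders: dict[str, Module] = {}
        for m in spec.modalities:
            if m == "I":
                continue
            names = spec.feature_names[m]
            if spec.pathway == "encoded":
                encoders[m] = EncodingBank(names, spec.d_rep, rng, d_enc=spec.d_enc,
                                           shared_affine=spec.shared_affine)
            else:
                encoders[m] = PlainTabularEncoder(len(names), spec.d_rep, rng)
        self.encoders = encoders
        if "I" in spec.modalities:
            self.image_branch = ImageBranch(
                BackboneConfig(architecture=spec.backbone, pooling=spec.pooling, d_rep=spec.d_rep), rng
            )
        fcfg = FusionConfig(method=spec.fusion, modalities=spec.modalities, hidden=spec.classifier_hidden)
        self.fusion = FusionLayer(fcfg, spec.d_rep, rng)
        self.head = ClassifierHead(fcfg.fused_width(spec.d_rep), spec.classifier_hidden, rng)
        if spec.use_meta and len(spec.modalities) >= 2:
            self.meta = MetaModule(spec.modalities, spec.d_rep, rng)
        else:
            self.meta = None
        self._dropout_rng = np.random.default_rng(rng.integers(2**31 - 1))

    # ------------------------------------------------------------- encoding
    def modality_reps(self, batch: ModelInputs, inputs_as_tensors: dict | None = None) -> dict[str, Tensor]:
        """Per-modality representations before any Meta substitution.

        ``inputs_as_tensors`` lets callers (Integrated Gradients) supply
        graph inputs with requires_grad; otherwise arrays are wrapped here.
        """
        t = inputs_as_tensors or {}
        reps: dict[str, Tensor] = {}
        for m in self.spec.modalities:
            if m == "I":
                if batch.tiles is None:
                    raise ConfigError("image modality active but batch has no tiles")
                tiles = t.get("I") or Tensor(batch.tiles)
                b, n_tiles = batch.tiles.shape[0], batch.tiles.shape[1]
                flat = tiles.reshape(b * n_tiles, *batch.tiles.shape[2:])
                reps[m] = self.image_branch(flat, b, n_tiles)
            else:
                v = t.get(f"{m}:values") or Tensor(batch.values[m])
                u = t.get(f"{m}:present") or Tensor(batch.present[m].astype(np.float64))
                reps[m] = self.encoders[m](v, u)
        return reps

    # -------------------------------------------------------------- forward
    def forward(
        self,
        batch: ModelInputs,
        replace_missing: str = "meta",
        inputs_as_tensors: dict | None = None,
    ) -> tuple[Tensor, dict]:
        """Batch -> (logits (B,1), aux) with missing-modality handling.

        ``replace_missing``: 'meta' routes single-missing patients through
        the Meta module (falling back to zeros if no Meta is attached),
        'zeros' substitutes a zero vector, 'none' asserts completeness.
        aux carries the raw reps and the Meta reconstruction loss term.
        """
        if replace_missing not in ("meta", "zeros", "none"):
            raise ConfigError("replace_missing must be 'meta', 'zeros' or 'none'")
        reps = self.modality_reps(batch, inputs_as_tensors)
        active = list(self.spec.modalities)
        pres = {m: batch.modality_present(m) for m in active}

        n_missing = np.zeros(batch.n, dtype=int)
        for m in active:
            n_missing += ~pres[m]
        if replace_missing == "none":
            if n_missing.any():
                raise ConfigError("batch contains missing modalities but replace_missing='none'")
        elif (n_missing > 1).any():
            bad = [batch.patient_ids[i] for i in np.where(n_missing > 1)[0]]
            raise UnsupportedCaseError(
                f"patients missing more than one active modality are not supported: {bad[:5]}"
            )

        final: dict[str, Tensor] = {}
        recon_terms: list[Tensor] = []
        complete = n_missing == 0
        for m in active:
            mask = Tensor(pres[m].astype(np.float64).reshape(-1, 1))
            if pres[m].all():
                final[m] = reps[m]
                continue
            if replace_missing == "meta" and self.meta is not None and len(active) >= 2:
                # patients missing m have every other modality present
                replacement = self.meta(reps, m)
            else:
                replacement = Tensor(np.zeros_like(reps[m].data))
            final[m] = mask * reps[m] + (1.0 - mask) * replacement

        # Meta reconstruction on complete patients (targets detached)
        if self.training and self.meta is not None and complete.any() and len(active) >= 2:
            w = Tensor(complete.astype(np.float64).reshape(-1, 1))
            denom = float(complete.sum() * self.spec.d_rep)
            for m in active:
                pred = self.meta(reps, m)
                diff = (pred - reps[m].detach()) * w
                recon_terms.append((diff * diff).sum() * (1.0 / denom))

        fused = self.fusion(final)
        if self.training and self.spec.dropout > 0:
            keep = 1.0 - self.spec.dropout
            mask = (self._dropout_rng.random(fused.shape) < keep) / keep
            fused = fused * Tensor(mask)
        logits = self.head.logits(fused)
        recon = None
        if recon_terms:
            recon = recon_terms[0]
            for term in recon_terms[1:]:
                recon = recon + term
        return logits, {"reps": reps, "final_reps": final, "recon_loss": recon}

    def predict_proba(self, batch: ModelInputs, replace_missing: str = "meta") -> np.ndarray:
        self.eval()
        logits, _ = self.forward(batch, replace_missing=replace_missing)
        return logits.sigmoid().data.ravel()

    # ---------------------------------------------------------- persistence
    def save(self, path: str | Path, extra: dict | None = None) -> None:
        path = Path(path)
        spec = self.spec
        meta = {
            "spec": {
                "modalities": list(spec.modalities),
                "feature_names": spec.feature_names,
                "pathway": spec.pathway,
                "d_rep": spec.d_rep,
                "d_enc": spec.d_enc,
                "fusion": spec.fusion,
                "classifier_hidden": spec.classifier_hidden,
                "backbone": spec.backbone,
                "pooling": spec.pooling,
                "use_meta": spec.use_meta,
                "shared_affine": spec.shared_affine,
                "dropout": spec.dropout,
            },
            "extra": extra or {},
        }
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> tuple["FlexModel", dict]:
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        spec = ModelSpec(
            modalities=tuple(meta["spec"]["modalities"]),
            feature_names=meta["spec"]["feature_names"],
            pathway=meta["spec"]["pathway"],
            d_rep=meta["spec"]["d_rep"],
            d_enc=meta["spec"]["d_enc"],
            fusion=meta["spec"]["fusion"],
            classifier_hidden=meta["spec"]["classifier_hidden"],
            backbone=meta["spec"]["backbone"],
            pooling=meta["spec"]["pooling"],
            use_meta=meta["spec"]["use_meta"],
            shared_affine=meta["spec"]["shared_affine"],
            dropout=meta["spec"].get("dropout", 0.0),
        )
        model = cls(spec, np.random.default_rng(0))
        with np.load(path.with_suffix(".npz")) as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
        return model, meta["extra"]
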