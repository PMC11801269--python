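"""Feature Encoding Trainer: hash mapping plus trainable feature encodings.

The tabular pathway has two stages:

1. **Hash mapping** — per-feature empirical quantile bucketing fitted on
   the training split only. Every feature, whatever its raw scale or
   distribution, is replaced by the midpoint of its bucket's probability
   mass on the common [0, 1] scale ((k + 0.5) / B for bucket k of B).
   Missing cells map to a reserved missing bucket, never to a numeric
   midpoint. This puts binary indicators, Gaussian labs and long-tailed
   omics intensities on one scale and is insensitive to monotone
   rescaling of the raw data.

2. **Encoding training** — each feature f owns a trainable
   ten-dimensional encoding vector e_f; the mapped scalar scales it
   (v_f * e_f), a per-feature learnable affine layer transforms it, and
   the transformed vectors are summed over features and projected to the
   modality representation. Missing cells contribute a dedicated learned
   missing-encoding vector instead of v_f * e_f, so missingness stays
   visible to the model. All of it trains end-to-end by backpropagation.

Two ablation pathways are provided for comparison: ``raw`` feeds
standardized raw values (plus the presence mask) through a plain two-layer
feedforward encoder, and ``hashed`` feeds the bucket midpoints through the
same plain encoder without trainable per-feature encodings.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .data import FeatureTable
from .errors import ConfigError, FitError, SchemaError
from .nn import MLP, Linear, Module, Tensor, feature_affine

__all__ = [
    "HashMapper",
    "MappedTable",
    "EncodingBank",
    "PlainTabularEncoder",
    "fit_hash_mapper",
    "apply_hash_map",
    "encode_modality",
    "encode_modality_raw",
    "encode_modality_hashed_only",
]

D_ENC_DEFAULT = 10  # encoding vectors are ten-dimensional by default
N_BUCKETS_DEFAULT = 16


@dataclass
class MappedTable:
    """Bucket-midpoint view of a FeatureTable on the common [0, 1] scale."""

    feature_names: list[str]
    patient_ids: list[str]
    values: np.ndarray  # midpoints in [0,1]; 0.0 placeholder where missing
    present: np.ndarray  # bool mask, False = missing-bucket code


class HashMapper:
    """Per-feature quantile bucketing fitted on a training split."""

    def __init__(self, feature_names: list[str], boundaries: list[np.ndarray], n_buckets: list[int]):
        self.feature_names = list(feature_names)
        self.boundaries = [np.asarray(b, dtype=np.float64) for b in boundaries]
        self.n_buckets = list(n_buckets)
        for b in self.boundaries:
            if np.any(np.diff(b) < 0):
                raise FitError("quantile boundaries must be non-decreasing")

    # ------------------------------------------------------------------ fit
    @classmethod
    def fit(cls, table: FeatureTable, n_buckets: int = N_BUCKETS_DEFAULT) -> "HashMapper":
        if n_buckets < 2:
            raise ConfigError("n_buckets must be >= 2")
        boundaries, counts = [], []
        for j, name in enumerate(table.feature_names):
            col = table.values[:, j]
            col = col[~np.isnan(col)]
            if col.size == 0:
                raise FitError(f"feature {name!r} has no observed values to fit on")
            qs = np.quantile(col, np.arange(1, n_buckets) / n_buckets)
            qs = np.unique(qs)  # ties collapse buckets
            if col.min() == col.max():
                qs = np.array([])  # constant feature -> single bucket
            boundaries.append(qs)
            counts.append(len(qs) + 1)
        return cls(table.feature_names, boundaries, counts)

    # ------------------------------------------------------------ transform
    def transform(self, table: FeatureTable) -> MappedTable:
        if list(table.feature_names) != self.feature_names:
            raise SchemaError(
                f"feature names do not match fitted mapper "
                f"(got {table.feature_names[:3]}..., expected {self.feature_names[:3]}...)"
            )
        n, f = table.values.shape
        mids = np.zeros((n, f))
        present = ~np.isnan(table.values)
        for j in range(f):
            col = table.values[:, j]
            obs = present[:, j]
            # searchsorted clamps out-of-range values into the extreme buckets;
            # a value exactly on a boundary falls in the lower bucket, so
            # heavily tied features keep their mass in one bucket
            k = np.searchsorted(self.boundaries[j], col[obs], side="left")
            mids[obs, j] = (k + 0.5) / self.n_buckets[j]
        return MappedTable(
            feature_names=list(table.feature_names),
            patient_ids=list(table.patient_ids),
            values=mids,
            present=present,
        )

    # ---------------------------------------------------------- persistence
    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "boundaries": [b.tolist() for b in self.boundaries],
                "n_buckets": self.n_buckets,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "HashMapper":
        d = json.loads(payload)
        return cls(d["feature_names"], [np.asarray(b) for b in d["boundaries"]], d["n_buckets"])


def fit_hash_mapper(table: FeatureTable, n_buckets: int = N_BUCKETS_DEFAULT) -> HashMapper:
    return HashMapper.fit(table, n_buckets)


def apply_hash_map(mapper: HashMapper, table: FeatureTable) -> MappedTable:
    return mapper.transform(table)


# --------------------------------------------------------------------- banks
class EncodingBank(Module):
    """Trainable per-feature encodings + per-feature affine + projection.

    Forward contract (B = batch, F = features, D = d_enc):
      contribution_f = present_f * (v_f * e_f) + (1 - present_f) * m_f
      h_f = ReLU(contribution_f @ W_f + b_f)        (per-feature affine)
      rep = ReLU(Linear(sum_f h_f))                 (projection to d_rep)

    The sum over features makes the representation invariant to feature
    column order, and the learned missing vectors m_f keep absent cells
    informative rather than imputed.
    """

    def __init__(
        self,
        feature_names: list[str],
        d_rep: int,
        rng: np.random.Generator,
        d_enc: int = D_ENC_DEFAULT,
        shared_affine: bool = False,
    ):
        super().__init__()
        self.feature_names = list(feature_names)
        f = len(self.feature_names)
        self.d_enc = d_enc
        self.d_rep = d_rep
        self.shared_affine = shared_affine
        scale = 1.0 / np.sqrt(d_enc)
        self.encodings = Tensor(rng.normal(0, scale, size=(f, d_enc)), requires_grad=True)
        self.missing_encodings = Tensor(np.zeros((f, d_enc)), requires_grad=True)
        if shared_affine:
            # one weight matrix broadcast over features
            self.affine_w = Tensor(rng.normal(0, scale, size=(1, d_enc, d_enc)), requires_grad=True)
            self.affine_b = Tensor(np.zeros((1, d_enc)), requires_grad=True)
        else:
            self.affine_w = Tensor(rng.normal(0, scale, size=(f, d_enc, d_enc)), requires_grad=True)
            self.affine_b = Tensor(np.zeros((f, d_enc)), requires_grad=True)
        self.proj = Linear(d_enc, d_rep, rng)

    def __call__(self, values: Tensor, present: Tensor) -> Tensor:
        """values, present: (B, F) tensors -> (B, d_rep) representation."""
        b, f = values.shape
        if f != len(self.feature_names):
            raise SchemaError(f"bank covers {len(self.feature_names)} features, got {f}")
        v = values.reshape(b, f, 1)
        u = present.reshape(b, f, 1)
        scaled = v * self.encodings  # (B,F,D) broadcast
        missing = (1.0 - u) * self.missing_encodings
        contrib = u * scaled + missing
        if self.shared_affine:
            h = (contrib @ self.affine_w.reshape(self.d_enc, self.d_enc)) + self.affine_b.reshape(1, 1, self.d_enc)
        else:
            h = feature_affine(contrib, self.affine_w, self.affine_b)
        h = h.relu()
        pooled = h.sum(axis=1)  # order-invariant aggregation over features
        return self.proj(pooled).relu()


class PlainTabularEncoder(Module):
    """Two-layer feedforward encoder for the raw / hashed-only pathways.

    Input is the feature vector concatenated with its presence mask, so
    the ablation pathways see the same missingness information as the
    encoding-training pathway.
    """

    def __init__(self, n_features: int, d_rep: int, rng: np.random.Generator, hidden: int = 32):
        super().__init__()
        self.n_features = n_features
        self.net = MLP([2 * n_features, hidden, d_rep], rng, final_relu=True)

    def __call__(self, values: Tensor, present: Tensor) -> Tensor:
        from .nn import concat

        if values.shape[1] != self.n_features:
            raise SchemaError(f"encoder covers {self.n_features} features, got {values.shape[1]}")
        return self.net(concat([values, present], axis=1))


# ---------------------------------------------------- operation-style facade
def encode_modality(mapped: MappedTable, bank: EncodingBank) -> np.ndarray:
    """Encoding-training pathway representation for each patient row."""
    if mapped.feature_names != bank.feature_names:
        raise SchemaError("mapped table features do not match encoding bank")
    out = bank(Tensor(mapped.values), Tensor(mapped.present.astype(np.float64)))
    return out.data


def encode_modality_raw(
    values: np.ndarray, present: np.ndarray, encoder: PlainTabularEncoder,
    mean: np.ndarray, std: np.ndarray,
) -> np.ndarray:
    """Raw-data ablation: standardized values (missing -> 0) + mask -> MLP."""
    std = np.where(std == 0, 1.0, std)
    z = np.where(present, (values - mean) / std, 0.0)
    return encoder(Tensor(z), Tensor(present.astype(np.float64))).data


def encode_modality_hashed_only(mapped: MappedTable, encoder: PlainTabularEncoder) -> np.ndarray:
    """Hash-mapping ablation: bucket midpoints (missing -> 0) + mask -> MLP."""
    v = np.where(mapped.present, mapped.values, 0.0)
    return encoder(Tensor(v), Tensor(mapped.present.astype(np.float64))).data
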