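"""Training loop, stratified five-fold cross-validation and metrics.

Fold hygiene: hash mappers (quantile boundaries), raw-pathway
standardization constants and tile normalization statistics are fitted on
the training fold only and frozen before the test fold is touched; each
fitted preprocessor records the patient IDs it saw, so leakage is
checkable after the fact. Training is fully seeded — model init, batch
order and the internal early-stopping split all derive from the config
seed — so a rerun reproduces the CVResult bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split

from .data import Cohort, FeatureTable
from .errors import ConfigError, FlexError
from .fet import HashMapper, MappedTable
from .images import tile_normalization_stats, normalize_tiles
from .model import FlexModel, ModelInputs, ModelSpec
from .nn import Adam, bce_with_logits

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "CVResult",
    "train",
    "cross_validate",
    "compute_metrics",
    "deduplicate_records",
]

METRIC_NAMES = ("auroc", "auprc", "accuracy", "sensitivity", "specificity", "f1")


@dataclass
class TrainConfig:
    epochs: int = 40
    batch_size: int = 32
    lr: float = 3e-3
    weight_decay: float = 1e-3  # decoupled; tames tile-memorization overfit
    seed: int = 0
    fusion: str = "concatenation"
    modalities: tuple[str, ...] = ("C", "P", "M", "I")
    pathway: str = "encoded"  # raw | hashed | encoded
    backbone: str = "tiny_cnn"
    pooling: str = "mean"
    d_rep: int = 32
    d_enc: int = 10
    n_buckets: int = 16
    classifier_hidden: int = 64
    dropout: float = 0.0  # fused-vector dropout during training
    augment_tiles: bool = True  # random dihedral (flip/rot90) tile augmentation
    use_meta: bool = True
    meta_weight: float = 0.5  # weight of the Meta reconstruction loss
    early_stopping: bool = True
    val_fraction: float = 0.2
    patience: int = 8
    min_epochs: int = 12  # burn-in before early stopping may trigger

    def validate(self) -> None:
        if self.epochs < 0 or self.batch_size <= 0 or self.lr < 0:
            raise ConfigError("epochs/batch_size/lr must be non-negative (batch_size positive)")
        if self.n_buckets < 2:
            raise ConfigError("n_buckets must be >= 2")


@dataclass
class Preprocessors:
    """Fold-fitted state; records which patients it was fitted on."""

    mappers: dict[str, HashMapper]
    raw_mean: dict[str, np.ndarray]
    raw_std: dict[str, np.ndarray]
    tile_mean: np.ndarray
    tile_std: np.ndarray
    fitted_on: set[str]


def fit_preprocessors(cohort: Cohort, train_idx: np.ndarray, config: TrainConfig) -> Preprocessors:
    """Fit quantile mappers / standardization on the training fold only."""
    train_ids = {cohort.patients[i].patient_id for i in train_idx}
    mappers, rmean, rstd = {}, {}, {}
    for m, table in cohort.tables.items():
        if m not in config.modalities:
            continue
        rows = [i for i, pid in enumerate(table.patient_ids) if pid in train_ids]
        sub = FeatureTable(
            modality_id=m,
            patient_ids=[table.patient_ids[i] for i in rows],
            feature_names=list(table.feature_names),
            values=table.values[rows],
        )
        mappers[m] = HashMapper.fit(sub, config.n_buckets)
        with np.errstate(all="ignore"):
            rmean[m] = np.nanmean(sub.values, axis=0)
            rstd[m] = np.nanstd(sub.values, axis=0)
        rmean[m] = np.nan_to_num(rmean[m])
        rstd[m] = np.where(np.nan_to_num(rstd[m]) == 0, 1.0, np.nan_to_num(rstd[m]))
    if "I" in config.modalities and cohort.images:
        train_sets = [s for pid, s in cohort.images.items() if pid in train_ids]
        tmean, tstd = tile_normalization_stats(train_sets)
    else:
        tmean, tstd = np.zeros(3), np.ones(3)
    return Preprocessors(mappers, rmean, rstd, tmean, tstd, fitted_on=train_ids)


def prepare_inputs(cohort: Cohort, prep: Preprocessors, config: TrainConfig) -> ModelInputs:
    """Numeric batch for the whole cohort under the fitted preprocessors."""
    pids = cohort.patient_ids
    index = {pid: i for i, pid in enumerate(pids)}
    values, present = {}, {}
    for m in config.modalities:
        if m == "I" or m not in cohort.tables:
            continue
        table = cohort.tables[m]
        nf = len(table.feature_names)
        vals = np.zeros((len(pids), nf))
        pres = np.zeros((len(pids), nf), dtype=bool)
        if config.pathway == "raw":
            z = np.where(
                np.isnan(table.values), 0.0,
                (np.nan_to_num(table.values) - prep.raw_mean[m]) / prep.raw_std[m],
            )
            cell_present = ~np.isnan(table.values)
        else:
            mapped: MappedTable = prep.mappers[m].transform(table)
            z = np.where(mapped.present, mapped.values, 0.0)
            cell_present = mapped.present
        for r, pid in enumerate(table.patient_ids):
            i = index[pid]
            vals[i] = z[r]
            pres[i] = cell_present[r]
        values[m] = vals
        present[m] = pres

    tiles = image_present = None
    if "I" in config.modalities:
        sets = [cohort.images.get(pid) for pid in pids]
        image_present = np.array([s is not None for s in sets])
        shapes = {s.tile_shape for s in sets if s is not None}
        if shapes:
            if len(shapes) != 1:
                raise ConfigError(f"tiles must share one shape across the cohort, got {shapes}")
            h, w, _ = shapes.pop()
            n_tiles = max(len(s.tiles) for s in sets if s is not None)
            tiles = np.zeros((len(pids), n_tiles, 3, h, w))
            for i, s in enumerate(sets):
                if s is None:
                    continue
                arr = np.stack([s.tiles[k % len(s.tiles)] for k in range(n_tiles)])
                tiles[i] = normalize_tiles(arr, prep.tile_mean, prep.tile_std)
        else:
            image_present = np.zeros(len(pids), dtype=bool)

    return ModelInputs(patient_ids=list(pids), values=values, present=present,
                       tiles=tiles, image_present=image_present)


def _model_spec(cohort: Cohort, config: TrainConfig) -> ModelSpec:
    names = {
        m: list(cohort.tables[m].feature_names)
        for m in config.modalities
        if m != "I" and m in cohort.tables
    }
    mods = tuple(m for m in config.modalities if m == "I" or m in names)
    return ModelSpec(
        modalities=mods,
        feature_names=names,
        pathway=config.pathway,
        d_rep=config.d_rep,
        d_enc=config.d_enc,
        fusion=config.fusion,
        classifier_hidden=config.classifier_hidden,
        backbone=config.backbone,
        pooling=config.pooling,
        use_meta=config.use_meta,
        dropout=config.dropout,
    )


@dataclass
class TrainedModel:
    model: FlexModel
    prep: Preprocessors
    config: TrainConfig
    history: list[dict] = field(default_factory=list)

    def predict_proba(self, cohort: Cohort, replace_missing: str = "meta") -> np.ndarray:
        batch = prepare_inputs(cohort, self.prep, self.config)
        return self.model.predict_proba(batch, replace_missing=replace_missing)

    def inputs(self, cohort: Cohort) -> ModelInputs:
        return prepare_inputs(cohort, self.prep, self.config)


def train(cohort: Cohort, config: TrainConfig, train_idx: np.ndarray | None = None) -> TrainedModel:
    """Fit the end-to-end model on ``cohort`` (optionally a subset of rows)."""
    config.validate()
    if train_idx is None:
        train_idx = np.arange(len(cohort))
    train_idx = np.asarray(train_idx)
    labels = cohort.labels[train_idx]
    if len(np.unique(labels)) < 2:
        raise ConfigError("training split contains a single class; cannot fit a classifier")

    rng = np.random.default_rng(config.seed)
    prep = fit_preprocessors(cohort, train_idx, config)
    all_inputs = prepare_inputs(cohort, prep, config)
    spec = _model_spec(cohort, config)
    model = FlexModel(spec, rng)

    fit_idx, val_idx = train_idx, None
    if config.early_stopping and len(train_idx) >= 20:
        fit_idx, val_idx = train_test_split(
            train_idx, test_size=config.val_fraction, stratify=labels,
            random_state=int(rng.integers(2**31 - 1)),
        )
        if len(np.unique(cohort.labels[fit_idx])) < 2:
            fit_idx, val_idx = train_idx, None

    opt = Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    y = cohort.labels.astype(np.float64)
    history: list[dict] = []
    best_val, best_state, since_best = -np.inf, None, 0

    for epoch in range(config.epochs):
        model.train()
        order = np.array(fit_idx, copy=True)
        rng.shuffle(order)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = all_inputs.select(idx)
            if config.augment_tiles and batch.tiles is not None:
                batch.tiles = _dihedral_augment(batch.tiles, rng)
            logits, aux = model.forward(batch, replace_missing="meta")
            loss = bce_with_logits(logits, y[idx].reshape(-1, 1))
            if aux["recon_loss"] is not None and config.meta_weight > 0:
                loss = loss + aux["recon_loss"] * config.meta_weight
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        entry = {"epoch": epoch, "loss": epoch_loss / max(n_batches, 1)}
        if val_idx is not None:
            val_probs = model.predict_proba(all_inputs.select(np.asarray(val_idx)))
            entry["val_auroc"] = float(roc_auc_score(cohort.labels[val_idx], val_probs))
            # validation AUROC is noisy before the model starts learning, so
            # best-state tracking (and hence stopping) begins after a burn-in
            if epoch >= config.min_epochs:
                if entry["val_auroc"] > best_val + 1e-12:
                    best_val, best_state, since_best = entry["val_auroc"], model.state_dict(), 0
                else:
                    since_best += 1
        history.append(entry)
        if val_idx is not None and since_best >= config.patience:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return TrainedModel(model=model, prep=prep, config=config, history=history)


def _dihedral_augment(tiles: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random flip/90-degree rotation per tile (the 8 dihedral symmetries)."""
    b, t = tiles.shape[:2]
    out = tiles.copy()
    ks = rng.integers(0, 4, size=(b, t))
    flips = rng.random((b, t)) < 0.5
    for i in range(b):
        for j in range(t):
            tile = out[i, j]
            if ks[i, j]:
                tile = np.rot90(tile, k=int(ks[i, j]), axes=(1, 2))
            if flips[i, j]:
                tile = tile[:, :, ::-1]
            out[i, j] = tile
    return out


# --------------------------------------------------------------------- CV
@dataclass
class CVResult:
    fold_scores: list[np.ndarray]
    fold_labels: list[np.ndarray]
    fold_patients: list[list[str]]
    fold_metrics: list[dict[str, float]]
    fold_assignment: dict[str, int]
    config: TrainConfig

    @property
    def mean_metrics(self) -> dict[str, float]:
        return {k: float(np.mean([m[k] for m in self.fold_metrics])) for k in METRIC_NAMES}

    @property
    def std_metrics(self) -> dict[str, float]:
        return {k: float(np.std([m[k] for m in self.fold_metrics])) for k in METRIC_NAMES}

    def metrics_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fold_metrics)
        df.index.name = "fold"
        return df

    def pooled_scores(self) -> tuple[np.ndarray, np.ndarray]:
        return np.concatenate(self.fold_scores), np.concatenate(self.fold_labels)


def cross_validate(cohort: Cohort, config: TrainConfig, k: int = 5) -> CVResult:
    """Label-stratified k-fold CV; every patient tested exactly once."""
    n = len(cohort)
    if k > n:
        raise ConfigError(f"k={k} exceeds cohort size {n}")
    labels = cohort.labels
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ConfigError(f"both classes need >= k={k} members, got {counts.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    fold_scores, fold_labels, fold_patients, fold_metrics = [], [], [], []
    assignment: dict[str, int] = {}
    for fold, (tr, te) in enumerate(skf.split(np.zeros(n), labels)):
        fitted = train(cohort, replace(config, seed=config.seed + 1000 * fold), train_idx=tr)
        test_cohort_idx = np.asarray(te)
        probs = fitted.model.predict_proba(fitted.inputs(cohort).select(test_cohort_idx))
        fold_scores.append(probs)
        fold_labels.append(labels[te])
        pids = [cohort.patients[i].patient_id for i in te]
        fold_patients.append(pids)
        for pid in pids:
            assignment[pid] = fold
        fold_metrics.append(compute_metrics(probs, labels[te]))
    return CVResult(fold_scores, fold_labels, fold_patients, fold_metrics, assignment, config)


# ---------------------------------------------------------------- metrics
def compute_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> dict[str, float]:
    """The six-metric panel: AUROC, AUPRC, accuracy, sensitivity, specificity, F1."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape:
        raise ConfigError("scores and labels must align")
    if len(np.unique(labels)) < 2:
        raise FlexError("AUROC undefined: labels contain a single class")
    pred = (scores >= threshold).astype(int)
    return {
        "auroc": float(roc_auc_score(labels, scores)),
        "auprc": float(average_precision_score(labels, scores)),
        "accuracy": float(accuracy_score(labels, pred)),
        "sensitivity": float(recall_score(labels, pred, pos_label=1, zero_division=0)),
        "specificity": float(recall_score(labels, pred, pos_label=0, zero_division=0)),
        "f1": float(f1_score(labels, pred, zero_division=0)),
    }


# ------------------------------------------------------------- dedup utility
def deduplicate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Resolve duplicate patient rows before CV.

    Policy: among a patient's duplicate records, progression-group rows
    (label == 1) win; ties break toward the earliest acquisition_time.
    Expects columns patient_id, label and optionally acquisition_time.
    """
    if "patient_id" not in records or "label" not in records:
        raise ConfigError("records need patient_id and label columns")
    df = records.copy()
    if "acquisition_time" not in df:
        df["acquisition_time"] = 0
    df = df.sort_values(
        ["patient_id", "label", "acquisition_time"], ascending=[True, False, True], kind="mergesort"
    )
    return df.drop_duplicates("patient_id", keep="first").reset_index(drop=True)
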