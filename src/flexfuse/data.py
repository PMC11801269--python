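"""Domain types and file IO: feature tables, image tile sets, cohorts.

Tabular modalities travel as :class:`FeatureTable` (patients x named
features, missing cells as NaN sentinels — never silently zero-filled).
Pathology tiles travel as :class:`ImageSet` per patient, read from a
manifest CSV. :func:`assemble_cohort` aligns everything by patient ID and
records per-modality presence flags; patients lacking a modality are kept
(the Meta module handles them downstream).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import AlignmentError, MissingLabelError, ParseError

TABULAR_MODALITIES = ("C", "P", "M")
MODALITIES = ("C", "P", "M", "I")  # fixed order, also the concatenation order


@dataclass
class FeatureTable:
    """One tabular modality: ordered patients x ordered named features."""

    modality_id: str
    patient_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # float matrix, NaN marks a missing cell

    def __post_init__(self) -> None:
        if self.modality_id not in TABULAR_MODALITIES:
            raise ValueError(f"modality_id must be one of {TABULAR_MODALITIES}, got {self.modality_id!r}")
        self.patient_ids = [str(p).strip() for p in self.patient_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(set(self.feature_names)) != len(self.feature_names):
            raise AlignmentError(f"duplicate feature names in modality {self.modality_id}")
        dupes = {p for p in self.patient_ids if self.patient_ids.count(p) > 1}
        if dupes:
            raise AlignmentError(f"duplicate patient IDs in modality {self.modality_id}: {sorted(dupes)}")
        if self.values.shape != (len(self.patient_ids), len(self.feature_names)):
            raise AlignmentError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.feature_names)} features"
            )

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def row(self, patient_id: str) -> np.ndarray:
        return self.values[self.patient_ids.index(patient_id)]

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.modality_id == other.modality_id
            and self.patient_ids == other.patient_ids
            and self.feature_names == other.feature_names
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass
class ImageSet:
    """All pathology tiles for one patient (uniform tile shape)."""

    patient_id: str
    tiles: list[np.ndarray]  # each H x W x 3, uint8
    magnification_tag: str = "20x"

    def __post_init__(self) -> None:
        self.patient_id = str(self.patient_id).strip()
        if not self.tiles:
            raise ValueError(f"ImageSet for {self.patient_id} must contain at least one tile")
        shapes = {t.shape for t in self.tiles}
        if len(shapes) != 1:
            raise ValueError(f"tiles for {self.patient_id} have mixed shapes: {shapes}")

    @property
    def tile_shape(self) -> tuple[int, ...]:
        return self.tiles[0].shape


@dataclass
class PatientRecord:
    patient_id: str
    label: int
    presence: dict[str, bool]  # over MODALITIES


@dataclass
class Cohort:
    """Aligned multi-modal cohort with binary labels and presence flags."""

    patients: list[PatientRecord]
    tables: dict[str, FeatureTable] = field(default_factory=dict)
    images: dict[str, ImageSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rec in self.patients:
            if rec.label not in (0, 1):
                raise ValueError(f"label for {rec.patient_id} must be 0 or 1")
            if not any(rec.presence.get(m, False) for m in MODALITIES):
                raise ValueError(f"patient {rec.patient_id} has no modality present")

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.patients], dtype=np.int64)

    def presence_matrix(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[p.presence.get(m, False) for m in MODALITIES] for p in self.patients],
            index=self.patient_ids,
            columns=list(MODALITIES),
        )

    def modalities_present(self) -> list[str]:
        pm = self.presence_matrix()
        return [m for m in MODALITIES if pm[m].any()]

    def subset(self, indices: Sequence[int]) -> "Cohort":
        keep = [self.patients[i] for i in indices]
        ids = {p.patient_id for p in keep}
        tables = {}
        for m, t in self.tables.items():
            rows = [i for i, pid in enumerate(t.patient_ids) if pid in ids]
            tables[m] = FeatureTable(
                modality_id=m,
                patient_ids=[t.patient_ids[i] for i in rows],
                feature_names=list(t.feature_names),
                values=t.values[rows],
            )
        images = {pid: s for pid, s in self.images.items() if pid in ids}
        return Cohort(patients=keep, tables=tables, images=images)


# ----------------------------------------------------------------- tabular IO
def load_feature_table(path: str | os.PathLike, modality_id: str) -> FeatureTable:
    """Read a CSV/TSV feature table (first column ``patient_id``).

    Empty cells become NaN sentinels; any other non-numeric cell raises
    :class:`ParseError` with its row/column location.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2 or df.columns[0] != "patient_id":
        raise ParseError(f"{path}: first column must be 'patient_id'")
    patient_ids = [s.strip() for s in df.iloc[:, 0]]
    feature_names = list(df.columns[1:])
    values = np.full((len(patient_ids), len(feature_names)), np.nan)
    for j, col in enumerate(feature_names):
        for i, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} at row {i + 2}, column {col!r}"
                ) from None
    return FeatureTable(modality_id=modality_id, patient_ids=patient_ids, feature_names=feature_names, values=values)


def write_feature_table(table: FeatureTable, path: str | os.PathLike) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df.insert(0, "patient_id", table.patient_ids)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g", na_rep="")


def load_labels(path: str | os.PathLike) -> dict[str, int]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    if list(df.columns[:2]) != ["patient_id", "label"]:
        raise ParseError(f"{path}: expected columns patient_id,label")
    labels = {}
    for _, row in df.iterrows():
        pid = str(row["patient_id"]).strip()
        if pid in labels:
            raise AlignmentError(f"duplicate patient ID in labels: {pid}")
        labels[pid] = int(row["label"])
    return labels


def write_labels(labels: Mapping[str, int], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"patient_id": list(labels.keys()), "label": list(labels.values())}
    ).to_csv(path, index=False)


# ------------------------------------------------------------------- image IO
def load_image_sets(manifest_path: str | os.PathLike) -> dict[str, ImageSet]:
    """Read tiles from a manifest CSV (patient_id, tile_path, magnification_tag).

    Tile paths are resolved relative to the manifest's directory. PNG and
    TIFF tiles are accepted (anything Pillow can decode to RGB).
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    df = pd.read_csv(manifest_path, dtype=str)
    required = {"patient_id", "tile_path", "magnification_tag"}
    if not required.issubset(df.columns):
        raise ParseError(f"{manifest_path}: manifest needs columns {sorted(required)}")
    sets: dict[str, ImageSet] = {}
    grouped: dict[str, list[tuple[str, str]]] = {}
    for _, row in df.iterrows():
        pid = str(row["patient_id"]).strip()
        grouped.setdefault(pid, []).append((row["tile_path"], row["magnification_tag"]))
    for pid, entries in grouped.items():
        tiles = []
        tag = entries[0][1]
        for rel, _ in entries:
            with Image.open(root / rel) as im:
                tiles.append(np.asarray(im.convert("RGB"), dtype=np.uint8))
        sets[pid] = ImageSet(patient_id=pid, tiles=tiles, magnification_tag=tag)
    return sets


def write_image_sets(sets: Mapping[str, ImageSet], out_dir: str | os.PathLike) -> pd.DataFrame:
    """Write tiles as PNGs in per-patient subdirectories; return the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid in sorted(sets):
        s = sets[pid]
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        for k, tile in enumerate(s.tiles):
            rel = f"{pid}/tile_{k:03d}.png"
            Image.fromarray(tile).save(out_dir / rel)
            rows.append({"patient_id": pid, "tile_path": rel, "magnification_tag": s.magnification_tag})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


# ------------------------------------------------------------ cohort assembly
def assemble_cohort(
    tables: Iterable[FeatureTable],
    images: Mapping[str, ImageSet] | None,
    labels: Mapping[str, int],
) -> Cohort:
    """Align modalities by exact (whitespace-stripped) patient ID.

    Every patient appearing in any modality must have a label; patients
    lacking a modality are retained with that presence flag false.
    """
    tables = list(tables)
    images = dict(images or {})
    by_mod: dict[str, FeatureTable] = {}
    for t in tables:
        if t.modality_id in by_mod:
            raise AlignmentError(f"two tables share modality {t.modality_id}")
        by_mod[t.modality_id] = t

    labels = {str(k).strip(): int(v) for k, v in labels.items()}
    all_ids: list[str] = []
    seen: set[str] = set()
    for t in tables:
        for pid in t.patient_ids:
            if pid not in seen:
                seen.add(pid)
                all_ids.append(pid)
    for pid in images:
        if pid not in seen:
            seen.add(pid)
            all_ids.append(pid)

    unlabeled = [pid for pid in all_ids if pid not in labels]
    if unlabeled:
        raise MissingLabelError(f"patients with data but no label: {sorted(unlabeled)}")

    # canonical patient order: sorted IDs, so assembly is input-order independent
    all_ids = sorted(all_ids)
    patients = []
    for pid in all_ids:
        presence = {m: (m in by_mod and pid in by_mod[m].patient_ids) for m in TABULAR_MODALITIES}
        presence["I"] = pid in images
        patients.append(PatientRecord(patient_id=pid, label=labels[pid], presence=presence))

    # reorder table rows to canonical order (patients absent from a table are skipped)
    aligned_tables = {}
    for m, t in by_mod.items():
        order = [t.patient_ids.index(pid) for pid in all_ids if pid in t.patient_ids]
        aligned_tables[m] = FeatureTable(
            modality_id=m,
            patient_ids=[t.patient_ids[i] for i in order],
            feature_names=list(t.feature_names),
            values=t.values[order],
        )
    return Cohort(patients=patients, tables=aligned_tables, images=images)


def load_cohort(directory: str | os.PathLike) -> Cohort:
    """Load a cohort from the standard on-disk layout (see write_cohort)."""
    directory = Path(directory)
    tables = []
    for m, fname in (("C", "clinical.csv"), ("P", "proteomics.csv"), ("M", "metabolomics.csv")):
        f = directory / fname
        if f.exists():
            tables.append(load_feature_table(f, m))
    manifest = directory / "images" / "manifest.csv"
    images = load_image_sets(manifest) if manifest.exists() else {}
    labels = load_labels(directory / "labels.csv")
    return assemble_cohort(tables, images, labels)
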