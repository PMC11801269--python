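"""Synthetic multi-modal cohort generator with planted, recoverable signal.

The generator emulates the distributional structure of a multi-modal
kidney-disease cohort: clinical features are a mix of binary indicators
(comorbidities, medication history) and Gaussian laboratory values, while
proteomic and metabolomic intensities are long-tailed (log-normal). A
binary three-year progression label is drawn from a logistic model over a
chosen subset of "informative" features, with the intercept calibrated so
that label prevalence matches a target (default 0.41, a realistic
progression fraction for such cohorts). Progression patients' pathology
tiles carry a bright ellipsoidal lesion blob with probability
``lesion_signal`` on a textured background.

Everything is driven by a single seed and the planted ground truth
(informative feature names, effect sizes, per-tile lesion ellipses) is
returned alongside the cohort and serialized to ``truth.json``, so
attribution-recovery and localization experiments can score themselves.
"""

from __future__ import annotations

import json
import os
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.ndimage import gaussian_filter

from .data import (
    Cohort,
    FeatureTable,
    ImageSet,
    assemble_cohort,
    write_feature_table,
    write_image_sets,
    write_labels,
)
from .errors import ConfigError

__all__ = ["SimConfig", "generate_cohort", "write_cohort", "lesion_mask"]


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort; defaults give a desk-scale cohort."""

    n_patients: int = 259
    n_features: dict[str, int] = field(default_factory=lambda: {"C": 20, "P": 40, "M": 40})
    informative: dict[str, int] = field(default_factory=lambda: {"C": 5, "P": 5, "M": 5})
    effect_size: float = 1.0  # log-odds per SD of each informative feature
    prevalence: float = 0.41  # calibrated target label prevalence
    tile_size: int = 64
    tiles_per_patient: int = 4
    lesion_signal: float = 0.0  # P(lesion blob | progression) per tile
    missing_rate: dict[str, float] = field(default_factory=lambda: {"C": 0.0, "P": 0.0, "M": 0.0, "I": 0.0})
    cell_missing_rate: float = 0.0  # element-wise missingness within tabular rows
    outlier_rate: float = 0.0  # long-tailed cells multiplied by outlier_scale
    outlier_scale: float = 100.0
    # loading of a shared latent patient factor on continuous features across
    # modalities; >0 induces the cross-modal correlation real cohorts show
    # (kidney-function covariates co-vary with urine omics), which is what
    # makes missing-modality imputation possible at all
    shared_factor: float = 0.0
    modalities: tuple[str, ...] = ("C", "P", "M", "I")
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        for m in self.modalities:
            if m not in ("C", "P", "M", "I"):
                raise ConfigError(f"unknown modality {m!r}")
        for m, n in self.n_features.items():
            if n <= 0:
                raise ConfigError(f"n_features[{m}] must be positive")
            if self.informative.get(m, 0) > n:
                raise ConfigError(f"informative[{m}] exceeds n_features[{m}]")
        rates = [self.lesion_signal, self.cell_missing_rate, self.outlier_rate, self.prevalence]
        rates += list(self.missing_rate.values())
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ConfigError("all rates must lie in [0, 1]")
        if self.tile_size < 16 or self.tiles_per_patient < 1:
            raise ConfigError("tile_size >= 16 and tiles_per_patient >= 1 required")


def _clinical_features(rng: np.random.Generator, n: int, n_feat: int,
                       z: np.ndarray, loading: float):
    """Half Bernoulli(p ~ U[0.1, 0.5]) indicators, half Gaussian labs.

    Gaussian labs optionally load (with random sign) on the shared latent
    patient factor ``z``.
    """
    n_bin = n_feat // 2
    probs = rng.uniform(0.1, 0.5, size=n_bin)
    binary = (rng.random((n, n_bin)) < probs).astype(np.float64)
    n_cont = n_feat - n_bin
    mus = rng.uniform(-1.0, 1.0, size=n_cont)
    sds = rng.uniform(0.5, 2.0, size=n_cont)
    signs = rng.choice([-1.0, 1.0], size=n_cont)
    gauss = rng.normal(mus, sds, size=(n, n_cont)) + loading * sds * (z[:, None] * signs[None, :])
    values = np.concatenate([binary, gauss], axis=1)
    kinds = ["binary"] * n_bin + ["gaussian"] * n_cont
    meta = {"bernoulli_p": probs.tolist()}
    return values, kinds, meta


def _longtail_features(rng: np.random.Generator, n: int, n_feat: int,
                       z: np.ndarray, loading: float):
    """Per-feature scaled log-normal intensities (long-tailed).

    The shared factor enters in log-space (multiplicatively), preserving
    the long tail.
    """
    scales = 10.0 ** rng.uniform(-1.0, 2.0, size=n_feat)
    signs = rng.choice([-1.0, 1.0], size=n_feat)
    logs = rng.normal(0.0, 1.0, size=(n, n_feat)) + loading * (z[:, None] * signs[None, :])
    values = np.exp(logs) * scales
    return values, ["lognormal"] * n_feat, {"scales": scales.tolist()}


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


def lesion_mask(tile_size: int, params: dict) -> np.ndarray:
    """Boolean mask of the ellipse described by lesion parameters."""
    yy, xx = np.mgrid[0:tile_size, 0:tile_size].astype(np.float64)
    cy, cx = params["center"]
    a, b = params["axes"]
    theta = params["angle"]
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _sample_ellipse(rng: np.random.Generator, tile_size: int) -> dict:
    margin = tile_size // 4
    a = rng.uniform(0.14, 0.26) * tile_size
    b = a * rng.uniform(0.6, 1.0)  # randomized eccentricity
    return {
        "center": [float(rng.uniform(margin, tile_size - margin)) for _ in range(2)],
        "axes": [float(a), float(b)],
        "angle": float(rng.uniform(0, np.pi)),
    }


def _render_tile(rng: np.random.Generator, tile_size: int, ellipse: dict | None) -> np.ndarray:
    """Textured grey background; optional bright lesion blob."""
    noise = rng.normal(0.0, 1.0, size=(tile_size, tile_size))
    texture = gaussian_filter(noise, sigma=2.0)
    texture = 30.0 * texture / max(texture.std(), 1e-9)
    base = 110.0 + texture
    if ellipse is not None:
        mask = lesion_mask(tile_size, ellipse)
        base = np.where(mask, 205.0 + 6.0 * rng.standard_normal((tile_size, tile_size)), base)
    tile = np.clip(base, 0, 255).astype(np.uint8)
    return np.stack([tile, tile, tile], axis=-1)


def generate_cohort(config: SimConfig) -> tuple[Cohort, dict]:
    """Draw a cohort plus its planted-signal ground truth ("truth" dict)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pids = [f"SYN{i:05d}" for i in range(n)]

    tabular = [m for m in ("C", "P", "M") if m in config.modalities]
    raw: dict[str, np.ndarray] = {}
    feature_names: dict[str, list[str]] = {}
    kinds: dict[str, list[str]] = {}
    gen_meta: dict[str, dict] = {}
    prefix = {"C": "clin", "P": "prot", "M": "met"}
    z = rng.normal(size=n)  # shared latent patient factor
    for m in tabular:
        nf = config.n_features[m]
        if m == "C":
            vals, kds, meta = _clinical_features(rng, n, nf, z, config.shared_factor)
        else:
            vals, kds, meta = _longtail_features(rng, n, nf, z, config.shared_factor)
        raw[m] = vals
        kinds[m] = kds
        gen_meta[m] = meta
        feature_names[m] = [f"{prefix[m]}_{k:03d}" for k in range(nf)]

    # latent logistic signal over standardized informative features
    linear = np.zeros(n)
    informative: dict[str, list[str]] = {}
    for m in tabular:
        k = config.informative.get(m, 0)
        informative[m] = feature_names[m][:k]
        if k:
            linear += config.effect_size * _standardize(raw[m][:, :k]).sum(axis=1)

    if np.allclose(linear, linear[0]):
        intercept = float(np.log(config.prevalence / (1.0 - config.prevalence)))
    else:
        def gap(b: float) -> float:
            return float(np.mean(1.0 / (1.0 + np.exp(-(linear + b)))) - config.prevalence)

        intercept = float(brentq(gap, -50.0, 50.0))
    probs = 1.0 / (1.0 + np.exp(-(linear + intercept)))
    labels = (rng.random(n) < probs).astype(int)

    # images: every tile gets a candidate ellipse; only lesion tiles render it
    images: dict[str, ImageSet] = {}
    lesions: dict[str, list[dict]] = {}
    if "I" in config.modalities:
        for i, pid in enumerate(pids):
            tiles, tile_truth = [], []
            for _ in range(config.tiles_per_patient):
                candidate = _sample_ellipse(rng, config.tile_size)
                has_lesion = bool(labels[i] == 1 and rng.random() < config.lesion_signal)
                tiles.append(_render_tile(rng, config.tile_size, candidate if has_lesion else None))
                tile_truth.append({"lesion": has_lesion, "ellipse": candidate})
            images[pid] = ImageSet(patient_id=pid, tiles=tiles, magnification_tag="20x")
            lesions[pid] = tile_truth

    # element-wise missingness (sentinels, applied after label generation)
    for m in tabular:
        if config.cell_missing_rate > 0:
            drop = rng.random(raw[m].shape) < config.cell_missing_rate
            raw[m][drop] = np.nan

    # outlier contamination of long-tailed modalities (measurement artifact,
    # applied after label generation so it is pure noise)
    for m in ("P", "M"):
        if m in raw and config.outlier_rate > 0:
            hit = rng.random(raw[m].shape) < config.outlier_rate
            raw[m] = np.where(hit & ~np.isnan(raw[m]), raw[m] * config.outlier_scale, raw[m])

    # modality-level missingness, guaranteeing >=1 modality per patient
    present = {m: np.ones(n, dtype=bool) for m in config.modalities}
    for m in config.modalities:
        rate = config.missing_rate.get(m, 0.0)
        if rate > 0:
            present[m] = rng.random(n) >= rate
    for i in range(n):
        if not any(present[m][i] for m in config.modalities):
            keep = config.modalities[int(rng.integers(len(config.modalities)))]
            present[keep][i] = True

    tables = []
    for m in tabular:
        rows = np.where(present[m])[0]
        tables.append(
            FeatureTable(
                modality_id=m,
                patient_ids=[pids[i] for i in rows],
                feature_names=feature_names[m],
                values=raw[m][rows],
            )
        )
    if "I" in config.modalities:
        images = {pid: images[pid] for i, pid in enumerate(pids) if present["I"][i]}

    cohort = assemble_cohort(tables, images, dict(zip(pids, labels.tolist())))
    truth = {
        "seed": config.seed,
        "config": _config_to_json(config),
        "intercept": intercept,
        "effect_size": config.effect_size,
        "informative_features": informative,
        "feature_kinds": kinds,
        "generator_meta": gen_meta,
        "lesions": lesions,
        "prevalence_target": config.prevalence,
        "realized_prevalence": float(labels.mean()),
    }
    return cohort, truth


def _config_to_json(config: SimConfig) -> dict:
    d = asdict(config)
    d["modalities"] = list(config.modalities)
    return d


def config_from_json(d: dict) -> SimConfig:
    d = dict(d)
    d["modalities"] = tuple(d.get("modalities", ("C", "P", "M", "I")))
    return SimConfig(**d)


def write_cohort(cohort: Cohort, truth: dict, out_dir: str | os.PathLike, force: bool = False) -> dict:
    """Write the cohort in the standard file layout; returns a manifest dict.

    Refuses to overwrite an existing cohort directory unless ``force``.
    """
    out_dir = Path(out_dir)
    if (out_dir / "labels.csv").exists() and not force:
        raise FileExistsError(f"{out_dir} already contains a cohort (use force=True to overwrite)")
    if out_dir.exists() and force:
        shutil.rmtree(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fnames = {"C": "clinical.csv", "P": "proteomics.csv", "M": "metabolomics.csv"}
    written = []
    for m, table in cohort.tables.items():
        write_feature_table(table, out_dir / fnames[m])
        written.append(fnames[m])
    write_labels({p.patient_id: p.label for p in cohort.patients}, out_dir / "labels.csv")
    written.append("labels.csv")
    if cohort.images:
        write_image_sets(cohort.images, out_dir / "images")
        written.append("images/manifest.csv")
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    written.append("truth.json")
    return {"directory": str(out_dir), "files": written, "n_patients": len(cohort), "n_labels": len(cohort)}
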