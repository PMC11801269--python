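"""Integrated Gradients attribution and SCDA image heatmaps.

Integrated Gradients assigns each model input a contribution to the
predicted probability relative to a baseline x'::

    IG_i = (x_i - x'_i) * (1/K) * sum_{k=1..K} dF/dx_i |_{x' + (k/K)(x - x')}

computed here by differentiating the model graph at K points along the
straight-line path (a right-endpoint Riemann sum, so attributions sum to
F(x) - F(x') up to discretization error — the completeness axiom).

Attribution is computed at the model-input level: for a tabular modality
the inputs are the mapped scalar v_f and its presence indicator u_f, and a
feature's attribution is the sum of its v- and u-components; the baseline
(v'=0, u'=0) is the model's native "all information absent" point, i.e.
every feature at the missing bucket. For images the input is the
normalized tile tensor with an all-zero baseline. Meta-module routing is
a discrete mechanism and is excluded from the attribution path; missing
modalities are represented by the learned missing encodings instead.

SCDA: the tap-point feature map is summed over channels, thresholded at
its mean (strict inequality), and the largest 4-connected above-threshold
component becomes the region of interest; the channel-sum map is
upsampled bilinearly to tile resolution for red(strong)/blue(weak)
rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .data import Cohort
from .errors import ConfigError
from .images import ImageBranch
from .model import FlexModel, ModelInputs
from .nn import Tensor

__all__ = [
    "AttributionReport",
    "integrated_gradients",
    "integrated_gradients_fn",
    "modal_importance",
    "modal_importance_by_group",
    "rank_features",
    "Heatmap",
    "scda_from_map",
    "scda_heatmap",
    "render_heatmap",
    "mask_iou",
    "lesion_overlap_stats",
]


# ----------------------------------------------------------------- IG core
def integrated_gradients_fn(
    forward: Callable[[dict[str, Tensor]], Tensor],
    inputs: dict[str, np.ndarray],
    baselines: dict[str, np.ndarray],
    steps: int = 50,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Generic IG over named input arrays.

    ``forward`` maps named Tensors to a (B,) or (B,1) output. Returns
    (attributions per input name, F(x), F(x')). The first axis of every
    input is the batch axis.
    """
    if steps < 1:
        raise ConfigError("steps must be >= 1")
    keys = list(inputs)
    diffs = {k: inputs[k] - baselines[k] for k in keys}
    grad_sums = {k: np.zeros_like(inputs[k], dtype=np.float64) for k in keys}
    for k_step in range(1, steps + 1):
        alpha = k_step / steps
        tensors = {
            k: Tensor(baselines[k] + alpha * diffs[k], requires_grad=True) for k in keys
        }
        out = forward(tensors)
        out.backward(np.ones_like(out.data))  # per-sample grads: samples are independent
        for k in keys:
            if tensors[k].grad is not None:
                grad_sums[k] += tensors[k].grad
    attributions = {k: diffs[k] * grad_sums[k] / steps for k in keys}
    f_x = _eval(forward, inputs)
    f_base = _eval(forward, baselines)
    return attributions, f_x, f_base


def _eval(forward, arrays: dict[str, np.ndarray]) -> np.ndarray:
    out = forward({k: Tensor(v) for k, v in arrays.items()})
    return out.data.reshape(-1)


# ------------------------------------------------------------ model wrapper
@dataclass
class AttributionReport:
    """Per-patient IG attributions with population aggregation helpers."""

    patient_ids: list[str]
    labels: np.ndarray
    feature_names: dict[str, list[str]]  # tabular modalities
    tabular: dict[str, np.ndarray]  # modality -> (B, F) per-feature attributions
    image_abs_mean: np.ndarray | None  # (B,) mean |pixel attribution|
    image_total: np.ndarray | None  # (B,) summed pixel attribution
    image_maps: np.ndarray | None  # optional (B, T, 3, H, W)
    output_at_input: np.ndarray  # F(x), (B,)
    output_at_baseline: np.ndarray  # F(x'), (B,)
    steps: int = 50

    @property
    def total_attribution(self) -> np.ndarray:
        total = np.zeros(len(self.patient_ids))
        for attr in self.tabular.values():
            total += attr.sum(axis=1)
        if self.image_total is not None:
            total += self.image_total
        return total

    @property
    def completeness_gap(self) -> np.ndarray:
        """|sum(attr) - (F(x) - F(x'))| per patient (absolute)."""
        return np.abs(self.total_attribution - (self.output_at_input - self.output_at_baseline))

    def relative_completeness_gap(self) -> np.ndarray:
        denom = np.abs(self.output_at_input - self.output_at_baseline)
        return self.completeness_gap / np.where(denom < 1e-12, np.nan, denom)

    def aggregate_relative_gap(self) -> float:
        """Batch-level completeness: mean |gap| over mean |F(x) - F(x')|.

        Robust to individual patients whose prediction barely moves from
        the baseline (their per-patient relative gap is ill-conditioned).
        """
        denom = np.abs(self.output_at_input - self.output_at_baseline).mean()
        return float(self.completeness_gap.mean() / max(denom, 1e-12))


def integrated_gradients(
    model: FlexModel,
    batch: ModelInputs,
    steps: int = 50,
    labels: np.ndarray | None = None,
    keep_image_maps: bool = False,
    signed: bool = True,
) -> AttributionReport:
    """IG attributions for every patient in ``batch``."""
    model.eval()
    active = list(model.spec.modalities)
    inputs: dict[str, np.ndarray] = {}
    baselines: dict[str, np.ndarray] = {}
    for m in active:
        if m == "I":
            if batch.tiles is None:
                raise ConfigError("image modality active but no tiles in batch")
            inputs["I"] = batch.tiles
            baselines["I"] = np.zeros_like(batch.tiles)
        else:
            inputs[f"{m}:values"] = batch.values[m]
            inputs[f"{m}:present"] = batch.present[m].astype(np.float64)
            baselines[f"{m}:values"] = np.zeros_like(batch.values[m])
            baselines[f"{m}:present"] = np.zeros_like(batch.values[m])

    def forward(tensors: dict[str, Tensor]) -> Tensor:
        reps = model.modality_reps(batch, inputs_as_tensors=tensors)
        fused = model.fusion(reps)
        return model.head.logits(fused).sigmoid()

    attr, f_x, f_base = integrated_gradients_fn(forward, inputs, baselines, steps=steps)

    tabular = {}
    for m in active:
        if m == "I":
            continue
        a = attr[f"{m}:values"] + attr[f"{m}:present"]
        tabular[m] = a if signed else np.abs(a)
    image_abs_mean = image_total = image_maps = None
    if "I" in active:
        maps = attr["I"]
        image_abs_mean = np.abs(maps).mean(axis=tuple(range(1, maps.ndim)))
        image_total = maps.sum(axis=tuple(range(1, maps.ndim)))
        if keep_image_maps:
            image_maps = maps
    return AttributionReport(
        patient_ids=list(batch.patient_ids),
        labels=np.asarray(labels) if labels is not None else np.full(batch.n, -1),
        feature_names={m: list(model.spec.feature_names[m]) for m in active if m != "I"},
        tabular=tabular,
        image_abs_mean=image_abs_mean,
        image_total=image_total,
        image_maps=image_maps,
        output_at_input=f_x,
        output_at_baseline=f_base,
        steps=steps,
    )


# ------------------------------------------------------------- aggregation
def modal_importance(report: AttributionReport, use_abs: bool = True) -> pd.DataFrame:
    """Per-patient modality score: mean |attribution| over that modality's inputs."""
    cols = {}
    for m, attr in report.tabular.items():
        a = np.abs(attr) if use_abs else attr
        cols[m] = a.mean(axis=1)
    if report.image_abs_mean is not None:
        cols["I"] = report.image_abs_mean if use_abs else report.image_total
    return pd.DataFrame(cols, index=report.patient_ids)


def modal_importance_by_group(report: AttributionReport, use_abs: bool = True) -> pd.DataFrame:
    """Median modality scores for progression / non-progression / all."""
    scores = modal_importance(report, use_abs=use_abs)
    labels = pd.Series(report.labels, index=scores.index)
    rows = {
        "progression": scores[labels == 1].median(),
        "non_progression": scores[labels == 0].median(),
        "all": scores.median(),
    }
    return pd.DataFrame(rows).T


def rank_features(report: AttributionReport, modality: str, top: int | None = None) -> pd.DataFrame:
    """Features sorted by median |attribution| descending; ties break by name."""
    if modality not in report.tabular:
        raise ConfigError(f"no tabular attributions for modality {modality!r}")
    med = np.median(np.abs(report.tabular[modality]), axis=0)
    df = pd.DataFrame({"feature": report.feature_names[modality], "median_importance": med})
    df = df.sort_values(["median_importance", "feature"], ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    return df.head(top) if top else df


# -------------------------------------------------------------------- SCDA
FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class Heatmap:
    scores: np.ndarray  # (h, w) channel-sum at tap resolution
    threshold: float
    mask: np.ndarray  # (h, w) bool, largest 4-connected component
    scores_full: np.ndarray  # (H, W) bilinear upsample
    mask_full: np.ndarray  # (H, W) bool nearest upsample
    tile_shape: tuple[int, int]


def scda_from_map(fmap: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Channel sum -> mean threshold (strict) -> largest 4-connected component."""
    if fmap.ndim != 3:
        raise ConfigError(f"expected (C, h, w) feature map, got shape {fmap.shape}")
    scores = fmap.sum(axis=0)
    threshold = float(scores.mean())
    above = scores > threshold
    labeled, n = ndimage.label(above, structure=FOUR_CONN)
    if n == 0:
        return scores, threshold, np.zeros_like(above)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1  # argmax -> first (smallest label) on ties
    return scores, threshold, labeled == best


def _upsample_bilinear(a: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    h, w = a.shape
    rows = (np.arange(out_shape[0]) + 0.5) * h / out_shape[0] - 0.5
    cols = (np.arange(out_shape[1]) + 0.5) * w / out_shape[1] - 0.5
    grid = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(a, grid, order=1, mode="nearest")


def _upsample_nearest(mask: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    h, w = mask.shape
    r = np.minimum((np.arange(out_shape[0]) * h) // out_shape[0], h - 1)
    c = np.minimum((np.arange(out_shape[1]) * w) // out_shape[1], w - 1)
    return mask[np.ix_(r, c)]


def scda_heatmap(branch: ImageBranch, tile: np.ndarray, tile_mean: np.ndarray, tile_std: np.ndarray) -> Heatmap:
    """SCDA heatmap + ROI for one uint8 HWC tile."""
    from .images import feature_map as _feature_map

    fmap = _feature_map(tile, branch, tile_mean, tile_std)
    scores, threshold, mask = scda_from_map(fmap)
    out_shape = tile.shape[:2]
    return Heatmap(
        scores=scores,
        threshold=threshold,
        mask=mask,
        scores_full=_upsample_bilinear(scores, out_shape),
        mask_full=_upsample_nearest(mask, out_shape),
        tile_shape=out_shape,
    )


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks (0 if both empty)."""
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def render_heatmap(heatmap: Heatmap, tile: np.ndarray, path: str) -> None:
    """Overlay rendering: red = strong relevance, blue = weak; ROI outlined."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    axes[0].imshow(tile)
    axes[0].set_title("tile")
    s = heatmap.scores_full
    rng_ = s.max() - s.min()
    norm = (s - s.min()) / (rng_ if rng_ > 0 else 1.0)
    axes[1].imshow(tile)
    axes[1].imshow(norm, cmap="bwr", alpha=0.5, vmin=0, vmax=1)
    axes[1].set_title("heatmap")
    axes[2].imshow(tile)
    axes[2].contour(heatmap.mask_full.astype(float), levels=[0.5], colors="lime")
    axes[2].set_title("ROI")
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def lesion_overlap_stats(
    branch: ImageBranch,
    cohort: Cohort,
    truth: dict,
    patient_ids: list[str],
    tile_mean: np.ndarray,
    tile_std: np.ndarray,
    iou_threshold: float = 0.3,
) -> dict[str, float]:
    """Score SCDA ROIs against the generator's planted lesion ellipses.

    Lesion tiles are scored against the rendered ellipse; lesion-free
    tiles serve as negative controls, scored against the candidate
    ellipse the generator sampled but never rendered (so a hit there is
    pure chance alignment).
    """
    from .simulate import lesion_mask

    pos_hits, pos_total, neg_hits, neg_total = 0, 0, 0, 0
    pos_ious: list[float] = []
    for pid in patient_ids:
        if pid not in cohort.images or pid not in truth["lesions"]:
            continue
        image_set = cohort.images[pid]
        size = image_set.tile_shape[0]
        for tile, entry in zip(image_set.tiles, truth["lesions"][pid]):
            hm = scda_heatmap(branch, tile, tile_mean, tile_std)
            iou = mask_iou(hm.mask_full, lesion_mask(size, entry["ellipse"]))
            if entry["lesion"]:
                pos_total += 1
                pos_ious.append(iou)
                pos_hits += iou > iou_threshold
            else:
                neg_total += 1
                neg_hits += iou > iou_threshold
    return {
        "lesion_tiles": pos_total,
        "lesion_hit_rate": pos_hits / max(pos_total, 1),
        "median_lesion_iou": float(np.median(pos_ious)) if pos_ious else 0.0,
        "control_tiles": neg_total,
        "control_hit_rate": neg_hits / max(neg_total, 1),
    }


def heatmap_mosaic(heatmaps: list[Heatmap], n_cols: int) -> np.ndarray:
    """Stitch per-tile upsampled score maps into one slide-level array."""
    if not heatmaps:
        raise ConfigError("no heatmaps to stitch")
    n_rows = int(np.ceil(len(heatmaps) / n_cols))
    h, w = heatmaps[0].scores_full.shape
    out = np.zeros((n_rows * h, n_cols * w))
    for i, hm in enumerate(heatmaps):
        r, c = divmod(i, n_cols)
        out[r * h : (r + 1) * h, c * w : (c + 1) * w] = hm.scores_full
    return out
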