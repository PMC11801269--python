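"""Integrated Gradients axioms and SCDA heatmap mechanics."""

import numpy as np
import pytest
from scipy import ndimage

from flexfuse.errors import ConfigError
from flexfuse.interpret import (
    FOUR_CONN,
    integrated_gradients,
    integrated_gradients_fn,
    mask_iou,
    modal_importance,
    modal_importance_by_group,
    rank_features,
    scda_from_map,
)
from flexfuse.nn import Tensor


# -------------------------------------------------------------- IG generic
def test_linear_model_closed_form_any_steps():
    w = np.array([1.5, -2.0, 0.5])
    x = np.array([[2.0, 1.0, -3.0]])

    def forward(t):
        return t["x"] @ Tensor(w.reshape(-1, 1))

    for steps in (1, 3, 50):
        attr, f_x, f_base = integrated_gradients_fn(
            forward, {"x": x}, {"x": np.zeros_like(x)}, steps=steps
        )
        assert np.allclose(attr["x"], w * x, atol=1e-12)  # IG_i = w_i x_i exactly
        assert np.allclose(attr["x"].sum(), f_x - f_base)


def test_sample_equal_to_baseline_gives_zero_attributions():
    x = np.array([[0.3, -0.7]])

    def forward(t):
        return (t["x"] ** 2.0).sum(axis=1)

    attr, _, _ = integrated_gradients_fn(forward, {"x": x}, {"x": x.copy()}, steps=10)
    assert np.allclose(attr["x"], 0.0)


def test_feature_fixed_at_baseline_value_gets_zero_attribution():
    w = np.array([[2.0], [3.0]])
    x = np.array([[5.0, 1.0]])
    base = np.array([[5.0, 0.0]])  # first feature already at baseline

    def forward(t):
        return t["x"] @ Tensor(w)

    attr, _, _ = integrated_gradients_fn(forward, {"x": x}, {"x": base}, steps=5)
    assert attr["x"][0, 0] == 0.0
    assert attr["x"][0, 1] == pytest.approx(3.0)


def test_steps_must_be_positive():
    with pytest.raises(ConfigError):
        integrated_gradients_fn(lambda t: t["x"].sum(), {"x": np.ones((1, 2))},
                                {"x": np.zeros((1, 2))}, steps=0)


# --------------------------------------------------------- IG on the model
def test_completeness_against_finer_riemann_oracle(fitted_tabular):
    fitted, cohort, _ = fitted_tabular
    batch = fitted.inputs(cohort).select(np.arange(8))
    report = integrated_gradients(fitted.model, batch, steps=300, labels=cohort.labels[:8])
    oracle = integrated_gradients(fitted.model, batch, steps=3000, labels=cohort.labels[:8])
    # at 300 steps the completeness gap is small relative to the output change
    assert report.aggregate_relative_gap() < 0.02
    # per-patient version holds wherever the prediction moved appreciably
    moved = np.abs(report.output_at_input - report.output_at_baseline) > 0.05
    assert np.nanmax(report.relative_completeness_gap()[moved]) < 0.02
    # and the 300-step totals agree with a 10x finer Riemann sum
    denom = np.abs(oracle.total_attribution)
    rel = np.abs(report.total_attribution - oracle.total_attribution) / np.where(denom < 1e-9, 1, denom)
    assert rel[moved].max() < 0.02


def test_modal_importance_shape_and_group_summary(fitted_tabular):
    fitted, cohort, _ = fitted_tabular
    batch = fitted.inputs(cohort).select(np.arange(12))
    report = integrated_gradients(fitted.model, batch, steps=20, labels=cohort.labels[:12])
    scores = modal_importance(report)
    assert list(scores.columns) == ["C", "P", "M"]  # four would include I
    assert len(scores) == 12
    assert (scores.to_numpy() >= 0).all()
    groups = modal_importance_by_group(report)
    assert set(groups.index) == {"progression", "non_progression", "all"}


def test_rank_features_ordering_and_tiebreak(fitted_tabular):
    fitted, cohort, _ = fitted_tabular
    batch = fitted.inputs(cohort).select(np.arange(10))
    report = integrated_gradients(fitted.model, batch, steps=20)
    ranked = rank_features(report, "C")
    med = ranked["median_importance"].to_numpy()
    assert (np.diff(med) <= 1e-15).all()  # descending
    top5 = rank_features(report, "P", top=5)
    assert len(top5) == 5
    # single patient: ranking equals that patient's |attribution| order
    single = integrated_gradients(fitted.model, fitted.inputs(cohort).select(np.arange(1)), steps=20)
    r1 = rank_features(single, "C")
    attrs = np.abs(single.tabular["C"][0])
    names = single.feature_names["C"]
    expected = sorted(zip(attrs, names), key=lambda p: (-p[0], p[1]))
    assert list(r1["feature"]) == [n for _, n in expected]


def test_zero_weight_model_zero_scores(fitted_tabular):
    fitted, cohort, _ = fitted_tabular
    import copy

    model = copy.deepcopy(fitted.model)
    for p in model.parameters():
        p.data = np.zeros_like(p.data)
    batch = fitted.inputs(cohort).select(np.arange(3))
    report = integrated_gradients(model, batch, steps=10)
    assert np.allclose(modal_importance(report).to_numpy(), 0.0)


# -------------------------------------------------------------------- SCDA
def _brute_force_scda(fmap):
    s = np.zeros(fmap.shape[1:])
    for c in range(fmap.shape[0]):
        s += fmap[c]
    thr = s.mean()
    above = s > thr
    labeled, n = ndimage.label(above, structure=FOUR_CONN)
    best, best_size = np.zeros_like(above), 0
    for k in range(1, n + 1):
        comp = labeled == k
        if comp.sum() > best_size:
            best, best_size = comp, comp.sum()
    return s, thr, best


def test_scda_matches_brute_force_on_random_maps(rng):
    for _ in range(20):
        fmap = rng.normal(size=(rng.integers(1, 5), rng.integers(3, 9), rng.integers(3, 9)))
        s, thr, mask = scda_from_map(fmap)
        s2, thr2, mask2 = _brute_force_scda(fmap)
        assert np.allclose(s, s2)
        assert thr == pytest.approx(thr2)
        assert np.array_equal(mask, mask2)
        assert not np.any(mask & ~(s > thr))  # mask subset of above-threshold set


def test_constant_map_empty_mask_under_strict_threshold():
    fmap = np.full((2, 5, 5), 3.7)
    _, thr, mask = scda_from_map(fmap)
    assert thr == pytest.approx(7.4)
    assert not mask.any()


def test_single_hot_block_becomes_mask():
    fmap = np.zeros((1, 6, 6))
    fmap[0, 2:4, 3:5] = 10.0
    _, _, mask = scda_from_map(fmap)
    expected = np.zeros((6, 6), dtype=bool)
    expected[2:4, 3:5] = True
    assert np.array_equal(mask, expected)


def test_mask_iou_values():
    a = np.zeros((4, 4), dtype=bool)
    b = np.zeros((4, 4), dtype=bool)
    assert mask_iou(a, b) == 0.0
    a[:2] = True
    b[1:3] = True
    assert mask_iou(a, b) == pytest.approx(4 / 12)
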