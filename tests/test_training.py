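"""End-to-end training, cross-validation mechanics and the metric panel."""

import numpy as np
import pandas as pd
import pytest

from flexfuse import SimConfig, TrainConfig, compute_metrics, cross_validate, generate_cohort, train
from flexfuse.errors import ConfigError, FlexError
from flexfuse.training import deduplicate_records, fit_preprocessors


def _tiny_cohort(seed=21, n=30, modalities=("C", "P")):
    config = SimConfig(
        n_patients=n,
        modalities=modalities,
        n_features={"C": 6, "P": 6, "M": 6},
        informative={"C": 2, "P": 2, "M": 0},
        effect_size=1.5,
        tile_size=32,
        tiles_per_patient=1,
        seed=seed,
    )
    return generate_cohort(config)[0]


def brute_force_auroc(scores, labels):
    """Pairwise rank-comparison AUROC; ties count 0.5."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


# ----------------------------------------------------------------- training
def test_same_seed_identical_parameters():
    cohort = _tiny_cohort()
    config = TrainConfig(modalities=("C", "P"), epochs=4, seed=9, early_stopping=False)
    a = train(cohort, config)
    b = train(cohort, config)
    sa, sb = a.model.state_dict(), b.model.state_dict()
    assert set(sa) == set(sb)
    for k in sa:
        assert np.array_equal(sa[k], sb[k]), k


def test_overfits_tiny_cohort():
    cohort = _tiny_cohort(n=16)
    config = TrainConfig(modalities=("C", "P"), epochs=20, seed=2, early_stopping=False,
                         use_meta=False, batch_size=16)
    fitted = train(cohort, config)
    losses = [h["loss"] for h in fitted.history]
    assert losses[-1] < losses[0]


def test_zero_learning_rate_leaves_parameters_unchanged():
    cohort = _tiny_cohort()
    config = TrainConfig(modalities=("C", "P"), epochs=3, lr=0.0, seed=3, early_stopping=False)
    fitted = train(cohort, config)
    from flexfuse.model import FlexModel
    from flexfuse.training import _model_spec

    fresh = FlexModel(_model_spec(cohort, config), np.random.default_rng(config.seed))
    ref = fresh.state_dict()
    got = fitted.model.state_dict()
    for k in ref:
        assert np.array_equal(ref[k], got[k]), k


def test_single_class_split_refused():
    cohort = _tiny_cohort()
    ones = np.where(cohort.labels == 1)[0]
    with pytest.raises(ConfigError, match="single class"):
        train(cohort, TrainConfig(modalities=("C", "P"), epochs=1), train_idx=ones)


def test_checkpoint_round_trip(tmp_path):
    cohort = _tiny_cohort()
    config = TrainConfig(modalities=("C", "P"), epochs=2, seed=4, early_stopping=False)
    fitted = train(cohort, config)
    fitted.model.save(tmp_path / "ckpt", extra={"seed": 4})
    from flexfuse.model import FlexModel

    clone, extra = FlexModel.load(tmp_path / "ckpt")
    assert extra["seed"] == 4
    batch = fitted.inputs(cohort)
    assert np.allclose(clone.predict_proba(batch), fitted.model.predict_proba(batch))


# ---------------------------------------------------------------------- CV
def test_cross_validation_defaults_to_five_folds():
    import inspect

    assert inspect.signature(cross_validate).parameters["k"].default == 5


def test_fold_sizes_for_259_patients():
    labels = np.array([1] * 106 + [0] * 153)
    rng = np.random.default_rng(0)
    rng.shuffle(labels)
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
    sizes = sorted(len(te) for _, te in skf.split(np.zeros(259), labels))
    assert sizes == [51, 52, 52, 52, 52]


def test_cross_validation_partition_and_reproducibility():
    cohort = _tiny_cohort(n=40)
    config = TrainConfig(modalities=("C", "P"), epochs=3, seed=5, early_stopping=False)
    result = cross_validate(cohort, config, k=5)
    # exhaustive and disjoint
    tested = [pid for fold in result.fold_patients for pid in fold]
    assert sorted(tested) == sorted(cohort.patient_ids)
    assert len(set(tested)) == len(tested)
    # stratified within +-1 positive per fold
    pos_per_fold = [int(l.sum()) for l in result.fold_labels]
    assert max(pos_per_fold) - min(pos_per_fold) <= 1
    # bitwise reproducible
    again = cross_validate(cohort, config, k=5)
    for a, b in zip(result.fold_scores, again.fold_scores):
        assert np.array_equal(a, b)
    assert result.fold_assignment == again.fold_assignment


def test_cv_rejects_k_larger_than_cohort():
    cohort = _tiny_cohort(n=10)
    with pytest.raises(ConfigError):
        cross_validate(cohort, TrainConfig(modalities=("C", "P")), k=11)


def test_leakage_guard_preprocessors_fitted_on_training_fold_only():
    cohort = _tiny_cohort(n=30)
    config = TrainConfig(modalities=("C", "P"))
    train_idx = np.arange(20)
    prep = fit_preprocessors(cohort, train_idx, config)
    train_ids = {cohort.patients[i].patient_id for i in train_idx}
    assert prep.fitted_on == train_ids
    test_ids = set(cohort.patient_ids) - train_ids
    assert prep.fitted_on.isdisjoint(test_ids)


# ----------------------------------------------------------------- metrics
def test_perfect_and_inverted_separation():
    scores = np.array([0.9, 0.8, 0.2, 0.1])
    labels = np.array([1, 1, 0, 0])
    assert compute_metrics(scores, labels)["auroc"] == 1.0
    assert compute_metrics(scores, 1 - labels)["auroc"] == 0.0


def test_random_scores_near_half_auroc():
    rng = np.random.default_rng(6)
    scores = rng.random(10000)
    labels = np.array([0, 1] * 5000)
    auc = compute_metrics(scores, labels)["auroc"]
    assert 0.47 <= auc <= 0.53


def test_auroc_matches_brute_force_rank_oracle_with_ties():
    rng = np.random.default_rng(7)
    scores = np.round(rng.random(60), 1)  # coarse grid forces ties
    labels = rng.integers(0, 2, size=60)
    labels[:2] = [0, 1]  # both classes guaranteed
    got = compute_metrics(scores, labels)["auroc"]
    assert got == pytest.approx(brute_force_auroc(scores, labels), abs=1e-12)


def test_metric_panel_has_six_entries_and_threshold_semantics():
    scores = np.array([0.6, 0.4, 0.7, 0.2])
    labels = np.array([1, 1, 0, 0])
    m = compute_metrics(scores, labels)
    assert set(m) == {"auroc", "auprc", "accuracy", "sensitivity", "specificity", "f1"}
    assert m["sensitivity"] == 0.5  # one of two positives above 0.5
    assert m["specificity"] == 0.5


def test_single_class_labels_rejected():
    with pytest.raises(FlexError):
        compute_metrics(np.array([0.1, 0.9]), np.array([1, 1]))


# ------------------------------------------------------------------- dedup
def test_deduplicate_prefers_progression_then_earlier_acquisition():
    records = pd.DataFrame(
        {
            "patient_id": ["a", "a", "b", "b", "c"],
            "label": [0, 1, 0, 0, 1],
            "acquisition_time": [1, 2, 5, 3, 9],
        }
    )
    out = deduplicate_records(records).set_index("patient_id")
    assert out.loc["a", "label"] == 1  # progression record wins
    assert out.loc["b", "acquisition_time"] == 3  # earlier sample wins
    assert len(out) == 3
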