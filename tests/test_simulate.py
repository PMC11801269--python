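"""Synthetic-cohort generator: distributions, planted signal, round trips."""

import numpy as np
import pytest
from scipy.stats import skew
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from flexfuse import SimConfig, generate_cohort, write_cohort
from flexfuse.data import load_cohort
from flexfuse.errors import ConfigError


def _logistic_oracle_auc(cohort, seed=0):
    """Held-out-half AUC of a standalone regularized logistic fit."""
    X = np.concatenate(
        [np.nan_to_num(cohort.tables[m].values) for m in ("C", "P", "M") if m in cohort.tables],
        axis=1,
    )
    y = cohort.labels
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    tr, te = idx[: len(y) // 2], idx[len(y) // 2 :]
    mu, sd = X[tr].mean(0), X[tr].std(0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    clf = LogisticRegression(max_iter=2000).fit(Z[tr], y[tr])
    return roc_auc_score(y[te], clf.predict_proba(Z[te])[:, 1])


def test_same_seed_bitwise_identical():
    config = SimConfig(n_patients=40, tile_size=32, tiles_per_patient=2, lesion_signal=0.5, seed=3)
    a, truth_a = generate_cohort(config)
    b, truth_b = generate_cohort(config)
    assert a.patient_ids == b.patient_ids
    assert np.array_equal(a.labels, b.labels)
    for m in a.tables:
        assert a.tables[m].equals(b.tables[m])
    for pid in a.images:
        for ta, tb in zip(a.images[pid].tiles, b.images[pid].tiles):
            assert np.array_equal(ta, tb)
    assert truth_a["intercept"] == truth_b["intercept"]


def test_null_effect_gives_chance_level_oracle():
    cohort, _ = generate_cohort(
        SimConfig(n_patients=2000, modalities=("C", "P", "M"), effect_size=0.0, lesion_signal=0.0, seed=11)
    )
    auc = _logistic_oracle_auc(cohort)
    assert 0.45 <= auc <= 0.55


def test_planted_clinical_signal_recoverable_by_logistic_fit():
    cohort, _ = generate_cohort(
        SimConfig(
            n_patients=2000,
            modalities=("C", "P", "M"),
            informative={"C": 5, "P": 0, "M": 0},
            effect_size=1.0,
            seed=12,
        )
    )
    assert _logistic_oracle_auc(cohort) > 0.80


def test_marginal_distributions():
    cohort, truth = generate_cohort(SimConfig(n_patients=5000, modalities=("C", "P", "M"), seed=13))
    probs = np.array(truth["generator_meta"]["C"]["bernoulli_p"])
    n_bin = len(probs)
    means = cohort.tables["C"].values[:, :n_bin].mean(axis=0)
    assert np.abs(means - probs).max() < 0.03
    for m in ("P", "M"):
        skews = skew(cohort.tables[m].values, axis=0)
        assert (skews > 1).all()  # long-tailed


def test_prevalence_calibration():
    cohort, _ = generate_cohort(SimConfig(n_patients=1500, modalities=("C", "P", "M"), seed=14))
    assert abs(cohort.labels.mean() - 0.41) < 0.05


def test_missingness_rate_realized():
    cohort, _ = generate_cohort(
        SimConfig(
            n_patients=1200,
            modalities=("C", "P", "M"),
            missing_rate={"C": 0.0, "P": 0.3, "M": 0.1, "I": 0.0},
            seed=15,
        )
    )
    pm = cohort.presence_matrix()
    assert abs((~pm["P"]).mean() - 0.3) < 0.05
    assert abs((~pm["M"]).mean() - 0.1) < 0.05
    assert pm["C"].all()


def test_lesions_only_on_progression_tiles():
    cohort, truth = generate_cohort(
        SimConfig(n_patients=60, tile_size=32, tiles_per_patient=3, lesion_signal=1.0, seed=16)
    )
    labels = dict(zip(cohort.patient_ids, cohort.labels))
    for pid, tiles in truth["lesions"].items():
        if pid not in cohort.images:
            continue
        for entry in tiles:
            if labels[pid] == 0:
                assert not entry["lesion"]
            else:
                assert entry["lesion"]  # lesion_signal=1 plants every tile


def test_write_load_round_trip(tmp_path):
    config = SimConfig(n_patients=10, tile_size=32, tiles_per_patient=2, lesion_signal=1.0, seed=17)
    cohort, truth = generate_cohort(config)
    manifest = write_cohort(cohort, truth, tmp_path / "cohort")
    assert manifest["n_labels"] == 10
    loaded = load_cohort(tmp_path / "cohort")
    assert loaded.patient_ids == cohort.patient_ids
    assert np.array_equal(loaded.labels, cohort.labels)
    for m in cohort.tables:
        assert loaded.tables[m].equals(cohort.tables[m])
    for pid in cohort.images:
        for ta, tb in zip(loaded.images[pid].tiles, cohort.images[pid].tiles):
            assert np.array_equal(ta, tb)


def test_overwrite_refused_without_force(tmp_path):
    config = SimConfig(
        n_patients=5,
        modalities=("C",),
        n_features={"C": 4, "P": 1, "M": 1},
        informative={"C": 2, "P": 0, "M": 0},
        seed=18,
    )
    cohort, truth = generate_cohort(config)
    write_cohort(cohort, truth, tmp_path / "c")
    with pytest.raises(FileExistsError):
        write_cohort(cohort, truth, tmp_path / "c")
    write_cohort(cohort, truth, tmp_path / "c", force=True)  # explicit force succeeds


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_patients": 0},
        {"n_features": {"C": 0, "P": 5, "M": 5}},
        {"informative": {"C": 99, "P": 0, "M": 0}},
        {"lesion_signal": 1.5},
    ],
)
def test_degenerate_configs_rejected(kwargs):
    with pytest.raises(ConfigError):
        generate_cohort(SimConfig(**kwargs))
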