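"""Hash mapping (quantile bucketing) and trainable encoding contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flexfuse import FeatureTable
from flexfuse.errors import ConfigError, FitError, SchemaError
from flexfuse.fet import (
    D_ENC_DEFAULT,
    EncodingBank,
    HashMapper,
    PlainTabularEncoder,
    apply_hash_map,
    encode_modality,
    encode_modality_hashed_only,
    encode_modality_raw,
    fit_hash_mapper,
)
from flexfuse.nn import Adam, Tensor, bce_with_logits


def _table(values, modality="C", names=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, f = values.shape
    return FeatureTable(
        modality_id=modality,
        patient_ids=[f"p{i}" for i in range(n)],
        feature_names=names or [f"f{j}" for j in range(f)],
        values=values,
    )


# ----------------------------------------------------------------- mapping
def test_quartile_boundaries_match_empirical_quantiles():
    t = _table(np.arange(1, 101).reshape(-1, 1))
    mapper = fit_hash_mapper(t, n_buckets=4)
    expected = np.quantile(np.arange(1, 101), [0.25, 0.5, 0.75])  # 25.75, 50.5, 75.25
    assert np.allclose(mapper.boundaries[0], expected)


def test_constant_feature_single_bucket_midpoint_half():
    t = _table(np.full((10, 1), 7.0))
    mapper = fit_hash_mapper(t, n_buckets=8)
    assert mapper.n_buckets[0] == 1
    mapped = apply_hash_map(mapper, t)
    assert np.allclose(mapped.values, 0.5)


def test_two_bucket_midpoints():
    t = _table(np.linspace(-3, 3, 20).reshape(-1, 1))
    mapper = fit_hash_mapper(t, n_buckets=2)
    mapped = apply_hash_map(mapper, t)
    assert set(np.round(mapped.values.ravel(), 6)) == {0.25, 0.75}
    below = t.values.ravel() < np.median(t.values)
    assert np.allclose(mapped.values.ravel()[below], 0.25)


def test_out_of_range_values_clamp_to_extreme_buckets():
    train = _table(np.arange(10, 20).reshape(-1, 1))
    mapper = fit_hash_mapper(train, n_buckets=4)
    probe = apply_hash_map(mapper, _table([[-1e9], [1e9]]))
    assert probe.values[0, 0] == pytest.approx(0.5 / 4)  # first-bucket midpoint
    assert probe.values[1, 0] == pytest.approx(3.5 / 4)


def test_missing_cells_become_missing_bucket_not_midpoint():
    t = _table([[1.0], [np.nan], [3.0]])
    mapper = fit_hash_mapper(t, n_buckets=2)
    mapped = apply_hash_map(mapper, t)
    assert not mapped.present[1, 0]
    assert mapped.present[0, 0] and mapped.present[2, 0]


def test_all_missing_feature_raises_naming_it():
    t = _table([[np.nan, 1.0], [np.nan, 2.0]], names=["bad", "good"])
    with pytest.raises(FitError, match="bad"):
        fit_hash_mapper(t, n_buckets=2)


def test_feature_name_mismatch_is_schema_error():
    mapper = fit_hash_mapper(_table([[1.0], [2.0]], names=["a"]), n_buckets=2)
    with pytest.raises(SchemaError):
        apply_hash_map(mapper, _table([[1.0], [2.0]], names=["b"]))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=8, max_size=40), st.integers(2, 8))
def test_mapping_monotone_vs_bruteforce_bucket_oracle(raw, n_buckets):
    values = np.asarray(raw).reshape(-1, 1)
    t = _table(values)
    mapper = fit_hash_mapper(t, n_buckets=n_buckets)
    mapped = apply_hash_map(mapper, t).values.ravel()
    # brute-force oracle: bucket k = number of boundaries strictly below x
    bounds = mapper.boundaries[0]
    nb = mapper.n_buckets[0]
    oracle = np.array([(np.sum(bounds < x) + 0.5) / nb for x in values.ravel()])
    assert np.allclose(mapped, oracle)
    order = np.argsort(values.ravel(), kind="mergesort")
    assert (np.diff(mapped[order]) >= -1e-12).all()  # monotone


def test_idempotent_on_equal_mass_midpoints():
    # 4 buckets x 8 observations each: refit on midpoints maps them to themselves
    rng = np.random.default_rng(0)
    values = np.sort(rng.normal(size=32)).reshape(-1, 1)
    t = _table(values)
    mapper = fit_hash_mapper(t, n_buckets=4)
    mids = apply_hash_map(mapper, t).values
    t2 = _table(mids)
    mapper2 = fit_hash_mapper(t2, n_buckets=4)
    assert np.allclose(apply_hash_map(mapper2, t2).values, mids)


def test_scale_invariance_of_hashed_pathway():
    rng = np.random.default_rng(1)
    values = rng.lognormal(size=(50, 3))
    scaled = values.copy()
    scaled[:, 1] *= 1e6  # rescale one long-tailed feature
    m1 = fit_hash_mapper(_table(values), n_buckets=8)
    m2 = fit_hash_mapper(_table(scaled), n_buckets=8)
    assert np.allclose(
        apply_hash_map(m1, _table(values)).values,
        apply_hash_map(m2, _table(scaled)).values,
    )


def test_mapper_json_round_trip():
    mapper = fit_hash_mapper(_table(np.arange(20.0).reshape(-1, 2)), n_buckets=4)
    clone = HashMapper.from_json(mapper.to_json())
    assert clone.feature_names == mapper.feature_names
    for a, b in zip(clone.boundaries, mapper.boundaries):
        assert np.allclose(a, b)


def test_too_few_buckets_rejected():
    with pytest.raises(ConfigError):
        fit_hash_mapper(_table([[1.0], [2.0]]), n_buckets=1)


# ---------------------------------------------------------------- encoding
def test_encoding_dimension_is_ten_by_default():
    bank = EncodingBank(["a", "b", "c"], d_rep=16, rng=np.random.default_rng(0))
    assert bank.encodings.data.shape == (3, D_ENC_DEFAULT)
    assert D_ENC_DEFAULT == 10


def test_all_missing_row_independent_of_values():
    rng = np.random.default_rng(2)
    bank = EncodingBank(["a", "b"], d_rep=8, rng=rng)
    absent = np.zeros((1, 2))
    out1 = bank(Tensor(np.array([[0.3, 0.9]])), Tensor(absent)).data
    out2 = bank(Tensor(np.array([[0.7, 0.1]])), Tensor(absent)).data
    assert np.allclose(out1, out2)


def test_zero_value_with_zero_missing_path_gives_zero_contribution():
    rng = np.random.default_rng(3)
    bank = EncodingBank(["only"], d_rep=4, rng=rng)
    # v=0 and present=1: scaled term v*e is exactly zero; representation equals
    # the projection of the (ReLU'd) per-feature bias path only
    v = Tensor(np.array([[0.0]]))
    u = Tensor(np.array([[1.0]]))
    contrib = v.reshape(1, 1, 1) * bank.encodings
    assert np.allclose(contrib.data, 0.0)
    out = bank(v, u)
    assert out.data.shape == (1, 4)


def test_feature_order_permutation_invariance():
    rng = np.random.default_rng(4)
    names = [f"f{j}" for j in range(6)]
    bank = EncodingBank(names, d_rep=8, rng=rng)
    v = rng.random((3, 6))
    u = np.ones((3, 6))
    base = bank(Tensor(v), Tensor(u)).data
    perm = rng.permutation(6)
    # permute features and the per-feature parameters consistently
    bank2 = EncodingBank([names[j] for j in perm], d_rep=8, rng=np.random.default_rng(99))
    bank2.encodings.data = bank.encodings.data[perm]
    bank2.missing_encodings.data = bank.missing_encodings.data[perm]
    bank2.affine_w.data = bank.affine_w.data[perm]
    bank2.affine_b.data = bank.affine_b.data[perm]
    bank2.proj.weight.data = bank.proj.weight.data.copy()
    bank2.proj.bias.data = bank.proj.bias.data.copy()
    assert np.allclose(bank2(Tensor(v[:, perm]), Tensor(u[:, perm])).data, base)


def test_gradient_flows_to_encodings():
    rng = np.random.default_rng(5)
    bank = EncodingBank(["a", "b", "c"], d_rep=4, rng=rng)
    head_w = Tensor(rng.normal(size=(4, 1)), requires_grad=True)
    before = bank.encodings.data.copy()
    opt = Adam(bank.parameters() + [head_w], lr=1e-2)
    v = Tensor(rng.random((8, 3)))
    u = Tensor(np.ones((8, 3)))
    y = rng.integers(0, 2, size=(8, 1)).astype(float)
    logits = bank(v, u) @ head_w
    loss = bce_with_logits(logits, y)
    loss.backward()
    assert bank.encodings.grad is not None and np.abs(bank.encodings.grad).max() > 0
    opt.step()
    assert not np.allclose(bank.encodings.data, before)


def test_plain_encoder_output_dim_and_determinism():
    rng = np.random.default_rng(6)
    enc = PlainTabularEncoder(5, d_rep=8, rng=rng)
    v = rng.random((4, 5))
    u = np.ones((4, 5))
    out1 = encode_modality_hashed_only(
        type("M", (), {"feature_names": list("abcde"), "patient_ids": [], "values": v, "present": u.astype(bool)})(),
        enc,
    )
    assert out1.shape == (4, 8)
    out2 = enc(Tensor(v), Tensor(u)).data
    assert np.allclose(out1, out2)  # deterministic given fixed parameters


def test_raw_pathway_standardizes_and_handles_missing():
    rng = np.random.default_rng(7)
    enc = PlainTabularEncoder(3, d_rep=6, rng=rng)
    values = rng.normal(loc=100.0, scale=10.0, size=(5, 3))
    present = np.ones((5, 3), dtype=bool)
    present[0, 0] = False
    mean, std = values.mean(0), values.std(0)
    out = encode_modality_raw(values, present, enc, mean, std)
    assert out.shape == (5, 6)
    assert np.all(np.isfinite(out))


def test_encode_modality_facade_matches_bank_call():
    rng = np.random.default_rng(8)
    t = _table(rng.lognormal(size=(12, 4)), modality="P", names=list("wxyz"))
    mapper = fit_hash_mapper(t, n_buckets=4)
    mapped = apply_hash_map(mapper, t)
    bank = EncodingBank(list("wxyz"), d_rep=8, rng=rng)
    out = encode_modality(mapped, bank)
    direct = bank(Tensor(mapped.values), Tensor(mapped.present.astype(float))).data
    assert np.allclose(out, direct)
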