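import numpy as np
import pytest

from shapaal import (
    NormalizationStats,
    TimeSeriesDataset,
    compute_norm_stats,
    read_ucr,
    write_ucr,
    z_normalize,
)
from shapaal.errors import (
    ContractError,
    DegenerateScaleError,
    EmptyInputError,
    FormatError,
    ParseError,
)


def test_read_basic_tab_file(tmp_path):
    p = tmp_path / "d.tsv"
    p.write_text("1\t0.0\t1.0\n2\t1.0\t0.0\n1\t0.5\t0.5\n")
    ds = read_ucr(p)
    assert (ds.n, ds.t, ds.n_classes) == (3, 2, 2)
    assert ds.labels.tolist() == [1, 2, 1]
    assert ds.encoded_labels.tolist() == [0, 1, 0]


def test_read_comma_dialect_autodetected(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text("-1,0.5,1.5\n1,2.5,3.5\n")
    ds = read_ucr(p)
    assert ds.label_set == (-1, 1)
    assert ds.encoded_labels.tolist() == [0, 1]
    assert ds.decode([0, 1]).tolist() == [-1, 1]


@pytest.mark.parametrize(
    "text,err",
    [
        ("1\t0.0\t1.0\t2.0\n2\t1.0\t0.0\n", FormatError),  # ragged
        ("1\t0.0\tfoo\n", ParseError),  # non-numeric
        ("", EmptyInputError),  # empty file
        ("1.5\t0.0\t1.0\n", ParseError),  # non-integer label
    ],
)
def test_read_rejects_malformed_files(tmp_path, text, err):
    p = tmp_path / "bad.tsv"
    p.write_text(text)
    with pytest.raises(err):
        read_ucr(p)


def test_write_read_round_trip_is_identity(tmp_path, rng):
    ds = TimeSeriesDataset(
        series=rng.normal(size=(10, 24)), labels=rng.integers(1, 3, size=10),
        name="rt_TRAIN", role="train",
    )
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_ucr(ds, p1)
    back = read_ucr(p1)
    assert np.array_equal(back.series, ds.series)  # bitwise-exact floats
    assert back.labels.tolist() == ds.labels.tolist()
    write_ucr(back, p2)
    assert p1.read_text() == p2.read_text()  # deterministic formatting


def test_norm_stats_two_value_example():
    ds = TimeSeriesDataset(series=np.array([[0.0, 0.0], [2.0, 2.0]]),
                           labels=np.array([1, 2]), role="train")
    st = compute_norm_stats(ds)
    assert st.mean == 1.0 and st.std == 1.0  # population convention


def test_norm_stats_matches_independent_two_pass(rng):
    x = rng.normal(size=(20, 24))
    ds = TimeSeriesDataset(series=x, labels=rng.integers(1, 3, size=20), role="train")
    st = compute_norm_stats(ds)
    # independent two-pass computation
    mean = sum(map(float, x.ravel())) / x.size
    var = sum((float(v) - mean) ** 2 for v in x.ravel()) / x.size
    assert st.mean == pytest.approx(mean, abs=1e-12)
    assert st.std == pytest.approx(var**0.5, abs=1e-12)


def test_norm_stats_rejects_constant_matrix():
    ds = TimeSeriesDataset(series=np.full((2, 2), 5.0), labels=np.array([1, 2]), role="train")
    with pytest.raises(DegenerateScaleError):
        compute_norm_stats(ds)


def test_norm_stats_require_training_role():
    ds = TimeSeriesDataset(series=np.eye(3), labels=np.array([1, 2, 1]), role="test")
    with pytest.raises(ContractError):
        compute_norm_stats(ds)


def test_self_normalization_gives_zero_mean_unit_std(rng):
    ds = TimeSeriesDataset(series=rng.normal(2.0, 3.0, size=(15, 20)),
                           labels=rng.integers(1, 3, size=15), role="train")
    out = z_normalize(ds, compute_norm_stats(ds))
    assert abs(out.series.mean()) < 1e-9
    assert abs(out.series.std() - 1.0) < 1e-9


def test_z_normalize_scalar_example():
    st = NormalizationStats(mean=1.0, std=2.0, source="x_TRAIN")
    ds = TimeSeriesDataset(series=np.array([[3.0, 3.0]]), labels=np.array([1]),
                           name="x_TEST", role="test")
    assert z_normalize(ds, st).series.tolist() == [[1.0, 1.0]]


def test_normalization_idempotent_after_recomputing_stats(rng):
    ds = TimeSeriesDataset(series=rng.normal(5, 2, size=(12, 10)),
                           labels=rng.integers(1, 3, size=12), role="train")
    once = z_normalize(ds, compute_norm_stats(ds))
    twice = z_normalize(once, compute_norm_stats(once))
    assert np.allclose(once.series, twice.series, atol=1e-9)


def test_z_normalize_preserves_row_order_statistics(rng):
    ds = TimeSeriesDataset(series=rng.normal(size=(8, 30)),
                           labels=rng.integers(1, 3, size=8), role="train")
    out = z_normalize(ds, compute_norm_stats(ds))
    assert np.array_equal(np.argsort(out.series, axis=1), np.argsort(ds.series, axis=1))


def test_two_test_sets_get_identical_affine_map(rng):
    """Test normalization consults only the train statistics."""
    tr = TimeSeriesDataset(series=rng.normal(3, 2, size=(10, 6)),
                           labels=rng.integers(1, 3, size=10), name="p_TRAIN", role="train")
    st = compute_norm_stats(tr)
    a = rng.normal(size=(4, 6))
    b = rng.normal(size=(4, 6))
    ta = TimeSeriesDataset(series=a, labels=np.ones(4, dtype=int), name="p_TEST", role="test")
    tb = TimeSeriesDataset(series=b, labels=np.ones(4, dtype=int), name="p_TEST", role="test")
    na, nb = z_normalize(ta, st), z_normalize(tb, st)
    # the identical affine map was applied to both: invert and compare
    assert np.allclose(na.series * st.std + st.mean, a, atol=1e-12)
    assert np.allclose((na.series - nb.series) * st.std, a - b, atol=1e-12)
    assert np.array_equal(na.series, (a - st.mean) / st.std)
    assert np.array_equal(nb.series, (b - st.mean) / st.std)


def test_unpaired_test_normalization_rejected(rng):
    st = NormalizationStats(mean=0.0, std=1.0, source="other_TRAIN")
    ds = TimeSeriesDataset(series=rng.normal(size=(3, 4)),
                           labels=np.array([1, 1, 2]), name="mine_TEST", role="test")
    with pytest.raises(ContractError):
        z_normalize(ds, st)


def test_dataset_invariants():
    with pytest.raises(EmptyInputError):
        TimeSeriesDataset(series=np.empty((0, 4)), labels=np.empty(0, dtype=int))
    with pytest.raises(FormatError):
        TimeSeriesDataset(series=np.array([[np.nan, 1.0]]), labels=np.array([1]))
    with pytest.raises(FormatError):
        TimeSeriesDataset(series=np.array([[1.0]]), labels=np.array([1]))  # T < 2
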