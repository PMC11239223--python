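"""Ion collation and the three quantification methods."""

import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import maxlfq_oracle, random_ion_matrix
from phosreport.quant import (
    IonQuantMatrix,
    collate_ions,
    quantify,
    quantify_max,
    quantify_maxlfq,
    quantify_sum,
)


def _matrix(values, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return IonQuantMatrix("k", [f"i{i}" for i in range(values.shape[0])],
                          list(samples), values)


def test_matrix_rejects_nonpositive_values():
    with pytest.raises(ValueError):
        _matrix([[1.0, 0.0]])


def test_sum_and_max_hand_values():
    m = _matrix([[2.0, np.nan], [4.0, 6.0]])
    np.testing.assert_allclose(quantify_sum(m), np.log2([6.0, 6.0]))
    np.testing.assert_allclose(quantify_max(m), np.log2([4.0, 6.0]))


def test_all_missing_column_stays_missing():
    m = _matrix([[2.0, np.nan], [4.0, np.nan]])
    for fn in (quantify_sum, quantify_max, quantify_maxlfq):
        out = fn(m)
        assert np.isfinite(out[0]) and np.isnan(out[1])


def test_single_ion_all_methods_agree():
    values = np.power(2.0, [[3.0, 5.0, 6.0]])
    m = _matrix(values)
    expected = np.array([3.0, 5.0, 6.0])
    np.testing.assert_allclose(quantify_sum(m), expected, atol=1e-12)
    np.testing.assert_allclose(quantify_max(m), expected, atol=1e-12)
    np.testing.assert_allclose(quantify_maxlfq(m), expected, atol=1e-12)


def test_sum_max_equal_naive_reductions():
    rng = np.random.default_rng(3)
    for _ in range(50):
        values = random_ion_matrix(rng)
        m = _matrix(values)
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            naive_sum = np.log2(np.nansum(values, axis=0))
            naive_max = np.log2(np.nanmax(values, axis=0))
        naive_sum[~np.isfinite(naive_sum)] = np.nan
        np.testing.assert_allclose(quantify_sum(m), naive_sum, equal_nan=True)
        np.testing.assert_allclose(quantify_max(m), naive_max, equal_nan=True)


def test_maxlfq_exact_multiplicative_data():
    """Complete data X[f,s] = a_f + b_s is recovered exactly: differences
    equal b differences and values equal mean(a) + b."""
    a = np.array([10.0, 12.0, 15.0, 9.5])
    b = np.array([0.0, 1.0, -2.0, 0.5, 3.0])
    m = _matrix(np.power(2.0, a[:, None] + b[None, :]))
    w = quantify_maxlfq(m)
    np.testing.assert_allclose(np.diff(w), np.diff(b), atol=1e-9)
    np.testing.assert_allclose(w, a.mean() + b, atol=1e-9)


def test_maxlfq_matches_oracle_on_fixed_random_matrix():
    rng = np.random.default_rng(42)
    values = np.power(2.0, rng.normal(14, 2, size=(5, 4)))
    values[rng.random((5, 4)) < 0.3] = np.nan
    m = _matrix(values)
    np.testing.assert_allclose(quantify_maxlfq(m), maxlfq_oracle(values),
                               atol=1e-8, equal_nan=True)


def test_maxlfq_disconnected_components():
    """Two sample blocks sharing no ion are quantified independently."""
    values = np.array([
        [4.0, 8.0, np.nan, np.nan],
        [16.0, 32.0, np.nan, np.nan],
        [np.nan, np.nan, 2.0, 2.0],
    ])
    w = quantify_maxlfq(_matrix(values))
    assert w[1] - w[0] == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(w[2:], [1.0, 1.0], atol=1e-9)
    np.testing.assert_allclose(w, maxlfq_oracle(values), atol=1e-8)


def test_maxlfq_shift_equivariance():
    """Scaling one sample's raw intensities by c shifts only that sample
    by log2(c) on complete matrices."""
    rng = np.random.default_rng(8)
    values = np.power(2.0, rng.normal(14, 2, size=(6, 5)))
    base = quantify_maxlfq(_matrix(values))
    for s, c in ((0, 4.0), (3, 0.125)):
        scaled = values.copy()
        scaled[:, s] *= c
        shifted = quantify_maxlfq(_matrix(scaled))
        expected = base.copy()
        expected[s] += np.log2(c)
        np.testing.assert_allclose(shifted, expected, atol=1e-9)


def test_maxlfq_permutation_equivariance():
    rng = np.random.default_rng(9)
    values = random_ion_matrix(rng, max_ions=6, max_samples=5, max_missing=0.4)
    m = _matrix(values)
    w = quantify_maxlfq(m)
    perm = rng.permutation(values.shape[1])
    w_perm = quantify_maxlfq(_matrix(values[:, perm]))
    np.testing.assert_allclose(w_perm, w[perm], atol=1e-9, equal_nan=True)
    # ion row order is irrelevant
    rows = rng.permutation(values.shape[0])
    np.testing.assert_allclose(quantify_maxlfq(_matrix(values[rows])), w,
                               atol=1e-9, equal_nan=True)


def _collate_rows(records):
    return pd.DataFrame(records, columns=[
        "run_id", "modified_sequence", "stripped_sequence", "protein_group",
        "precursor_id", "fragment_id", "intensity", "q_value", "localization",
    ])


def test_collate_shared_key_unions_ions():
    rows = _collate_rows([
        ("r1", "m1", "AASK", ("P1",), "p1", "y3", 10.0, 0.001, 0.9),
        ("r1", "m2", "AASKR", ("P1",), "p2", "y3", 20.0, 0.001, 0.9),
        ("r2", "m1", "AASK", ("P1",), "p1", "y3", 30.0, 0.001, 0.9),
    ])
    matrices, dups = collate_ions(rows, lambda row: ["site1"])
    assert dups == 0
    (m,) = matrices
    assert m.sample_ids == ["r1", "r2"]
    assert sorted(m.ion_ids) == ["p1/y3", "p2/y3"]  # same fragment label, two ions


def test_collate_row_feeds_every_key():
    rows = _collate_rows([
        ("r1", "m1", "ASSK", ("P1",), "p1", "y3", 10.0, 0.001, 0.9),
    ])
    matrices, _ = collate_ions(rows, lambda row: ["siteA_M2", "siteB_M2"])
    assert [m.key for m in matrices] == ["siteA_M2", "siteB_M2"]
    assert all(m.values[0, 0] == 10.0 for m in matrices)


def test_collate_duplicates_reduced_by_max():
    rows = _collate_rows([
        ("r1", "m1", "AASK", ("P1",), "p1", "y3", 90.0, 0.001, 0.9),
        ("r1", "m1", "AASK", ("P1",), "p1", "y3", 110.0, 0.001, 0.9),
    ])
    matrices, dups = collate_ions(rows, lambda row: ["k"])
    assert dups == 1
    assert matrices[0].values[0, 0] == 110.0


def test_quantify_unknown_method():
    with pytest.raises(ValueError, match="unknown quantification method"):
        quantify([], method="median")
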