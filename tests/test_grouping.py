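"""Phenotype pattern groups and PCA diagnostics."""

import numpy as np
import pytest

from pgpb_select.grouping import pattern_groups, run_pca
from pgpb_select.records import TRAIT_ORDER
from pgpb_select.screen import BinaryTraitMatrix


def _matrix(rows, ids=None):
    rows = np.asarray(rows)
    ids = ids or [f"{i + 1}M" for i in range(rows.shape[0])]
    return BinaryTraitMatrix(isolates=ids, traits=list(TRAIT_ORDER), entries=rows)


def test_pattern_groups_partition_and_flags():
    m = _matrix([[1, 1, 1, 1], [1, 1, 1, 1], [0, 0, 0, 0], [1, 0, 1, 0]])
    groups = pattern_groups(m)
    assert [g.pattern for g in groups] == [(1, 1, 1, 1), (1, 0, 1, 0), (0, 0, 0, 0)]
    assert [g.label for g in groups] == ["A", "B", "C"]
    by_pattern = {g.pattern: g for g in groups}
    assert by_pattern[(1, 1, 1, 1)].members == ["1M", "2M"]
    assert by_pattern[(1, 1, 1, 1)].positive_to_all
    assert by_pattern[(0, 0, 0, 0)].negative_to_all
    # partition: members cover all isolates exactly once
    members = sorted(sum((g.members for g in groups), []))
    assert members == sorted(m.isolates)


def test_pattern_groups_at_most_16_and_order_invariant():
    rng = np.random.default_rng(0)
    rows = rng.integers(0, 2, size=(40, 4))
    m = _matrix(rows)
    groups = pattern_groups(m)
    assert len(groups) <= 16
    perm = rng.permutation(40)
    m2 = _matrix(rows[perm], ids=[m.isolates[i] for i in perm])
    g2 = pattern_groups(m2)
    assert {g.pattern: tuple(g.members) for g in groups} == {
        g.pattern: tuple(g.members) for g in g2
    }
    assert [g.label for g in groups] == [g.label for g in g2]


def test_pca_rank_one_two_traits():
    """Perfectly correlated variation loads entirely on the first component."""
    rows = np.array([[0, 0, 1, 0], [1, 1, 1, 0]])
    with pytest.warns(UserWarning, match="zero-variance"):
        res = run_pca(_matrix(rows))
    assert res.variance_fraction[0] == pytest.approx(1.0)
    assert [t.value for t in res.excluded_traits] == [
        "ammonium",
        "nitrification_qual",
    ]


def test_pca_matches_eigendecomposition_oracle():
    """Loadings/variance agree with a direct correlation-matrix eigendecomposition."""
    rng = np.random.default_rng(42)
    rows = rng.integers(0, 2, size=(20, 4))
    while (rows.std(axis=0) == 0).any():
        rows = rng.integers(0, 2, size=(20, 4))
    res = run_pca(_matrix(rows))

    Z = (rows - rows.mean(0)) / rows.std(0, ddof=1)
    corr = Z.T @ Z / (len(rows) - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    np.testing.assert_allclose(
        res.variance_fraction, evals[: len(res.variance_fraction)] / evals.sum(),
        atol=1e-8,
    )
    expected = evecs * np.sqrt(evals)
    for c in range(res.loadings.shape[1]):
        got = res.loadings.iloc[:, c].to_numpy()
        ref = expected[:, c]
        j = np.argmax(np.abs(ref))
        if ref[j] < 0:
            ref = -ref
        np.testing.assert_allclose(got, ref, atol=1e-8)
    assert (np.abs(res.loadings.to_numpy()) <= 1 + 1e-12).all()
    assert res.variance_fraction.sum() == pytest.approx(1.0)


def test_pca_scores_reconstruct_standardized_matrix():
    rng = np.random.default_rng(3)
    rows = rng.integers(0, 2, size=(15, 4))
    while (rows.std(axis=0) == 0).any():
        rows = rng.integers(0, 2, size=(15, 4))
    res = run_pca(_matrix(rows))
    Z = (rows - rows.mean(0)) / rows.std(0, ddof=1)
    # scores @ eigvecs^T reconstructs Z; eigvec = loading / sqrt(eigval)
    evals = res.variance_fraction * 4  # total variance = n_traits on corr matrix
    eigvecs = res.loadings.to_numpy() / np.sqrt(evals)
    np.testing.assert_allclose(res.scores @ eigvecs.T, Z, atol=1e-8)


def test_pca_all_constant_errors():
    with pytest.raises(ValueError):
        with pytest.warns(UserWarning):
            run_pca(_matrix(np.ones((5, 4), dtype=int)))
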