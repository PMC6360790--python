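"""NMF extraction, cosine matching, QP refitting and pruning."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from somacat.signatures import (
    SignatureModel,
    cosine_similarity,
    extract_signatures,
    fit_exposures,
    match_to_reference,
    prune_and_reassign,
    refit_cohort,
)

from conftest import grid_search_simplex


def hungarian_cosines(truth: np.ndarray, extracted: np.ndarray) -> np.ndarray:
    """Best one-to-one matching of extracted to truth columns."""
    C = np.array(
        [
            [cosine_similarity(truth[:, i], extracted[:, j]) for j in range(extracted.shape[1])]
            for i in range(truth.shape[1])
        ]
    )
    ri, ci = linear_sum_assignment(-C)
    return C[ri, ci], ci


def test_rank_one_exact_recovery():
    rng = np.random.default_rng(0)
    s = rng.dirichlet(np.ones(20))
    e = rng.uniform(100, 1000, size=8)
    V = np.outer(s, e)
    model = extract_signatures(V, k=1, n_restarts=5, seed=1)
    assert cosine_similarity(model.signatures[:, 0], s) >= 0.999


def test_two_separated_signatures_recovered():
    rng = np.random.default_rng(1)
    S = np.zeros((30, 2))
    S[:15, 0] = rng.dirichlet(np.ones(15))
    S[15:, 1] = rng.dirichlet(np.ones(15))
    W = rng.dirichlet(np.ones(2), size=20).T
    V = np.array([rng.multinomial(1500, (S @ W[:, j])) for j in range(20)]).T
    model = extract_signatures(V, k=2, n_restarts=20, seed=2)
    cos, _ = hungarian_cosines(S, model.signatures)
    assert (cos >= 0.95).all()


def test_nested_rank_reduces_error(synthetic_cohort):
    catalogues, _ = synthetic_cohort
    V = catalogues.to_numpy(dtype=float)
    err5 = extract_signatures(V, k=5, n_restarts=10, seed=3).reconstruction_error
    err1 = extract_signatures(V, k=1, n_restarts=10, seed=3).reconstruction_error
    assert err5 < err1


def test_extraction_is_deterministic(synthetic_cohort):
    catalogues, _ = synthetic_cohort
    m1 = extract_signatures(catalogues, k=3, n_restarts=5, seed=11)
    m2 = extract_signatures(catalogues, k=3, n_restarts=5, seed=11)
    np.testing.assert_array_equal(m1.signatures, m2.signatures)
    np.testing.assert_array_equal(m1.exposures, m2.exposures)


def test_extraction_rejects_bad_rank_and_zero_matrix():
    with pytest.raises(ValueError):
        extract_signatures(np.ones((4, 3)), k=4)
    with pytest.raises(ValueError):
        extract_signatures(np.zeros((4, 3)), k=2)


def test_exposure_columns_conserve_totals(synthetic_cohort):
    catalogues, _ = synthetic_cohort
    model = extract_signatures(catalogues, k=5, n_restarts=10, seed=5)
    totals = catalogues.sum(axis=0).to_numpy(dtype=float)
    np.testing.assert_allclose(model.exposures.sum(axis=0), totals, rtol=1e-6)
    assert np.allclose(model.signatures.sum(axis=0), 1.0, atol=1e-9)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        (np.array([1.0, 0, 1.0]), np.array([1.0, 1.0, 0]), 0.5),
        (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), 0.0),
        (np.array([2.0, 1.0]), np.array([4.0, 2.0]), 1.0),
    ],
)
def test_cosine_hand_values(a, b, expected):
    assert cosine_similarity(a, b) == pytest.approx(expected, abs=1e-12)


def test_match_to_reference_identity_and_mismatch(bundled_signatures):
    model = SignatureModel(
        class_labels=list(bundled_signatures.index),
        signatures=bundled_signatures.to_numpy(),
        exposures=np.zeros((5, 1)),
        reconstruction_error=0.0,
    )
    matches = match_to_reference(model, bundled_signatures)
    assert [m.reference_id for m in matches] == list(bundled_signatures.columns)
    assert all(m.cosine == pytest.approx(1.0) for m in matches)
    with pytest.raises(ValueError):
        match_to_reference(model, bundled_signatures.iloc[:-1])


def test_fit_exposures_exact_single_signature(bundled_signatures):
    S = bundled_signatures.to_numpy()
    v = 200.0 * S[:, 2]
    w = fit_exposures(v, S)
    assert w[2] == pytest.approx(200.0, abs=1e-6)
    assert np.delete(w, 2).max() < 1e-6


def test_fit_exposures_matches_grid_oracle_two_signatures(bundled_signatures):
    S = bundled_signatures.to_numpy()[:, :2]
    v = 1000.0 * (0.7 * S[:, 0] + 0.3 * S[:, 1])
    w = fit_exposures(v, S)
    w_oracle, _ = grid_search_simplex(v / v.sum(), S)
    assert np.abs(w - 1000.0 * w_oracle).sum() <= 1.0
    assert w[0] == pytest.approx(700.0, abs=1.0)
    assert w[1] == pytest.approx(300.0, abs=1.0)


def test_fit_exposures_matches_grid_oracle_random_instances(bundled_signatures):
    """QP within 0.5% L1 of the nested grid-search oracle, 20 instances."""
    S_full = bundled_signatures.to_numpy()
    rng = np.random.default_rng(42)
    for trial in range(20):
        k = int(rng.integers(2, 6))
        cols = rng.choice(5, size=k, replace=False)
        S = S_full[:, cols]
        w_true = rng.dirichlet(np.ones(k))
        v = 1000.0 * (S @ w_true)
        w_fit = fit_exposures(v, S) / 1000.0
        _w_oracle, f_oracle = grid_search_simplex(v / v.sum(), S)
        # noiseless: truth is the global optimum; oracle and QP both near it
        assert np.abs(w_fit - w_true).sum() <= 0.005
        r = S @ w_fit - v / v.sum()
        assert float(r @ r) <= f_oracle + 1e-12


def test_fit_exposures_orthogonal_catalogue_leaves_residual():
    S = np.zeros((6, 2))
    S[0, 0] = S[1, 1] = 1.0
    v = np.zeros(6)
    v[5] = 50.0  # mass entirely outside the signatures' support
    w = fit_exposures(v, S)
    assert w.sum() == pytest.approx(50.0)
    residual = v - S @ w
    assert residual[5] == pytest.approx(50.0)


def test_fit_exposures_rejects_empty_signature_set():
    with pytest.raises(ValueError):
        fit_exposures(np.ones(4), np.empty((4, 0)))


def test_prune_drops_minor_signature(bundled_signatures):
    S = bundled_signatures.to_numpy()[:, :2]
    T = 1000.0
    v = T * (0.95 * S[:, 0] + 0.05 * S[:, 1])
    w = fit_exposures(v, S)
    pruned = prune_and_reassign(w, v, S)
    assert pruned[0] == pytest.approx(T, rel=1e-6)
    assert pruned[1] == 0.0


def test_prune_fixed_point_when_all_above_threshold(bundled_signatures):
    S = bundled_signatures.to_numpy()[:, :3]
    v = 900.0 * (S @ np.array([0.4, 0.35, 0.25]))
    w = fit_exposures(v, S)
    np.testing.assert_allclose(prune_and_reassign(w, v, S), w)


def test_prune_three_signature_case(bundled_signatures):
    S = bundled_signatures.to_numpy()[:, :3]
    T = 1000.0
    v = T * (S @ np.array([0.50, 0.42, 0.08]))
    w = fit_exposures(v, S)
    pruned = prune_and_reassign(w, v, S)
    assert pruned[2] == 0.0
    survivors = pruned[pruned > 0]
    assert (survivors / T >= 0.10).all()
    assert pruned.sum() == pytest.approx(T, rel=1e-6)


def test_prune_conserves_totals_cohort_wide(synthetic_cohort, bundled_signatures):
    catalogues, _ = synthetic_cohort
    V = catalogues.to_numpy(dtype=float)
    S = bundled_signatures.to_numpy()
    E = refit_cohort(V, S, prune_threshold=0.10)
    totals = V.sum(axis=0)
    np.testing.assert_allclose(E.sum(axis=0), totals, rtol=1e-6)
    props = E / totals
    assert ((props == 0) | (props >= 0.10 - 1e-9)).all()


def test_exposure_recovery_correlates_with_truth(synthetic_cohort, bundled_signatures):
    """Refit proportions track the generating Dirichlet exposures."""
    catalogues, truth = synthetic_cohort
    V = catalogues.to_numpy(dtype=float)
    S = bundled_signatures.to_numpy()
    E = refit_cohort(V, S, prune_threshold=None)
    props = E / V.sum(axis=0)
    r = np.corrcoef(props.ravel(), truth.to_numpy().ravel())[0, 1]
    assert r >= 0.9
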