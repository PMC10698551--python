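"""Selector bank: oracles, convergence properties, determinism, invariances."""

import warnings
from itertools import combinations

import numpy as np
import pytest

from radfuse.selectors import (
    default_selector_bank,
    mcfs_select,
    run_selector,
    trace_ratio_select,
    udfs_select,
)


def _blobs(seed, sep=3.0, n=60, p=10):
    """Two Gaussian blobs; features 0 and 1 carry the class signal."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, p))
    X[:, 0] += sep * y
    X[:, 1] -= sep * y
    return X, y


def _complementary_blobs(seed, sep=5.0, n=60, p=10):
    """Blobs whose two informative features carry complementary halves of
    the signal (a shared nuisance factor cancels only jointly)."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    u = rng.normal(scale=1.0, size=n)
    X = rng.normal(size=(n, p))
    X[:, 0] += sep * y + u
    X[:, 1] += sep * y - u
    return X, y


# --- bank-level properties ------------------------------------------------

def test_bank_has_fifteen_unique_members():
    bank = default_selector_bank()
    names = [s.name for s in bank]
    assert len(bank) == 15
    assert len(set(names)) == 15
    for required in ("mcfs", "udfs", "trace_ratio"):
        assert required in names


def test_unknown_selector_rejected():
    from radfuse.selectors import SelectorSpec

    with pytest.raises(ValueError, match="unknown"):
        run_selector(SelectorSpec(name="nope", requires_labels=False),
                     np.zeros((4, 3)))


@pytest.mark.parametrize("name", [s.name for s in default_selector_bank()])
def test_every_selector_deterministic(name):
    spec = next(s for s in default_selector_bank() if s.name == name)
    X, y = _blobs(0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = run_selector(spec, X, y, k=4, seed=11)
        r2 = run_selector(spec, X, y, k=4, seed=11)
    assert r1.selected_indices == r2.selected_indices
    np.testing.assert_array_equal(r1.scores, r2.scores)


@pytest.mark.parametrize("name", ["fisher_score", "t_score", "trace_ratio",
                                  "relieff", "laplacian_score"])
def test_selection_invariant_to_feature_rescaling(name):
    spec = next(s for s in default_selector_bank() if s.name == name)
    X, y = _blobs(2)
    scale = np.linspace(0.1, 50, X.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = run_selector(spec, X, y, k=3, seed=0)
        r2 = run_selector(spec, X * scale + 7.0, y, k=3, seed=0)
    assert r1.selected_indices == r2.selected_indices


def test_variance_selector_constant_matrix_zero_scores():
    spec = next(s for s in default_selector_bank() if s.name == "variance")
    res = run_selector(spec, np.full((10, 4), 3.0), None, k=2)
    assert np.allclose(res.scores, 0.0)
    assert res.selected_indices == [0, 1]  # tie-break by index


def test_fisher_selector_matches_direct_ratio_oracle():
    X, y = _blobs(4)
    spec = next(s for s in default_selector_bank() if s.name == "fisher_score")
    res = run_selector(spec, X, y, k=X.shape[1])
    Xs = (X - X.mean(0)) / X.std(0)
    n = len(X)
    a = np.zeros(X.shape[1])
    b = np.zeros(X.shape[1])
    for cls in (0, 1):
        xc = Xs[y == cls]
        a += len(xc) / n * (xc.mean(0) - Xs.mean(0)) ** 2
        b += ((xc - xc.mean(0)) ** 2).sum(0) / n
    np.testing.assert_allclose(res.scores, a / b, rtol=1e-10)


# --- trace ratio ----------------------------------------------------------

def test_trace_ratio_matches_exhaustive_subset_oracle():
    """Converged subset equals the argmax of sum(a)/sum(b) over all
    k-subsets (p <= 10, k <= 3)."""
    for seed in range(5):
        X, y = _blobs(seed, n=40, p=8)
        Xs = (X - X.mean(0)) / X.std(0)
        n = len(X)
        a = np.zeros(8)
        b = np.zeros(8)
        for cls in (0, 1):
            xc = Xs[y == cls]
            a += len(xc) / n * (xc.mean(0) - Xs.mean(0)) ** 2
            b += ((xc - xc.mean(0)) ** 2).sum(0) / n
        for k in (1, 2, 3):
            res = trace_ratio_select(X, y, k)
            best = max(combinations(range(8), k),
                       key=lambda S: a[list(S)].sum() / b[list(S)].sum())
            assert set(res.selected_indices) == set(best)


def test_trace_ratio_lambda_monotone_and_dominant_feature():
    rng = np.random.default_rng(0)
    y = np.repeat([0, 1], 20)
    X = rng.normal(size=(40, 6))
    X[:, 3] = y * 2.0  # between-class variance, zero within
    res = trace_ratio_select(X, y, k=1)
    assert res.selected_indices == [3]
    lam = res.info["lambdas"]
    assert all(lam[i + 1] >= lam[i] - 1e-9 for i in range(len(lam) - 1))


def test_trace_ratio_identical_features_tie_break():
    X = np.tile(np.random.default_rng(1).normal(size=(30, 1)), (1, 5))
    y = np.repeat([0, 1], 15)
    res = trace_ratio_select(X, y, k=2)
    assert res.selected_indices == [0, 1]


def test_trace_ratio_k_equals_p_gives_global_fisher_ratio():
    X, y = _blobs(5, p=6)
    res = trace_ratio_select(X, y, k=6)
    assert sorted(res.selected_indices) == list(range(6))


# --- MCFS -----------------------------------------------------------------

def test_mcfs_recovers_informative_features_fixed_seeds():
    for seed in (0, 1, 2):
        X, y = _complementary_blobs(seed)
        res = mcfs_select(X, k=2, n_clusters=2, seed=seed)
        assert set(res.selected_indices[:2]) == {0, 1}


def test_mcfs_lars_step_matches_independent_l1_oracle():
    """The least-angle regression inside MCFS agrees with an independent
    coordinate-descent lasso at the matched penalty."""
    from sklearn.linear_model import Lars

    from radfuse.selectors import _knn_graph, _laplacian_eigenvectors, _standardize

    X, _ = _complementary_blobs(0)
    Xs = _standardize(X)
    vec = _laplacian_eigenvectors(_knn_graph(Xs, 5), 1)[:, 0]
    lars = Lars(n_nonzero_coefs=2).fit(Xs, vec)
    alpha = lars.alphas_[-1]

    def cd_lasso(X, t, alpha, iters=3000):
        n, p = X.shape
        w = np.zeros(p)
        for _ in range(iters):
            for j in range(p):
                r = t - t.mean() - X @ w + X[:, j] * w[j]
                rho = X[:, j] @ r / n
                z = (X[:, j] ** 2).sum() / n
                w[j] = np.sign(rho) * max(abs(rho) - alpha, 0) / z
        return w

    w_oracle = cd_lasso(Xs, vec, alpha * 1.0001)
    active_oracle = set(np.flatnonzero(np.abs(w_oracle) > 1e-8))
    active_lars = set(np.flatnonzero(np.abs(lars.coef_) > 1e-12))
    assert active_lars == active_oracle
    np.testing.assert_allclose(lars.coef_[list(active_lars)],
                               w_oracle[list(active_lars)], atol=5e-3)


def test_mcfs_errors_and_duplicate_columns():
    X, _ = _blobs(0, n=20)
    with pytest.raises(ValueError):
        mcfs_select(X, k=2, n_clusters=25)
    Xdup = np.tile(np.random.default_rng(0).normal(size=(30, 1)), (1, 4))
    res = mcfs_select(Xdup, k=2, n_clusters=2)
    assert res.selected_indices[0] == 0  # equal scores tie-broken by index


# --- UDFS -----------------------------------------------------------------

def test_udfs_objective_monotone_nonincreasing():
    X, _ = _blobs(0)
    res = udfs_select(X, k=3, gamma=0.5)
    h = res.info["objective_history"]
    assert len(h) >= 1
    assert all(h[i + 1] <= h[i] + 1e-9 * max(abs(h[i]), 1) for i in range(len(h) - 1))


def test_udfs_extreme_gamma_still_valid_and_deterministic():
    """With the penalty dominating, the discriminative signal is drowned out
    but the result stays a valid, reproducible k-selection."""
    X, _ = _blobs(1)
    res1 = udfs_select(X, k=3, gamma=1e9)
    res2 = udfs_select(X, k=3, gamma=1e9)
    assert res1.selected_indices == res2.selected_indices
    assert len(res1.selected_indices) == 3
    assert set(res1.selected_indices) <= set(range(X.shape[1]))


def test_udfs_recovers_informative_over_seeds():
    hits = 0
    for seed in range(20):
        X, _ = _blobs(seed)
        res = udfs_select(X, k=3, seed=seed)
        hits += {0, 1} <= set(res.selected_indices[:3])
    assert hits >= 18


def test_udfs_too_few_samples_error():
    with pytest.raises(ValueError):
        udfs_select(np.zeros((2, 4)), k=2)
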