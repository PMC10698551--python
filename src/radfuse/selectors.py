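"""Feature-selection bank.

Fifteen selectors behind one interface: three fully specified methods that
the model ranking singles out — multi-cluster feature selection (MCFS),
L2,1-regularized unsupervised discriminative selection (UDFS) and the
iterative trace-ratio criterion — plus twelve standard filter / embedded /
wrapper methods. Every selector is deterministic given (X, y, spec, seed)
and returns per-feature scores together with the top-k selection
(ties broken toward the lower feature index).

Selectors that are scale-sensitive standardize their input internally, so
rankings are invariant to per-feature affine rescaling of the raw matrix
(the plain variance filter is the deliberate exception).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from sklearn.feature_selection import RFE
from sklearn.feature_selection import chi2 as _sk_chi2
from sklearn.linear_model import Lars, LogisticRegression

from ._seeds import subseed


@dataclass(frozen=True)
class SelectorSpec:
    name: str
    requires_labels: bool
    hyperparameters: dict = field(default_factory=dict)


@dataclass
class SelectionResult:
    scores: np.ndarray
    selected_indices: list[int]
    seed: int
    info: dict = field(default_factory=dict)


def _top_k(scores: np.ndarray, k: int) -> list[int]:
    order = np.lexsort((np.arange(len(scores)), -np.asarray(scores, dtype=float)))
    return [int(i) for i in order[:k]]


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    return (X - mu) / np.where(sd > 0, sd, 1.0)


def _class_scatter_diag(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature between- and within-class scatter (Fisher diagonals)."""
    n = len(X)
    m = X.mean(axis=0)
    a = np.zeros(X.shape[1])
    b = np.zeros(X.shape[1])
    for cls in np.unique(y):
        xc = X[y == cls]
        a += len(xc) / n * (xc.mean(axis=0) - m) ** 2
        b += ((xc - xc.mean(axis=0)) ** 2).sum(axis=0) / n
    return a, b


# ---------------------------------------------------------------------------
# fully specified methods
# ---------------------------------------------------------------------------

def trace_ratio_select(X, y, k: int, tol: float = 1e-8, max_iter: int = 100) -> SelectionResult:
    """Iterative trace-ratio feature selection.

    Maximizes the subset trace ratio ``sum_j a_j / sum_j b_j`` over k-subsets
    (a = between-class, b = within-class scatter diagonals) by the classic
    lambda iteration: rank features by ``a_j - lambda * b_j``, update lambda
    to the selected subset's ratio, repeat to convergence. The lambda
    sequence is monotone non-decreasing and the fixed point is the global
    optimum of the subset ratio.
    """
    X = _standardize(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if k > X.shape[1]:
        raise ValueError("k exceeds feature count")
    a, b = _class_scatter_diag(X, y)
    if np.all(b == 0):
        raise ValueError("within-class scatter is zero for every feature")
    # degenerate separability: zero within-scatter features are ranked by a
    b_safe = np.where(b > 0, b, 1e-12)
    lam = 0.0
    lambdas = [lam]
    selected = _top_k(a - lam * b_safe, k)
    for _ in range(max_iter):
        lam_new = a[selected].sum() / b_safe[selected].sum()
        lambdas.append(float(lam_new))
        if abs(lam_new - lam) < tol:
            lam = lam_new
            break
        lam = lam_new
        selected = _top_k(a - lam * b_safe, k)
    scores = a - lam * b_safe
    return SelectionResult(scores=scores, selected_indices=_top_k(scores, k),
                           seed=0, info={"lambda": float(lam), "lambdas": lambdas})


def _knn_graph(X: np.ndarray, k: int) -> np.ndarray:
    d = squareform(pdist(X))
    sigma = np.median(d[np.triu_indices_from(d, k=1)]) if len(X) > 1 else 1.0
    sigma = sigma if sigma > 0 else 1.0
    W = np.zeros_like(d)
    for i in range(len(X)):
        nb = np.argsort(d[i])[1: k + 1]
        W[i, nb] = np.exp(-(d[i, nb] ** 2) / (2 * sigma**2))
    return np.maximum(W, W.T)


def _laplacian_eigenvectors(W: np.ndarray, n_vecs: int) -> np.ndarray:
    """Bottom non-trivial eigenvectors of the normalized graph Laplacian."""
    deg = W.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0))
    L = np.eye(len(W)) - d_isqrt[:, None] * W * d_isqrt[None, :]
    _, vecs = np.linalg.eigh(L)
    return vecs[:, 1: n_vecs + 1]


def mcfs_select(X, k: int, n_clusters: int = 2, seed: int = 0,
                n_neighbors: int = 5) -> SelectionResult:
    """Multi-cluster feature selection.

    Spectral embedding of a heat-kernel k-NN graph followed by an L1
    (least-angle) regression of each embedding dimension on the features;
    a feature's score is its largest absolute coefficient across dimensions.
    """
    X = _standardize(np.asarray(X, dtype=float))
    n, p = X.shape
    if n_clusters >= n:
        raise ValueError("n_clusters must be < n_samples")
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    W = _knn_graph(X, n_neighbors)
    n_comp, comp = connected_components(sparse.csr_matrix(W > 0), directed=False)
    if n_comp > 1:
        # a disconnected graph's zero-eigenspace is spanned by component
        # indicators: keep those (centered) as the leading embedding
        # dimensions, then fill with component-wise nontrivial eigenvectors
        warnings.warn("k-NN graph is disconnected; using component-wise Laplacians")
        cols = []
        for c in range(1, n_comp):
            ind = (comp == c).astype(float)
            cols.append(ind - ind.mean())
        comp_order = np.argsort([-np.count_nonzero(comp == c) for c in range(n_comp)])
        local_rank = 1
        while len(cols) < n_clusters:
            added = False
            for c in comp_order:
                if len(cols) >= n_clusters:
                    break
                idx = np.flatnonzero(comp == c)
                if len(idx) <= local_rank:
                    continue
                sub = _laplacian_eigenvectors(W[np.ix_(idx, idx)], local_rank)
                v = np.zeros(n)
                v[idx] = sub[:, local_rank - 1]
                cols.append(v)
                added = True
            local_rank += 1
            if not added:
                break
        vecs = np.stack(cols, axis=1) if cols else np.zeros((n, 1))
    else:
        vecs = _laplacian_eigenvectors(W, n_clusters)
    coefs = np.zeros((p, vecs.shape[1]))
    for j in range(vecs.shape[1]):
        model = Lars(n_nonzero_coefs=min(k, p), fit_intercept=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, vecs[:, j])
        coefs[:, j] = model.coef_
    scores = np.abs(coefs).max(axis=1)
    return SelectionResult(scores=scores, selected_indices=_top_k(scores, k), seed=seed)


def udfs_select(X, k: int, gamma: float = 0.1, seed: int = 0,
                n_neighbors: int = 5, n_components: int = 2,
                tol: float = 1e-6, max_iter: int = 200) -> SelectionResult:
    """L2,1-regularized unsupervised discriminative feature selection.

    Minimizes ``tr(W' M W) + gamma * ||W||_{2,1}`` over orthonormal W, where
    M is the local total-scatter matrix accumulated over k-NN neighborhoods;
    solved by iteratively reweighted eigendecomposition. Features are scored
    by the row norms of W. The surrogate objective decreases monotonically;
    iteration stops at relative change < ``tol``.
    """
    X = _standardize(np.asarray(X, dtype=float))
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    kn = min(n_neighbors, n - 1)
    d = squareform(pdist(X))
    G = np.zeros((n, n))
    H = np.eye(kn + 1) - np.ones((kn + 1, kn + 1)) / (kn + 1)
    for i in range(n):
        nb = np.concatenate([[i], np.argsort(d[i])[1: kn + 1]])
        G[np.ix_(nb, nb)] += H
    M = X.T @ G @ X / n
    c = min(n_components, p)
    D = np.ones(p)
    history: list[float] = []
    Wmat = np.zeros((p, c))
    for _ in range(max_iter):
        _, vecs = np.linalg.eigh(M + gamma * np.diag(D))
        Wmat = vecs[:, :c]
        row_norms = np.linalg.norm(Wmat, axis=1)
        obj = float(np.trace(Wmat.T @ M @ Wmat) + gamma * row_norms.sum())
        if not np.isfinite(obj):
            raise ValueError("UDFS objective became non-finite")
        if history and obj > history[-1] + 1e-9 * max(abs(history[-1]), 1.0):
            break  # surrogate can no longer improve the true objective
        history.append(obj)
        D = 1.0 / (2.0 * np.maximum(row_norms, 1e-12))
        if len(history) > 1 and history[-2] - history[-1] < tol * max(abs(history[-2]), 1.0):
            break
    scores = np.linalg.norm(Wmat, axis=1)
    return SelectionResult(scores=scores, selected_indices=_top_k(scores, k), seed=seed,
                           info={"objective_history": history})


# ---------------------------------------------------------------------------
# standard bank members
# ---------------------------------------------------------------------------

def _variance(X, y, k, seed, hp):
    scores = np.var(np.asarray(X, dtype=float), axis=0)
    return SelectionResult(scores, _top_k(scores, k), seed)


def _fisher(X, y, k, seed, hp):
    a, b = _class_scatter_diag(_standardize(X), y)
    scores = np.where(b > 0, a / np.where(b > 0, b, 1.0), a * 1e12)
    return SelectionResult(scores, _top_k(scores, k), seed)


def _t_score(X, y, k, seed, hp):
    X = _standardize(X)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("t-score needs exactly 2 classes")
    x0, x1 = X[y == classes[0]], X[y == classes[1]]
    se = np.sqrt(x0.var(axis=0, ddof=1) / len(x0) + x1.var(axis=0, ddof=1) / len(x1))
    scores = np.abs(x0.mean(axis=0) - x1.mean(axis=0)) / np.where(se > 0, se, 1e-12)
    return SelectionResult(scores, _top_k(scores, k), seed)


def _gini(X, y, k, seed, hp):
    """Impurity decrease of the best single-threshold split, per feature."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, yi = np.unique(y, return_inverse=True)
    n, p = X.shape
    onehot = np.eye(len(classes))[yi]
    total = onehot.sum(axis=0)
    gini_root = 1.0 - ((total / n) ** 2).sum()
    scores = np.zeros(p)
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        cum = np.cumsum(onehot[order], axis=0)
        left_n = np.arange(1, n + 1)
        right_n = n - left_n
        valid = slice(0, n - 1)
        pl = cum[valid] / left_n[valid, None]
        pr = (total - cum[valid]) / right_n[valid, None]
        g = (left_n[valid] / n) * (1 - (pl**2).sum(axis=1)) \
            + (right_n[valid] / n) * (1 - (pr**2).sum(axis=1))
        scores[j] = gini_root - g.min() if len(g) else 0.0
    return SelectionResult(scores, _top_k(scores, k), seed)


def _relieff(X, y, k, seed, hp):
    X = _standardize(X)
    y = np.asarray(y)
    n, p = X.shape
    kn = int(hp.get("n_neighbors", 5))
    d = squareform(pdist(X, metric="cityblock"))
    scores = np.zeros(p)
    for i in range(n):
        same = np.flatnonzero((y == y[i]) & (np.arange(n) != i))
        diff = np.flatnonzero(y != y[i])
        if len(same) == 0 or len(diff) == 0:
            continue
        hits = same[np.argsort(d[i, same])[:kn]]
        misses = diff[np.argsort(d[i, diff])[:kn]]
        scores -= np.abs(X[hits] - X[i]).mean(axis=0)
        scores += np.abs(X[misses] - X[i]).mean(axis=0)
    return SelectionResult(scores / n, _top_k(scores, k), seed)


def _mrmr(X, y, k, seed, hp):
    """Greedy max-relevance (F-statistic) min-redundancy (|Pearson|)."""
    X = _standardize(X)
    a, b = _class_scatter_diag(X, y)
    n = len(X)
    c = len(np.unique(y))
    rel = (a / np.where(b > 0, b, 1e-12)) * (n - c) / max(c - 1, 1)
    p = X.shape[1]
    corr = np.abs(np.corrcoef(X, rowvar=False)) if p > 1 else np.ones((1, 1))
    corr = np.nan_to_num(corr, nan=0.0)
    selected = [int(np.lexsort((np.arange(p), -rel))[0])]
    while len(selected) < min(k, p):
        cand = [j for j in range(p) if j not in selected]
        red = corr[np.ix_(cand, selected)].mean(axis=1)
        crit = rel[cand] - red
        j = cand[int(np.lexsort((np.arange(len(cand)), -crit))[0])]
        selected.append(j)
    scores = np.full(p, -np.inf)
    for rank, j in enumerate(selected):
        scores[j] = float(p - rank)
    return SelectionResult(scores, selected[:k], seed)


def _laplacian_score(X, y, k, seed, hp):
    X = _standardize(X)
    W = _knn_graph(X, int(hp.get("n_neighbors", 5)))
    deg = W.sum(axis=1)
    n = len(X)
    scores = np.zeros(X.shape[1])
    dsum = deg.sum()
    for j in range(X.shape[1]):
        f = X[:, j] - (X[:, j] @ deg) / dsum if dsum > 0 else X[:, j]
        num = f @ (np.diag(deg) - W) @ f
        den = f @ (deg * f)
        scores[j] = num / den if den > 0 else np.inf
    return SelectionResult(-scores, _top_k(-scores, k), seed)


def _spec(X, y, k, seed, hp):
    """SPEC spectral ranking (smoothness on the normalized affinity graph)."""
    X = _standardize(X)
    W = _knn_graph(X, int(hp.get("n_neighbors", 5)))
    deg = W.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0))
    L = np.eye(len(X)) - d_isqrt[:, None] * W * d_isqrt[None, :]
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        f = d_isqrt * X[:, j]
        norm = np.linalg.norm(f)
        f = f / norm if norm > 0 else f
        scores[j] = f @ L @ f
    return SelectionResult(-scores, _top_k(-scores, k), seed)


def _chi2(X, y, k, seed, hp):
    X = np.asarray(X, dtype=float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Xs = (X - lo) / span
    scores, _ = _sk_chi2(Xs, y)
    scores = np.nan_to_num(scores, nan=0.0)
    return SelectionResult(scores, _top_k(scores, k), seed)


def _cfs(X, y, k, seed, hp):
    """Correlation-redundancy greedy forward selection (CFS-style merit)."""
    X = _standardize(X)
    classes, yi = np.unique(y, return_inverse=True)
    ybin = yi.astype(float)
    p = X.shape[1]
    sy = ybin.std()
    rcy = np.abs((X * (ybin - ybin.mean())[:, None]).mean(axis=0)
                 / np.where(sy > 0, sy, 1.0))
    corr = np.abs(np.corrcoef(X, rowvar=False)) if p > 1 else np.ones((1, 1))
    corr = np.nan_to_num(corr, nan=0.0)
    selected = [int(np.lexsort((np.arange(p), -rcy))[0])]
    while len(selected) < min(k, p):
        cand = [j for j in range(p) if j not in selected]
        merits = []
        for j in cand:
            sub = selected + [j]
            m = len(sub)
            rff = corr[np.ix_(sub, sub)][np.triu_indices(m, 1)].mean() if m > 1 else 0.0
            merits.append(m * rcy[sub].mean() / np.sqrt(m + m * (m - 1) * rff))
        merits = np.asarray(merits)
        selected.append(cand[int(np.lexsort((np.arange(len(cand)), -merits))[0])])
    scores = np.full(p, -np.inf)
    for rank, j in enumerate(selected):
        scores[j] = float(p - rank)
    return SelectionResult(scores, selected[:k], seed)


def _l1_logistic(X, y, k, seed, hp):
    X = _standardize(X)
    model = LogisticRegression(penalty="l1", solver="liblinear",
                               C=float(hp.get("C", 1.0)), random_state=seed)
    model.fit(X, y)
    scores = np.abs(model.coef_).max(axis=0)
    return SelectionResult(scores, _top_k(scores, k), seed)


def _rfe(X, y, k, seed, hp):
    X = _standardize(X)
    base = LogisticRegression(max_iter=200, random_state=seed)
    rfe = RFE(base, n_features_to_select=min(k, X.shape[1]), step=1)
    rfe.fit(X, y)
    scores = -rfe.ranking_.astype(float)
    return SelectionResult(scores, _top_k(scores, k), seed)


def _mcfs_wrap(X, y, k, seed, hp):
    return mcfs_select(X, k, n_clusters=int(hp.get("n_clusters", 2)), seed=seed,
                       n_neighbors=int(hp.get("n_neighbors", 5)))


def _udfs_wrap(X, y, k, seed, hp):
    return udfs_select(X, k, gamma=float(hp.get("gamma", 0.1)), seed=seed,
                       n_neighbors=int(hp.get("n_neighbors", 5)))


def _trace_ratio_wrap(X, y, k, seed, hp):
    res = trace_ratio_select(X, y, k)
    res.seed = seed
    return res


_DISPATCH = {
    "variance": (_variance, False),
    "fisher_score": (_fisher, True),
    "t_score": (_t_score, True),
    "gini_index": (_gini, True),
    "relieff": (_relieff, True),
    "mrmr": (_mrmr, True),
    "laplacian_score": (_laplacian_score, False),
    "spec": (_spec, False),
    "chi2": (_chi2, True),
    "cfs": (_cfs, True),
    "l1_logistic": (_l1_logistic, True),
    "rfe_linear": (_rfe, True),
    "mcfs": (_mcfs_wrap, False),
    "udfs": (_udfs_wrap, False),
    "trace_ratio": (_trace_ratio_wrap, True),
}


def default_selector_bank() -> list[SelectorSpec]:
    """The default 15-member bank."""
    return [SelectorSpec(name=n, requires_labels=lab, hyperparameters={})
            for n, (_, lab) in _DISPATCH.items()]


def run_selector(spec: SelectorSpec, X, y=None, k: int | None = None,
                 seed: int = 0) -> SelectionResult:
    """Dispatch one selector; unsupervised members ignore ``y``."""
    if spec.name not in _DISPATCH:
        raise ValueError(f"unknown selector {spec.name!r}")
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if k is None:
        k = int(spec.hyperparameters.get("k_selected", min(20, p)))
    k = min(k, p)
    fn, needs_labels = _DISPATCH[spec.name]
    if needs_labels and y is None:
        raise ValueError(f"selector {spec.name!r} requires labels")
    res = fn(X, y, k, subseed(seed, "selector", spec.name), spec.hyperparameters)
    res.seed = seed
    return res
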