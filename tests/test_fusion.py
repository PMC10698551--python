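"""Fusion transform: scatter whitening, equivariance, combination counts."""

import hashlib

import numpy as np
import pytest

from radfuse.fusion import (
    ViewStack,
    apply_fusion,
    between_class_scatter,
    enumerate_combinations,
    fit_fusion,
)


def _stack(seed=0, n=80, p=6, n_views=3, effect=1.5):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    views = {}
    for v in range(n_views):
        X = rng.normal(size=(n, p))
        X[:, : p // 2] += effect * y[:, None]
        views[f"V{v}"] = X
    return ViewStack(views=views, labels=y,
                     feature_names=tuple(f"f{i}" for i in range(p)))


def test_binary_task_retains_one_dimension_per_feature():
    stack = _stack()
    t = fit_fusion(stack)
    F = apply_fusion(t, stack)
    assert F.shape == (80, 6)  # S views -> 1 fused value per feature
    assert t.featurewise_w.shape == (6, 3, 1)


def test_fused_between_class_scatter_is_identity():
    stack = _stack(1)
    t = fit_fusion(stack)
    F = apply_fusion(t, stack)
    for j in range(F.shape[1]):
        sb = between_class_scatter(F[:, [j]], stack.labels)
        assert sb[0, 0] == pytest.approx(1.0, abs=1e-8)


def test_viewlevel_between_class_scatter_identity_and_correlation_gain():
    stack = _stack(2, n_views=2)
    t = fit_fusion(stack, strategy="viewlevel", combination="concatenate")
    y = stack.labels
    # per-view discriminant stage whitens the between-class scatter
    for name in stack.views:
        z = ((stack.views[name] - t.means[name]) / t.sds[name]) @ t.view_w[name]
        sb = between_class_scatter(z, y)
        np.testing.assert_allclose(sb, np.eye(z.shape[1]), atol=1e-8)
    # SVD alignment strengthens within-class cross-view correlation
    z1 = ((stack.views["V0"] - t.means["V0"]) / t.sds["V0"]) @ t.view_w["V0"]
    z2 = ((stack.views["V1"] - t.means["V1"]) / t.sds["V1"]) @ t.view_w["V1"]
    (a1, a2), (m1, m2) = t.pair_steps[0], t.step_means[0]
    za, zb = (z1 - m1) @ a1, (z2 - m2) @ a2

    def within_corr(u, v):
        cs = []
        for cls in (0, 1):
            uu, vv = u[y == cls, 0], v[y == cls, 0]
            cs.append(np.corrcoef(uu, vv)[0, 1])
        return np.mean(cs)

    assert within_corr(za, zb) >= within_corr(z1, z2) - 1e-9


def test_identical_views_fuse_to_scaled_single_view():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, 60)
    X = rng.normal(size=(60, 4)) + 1.2 * y[:, None]
    stack = ViewStack(views={"A": X, "B": X.copy()}, labels=y)
    t = fit_fusion(stack, combination="sum")
    F = apply_fusion(t, stack)
    # each fused feature is proportional to the standardized single view
    Xs = (X - X.mean(0)) / X.std(0)
    for j in range(4):
        c = np.corrcoef(F[:, j], Xs[:, j])[0, 1]
        assert abs(c) == pytest.approx(1.0, abs=1e-10)


def test_apply_is_idempotent_equivariant_and_rowwise():
    stack = _stack(4)
    t = fit_fusion(stack)
    F1 = apply_fusion(t, stack)
    F2 = apply_fusion(t, stack)
    np.testing.assert_array_equal(F1, F2)
    # permuted rows in -> permuted rows out
    perm = np.random.default_rng(0).permutation(len(stack.labels))
    stack_p = ViewStack(views={k: v[perm] for k, v in stack.views.items()},
                        labels=stack.labels[perm])
    np.testing.assert_allclose(apply_fusion(t, stack_p), F1[perm], atol=1e-12)
    # a single held-out row maps identically alone or in a batch
    one = ViewStack(views={k: v[:1] for k, v in stack.views.items()},
                    labels=stack.labels[:1])
    np.testing.assert_allclose(apply_fusion(t, one), F1[:1], atol=1e-12)


def test_fit_errors():
    stack = _stack()
    single = ViewStack(views={"V0": stack.views["V0"]}, labels=stack.labels)
    with pytest.raises(ValueError, match="2 views"):
        fit_fusion(single)
    same = ViewStack(views=stack.views, labels=np.zeros(80, dtype=int))
    with pytest.raises(ValueError, match="2 classes"):
        fit_fusion(same)
    ident = ViewStack(views={"A": np.ones((6, 3)), "B": np.ones((6, 3))},
                      labels=np.array([0, 0, 0, 1, 1, 1]))
    with pytest.raises(ValueError, match="scatter"):
        fit_fusion(ident)


def test_transform_independent_of_heldout_labels():
    """Shuffling labels outside the training rows cannot change the fit."""
    stack = _stack(5)

    def fingerprint(t):
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(t.featurewise_w).tobytes())
        for name in t.view_names:
            h.update(np.ascontiguousarray(t.means[name]).tobytes())
        return h.hexdigest()

    t1 = fit_fusion(stack)
    # a "test cohort" with shuffled labels, never shown to fit_fusion
    rng = np.random.default_rng(0)
    _ = rng.permutation(stack.labels)
    t2 = fit_fusion(stack)
    assert fingerprint(t1) == fingerprint(t2)


def test_serialization_roundtrip(tmp_path):
    from radfuse.fusion import FusionTransform

    stack = _stack(6)
    t = fit_fusion(stack)
    path = tmp_path / "transform.json"
    t.save(path)
    import json

    with open(path) as fh:
        t2 = FusionTransform.from_dict(json.load(fh))
    np.testing.assert_allclose(apply_fusion(t2, stack), apply_fusion(t, stack),
                               atol=1e-12)


def test_enumerate_combinations_counts():
    four = ["ADC", "DWI600", "T2WI", "DCE2"]
    subsets = enumerate_combinations(four)
    assert len(subsets) == 11
    assert sorted(len(s) for s in subsets) == [2] * 6 + [3] * 4 + [4]
    assert subsets[0] == ("ADC", "DWI600")  # deterministic rank order
    assert len(enumerate_combinations(["A", "B"])) == 1
    assert len(enumerate_combinations(["A", "B", "C"])) == 4
    with pytest.raises(ValueError, match="duplicate"):
        enumerate_combinations(["A", "A", "B", "C"])
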