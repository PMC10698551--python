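"""Class-structure-aware multi-sequence feature fusion.

Maps a set of per-sequence feature matrices (views) to a fused feature
matrix in which between-class correlations are suppressed: the between-class
scatter of the fused training features is the identity on the retained
discriminant dimensions (at most ``n_classes - 1`` per stage).

Two strategies are implemented:

* ``featurewise`` (default): for each feature index j, the values of that
  feature across the S views form an S-vector per lesion; the between-class
  scatter of these vectors is whitened and projected on its leading
  ``c - 1`` eigenvectors. For binary tasks this maps S values to 1 fused
  value per feature, so the fused matrix keeps the original feature count.
* ``viewlevel``: discriminant-correlation analysis between whole-view
  matrices — per view, whiten the between-class scatter and retain
  ``c - 1`` dimensions, then align view pairs by an SVD of the cross-view
  covariance and combine (sum or concatenation), folding views in
  sequentially in the order given (callers pass descending single-view AUC
  rank; pairwise fusion is order-dependent).

Transforms are fitted exclusively on training rows; application is
deterministic and row-wise (no batch dependence).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations as _combinations

import numpy as np
import pandas as pd

_EIG_CUTOFF = 1e-10  # relative eigenvalue cutoff for whitening


def between_class_scatter(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Weighted between-class scatter sum_c (n_c/n) (m_c-m)(m_c-m)^T."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    m = X.mean(axis=0)
    sb = np.zeros((X.shape[1], X.shape[1]))
    for cls in np.unique(y):
        xc = X[y == cls]
        d = xc.mean(axis=0) - m
        sb += (len(xc) / len(X)) * np.outer(d, d)
    return sb


def _whitening_projection(sb: np.ndarray, n_classes: int) -> np.ndarray:
    """Top c-1 eigenvectors of sb, scaled so the projected scatter is I."""
    evals, evecs = np.linalg.eigh(sb)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0 or not np.isfinite(evals[0]):
        raise ValueError("between-class scatter is numerically zero (classes identical)")
    keep = (evals > _EIG_CUTOFF * evals[0]) & (np.arange(len(evals)) < n_classes - 1)
    evals, evecs = evals[keep], evecs[:, keep]
    # deterministic sign: largest-magnitude component positive
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return evecs / np.sqrt(evals)


@dataclass
class ViewStack:
    """Ordered per-channel feature matrices sharing lesion order and registry."""

    views: dict[str, np.ndarray]
    labels: np.ndarray
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.views.values()}
        if len(shapes) != 1:
            raise ValueError("all views must share lesion count and feature count")
        (shape,) = shapes
        if shape[0] != len(self.labels):
            raise ValueError("labels must match lesion count")

    @classmethod
    def from_tables(cls, tables: dict[str, pd.DataFrame], channels=None) -> "ViewStack":
        channels = list(channels) if channels is not None else list(tables)
        first = tables[channels[0]]
        feats = [c for c in first.columns if c != "class"]
        views = {ch: tables[ch][feats].to_numpy(dtype=float) for ch in channels}
        return cls(views=views, labels=first["class"].to_numpy(), feature_names=tuple(feats))


@dataclass
class FusionTransform:
    strategy: str
    combination: str
    view_names: tuple[str, ...]
    n_classes: int
    means: dict[str, np.ndarray]          # per-view standardization
    sds: dict[str, np.ndarray]
    featurewise_w: np.ndarray | None = None   # p x S x r
    view_w: dict[str, np.ndarray] = field(default_factory=dict)   # viewlevel stage 1
    pair_steps: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    step_means: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    feature_names: tuple[str, ...] | None = None

    def to_dict(self) -> dict:
        def arr(a):
            return np.asarray(a).tolist()
        return {
            "strategy": self.strategy,
            "combination": self.combination,
            "view_names": list(self.view_names),
            "n_classes": self.n_classes,
            "means": {k: arr(v) for k, v in self.means.items()},
            "sds": {k: arr(v) for k, v in self.sds.items()},
            "featurewise_w": arr(self.featurewise_w) if self.featurewise_w is not None else None,
            "view_w": {k: arr(v) for k, v in self.view_w.items()},
            "pair_steps": [[arr(a), arr(b)] for a, b in self.pair_steps],
            "step_means": [[arr(a), arr(b)] for a, b in self.step_means],
            "feature_names": list(self.feature_names) if self.feature_names else None,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "FusionTransform":
        return cls(
            strategy=d["strategy"], combination=d["combination"],
            view_names=tuple(d["view_names"]), n_classes=d["n_classes"],
            means={k: np.array(v) for k, v in d["means"].items()},
            sds={k: np.array(v) for k, v in d["sds"].items()},
            featurewise_w=None if d["featurewise_w"] is None else np.array(d["featurewise_w"]),
            view_w={k: np.array(v) for k, v in d["view_w"].items()},
            pair_steps=[(np.array(a), np.array(b)) for a, b in d["pair_steps"]],
            step_means=[(np.array(a), np.array(b)) for a, b in d["step_means"]],
            feature_names=tuple(d["feature_names"]) if d.get("feature_names") else None,
        )


def _standardize_fit(stack: ViewStack) -> tuple[dict, dict]:
    means, sds = {}, {}
    for name, X in stack.views.items():
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        means[name], sds[name] = mu, sd
    return means, sds


def _pair_align(z1: np.ndarray, z2: np.ndarray):
    """SVD alignment of two transformed views' cross covariance."""
    m1, m2 = z1.mean(axis=0), z2.mean(axis=0)
    c = (z1 - m1).T @ (z2 - m2) / max(len(z1) - 1, 1)
    u, s, vt = np.linalg.svd(c)
    r = min(z1.shape[1], z2.shape[1])
    s = np.where(s > _EIG_CUTOFF, s, _EIG_CUTOFF)
    a1 = u[:, :r] / np.sqrt(s[:r])
    a2 = vt.T[:, :r] / np.sqrt(s[:r])
    return a1, a2, (m1, m2)


def fit_fusion(stack: ViewStack, strategy: str = "featurewise",
               combination: str = "sum") -> FusionTransform:
    """Fit the fusion transform on training data."""
    if strategy not in ("featurewise", "viewlevel"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if combination not in ("sum", "concatenate"):
        raise ValueError(f"unknown combination {combination!r}")
    if len(stack.views) < 2:
        raise ValueError("fusion needs at least 2 views")
    classes = np.unique(stack.labels)
    if len(classes) < 2:
        raise ValueError("fusion needs at least 2 classes")
    for cls in classes:
        if (stack.labels == cls).sum() < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 training lesions")

    means, sds = _standardize_fit(stack)
    std_views = {k: (v - means[k]) / sds[k] for k, v in stack.views.items()}
    names = tuple(stack.views)
    c = len(classes)
    t = FusionTransform(strategy=strategy, combination=combination, view_names=names,
                        n_classes=c, means=means, sds=sds,
                        feature_names=stack.feature_names)

    if strategy == "featurewise":
        s = len(names)
        p = next(iter(std_views.values())).shape[1]
        r = c - 1
        W = np.zeros((p, s, r))
        for j in range(p):
            vj = np.stack([std_views[n][:, j] for n in names], axis=1)  # n x S
            sb = between_class_scatter(vj, stack.labels)
            wj = _whitening_projection(sb, c)
            W[j, :, : wj.shape[1]] = wj
        t.featurewise_w = W
        return t

    # viewlevel: per-view discriminant whitening, then sequential pair alignment
    zs = []
    for n in names:
        sb = between_class_scatter(std_views[n], stack.labels)
        w = _whitening_projection(sb, c)
        t.view_w[n] = w
        zs.append(std_views[n] @ w)
    fused = zs[0]
    for z_next in zs[1:]:
        a1, a2, ms = _pair_align(fused, z_next)
        t.pair_steps.append((a1, a2))
        t.step_means.append(ms)
        z1 = (fused - ms[0]) @ a1
        z2 = (z_next - ms[1]) @ a2
        fused = z1 + z2 if combination == "sum" else np.hstack([z1, z2])
    return t


def apply_fusion(transform: FusionTransform, stack: ViewStack) -> np.ndarray:
    """Apply a fitted transform; rows map independently (no batch effects)."""
    if tuple(stack.views) != transform.view_names:
        raise ValueError("view names/order do not match the fitted transform")
    std_views = {}
    for n, X in stack.views.items():
        if X.shape[1] != len(transform.means[n]):
            raise ValueError("feature count mismatch with fitted transform")
        std_views[n] = (X - transform.means[n]) / transform.sds[n]

    if transform.strategy == "featurewise":
        W = transform.featurewise_w
        p, s, r = W.shape
        stacked = np.stack([std_views[n] for n in transform.view_names], axis=2)  # n x p x S
        fused = np.einsum("nps,psr->npr", stacked, W)
        return fused.reshape(len(fused), p * r)

    zs = [std_views[n] @ transform.view_w[n] for n in transform.view_names]
    fused = zs[0]
    for (a1, a2), (m1, m2), z_next in zip(transform.pair_steps, transform.step_means, zs[1:]):
        z1 = (fused - m1) @ a1
        z2 = (z_next - m2) @ a2
        fused = z1 + z2 if transform.combination == "sum" else np.hstack([z1, z2])
    return fused


def fused_table(transform: FusionTransform, stack: ViewStack, index=None) -> pd.DataFrame:
    """Fused matrix as a DataFrame, naming columns after the source features."""
    F = apply_fusion(transform, stack)
    if transform.strategy == "featurewise" and transform.feature_names:
        r = F.shape[1] // len(transform.feature_names)
        if r == 1:
            cols = list(transform.feature_names)
        else:
            cols = [f"{n}__d{k}" for n in transform.feature_names for k in range(r)]
    else:
        cols = [f"fused_{k}" for k in range(F.shape[1])]
    return pd.DataFrame(F, columns=cols, index=index)


def enumerate_combinations(top_sequences, min_size: int = 2) -> list[tuple[str, ...]]:
    """All channel subsets of size >= ``min_size``, smaller subsets first.

    Within each size, order is lexicographic by the input ranking. Four
    input channels yield the canonical 11 combinations (6 pairs, 4 triples,
    1 quadruple).
    """
    seqs = list(top_sequences)
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate channels in top_sequences")
    if len(seqs) < min_size:
        raise ValueError("need at least min_size channels")
    out: list[tuple[str, ...]] = []
    for size in range(min_size, len(seqs) + 1):
        out.extend(_combinations(seqs, size))
    return out
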