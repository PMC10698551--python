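"""3D texture features: GLCM, GLRLM, GLSZM, NGTDM.

All matrices operate on a discretized volume with gray levels 1..Ng inside
the mask and 0 outside. Co-occurrence and run-length statistics are
accumulated along the 13 unique 3D direction offsets at Chebyshev distance
1 and aggregated by averaging the per-direction feature values
(symmetrically for GLCM). Gray-level zones use 26-connectivity.

The GLCM family additionally exposes the per-direction *variance* of a
subset of features (the ``DirectionVariance`` variants), quantifying
directional anisotropy of the texture.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

#: the 13 unique direction offsets (one per +/- pair) at distance 1
OFFSETS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0) or (dx == 0 and ((dy > 0) or (dy == 0 and dz > 0)))
)
assert len(OFFSETS_13) == 13

GLCM_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
    "MCC",
)

#: GLCM features whose across-direction variance is reported as an extra feature
GLCM_DIRVAR_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "JointEnergy",
    "JointEntropy",
    "MaximumProbability",
)

GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

_EPS = np.spacing(1.0)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(disc: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one direction offset.

    ``disc`` holds levels 1..Ng inside the mask, 0 outside; both voxels of a
    pair must lie inside the mask.
    """
    disc = np.asarray(disc)
    ng = int(disc.max())
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, d in enumerate(offset):
        if d > 0:
            src[ax], dst[ax] = slice(0, disc.shape[ax] - d), slice(d, None)
        elif d < 0:
            src[ax], dst[ax] = slice(-d, None), slice(0, disc.shape[ax] + d)
    a = disc[tuple(src)].ravel()
    b = disc[tuple(dst)].ravel()
    valid = (a > 0) & (b > 0)
    a, b = a[valid] - 1, b[valid] - 1
    counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng).astype(float)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        return np.zeros((ng, ng))
    return counts / total


def glcm_features_single(P: np.ndarray) -> dict[str, float]:
    """The 24 GLCM features of one (already normalized, symmetric) matrix."""
    ng = P.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((I * P).sum())  # == mean of marginal, symmetric matrix
    sigma2 = float(((I - mu) ** 2 * P).sum())
    sigma = np.sqrt(sigma2)

    # difference and sum distributions
    k_diff = np.arange(ng, dtype=float)
    p_diff = np.array([P[np.abs(I - J) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.array([P[(I + J) == k].sum() for k in k_sum])

    diff_avg = float((k_diff * p_diff).sum())
    nz_d = p_diff > 0
    nz_s = p_sum > 0

    hxy = float(-(P[P > 0] * np.log2(P[P > 0])).sum())
    pxpy = np.outer(px, px)
    nz = (P > 0) & (pxpy > 0)
    hxy1 = float(-(P[nz] * np.log2(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())

    if hx > 0:
        imc1 = (hxy - hxy1) / hx
    else:
        imc1 = 0.0
    arg = 1.0 - np.exp(-2.0 * max(hxy2 - hxy, 0.0))
    imc2 = float(np.sqrt(max(arg, 0.0)))

    if sigma2 > 0:
        correlation = float(((I * J * P).sum() - mu * mu) / sigma2)
    else:
        correlation = 1.0

    # MCC via the second largest eigenvalue of Q
    if ng > 1 and (px > 0).sum() > 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            Pn = np.where(px[:, None] > 0, P / px[:, None], 0.0)
            Pk = np.where(px[None, :] > 0, P / px[None, :], 0.0)
        Q = Pn @ Pk.T
        eig = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
        mcc = float(np.sqrt(max(eig[1], 0.0))) if len(eig) > 1 else 1.0
    else:
        mcc = 1.0

    inv_var_mask = np.abs(I - J) > 0
    return {
        "Autocorrelation": float((I * J * P).sum()),
        "ClusterProminence": float(((I + J - 2 * mu) ** 4 * P).sum()),
        "ClusterShade": float(((I + J - 2 * mu) ** 3 * P).sum()),
        "ClusterTendency": float(((I + J - 2 * mu) ** 2 * P).sum()),
        "Contrast": float(((I - J) ** 2 * P).sum()),
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-(p_diff[nz_d] * np.log2(p_diff[nz_d])).sum()),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "Id": float((P / (1.0 + np.abs(I - J))).sum()),
        "Idm": float((P / (1.0 + (I - J) ** 2)).sum()),
        "Idmn": float((P / (1.0 + ((I - J) / ng) ** 2)).sum()),
        "Idn": float((P / (1.0 + np.abs(I - J) / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float((P[inv_var_mask] / (I - J)[inv_var_mask] ** 2).sum()),
        "JointAverage": mu,
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(P.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(p_sum[nz_s] * np.log2(p_sum[nz_s])).sum()),
        "SumSquares": sigma2,
        "MCC": mcc,
    }


def glcm_features(disc: np.ndarray, offsets=OFFSETS_13) -> tuple[dict[str, float], dict[str, float]]:
    """Direction-averaged GLCM features and their across-direction variances.

    Returns ``(mean_features, dirvar_features)``; the latter is restricted
    to :data:`GLCM_DIRVAR_NAMES` (population variance over the offsets).
    """
    per_dir = [glcm_features_single(glcm_matrix(disc, off)) for off in offsets]
    mean = {k: float(np.mean([d[k] for d in per_dir])) for k in GLCM_NAMES}
    dirvar = {k: float(np.var([d[k] for d in per_dir])) for k in GLCM_DIRVAR_NAMES}
    return mean, dirvar


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _line_indices(shape, offset):
    """Flat voxel indices of every grid line along ``offset``, separator -1."""
    nx, ny, nz = shape
    dx, dy, dz = offset
    step = dx * ny * nz + dy * nz + dz
    starts = np.ones(shape, dtype=bool)
    # a voxel starts a line if stepping backwards leaves the grid
    idx = np.indices(shape)
    prev = [idx[0] - dx, idx[1] - dy, idx[2] - dz]
    inside = (
        (prev[0] >= 0) & (prev[0] < nx)
        & (prev[1] >= 0) & (prev[1] < ny)
        & (prev[2] >= 0) & (prev[2] < nz)
    )
    starts[inside] = False
    def _span(pos: int, d: int, size: int) -> int:
        if d > 0:
            return (size - pos + d - 1) // d
        if d < 0:
            return pos // (-d) + 1
        return size  # unconstrained along this axis

    pieces = []
    for x, y, z in np.argwhere(starts):
        L = int(min(_span(x, dx, nx), _span(y, dy, ny), _span(z, dz, nz)))
        start_flat = (x * ny + y) * nz + z
        pieces.append(start_flat + step * np.arange(L))
        pieces.append(np.array([-1]))
    return np.concatenate(pieces) if pieces else np.array([-1])


def glrlm_matrix(disc: np.ndarray, offset) -> np.ndarray:
    """Run-length matrix R[gray-1, length-1] along one direction."""
    ng = int(disc.max())
    flat = np.concatenate([disc.ravel(), [-1]])  # index -1 -> separator value -1
    lines = flat[_line_indices(disc.shape, offset)]
    change = np.flatnonzero(np.diff(lines) != 0) + 1
    bounds = np.concatenate([[0], change, [len(lines)]])
    run_vals = lines[bounds[:-1]]
    run_lens = np.diff(bounds)
    keep = run_vals > 0
    run_vals, run_lens = run_vals[keep], run_lens[keep]
    max_len = int(run_lens.max()) if len(run_lens) else 1
    R = np.zeros((ng, max_len))
    np.add.at(R, (run_vals - 1, run_lens - 1), 1.0)
    return R


def _rl_features(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = R.sum()
    if nr == 0:
        return {k: 0.0 for k in GLRLM_NAMES}
    p = R / nr
    ng, lmax = R.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    l = np.arange(1, lmax + 1, dtype=float)[None, :]
    gi = R.sum(axis=1)
    rl = R.sum(axis=0)
    mu_g = float((p * i).sum())
    mu_l = float((p * l).sum())
    pz = p[p > 0]
    return {
        "ShortRunEmphasis": float((p / l**2).sum()),
        "LongRunEmphasis": float((p * l**2).sum()),
        "GrayLevelNonUniformity": float((gi**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((gi**2).sum() / nr**2),
        "RunLengthNonUniformity": float((rl**2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((rl**2).sum() / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_g) ** 2).sum()),
        "RunVariance": float((p * (l - mu_l) ** 2).sum()),
        "RunEntropy": float(-(pz * np.log2(pz)).sum()),
        "LowGrayLevelRunEmphasis": float((p / i**2).sum()),
        "HighGrayLevelRunEmphasis": float((p * i**2).sum()),
        "ShortRunLowGrayLevelEmphasis": float((p / (i**2 * l**2)).sum()),
        "ShortRunHighGrayLevelEmphasis": float((p * i**2 / l**2).sum()),
        "LongRunLowGrayLevelEmphasis": float((p * l**2 / i**2).sum()),
        "LongRunHighGrayLevelEmphasis": float((p * i**2 * l**2).sum()),
    }


def glrlm_features(disc: np.ndarray, offsets=OFFSETS_13) -> dict[str, float]:
    n_voxels = int((disc > 0).sum())
    per_dir = [_rl_features(glrlm_matrix(disc, off), n_voxels) for off in offsets]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm_features(disc: np.ndarray) -> dict[str, float]:
    """Gray-level size-zone features (26-connected zones)."""
    ng = int(disc.max())
    n_voxels = int((disc > 0).sum())
    structure = np.ones((3, 3, 3), dtype=int)
    zones: list[tuple[int, int]] = []  # (gray, size)
    for g in range(1, ng + 1):
        region = disc == g
        if not region.any():
            continue
        labels, nlab = ndimage.label(region, structure=structure)
        sizes = np.bincount(labels.ravel())[1:]
        zones.extend((g, int(s)) for s in sizes)
    if not zones:
        return {k: 0.0 for k in GLSZM_NAMES}
    grays = np.array([z[0] for z in zones], dtype=float)
    sizes = np.array([z[1] for z in zones], dtype=float)
    nz = float(len(zones))
    smax = int(sizes.max())
    Z = np.zeros((ng, smax))
    np.add.at(Z, (grays.astype(int) - 1, sizes.astype(int) - 1), 1.0)
    p = Z / nz
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    s = np.arange(1, smax + 1, dtype=float)[None, :]
    gi = Z.sum(axis=1)
    zs = Z.sum(axis=0)
    mu_g = float((p * i).sum())
    mu_s = float((p * s).sum())
    pz = p[p > 0]
    return {
        "SmallAreaEmphasis": float((p / s**2).sum()),
        "LargeAreaEmphasis": float((p * s**2).sum()),
        "GrayLevelNonUniformity": float((gi**2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((gi**2).sum() / nz**2),
        "SizeZoneNonUniformity": float((zs**2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((zs**2).sum() / nz**2),
        "ZonePercentage": float(nz / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_g) ** 2).sum()),
        "ZoneVariance": float((p * (s - mu_s) ** 2).sum()),
        "ZoneEntropy": float(-(pz * np.log2(pz)).sum()),
        "LowGrayLevelZoneEmphasis": float((p / i**2).sum()),
        "HighGrayLevelZoneEmphasis": float((p * i**2).sum()),
        "SmallAreaLowGrayLevelEmphasis": float((p / (i**2 * s**2)).sum()),
        "SmallAreaHighGrayLevelEmphasis": float((p * i**2 / s**2).sum()),
        "LargeAreaLowGrayLevelEmphasis": float((p * s**2 / i**2).sum()),
        "LargeAreaHighGrayLevelEmphasis": float((p * i**2 * s**2).sum()),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_features(disc: np.ndarray) -> dict[str, float]:
    """Neighborhood gray-tone difference features (26-neighborhood means)."""
    mask = disc > 0
    ng = int(disc.max())
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    vals = np.where(mask, disc, 0).astype(float)
    nb_sum = ndimage.correlate(vals, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(mask.astype(float), kernel, mode="constant", cval=0.0)
    valid = mask & (nb_cnt > 0)
    nvc = int(valid.sum())
    if nvc == 0:
        return {k: 0.0 for k in NGTDM_NAMES}
    avg = nb_sum[valid] / nb_cnt[valid]
    lev = disc[valid].astype(float)
    s = np.zeros(ng)
    n_i = np.zeros(ng)
    np.add.at(s, (lev - 1).astype(int), np.abs(lev - avg))
    np.add.at(n_i, (lev - 1).astype(int), 1.0)
    p = n_i / nvc
    i = np.arange(1, ng + 1, dtype=float)
    present = p > 0
    ngp = int(present.sum())

    coarseness = 1.0 / max(float((p * s).sum()), _EPS)
    coarseness = min(coarseness, 1e6)

    if ngp > 1:
        pi, pj = np.meshgrid(p, p, indexing="ij")
        ii, jj = np.meshgrid(i, i, indexing="ij")
        both = (pi > 0) & (pj > 0)
        contrast = float((pi * pj * (ii - jj) ** 2)[both].sum()) / (ngp * (ngp - 1))
        contrast *= float(s.sum()) / nvc
        denom_b = float(np.abs((ii * pi - jj * pj))[both].sum())
        busyness = float((p * s).sum()) / denom_b if denom_b > 0 else 0.0
        num_c = ((np.abs(ii - jj))[both] * (pi * s[:, None] + pj * s[None, :])[both] /
                 (pi + pj)[both]).sum()
        complexity = float(num_c) / nvc
        strength_num = float(((pi + pj) * (ii - jj) ** 2)[both].sum())
        s_sum = float(s.sum())
        strength = strength_num / s_sum if s_sum > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }
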