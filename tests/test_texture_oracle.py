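"""Brute-force co-occurrence / run-length oracles for the texture features.

The oracle builds matrices by explicit voxel loops and evaluates every
feature with direct formula transcriptions, independently of the
vectorized implementation.
"""

import numpy as np
import pytest

from radfuse.features.texture import (
    GLCM_NAMES,
    OFFSETS_13,
    glcm_features,
    glcm_features_single,
    glcm_matrix,
    glrlm_matrix,
)


def brute_glcm(disc, offset):
    ng = int(disc.max())
    C = np.zeros((ng, ng))
    nx, ny, nz = disc.shape
    dx, dy, dz = offset
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = disc[x, y, z]
                if a == 0:
                    continue
                for s in (1, -1):
                    xx, yy, zz = x + s * dx, y + s * dy, z + s * dz
                    if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                        b = disc[xx, yy, zz]
                        if b > 0:
                            C[a - 1, b - 1] += 1
    return C / C.sum() if C.sum() else C


def brute_glcm_features(P):
    ng = P.shape[0]
    px = P.sum(axis=1)
    mu = sum((i + 1) * P[i, j] for i in range(ng) for j in range(ng))
    var = sum((i + 1 - mu) ** 2 * P[i, j] for i in range(ng) for j in range(ng))
    out = {}
    out["Autocorrelation"] = sum((i + 1) * (j + 1) * P[i, j]
                                 for i in range(ng) for j in range(ng))
    for power, key in ((2, "ClusterTendency"), (3, "ClusterShade"), (4, "ClusterProminence")):
        out[key] = sum((i + j + 2 - 2 * mu) ** power * P[i, j]
                       for i in range(ng) for j in range(ng))
    out["Contrast"] = sum((i - j) ** 2 * P[i, j] for i in range(ng) for j in range(ng))
    out["Correlation"] = (out["Autocorrelation"] - mu * mu) / var if var > 0 else 1.0
    p_diff = np.zeros(ng)
    p_sum = np.zeros(2 * ng + 1)
    for i in range(ng):
        for j in range(ng):
            p_diff[abs(i - j)] += P[i, j]
            p_sum[i + j + 2] += P[i, j]
    da = sum(k * p_diff[k] for k in range(ng))
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = -sum(p * np.log2(p) for p in p_diff if p > 0)
    out["DifferenceVariance"] = sum((k - da) ** 2 * p_diff[k] for k in range(ng))
    out["Id"] = sum(P[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    out["Idm"] = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    out["Idmn"] = sum(P[i, j] / (1 + ((i - j) / ng) ** 2)
                      for i in range(ng) for j in range(ng))
    out["Idn"] = sum(P[i, j] / (1 + abs(i - j) / ng)
                     for i in range(ng) for j in range(ng))
    hxy = -sum(P[i, j] * np.log2(P[i, j])
               for i in range(ng) for j in range(ng) if P[i, j] > 0)
    hxy1 = -sum(P[i, j] * np.log2(px[i] * px[j])
                for i in range(ng) for j in range(ng)
                if P[i, j] > 0 and px[i] * px[j] > 0)
    hxy2 = -sum(px[i] * px[j] * np.log2(px[i] * px[j])
                for i in range(ng) for j in range(ng) if px[i] * px[j] > 0)
    hx = -sum(p * np.log2(p) for p in px if p > 0)
    out["Imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    out["Imc2"] = np.sqrt(max(1 - np.exp(-2 * max(hxy2 - hxy, 0.0)), 0.0))
    out["InverseVariance"] = sum(P[i, j] / (i - j) ** 2
                                 for i in range(ng) for j in range(ng) if i != j)
    out["JointAverage"] = mu
    out["JointEnergy"] = sum(P[i, j] ** 2 for i in range(ng) for j in range(ng))
    out["JointEntropy"] = hxy
    out["MaximumProbability"] = P.max()
    out["SumAverage"] = sum(k * p_sum[k] for k in range(2, 2 * ng + 1))
    out["SumEntropy"] = -sum(p * np.log2(p) for p in p_sum if p > 0)
    out["SumSquares"] = var
    # MCC: second-largest eigenvalue of Q
    if ng > 1 and (px > 0).sum() > 1:
        Q = np.zeros((ng, ng))
        for i in range(ng):
            for j in range(ng):
                if px[i] > 0:
                    Q[i, j] = sum(P[i, kk] * P[j, kk] / (px[i] * px[kk])
                                  for kk in range(ng) if px[kk] > 0)
        eig = sorted(np.real(np.linalg.eigvals(Q)), reverse=True)
        out["MCC"] = np.sqrt(max(eig[1], 0.0))
    else:
        out["MCC"] = 1.0
    return out


def _random_disc(seed, shape=(8, 8, 8), levels=5):
    rng = np.random.default_rng(seed)
    disc = rng.integers(1, levels + 1, size=shape)
    mask = rng.random(shape) > 0.25
    return np.where(mask, disc, 0).astype(np.int64)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_glcm_matches_brute_force_oracle(seed):
    """Every GLCM feature equals the brute-force loop oracle to 1e-10 relative."""
    disc = _random_disc(seed)
    for offset in OFFSETS_13[::4]:  # spot-check individual directions
        P_impl = glcm_matrix(disc, offset)
        P_oracle = brute_glcm(disc, offset)
        np.testing.assert_allclose(P_impl, P_oracle, atol=1e-14)
        impl = glcm_features_single(P_impl)
        oracle = brute_glcm_features(P_oracle)
        for name in GLCM_NAMES:
            assert impl[name] == pytest.approx(oracle[name], rel=1e-10, abs=1e-12), name
    # direction-aggregated values equal the mean/variance of per-direction oracles
    mean_impl, dirvar_impl = glcm_features(disc)
    per_dir = [brute_glcm_features(brute_glcm(disc, off)) for off in OFFSETS_13]
    for name in GLCM_NAMES:
        expected = np.mean([d[name] for d in per_dir])
        assert mean_impl[name] == pytest.approx(expected, rel=1e-10, abs=1e-12), name
    for name, value in dirvar_impl.items():
        expected = np.var([d[name] for d in per_dir])
        assert value == pytest.approx(expected, rel=1e-9, abs=1e-12), name


def brute_runs(disc, offset):
    """Run-length matrix by explicit line walking."""
    ng = int(disc.max())
    shape = disc.shape
    runs = {}
    starts = []
    for idx in np.ndindex(shape):
        prev = tuple(np.array(idx) - np.array(offset))
        if not all(0 <= p < s for p, s in zip(prev, shape)):
            starts.append(idx)
    for start in starts:
        line = []
        pos = np.array(start)
        while all(0 <= p < s for p, s in zip(pos, shape)):
            line.append(disc[tuple(pos)])
            pos = pos + np.array(offset)
        i = 0
        while i < len(line):
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            if line[i] > 0:
                runs[(line[i], j - i)] = runs.get((line[i], j - i), 0) + 1
            i = j
    max_len = max((l for (_, l) in runs), default=1)
    R = np.zeros((ng, max_len))
    for (g, l), c in runs.items():
        R[g - 1, l - 1] = c
    return R


@pytest.mark.parametrize("offset", [(1, 0, 0), (0, 0, 1), (1, -1, 1)])
def test_glrlm_matrix_matches_brute_force(offset):
    disc = _random_disc(7, shape=(6, 6, 6), levels=3)
    R_impl = glrlm_matrix(disc, offset)
    R_oracle = brute_runs(disc, offset)
    np.testing.assert_array_equal(R_impl, R_oracle)
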