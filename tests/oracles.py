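"""Independent brute-force oracles used to verify the vectorized pipeline.

Everything here is written as plain loops over definitions, deliberately
ignoring how the package computes the same quantities.
"""
from __future__ import annotations

import numpy as np


def glcm_oracle(levels: np.ndarray, n_levels: int, offset) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix by exhaustive pair scan."""
    counts = np.zeros((n_levels, n_levels))
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = levels[x, y, z]
                if a == 0:
                    continue
                px, py, pz = x + offset[0], y + offset[1], z + offset[2]
                if not (0 <= px < nx and 0 <= py < ny and 0 <= pz < nz):
                    continue
                b = levels[px, py, pz]
                if b == 0:
                    continue
                counts[a - 1, b - 1] += 1
                counts[b - 1, a - 1] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no pair")
    return counts / total


def haralick_oracle(P: np.ndarray, log=np.log) -> dict[str, float]:
    """All 16 features by naive double loops over the matrix definition."""
    ng = P.shape[0]

    def xlogx(p):
        return p * log(p) if p > 0 else 0.0

    px = [sum(P[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(P[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sigma_x = np.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sigma_y = np.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))

    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(0, ng)}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]

    asm = sum(P[i, j] ** 2 for i in range(ng) for j in range(ng))
    contrast = sum((i - j) ** 2 * P[i, j] for i in range(ng) for j in range(ng))
    if sigma_x * sigma_y == 0:
        correlation = 1.0
    else:
        correlation = (
            sum((i + 1) * (j + 1) * P[i, j] for i in range(ng) for j in range(ng))
            - mu_x * mu_y
        ) / (sigma_x * sigma_y)
    entropy = -sum(xlogx(P[i, j]) for i in range(ng) for j in range(ng))
    homogeneity = sum(P[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    idm = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    sum_average = sum(k * p_sum[k] for k in p_sum)
    sum_entropy = -sum(xlogx(p_sum[k]) for k in p_sum)
    sum_variance = sum((k - sum_average) ** 2 * p_sum[k] for k in p_sum)
    difference_entropy = -sum(xlogx(p_diff[k]) for k in p_diff)
    mu_d = sum(k * p_diff[k] for k in p_diff)
    difference_variance = sum((k - mu_d) ** 2 * p_diff[k] for k in p_diff)
    shade = sum(
        (i + 1 + j + 1 - mu_x - mu_y) ** 3 * P[i, j] for i in range(ng) for j in range(ng)
    )
    prominence = sum(
        (i + 1 + j + 1 - mu_x - mu_y) ** 4 * P[i, j] for i in range(ng) for j in range(ng)
    )
    max_prob = max(P[i, j] for i in range(ng) for j in range(ng))
    hx = -sum(xlogx(p) for p in px)
    hy = -sum(xlogx(p) for p in py)
    # P(i,j) > 0 implies px(i), py(j) > 0; 0 * log(.) terms drop out
    hxy1 = -sum(
        P[i, j] * log(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if P[i, j] > 0
    )
    hxy2 = -sum(
        xlogx(px[i] * py[j]) for i in range(ng) for j in range(ng)
    )
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy))))
    return {
        "entropy": entropy,
        "homogeneity": homogeneity,
        "contrast": contrast,
        "correlation": correlation,
        "angular_second_moment": asm,
        "difference_entropy": difference_entropy,
        "difference_variance": difference_variance,
        "inverse_difference_moment": idm,
        "sum_average": sum_average,
        "sum_entropy": sum_entropy,
        "sum_variance": sum_variance,
        "cluster_prominence": prominence,
        "cluster_shade": shade,
        "maximum_probability": max_prob,
        "imc1": imc1,
        "imc2": imc2,
    }


def auc_pairs_oracle(scores, labels) -> float:
    """AUC by exhaustive enumeration of positive-negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def sphere_peak_oracle(values, spacing, center, radius_mm) -> float:
    """Mean SUV over all voxels whose centers lie within radius of center."""
    sel = []
    nx, ny, nz = values.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                d2 = (
                    ((x - center[0]) * spacing[0]) ** 2
                    + ((y - center[1]) * spacing[1]) ** 2
                    + ((z - center[2]) * spacing[2]) ** 2
                )
                if d2 <= radius_mm ** 2:
                    sel.append(values[x, y, z])
    return float(np.mean(sel))


def brute_mtv(values, search, fraction) -> np.ndarray:
    """Voxel-by-voxel threshold scan."""
    suv_max = max(
        values[x, y, z]
        for x in range(values.shape[0])
        for y in range(values.shape[1])
        for z in range(values.shape[2])
        if search[x, y, z]
    )
    out = np.zeros(values.shape, dtype=bool)
    thr = fraction * suv_max
    for x in range(values.shape[0]):
        for y in range(values.shape[1]):
            for z in range(values.shape[2]):
                if search[x, y, z] and values[x, y, z] >= thr:
                    out[x, y, z] = True
    return out
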