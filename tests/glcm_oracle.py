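"""Independent brute-force oracle for GLCM construction and features.

Everything here is written as naive loops over voxel pairs and matrix cells,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def naive_glcm(labels, mask, offset, levels, symmetrize):
    """Co-occurrence matrix by explicit pair enumeration."""
    members = {tuple(v) for v in np.argwhere(mask)}
    counts = [[0.0] * levels for _ in range(levels)]
    n = 0
    for z, y, x in members:
        other = (z + offset[0], y + offset[1], x + offset[2])
        if other in members:
            a = int(labels[z, y, x]) - 1
            b = int(labels[other]) - 1
            counts[a][b] += 1.0
            n += 1
    if n == 0:
        return None
    if symmetrize:
        counts = [
            [counts[i][j] + counts[j][i] for j in range(levels)]
            for i in range(levels)
        ]
    total = sum(sum(row) for row in counts)
    return [[c / total for c in row] for row in counts]


def naive_features(P):
    """All 18 base features from a normalised matrix, by direct summation."""
    L = len(P)
    idx = range(1, L + 1)
    Px = [sum(P[i - 1][j - 1] for j in idx) for i in idx]
    Py = [sum(P[i - 1][j - 1] for i in idx) for j in idx]
    mu_x = sum(i * Px[i - 1] for i in idx)
    mu_y = sum(j * Py[j - 1] for j in idx)
    sig_x = math.sqrt(sum((i - mu_x) ** 2 * Px[i - 1] for i in idx))
    sig_y = math.sqrt(sum((j - mu_y) ** 2 * Py[j - 1] for j in idx))

    def xlnx(p):
        return p * math.log(p) if p > 0 else 0.0

    pxy_sum = {}
    pxy_diff = {}
    for i in idx:
        for j in idx:
            pxy_sum[i + j] = pxy_sum.get(i + j, 0.0) + P[i - 1][j - 1]
            pxy_diff[abs(i - j)] = pxy_diff.get(abs(i - j), 0.0) + P[i - 1][j - 1]

    Hx = -sum(xlnx(p) for p in Px)
    Hy = -sum(xlnx(p) for p in Py)
    Hxy = -sum(xlnx(P[i - 1][j - 1]) for i in idx for j in idx)
    Hxy1 = -sum(
        P[i - 1][j - 1] * math.log(Px[i - 1] * Py[j - 1])
        for i in idx
        for j in idx
        if P[i - 1][j - 1] > 0
    )
    Hxy2 = -sum(xlnx(Px[i - 1] * Py[j - 1]) for i in idx for j in idx)

    out = {}
    out["Mean"] = mu_x
    out["Variance"] = sig_x**2
    out["Energy"] = sum(P[i - 1][j - 1] ** 2 for i in idx for j in idx)
    out["Angular 2nd moment"] = out["Energy"]
    out["Entropy"] = Hxy
    out["Contrast"] = sum((i - j) ** 2 * P[i - 1][j - 1] for i in idx for j in idx)
    if sig_x * sig_y > 0:
        out["Correlation"] = (
            sum(i * j * P[i - 1][j - 1] for i in idx for j in idx) - mu_x * mu_y
        ) / (sig_x * sig_y)
    else:
        out["Correlation"] = 0.0
    out["Dissimilarity"] = sum(
        abs(i - j) * P[i - 1][j - 1] for i in idx for j in idx
    )
    out["Homogeneity"] = sum(
        P[i - 1][j - 1] / (1 + (i - j) ** 2) for i in idx for j in idx
    )
    denom = max(Hx, Hy)
    out["Information correlation A"] = (Hxy - Hxy1) / denom if denom > 0 else 0.0
    out["Information correlation B"] = 1.0 - math.exp(-2.0 * (Hxy2 - Hxy))

    # U(i,j) = sum_k P(i,k) P(j,k) / (Px(i) Py(k)), zero-marginal rows removed
    keep_i = [i for i in idx if Px[i - 1] > 0]
    keep_j = [j for j in idx if Py[j - 1] > 0]
    U = np.array(
        [
            [
                sum(
                    P[i - 1][k - 1] * P[j - 1][k - 1] / (Px[i - 1] * Py[k - 1])
                    for k in keep_j
                )
                for j in keep_i
            ]
            for i in keep_i
        ]
    )
    if U.shape[0] >= 2:
        ev = np.linalg.eigvals(U)
        ev = sorted((v.real for v in ev if abs(v.imag) < 1e-8), reverse=True)
        out["Maximal correlation coefficient"] = ev[1] if len(ev) >= 2 else 0.0
    else:
        out["Maximal correlation coefficient"] = 0.0

    mu_d = sum(k * p for k, p in pxy_diff.items())
    out["Diff average"] = mu_d
    out["Diff variance"] = sum((k - mu_d) ** 2 * p for k, p in pxy_diff.items())
    out["Diff entropy"] = -sum(xlnx(p) for p in pxy_diff.values())
    mu_s = sum(k * p for k, p in pxy_sum.items())
    out["Sum average"] = mu_s
    out["Sum variance"] = sum((k - mu_s) ** 2 * p for k, p in pxy_sum.items())
    out["Sum entropy"] = -sum(xlnx(p) for p in pxy_sum.values())
    return out


def naive_quantize(values, levels):
    """Equal-width quantization over [min, max] into 1..levels."""
    vmin = min(values)
    vmax = max(values)
    if vmax == vmin:
        return [1 for _ in values]
    width = (vmax - vmin) / levels
    out = []
    for v in values:
        lab = int((v - vmin) // width) + 1
        out.append(min(max(lab, 1), levels))
    return out
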