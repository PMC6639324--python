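"""Independent brute-force oracles, written before the implementations they
check and kept free of any code shared with the package's own feature paths."""

import math

import numpy as np


def glcm_brute_force(levels, mask, direction, distance, G):
    """Enumerate every in-mask voxel pair explicitly; symmetrize at the end."""
    dr, dc = direction
    nr, nc, ns = levels.shape
    C = np.zeros((G, G))
    for s in range(ns):
        for r in range(nr):
            for c in range(nc):
                r2, c2 = r + dr * distance, c + dc * distance
                if 0 <= r2 < nr and 0 <= c2 < nc:
                    if mask[r, c, s] and mask[r2, c2, s]:
                        C[levels[r, c, s] - 1, levels[r2, c2, s] - 1] += 1
    return C + C.T


def haralick_brute_force(P):
    """All 20 co-occurrence features by direct double-summation over (i, j).

    P is a normalized symmetric G x G matrix; levels are 1-based; logs base 2.
    """
    G = P.shape[0]
    px = [sum(P[i, j] for j in range(G)) for i in range(G)]
    py = [sum(P[i, j] for i in range(G)) for j in range(G)]
    mu_x = sum((i + 1) * px[i] for i in range(G))
    mu_y = sum((j + 1) * py[j] for j in range(G))
    sigma_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(G)))
    sigma_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(G)))

    p_sum = {}
    p_diff = {}
    for i in range(G):
        for j in range(G):
            p_sum[i + j + 2] = p_sum.get(i + j + 2, 0.0) + P[i, j]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + P[i, j]

    def h(values):
        return -sum(v * math.log2(v) for v in values if v > 0)

    out = {}
    out["autocorrelation"] = sum(
        (i + 1) * (j + 1) * P[i, j] for i in range(G) for j in range(G)
    )
    out["contrast"] = sum((i - j) ** 2 * P[i, j] for i in range(G) for j in range(G))
    if sigma_x * sigma_y > 1e-12:
        corr = (out["autocorrelation"] - mu_x * mu_y) / (sigma_x * sigma_y)
        out["correlation"] = min(1.0, max(-1.0, corr))
    else:
        out["correlation"] = 0.0
    out["cluster_shade"] = sum(
        (i + 1 + j + 1 - mu_x - mu_y) ** 3 * P[i, j] for i in range(G) for j in range(G)
    )
    out["cluster_prominence"] = sum(
        (i + 1 + j + 1 - mu_x - mu_y) ** 4 * P[i, j] for i in range(G) for j in range(G)
    )
    out["dissimilarity"] = sum(abs(i - j) * P[i, j] for i in range(G) for j in range(G))
    out["energy"] = sum(P[i, j] ** 2 for i in range(G) for j in range(G))
    out["entropy"] = h(P.ravel())
    out["homogeneity"] = sum(
        P[i, j] / (1 + abs(i - j)) for i in range(G) for j in range(G)
    )
    out["maximum_probability"] = max(P.ravel())
    mu = sum((i + 1) * P[i, j] for i in range(G) for j in range(G))
    out["variance"] = sum(
        (i + 1 - mu) ** 2 * P[i, j] for i in range(G) for j in range(G)
    )
    out["sum_average"] = sum(k * v for k, v in p_sum.items())
    out["sum_variance"] = sum(
        (k - out["sum_average"]) ** 2 * v for k, v in p_sum.items()
    )
    out["sum_entropy"] = h(list(p_sum.values()))
    dmean = sum(k * v for k, v in p_diff.items())
    out["difference_variance"] = sum((k - dmean) ** 2 * v for k, v in p_diff.items())
    out["difference_entropy"] = h(list(p_diff.values()))
    hx, hy = h(px), h(py)
    hxy = out["entropy"]
    hxy1 = -sum(
        P[i, j] * math.log2(px[i] * py[j])
        for i in range(G)
        for j in range(G)
        if P[i, j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in range(G)
        for j in range(G)
        if px[i] * py[j] > 0
    )
    out["imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 1e-12 else 0.0
    out["imc2"] = math.sqrt(min(1.0, max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))))
    out["inverse_difference_moment"] = sum(
        P[i, j] / (1 + (i - j) ** 2) for i in range(G) for j in range(G)
    )
    out["normalized_inverse_difference_moment"] = sum(
        P[i, j] / (1 + ((i - j) / G) ** 2) for i in range(G) for j in range(G)
    )
    return out


def mutual_information_brute_force(a, b):
    """Plug-in MI in bits via the explicit sum p log2(p / (p1 p2))."""
    a = list(a)
    b = list(b)
    n = len(a)
    pairs = {}
    for x, y in zip(a, b):
        pairs[(x, y)] = pairs.get((x, y), 0) + 1
    pa = {}
    pb = {}
    for x in a:
        pa[x] = pa.get(x, 0) + 1
    for y in b:
        pb[y] = pb.get(y, 0) + 1
    mi = 0.0
    for (x, y), c in pairs.items():
        p = c / n
        mi += p * math.log2(p / ((pa[x] / n) * (pb[y] / n)))
    return mi


def auc_brute_force(scores, labels):
    """Concordant-pair fraction; tied scores count one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
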