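"""Independent brute-force reference implementations used only by tests.

These enumerate pixel pairs and runs directly with explicit Python loops
and recompute every feature from its defining sum, sharing no code with
the package implementation.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_glcm(img, levels, directions=(0, 45, 90, 135), distance=1):
    img = np.asarray(img)
    h, w = img.shape
    P = np.zeros((levels, levels), dtype=float)
    for d in directions:
        dr, dc = OFFSETS[d]
        dr, dc = dr * distance, dc * distance
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    P[img[r, c], img[r2, c2]] += 1
                    P[img[r2, c2], img[r, c]] += 1  # symmetrize
    return P / P.sum()


def brute_glcm_features(P):
    n = P.shape[0]
    contrast = dis = asm = homog = 0.0
    mu_i = mu_j = 0.0
    for i in range(n):
        for j in range(n):
            p = P[i, j]
            contrast += p * (i - j) ** 2
            dis += p * abs(i - j)
            asm += p * p
            homog += p / (1 + (i - j) ** 2)
            mu_i += i * p
            mu_j += j * p
    var_i = sum((i - mu_i) ** 2 * P[i, j] for i in range(n) for j in range(n))
    var_j = sum((j - mu_j) ** 2 * P[i, j] for i in range(n) for j in range(n))
    sig = math.sqrt(var_i) * math.sqrt(var_j)
    if sig == 0:
        corr = 1.0
    else:
        corr = sum((i - mu_i) * (j - mu_j) * P[i, j]
                   for i in range(n) for j in range(n)) / sig
    return {"contrast": contrast, "dissimilarity": dis, "energy": math.sqrt(asm),
            "homogeneity": homog, "correlation": corr, "asm": asm}


def brute_glrlm(img, levels, directions=(0, 45, 90, 135)):
    """Run counts by walking each direction from every run-start pixel."""
    img = np.asarray(img)
    h, w = img.shape
    max_len = max(h, w)
    r = np.zeros((levels, max_len), dtype=int)
    for d in directions:
        dr, dc = OFFSETS[d]
        for r0 in range(h):
            for c0 in range(w):
                pr, pc = r0 - dr, c0 - dc
                if 0 <= pr < h and 0 <= pc < w and img[pr, pc] == img[r0, c0]:
                    continue  # not a run start
                length = 1
                rr, cc = r0 + dr, c0 + dc
                while 0 <= rr < h and 0 <= cc < w and img[rr, cc] == img[r0, c0]:
                    length += 1
                    rr, cc = rr + dr, cc + dc
                r[img[r0, c0], length - 1] += 1
    return r


def brute_glrlm_features(r, n_pixels):
    n_r = int(r.sum())
    sre = lre = 0.0
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            if r[i, j]:
                sre += r[i, j] / (j + 1) ** 2
                lre += r[i, j] * (j + 1) ** 2
    gln = sum(float(r[i, :].sum()) ** 2 for i in range(r.shape[0]))
    rln = sum(float(r[:, j].sum()) ** 2 for j in range(r.shape[1]))
    return {"sre": sre / n_r, "lre": lre / n_r, "gln": gln / n_r,
            "rln": rln / n_r, "rp": n_r / n_pixels}


def brute_lda_axes(X, y, ridge=1e-6):
    """Generalized-eigenvector discriminant subspace via scipy.linalg.eig
    on the explicitly inverted problem (dense, no symmetry exploited)."""
    import scipy.linalg

    X = np.asarray(X, float)
    classes = np.unique(y)
    n, p = X.shape
    xbar = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c in classes:
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        Sw += (Xc - mc).T @ (Xc - mc)
        Sb += len(Xc) * np.outer(mc - xbar, mc - xbar)
    Sw = Sw + ridge * (np.trace(Sw) / p) * np.eye(p)
    vals, vecs = scipy.linalg.eig(np.linalg.inv(Sw) @ Sb)
    order = np.argsort(-vals.real)
    k = len(classes) - 1
    return vals.real[order][:k], vecs.real[:, order][:, :k]
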