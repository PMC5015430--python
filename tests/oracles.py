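"""Brute-force reference implementations used to check the package.

Everything here is deliberately naive (nested loops, dense algebra) and
independent of the code paths it validates.
"""

from __future__ import annotations

import numpy as np


def dense_eigenfilters(images, k1: int, k2: int, L: int) -> np.ndarray:
    """Leading eigenvectors of the pooled mean-removed window scatter,
    computed by explicit outer-product accumulation and np.linalg.eigh."""
    d = k1 * k2
    scatter = np.zeros((d, d))
    for img in images:
        img = np.asarray(img, dtype=np.float64)
        h, w = img.shape
        for r in range(h - k1 + 1):
            for c in range(w - k2 + 1):
                v = img[r:r + k1, c:c + k2].ravel().copy()
                v -= v.mean()
                scatter += np.outer(v, v)
    vals, vecs = np.linalg.eigh(scatter)
    order = np.argsort(vals)[::-1]
    filters = np.empty((L, k1, k2))
    for i in range(L):
        v = vecs[:, order[i]]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        filters[i] = v.reshape(k1, k2)
    return filters


def naive_correlation(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-size zero-padded correlation by nested loops."""
    img = np.asarray(image, dtype=np.float64)
    k = np.asarray(kernel, dtype=np.float64)
    h, w = img.shape
    k1, k2 = k.shape
    ph, pw = (k1 - 1) // 2, (k2 - 1) // 2
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            acc = 0.0
            for u in range(k1):
                for v in range(k2):
                    yy, xx = y + u - ph, x + v - pw
                    if 0 <= yy < h and 0 <= xx < w:
                        acc += img[yy, xx] * k[u, v]
            out[y, x] = acc
    return out


def naive_hash(responses) -> np.ndarray:
    """Per-pixel bit assembly, first map = most significant bit."""
    responses = [np.asarray(r) for r in responses]
    width = len(responses)
    h, w = responses[0].shape
    out = np.zeros((h, w), dtype=np.int64)
    for y in range(h):
        for x in range(w):
            code = 0
            for ell in range(width):
                bit = 1 if responses[ell][y, x] > 0 else 0
                code += bit * 2 ** (width - 1 - ell)
            out[y, x] = code
    return out


def naive_block_histogram(codes: np.ndarray, block_size: int,
                          overlap_fraction: float, n_bins: int) -> np.ndarray:
    """Row-major block tiling with edge-anchored final blocks, counted
    element by element."""
    codes = np.asarray(codes)
    side_r, side_c = codes.shape
    stride = max(1, int(round(block_size * (1.0 - overlap_fraction))))

    def starts(side):
        s = list(range(0, side - block_size + 1, stride))
        if s[-1] != side - block_size:
            s.append(side - block_size)
        return s

    hists = []
    for r in starts(side_r):
        for c in starts(side_c):
            hist = np.zeros(n_bins)
            for y in range(r, r + block_size):
                for x in range(c, c + block_size):
                    hist[codes[y, x]] += 1
            hists.append(hist)
    return np.concatenate(hists)


def bilinear_resample(frame: np.ndarray, rect: tuple[int, int, int, int],
                      size: int) -> np.ndarray:
    """Pixel-center-aligned bilinear resize of an integer rect of ``frame``,
    reading zero outside the frame, by nested loops."""
    img = np.asarray(frame, dtype=np.float64)
    fh, fw = img.shape
    x0, y0, w, h = rect

    def at(yy, xx):
        return img[yy, xx] if 0 <= yy < fh and 0 <= xx < fw else 0.0

    out = np.zeros((size, size))
    for r in range(size):
        for c in range(size):
            sy = y0 + (r + 0.5) * (h / size) - 0.5
            sx = x0 + (c + 0.5) * (w / size) - 0.5
            fy, fx = int(np.floor(sy)), int(np.floor(sx))
            dy, dx = sy - fy, sx - fx
            out[r, c] = ((1 - dy) * (1 - dx) * at(fy, fx)
                         + (1 - dy) * dx * at(fy, fx + 1)
                         + dy * (1 - dx) * at(fy + 1, fx)
                         + dy * dx * at(fy + 1, fx + 1))
    return out


def systematic_copy_counts(weights: np.ndarray, n: int, u: float) -> np.ndarray:
    """Copy count per parent under systematic resampling with offset ``u``."""
    weights = np.asarray(weights, dtype=np.float64)
    counts = np.zeros(len(weights), dtype=int)
    cum = np.cumsum(weights)
    cum[-1] = 1.0
    for j in range(n):
        pos = (j + u) / n
        i = 0
        while cum[i] <= pos:
            i += 1
        counts[i] += 1
    return counts


def rank_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Probability a random positive outscores a random negative (ties = 1/2)."""
    total = 0.0
    for p in scores_pos:
        for q in scores_neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(scores_pos) * len(scores_neg))
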