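"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use explicit Python loops and first-principles
definitions, sharing no code with the package's vectorized paths.
"""

from __future__ import annotations

import math

import numpy as np


def flood_fill_component_count(mask: np.ndarray) -> int:
    """Count 4-connected foreground components by iterative flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    count = 0
    for si in range(h):
        for sj in range(w):
            if mask[si, sj] and not seen[si, sj]:
                count += 1
                stack = [(si, sj)]
                seen[si, sj] = True
                while stack:
                    i, j = stack.pop()
                    for ni, nj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
                        if 0 <= ni < h and 0 <= nj < w and mask[ni, nj] \
                                and not seen[ni, nj]:
                            seen[ni, nj] = True
                            stack.append((ni, nj))
    return count


def hog_bruteforce(patch: np.ndarray, orientations: int = 16,
                   cell: int = 14) -> np.ndarray:
    """Loop-based HOG on an RGB patch: ITU-R 601 luma, central-difference
    gradients, unsigned orientation, hard binning weighted by magnitude,
    per-cell L2 normalization."""
    h, w = patch.shape[:2]
    gray = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            r, g, b = (patch[i, j, 0] / 255.0, patch[i, j, 1] / 255.0,
                       patch[i, j, 2] / 255.0)
            gray[i, j] = 0.299 * r + 0.587 * g + 0.114 * b
    gx = np.zeros_like(gray, dtype=float)
    gy = np.zeros_like(gray, dtype=float)
    for i in range(h):
        for j in range(w):
            if 0 < j < w - 1:
                gx[i, j] = (gray[i, j + 1] - gray[i, j - 1]) / 2.0
            elif j == 0:
                gx[i, j] = gray[i, 1] - gray[i, 0]
            else:
                gx[i, j] = gray[i, w - 1] - gray[i, w - 2]
            if 0 < i < h - 1:
                gy[i, j] = (gray[i + 1, j] - gray[i - 1, j]) / 2.0
            elif i == 0:
                gy[i, j] = gray[1, j] - gray[0, j]
            else:
                gy[i, j] = gray[h - 1, j] - gray[h - 2, j]
    ncy, ncx = h // cell, w // cell
    features = []
    for ci in range(ncy):
        for cj in range(ncx):
            hist = [0.0] * orientations
            for i in range(ci * cell, (ci + 1) * cell):
                for j in range(cj * cell, (cj + 1) * cell):
                    mag = math.hypot(gx[i, j], gy[i, j])
                    ang = math.degrees(math.atan2(gy[i, j], gx[i, j])) % 180.0
                    b = min(int(ang / (180.0 / orientations)), orientations - 1)
                    hist[b] += mag
            norm = math.sqrt(sum(v * v for v in hist))
            if norm > 1e-12:
                hist = [v / norm for v in hist]
            features.extend(hist)
    return np.asarray(features)


def lbp_uniform_oracle(gray: np.ndarray, p: int = 8, r: float = 1.0) -> np.ndarray:
    """Exhaustive rotation-invariant uniform LBP codes.

    For every pixel, sample ``p`` circular neighbors by bilinear
    interpolation, threshold against the center, count circular 0/1
    transitions; codes with <= 2 transitions map to their popcount, all
    others to p + 1.  Neighbors falling outside the image make the pixel's
    code undefined (NaN) so callers compare interior pixels only.
    """
    h, w = gray.shape
    img = gray.astype(float)
    codes = np.full((h, w), np.nan)
    for i in range(h):
        for j in range(w):
            bits = []
            ok = True
            for k in range(p):
                ang = 2.0 * math.pi * k / p
                y = i + r * math.sin(ang)
                x = j + r * math.cos(ang)
                if y < 0 or x < 0 or y > h - 1 or x > w - 1:
                    ok = False
                    break
                y0, x0 = int(math.floor(y)), int(math.floor(x))
                y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
                fy, fx = y - y0, x - x0
                val = (img[y0, x0] * (1 - fy) * (1 - fx)
                       + img[y0, x1] * (1 - fy) * fx
                       + img[y1, x0] * fy * (1 - fx)
                       + img[y1, x1] * fy * fx)
                # round to the sampling precision used by circular LBP so
                # interpolation noise at exact-tie positions is suppressed
                bits.append(1 if round(val - img[i, j], 8) >= 0 else 0)
            if not ok:
                continue
            transitions = sum(bits[k] != bits[(k + 1) % p] for k in range(p))
            codes[i, j] = sum(bits) if transitions <= 2 else p + 1
    return codes


def auc_pair_counting(y: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: concordant pairs + half ties over all pos/neg pairs."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
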