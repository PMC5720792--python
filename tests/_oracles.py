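"""Independent brute-force oracles for the texture operators.

Everything here is written as explicit per-pixel Python loops, deliberately
sharing no code with the package implementation, so agreement between the
two routes is meaningful evidence of correctness on small fixtures.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_bruteforce(
    levels: np.ndarray, mask: np.ndarray, N: int, d: int, angles: Sequence[int]
) -> np.ndarray:
    """Four-direction-averaged symmetric GLCM by exhaustive pair enumeration."""
    nr, nc = levels.shape
    mats = []
    for ang in angles:
        dr, dc = OFFSETS[ang]
        dr, dc = dr * d, dc * d
        S = np.zeros((N, N))
        for r in range(nr):
            for c in range(nc):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nr and 0 <= c2 < nc and mask[r, c] and mask[r2, c2]:
                    i, j = levels[r, c] - 1, levels[r2, c2] - 1
                    S[i, j] += 1
                    S[j, i] += 1
        if S.sum() > 0:
            mats.append(S / S.sum())
    return np.mean(mats, axis=0)


def rlm_bruteforce(levels: np.ndarray, mask: np.ndarray, direction: int) -> Dict:
    """Run counts {(level, length): n} by walking every scan line."""
    nr, nc = levels.shape
    dr, dc = OFFSETS[direction]
    # line starts: cells with no in-bounds predecessor along (dr, dc)
    runs: Dict[Tuple[int, int], int] = {}
    starts = [
        (r, c)
        for r in range(nr)
        for c in range(nc)
        if not (0 <= r - dr < nr and 0 <= c - dc < nc)
    ]
    for r0, c0 in starts:
        seq = []
        r, c = r0, c0
        while 0 <= r < nr and 0 <= c < nc:
            seq.append(levels[r, c] if mask[r, c] else 0)
            r, c = r + dr, c + dc
        k = 0
        while k < len(seq):
            if seq[k] == 0:
                k += 1
                continue
            j = k
            while j < len(seq) and seq[j] == seq[k]:
                j += 1
            runs[(seq[k], j - k)] = runs.get((seq[k], j - k), 0) + 1
            k = j
    return runs


def sobel_bruteforce(img: np.ndarray, mask: np.ndarray):
    """Per-pixel 3x3 Sobel via explicit kernel sums on interior pixels."""
    kx = [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]
    ky = [[-1, -2, -1], [0, 0, 0], [1, 2, 1]]
    nr, nc = img.shape
    gx = np.zeros_like(img, dtype=float)
    gy = np.zeros_like(img, dtype=float)
    valid = np.zeros((nr, nc), dtype=bool)
    for r in range(1, nr - 1):
        for c in range(1, nc - 1):
            if all(
                mask[r + u, c + v] for u in (-1, 0, 1) for v in (-1, 0, 1)
            ):
                valid[r, c] = True
                gx[r, c] = sum(
                    kx[u + 1][v + 1] * img[r + u, c + v]
                    for u in (-1, 0, 1)
                    for v in (-1, 0, 1)
                )
                gy[r, c] = sum(
                    ky[u + 1][v + 1] * img[r + u, c + v]
                    for u in (-1, 0, 1)
                    for v in (-1, 0, 1)
                )
    return gx, gy, valid


def acm_bruteforce(
    angle_deg: np.ndarray,
    magnitude: np.ndarray,
    valid: np.ndarray,
    l: int,
    n_theta: int,
    weighted: bool,
    angles: Sequence[int],
) -> np.ndarray:
    """Angle co-occurrence by exhaustive valid-pair enumeration."""
    nr, nc = angle_deg.shape
    width = 360.0 / n_theta
    bins = np.minimum((angle_deg // width).astype(int), n_theta - 1)
    mats = []
    for ang in angles:
        dr, dc = OFFSETS[ang]
        dr, dc = dr * l, dc * l
        S = np.zeros((n_theta, n_theta))
        n_pairs = 0
        for r in range(nr):
            for c in range(nc):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nr and 0 <= c2 < nc and valid[r, c] and valid[r2, c2]:
                    w = magnitude[r, c] + magnitude[r2, c2] if weighted else 1.0
                    S[bins[r, c], bins[r2, c2]] += w
                    S[bins[r2, c2], bins[r, c]] += w
                    n_pairs += 1
        if weighted and S.sum() == 0 and n_pairs > 0:
            # zero-weight convention: a flat field falls back to counts
            return acm_bruteforce(
                angle_deg, magnitude, valid, l, n_theta, False, angles
            )
        if S.sum() > 0:
            mats.append(S / S.sum())
    return np.mean(mats, axis=0)


_NB_OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


def lbp_bruteforce(img: np.ndarray, mask: np.ndarray):
    """Plain / min-rotation / dominant-rotation LBP codes per pixel."""
    nr, nc = img.shape
    lbp = np.zeros((nr, nc), dtype=int)
    ri = np.zeros((nr, nc), dtype=int)
    rot = np.zeros((nr, nc), dtype=int)
    valid = np.zeros((nr, nc), dtype=bool)

    def rot_right(code, s):
        s %= 8
        return ((code >> s) | (code << (8 - s))) & 0xFF

    for r in range(1, nr - 1):
        for c in range(1, nc - 1):
            if not all(
                mask[r + u, c + v] for u in (-1, 0, 1) for v in (-1, 0, 1)
            ):
                continue
            valid[r, c] = True
            bits = []
            diffs = []
            for dr, dc in _NB_OFFSETS:
                nb = img[r + dr, c + dc]
                bits.append(1 if nb >= img[r, c] else 0)
                diffs.append(abs(nb - img[r, c]))
            code = sum(b << k for k, b in enumerate(bits))
            lbp[r, c] = code
            ri[r, c] = min(rot_right(code, s) for s in range(8))
            dom = diffs.index(max(diffs))
            rot[r, c] = sum(bits[(k + dom) % 8] << k for k in range(8))
    return lbp, ri, rot, valid


def dbc_window_bruteforce(
    window: np.ndarray, G: float, box_sizes: Sequence[int]
) -> float:
    """Local DBC dimension of one window by explicit block loops."""
    M = window.shape[0]
    w = window - window.min()
    xs, ys = [], []
    for s in box_sizes:
        h = s * G / M
        nb = M // s
        total = 0.0
        for bi in range(nb):
            for bj in range(nb):
                block = w[bi * s : (bi + 1) * s, bj * s : (bj + 1) * s]
                total += math.ceil(block.max() / h) - math.ceil(block.min() / h) + 1
        n_r = (total / nb**2) * (M / s) ** 2
        xs.append(math.log(M / s))
        ys.append(math.log(n_r))
    xm = sum(xs) / len(xs)
    ym = sum(ys) / len(ys)
    num = sum((x - xm) * (y - ym) for x, y in zip(xs, ys))
    den = sum((x - xm) ** 2 for x in xs)
    return num / den


def box_count_bruteforce(points: np.ndarray, sizes: Sequence[int]) -> List[int]:
    """Occupied-box counts per size on an origin-anchored grid."""
    rr, cc = np.nonzero(points)
    out = []
    for s in sizes:
        out.append(len({(r // s, c // s) for r, c in zip(rr, cc)}))
    return out


def auc_bruteforce(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a positive outscores a negative, ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def mi_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    """Fuzzy MI from the joint membership frequency table, term by term."""
    n = a.shape[0]
    ka, kb = a.shape[1], b.shape[1]
    joint = [[sum(a[s, i] * b[s, j] for s in range(n)) / n for j in range(kb)]
             for i in range(ka)]
    px = [sum(row) for row in joint]
    py = [sum(joint[i][j] for i in range(ka)) for j in range(kb)]
    mi = 0.0
    for i in range(ka):
        for j in range(kb):
            p = joint[i][j]
            if p > 0 and px[i] > 0 and py[j] > 0:
                mi += p * math.log2(p / (px[i] * py[j]))
    return max(mi, 0.0)
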