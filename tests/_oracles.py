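"""Independent brute-force oracles used to cross-check the fast implementations.

Everything here is written as plain double loops over pixels/pairs/runs so it
shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np

DIR_VEC = {"H": (0, 1), "V": (1, 0), "N": (1, 1), "Z": (1, -1)}


def brute_glcm(levels: np.ndarray, mask: np.ndarray, direction: str, distance: int, ng: int):
    """Symmetric normalized co-occurrence matrix by explicit pair enumeration."""
    dr, dc = DIR_VEC[direction]
    dr, dc = dr * distance, dc * distance
    P = np.zeros((ng, ng))
    rows, cols = levels.shape
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols and mask[r, c] and mask[r2, c2]:
                i, j = levels[r, c] - 1, levels[r2, c2] - 1
                P[i, j] += 1
                P[j, i] += 1
    total = P.sum()
    return P / total if total else P


def brute_glcm_features(P: np.ndarray) -> dict:
    """Haralick-style features via direct summation over matrix cells."""
    ng = P.shape[0]
    f: dict[str, float] = {}
    px = [sum(P[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(P[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sd_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sd_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))
    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_dif = {k: 0.0 for k in range(ng)}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] += P[i, j]
            p_dif[abs(i - j)] += P[i, j]

    def ent(ps):
        return -sum(p * math.log(p) for p in ps if p > 0)

    f["AngScMom"] = sum(P[i, j] ** 2 for i in range(ng) for j in range(ng))
    f["Contrast"] = sum((i - j) ** 2 * P[i, j] for i in range(ng) for j in range(ng))
    if sd_x * sd_y > 0:
        f["Correlat"] = (
            sum((i + 1) * (j + 1) * P[i, j] for i in range(ng) for j in range(ng))
            - mu_x * mu_y
        ) / (sd_x * sd_y)
    f["SumOfSqs"] = sum((i + 1 - mu_x) ** 2 * P[i, j] for i in range(ng) for j in range(ng))
    f["InvDfMom"] = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    f["SumAverg"] = sum(k * v for k, v in p_sum.items())
    f["SumVarnc"] = sum((k - f["SumAverg"]) ** 2 * v for k, v in p_sum.items())
    f["SumEntrp"] = ent(p_sum.values())
    f["Entropy"] = ent(P.ravel())
    mu_d = sum(k * v for k, v in p_dif.items())
    f["DifVarnc"] = sum((k - mu_d) ** 2 * v for k, v in p_dif.items())
    f["DifEntrp"] = ent(p_dif.values())
    return f


def brute_runs(levels: np.ndarray, mask: np.ndarray, direction: str):
    """Enumerate maximal equal-level runs along every scan line of a direction."""
    dr, dc = DIR_VEC[direction]
    rows, cols = levels.shape
    # line starts: pixels with no in-bounds predecessor along (dr, dc)
    runs = []
    starts = [
        (r, c)
        for r in range(rows)
        for c in range(cols)
        if not (0 <= r - dr < rows and 0 <= c - dc < cols)
    ]
    for r0, c0 in starts:
        line = []
        r, c = r0, c0
        while 0 <= r < rows and 0 <= c < cols:
            line.append((r, c))
            r, c = r + dr, c + dc
        current = None
        length = 0
        for r, c in line:
            v = levels[r, c] if mask[r, c] else None
            if v is not None and v == current:
                length += 1
            else:
                if current is not None:
                    runs.append((current, length))
                current, length = v, (1 if v is not None else 0)
        if current is not None:
            runs.append((current, length))
    return runs


def brute_rlm_features(levels: np.ndarray, mask: np.ndarray, direction: str) -> dict:
    runs = brute_runs(levels, mask, direction)
    nr = len(runs)
    np_pix = int(mask.sum())
    by_level: dict[int, int] = {}
    by_length: dict[int, int] = {}
    for lvl, ln in runs:
        by_level[lvl] = by_level.get(lvl, 0) + 1
        by_length[ln] = by_length.get(ln, 0) + 1
    return {
        "ShrtREmp": sum(1 / ln**2 for _, ln in runs) / nr,
        "LngREmph": sum(ln**2 for _, ln in runs) / nr,
        "GLevNonU": sum(v**2 for v in by_level.values()) / nr,
        "RLNonUni": sum(v**2 for v in by_length.values()) / nr,
        "Fraction": nr / np_pix,
    }


def haar_dwt2_oracle(arr: np.ndarray):
    """One level of the orthonormal 2D Haar transform, even sizes only."""
    a = np.asarray(arr, dtype=float)
    lo_r = (a[0::2, :] + a[1::2, :]) / np.sqrt(2)
    hi_r = (a[0::2, :] - a[1::2, :]) / np.sqrt(2)

    def cols(m):
        return (m[:, 0::2] + m[:, 1::2]) / np.sqrt(2), (m[:, 0::2] - m[:, 1::2]) / np.sqrt(2)

    ll, lh = cols(lo_r)
    hl, hh = cols(hi_r)
    return {"LL": ll, "LH": lh, "HL": hl, "HH": hh}
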