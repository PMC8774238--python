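"""Gray-level co-occurrence matrices and the eleven Haralick-style features.

The matrix ``P`` is accumulated symmetrically (each in-mask pixel pair is
counted in both orders) and normalized to sum 1; pairs with either pixel
outside the mask are dropped rather than padded, because the peritumoral ROI
is irregular.  Entropies use the natural logarithm.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from ..imaging import QuantizedROI
from .core import GLCM_FEATURES, FeatureVector, Offset

__all__ = ["glcm", "glcm_features"]


def glcm(q: QuantizedROI, off: Offset) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix (``Ng x Ng``) for one offset."""
    dr, dc = off.vector
    rows, cols = q.levels.shape
    # shift the grid by (dr, dc) and keep pairs whose both ends are in-mask
    r0 = slice(max(0, -dr), min(rows, rows - dr))
    c0 = slice(max(0, -dc), min(cols, cols - dc))
    r1 = slice(max(0, dr), min(rows, rows + dr))
    c1 = slice(max(0, dc), min(cols, cols + dc))
    a = q.levels[r0, c0]
    b = q.levels[r1, c1]
    valid = q.mask[r0, c0] & q.mask[r1, c1]
    if not valid.any():
        raise ValueError(f"no valid pixel pairs for offset {off.direction} d={off.distance}")
    ng = q.n_levels
    i = a[valid].astype(np.int64) - 1
    j = b[valid].astype(np.int64) - 1
    counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(float)
    counts += counts.T  # symmetric accumulation: both pair orders
    return counts / counts.sum()


def glcm_features(P: np.ndarray) -> FeatureVector:
    """The 11 co-occurrence features of a normalized matrix.

    Marginal conventions: ``p_x(i) = sum_j p(i,j)``, ``p_{x+y}(k)`` sums over
    ``i + j = k`` and ``p_{x-y}(k)`` over ``|i - j| = k``, with levels indexed
    ``1..Ng``.  ``SumOfSqs`` uses the mean of the ``p_x`` marginal, per
    Haralick's original definition.  ``0 * ln 0`` is taken as 0.
    """
    P = np.asarray(P, dtype=float)
    ng = P.shape[0]
    if not np.isclose(P.sum(), 1.0):
        raise ValueError("co-occurrence matrix must be normalized to sum 1")
    lv, ii, jj, ksum, kdif, sum_idx, dif_idx = _level_grids(ng)

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(px @ lv)
    mu_y = float(py @ lv)
    sd_x = float(np.sqrt(px @ (lv - mu_x) ** 2))
    sd_y = float(np.sqrt(py @ (lv - mu_y) ** 2))

    # p_{x+y} over k = 2..2Ng ; p_{x-y} over k = 0..Ng-1
    p_sum = np.bincount(sum_idx, weights=P.ravel(), minlength=2 * ng - 1)
    p_dif = np.bincount(dif_idx, weights=P.ravel(), minlength=ng)

    fv = FeatureVector()
    fv.set("AngScMom", np.sum(P**2))
    fv.set("Contrast", np.sum((ii - jj) ** 2 * P))
    if sd_x * sd_y == 0:
        fv.set_undefined("Correlat", "zero marginal variance (single occupied level)")
    else:
        fv.set("Correlat", (float(np.sum(ii * jj * P)) - mu_x * mu_y) / (sd_x * sd_y))
    fv.set("SumOfSqs", np.sum((ii - mu_x) ** 2 * P))
    fv.set("InvDfMom", np.sum(P / (1.0 + (ii - jj) ** 2)))
    sum_avg = float(ksum @ p_sum)
    fv.set("SumAverg", sum_avg)
    fv.set("SumVarnc", (ksum - sum_avg) ** 2 @ p_sum)
    fv.set("SumEntrp", -np.sum(_xlogx(p_sum)))
    fv.set("Entropy", -np.sum(_xlogx(P)))
    mu_dif = float(kdif @ p_dif)
    fv.set("DifVarnc", (kdif - mu_dif) ** 2 @ p_dif)
    fv.set("DifEntrp", -np.sum(_xlogx(p_dif)))
    return fv


@lru_cache(maxsize=8)
def _level_grids(ng: int):
    lv = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(lv, lv, indexing="ij")
    ksum = np.arange(2, 2 * ng + 1, dtype=float)
    kdif = np.arange(0, ng, dtype=float)
    sum_idx = (ii + jj).astype(np.int64).ravel() - 2
    dif_idx = np.abs(ii - jj).astype(np.int64).ravel()
    return lv, ii, jj, ksum, kdif, sum_idx, dif_idx


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def glcm_feature_block(q: QuantizedROI, off: Offset) -> FeatureVector:
    """Convenience: matrix + features, named ``GLCM_{dir}_d{k}_{Feature}``."""
    prefix = f"GLCM_{off.direction}_d{off.distance}_"
    out = FeatureVector()
    try:
        P = glcm(q, off)
    except ValueError as exc:
        for f in GLCM_FEATURES:
            out.set_undefined(prefix + f, str(exc))
        return out
    out.update(glcm_features(P), prefix=prefix)
    return out
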