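"""Run-length matrix features.

A run is a maximal sequence of equal gray levels along a direction, truncated
at the mask boundary.  With ``p(i, r)`` the count of runs at level ``i`` and
length ``r``, ``Nr`` the total number of runs and ``Np`` the number of in-mask
pixels:

    ShrtREmp = (1/Nr) sum p(i,r) / r^2        (short-run emphasis)
    LngREmph = (1/Nr) sum p(i,r) * r^2        (long-run emphasis)
    GLevNonU = (1/Nr) sum_i (sum_r p(i,r))^2  (gray-level non-uniformity)
    RLNonUni = (1/Nr) sum_r (sum_i p(i,r))^2  (run-length non-uniformity)
    Fraction = Nr / Np                        (fraction of image in runs)
"""

from __future__ import annotations

import numpy as np

from ..imaging import QuantizedROI
from .core import DIRECTIONS, FeatureVector

__all__ = ["run_lengths", "rlm_features"]


def _direction_lines(levels: np.ndarray, direction: str) -> np.ndarray:
    """Concatenate the scan lines of a direction, separated by 0 sentinels.

    Out-of-mask pixels already carry the 0 sentinel, so a single run-length
    encoding pass over the concatenated array enumerates every in-mask run.
    """
    if direction == "H":
        padded = np.concatenate([levels, np.zeros((levels.shape[0], 1), levels.dtype)], axis=1)
        return padded.ravel()
    if direction == "V":
        return _direction_lines(levels.T, "H")
    if direction == "N":  # down-right diagonals
        rows, cols = levels.shape
        parts = []
        for off in range(-(rows - 1), cols):
            parts.append(np.diagonal(levels, offset=off))
            parts.append(np.zeros(1, levels.dtype))
        return np.concatenate(parts)
    if direction == "Z":  # down-left (anti-)diagonals
        return _direction_lines(levels[:, ::-1], "N")
    raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}")


def run_lengths(q: QuantizedROI, direction: str) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(levels, lengths)`` of every maximal in-mask run."""
    line = _direction_lines(np.where(q.mask, q.levels, 0), direction)
    # boundaries where the value changes; prepend/append sentinel
    arr = np.concatenate([[0], line, [0]])
    change = np.flatnonzero(arr[1:] != arr[:-1])
    values = arr[change + 1]
    lengths = np.diff(np.concatenate([change, [arr.size - 1]]))[: len(change)]
    keep = values > 0
    return values[keep], lengths[keep]


def rlm_features(q: QuantizedROI, direction: str) -> FeatureVector:
    if not q.mask.any():
        raise ValueError("empty mask")
    values, lengths = run_lengths(q, direction)
    nr = float(len(values))
    np_pix = float(q.mask.sum())
    fv = FeatureVector()
    prefix = f"RLM_{direction}_"
    r = lengths.astype(float)
    level_counts = np.bincount(values.astype(int))  # runs per gray level
    length_counts = np.bincount(lengths.astype(int))  # runs per length
    fv.set(prefix + "RLNonUni", np.sum(length_counts.astype(float) ** 2) / nr)
    fv.set(prefix + "GLevNonU", np.sum(level_counts.astype(float) ** 2) / nr)
    fv.set(prefix + "LngREmph", np.sum(r**2) / nr)
    fv.set(prefix + "ShrtREmp", np.sum(1.0 / r**2) / nr)
    fv.set(prefix + "Fraction", nr / np_pix)
    return fv
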