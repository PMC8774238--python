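"""Causal autoregressive texture model.

Each in-mask pixel with its four causal neighbors (left, up-right, up,
up-left) in-mask contributes one row to a least-squares fit of

    x(s) - m = th1 (x_left - m) + th2 (x_upright - m)
             + th3 (x_up - m)   + th4 (x_upleft - m) + e(s)

where ``m`` is the ROI mean gray level.  ``Sigma`` is the (population)
standard deviation of the residuals.
"""

from __future__ import annotations

import numpy as np

from ..imaging import QuantizedROI
from .core import FeatureVector

__all__ = ["ar_model"]

#: causal neighbor displacements, in theta order
_NEIGHBORS = ((0, -1), (-1, 1), (-1, 0), (-1, -1))
_MIN_PIXELS = 20


def ar_model(q: QuantizedROI) -> FeatureVector:
    lv = q.levels.astype(float)
    m = q.mask
    rows, cols = m.shape
    eligible = m.copy()
    eligible[0, :] = False
    eligible[:, 0] = False
    eligible[:, -1] = False
    for dr, dc in _NEIGHBORS:
        shifted = np.zeros_like(m)
        shifted[max(0, -dr) : rows - max(0, dr), max(0, -dc) : cols - max(0, dc)] = m[
            max(0, dr) : rows - max(0, -dr), max(0, dc) : cols - max(0, -dc)
        ]
        eligible &= shifted

    fv = FeatureVector()
    names = ["AR_Teta1", "AR_Teta2", "AR_Teta3", "AR_Teta4"]
    if eligible.sum() < _MIN_PIXELS:
        for name in names + ["AR_Sigma"]:
            fv.set_undefined(name, f"fewer than {_MIN_PIXELS} pixels with causal neighborhood")
        return fv

    mean = lv[m].mean()
    rr, cc = np.nonzero(eligible)
    y = lv[rr, cc] - mean
    X = np.column_stack([lv[rr + dr, cc + dc] - mean for dr, dc in _NEIGHBORS])

    if np.linalg.matrix_rank(X) < 4:
        # constant (or otherwise degenerate) ROI: no identifiable dynamics
        for name in names:
            fv.set_undefined(name, "rank-deficient normal equations (degenerate ROI)")
        fv.set("AR_Sigma", float(np.std(y)))
        return fv

    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ theta
    for name, th in zip(names, theta):
        fv.set(name, th)
    fv.set("AR_Sigma", float(np.std(resid)))
    return fv
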