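"""Absolute-gradient features.

The image is first quantized to a coarse gray-level grid (4 bits by default),
then the gradient magnitude ``G = sqrt(dr^2 + dc^2)`` is evaluated with
central differences at every pixel whose full 4-neighborhood lies in the mask.
Features are the population mean/variance/skewness/excess-kurtosis of ``G``
and the fraction of eligible pixels with nonzero gradient.
"""

from __future__ import annotations

import numpy as np

from ..imaging import GrayImage, ROIMask, normalize_and_quantize
from .core import FeatureVector

__all__ = ["gradient_features", "gradient_from_levels"]

_NAMES = ("Grad_GrMean", "Grad_GrVariance", "Grad_GrSkewness", "Grad_GrKurtosis", "Grad_GrNonZeros")


def gradient_features(image: GrayImage, roi: ROIMask, bits: int = 4) -> FeatureVector:
    return gradient_from_levels(normalize_and_quantize(image, roi, bits=bits))


def gradient_from_levels(q) -> FeatureVector:
    """Gradient features of an already-quantized level grid."""
    lv = q.levels.astype(float)
    m = q.mask
    eligible = np.zeros_like(m)
    eligible[1:-1, 1:-1] = (
        m[1:-1, 1:-1] & m[:-2, 1:-1] & m[2:, 1:-1] & m[1:-1, :-2] & m[1:-1, 2:]
    )
    fv = FeatureVector()
    if not eligible.any():
        for name in _NAMES:
            fv.set_undefined(name, "no pixel with a full in-mask 4-neighborhood")
        return fv
    dr = np.zeros_like(lv)
    dc = np.zeros_like(lv)
    dr[1:-1, :] = (lv[2:, :] - lv[:-2, :]) / 2.0
    dc[:, 1:-1] = (lv[:, 2:] - lv[:, :-2]) / 2.0
    g = np.hypot(dr, dc)[eligible]
    mu = g.mean()
    var = float(np.mean((g - mu) ** 2))
    fv.set("Grad_GrMean", mu)
    fv.set("Grad_GrVariance", var)
    if var == 0:
        fv.set_undefined("Grad_GrSkewness", "constant gradient magnitude")
        fv.set_undefined("Grad_GrKurtosis", "constant gradient magnitude")
    else:
        sd = np.sqrt(var)
        fv.set("Grad_GrSkewness", float(np.mean((g - mu) ** 3)) / sd**3)
        fv.set("Grad_GrKurtosis", float(np.mean((g - mu) ** 4)) / sd**4 - 3.0)
    fv.set("Grad_GrNonZeros", float(np.mean(g > 0)))
    return fv
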