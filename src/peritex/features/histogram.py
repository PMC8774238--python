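"""First-order (histogram) features of the quantized ROI.

Moments use population definitions; kurtosis is excess (Gaussian -> 0).  The
``n``-th percentile is the smallest gray level ``v`` such that at least ``n``
percent of the in-mask pixels are ``<= v``.
"""

from __future__ import annotations

import numpy as np

from ..imaging import QuantizedROI
from .core import FeatureVector

__all__ = ["histogram_features"]


def histogram_features(
    q: QuantizedROI, percentiles: tuple[int, ...] = (10,)
) -> FeatureVector:
    x = q.in_mask_levels.astype(float)
    if x.size == 0:
        raise ValueError("empty mask")
    mu = x.mean()
    var = float(np.mean((x - mu) ** 2))
    fv = FeatureVector()
    fv.set("Hist_Mean", mu)
    fv.set("Hist_Variance", var)
    if var == 0:
        fv.set_undefined("Hist_Skewness", "constant ROI: zero variance")
        fv.set_undefined("Hist_Kurtosis", "constant ROI: zero variance")
    else:
        sd = np.sqrt(var)
        fv.set("Hist_Skewness", float(np.mean((x - mu) ** 3)) / sd**3)
        fv.set("Hist_Kurtosis", float(np.mean((x - mu) ** 4)) / sd**4 - 3.0)
    xs = np.sort(x)
    for p in percentiles:
        # smallest level with cumulative fraction >= p%
        idx = int(np.ceil(p / 100.0 * x.size)) - 1
        fv.set(f"Hist_Perc{p}", xs[max(idx, 0)])
    return fv
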