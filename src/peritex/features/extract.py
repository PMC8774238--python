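"""Full-profile extraction and per-pixel feature maps."""

from __future__ import annotations

import numpy as np

from ..imaging import GrayImage, ROIMask, normalize_and_quantize
from .armodel import ar_model
from .core import ExtractionProfile, FeatureVector, Offset
from .glcm import glcm_feature_block
from .gradient import gradient_features
from .histogram import histogram_features
from .rlm import rlm_features
from .wavelet import wavelet_energies

__all__ = ["extract_all", "feature_map"]


def extract_all(
    image: GrayImage, roi: ROIMask, profile: ExtractionProfile | None = None
) -> FeatureVector:
    """Compute every feature class of the profile on one image/ROI pair.

    The default profile emits exactly 275 named values.  Per-class undefined
    values (e.g. deep wavelet scales on a tiny ROI) propagate as NaN with a
    recorded reason instead of aborting the subject.
    """
    profile = profile or ExtractionProfile()
    fv = FeatureVector()
    cls = profile.feature_classes
    quantized = {}

    def q(bits: int, mode: str = "mu3sigma"):
        if (bits, mode) not in quantized:
            quantized[bits, mode] = normalize_and_quantize(image, roi, bits=bits, mode=mode)
        return quantized[bits, mode]

    if "RLM" in cls:
        for d in profile.rlm_directions:
            fv.update(rlm_features(q(profile.rlm_bits), d))
    if "WavEn" in cls:
        fv.update(
            wavelet_energies(
                q(profile.wavelet_bits, profile.wavelet_norm_mode),
                scales=profile.wavelet_scales,
            )
        )
    if "GLCM" in cls:
        for d in profile.glcm_directions:
            for k in profile.glcm_distances:
                fv.update(glcm_feature_block(q(profile.glcm_bits), Offset(d, k)))
    if "Hist" in cls:
        fv.update(histogram_features(q(profile.histogram_bits), profile.histogram_percentiles))
    if "Grad" in cls:
        fv.update(gradient_features(image, roi, bits=profile.gradient_bits))
    if "AR" in cls:
        fv.update(ar_model(q(profile.glcm_bits)))
    return fv


def feature_map(
    image: GrayImage,
    window_px: int,
    feature_name: str,
    profile: ExtractionProfile | None = None,
) -> np.ndarray:
    """Per-pixel map of a single named feature over a sliding square window.

    The window is treated as a full mask.  The returned array matches the
    image shape, with a NaN margin of width ``(window_px - 1) // 2`` where the
    window does not fit.
    """
    profile = profile or ExtractionProfile()
    if window_px % 2 != 1 or window_px < 3:
        raise ValueError("window_px must be an odd integer >= 3")
    rows, cols = image.shape
    if window_px > rows or window_px > cols:
        raise ValueError("window does not fit inside the image")
    canonical = _resolve_name(feature_name, profile)
    half = (window_px - 1) // 2
    out = np.full(image.shape, np.nan)
    full = np.ones((window_px, window_px), dtype=bool)
    for r in range(half, rows - half):
        for c in range(half, cols - half):
            win = GrayImage(
                image.pixels[r - half : r + half + 1, c - half : c + half + 1],
                spacing=image.spacing,
            )
            fv = extract_all(win, ROIMask(full), profile=_restrict(canonical, profile))
            out[r, c] = fv[canonical]
    return out


def _resolve_name(name: str, profile: ExtractionProfile) -> str:
    from .core import ALIASES

    canonical = ALIASES.get(name, name)
    if canonical not in profile.expected_names():
        raise KeyError(f"unknown feature name {name!r}")
    return canonical


def _restrict(canonical: str, profile: ExtractionProfile) -> ExtractionProfile:
    """Narrow a profile to the single class (and offset) a feature needs."""
    cls = canonical.split("_", 1)[0]
    kw = {"feature_classes": (cls,)}
    if cls == "GLCM":
        _, d, dist, _ = canonical.split("_", 3)
        kw |= {"glcm_directions": (d,), "glcm_distances": (int(dist[1:]),)}
    elif cls == "RLM":
        kw |= {"rlm_directions": (canonical.split("_")[1],)}
    from dataclasses import replace

    return replace(profile, **kw)
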