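"""Feature-vector container, pixel offsets, and the extraction profile.

Feature names are canonical, ``{CLASS}_{qualifiers}_{Feature}`` (for example
``GLCM_H_d4_DifVarnc`` or ``WavEn_HH_s2``).  The MaZda-style codes used in the
clinical literature (``CN6D4Contrast``, ``RZD5GLevNonU``, ``WavEnHH_s-2`` ...)
are attached as aliases for the handful of parameters that recur in reports;
the mapping is a best-effort reading (leading letter = direction, ``D`` =
distance, ``s`` = scale) and the embedded digits are treated as opaque.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DIRECTIONS", "Offset", "FeatureVector", "ExtractionProfile", "ALIASES"]

#: The four pixel-pair directions used for co-occurrence and run-length
#: analysis: horizontal, vertical, and the two diagonals.
DIRECTIONS: dict[str, tuple[int, int]] = {
    "H": (0, 1),
    "V": (1, 0),
    "N": (1, 1),
    "Z": (1, -1),
}

#: MaZda-style aliases for the recurrent report parameters (non-authoritative).
ALIASES: dict[str, str] = {
    "Perc10": "Hist_Perc10",
    "CN6D4Contrast": "GLCM_N_d4_Contrast",
    "CH5D4DifVarnc": "GLCM_H_d4_DifVarnc",
    "CZ2D4DifVarnc": "GLCM_Z_d4_DifVarnc",
    "RZD5GLevNonU": "RLM_Z_GLevNonU",
    "WavEnHH_s-2": "WavEn_HH_s2",
    "WavEnHL_s-3": "WavEn_HL_s3",
}


@dataclass(frozen=True)
class Offset:
    """A co-occurrence displacement: direction key plus pixel distance."""

    direction: str
    distance: int = 1

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")

    @property
    def vector(self) -> tuple[int, int]:
        dr, dc = DIRECTIONS[self.direction]
        return dr * self.distance, dc * self.distance


class FeatureVector:
    """Ordered mapping of feature name -> value, with undefined-value reasons.

    A feature can be undefined only with a recorded reason (e.g. a constant
    ROI makes skewness undefined); undefined entries read as NaN.
    """

    def __init__(self) -> None:
        self._values: dict[str, float] = {}
        self._reasons: dict[str, str] = {}

    def set(self, name: str, value: float) -> None:
        if name in self._values:
            raise KeyError(f"duplicate feature name {name!r}")
        self._values[name] = float(value)

    def set_undefined(self, name: str, reason: str) -> None:
        if name in self._values:
            raise KeyError(f"duplicate feature name {name!r}")
        self._values[name] = float("nan")
        self._reasons[name] = reason

    def update(self, other: "FeatureVector", prefix: str = "") -> None:
        for name, value in other._values.items():
            full = prefix + name
            if name in other._reasons:
                self.set_undefined(full, other._reasons[name])
            else:
                self.set(full, value)

    def __getitem__(self, name: str) -> float:
        return self._values[ALIASES.get(name, name)]

    def __contains__(self, name: str) -> bool:
        return ALIASES.get(name, name) in self._values

    def __len__(self) -> int:
        return len(self._values)

    def __iter__(self):
        return iter(self._values)

    @property
    def names(self) -> list[str]:
        return list(self._values)

    @property
    def undefined(self) -> dict[str, str]:
        return dict(self._reasons)

    def reason(self, name: str) -> str | None:
        return self._reasons.get(ALIASES.get(name, name))

    def to_dict(self) -> dict[str, float]:
        return dict(self._values)

    def to_series(self):
        import pandas as pd

        return pd.Series(self._values)

    def __repr__(self) -> str:  # pragma: no cover
        return f"FeatureVector({len(self)} features, {len(self._reasons)} undefined)"


@dataclass(frozen=True)
class ExtractionProfile:
    """Settings of the full texture-parameter set.

    The default profile emits exactly 275 features: 20 run-length (5 features
    x 4 directions), 20 wavelet energies (4 subbands x 5 scales), 220
    co-occurrence (11 features x 5 distances x 4 directions), 5 histogram,
    5 gradient, and 5 autoregressive-model parameters.  ``feature_classes``
    can restrict extraction to a subset of classes; ``glcm_distances`` and
    ``glcm_directions`` narrow the co-occurrence grid.
    """

    glcm_bits: int = 6
    glcm_distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    glcm_directions: tuple[str, ...] = ("H", "V", "N", "Z")
    rlm_bits: int = 6
    rlm_directions: tuple[str, ...] = ("H", "V", "N", "Z")
    gradient_bits: int = 4
    wavelet_bits: int = 6
    #: the wavelet class is quantized over the ROI's full dynamic range
    #: rather than the mu +/- 3 sigma window: subband energies measure how
    #: fluctuation at each scale fills the ROI's intensity range, and a
    #: symmetric clip would distort that for skewed ROIs
    wavelet_norm_mode: str = "full_range"
    wavelet_scales: int = 5
    histogram_bits: int = 6
    histogram_percentiles: tuple[int, ...] = (10,)
    feature_classes: tuple[str, ...] = ("RLM", "WavEn", "GLCM", "Hist", "Grad", "AR")

    @classmethod
    def extended(cls) -> "ExtractionProfile":
        """Histogram profile extended with the 1/50/90/99 percentiles."""
        return cls(histogram_percentiles=(1, 10, 50, 90, 99))

    def expected_names(self) -> list[str]:
        """Canonical feature names, in emission order."""
        names: list[str] = []
        if "RLM" in self.feature_classes:
            for d in self.rlm_directions:
                names += [f"RLM_{d}_{f}" for f in RLM_FEATURES]
        if "WavEn" in self.feature_classes:
            for s in range(1, self.wavelet_scales + 1):
                names += [f"WavEn_{b}_s{s}" for b in WAVELET_BANDS]
        if "GLCM" in self.feature_classes:
            for d in self.glcm_directions:
                for k in self.glcm_distances:
                    names += [f"GLCM_{d}_d{k}_{f}" for f in GLCM_FEATURES]
        if "Hist" in self.feature_classes:
            names += [f"Hist_{f}" for f in ("Mean", "Variance", "Skewness", "Kurtosis")]
            names += [f"Hist_Perc{p}" for p in self.histogram_percentiles]
        if "Grad" in self.feature_classes:
            names += [f"Grad_{f}" for f in GRADIENT_FEATURES]
        if "AR" in self.feature_classes:
            names += [f"AR_{f}" for f in AR_FEATURES]
        return names


GLCM_FEATURES = (
    "AngScMom",
    "Contrast",
    "Correlat",
    "SumOfSqs",
    "InvDfMom",
    "SumAverg",
    "SumVarnc",
    "SumEntrp",
    "Entropy",
    "DifVarnc",
    "DifEntrp",
)
RLM_FEATURES = ("RLNonUni", "GLevNonU", "LngREmph", "ShrtREmp", "Fraction")
WAVELET_BANDS = ("LL", "LH", "HL", "HH")
GRADIENT_FEATURES = ("GrMean", "GrVariance", "GrSkewness", "GrKurtosis", "GrNonZeros")
AR_FEATURES = ("Teta1", "Teta2", "Teta3", "Teta4", "Sigma")
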