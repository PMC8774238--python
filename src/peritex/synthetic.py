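"""Synthetic two-class peritumoral-zone cohorts.

Real peritumoral CT data cannot be redistributed, so the pipeline is
exercised on phantoms that reproduce the *statistical* contrast the analysis
assumes between the two classes:

* **Class A** (infiltrated, high-grade-glioma-like): the low-attenuation
  edema plateau carries sparse Poisson-scattered hyperdense Gaussian blobs
  (local cell-density excesses) on top of a short-range correlated field,
  producing high local intensity variation, a right-skewed histogram (hence
  an upward-shifted lower percentile after dynamic-range normalization),
  and high gray-level non-uniformity.
* **Class B** (pure vasogenic edema, metastasis-like): a smooth long-range
  correlated field with no blobs; relative to its own dynamic range the
  mid-scale fluctuation content is larger, so normalized wavelet detail
  energies at intermediate scales run higher than in class A.

Images are ``base_hu`` plus a Gaussian-kernel-smoothed white-noise field
(scaled to unit variance before multiplying by the class amplitude), plus the
class-A blobs, plus i.i.d. Gaussian pixel noise.  The ROI is an annulus
between an inner "enhancing rim" disc and an outer margin, at least 10 px
wide (mirroring the clinical inclusion rule of a peritumoral zone of at
least 10 mm).  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imaging import GrayImage, ROIMask

__all__ = [
    "ClassParams",
    "CohortConfig",
    "SyntheticSubject",
    "generate_subject",
    "generate_cohort",
    "cohort_feature_matrix",
    "exclusion_cascade",
]


@dataclass(frozen=True)
class ClassParams:
    """Generative texture parameters of one class."""

    field_amplitude: float
    field_corr_len_px: float
    blob_density_per_cm2: float = 0.0
    blob_radius_px: float = 0.0
    blob_amplitude_hu: float = 0.0

    def __post_init__(self) -> None:
        for name in ("field_amplitude", "blob_density_per_cm2", "blob_amplitude_hu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a synthetic cohort.

    Defaults emulate peri-tumoral edema on contrast CT: a plateau of ~8 HU
    with ~3 HU pixel noise.  Class A carries sparse tall infiltration blobs
    (~60 HU peaks, ~1 px core) over a strong fine-grained field — giving it
    high local variance, a heavy right tail (which also widens its dynamic
    range, suppressing its range-normalized fine-scale wavelet content), and
    a gray-level histogram concentrated near the plateau.  Class B is a weak
    long-range field over the same noise floor, so it is smoother in absolute
    terms while its narrow dynamic range inflates its normalized wavelet
    detail energies at every scale.  ``n_per_class`` may be a single int or
    an (A, B) pair; the packaged study uses (17, 19).
    """

    n_per_class: int | tuple[int, int] = (17, 19)
    image_px: tuple[int, int] = (128, 128)
    spacing_mm: tuple[float, float] = (1.0, 1.0)
    base_hu: float = 8.0
    noise_sd: float = 3.0
    class_a: ClassParams = field(
        default_factory=lambda: ClassParams(
            field_amplitude=5.0,
            field_corr_len_px=0.8,
            blob_density_per_cm2=0.3,
            blob_radius_px=1.0,
            blob_amplitude_hu=60.0,
        )
    )
    class_b: ClassParams = field(
        default_factory=lambda: ClassParams(field_amplitude=3.0, field_corr_len_px=6.0)
    )
    rng_seed: int = 0

    @property
    def group_sizes(self) -> tuple[int, int]:
        n = self.n_per_class
        return (n, n) if isinstance(n, int) else tuple(n)


@dataclass
class SyntheticSubject:
    image: GrayImage
    roi: ROIMask
    label: str  # "A" (positive / HGG-like) or "B" (BM-like)
    ground_truth: dict


def _correlated_field(rng: np.random.Generator, shape, corr_len: float) -> np.ndarray:
    white = rng.standard_normal(shape)
    if corr_len <= 0:
        return white
    smooth = gaussian_filter(white, sigma=corr_len, mode="wrap")
    return smooth / smooth.std()


def _blob_field(
    rng: np.random.Generator, shape, spacing, density_per_cm2, radius_px, amplitude
) -> np.ndarray:
    area_cm2 = shape[0] * shape[1] * spacing[0] * spacing[1] / 100.0
    n_blobs = rng.poisson(density_per_cm2 * area_cm2)
    out = np.zeros(shape)
    if n_blobs == 0 or amplitude == 0:
        return out
    rows = rng.uniform(0, shape[0], n_blobs)
    cols = rng.uniform(0, shape[1], n_blobs)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    for r0, c0 in zip(rows, cols):
        out += np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * radius_px**2))
    return amplitude * out


def _annulus(rng: np.random.Generator, shape) -> np.ndarray:
    rows, cols = shape
    max_fit = min(rows, cols) / 2.0 - 2.0
    scale = min(rows, cols) / 128.0
    for _ in range(10):
        cy = rows / 2.0 + rng.uniform(-4, 4) * scale
        cx = cols / 2.0 + rng.uniform(-4, 4) * scale
        inner = rng.uniform(16, 24) * scale
        outer = inner + max(10.0, rng.uniform(14, 20) * scale)
        if outer >= max_fit:
            continue
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        d = np.hypot(rr - cy, cc - cx)
        band = (d >= inner) & (d <= outer)
        if outer - inner >= 10 and band.any():
            return band
    raise RuntimeError("could not place an annular ROI at least 10 px wide")


def generate_subject(config: CohortConfig, label: str, seed: int) -> SyntheticSubject:
    """One deterministic phantom subject of the given class."""
    if label not in ("A", "B"):
        raise ValueError("label must be 'A' or 'B'")
    params = config.class_a if label == "A" else config.class_b
    rng = np.random.default_rng(seed)
    shape = config.image_px

    img = np.full(shape, config.base_hu, dtype=float)
    img += params.field_amplitude * _correlated_field(rng, shape, params.field_corr_len_px)
    if params.blob_density_per_cm2 > 0:
        img += _blob_field(
            rng,
            shape,
            config.spacing_mm,
            params.blob_density_per_cm2,
            params.blob_radius_px,
            params.blob_amplitude_hu,
        )
    img += rng.normal(0.0, config.noise_sd, shape)
    roi = ROIMask(_annulus(rng, shape), source="synthetic")
    gt = {"label": label, "seed": seed, **asdict(params), "noise_sd": config.noise_sd}
    return SyntheticSubject(
        image=GrayImage(img, spacing=config.spacing_mm, identifier=f"{label}{seed}"),
        roi=roi,
        label=label,
        ground_truth=gt,
    )


def generate_cohort(config: CohortConfig) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """All subjects of both classes plus a manifest of ids and ground truth.

    Per-subject seeds are ``rng_seed + index`` so the cohort is reproducible
    and stable under resizing.
    """
    n_a, n_b = config.group_sizes
    if n_a == 0 or n_b == 0:
        raise ValueError("each class needs at least one subject")
    subjects = []
    rows = []
    for idx, label in enumerate(["A"] * n_a + ["B"] * n_b):
        seed = config.rng_seed + idx
        subj = generate_subject(config, label, seed)
        sid = f"S{idx:03d}"
        subj.ground_truth["subject_id"] = sid
        subjects.append(subj)
        rows.append(dict(subj.ground_truth))
    manifest = pd.DataFrame(rows)
    manifest = manifest[
        ["subject_id"] + [c for c in manifest.columns if c != "subject_id"]
    ]
    return subjects, manifest


def cohort_feature_matrix(subjects, profile=None):
    """Extract features for every subject into a :class:`FeatureMatrix`."""
    from .features import extract_all
    from .selection import FeatureMatrix

    vectors = [extract_all(s.image, s.roi, profile=profile) for s in subjects]
    names = vectors[0].names
    values = np.array([[v.to_dict()[n] for n in names] for v in vectors])
    return FeatureMatrix(
        subjects=[s.ground_truth.get("subject_id", f"S{i:03d}") for i, s in enumerate(subjects)],
        features=names,
        values=values,
        labels=np.array([s.label == "A" for s in subjects]),
    )


def exclusion_cascade(initial: int, steps: list[tuple[str, int]]) -> tuple[int, pd.DataFrame]:
    """Stepwise cohort bookkeeping: subtract each exclusion, log the ledger.

    Raises if any step would leave a negative remainder.
    """
    remaining = initial
    rows = []
    for label, count in steps:
        if count < 0:
            raise ValueError(f"negative exclusion count for {label!r}")
        remaining -= count
        if remaining < 0:
            raise ValueError(f"exclusions exceed the cohort at step {label!r}")
        rows.append({"step": label, "excluded": count, "remaining": remaining})
    return remaining, pd.DataFrame(rows)
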