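"""Image/mask containers, file I/O, and gray-level normalization.

The analysis operates on single 2D CT slices in Hounsfield units (HU) with a
binary region of interest (ROI) marking the peritumoral zone.  Before any
texture feature is computed, in-ROI intensities are remapped to a small number
of integer gray levels (``1..Ng``); by default the intensity dynamics are first
limited to ``mu +/- 3*sigma`` computed over the ROI, which removes the
dependence of texture features on scanner brightness/contrast settings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "GrayImage",
    "ROIMask",
    "QuantizedROI",
    "SENTINEL",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "normalize_and_quantize",
]

#: Level value carried by out-of-mask pixels of a :class:`QuantizedROI`.
#: Never a valid gray level; feature code must consult the mask.
SENTINEL = 0


@dataclass(frozen=True)
class GrayImage:
    """A 2D intensity grid with physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        Real-valued intensities (HU for CT).
    spacing : (float, float)
        Physical size of a pixel in mm, ``(row_mm, col_mm)``.
    identifier : str
        Free-text id (file stem, subject id, ...).
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    identifier: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("image must be a 2D grid of at least 2x2 pixels")
        if not np.all(np.isfinite(px)):
            raise ValueError("image intensities must be finite")
        if not (self.spacing[0] > 0 and self.spacing[1] > 0):
            raise ValueError("pixel spacing must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ROIMask:
    """Binary mask congruent with a :class:`GrayImage`."""

    mask: np.ndarray
    source: Literal["seeded", "manual", "synthetic"] = "manual"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask).astype(bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2D")
        if not m.any():
            raise ValueError("mask must contain at least one pixel")
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class QuantizedROI:
    """ROI intensities remapped to integer gray levels ``1..Ng``.

    ``levels`` holds the quantized grid (``SENTINEL`` outside the mask),
    ``norm_stats`` the ``(mu, sigma, low, high)`` used for the mapping, and
    ``degenerate`` flags a constant ROI (``sigma == 0``), in which case every
    in-mask level is 1.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    norm_stats: tuple[float, float, float, float]
    degenerate: bool = False
    spacing: tuple[float, float] = (1.0, 1.0)

    @property
    def in_mask_levels(self) -> np.ndarray:
        """Flat array of the in-mask gray levels."""
        return self.levels[self.mask]


def normalize_and_quantize(
    image: GrayImage,
    roi: ROIMask,
    bits: int = 6,
    mode: Literal["mu3sigma", "full_range", "fixed_window"] = "mu3sigma",
    window: tuple[float, float] | None = None,
) -> QuantizedROI:
    """Limit intensity dynamics and quantize the ROI to ``Ng = 2**bits`` levels.

    In ``mu3sigma`` mode the window is ``[mu - 3*sigma, mu + 3*sigma]`` with the
    mean and (population) standard deviation taken over in-mask pixels only.
    An in-mask pixel ``x`` maps to

        ``level = 1 + floor((clip(x, low, high) - low) * (Ng - 1) / (high - low) + 0.5)``

    i.e. linear rescaling with half-up rounding; the mapping is monotone
    non-decreasing in ``x``.  A constant ROI (``sigma == 0``) maps every pixel
    to level 1 and raises the ``degenerate`` flag instead of erroring, so batch
    runs can proceed and mark the subject.
    """
    if image.shape != roi.shape:
        raise ValueError("ROI mask must be congruent with the image")
    if bits not in (4, 6, 8):
        raise ValueError("bits must be one of 4, 6, 8")
    ng = 2**bits
    m = roi.mask
    vals = image.pixels[m]
    mu = float(vals.mean())
    sigma = float(vals.std())  # population: divide by N

    if mode == "mu3sigma":
        low, high = mu - 3.0 * sigma, mu + 3.0 * sigma
    elif mode == "full_range":
        low, high = float(vals.min()), float(vals.max())
    elif mode == "fixed_window":
        if window is None:
            raise ValueError("fixed_window mode requires an explicit window")
        low, high = float(window[0]), float(window[1])
        if not high > low:
            raise ValueError("window must satisfy high > low")
    else:  # pragma: no cover
        raise ValueError(f"unknown mode {mode!r}")

    levels = np.full(image.shape, SENTINEL, dtype=np.int32)
    degenerate = high <= low
    if degenerate:
        levels[m] = 1
    else:
        clipped = np.clip(image.pixels[m], low, high)
        lv = 1 + np.floor((clipped - low) * (ng - 1) / (high - low) + 0.5)
        levels[m] = lv.astype(np.int32)
    return QuantizedROI(
        levels=levels,
        mask=m,
        n_levels=ng,
        norm_stats=(mu, sigma, low, high),
        degenerate=degenerate,
        spacing=image.spacing,
    )


# ----------------------------------------------------------------------------
# File I/O: DICOM (read-only), binary PGM (P5), 16-bit PNG, masks.
# ----------------------------------------------------------------------------


def read_image(path: str | Path, format: str | None = None) -> GrayImage:
    """Read a grayscale image as a :class:`GrayImage`.

    ``format`` is ``"dicom"`` or ``"portable_gray"`` (PGM/PNG); inferred from
    the file suffix when omitted.  DICOM pixel data are rescaled to HU when
    RescaleSlope/RescaleIntercept are present; pixel spacing is taken from the
    metadata and defaults to (1, 1) mm when absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "dicom" if path.suffix.lower() in {".dcm", ".dicom"} else "portable_gray"
    if format == "dicom":
        return _read_dicom(path)
    if format == "portable_gray":
        import imageio.v3 as iio

        try:
            arr = iio.imread(path)
        except Exception as exc:  # unreadable / not an image
            raise ValueError(f"could not parse {path} as a grayscale image: {exc}") from exc
        if arr.ndim == 3:
            raise ValueError(f"{path} is not single-channel grayscale")
        return GrayImage(arr.astype(float), identifier=path.stem)
    raise ValueError(f"unknown format {format!r}")


def _read_dicom(path: Path) -> GrayImage:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:
        raise ValueError(f"could not parse {path} as DICOM: {exc}") from exc
    if "PixelData" not in ds:
        raise ValueError(f"{path}: DICOM file has no pixel data")
    arr = ds.pixel_array.astype(float)
    if arr.ndim != 2:
        raise ValueError(f"{path}: only single-frame grayscale DICOM is supported")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    spacing = getattr(ds, "PixelSpacing", None)
    sp = (float(spacing[0]), float(spacing[1])) if spacing is not None else (1.0, 1.0)
    return GrayImage(arr, spacing=sp, identifier=path.stem)


def write_image(image: GrayImage, path: str | Path) -> Path:
    """Write as binary PGM (P5) or PNG; integer grids round-trip exactly.

    PGM is written 16-bit when any value exceeds 255.  Values must be
    non-negative integers (HU images should be offset before writing).
    """
    path = Path(path)
    px = image.pixels
    if not np.allclose(px, np.round(px)) or px.min() < 0:
        raise ValueError("only non-negative integer grids can be written losslessly")
    arr = np.round(px).astype(np.uint16 if px.max() > 255 else np.uint8)
    if path.suffix.lower() == ".pgm":
        _write_pgm(arr, path)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    return path


def _write_pgm(arr: np.ndarray, path: Path) -> None:
    maxval = 65535 if arr.dtype == np.uint16 else 255
    header = f"P5\n{arr.shape[1]} {arr.shape[0]}\n{maxval}\n".encode("ascii")
    data = arr.astype(">u2" if maxval > 255 else "u1").tobytes()
    path.write_bytes(header + data)


def read_mask(path: str | Path) -> ROIMask:
    """Read a mask stored as PGM {0, 255} or as a run-length JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        spec = json.loads(path.read_text())
        m = np.zeros(tuple(spec["shape"]), dtype=bool)
        for row, start, length in spec["runs"]:
            m[row, start : start + length] = True
        return ROIMask(m, source=spec.get("source", "manual"))
    img = read_image(path, format="portable_gray")
    return ROIMask(img.pixels > 0)


def write_mask(mask: ROIMask, path: str | Path) -> Path:
    """Write as PGM {0, 255} or, for a ``.json`` suffix, as row run-lengths."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        runs = []
        for r, row in enumerate(mask.mask):
            idx = np.flatnonzero(np.diff(np.concatenate(([0], row.view(np.uint8), [0]))))
            for start, stop in zip(idx[::2], idx[1::2]):
                runs.append([int(r), int(start), int(stop - start)])
        path.write_text(
            json.dumps({"shape": list(mask.shape), "runs": runs, "source": mask.source})
        )
        return path
    return write_image(GrayImage(mask.mask.astype(float) * 255), path)
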