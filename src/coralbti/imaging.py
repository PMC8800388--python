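"""Grayscale extraction and color-strip standardization.

Each coral photograph contains, besides the coral fragment, a reference
strip with one black and one white patch.  The mean gray of the coral
region of interest (ROI), ``G_C``, is mapped onto the scale defined by the
strip means ``G_B`` (black) and ``G_W`` (white)::

    G_0 = (G_C - G_W) / (G_B - G_W)

``G_0`` is dimensionless: 0 at the white reference, 1 at the black
reference.  Because the map is affine in the pixel values, any global
brightness/contrast change that affects coral and strip alike (and does
not clip) cancels out — this is what makes photographs from different
sessions comparable.

Color images are reduced to gray with the ITU-R BT.601 luma weights
(0.299, 0.587, 0.114), rounded half-to-even to an 8-bit integer.  ROIs are
0-based, half-open pixel rectangles declared in a manifest; the same ROI
is reused for a fragment across the whole time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "GrayImage",
    "RegionSpec",
    "CalibrationRefs",
    "GrayMeasurement",
    "DegenerateCalibrationError",
    "SaturationWarning",
    "OutOfRangeWarning",
    "to_grayscale",
    "load_gray_image",
    "mean_gray",
    "standardize",
    "measure_image",
    "extract_measurements",
    "MANIFEST_COLUMNS",
]

#: ITU-R BT.601 luma weights for R, G, B.
BT601_WEIGHTS = (0.299, 0.587, 0.114)

#: Columns required in an image manifest CSV.
MANIFEST_COLUMNS = [
    "image_path",
    "timestamp_iso",
    "fragment_id",
    "species",
    "colony",
    "regime",
    "coral_roi",
    "black_roi",
    "white_roi",
]


class DegenerateCalibrationError(ValueError):
    """Black and white reference patches have the same mean gray.

    This signals a failed or fully overexposed strip: the standardization
    denominator ``G_B - G_W`` vanishes.
    """


class SaturationWarning(UserWarning):
    """More than 1% of reference-patch pixels are clipped at 0 or 255."""


class OutOfRangeWarning(UserWarning):
    """A standardized gray value fell outside [0, 1]."""


@dataclass(frozen=True)
class GrayImage:
    """An 8-bit grayscale raster."""

    pixels: np.ndarray  # shape (height, width), values in [0, 255]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a non-empty 2-D array")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("gray values must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RegionSpec:
    """A 0-based, half-open pixel rectangle: rows y..y+h-1, cols x..x+w-1."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError("region extent must be at least 1x1")
        if self.x < 0 or self.y < 0:
            raise ValueError("region origin must be non-negative")

    @classmethod
    def parse(cls, text: str) -> "RegionSpec":
        """Parse the manifest encoding ``"x;y;w;h"``."""
        parts = text.split(";")
        if len(parts) != 4:
            raise ValueError(f"ROI spec must have 4 fields, got {text!r}")
        x, y, w, h = (int(p) for p in parts)
        return cls(x, y, w, h)

    def unparse(self) -> str:
        return f"{self.x};{self.y};{self.w};{self.h}"


@dataclass(frozen=True)
class CalibrationRefs:
    """Mean grays of the black (``G_B``) and white (``G_W``) patches."""

    g_black: float
    g_white: float

    def __post_init__(self) -> None:
        for v in (self.g_black, self.g_white):
            if not 0 <= v <= 255:
                raise ValueError("reference grays must lie in [0, 255]")
        if self.g_black == self.g_white:
            raise DegenerateCalibrationError(
                "black and white references coincide "
                f"(G_B = G_W = {self.g_black}); strip failed or overexposed"
            )


@dataclass(frozen=True)
class GrayMeasurement:
    """One standardized measurement: coral mean gray and its G_0."""

    g_coral: float
    refs: CalibrationRefs
    g0: float


def to_grayscale(rgb_image: np.ndarray) -> GrayImage:
    """Convert a 3-channel raster to 8-bit gray.

    Per-pixel gray is ``0.299 R + 0.587 G + 0.114 B`` rounded half-to-even,
    so the conversion is bit-reproducible across platforms.

    Parameters
    ----------
    rgb_image
        Array of shape (height, width, 3) with channel values in [0, 255].
    """
    arr = np.asarray(rgb_image, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected a 3-channel raster, got shape {arr.shape}"
        )
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("channel values must lie in [0, 255]")
    wr, wg, wb = BT601_WEIGHTS
    gray = wr * arr[..., 0] + wg * arr[..., 1] + wb * arr[..., 2]
    return GrayImage(np.rint(gray).astype(np.uint8))


def load_gray_image(path: str | Path) -> GrayImage:
    """Read a JPEG/PNG file and convert it to gray.

    Images already stored as single-channel gray are used as-is; color
    images go through :func:`to_grayscale`.
    """
    with Image.open(path) as im:
        if im.mode == "L":
            return GrayImage(np.asarray(im))
        rgb = np.asarray(im.convert("RGB"))
    return to_grayscale(rgb)


def mean_gray(img: GrayImage, roi: RegionSpec) -> float:
    """Arithmetic mean intensity over an ROI, at full float precision."""
    if roi.x + roi.w > img.width or roi.y + roi.h > img.height:
        raise IndexError(
            f"ROI {roi} exceeds image bounds {img.width}x{img.height}"
        )
    patch = img.pixels[roi.y : roi.y + roi.h, roi.x : roi.x + roi.w]
    return float(patch.mean(dtype=np.float64))


def _check_clipping(img: GrayImage, roi: RegionSpec, label: str) -> bool:
    patch = img.pixels[roi.y : roi.y + roi.h, roi.x : roi.x + roi.w]
    frac = float(np.mean((patch == 0) | (patch == 255)))
    if frac > 0.01:
        warnings.warn(
            f"{frac:.1%} of {label} reference pixels clipped at 0/255; "
            "standardization may be biased",
            SaturationWarning,
            stacklevel=3,
        )
        return True
    return False


def standardize(g_coral: float, refs: CalibrationRefs) -> GrayMeasurement:
    """Standardize a coral mean gray against the strip references.

    Returns ``G_0 = (G_C - G_W) / (G_B - G_W)``.  Values outside [0, 1]
    are legal (a coral darker than the black patch or brighter than the
    white patch) and are flagged with :class:`OutOfRangeWarning`, never
    clamped.
    """
    g0 = (g_coral - refs.g_white) / (refs.g_black - refs.g_white)
    if not np.isfinite(g0):
        raise DegenerateCalibrationError("non-finite standardized gray")
    if g0 < 0 or g0 > 1:
        warnings.warn(
            f"standardized gray {g0:.4f} outside [0, 1]",
            OutOfRangeWarning,
            stacklevel=2,
        )
    return GrayMeasurement(g_coral=g_coral, refs=refs, g0=float(g0))


def measure_image(
    img: GrayImage,
    coral_roi: RegionSpec,
    black_roi: RegionSpec,
    white_roi: RegionSpec,
) -> tuple[GrayMeasurement, list[str]]:
    """Extract and standardize one image; returns the measurement and flags."""
    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        g_c = mean_gray(img, coral_roi)
        refs = CalibrationRefs(
            g_black=mean_gray(img, black_roi),
            g_white=mean_gray(img, white_roi),
        )
        _check_clipping(img, black_roi, "black")
        _check_clipping(img, white_roi, "white")
        meas = standardize(g_c, refs)
    for w in caught:
        if issubclass(w.category, SaturationWarning):
            flags.append("saturated-reference")
        elif issubclass(w.category, OutOfRangeWarning):
            flags.append("g0-out-of-range")
    return meas, flags


def extract_measurements(
    manifest: pd.DataFrame | str | Path,
    base_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run grayscale extraction over every image in a manifest.

    Parameters
    ----------
    manifest
        DataFrame or CSV path with columns :data:`MANIFEST_COLUMNS`.
        ROI columns use the ``"x;y;w;h"`` encoding.
    base_dir
        Directory against which relative ``image_path`` entries are
        resolved.  Defaults to the manifest's own directory when the
        manifest is given as a path.

    Returns
    -------
    DataFrame with one row per image: fragment_id, species, colony,
    regime, timestamp_iso, g_coral, g_black, g_white, g0, warnings.
    """
    if not isinstance(manifest, pd.DataFrame):
        path = Path(manifest)
        if base_dir is None:
            base_dir = path.parent
        manifest = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    base = Path(base_dir) if base_dir is not None else Path(".")

    rows = []
    for rec in manifest.itertuples(index=False):
        img_path = Path(rec.image_path)
        if not img_path.is_absolute():
            img_path = base / img_path
        if not img_path.exists():
            raise FileNotFoundError(f"image not found: {img_path}")
        img = load_gray_image(img_path)
        meas, flags = measure_image(
            img,
            RegionSpec.parse(rec.coral_roi),
            RegionSpec.parse(rec.black_roi),
            RegionSpec.parse(rec.white_roi),
        )
        rows.append(
            {
                "fragment_id": rec.fragment_id,
                "species": rec.species,
                "colony": rec.colony,
                "regime": rec.regime,
                "timestamp_iso": rec.timestamp_iso,
                "g_coral": meas.g_coral,
                "g_black": meas.refs.g_black,
                "g_white": meas.refs.g_white,
                "g0": meas.g0,
                "warnings": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)
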