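"""Raster and table I/O plus run configuration.

The pipeline's entry raster is an RGB brightfield scan (TIFF or PNG).
Intensities are normalized to [0, 1] by the white level of the source bit
depth immediately on access, so every downstream constant (log-enhancement
``k``, fixed thresholds) is bit-depth independent.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("ihcmorph")

__all__ = [
    "RGBImage",
    "AnalysisConfig",
    "FormatError",
    "read_image",
    "write_image",
    "write_records",
    "read_records",
    "write_overlay",
    "RECORD_COLUMNS",
]

#: CSV schema for per-cell output, in column order.
RECORD_COLUMNS = [
    "label",
    "area_px",
    "area_um2",
    "centroid_row",
    "centroid_col",
    "ring_pixels",
    "perinuclear_mean",
    "perinuclear_integrated",
    "border_flag",
]


class FormatError(ValueError):
    """Raised when a raster does not satisfy the RGB input contract."""


def _white_level(dtype: np.dtype) -> float:
    dtype = np.dtype(dtype)
    if dtype == np.uint8:
        return 255.0
    if dtype == np.uint16:
        return 65535.0
    if dtype.kind == "f":
        return 1.0
    if dtype.kind in "iu":
        return float(np.iinfo(dtype).max)
    raise FormatError(f"unsupported pixel dtype {dtype}")


@dataclass(frozen=True)
class RGBImage:
    """An H x W x 3 brightfield raster with its white level.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3)
        Raw intensities as stored in the file.
    dtype_scale : float
        The white level: 255 for 8-bit, 65535 for 16-bit, 1.0 for float.
    pixel_size_um : float, optional
        Micrometers per pixel. When absent, areas are reported in pixels
        only.
    """

    pixels: np.ndarray
    dtype_scale: float
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(
                f"expected an H x W x 3 raster, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError("image must be at least 1 x 1")
        if not np.isfinite(np.asarray(self.dtype_scale)) or self.dtype_scale <= 0:
            raise FormatError("dtype_scale must be positive and finite")
        vals = px.astype(np.float64, copy=False)
        if not np.all(np.isfinite(vals)):
            raise FormatError("pixel values must be finite")
        if vals.min() < 0 or vals.max() > self.dtype_scale:
            raise FormatError(
                "pixel values must lie in [0, dtype_scale]="
                f"[0, {self.dtype_scale}]"
            )
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise FormatError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def normalized(self) -> np.ndarray:
        """Pixels as float64 in [0, 1] (divided by the white level)."""
        return self.pixels.astype(np.float64) / float(self.dtype_scale)


@dataclass
class AnalysisConfig:
    """Tunable knobs of the morphometric pipeline.

    ``ring_width_px`` is the half-width of the perinuclear band used as the
    cytoplasmic region of interest; the default of 7 pixels matches the
    published protocol this tool reimplements.  All other fields control
    standard segmentation plumbing the protocol leaves unstated.
    """

    ring_width_px: int = 7
    threshold_method: str = "otsu"
    fixed_threshold: Optional[float] = None
    min_nucleus_area_px: int = 50
    max_nucleus_area_px: Optional[int] = None
    split_touching: bool = True
    exclude_border: bool = True
    log_constant_k: float = 255.0
    intensity_statistic: str = "mean"
    ring_metric: str = "euclidean"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if int(self.ring_width_px) < 1:
            raise ValueError("ring_width_px must be >= 1")
        self.ring_width_px = int(self.ring_width_px)
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(
                f"threshold_method must be 'otsu' or 'fixed', got "
                f"{self.threshold_method!r}"
            )
        if self.threshold_method == "fixed":
            if self.fixed_threshold is None:
                raise ValueError(
                    "fixed_threshold is required when threshold_method='fixed'"
                )
            if not 0.0 <= float(self.fixed_threshold) <= 1.0:
                raise ValueError("fixed_threshold must lie in [0, 1]")
        elif self.fixed_threshold is not None:
            raise ValueError(
                "fixed_threshold is only meaningful with threshold_method='fixed'"
            )
        if self.min_nucleus_area_px < 0:
            raise ValueError("min_nucleus_area_px must be >= 0")
        if self.max_nucleus_area_px is not None:
            if self.min_nucleus_area_px >= self.max_nucleus_area_px:
                raise ValueError(
                    "min_nucleus_area_px must be < max_nucleus_area_px"
                )
        if self.log_constant_k <= 0:
            raise ValueError("log_constant_k must be > 0")
        if self.intensity_statistic not in ("mean", "integrated"):
            raise ValueError(
                "intensity_statistic must be 'mean' or 'integrated'"
            )
        if self.ring_metric not in ("euclidean", "cityblock"):
            raise ValueError("ring_metric must be 'euclidean' or 'cityblock'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: os.PathLike | str) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)


def read_image(path: os.PathLike | str, pixel_size_um: Optional[float] = None) -> RGBImage:
    """Read a TIFF or PNG raster as an :class:`RGBImage`.

    Grayscale inputs are rejected; a 4th (alpha) channel is dropped with a
    logged warning.  ``dtype_scale`` is inferred from the stored bit depth.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # unreadable container
        raise IOError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        raise FormatError(
            f"{path} is single-channel (grayscale); an RGB brightfield scan "
            "with 3 channels is required"
        )
    if arr.ndim != 3:
        raise FormatError(f"{path}: unsupported raster shape {arr.shape}")
    if arr.shape[2] < 3:
        raise FormatError(
            f"{path} has {arr.shape[2]} channels; 3 (RGB) are required"
        )
    if arr.shape[2] > 3:
        logger.warning(
            "%s has %d channels; keeping RGB, dropping the rest (alpha)",
            path, arr.shape[2],
        )
        arr = arr[:, :, :3]
    return RGBImage(arr, _white_level(arr.dtype), pixel_size_um=pixel_size_um)


def write_image(image: RGBImage, path: os.PathLike | str) -> None:
    """Write the raster losslessly (TIFF or PNG by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels, photometric="rgb")
    else:
        iio.imwrite(path, image.pixels)


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Per-cell records as a label-sorted DataFrame with the CSV schema."""
    rows = []
    for r in records:
        rows.append(
            {
                "label": r.label,
                "area_px": r.area_px,
                "area_um2": np.nan if r.area_um2 is None else r.area_um2,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "ring_pixels": r.ring_pixels,
                "perinuclear_mean": (
                    np.nan if r.perinuclear_mean is None else r.perinuclear_mean
                ),
                "perinuclear_integrated": r.perinuclear_integrated,
                "border_flag": bool(r.border_flag),
            }
        )
    frame = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if len(frame):
        frame = frame.sort_values("label", kind="stable").reset_index(drop=True)
    return frame


def write_records(records: Sequence, path: os.PathLike | str) -> None:
    """Write per-cell records to CSV (UTF-8, header row, label-sorted).

    Floats are written with ``repr`` round-trip formatting, so parsing the
    file recovers the exact values; output is deterministic for a fixed
    record list.
    """
    frame = records_to_frame(records)
    try:
        frame.to_csv(path, index=False)
    except OSError as exc:
        raise IOError(f"could not write records to {path}: {exc}") from exc


def read_records(path: os.PathLike | str) -> pd.DataFrame:
    """Parse a per-cell CSV, validating the schema written by write_records."""
    try:
        frame = pd.read_csv(path)
    except OSError as exc:
        raise IOError(f"could not read records from {path}: {exc}") from exc
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{path} is missing per-cell column(s): {', '.join(missing)}"
        )
    return frame


def write_overlay(
    image: RGBImage,
    nuclei: np.ndarray,
    rings: np.ndarray,
    path: os.PathLike | str,
    nucleus_color: tuple[int, int, int] = (0, 200, 60),
    ring_color: tuple[int, int, int] = (230, 40, 200),
) -> None:
    """Write a QC raster with nuclear and ring contours over the input.

    Contours are the inner boundaries of each labeled region, so nucleus
    and ring contours never share a pixel (the masks are disjoint by
    construction).
    """
    from skimage.segmentation import find_boundaries

    nuclei = np.asarray(nuclei)
    rings = np.asarray(rings)
    if nuclei.shape != image.shape or rings.shape != image.shape:
        raise ValueError(
            f"mask shape {nuclei.shape}/{rings.shape} does not match image "
            f"shape {image.shape}"
        )
    base = np.clip(image.normalized() * 255.0, 0, 255).astype(np.uint8)
    out = base.copy()
    if nuclei.any():
        nb = find_boundaries(nuclei, mode="inner")
        out[nb] = nucleus_color
    if rings.any():
        rb = find_boundaries(rings, mode="inner")
        out[rb] = ring_color
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)
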