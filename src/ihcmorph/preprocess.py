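"""Channel extraction and log enhancement.

Brightfield IHC uses two absorbing stains: hematoxylin (blue nuclear
counterstain, absorbs red light most strongly) and DAB (brown chromogen,
absorbs blue most strongly).  The pipeline therefore extracts the red and
blue planes, enhances each with a bounded log transform, and inverts them
into two purpose-specific maps:

* ``nuclear_map = 1 - L(red)`` — high where hematoxylin is dense; drives
  nucleus segmentation.
* ``signal_map = 1 - L(blue)`` — high where DAB chromogen is dense; drives
  perinuclear intensity quantification.

The inversion ``1 - L(x)`` is used instead of optical density ``-log(x)``
because it is bounded on [0, 1] and has no singularity at saturated dark
pixels, while remaining monotone-equivalent for thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AnalysisConfig, RGBImage

__all__ = ["ChannelMaps", "extract_channels", "log_enhance", "log_enhance_inverse", "build_maps"]


@dataclass(frozen=True)
class ChannelMaps:
    """The six per-pixel maps derived from one RGB scan, all in [0, 1]."""

    red: np.ndarray
    blue: np.ndarray
    red_enhanced: np.ndarray
    blue_enhanced: np.ndarray
    nuclear_map: np.ndarray
    signal_map: np.ndarray

    def __post_init__(self) -> None:
        shape = self.red.shape
        for name in ("blue", "red_enhanced", "blue_enhanced", "nuclear_map", "signal_map"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"map {name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"map {name} contains non-finite values")
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"map {name} leaves [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape


def extract_channels(image: RGBImage) -> tuple[np.ndarray, np.ndarray]:
    """Return the red and blue planes normalized to [0, 1].

    The green plane carries the least stain-specific contrast for this
    hematoxylin/DAB pairing and is discarded.
    """
    norm = image.normalized()
    return norm[:, :, 0], norm[:, :, 2]


def log_enhance(channel: np.ndarray, k: float) -> np.ndarray:
    """Bounded log enhancement ``L(x) = log(1 + k*x) / log(1 + k)``.

    Strictly increasing on [0, 1] with ``L(0) = 0`` and ``L(1) = 1`` for any
    ``k > 0``; larger ``k`` expands contrast in the dark (stained) range.
    """
    if k <= 0:
        raise ValueError(f"log constant k must be > 0, got {k}")
    x = np.asarray(channel, dtype=np.float64)
    return np.log1p(k * x) / np.log1p(k)


def log_enhance_inverse(enhanced: np.ndarray, k: float) -> np.ndarray:
    """Inverse of :func:`log_enhance`: ``x = (exp(y * log(1+k)) - 1) / k``."""
    if k <= 0:
        raise ValueError(f"log constant k must be > 0, got {k}")
    y = np.asarray(enhanced, dtype=np.float64)
    return np.expm1(y * np.log1p(k)) / k


def build_maps(image: RGBImage, config: AnalysisConfig) -> ChannelMaps:
    """Run channel extraction and log enhancement; derive the stain maps."""
    red, blue = extract_channels(image)
    k = config.log_constant_k
    red_enh = log_enhance(red, k)
    blue_enh = log_enhance(blue, k)
    return ChannelMaps(
        red=red,
        blue=blue,
        red_enhanced=red_enh,
        blue_enhanced=blue_enh,
        nuclear_map=1.0 - red_enh,
        signal_map=1.0 - blue_enh,
    )
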