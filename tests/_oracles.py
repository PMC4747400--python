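"""Independent brute-force oracles used to check the fast implementations."""

from __future__ import annotations

import numpy as np
from skimage.measure import label as cc_label


def brute_force_rings(labels: np.ndarray, width: int, metric: str = "euclidean") -> np.ndarray:
    """Exhaustive per-pixel ring construction.

    For every pixel, the minimum distance to each nucleus is computed
    directly over all of that nucleus's pixels (integer squared Euclidean
    or city-block counts).  Background pixels within ``width`` of some
    nucleus get the label of the nearest one; exact distance ties go to the
    smaller label.
    """
    labels = np.asarray(labels)
    h, w = labels.shape
    n = int(labels.max(initial=0))
    pix = np.stack(np.mgrid[0:h, 0:w], axis=-1).reshape(-1, 2).astype(np.int64)
    best = np.full(h * w, np.iinfo(np.int64).max, dtype=np.int64)
    owner = np.zeros(h * w, dtype=np.int32)
    limit = width * width if metric == "euclidean" else width
    for lab in range(1, n + 1):
        pts = np.argwhere(labels == lab).astype(np.int64)
        dmin = np.empty(h * w, dtype=np.int64)
        for start in range(0, h * w, 4096):  # bound the broadcast buffer
            block = pix[start : start + 4096]
            diff = block[:, None, :] - pts[None, :, :]
            if metric == "euclidean":
                d = (diff * diff).sum(axis=-1).min(axis=1)
            else:
                d = np.abs(diff).sum(axis=-1).min(axis=1)
            dmin[start : start + 4096] = d
        upd = dmin < best
        best[upd] = dmin[upd]
        owner[upd] = lab
    ring = (labels.ravel() == 0) & (best <= limit)
    return np.where(ring, owner, 0).reshape(h, w).astype(np.int32)


def random_blob_mask(
    rng: np.random.Generator,
    shape: tuple[int, int] = (112, 112),
    max_blobs: int = 5,
    radius_range: tuple[float, float] = (4.0, 14.0),
) -> np.ndarray:
    """A random labeled mask of overlapping disks/ellipses.

    Overlapping blobs merge into single 8-connected objects; labels are
    contiguous 1..N in raster-scan order (scikit-image labeling).
    """
    h, w = shape
    n = rng.integers(1, max_blobs + 1)
    binary = np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[0:h, 0:w]
    for _ in range(n):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        a = rng.uniform(*radius_range)
        b = rng.uniform(*radius_range)
        th = rng.uniform(0, np.pi)
        dr, dc = rr - cy, cc - cx
        u = dr * np.cos(th) + dc * np.sin(th)
        v = -dr * np.sin(th) + dc * np.cos(th)
        binary |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return cc_label(binary, connectivity=2).astype(np.int32)


def disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
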