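"""Per-cell quantification and group-level statistics.

Each segmented nucleus yields one record: its pixel area (the ploidy
surrogate) and the chromogen signal over its perinuclear ring (the ER-stress
surrogate), reported both as the ring mean and as the integrated (summed)
signal.  Group summaries report mean +/- SEM and histograms; groups are
compared with a one-tailed two-sample Student's t test (pooled variance;
Welch optional).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy import stats

from .segmentation import RingMaskPair, border_labels

__all__ = ["CellRecord", "GroupSummary", "measure_cells", "summarize", "compare_groups"]


@dataclass(frozen=True)
class CellRecord:
    """One segmented nucleus with its perinuclear signal.

    ``perinuclear_mean`` is None when the ring is empty (a nucleus fully
    enclosed by neighbors); such cells keep their area but are excluded
    from signal summaries.
    """

    label: int
    area_px: int
    centroid: tuple[float, float]
    ring_pixels: int
    perinuclear_mean: Optional[float]
    perinuclear_integrated: float
    border_flag: bool
    area_um2: Optional[float] = None


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean_area: float
    sem_area: Optional[float]
    mean_signal: Optional[float]
    sem_signal: Optional[float]
    n_signal_excluded: int
    area_histogram: tuple[np.ndarray, np.ndarray]
    signal_histogram: Optional[tuple[np.ndarray, np.ndarray]]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_area": self.mean_area,
            "sem_area": self.sem_area,
            "mean_signal": self.mean_signal,
            "sem_signal": self.sem_signal,
            "n_signal_excluded": self.n_signal_excluded,
            "area_histogram": {
                "bin_edges": self.area_histogram[0].tolist(),
                "counts": self.area_histogram[1].tolist(),
            },
            "signal_histogram": (
                None
                if self.signal_histogram is None
                else {
                    "bin_edges": self.signal_histogram[0].tolist(),
                    "counts": self.signal_histogram[1].tolist(),
                }
            ),
        }


def measure_cells(
    pair: RingMaskPair,
    signal_map: np.ndarray,
    pixel_size_um: Optional[float] = None,
) -> list[CellRecord]:
    """Quantify every nucleus: area, centroid, and perinuclear signal.

    ``perinuclear_mean`` is the mean of ``signal_map`` over the cell's ring
    pixels; ``perinuclear_integrated`` is the sum.  Records are returned
    sorted by label.
    """
    signal_map = np.asarray(signal_map, dtype=np.float64)
    if signal_map.shape != pair.nuclei.shape:
        raise ValueError(
            f"signal map shape {signal_map.shape} does not match mask shape "
            f"{pair.nuclei.shape}"
        )
    nuclei = pair.nuclei
    top = int(nuclei.max(initial=0))
    if top == 0:
        return []
    labels = np.arange(1, top + 1)
    areas = np.bincount(nuclei.ravel(), minlength=top + 1)[1:]
    centroids = ndi.center_of_mass(nuclei > 0, nuclei, labels)
    ring_counts = np.bincount(pair.rings.ravel(), minlength=top + 1)[1:]
    ring_sums = ndi.sum_labels(signal_map, pair.rings, labels)
    on_border = set(border_labels(nuclei).tolist())

    records = []
    for i, lab in enumerate(labels):
        npx = int(ring_counts[i])
        total = float(ring_sums[i])
        mean = total / npx if npx > 0 else None
        area_um2 = (
            float(areas[i]) * pixel_size_um**2 if pixel_size_um else None
        )
        records.append(
            CellRecord(
                label=int(lab),
                area_px=int(areas[i]),
                centroid=(float(centroids[i][0]), float(centroids[i][1])),
                ring_pixels=npx,
                perinuclear_mean=mean,
                perinuclear_integrated=total,
                border_flag=int(lab) in on_border,
                area_um2=area_um2,
            )
        )
    return records


def _signal_values(records: Sequence[CellRecord], statistic: str) -> np.ndarray:
    if statistic == "mean":
        vals = [r.perinuclear_mean for r in records if r.perinuclear_mean is not None]
    elif statistic == "integrated":
        vals = [
            r.perinuclear_integrated for r in records if r.perinuclear_mean is not None
        ]
    else:
        raise ValueError("statistic must be 'mean' or 'integrated'")
    return np.asarray(vals, dtype=np.float64)


def _sem(values: np.ndarray) -> Optional[float]:
    if len(values) < 2:
        return None
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def summarize(
    records: Sequence[CellRecord],
    statistic: str = "mean",
    bins: int = 30,
) -> GroupSummary:
    """Group-level means, SEMs, and histograms of area and signal.

    Histograms use ``bins`` equal-width bins spanning the observed range.
    Cells without a ring are excluded from signal summaries; the excluded
    count is reported.
    """
    if len(records) == 0:
        raise ValueError("cannot summarize an empty group of cell records")
    areas = np.asarray([r.area_px for r in records], dtype=np.float64)
    signals = _signal_values(records, statistic)
    n_excluded = len(records) - len(signals)

    area_hist = np.histogram(areas, bins=bins)
    counts, edges = area_hist[0], area_hist[1]
    if len(signals):
        s_counts, s_edges = np.histogram(signals, bins=bins)
        signal_hist = (s_edges, s_counts)
        mean_signal = float(signals.mean())
        sem_signal = _sem(signals)
    else:
        signal_hist = None
        mean_signal = None
        sem_signal = None
    return GroupSummary(
        n=len(records),
        mean_area=float(areas.mean()),
        sem_area=_sem(areas),
        mean_signal=mean_signal,
        sem_signal=sem_signal,
        n_signal_excluded=n_excluded,
        area_histogram=(edges, counts),
        signal_histogram=signal_hist,
    )


def compare_groups(
    a: Sequence[CellRecord],
    b: Sequence[CellRecord],
    variable: str = "area",
    alternative: str = "greater",
    statistic: str = "mean",
    welch: bool = False,
) -> tuple[float, float]:
    """One-tailed two-sample Student's t test between two cell groups.

    ``alternative='greater'`` tests whether group ``a``'s mean exceeds
    group ``b``'s (``'less'`` the reverse).  The default pools variances
    (classic Student's t); ``welch=True`` drops the equal-variance
    assumption.  Returns ``(t_statistic, p_value)``.
    """
    if variable == "area":
        xa = np.asarray([r.area_px for r in a], dtype=np.float64)
        xb = np.asarray([r.area_px for r in b], dtype=np.float64)
    elif variable == "signal":
        xa = _signal_values(a, statistic)
        xb = _signal_values(b, statistic)
    else:
        raise ValueError("variable must be 'area' or 'signal'")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError(
            f"each group needs n >= 2 defined values (got {len(xa)}, {len(xb)})"
        )
    res = stats.ttest_ind(
        xa, xb, equal_var=not welch, alternative=alternative
    )
    return float(res.statistic), float(res.pvalue)
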