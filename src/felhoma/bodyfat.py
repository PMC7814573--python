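"""Body-fat percentage from whole-body CT Hounsfield-unit histograms.

Soft-tissue voxels (HU in [-250, +250], pre-masked upstream: patient table,
bladder urine and external objects already removed) form a bimodal
frequency histogram with a fat-attenuation peak near -100 HU and a lean
soft-tissue peak near +40..60 HU.  The midpoint between the two smoothed
peaks splits the window: voxels at or below the midpoint are fat, voxels
above are lean, and BF% = 100 * n_fat / (n_fat + n_lean).

Also provides the predictive values of the clinical body condition score
against BF% as reference method.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .homa import WeightClassBF, classify_bf

HU_WINDOW = (-250, 250)
#: peak search regions (fat and lean attenuation are well separated)
FAT_SEARCH = (-250, -10)
LEAN_SEARCH = (10, 250)
SMOOTH_BINS = 5


class UnimodalHistogram(ValueError):
    """No distinct fat and lean peaks were found."""


@dataclasses.dataclass
class HUHistogram:
    """Voxel counts over half-open HU bins [edge[i], edge[i+1]) covering the window."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("counts length must equal number of bins")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("empty histogram: no voxels in the HU window")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclasses.dataclass
class BodyFatResult:
    """Peaks, midpoint, voxel split and the resulting BF% and category."""

    fat_peak_hu: float
    lean_peak_hu: float
    midpoint_hu: float
    n_fat_voxels: int
    n_lean_voxels: int
    bf_percent: float
    category: WeightClassBF

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["category"] = self.category.value
        return d


def hu_histogram(
    voxels: Sequence[float],
    bin_width: float = 1.0,
    window: tuple[int, int] = HU_WINDOW,
) -> HUHistogram:
    """Bin pre-masked HU voxel values; voxels outside the window are discarded."""
    x = np.asarray(voxels, dtype=float)
    if x.size == 0:
        raise ValueError("empty voxel list")
    lo, hi = window
    x = x[(x >= lo) & (x <= hi)]
    if x.size == 0:
        raise ValueError(f"no voxels inside the HU window [{lo}, {hi}]")
    n_bins = int(np.ceil((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi)
    counts, _ = np.histogram(x, bins=edges)
    # np.histogram closes the last bin on the right, matching the inclusive window
    return HUHistogram(bin_edges=edges, counts=counts)


def _smooth(counts: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return counts.astype(float)
    kernel = np.ones(width) / width
    return np.convolve(counts.astype(float), kernel, mode="same")


def _peak_in(centers: np.ndarray, smoothed: np.ndarray, region: tuple[float, float]) -> float:
    lo, hi = region
    mask = (centers >= lo) & (centers <= hi)
    if not mask.any() or smoothed[mask].sum() == 0:
        raise UnimodalHistogram(f"no counts in the search region [{lo}, {hi}] HU")
    sub_c = centers[mask]
    sub_s = smoothed[mask]
    best = sub_s.max()
    tied = sub_c[sub_s == best]
    # tie-break toward the window centre (0 HU)
    return float(tied[np.argmin(np.abs(tied))])


def find_peaks_midpoint(
    hist: HUHistogram,
    smooth_bins: int = SMOOTH_BINS,
    fat_search: tuple[float, float] = FAT_SEARCH,
    lean_search: tuple[float, float] = LEAN_SEARCH,
) -> tuple[float, float, float]:
    """Locate the fat and lean peaks and their arithmetic midpoint.

    Counts are smoothed with a moving average (default 5 bins); the fat
    peak is the argmax over [-250, -10] HU and the lean peak over
    [+10, +250] HU; bin-centre positions are reported.  A flat or one-sided
    histogram raises :class:`UnimodalHistogram`.
    """
    if np.ptp(hist.counts) == 0:
        raise UnimodalHistogram("flat histogram: no distinct peaks")
    smoothed = _smooth(hist.counts, smooth_bins)
    fat = _peak_in(hist.centers, smoothed, fat_search)
    lean = _peak_in(hist.centers, smoothed, lean_search)
    return fat, lean, 0.5 * (fat + lean)


def bf_percent(hist: HUHistogram, midpoint_hu: float) -> BodyFatResult:
    """Split the histogram at the midpoint and compute BF%.

    Fat voxels have HU <= midpoint (closed), lean voxels HU > midpoint;
    BF% = 100 * n_fat / (n_fat + n_lean).
    """
    lo, hi = hist.bin_edges[0], hist.bin_edges[-1]
    if not lo <= midpoint_hu <= hi:
        raise ValueError(f"midpoint {midpoint_hu} outside the histogram window")
    fat_mask = hist.centers <= midpoint_hu
    n_fat = int(hist.counts[fat_mask].sum())
    n_lean = int(hist.counts[~fat_mask].sum())
    total = n_fat + n_lean
    if total == 0:
        raise ValueError("no voxels to classify")
    bf = 100.0 * n_fat / total
    return BodyFatResult(
        fat_peak_hu=np.nan,
        lean_peak_hu=np.nan,
        midpoint_hu=float(midpoint_hu),
        n_fat_voxels=n_fat,
        n_lean_voxels=n_lean,
        bf_percent=bf,
        category=classify_bf(bf) if 0 < bf < 100 else (
            WeightClassBF.lean if bf == 0 else WeightClassBF.obese
        ),
    )


def body_fat_from_voxels(
    voxels: Sequence[float],
    bin_width: float = 1.0,
    window: tuple[int, int] = HU_WINDOW,
    smooth_bins: int = SMOOTH_BINS,
    on_unimodal: str = "raise",
) -> BodyFatResult:
    """Whole pipeline: histogram -> peaks & midpoint -> BF% and category.

    ``on_unimodal`` controls one-sided histograms (one search region empty
    of counts): ``"raise"`` (default) propagates
    :class:`UnimodalHistogram`; ``"degenerate"`` returns BF% 0 (no fat
    peak) or 100 (no lean peak), for inputs known to be single-tissue.
    """
    hist = hu_histogram(voxels, bin_width=bin_width, window=window)
    try:
        fat, lean, mid = find_peaks_midpoint(hist, smooth_bins=smooth_bins)
    except UnimodalHistogram:
        if on_unimodal != "degenerate":
            raise
        smoothed = _smooth(hist.counts, smooth_bins)
        if np.ptp(smoothed) == 0:
            raise
        centers = hist.centers
        fat_empty = not (
            ((centers >= FAT_SEARCH[0]) & (centers <= FAT_SEARCH[1]))
            & (smoothed > 0)
        ).any()
        mid = float(window[0]) if fat_empty else float(window[1])
        result = bf_percent(hist, mid)
        result.fat_peak_hu = float("nan")
        result.lean_peak_hu = float("nan")
        return result
    result = bf_percent(hist, mid)
    result.fat_peak_hu = fat
    result.lean_peak_hu = lean
    return result


def predictive_values(
    pairs: Iterable[tuple[str, str]]
) -> tuple[float, float, dict[str, int]]:
    """NPV/PPV of BCS-based grading against BF%-based grading.

    ``pairs`` yields (bcs_class, bf_class) with bcs_class in {"lean",
    "overweight"} and bf_class in {"lean", "overweight", "obese"}.  Using
    BF% as reference: NPV = P(BF-lean | BCS-lean) and PPV =
    P(BF-overweight-or-obese | BCS-overweight), both as percent.
    Returns (npv, ppv, contingency counts); an empty BCS class yields NaN
    for the corresponding value.
    """
    counts = {"lean_lean": 0, "lean_over": 0, "over_lean": 0, "over_over": 0}
    for bcs, bf in pairs:
        bf_over = bf in ("overweight", "obese")
        if bcs == "lean":
            counts["lean_over" if bf_over else "lean_lean"] += 1
        elif bcs == "overweight":
            counts["over_over" if bf_over else "over_lean"] += 1
        else:
            raise ValueError(f"unknown BCS class {bcs!r}")
    n_bcs_lean = counts["lean_lean"] + counts["lean_over"]
    n_bcs_over = counts["over_lean"] + counts["over_over"]
    npv = 100.0 * counts["lean_lean"] / n_bcs_lean if n_bcs_lean else float("nan")
    ppv = 100.0 * counts["over_over"] / n_bcs_over if n_bcs_over else float("nan")
    return npv, ppv, counts
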