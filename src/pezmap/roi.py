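"""Cohort histogram normalization and per-ROI statistics.

Maps are compared across patients after a histogram-based affine rescaling:
each case's within-brain (low, high) percentile values (default 1st/99th) are
mapped onto the cohort-mean anchor values. This removes global acquisition
gain/offset differences while preserving within-case value ordering, and
deliberately avoids reference-region (contralateral white matter)
normalization.

Per-ROI statistics are the voxel mean and SD plus two 20th-percentile-trimmed
means: ``mean_high`` excludes the lowest 20 % of voxels, ``mean_low`` the
highest 20 %. Percentiles use the linear-interpolation convention and ties at
the cut are excluded together with the trimmed tail, so the result is
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volumes import BINARY_MASK, VoxelGrid

__all__ = [
    "CohortReference",
    "RoiStats",
    "compute_cohort_reference",
    "normalize_map",
    "roi_statistics",
    "stats_from_values",
    "percent_difference",
]


@dataclass
class CohortReference:
    """Cohort-mean anchor values for histogram normalization."""

    low_anchor: float
    high_anchor: float
    percentiles: tuple[float, float] = (1.0, 99.0)
    modality: str = ""

    def __post_init__(self) -> None:
        if not self.high_anchor > self.low_anchor:
            raise ValueError("high anchor must exceed low anchor")


@dataclass
class RoiStats:
    roi_label: str
    n_voxels: int
    mean: float
    sd: float
    mean_low: float   # highest 20th percentile excluded
    mean_high: float  # lowest 20th percentile excluded

    @property
    def defined(self) -> bool:
        return self.n_voxels > 0


def compute_cohort_reference(maps: list[VoxelGrid],
                             brain_masks: list[VoxelGrid],
                             percentiles: tuple[float, float] = (1.0, 99.0),
                             modality: str = "") -> CohortReference:
    """Across-case means of the within-brain percentile values."""
    if len(maps) != len(brain_masks) or not maps:
        raise ValueError("need matching, non-empty map and mask lists")
    lows, highs = [], []
    for i, (m, b) in enumerate(zip(maps, brain_masks)):
        mask = b.astype_bool()
        if not mask.any():
            warnings.warn(f"case {i}: empty brain mask skipped")
            continue
        vals = m.data[mask]
        lo, hi = np.percentile(vals, percentiles)
        lows.append(lo)
        highs.append(hi)
    if not lows:
        raise ValueError("no case contributed a non-empty brain mask")
    return CohortReference(low_anchor=float(np.mean(lows)),
                           high_anchor=float(np.mean(highs)),
                           percentiles=tuple(percentiles), modality=modality)


def normalize_map(map_grid: VoxelGrid, brain_mask: VoxelGrid,
                  ref: CohortReference) -> VoxelGrid:
    """Affinely map the case's (low, high) percentiles onto the anchors.

    Applied to in-brain voxels; voxels outside the brain are set to 0.
    A constant in-brain map (zero percentile spread) cannot be normalized.
    """
    mask = brain_mask.astype_bool()
    vals = map_grid.data[mask]
    lo, hi = np.percentile(vals, ref.percentiles)
    if hi <= lo:
        raise ValueError("zero percentile spread; map cannot be normalized")
    scale = (ref.high_anchor - ref.low_anchor) / (hi - lo)
    out = np.zeros_like(map_grid.data, dtype=float)
    out[mask] = (vals - lo) * scale + ref.low_anchor
    return map_grid.with_data(out)


def stats_from_values(values: np.ndarray, roi_label: str = "",
                      trim_fraction: float = 0.20) -> RoiStats:
    """ROI statistics from a flat voxel-value array (see module docstring)."""
    if not 0 < trim_fraction < 0.5:
        raise ValueError("trim fraction must lie in (0, 0.5)")
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n == 0:
        nan = float("nan")
        return RoiStats(roi_label, 0, nan, nan, nan, nan)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    q_lo = np.quantile(values, trim_fraction)       # linear interpolation
    q_hi = np.quantile(values, 1.0 - trim_fraction)
    upper = values[values > q_lo]
    lower = values[values < q_hi]
    # constant ROI (or all values tied at the cut): trimming removes nothing
    mean_high = float(upper.mean()) if upper.size else mean
    mean_low = float(lower.mean()) if lower.size else mean
    return RoiStats(roi_label, int(n), mean, sd, mean_low, mean_high)


def roi_statistics(map_grid: VoxelGrid, roi_mask: VoxelGrid,
                   trim_fraction: float = 0.20) -> RoiStats:
    """Mean, SD and trimmed means of a map over a binary ROI.

    An empty ROI yields NaN statistics flagged undefined, never zeros.
    """
    if roi_mask.kind != BINARY_MASK:
        raise ValueError("roi_mask must be a binary mask")
    if map_grid.shape != roi_mask.shape:
        raise ValueError("map and ROI grids differ")
    vals = map_grid.data[roi_mask.astype_bool()]
    return stats_from_values(vals, trim_fraction=trim_fraction)


def percent_difference(value_pos: float, value_neg: float) -> float:
    """Relative change of the T1+ value vs the T1- value, in percent.

    ``100 * (value_pos - value_neg) / value_neg``; report to one decimal.
    """
    if value_neg == 0:
        raise ValueError("percent difference undefined for zero reference")
    return 100.0 * (value_pos - value_neg) / value_neg
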