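"""Semi-quantitative rCBV reconstruction from DSC-MRI.

The model is the standard spin-echo DSC signal equation: during bolus passage
the signal drops as ``S(t) = S0 * exp(-TE * C(t))`` (concentration in units
proportional to Delta-R2), so concentration is recovered voxel-wise as

    C(t) = -(1/TE) * ln(S(t) / S0)

with ``S0`` the pre-bolus baseline mean. rCBV is the ratio of the trapezoidal
integral of a voxel's concentration-time curve to that of a slice-wise
arterial input function (AIF). The AIF of a transverse slice is the
per-timepoint median over "candidate" vascular voxels - the in-mask voxels
whose peak concentration reaches the 98th percentile of peaks within that
slice (at least ten voxels enforced) - smoothed with a Gaussian of one time
point. Because only the integral ratio is used, concentration units are
arbitrary and cancel.

No deconvolution, leakage correction or Delta-R2* nonlinearity is applied:
this is deliberately the simple integral-ratio estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter1d

from .volumes import BINARY_MASK, PARAMETRIC_MAP, VoxelGrid

__all__ = [
    "DscSeries",
    "AifCurve",
    "RcbvMap",
    "signal_to_concentration",
    "estimate_slice_aif",
    "compute_rcbv_map",
]

SLICE_AXIS = 2  # transverse slices are along the third voxel axis


@dataclass
class DscSeries:
    """4D DSC signal S(x, y, z, t) with acquisition timing.

    Defaults mirror a standard clinical protocol: TE = 29 ms, 1.8 s temporal
    resolution, 60 dynamic frames. ``baseline_window`` gives the number of
    leading pre-bolus frames averaged into S0.
    """

    signal: np.ndarray
    te_s: float = 0.029
    dt_s: float = 1.8
    baseline_window: int = 5
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 4:
            raise ValueError("DSC signal must be 4D (x, y, z, t)")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 time points for integration")
        if self.te_s <= 0 or self.dt_s <= 0:
            raise ValueError("TE and temporal spacing must be positive")
        if not (0 < self.baseline_window <= self.n_timepoints):
            raise ValueError("baseline_window out of range")
        if self.affine is None:
            self.affine = np.diag([*self.spacing_mm, 1.0])

    @property
    def n_timepoints(self) -> int:
        return self.signal.shape[3]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.dt_s

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.signal.astype(np.float32), self.affine)
        img.header.set_zooms((*self.spacing_mm, self.dt_s))
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, te_s: float = 0.029,
                   dt_s: float = 1.8, baseline_window: int = 5) -> "DscSeries":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(signal=data, te_s=te_s, dt_s=dt_s,
                   baseline_window=baseline_window, spacing_mm=spacing,
                   affine=np.asarray(img.affine))


@dataclass
class AifCurve:
    """Per-slice arterial input concentration curve with provenance."""

    concentration: np.ndarray
    slice_index: int
    candidate_count: int
    p_top_value: float
    smoothing_sigma_timepoints: float = 1.0
    borrowed_from: int | None = None  # set when a slice had no AIF of its own


@dataclass
class RcbvMap:
    grid: VoxelGrid
    per_slice_aifs: list[AifCurve] = field(default_factory=list)
    excluded_voxels: np.ndarray | None = None  # non-positive-signal voxels


def signal_to_concentration(series: DscSeries, brain_mask: VoxelGrid
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Convert DSC signal to concentration, C(t) = -(1/TE) ln(S(t)/S0).

    S0 is the mean over the leading ``baseline_window`` frames. Voxels with
    non-positive signal (or non-positive S0) inside the mask cannot be
    converted; they are zeroed and returned in a flagged mask.

    Returns
    -------
    conc : 4D array, zero outside the brain mask and at flagged voxels.
    flagged : 3D boolean array of excluded in-mask voxels.
    """
    if brain_mask.kind != BINARY_MASK:
        raise ValueError("brain_mask must be a binary mask")
    if series.signal.shape[:3] != brain_mask.shape:
        raise ValueError("DSC series and brain mask grids differ")
    mask = brain_mask.astype_bool()
    sig = series.signal  # float32 series are processed in float32
    if not np.issubdtype(sig.dtype, np.floating):
        sig = sig.astype(float)
    s0 = sig[..., :series.baseline_window].mean(axis=3)

    bad = mask & ((s0 <= 0) | (sig.min(axis=3) <= 0))
    ok = mask & ~bad
    conc = np.zeros_like(sig)
    if ok.any():
        ratio = sig[ok] / s0[ok][:, None]
        conc[ok] = -np.log(ratio) / series.te_s
    if bad.any():
        warnings.warn(f"{int(bad.sum())} in-mask voxels with non-positive "
                      "signal excluded from concentration conversion")
    if mask.any() and not ok.any():
        raise ValueError("no in-mask voxel has a valid (positive) signal")
    return conc, bad


def estimate_slice_aif(conc_slice: np.ndarray, mask_slice: np.ndarray,
                       slice_index: int = 0, min_candidates: int = 10,
                       percentile: float = 98.0,
                       sigma_timepoints: float = 1.0) -> AifCurve:
    """Estimate the arterial input function of one transverse slice.

    Candidate vascular voxels are the in-mask voxels whose peak concentration
    reaches the ``percentile``-th percentile of in-mask peaks; if fewer than
    ``min_candidates`` qualify, the ``min_candidates`` largest-peak voxels are
    taken instead. The AIF is the per-timepoint median over candidate curves,
    Gaussian-smoothed along time (reflection boundaries).
    """
    conc_slice = np.asarray(conc_slice, dtype=float)
    mask_slice = np.asarray(mask_slice).astype(bool)
    n_in = int(mask_slice.sum())
    if n_in < min_candidates:
        raise ValueError(
            f"slice {slice_index}: only {n_in} in-mask voxels "
            f"(< {min_candidates}); no AIF can be estimated")
    curves = conc_slice[mask_slice]          # (n_in, t)
    peaks = curves.max(axis=1)
    p_top = float(np.percentile(peaks, percentile))
    cand = peaks >= p_top
    if cand.sum() < min_candidates:
        cand = np.zeros_like(cand)
        cand[np.argsort(peaks)[-min_candidates:]] = True
    aif = np.median(curves[cand], axis=0)
    if sigma_timepoints > 0:
        aif = gaussian_filter1d(aif, sigma_timepoints, mode="reflect")
    return AifCurve(concentration=aif, slice_index=slice_index,
                    candidate_count=int(cand.sum()), p_top_value=p_top,
                    smoothing_sigma_timepoints=sigma_timepoints)


def compute_rcbv_map(series: DscSeries, brain_mask: VoxelGrid,
                     min_candidates: int = 10, percentile: float = 98.0,
                     sigma_timepoints: float = 1.0,
                     clamp_negative: bool = False) -> RcbvMap:
    """Voxel-wise rCBV: trapezoidal curve integral over the slice AIF integral.

    Slices with too few in-mask voxels for an AIF of their own borrow the
    nearest valid slice's AIF (thin apex slices would otherwise be dropped
    and bias rim coverage). Slices whose AIF integral is non-positive are
    excluded with a warning. Negative concentration excursions are kept in
    the integral unless ``clamp_negative`` is set.
    """
    conc, flagged = signal_to_concentration(series, brain_mask)
    if clamp_negative:
        conc = np.clip(conc, 0.0, None)
    mask = brain_mask.astype_bool()
    nz = series.signal.shape[SLICE_AXIS]
    dt = series.dt_s

    aifs: dict[int, AifCurve] = {}
    for z in range(nz):
        m = mask[:, :, z]
        if not m.any():
            continue
        try:
            aifs[z] = estimate_slice_aif(
                conc[:, :, z, :], m, slice_index=z,
                min_candidates=min_candidates, percentile=percentile,
                sigma_timepoints=sigma_timepoints)
        except ValueError:
            aifs[z] = None  # AIF-less; resolved below
    valid = [z for z, a in aifs.items()
             if a is not None and np.trapezoid(a.concentration, dx=dt) > 0]
    if not valid:
        raise ValueError("no slice yields a valid AIF")

    rcbv = np.zeros(brain_mask.shape)
    aif_list: list[AifCurve] = []
    for z, aif in aifs.items():
        if z not in valid:
            src = min(valid, key=lambda v: abs(v - z))
            borrowed = aifs[src]
            if aif is not None:
                warnings.warn(f"slice {z}: non-positive AIF integral; "
                              f"borrowing slice {src}")
            aif = AifCurve(concentration=borrowed.concentration,
                           slice_index=z,
                           candidate_count=borrowed.candidate_count,
                           p_top_value=borrowed.p_top_value,
                           smoothing_sigma_timepoints=sigma_timepoints,
                           borrowed_from=src)
        denom = np.trapezoid(aif.concentration, dx=dt)
        m = mask[:, :, z]
        num = np.trapezoid(conc[:, :, z, :], dx=dt, axis=2)
        rcbv[:, :, z][m] = num[m] / denom
        aif_list.append(aif)

    rcbv[flagged] = 0.0
    grid = VoxelGrid(rcbv, spacing_mm=brain_mask.spacing_mm,
                     kind=PARAMETRIC_MAP, units="",
                     affine=brain_mask.affine.copy())
    return RcbvMap(grid=grid, per_slice_aifs=aif_list, excluded_voxels=flagged)
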