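"""Volume data model, NIfTI I/O, isotropic resampling and voxel-count volumetry.

Every map and mask in the pipeline lives on a common 1 mm isotropic working
grid (the study protocol resamples all sequences to such a grid before any
geometry is built), so all internal geometry operates directly in voxel space.
World coordinates are carried along via the NIfTI affine but never used for
measurement: volumes are obtained by voxel counting at 1 mm^3 per voxel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "CaseVolumes",
    "resample_isotropic",
    "mask_volume_mm3",
    "load_case",
    "save_case",
]

PARAMETRIC_MAP = "parametric_map"
BINARY_MASK = "binary_mask"


def _default_affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


@dataclass
class VoxelGrid:
    """A 3D scalar field on a regular lattice.

    Parameters
    ----------
    data:
        3D array. For ``kind="binary_mask"`` the values must be in {0, 1}.
    spacing_mm:
        Per-axis voxel size in millimetres; strictly positive. The working
        grid of the pipeline is 1 mm isotropic.
    kind:
        ``"parametric_map"`` (ADC, rCBV, ...) or ``"binary_mask"``.
    units:
        Free-text physical units, e.g. ``"1e-6 mm^2/s"`` for ADC. Empty for
        unitless maps (rCBV) and masks.
    affine:
        Voxel-to-world affine, stored and propagated through I/O; defaults to
        a diagonal affine built from the spacing.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    kind: str = PARAMETRIC_MAP
    units: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("VoxelGrid data must be a non-empty 3D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be three strictly positive values")
        if self.kind not in (PARAMETRIC_MAP, BINARY_MASK):
            raise ValueError(f"unknown grid kind {self.kind!r}")
        if self.kind == BINARY_MASK:
            if self.data.dtype != np.bool_ and \
                    not ((self.data == 0) | (self.data == 1)).all():
                raise ValueError("binary_mask grids may only contain {0, 1}")
            self.data = self.data.astype(np.uint8)
        if self.affine is None:
            self.affine = _default_affine(self.spacing_mm)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def astype_bool(self) -> np.ndarray:
        return self.data.astype(bool)

    def with_data(self, data: np.ndarray, **kw) -> "VoxelGrid":
        return replace(self, data=data, **kw)

    # ---- NIfTI round trip -------------------------------------------------
    def to_nifti(self, path: str | Path) -> None:
        """Write the grid as NIfTI-1 (.nii / .nii.gz), preserving the affine.

        Masks are written as uint8 and round-trip bit-exactly; parametric maps
        are written in their native float dtype.
        """
        data = self.data
        if self.kind == BINARY_MASK:
            data = data.astype(np.uint8)
        img = nib.Nifti1Image(data, self.affine)
        img.header.set_zooms(self.spacing_mm)
        if self.units:
            img.header["descrip"] = self.units.encode()[:79]
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, kind: str = PARAMETRIC_MAP,
                   units: str = "") -> "VoxelGrid":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data=data, spacing_mm=spacing, kind=kind, units=units,
                   affine=np.asarray(img.affine))


def resample_isotropic(grid: VoxelGrid, target_spacing: float | tuple = 1.0,
                       target_shape: tuple[int, int, int] | None = None) -> VoxelGrid:
    """Resample a grid to a target spacing/shape.

    Parametric maps are interpolated linearly; binary masks with nearest
    neighbour so values stay in {0, 1}. Out-of-field voxels are filled with 0.
    """
    if np.isscalar(target_spacing):
        target_spacing = (float(target_spacing),) * 3
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be strictly positive")
    if target_shape is None:
        target_shape = tuple(
            int(np.ceil(n * sp / ts))
            for n, sp, ts in zip(grid.shape, grid.spacing_mm, target_spacing)
        )
    target_shape = tuple(int(n) for n in target_shape)
    if any(n < 1 for n in target_shape):
        raise ValueError("target shape must be positive")

    if target_spacing == grid.spacing_mm and target_shape == grid.shape:
        return grid.with_data(grid.data.copy(),
                              affine=grid.affine.copy())

    # output voxel index i maps to input voxel coordinate i * ts / sp
    coords = np.meshgrid(
        *[np.arange(n) * ts / sp
          for n, ts, sp in zip(target_shape, target_spacing, grid.spacing_mm)],
        indexing="ij",
    )
    order = 0 if grid.kind == BINARY_MASK else 1
    out = ndimage.map_coordinates(
        grid.data.astype(float), np.stack(coords), order=order,
        mode="constant", cval=0.0,
    )
    if grid.kind == BINARY_MASK:
        out = out.astype(np.uint8)
    aff = grid.affine.copy()
    aff[:3, :3] = aff[:3, :3] @ np.diag(
        [ts / sp for ts, sp in zip(target_spacing, grid.spacing_mm)]
    )
    return VoxelGrid(out, spacing_mm=target_spacing, kind=grid.kind,
                     units=grid.units, affine=aff)


def mask_volume_mm3(mask: VoxelGrid) -> float:
    """Volume of a binary mask by voxel counting: count x voxel volume."""
    if mask.kind != BINARY_MASK:
        raise ValueError("mask_volume_mm3 requires a binary_mask grid")
    voxel_mm3 = float(np.prod(mask.spacing_mm))
    return float(mask.data.sum()) * voxel_mm3


@dataclass
class CaseVolumes:
    """All co-registered volumes of one case on a shared grid.

    ``dsc`` may be ``None`` for diffusion-only workflows (e.g. large
    simulation studies that never touch perfusion).
    """

    case_id: str
    adc: VoxelGrid
    core_mask: VoxelGrid       # T1-enhancing core incl. necrosis
    flair_mask: VoxelGrid      # FLAIR-hyperintense region
    recurrence_mask: VoxelGrid  # follow-up abnormal T1c mapped to baseline
    brain_mask: VoxelGrid
    dsc: "object | None" = None  # DscSeries; typed loosely to avoid a cycle

    def __post_init__(self) -> None:
        grids = {
            "adc": self.adc, "core_mask": self.core_mask,
            "flair_mask": self.flair_mask, "recurrence_mask": self.recurrence_mask,
            "brain_mask": self.brain_mask,
        }
        ref = self.adc
        for name, g in grids.items():
            if g.shape != ref.shape or g.spacing_mm != ref.spacing_mm:
                raise ValueError(f"{name} grid does not match the case grid")
        if np.any(self.core_mask.data > self.brain_mask.data):
            raise ValueError("core_mask must be contained in brain_mask")


_ROLE_KINDS = {
    "adc": (PARAMETRIC_MAP, "1e-6 mm^2/s"),
    "core_mask": (BINARY_MASK, ""),
    "flair_mask": (BINARY_MASK, ""),
    "recurrence_mask": (BINARY_MASK, ""),
    "brain_mask": (BINARY_MASK, ""),
}


def load_case(manifest_path: str | Path) -> CaseVolumes:
    """Load a case from a JSON manifest mapping role -> NIfTI path.

    Required roles: adc, core_mask, flair_mask, recurrence_mask, brain_mask.
    Optional: dsc (4D NIfTI) with te_s / dt_s entries.
    """
    from .perfusion import DscSeries  # local import to avoid a cycle

    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    missing = [role for role in _ROLE_KINDS if role not in manifest]
    if missing:
        raise ValueError(f"manifest is missing required roles: {missing}")
    grids = {
        role: VoxelGrid.from_nifti(base / manifest[role], kind=kind,
                                   units=units)
        for role, (kind, units) in _ROLE_KINDS.items()
    }
    dsc = None
    if "dsc" in manifest:
        dsc = DscSeries.from_nifti(
            base / manifest["dsc"],
            te_s=float(manifest.get("te_s", 0.029)),
            dt_s=float(manifest.get("dt_s", 1.8)),
        )
    return CaseVolumes(case_id=str(manifest.get("case_id", manifest_path.stem)),
                       dsc=dsc, **grids)


def save_case(case: CaseVolumes, out_dir: str | Path) -> Path:
    """Write all case volumes plus a manifest JSON; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"case_id": case.case_id}
    for role in _ROLE_KINDS:
        path = out_dir / f"{case.case_id}_{role}.nii.gz"
        getattr(case, role).to_nifti(path)
        manifest[role] = path.name
    if case.dsc is not None:
        path = out_dir / f"{case.case_id}_dsc.nii.gz"
        case.dsc.to_nifti(path)
        manifest["dsc"] = path.name
        manifest["te_s"] = case.dsc.te_s
        manifest["dt_s"] = case.dsc.dt_s
    mpath = out_dir / f"{case.case_id}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath
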