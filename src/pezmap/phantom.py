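"""Synthetic multi-contrast brain-tumour phantom cohorts with known truth.

Each phantom case emulates the geometry the analysis consumes: a spherical
contrast-enhancing core with a necrotic interior, an anisotropic
FLAIR-hyperintense halo (thick on one hemisphere, thin on the other, so the
peri-enhancing rim contains both FLAIR+ and FLAIR- tissue), a recurrence lobe
contiguous with the core whose centre is solved by bisection so that a target
fraction (default one third) of its volume falls outside the FLAIR halo, a
ventricle abutting the rim plus a sulcal CSF shell (high-ADC fluid), and
scattered intraparenchymal vessels that carry the highest-amplitude bolus
curves for slice-wise AIF estimation.

ADC is drawn as class mean + i.i.d. Gaussian voxel noise; DSC signal is
synthesized from tissue concentration curves through the spin-echo signal
model ``S(t) = S0 exp(-TE * C(t))`` with ``C(t) = scale * cbv * b(t)`` and a
gamma-variate bolus ``b``. Between-subject variability has two parts: a
shared peritumoral component (negatively coupling ADC and CBV across cases,
mimicking the joint microenvironment shifts that drive the observed ADC-rCBV
anticorrelation) and independent per-class deviations that set the power of
the paired group tests; a per-case global gain/offset on the ADC map emulates
acquisition variability and is what cohort histogram normalization removes.
Spatially correlated texture is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .perfusion import DscSeries
from .volumes import BINARY_MASK, PARAMETRIC_MAP, CaseVolumes, VoxelGrid

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomCase",
    "GenerationError",
    "generate_case",
    "generate_cohort",
    "cohort_plan",
    "LABEL_NAMES",
]


class GenerationError(RuntimeError):
    """A phantom could not be built under the requested geometry."""


# integer tissue labels of the truth grid
LABEL_NAMES = {
    0: "background",
    1: "normal",
    2: "flairpos_stable",
    3: "flairpos_recurrence",
    4: "flairneg_stable",
    5: "flairneg_recurrence",
    6: "fluid",
    7: "arterial",
    8: "core",
    9: "necrosis",
}
PERITUMORAL_CLASSES = ("flairpos_stable", "flairpos_recurrence",
                       "flairneg_stable", "flairneg_recurrence")

_REFERENCE_EXTENT = 96.0  # geometry defaults below are stated at this extent


@dataclass
class PhantomSpec:
    """Study conditions for one phantom case / cohort.

    Geometric fields are in millimetres on the 1 mm isotropic grid; the
    defaults describe a 96 mm working cube and are rescaled proportionally by
    :meth:`scaled` for other grid sizes. ADC class means are in 1e-6 mm^2/s,
    CBV class means unitless with the arterial class at 1.0 (so recovered
    rCBV is directly comparable to the class table).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    brain_radius_mm: float = 40.0
    core_radius_mm: float = 12.0
    necrosis_radius_mm: float = 6.0
    flair_halo_thickness_mm: float = 10.0
    flair_thin_thickness_mm: float = 2.0
    recurrence_radius_mm: float = 8.0
    recurrence_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    flair_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    fraction_recurrence_outside_flair: float = 1.0 / 3.0
    core_offset_mm: tuple[float, float, float] = (6.0, -4.0, 0.0)
    ventricle_gap_mm: float = 2.0
    ventricle_semiaxes_mm: tuple[float, float, float] = (4.8, 6.6, 4.8)
    sulci_shell_voxels: int = 2
    # dense enough that vessels exceed the 2 % peak-percentile cut of the
    # slice-wise AIF selector in every slice that matters
    vessel_fraction: float = 0.12

    # FLAIR+ contrasts carry the recurrence signature; FLAIR- contrasts are
    # null by construction (the small printed FLAIR- differences of the
    # reference cohort are treated as sampling noise around a common mean).
    adc_means: dict = field(default_factory=lambda: {
        "flairpos_stable": 1291.0, "flairpos_recurrence": 1192.0,
        "flairneg_stable": 971.0, "flairneg_recurrence": 971.0,
        "normal": 800.0, "fluid": 3000.0, "core": 900.0,
        "necrosis": 2200.0, "arterial": 1000.0,
    })
    cbv_means: dict = field(default_factory=lambda: {
        "flairpos_stable": 0.29, "flairpos_recurrence": 0.33,
        "flairneg_stable": 0.35, "flairneg_recurrence": 0.35,
        "normal": 0.35, "fluid": 0.05, "core": 0.60,
        "necrosis": 0.05, "arterial": 1.0,
    })

    # voxel-level noise
    adc_noise_sd: float = 150.0
    cbv_noise_sd: float = 0.04
    signal_noise_sd: float = 2.0

    # between-subject variability of the peritumoral class means
    adc_shared_sd: float = 140.0
    adc_class_sd: float = 105.0
    cbv_shared_sd: float = 0.056
    cbv_class_sd: float = 0.05
    adc_cbv_coupling: float = 0.8  # negative ADC/CBV coupling of the shared part

    # per-case acquisition affine on the ADC map
    adc_gain_sd: float = 0.04
    adc_offset_sd: float = 25.0

    # DSC acquisition and bolus model
    te_s: float = 0.029
    dt_s: float = 1.8
    n_timepoints: int = 60
    baseline_window: int = 5
    s0: float = 1000.0
    bolus_t0_s: float = 18.0
    bolus_alpha: float = 3.0
    bolus_tp_s: float = 9.0
    conc_scale: float = 25.0

    geometry_jitter: float = 0.10  # relative jitter of radii across a cohort
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("brain_radius_mm", "core_radius_mm", "necrosis_radius_mm",
                     "flair_halo_thickness_mm", "recurrence_radius_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        emitted = set(LABEL_NAMES.values()) - {"background"}
        for table, tname in ((self.adc_means, "adc_means"),
                             (self.cbv_means, "cbv_means")):
            missing = emitted - set(table)
            if missing:
                raise ValueError(f"{tname} missing classes: {sorted(missing)}")

    @classmethod
    def scaled(cls, grid_shape: tuple[int, int, int] = (96, 96, 96),
               **overrides) -> "PhantomSpec":
        """Spec with all geometric defaults rescaled to ``grid_shape``."""
        f = min(grid_shape) / _REFERENCE_EXTENT
        base = cls()
        geo = dict(
            grid_shape=tuple(int(n) for n in grid_shape),
            brain_radius_mm=base.brain_radius_mm * f,
            core_radius_mm=base.core_radius_mm * f,
            necrosis_radius_mm=base.necrosis_radius_mm * f,
            flair_halo_thickness_mm=base.flair_halo_thickness_mm * f,
            flair_thin_thickness_mm=base.flair_thin_thickness_mm * f,
            recurrence_radius_mm=base.recurrence_radius_mm * f,
            core_offset_mm=tuple(c * f for c in base.core_offset_mm),
            ventricle_gap_mm=base.ventricle_gap_mm * f,
            ventricle_semiaxes_mm=tuple(a * f for a in base.ventricle_semiaxes_mm),
        )
        geo.update(overrides)
        return cls(**geo)

    def noise_free(self) -> "PhantomSpec":
        """All voxel noise, between-subject variability and gain/offset off."""
        return replace(self, adc_noise_sd=0.0, cbv_noise_sd=0.0,
                       signal_noise_sd=0.0, adc_shared_sd=0.0,
                       adc_class_sd=0.0, cbv_shared_sd=0.0, cbv_class_sd=0.0,
                       adc_gain_sd=0.0, adc_offset_sd=0.0)

    def null_effect(self) -> "PhantomSpec":
        """Recurrence-prone class means set equal to the stable ones."""
        adc = dict(self.adc_means)
        cbv = dict(self.cbv_means)
        adc["flairpos_recurrence"] = adc["flairpos_stable"]
        adc["flairneg_recurrence"] = adc["flairneg_stable"]
        cbv["flairpos_recurrence"] = cbv["flairpos_stable"]
        cbv["flairneg_recurrence"] = cbv["flairneg_stable"]
        return replace(self, adc_means=adc, cbv_means=cbv)


@dataclass
class PhantomTruth:
    labels: np.ndarray                  # int8 tissue-class grid
    adc_class_means: dict               # per-case (sampled) class means
    cbv_class_means: dict
    fraction_outside_flair: float
    lobe_center_offset_mm: float
    adc_gain: float
    adc_offset: float

    def class_mask(self, name: str) -> np.ndarray:
        code = {v: k for k, v in LABEL_NAMES.items()}[name]
        return self.labels == code


@dataclass
class PhantomCase:
    volumes: CaseVolumes
    truth: PhantomTruth
    spec: PhantomSpec


_COORD_CACHE: dict[tuple, np.ndarray] = {}


def _coords(shape: tuple[int, int, int]) -> np.ndarray:
    """Voxel-index coordinate field, cached for desk-scale grids."""
    if np.prod(shape) > 2_000_000:  # full working grids are not cached
        return np.indices(shape, dtype=float)
    if shape not in _COORD_CACHE:
        _COORD_CACHE[shape] = np.indices(shape, dtype=float)
    return _COORD_CACHE[shape]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction vector")
    return v / n


def _gamma_variate(times_s: np.ndarray, t0: float, alpha: float,
                   tp: float) -> np.ndarray:
    """Gamma-variate bolus, unit peak at t0 + tp."""
    tau = np.clip(times_s - t0, 0.0, None) / tp
    return tau ** alpha * np.exp(alpha * (1.0 - tau))


def _sample_case_means(spec: PhantomSpec, rng: np.random.Generator
                       ) -> tuple[dict, dict, float, float]:
    """Per-case class-mean tables plus the ADC acquisition affine."""
    z = rng.standard_normal()
    w = rng.standard_normal()
    rho = spec.adc_cbv_coupling
    adc_shift = spec.adc_shared_sd * z
    cbv_shift = spec.cbv_shared_sd * (-rho * z + np.sqrt(1 - rho ** 2) * w)
    adc = dict(spec.adc_means)
    cbv = dict(spec.cbv_means)
    for name in PERITUMORAL_CLASSES:
        adc[name] = adc[name] + adc_shift + rng.normal(0.0, spec.adc_class_sd)
        cbv[name] = cbv[name] + cbv_shift + rng.normal(0.0, spec.cbv_class_sd)
    gain = 1.0 + rng.normal(0.0, spec.adc_gain_sd)
    offset = rng.normal(0.0, spec.adc_offset_sd)
    return adc, cbv, gain, offset


def _solve_lobe_offset(rho2: np.ndarray, s_proj: np.ndarray,
                       eligible: np.ndarray, outside_flair: np.ndarray,
                       spec: PhantomSpec) -> float:
    """Bisection on the lobe-centre offset for the outside-FLAIR fraction."""
    r = spec.recurrence_radius_mm
    target = spec.fraction_recurrence_outside_flair

    def fraction(c: float) -> float:
        lobe = (rho2 + (s_proj - c) ** 2 <= r * r) & eligible
        n = int(lobe.sum())
        if n == 0:
            return 0.0
        return float((lobe & outside_flair).sum()) / n

    lo = max(spec.core_radius_mm - r + 1.0, 1.0)
    hi = spec.core_radius_mm + spec.flair_halo_thickness_mm + r
    if fraction(hi) < target:
        return hi
    if fraction(lo) > target:
        return lo
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        if fraction(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_case(spec: PhantomSpec, seed: int,
                  with_dsc: bool = True) -> PhantomCase:
    """Build one phantom case; deterministic given (spec, seed)."""
    rng = np.random.default_rng(seed)
    adc_means, cbv_means, gain, offset = _sample_case_means(spec, rng)

    shape = tuple(spec.grid_shape)
    center = (np.array(shape, dtype=float) - 1.0) / 2.0
    cc = center + np.asarray(spec.core_offset_mm, dtype=float)
    u_r = _unit(spec.recurrence_direction)
    u_f = _unit(np.asarray(spec.flair_axis, dtype=float)
                - np.dot(spec.flair_axis, u_r) * u_r)

    idx = _coords(shape)
    rel = idx - cc.reshape(3, 1, 1, 1)
    r2_core = np.einsum("i...,i...->...", rel, rel)
    rel_b = idx - center.reshape(3, 1, 1, 1)
    r2_brain = np.einsum("i...,i...->...", rel_b, rel_b)

    brain = r2_brain <= spec.brain_radius_mm ** 2
    core = r2_core <= spec.core_radius_mm ** 2
    necrosis = r2_core <= spec.necrosis_radius_mm ** 2
    d_core = ndimage.distance_transform_edt(~core)

    # anisotropic FLAIR halo: thick on the +flair_axis hemisphere, thin on -
    proj_f = np.einsum("i...,i->...", rel, u_f)
    thickness = np.where(proj_f >= 0, spec.flair_halo_thickness_mm,
                         spec.flair_thin_thickness_mm)
    flair_halo = (d_core > 0) & (d_core <= thickness) & brain

    # recurrence lobe: sphere along u_r, centre offset solved for the
    # target outside-FLAIR fraction
    s_proj = np.einsum("i...,i->...", rel, u_r)
    rho2 = r2_core - s_proj ** 2
    eligible = brain & ~core
    c_off = _solve_lobe_offset(rho2, s_proj, eligible,
                               eligible & ~flair_halo, spec)
    lobe = (rho2 + (s_proj - c_off) ** 2 <= spec.recurrence_radius_mm ** 2)
    recurrence = lobe & brain
    if not recurrence.any():
        raise GenerationError("recurrence lobe is empty")
    dilated_core = ndimage.binary_dilation(core)
    if not (recurrence & dilated_core).any():
        raise GenerationError("recurrence lobe is not contiguous with the core")
    n_comp = ndimage.label(recurrence)[1]
    if n_comp != 1:
        raise GenerationError("recurrence mask is not a single component")
    achieved = (float((recurrence & ~core & ~flair_halo).sum())
                / max(int((recurrence & ~core).sum()), 1))

    # fluid: ventricle ellipsoid abutting the rim + sulcal CSF shell
    vc = cc - u_r * (spec.core_radius_mm + spec.ventricle_gap_mm)
    rel_v = idx - vc.reshape(3, 1, 1, 1)
    ax = np.asarray(spec.ventricle_semiaxes_mm).reshape(3, 1, 1, 1)
    ventricle = np.einsum("i...,i...->...", rel_v / ax, rel_v / ax) <= 1.0
    eroded = ndimage.binary_erosion(brain,
                                    iterations=spec.sulci_shell_voxels)
    fluid = ((ventricle | (brain & ~eroded)) & brain) & ~core

    # scattered vessels outside the peritumoral band
    vessel_ok = brain & ~core & ~fluid & (d_core > spec.flair_halo_thickness_mm)
    vessels = vessel_ok & (rng.random(shape) < spec.vessel_fraction)

    labels = np.zeros(shape, dtype=np.int8)
    labels[brain] = 1  # normal
    band = (d_core > 0) & (d_core <= spec.flair_halo_thickness_mm) & brain
    labels[band & ~flair_halo & ~recurrence] = 4      # flairneg_stable
    labels[flair_halo & ~recurrence] = 2              # flairpos_stable
    labels[flair_halo & recurrence] = 3               # flairpos_recurrence
    labels[brain & recurrence & ~flair_halo & ~core] = 5  # flairneg_recurrence
    labels[vessels] = 7
    labels[fluid] = 6
    labels[core & brain] = 8
    labels[necrosis & brain] = 9

    adc_lut = np.array([0.0] + [adc_means[LABEL_NAMES[i]] for i in range(1, 10)])
    cbv_lut = np.array([0.0] + [cbv_means[LABEL_NAMES[i]] for i in range(1, 10)])

    adc = adc_lut[labels]
    if spec.adc_noise_sd > 0:
        adc = adc + rng.normal(0.0, spec.adc_noise_sd, shape)
    adc = np.where(brain, gain * adc + offset, 0.0)

    mk_mask = lambda m: VoxelGrid(m.astype(np.uint8), kind=BINARY_MASK)
    grids = dict(
        adc=VoxelGrid(adc, kind=PARAMETRIC_MAP, units="1e-6 mm^2/s"),
        core_mask=mk_mask(core & brain),
        flair_mask=mk_mask((flair_halo | (core & brain))),
        recurrence_mask=mk_mask(recurrence),
        brain_mask=mk_mask(brain),
    )

    dsc = None
    if with_dsc:
        cbv_vox = cbv_lut[labels]
        if spec.cbv_noise_sd > 0:
            cbv_vox = cbv_vox + rng.normal(0.0, spec.cbv_noise_sd, shape)
            cbv_vox = np.clip(cbv_vox, 0.01, None)
        times = np.arange(spec.n_timepoints) * spec.dt_s
        bolus = _gamma_variate(times, spec.bolus_t0_s, spec.bolus_alpha,
                               spec.bolus_tp_s)
        # synthesize curves for brain voxels only (float32 throughout);
        # outside the brain the signal stays at the flat baseline S0
        amp = (spec.conc_scale * cbv_vox[brain]).astype(np.float32)
        curves = np.exp(np.float32(-spec.te_s) * amp[:, None]
                        * bolus.astype(np.float32)[None, :])
        signal = np.full(shape + (spec.n_timepoints,), spec.s0,
                         dtype=np.float32)
        signal[brain] = np.float32(spec.s0) * curves
        if spec.signal_noise_sd > 0:
            noise = rng.standard_normal((int(brain.sum()),
                                         spec.n_timepoints),
                                        dtype=np.float32)
            signal[brain] += np.float32(spec.signal_noise_sd) * noise
        dsc = DscSeries(signal=signal, te_s=spec.te_s, dt_s=spec.dt_s,
                        baseline_window=spec.baseline_window)

    volumes = CaseVolumes(case_id=f"phantom-{seed}", dsc=dsc, **grids)
    truth = PhantomTruth(labels=labels, adc_class_means=adc_means,
                         cbv_class_means=cbv_means,
                         fraction_outside_flair=achieved,
                         lobe_center_offset_mm=float(c_off),
                         adc_gain=gain, adc_offset=offset)
    return PhantomCase(volumes=volumes, truth=truth, spec=spec)


def cohort_plan(n_cases: int, spec: PhantomSpec,
                seed: int) -> list[tuple[PhantomSpec, int]]:
    """Deterministic per-case (jittered spec, derived seed) pairs."""
    if n_cases < 1:
        raise ValueError("n_cases must be at least 1")
    master = np.random.default_rng(seed)
    plan = []
    for _ in range(n_cases):
        case_seed = int(master.integers(0, 2 ** 31 - 1))
        j = spec.geometry_jitter
        jit = lambda: float(master.uniform(1.0 - j, 1.0 + j))
        a = master.standard_normal(3)
        b = master.standard_normal(3)
        u_r = _unit(a)
        u_f = _unit(b - np.dot(b, u_r) * u_r)
        case_spec = replace(
            spec,
            core_radius_mm=spec.core_radius_mm * jit(),
            necrosis_radius_mm=spec.necrosis_radius_mm * jit(),
            flair_halo_thickness_mm=spec.flair_halo_thickness_mm * jit(),
            recurrence_radius_mm=spec.recurrence_radius_mm * jit(),
            recurrence_direction=tuple(u_r),
            flair_axis=tuple(u_f),
        )
        plan.append((case_spec, case_seed))
    return plan


def iter_cohort(n_cases: int, spec: PhantomSpec, seed: int,
                with_dsc: bool = True):
    """Lazily yield cohort phantoms one at a time.

    A 4D DSC series is large; generating lazily lets a consumer discard each
    series once its rCBV map has been reconstructed.
    """
    for i, (case_spec, case_seed) in enumerate(cohort_plan(n_cases, spec, seed)):
        case = generate_case(case_spec, case_seed, with_dsc=with_dsc)
        case.volumes.case_id = f"case{i:03d}"
        yield case


def generate_cohort(n_cases: int, spec: PhantomSpec, seed: int,
                    with_dsc: bool = True) -> list[PhantomCase]:
    """Generate ``n_cases`` phantoms with jittered geometry and derived seeds."""
    return list(iter_cohort(n_cases, spec, seed, with_dsc=with_dsc))
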