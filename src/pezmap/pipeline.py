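"""Per-case and cohort orchestration.

Per case: rCBV reconstruction -> PEZ rim -> fluid exclusion -> four-way
partition -> ROI statistics (4 compartments x 2 modalities). Per cohort:
cohort histogram references -> normalization -> cohort table -> paired
inference, ADC-rCBV correlation and ROC/Youden discrimination on the FLAIR+
compartment means. Processing is deterministic given inputs and config; cases
are independent and merged by case_id sort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inference, roi
from .perfusion import RcbvMap, compute_rcbv_map
from .pez import COMPARTMENTS, PezPartition, build_pez, exclude_fluid, \
    partition_pez, suggest_fluid_threshold
from .volumes import CaseVolumes, VoxelGrid, mask_volume_mm3

__all__ = ["PipelineConfig", "CaseResult", "CohortResult",
           "analyze_case", "analyze_cohort"]

MODALITIES = ("adc", "rcbv")


@dataclass
class PipelineConfig:
    """Every under-specified analysis parameter, surfaced in one place."""

    pez_width_voxels: int = 5
    fluid_threshold: float | str = "auto"  # "auto" or a fixed 1e-6 mm^2/s value
    norm_percentiles: tuple[float, float] = (1.0, 99.0)
    normalize_adc: bool = True
    trim_fraction: float = 0.20
    test_mode: str = "signed_rank"
    roc_region: str = "FLAIR+"
    clamp_negative_concentration: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.trim_fraction < 0.5:
            raise ValueError("trim fraction must lie in (0, 0.5)")
        if self.pez_width_voxels < 1:
            raise ValueError("PEZ width must be at least 1 voxel")


@dataclass
class CaseResult:
    case_id: str
    partition: PezPartition
    rcbv: RcbvMap | None
    stats: pd.DataFrame          # 8 rows: compartment x modality, raw maps
    fluid_threshold: float
    compartment_volumes_mm3: dict
    adc: VoxelGrid = None
    brain_mask: VoxelGrid = None


@dataclass
class CohortResult:
    per_case: list[CaseResult]
    table: pd.DataFrame          # cohort table on normalized maps
    summary: pd.DataFrame
    roc: dict
    correlations: dict
    references: dict
    volume_summary: pd.DataFrame


def _stats_rows(case_id: str, maps: dict, partition: PezPartition,
                trim_fraction: float) -> pd.DataFrame:
    rows = []
    for name, comp in partition.compartments().items():
        for modality, grid in maps.items():
            st = roi.roi_statistics(grid, comp, trim_fraction=trim_fraction)
            rows.append({
                "case_id": case_id, "roi_label": name, "modality": modality,
                "n_voxels": st.n_voxels, "mean": st.mean, "sd": st.sd,
                "mean_low": st.mean_low, "mean_high": st.mean_high,
            })
    return pd.DataFrame(rows)


def analyze_case(volumes: CaseVolumes, config: PipelineConfig) -> CaseResult:
    """Run the per-case chain on raw (un-normalized) maps."""
    rcbv = None
    maps: dict[str, VoxelGrid] = {"adc": volumes.adc}
    if volumes.dsc is not None:
        rcbv = compute_rcbv_map(
            volumes.dsc, volumes.brain_mask,
            clamp_negative=config.clamp_negative_concentration)
        maps["rcbv"] = rcbv.grid

    pez = build_pez(volumes.core_mask, volumes.brain_mask,
                    width_voxels=config.pez_width_voxels)
    if config.fluid_threshold == "auto":
        threshold = suggest_fluid_threshold(volumes.adc, pez)
    else:
        threshold = float(config.fluid_threshold)
    cleaned, excluded = exclude_fluid(pez, volumes.adc, threshold)
    partition = partition_pez(cleaned, volumes.flair_mask,
                              volumes.recurrence_mask,
                              excluded_fluid=excluded,
                              width_voxels=config.pez_width_voxels,
                              adc_fluid_threshold=threshold)
    stats = _stats_rows(volumes.case_id, maps, partition, config.trim_fraction)
    vols = {name: mask_volume_mm3(comp)
            for name, comp in partition.compartments().items()}
    return CaseResult(case_id=volumes.case_id, partition=partition, rcbv=rcbv,
                      stats=stats, fluid_threshold=threshold,
                      compartment_volumes_mm3=vols, adc=volumes.adc,
                      brain_mask=volumes.brain_mask)


def _volume_summary(results: list[CaseResult]) -> pd.DataFrame:
    """Across-case compartment volumes and the T1+ share per FLAIR stratum."""
    vols = pd.DataFrame([r.compartment_volumes_mm3 | {"case_id": r.case_id}
                         for r in results]).set_index("case_id").sort_index()
    rows = []
    for region, pos_lab, neg_lab in (
            ("FLAIR+", "t1pos_flairpos", "t1neg_flairpos"),
            ("FLAIR-", "t1pos_flairneg", "t1neg_flairneg")):
        mp, mn = vols[pos_lab].mean(), vols[neg_lab].mean()
        rows.append({
            "region": region,
            "t1pos_mean_mm3": mp, "t1pos_sd_mm3": vols[pos_lab].std(ddof=1),
            "t1neg_mean_mm3": mn, "t1neg_sd_mm3": vols[neg_lab].std(ddof=1),
            "t1pos_share_pct": 100.0 * mp / (mp + mn) if mp + mn > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def analyze_cohort(cases,
                   config: PipelineConfig | None = None) -> CohortResult:
    """Run per-case analyses, normalize across the cohort, and infer.

    ``cases`` is any iterable of :class:`CaseVolumes`; it is consumed
    lazily so that large 4D DSC series can be discarded case by case once
    their rCBV map is reconstructed.
    """
    config = config or PipelineConfig()
    results, failures = [], []
    n_seen = 0
    for vols in cases:
        n_seen += 1
        try:
            results.append(analyze_case(vols, config))
        except Exception as exc:  # collected, re-raised if nothing succeeds
            failures.append((vols.case_id, exc))
    if n_seen < 2:
        raise ValueError("a cohort needs at least 2 cases")
    if not results:
        raise RuntimeError(f"all cases failed: {failures}")
    results.sort(key=lambda r: r.case_id)

    # cohort references + normalized per-case maps
    references: dict[str, roi.CohortReference] = {}
    norm_maps: dict[str, list[VoxelGrid]] = {}
    brains = [r.brain_mask for r in results]
    if config.normalize_adc:
        references["adc"] = roi.compute_cohort_reference(
            [r.adc for r in results], brains,
            percentiles=config.norm_percentiles, modality="adc")
        norm_maps["adc"] = [roi.normalize_map(r.adc, b, references["adc"])
                            for r, b in zip(results, brains)]
    else:
        norm_maps["adc"] = [r.adc for r in results]
    has_rcbv = all(r.rcbv is not None for r in results)
    if has_rcbv:
        references["rcbv"] = roi.compute_cohort_reference(
            [r.rcbv.grid for r in results], brains,
            percentiles=config.norm_percentiles, modality="rcbv")
        norm_maps["rcbv"] = [roi.normalize_map(r.rcbv.grid, b, references["rcbv"])
                             for r, b in zip(results, brains)]

    tables = []
    for i, r in enumerate(results):
        maps = {m: norm_maps[m][i] for m in norm_maps}
        tables.append(_stats_rows(r.case_id, maps, r.partition,
                                  config.trim_fraction))
    table = pd.concat(tables, ignore_index=True)

    summary = inference.summarize_cohort(table, mode=config.test_mode)

    pos_lab, neg_lab = (("t1pos_flairpos", "t1neg_flairpos")
                        if config.roc_region == "FLAIR+"
                        else ("t1pos_flairneg", "t1neg_flairneg"))
    roc: dict = {}
    correlations: dict = {}
    for modality in norm_maps:
        sub = table[table["modality"] == modality]
        pivot = sub.pivot(index="case_id", columns="roi_label", values="mean")
        pos = pivot[pos_lab].dropna()
        neg = pivot[neg_lab].dropna()
        values = np.concatenate([pos.values, neg.values])
        labels = np.concatenate([np.ones(len(pos), dtype=bool),
                                 np.zeros(len(neg), dtype=bool)])
        direction = "less" if modality == "adc" else "greater"
        roc[modality] = inference.roc_youden(values, labels,
                                             direction=direction)
    if has_rcbv:
        adc_piv = table[table["modality"] == "adc"].pivot(
            index="case_id", columns="roi_label", values="mean")
        cbv_piv = table[table["modality"] == "rcbv"].pivot(
            index="case_id", columns="roi_label", values="mean")
        for lab in (pos_lab, neg_lab):
            correlations[lab] = inference.correlate(adc_piv[lab].values,
                                                    cbv_piv[lab].values)

    return CohortResult(per_case=results, table=table, summary=summary,
                        roc=roc, correlations=correlations,
                        references=references,
                        volume_summary=_volume_summary(results))
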