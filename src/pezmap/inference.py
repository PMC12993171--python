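"""Cohort-level statistics for the PEZ compartment comparison.

Each patient contributes paired compartment means (T1+ and T1- within each
FLAIR stratum), so the primary comparison is the two-sided Wilcoxon
signed-rank test on the within-patient differences; an unpaired rank-sum
(Mann-Whitney) mode is also available. ADC-rCBV association uses Pearson's r.
Discrimination between recurrence-prone and stable compartments is summarized
with the rank-formulation AUC (ties counted as one half) and the threshold
maximizing Youden's J = sensitivity + specificity - 1, ties in J broken
toward higher specificity. No multiple-testing correction is applied; raw
p-values are reported together with the number of tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .roi import percent_difference

__all__ = [
    "StatResult",
    "RocResult",
    "paired_compare",
    "correlate",
    "roc_youden",
    "summarize_cohort",
]


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    n_pairs: int
    effect_direction: str  # "positive", "negative" or "none"
    n_dropped: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class RocResult:
    auc: float
    youden_threshold: float
    sensitivity_at_threshold: float
    specificity_at_threshold: float
    direction: str = "greater"  # rule: predict positive if value >=/<= threshold

    @property
    def youden_j(self) -> float:
        return self.sensitivity_at_threshold + self.specificity_at_threshold - 1.0


def _direction(diff_mean: float) -> str:
    if diff_mean > 0:
        return "positive"
    if diff_mean < 0:
        return "negative"
    return "none"


def paired_compare(values_t1pos, values_t1neg,
                   mode: str = "signed_rank") -> StatResult:
    """Two-sided comparison of the T1+ vs T1- per-case values.

    ``signed_rank`` (paired, the primary mode): cases missing either side are
    dropped and counted; the exact null distribution is used for small n
    (no ties/zeros), the normal approximation with tie and zero handling
    otherwise. ``rank_sum``: unpaired Wilcoxon-Mann-Whitney.
    """
    x = np.asarray(values_t1pos, dtype=float)
    y = np.asarray(values_t1neg, dtype=float)
    if mode == "signed_rank":
        if x.shape != y.shape:
            raise ValueError("paired mode needs equal-length samples")
        keep = np.isfinite(x) & np.isfinite(y)
        dropped = int((~keep).sum())
        x, y = x[keep], y[keep]
        d = x - y
        if d.size == 0 or np.all(d == 0):
            return StatResult("wilcoxon_signed_rank", float("nan"),
                              float("nan"), int(d.size), "none",
                              n_dropped=dropped, degenerate=True)
        res = sps.wilcoxon(x, y, alternative="two-sided", method="auto",
                           zero_method="wilcox")
        return StatResult("wilcoxon_signed_rank", float(res.statistic),
                          float(res.pvalue), int(d.size),
                          _direction(float(np.mean(d))), n_dropped=dropped,
                          degenerate=d.size < 5)  # too few pairs for meaning
    if mode == "rank_sum":
        x = x[np.isfinite(x)]
        y = y[np.isfinite(y)]
        if x.size == 0 or y.size == 0:
            raise ValueError("rank_sum needs non-empty samples on both sides")
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        return StatResult("wilcoxon_mann_whitney", float(res.statistic),
                          float(res.pvalue), int(min(x.size, y.size)),
                          _direction(float(np.mean(x) - np.mean(y))))
    raise ValueError(f"unknown mode {mode!r}")


def correlate(x, y) -> StatResult:
    """Pearson correlation with a two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("correlation needs at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return StatResult("pearson", float(r), float(p), int(x.size),
                      _direction(float(r)))


def roc_youden(values, labels, direction: str = "greater") -> RocResult:
    """AUC (rank formulation, tie-corrected) and the Youden-optimal threshold.

    ``direction="greater"``: higher values indicate the positive class and a
    case is called positive when its value >= threshold. ``"less"`` flips
    both. The threshold maximizing J is searched over the observed values;
    ties in J are broken toward higher specificity.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels).astype(bool)
    if v.shape != lab.shape:
        raise ValueError("values and labels differ in length")
    if lab.all() or not lab.any():
        raise ValueError("both classes must be represented")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    s = v if direction == "greater" else -v

    n1 = int(lab.sum())
    n0 = lab.size - n1
    ranks = sps.rankdata(s)  # average ranks handle ties (count as 1/2)
    auc = (ranks[lab].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    pos, neg = s[lab], s[~lab]
    best = None
    for t in np.unique(s):
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        j = sens + spec - 1.0
        key = (j, spec)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    _, thr, sens, spec = best
    thr = thr if direction == "greater" else -thr
    return RocResult(auc=float(auc), youden_threshold=float(thr),
                     sensitivity_at_threshold=sens,
                     specificity_at_threshold=spec, direction=direction)


_REGIONS = {"FLAIR+": ("t1pos_flairpos", "t1neg_flairpos"),
            "FLAIR-": ("t1pos_flairneg", "t1neg_flairneg")}
_MEASURES = ("mean", "mean_low", "mean_high")


def summarize_cohort(table: pd.DataFrame,
                     mode: str = "signed_rank") -> pd.DataFrame:
    """Group-mean summary rows per (region, modality, measure).

    ``table`` holds one row per (case_id, roi_label, modality) with columns
    ``mean``, ``mean_low``, ``mean_high`` (a cohort table). Each summary row
    carries the across-case mean +/- SD for T1+ and T1-, the percent
    difference of the across-case means, and the paired two-sided p-value.
    Case order is irrelevant (rows are aligned by case_id).
    """
    if table.empty:
        raise ValueError("empty cohort table")
    dup = table.duplicated(subset=["case_id", "roi_label", "modality"])
    if dup.any():
        raise ValueError("cohort table has duplicate (case, roi, modality) rows")
    rows = []
    for modality in sorted(table["modality"].unique()):
        sub = table[table["modality"] == modality]
        for region, (pos_lab, neg_lab) in _REGIONS.items():
            for measure in _MEASURES:
                pivot = sub.pivot(index="case_id", columns="roi_label",
                                  values=measure).sort_index()
                pos = pivot[pos_lab] if pos_lab in pivot else pd.Series(dtype=float)
                neg = pivot[neg_lab] if neg_lab in pivot else pd.Series(dtype=float)
                pos, neg = pos.align(neg)
                complete = pos.notna() & neg.notna()
                if complete.sum() == 0:
                    rows.append({"region": region, "modality": modality,
                                 "measure": measure, "n_cases": 0,
                                 "flagged": True})
                    continue
                test = paired_compare(pos.values, neg.values, mode=mode)
                mp, mn = float(pos[complete].mean()), float(neg[complete].mean())
                rows.append({
                    "region": region, "modality": modality, "measure": measure,
                    "n_cases": int(complete.sum()),
                    "t1pos_mean": mp,
                    "t1pos_sd": float(pos[complete].std(ddof=1)),
                    "t1neg_mean": mn,
                    "t1neg_sd": float(neg[complete].std(ddof=1)),
                    "pct_difference": percent_difference(mp, mn),
                    "p_value": test.p_value,
                    "degenerate": test.degenerate,
                    "flagged": False,
                })
    return pd.DataFrame(rows)
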