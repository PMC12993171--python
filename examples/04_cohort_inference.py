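"""Cohort-level inference on a small phantom cohort.

Generates co-registered phantom cases, normalizes ADC and rCBV maps to the
cohort histogram reference, builds the compartment table, and runs the
paired signed-rank comparison plus ROC/Youden discrimination. (The full
study-scale run uses 46 cases at 96^3; this desk example uses 12 cases at
64^3 and finishes in well under a minute.)
"""

import warnings

warnings.simplefilter("ignore")

from pezmap import PhantomSpec, PipelineConfig, analyze_cohort
from pezmap.phantom import iter_cohort

spec = PhantomSpec.scaled((64, 64, 64))
result = analyze_cohort((c.volumes for c in iter_cohort(12, spec, seed=7)),
                        PipelineConfig())

s = result.summary
for _, row in s[s.measure == "mean"].iterrows():
    print(f"{row.region:6s} {row.modality:4s}: "
          f"T1+ {row.t1pos_mean:8.2f}  T1- {row.t1neg_mean:8.2f}  "
          f"diff {row.pct_difference:+6.1f} %  p={row.p_value:.4f}")
for modality, roc in result.roc.items():
    print(f"ROC {modality}: AUC {roc.auc:.2f}, "
          f"Youden threshold {roc.youden_threshold:.3g}")
# Expected pattern: ADC lower and rCBV higher in FLAIR+ recurrence-prone
# tissue; FLAIR- differences are compatible with zero. p-values at n=12 are
# noisier than at the full cohort size.
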