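# pezmap

Three-dimensional quantitative analysis of the **peri-enhancing zone (PEZ)**
of glioblastoma: the thin rim of tissue immediately surrounding the
contrast-enhancing tumour core, where most local relapses arise. `pezmap` is
aimed at neuroimaging researchers who want a tested, reusable implementation
of the full chain from raw 4D perfusion MRI and segmentation masks to
cohort-level statistics — together with a synthetic phantom-cohort generator
with known ground truth for validating every step.

## What it computes

Given co-registered 1 mm isotropic volumes per case (ADC map, 4D DSC series,
masks for the enhancing core incl. necrosis, FLAIR hyperintensity, follow-up
recurrence mapped to baseline, and brain):

1. **rCBV reconstruction** (`pezmap.perfusion`). DSC signal is converted to
   contrast-agent concentration with the spin-echo model

   C(t) = −(1/TE) · ln( S(t) / S₀ ),

   a slice-wise arterial input function AIF(t) is taken as the per-timepoint
   median over candidate vascular voxels — those whose peak concentration
   reaches the 98th percentile of in-slice peaks (≥ 10 voxels enforced) —
   smoothed with a Gaussian of σ = 1 time point, and

   rCBV(x, y) = ∫₀ᵀ C(x, y, t) dt / ∫₀ᵀ AIF(t) dt

   by the trapezoidal rule.
2. **PEZ construction and partition** (`pezmap.pez`). The PEZ is
   {v ∈ brain : 0 < d_E(v, core) ≤ 5} with d_E the Euclidean distance
   transform in voxel units. Fluid voxels (ventricles/sulci) are removed by
   an ADC threshold suggested from the rim histogram, then the rim is split
   by FLAIR status × overlap with the follow-up recurrence into four
   compartments: T1+/T1− × FLAIR+/FLAIR−.
3. **ROI statistics and normalization** (`pezmap.roi`). Per compartment:
   mean, SD, and the 20th-percentile-trimmed means (mean_high drops the
   lowest 20 % of voxels, mean_low the highest 20 %). Maps are compared
   across patients after an affine histogram rescaling of each case's
   within-brain 1st/99th percentiles onto the cohort-mean anchors.
4. **Group inference** (`pezmap.inference`). Paired two-sided Wilcoxon
   signed-rank tests of T1+ vs T1− compartment means within each FLAIR
   stratum, Pearson ADC–rCBV correlation, and ROC analysis with the
   rank-formulation AUC and the threshold maximizing Youden's
   J = sensitivity + specificity − 1.
5. **Phantom cohorts** (`pezmap.phantom`). Co-registered multi-contrast
   phantoms whose recurrence-prone FLAIR+ tissue carries an ≈ −8 % ADC and
   ≈ +14 % CBV contrast (null contrasts in FLAIR−), with DSC signal
   synthesized through the same signal model the reconstruction inverts.

## Worked example

```python
from pezmap import PhantomSpec, PipelineConfig, analyze_cohort
from pezmap.phantom import iter_cohort

spec = PhantomSpec.scaled((64, 64, 64))
result = analyze_cohort((c.volumes for c in iter_cohort(12, spec, seed=7)),
                        PipelineConfig())
print(result.summary[result.summary.measure == "mean"])
```

prints (see `examples/04_cohort_inference.py`):

```
FLAIR+ adc : T1+  1192.10  T1-  1351.22  diff  -11.8 %  p=0.0049
FLAIR- adc : T1+   970.19  T1-   972.77  diff   -0.3 %  p=0.7334
FLAIR+ rcbv: T1+     0.32  T1-     0.28  diff  +15.5 %  p=0.0771
FLAIR- rcbv: T1+     0.34  T1-     0.36  diff   -5.8 %  p=0.3804
ROC adc: AUC 0.73, Youden threshold 1.19e+03
ROC rcbv: AUC 0.68, Youden threshold 0.317
```

Reading: in FLAIR-hyperintense rim tissue, voxels that later recur show
lower ADC (higher cellularity) and higher rCBV (more vascularity) than
stable tissue, while FLAIR-normal rim tissue shows no detectable contrast —
the diffusion/perfusion signature the pipeline is designed to recover. ADC
is in 10⁻⁶ mm²/s; rCBV is unitless. At this small desk-scale cohort (n = 12)
p-values are noisier than at the study scale (n = 46).

The other examples walk through phantom generation, rCBV reconstruction and
rim partitioning individually. A thin CLI mirrors the library:
`pezmap simulate | rcbv | pez | analyze-case | analyze-cohort`.

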