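"""Generate one synthetic phantom case and inspect its ground truth.

The phantom emulates the study geometry: an enhancing core with necrosis, an
anisotropic FLAIR halo, a recurrence lobe contiguous with the core (about one
third of it outside the halo), fluid compartments, and vessels carrying the
strongest bolus curves.
"""

from pezmap import PhantomSpec, generate_case, mask_volume_mm3

spec = PhantomSpec.scaled((96, 96, 96))
case = generate_case(spec, seed=1)

v = case.volumes
print(f"case {v.case_id}: grid {v.adc.shape}, 1 mm isotropic")
print(f"core volume           {mask_volume_mm3(v.core_mask):8.0f} mm^3")
print(f"FLAIR-abnormal volume {mask_volume_mm3(v.flair_mask):8.0f} mm^3")
print(f"recurrence volume     {mask_volume_mm3(v.recurrence_mask):8.0f} mm^3")
print(f"fraction of recurrence outside FLAIR halo: "
      f"{case.truth.fraction_outside_flair:.3f}  (target 1/3)")

for cls in ("flairpos_recurrence", "flairpos_stable"):
    m = case.truth.class_mask(cls)
    print(f"ADC in {cls:22s}: {v.adc.data[m].mean():7.1f} x 1e-6 mm^2/s "
          f"(true class mean {case.truth.adc_class_means[cls]:.1f})")
# The recurrence-prone FLAIR+ class sits ~8 % below the stable class - the
# diffusion signature the group analysis is designed to recover.
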