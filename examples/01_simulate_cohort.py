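"""Generate a synthetic cohort: atlas, subject records, planted severities.

The cohort mimics the study design: 7 unilaterally lesioned animals with a
continuum of dopamine-depletion severities and 6 shams, with randomised
injection side.
"""

import hemipark as hp

atlas = hp.generate_atlas()
print(f"atlas: {atlas.shape} voxels at {atlas.voxel_size} mm")
print(f"regions: {len(atlas.region_names)} "
      f"({sum(1 for _ in atlas.pairs) // 2} mirrored pairs)")
left = atlas.mask("striatum_medial_L").sum()
right = atlas.mask("striatum_medial_R").sum()
print(f"medial striatum: {left} voxels left, {right} right (mirror symmetric)")

spec = hp.CohortSpec(seed=1)
for rec in hp.generate_cohort(spec):
    print(f"  {rec.subject_id:9s} {rec.group:6s} side={rec.injection_side:5s} "
          f"severity={rec.severity:.2f}")
print("severity is the planted ground truth the analysis should recover;")
print("shams are 0 (intact) and lesioned animals span mild to near-complete loss.")
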