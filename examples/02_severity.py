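"""Depletion severity from FDOPA: simulate, normalise to cerebellum, score.

severity = 1 - (ipsilesional mean / contralesional mean) over the combined
striatum + accumbens VOI.  With 5% image noise the recovered score tracks
the planted one almost perfectly.
"""

import numpy as np

import hemipark as hp

atlas = hp.generate_atlas()
cereb = atlas.mask("cerebellum")
spec = hp.CohortSpec(seed=2)

print(f"{'subject':9s} {'group':6s} {'planted':>8s} {'recovered':>10s}")
planted, recovered = [], []
for rec in hp.generate_cohort(spec):
    img = hp.simulate_fdopa(rec, atlas, spec)
    if rec.injection_side == "right":
        img = hp.flip_lateral(img)  # lesion displayed on the left
    suvr = hp.normalize_suvr(img, cereb, "cerebellum")
    score = hp.depletion_severity(suvr, atlas, subject_id=rec.subject_id)
    print(f"{rec.subject_id:9s} {rec.group:6s} {rec.severity:8.3f} {score.severity:10.3f}")
    if rec.group == "lesion":
        planted.append(rec.severity)
        recovered.append(score.severity)

r = np.corrcoef(planted, recovered)[0, 1]
print(f"\nplanted vs recovered correlation over lesioned animals: r = {r:.4f}")
print("a value near 1 means the SUVR ratio statistic recovers the ground truth.")
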