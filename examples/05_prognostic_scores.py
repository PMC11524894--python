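"""TLS and necrosis prognostic parameters for one slide.

Generates a mask with planted TLS (3% of tumor area, mixed intratumoral
and peritumoral) and necrosis (6%), extracts and qualifies the objects,
and prints the four explainable parameters.
"""

import lungquant as lq

spec = lq.SyntheticMaskSpec(
    height=1024, width=1024, tumor_fraction=0.25,
    f_tls=0.03, f_necrosis=0.06,
    tls_placement=(0.6, 0.3, 0.1),   # intratumoral : peritumoral : distant
)
mask, gt = lq.generate_mask(spec, seed=3)

objs = lq.qualify_objects(lq.extract_objects(mask, "TLS"), mask,
                          peritumoral_dist_um=250.0)
counts = {}
for o in objs:
    counts[o.qualification] = counts.get(o.qualification, 0) + 1
print("TLS objects by qualification:", counts)

scores = lq.compute_scores(mask, peritumoral_dist_um=250.0)
print(f"TLS-TD  = {scores.tls_td:.4f}   (planted 0.0300)")
print(f"NECR-TD = {scores.necr_td:.4f}   (planted 0.0600)")
print(f"T/NR    = {scores.t_nr:.3f}")
# TLS-TD counts only intratumoral + peritumoral objects; the distant ones
# (placed >300 um from tumor) are excluded, matching their planted share.
# A necrosis-free slide would report T/NR as undefined (None), not 0.
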