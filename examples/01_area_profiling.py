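"""Profile per-class areas of a synthetic slide mask.

Generates a small synthetic NSCLC mask and tallies pixels and um^2 per
tissue class.  The printed table is the substrate for everything else in
the package: subtype percentages and prognostic densities are ratios of
these areas.
"""

import lungquant as lq

spec = lq.SyntheticMaskSpec(height=512, width=512, tumor_fraction=0.3,
                            f_tls=0.03, f_necrosis=0.05, back_margin_px=6)
mask, _ = lq.generate_mask(spec, seed=7)
profile = lq.profile_areas(mask)

print(f"{'class':<14}{'pixels':>10}{'area (um^2)':>14}")
for name, px in profile.pixel_counts.items():
    if px:
        print(f"{name:<14}{px:>10}{profile.area_um2[name]:>14.0f}")
print(f"\ntotal pixels: {profile.total_pixels} "
      f"(= {mask.shape[0]}x{mask.shape[1]} canvas, mpp {mask.mpp})")
# Each row is exact: pixel count times mpp^2.  TUMOR + TU_STROMA is the
# denominator used later by the prognostic densities.
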