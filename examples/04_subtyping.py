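"""LUAD-vs-LUSC subtyping from area percentages.

Pairs a main tissue mask with a subtype mask carrying a planted 58%
LUAD share, classifies the slide, and pools two slides into a case
call.  A winning percentage inside the closed 40-60% band is flagged
borderline (would go to immunohistochemistry review).
"""

import lungquant as lq

spec = lq.SyntheticMaskSpec(height=512, width=512, tumor_fraction=0.3,
                            back_margin_px=6)
main, _ = lq.generate_mask(spec, seed=4)
sub = lq.generate_subtype_mask(main, pct_luad=58.0, seed=0)

call = lq.classify_slide(main, sub)
print(f"slide call: {call.call}  (LUAD {call.pct_luad:.1f}% / "
      f"LUSC {call.pct_lusc:.1f}%)  borderline={call.borderline}")
print(f"mucin fraction: {call.mucin_pct:.2f}%")

# a second slide of the same case with a clearer LUAD picture
main2, _ = lq.generate_mask(spec, seed=5)
sub2 = lq.generate_subtype_mask(main2, pct_luad=85.0, seed=1)
call2 = lq.classify_slide(main2, sub2)
case = lq.aggregate_case([call, call2])
print(f"\nsecond slide: {call2.call} (LUAD {call2.pct_luad:.1f}%)")
print(f"case call (pooled pixel counts): {case.call} "
      f"(LUAD {case.pct_luad:.1f}%), borderline={case.borderline}")
# Case pooling is area-weighted: the slide with more evaluated tumor
# pixels dominates, so splitting one tumor across blocks cannot flip the
# case call.
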