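"""Medial-lateral composition of the subicular complex along the body.

On body slices selected at 10%..50% of total length posterior to the uncal
apex, the subicular cortex (SUB -> PrS -> PaS) is traced along its
mid-cortical centerline and each region's share of the centerline length is
reported. When the PaS has disappeared, the PrS absorbs its share.
"""

import hippomorph as hm

volume, landmarks, _, truth = hm.generate(hm.PhantomSpec())

print("position  pct_SUB  pct_PrS  pct_PaS   (centerline length)")
for rec in hm.subicular_profile(volume, landmarks):
    pas = f"{rec.pct['PaS']:7.1f}" if "PaS" in rec.pct else "      -"
    prs = f"{rec.pct['PrS']:7.1f}" if "PrS" in rec.pct else "      -"
    print(f"  {rec.position_pct:3.0f}%   {rec.pct['SUB']:7.1f}  {prs}  {pas}"
          f"   ({rec.total_length_mm:.1f} mm)")

print("\nThe percentages of present regions sum to 100; the generator drew the")
print("strip with fractions", tuple(round(f, 2) for f in hm.PhantomSpec().strip_fractions),
      "(SUB, PrS, PaS).")
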