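"""Flashlight projection of CA subfields onto the SRLM band.

Every SRLM voxel lateral to the most medial DG point is assigned to its
nearest CA subfield; the per-subfield voxel share expresses subfield size as
a proportion of the visible dark band. The proportions sum to one except
when the SUB-CA1 border lies lateral to the medial DG point, in which case
the stretch of band medial to the border midpoint stays unassigned.
"""

import hippomorph as hm

spec = hm.PhantomSpec(srlm_arc="ribbon", digitation_count=0)
volume, landmarks, _, truth = hm.generate(spec)

print("position  prop_CA1  prop_CA2  prop_CA3   n_voxels  sum")
for res in hm.srlm_profile(volume, landmarks):
    s = sum(res.prop.values())
    print(f"  {res.position_pct:3.0f}%    {res.prop['CA1']:8.3f}  {res.prop['CA2']:8.3f}"
          f"  {res.prop['CA3']:8.3f}   {res.n_srlm_total:8d}  {s:.3f}")

spans = spec.ca_spans_deg
total = sum(spans)
print("\nangular truth:", tuple(round(s / total, 3) for s in spans), "(CA1, CA2, CA3)")
print("\nA worked conversion: with the SUB-CA1 border at 33% and the CA1-CA2")
print("border at 80% of the curved SRLM length, CA1 occupies",
      hm.curved_length_occupancy(33.0, 80.0), "% of the band.")
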