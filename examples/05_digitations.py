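"""Digitation count and the location of anterior CA3.

Digitations are bumps of the superior surface of the hippocampal head. On
the first slice where CA3 reaches the superior CA strip, the surface height
profile is scanned for prominent peaks, and CA3 is classified relative to
the peaks (on-top / in-between / both) and to the medial-lateral thirds of
the hippocampal footprint.
"""

import hippomorph as hm

spec = hm.PhantomSpec(digitation_count=3)
volume, landmarks, coverage, truth = hm.generate(spec)

z = hm.anterior_ca3_slice(volume, coverage)
profile = hm.digitation_profile(hm.footprint_mask(volume, z), z=z)
record = hm.classify_ca3(profile, hm.ca3_superior_strip(volume, z))

print(f"anterior CA3 slice: {z} (construction truth {truth.anterior_ca3_z})")
print(f"digitations: {profile.n_digitations} (drawn with {truth.digitation_count}),"
      f" peak columns {profile.peak_xs.tolist()}")
print(f"CA3 relation to digitations: {record.relation}"
      f" ({record.on_peak_fraction:.0%} of its columns near a peak)")
print(f"CA3 medial-lateral position: {record.position}"
      f" (bulk centroid at column {record.centroid_x:.0f})")
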