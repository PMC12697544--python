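"""Relative SUB-CA1 border position at 0 mm and 20 mm past the uncal apex.

The border position is the distance from the medial anchor (vertical drop
from the most medial CA3/DG voxel onto the SUB/CA1 cortex) to the border
midpoint line, as a percentage of the full hippocampal width and of the DG
width. The generator ramps the border medially along the long axis, so the
20 mm value is smaller - the medial shift real specimens show.
"""

import numpy as np

import hippomorph as hm

rng = np.random.default_rng(12)
spec = hm.random_spec(rng, mode="border")
volume, landmarks, _, truth = hm.generate(spec)

for off, m in hm.measure_at_offsets(volume, landmarks).items():
    t = truth.border[m.z]
    print(f"{off:4.0f} mm (slice {m.z}):"
          f"  {m.pct_of_full_width:6.1f}% of full width,"
          f"  {m.pct_of_dg_width:6.1f}% of DG width"
          f"   [truth {t['rel_full_pct']:.1f}%]")

print("\nNegative values would mean the border lies medial to the anchor point.")
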