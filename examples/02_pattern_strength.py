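"""Similarity versus intensity: target-related pattern strength.

Correlation-based similarity ignores amplitude: engaging *more strongly* in
the same emotion scales the voxel pattern without changing its correlation
to the target.  Pattern strength — the projection of the current-state (CMS)
vector onto the target-state (TMS) vector, relative to the TMS length —
captures exactly that missing intensity axis.
"""

import numpy as np

from semnf import make_anchors, pattern_strength

anchors, _ = make_anchors(n_cond=4, voxel_count=500, seed=42)
tms = anchors.pattern("happy")

rng = np.random.default_rng(0)
cms = anchors.patterns[0] + 0.4 * rng.standard_normal(500)

for k in (1.0, 2.0):
    res = pattern_strength(k * cms, tms)
    print(f"CMS scaled by {k:.0f}: similarity r = {res.similarity:.3f}, "
          f"theta = {np.degrees(res.angle_theta):.1f} deg, "
          f"strength = {res.strength:.3f}")
print("-> doubling engagement leaves r and theta unchanged and doubles the "
      "strength: the display can show both.")
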