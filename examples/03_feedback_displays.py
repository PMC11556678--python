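"""The two feedback display geometries for one moment in time.

Map variant: the CMS is a point on the semantic map whose marker size
encodes pattern strength.  Circular variant: one thermometer per emotion on
a circle; only the target's thermometer fills, and a central arrow points
between the target and its most similar neighbour according to
dist = 1 - target_r / (target_r + neighbour_r).
"""

import numpy as np

from semnf import (build_rdm, circular_frame, circular_layout, embed_rdm,
                   make_anchors, map_frame, pattern_strength, project_pattern,
                   select_target)
from semnf.feedback import similarities_to_anchors

anchors, _ = make_anchors(n_cond=4, voxel_count=500, seed=42)
smap = embed_rdm(build_rdm(anchors), dims=2)

# a participant mostly in 'happy', leaning toward 'content'
rng = np.random.default_rng(1)
cms = 1.2 * anchors.patterns[0] + 0.5 * anchors.patterns[1] \
    + 0.3 * rng.standard_normal(500)

target = select_target(cms, anchors)
intensity = pattern_strength(cms, anchors.pattern(target))
coords = project_pattern(smap, anchors, cms)

frame_a = map_frame(smap, coords, intensity)
print(f"map display: CMS at ({coords[0]:+.3f}, {coords[1]:+.3f}), "
      f"target {target!r}, marker size {frame_a.marker_size:.1f} "
      f"(strength {intensity.strength:.2f})")

layout = circular_layout(anchors, rdm=build_rdm(anchors), mode="dissimilarity")
sims = similarities_to_anchors(cms, anchors)
frame_b = circular_frame({lab: sims[i] for i, lab in enumerate(anchors.labels)},
                         intensity, layout, cms_coords=tuple(coords))
print("circular display:")
for lab, fill in zip(frame_b.thermometer_labels, frame_b.thermometer_fills):
    deg = np.degrees(layout[lab])
    print(f"  {lab:>8s} at {deg:6.1f} deg: fill {fill:.2f}")
print(f"  arrow at {np.degrees(frame_b.arrow_angle):.1f} deg "
      f"(dist = {frame_b.dist:.2f}; 0 = at target, 0.5 = halfway to neighbour)")
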