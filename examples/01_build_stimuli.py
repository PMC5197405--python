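"""Build the eight factorial display variants of an annotated scene.

A synthetic textured scene stands in for a photograph; the annotated
contour point defines the CRF center, radius and the two region masks.
"""

import numpy as np

from borderown import simulate as sim
from borderown import stimuli as st

fx = sim.generate_scene_fixture(seed=7, size=65, object_shape="disc")
m1, m2 = st.region_means(fx.image, fx.point)
bg = st.background_color(fx.image, fx.point)
print(f"object-side region mean  : {np.round(m1, 3)}")
print(f"background-side mean     : {np.round(m2, 3)}")
print(f"display background BG(s) : {np.round(bg, 3)}  (midpoint of the means)")

variants = st.build_variant_set(fx.image, fx.point, k=1.8, scene_id=fx.scene_id)
print(f"\n{len(variants)} variants (side x contrast polarity x extent):")
for v in variants:
    print(f"  {v.key.side:8s} {v.key.polarity:8s} {v.key.extent:5s}"
          f"  clipped px: {v.n_clipped}")

# the local stimulus is identical between full and patch variants
d = st._distance_grid(fx.image.shape[:2], fx.point.center)
inside = d < fx.point.radius_px
full = variants[0].image
patch = variants[1].image
print(f"\nmax |full - patch| inside the CRF radius: "
      f"{np.abs(full[inside] - patch[inside]).max():.2e} (identical by design)")
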