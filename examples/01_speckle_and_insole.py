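"""Generate a speckle texture and a contoured insole surface.

Builds the speckle pattern from its statistical spec (target coverage,
dot diameter, diameter variation), measures the realised coverage, and
constructs a foot-shaped insole surface with a 12 mm arch.
"""

import numpy as np

from stamps3d import SpeckleSpec, coverage_fraction, make_insole_surface, make_speckle_texture

spec = SpeckleSpec(dot_density=0.65, dot_diameter_mm=0.8,
                   diameter_variation=0.75, mm_per_px=0.18, seed=1)
texture = make_speckle_texture(spec, (512, 512))
print(f"speckle: target coverage {spec.dot_density:.2f}, "
      f"measured {coverage_fraction(texture):.3f}")
# the measured covered-area fraction should sit within a few percent of the
# spec; it is what makes subsets uniquely matchable in DIC

surface = make_insole_surface(length_mm=260, width_mm=95, contoured=True,
                              arch_height_mm=12.0, side="right")
z = surface.grid_points[:, 2]
print(f"insole: {len(surface.grid_points)} surface grid points, "
      f"outline area {surface.outline.area:.0f} mm^2, "
      f"arch peak {z.max():.1f} mm")
# the arch bulge sits on the medial side; max height equals the requested
# arch_height_mm within the grid resolution
medial = surface.grid_points[:, 1] > 0
print(f"mean height medial {z[medial].mean():.2f} mm "
      f"vs lateral {z[~medial].mean():.2f} mm")
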