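"""Per-slice water-equivalent area and diameter of a phantom, plus a mesh.

D_w per axial slice is the diameter of a water cylinder with the same total
attenuation as that slice — the standard patient-size input for tube-current
dose modulation and size-specific dose estimates (SSDE). For the default
phantom (elliptical soft-tissue body with air-filled lungs) D_w is well below
the geometric body width because the lungs attenuate almost nothing.
"""

import numpy as np

from surview3d import ThoraxPhantomSpec, body_mask, generate_phantom, water_equivalent_profile
from surview3d.evaluation import export_aw_mesh

phantom = generate_phantom(ThoraxPhantomSpec(seed=0))
mask = body_mask(phantom.volume)
profile = water_equivalent_profile(phantom.volume, mask)

mid = len(profile.d_w) // 2
print(f"slices: {len(profile.d_w)}, pixel area {profile.a_pixel:.1f} mm^2")
print(f"central slice: A_w = {profile.a_w[mid]:.0f} mm^2, D_w = {profile.d_w[mid]:.1f} mm")
print(f"D_w along patient axis: min {profile.d_w.min():.1f} mm, max {profile.d_w.max():.1f} mm")

mesh = export_aw_mesh(profile, "aw_mesh.obj")
print(f"wrote aw_mesh.obj; mesh volume {abs(mesh.volume)/1e6:.2f} L "
      f"vs profile integral {profile.a_w.sum()*profile.slice_thickness_mm/1e6:.2f} L")
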