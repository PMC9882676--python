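"""Ray-trace coronal and sagittal topograms of a synthetic thoracic phantom.

Builds a seeded 64^3 thorax phantom (4 mm voxels), places the default
cone-beam geometry (600 mm source-isocenter, 1100 mm source-detector), and
synthesizes one topogram per view. The printed line-integral range is the
dimensionless -ln(I/I0) image: 0 where rays miss the patient, larger values
where rays cross more attenuating tissue (spine, full body width).
"""

from surview3d import ThoraxPhantomSpec, build_geometry, generate_phantom, synthesize_topogram

phantom = generate_phantom(ThoraxPhantomSpec(seed=0))
print(f"phantom: {phantom.volume.shape} voxels, {phantom.volume.spacing} mm spacing")

for view in ("coronal", "sagittal"):
    geometry = build_geometry(view, phantom.volume, {"detector_pixels": (128, 128)})
    topo = synthesize_topogram(phantom.volume, geometry)
    li = topo.line_integral
    print(
        f"{view:8s} topogram {li.shape}: line integral range "
        f"[{li.min():.3f}, {li.max():.3f}], mean transmitted fraction "
        f"{topo.intensity.mean() / geometry.i0:.3f}"
    )
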