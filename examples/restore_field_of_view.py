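"""Recover field-of-view lost to field curvature by multifocus fusion.

A ball lens focuses a sphere, not a plane: only a ring of the flat sample
intersecting the focal sphere is sharp in any one frame.  Two frames taken
2 um apart put different rings in focus; fusing them in the wavelet domain
(each coefficient from the frame with the larger local sum-modified
Laplacian) yields one image sharp from the centre out to the second ring.
"""

from pocketscope import restore, synth

scene = synth.make_texture(seed=42)
stack = synth.apply_aberrations(scene, synth.AberrationSpec(),
                                focal_offsets_um=(0.0, 2.0))
fused, decision = restore.fuse_multifocus(
    restore.ImageStack(stack.frames, stack.focal_offsets_um)
)

sides = [restore.usable_fov(f, pixel_size_um=0.5) for f in stack.frames]
fused_fov = restore.usable_fov(fused, pixel_size_um=0.5)

for off, s in zip(stack.focal_offsets_um, sides):
    print(f"frame at {off:+.0f} um offset: usable square {s['side_um']:.0f} um")
print(f"fused image            : usable square {fused_fov['side_um']:.0f} um")
best = max(s["side_px"] for s in sides)
print(f"usable-area gain       : {(fused_fov['side_px'] / best) ** 2:.2f} x")
print()
print("The usable square is the largest centred region whose block-wise")
print("sharpness stays above half the peak; fusion roughly doubles its area.")
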