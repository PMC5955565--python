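"""Mask actin bands and segment individual sarcomeres.

The ratio-to-smoothed mask keeps locally actin-rich pixels (Z-disc-centred
bands) and discards the dim M-lines; connected components are then filtered
by area, convexity and ellipse axis ratio to yield one object per sarcomere.
"""

from actinorder import (
    AcquisitionConfig,
    compute_actin_mask,
    compute_modulation_coefficients,
    criteria_for_stage,
    forward_simulate,
    make_preset_scene,
    segment_sarcomeres,
    segmentation_scores,
    select_central,
)

scene = make_preset_scene("48h", shape=(256, 256), seed=0)
stack = forward_simulate(scene, AcquisitionConfig(noise="poisson", seed=1))
coeffs = compute_modulation_coefficients(stack)

mask = compute_actin_mask(coeffs.a0, smoothing_scale=2.0, threshold=1.0,
                          pixel_size=stack.pixel_size)
objects = segment_sarcomeres(mask, criteria_for_stage("48h"), pixel_size=stack.pixel_size)
accepted = [o for o in objects if o.accepted]
recall, precision = segmentation_scores(accepted, scene)

px = stack.pixel_size / 1000.0
center = ((256 - 1) / 2 * px, (256 - 1) / 2 * px)
central = select_central(objects, 20, center)

print(f"mask keeps {mask.mask.mean() * 100:.1f}% of pixels")
print(f"{len(accepted)}/{len(objects)} components accepted as sarcomeres")
print(f"recall {recall:.3f}, precision {precision:.3f} vs generator ground truth")
print(f"20 most central: max distance {max(o.distance_to_center for o in central):.2f} um")
# recall/precision near 1 mean the geometric criteria isolate exactly the
# Z-disc-centred actin bands of the synthetic lattice.
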