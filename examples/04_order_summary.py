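"""Hierarchical order summary, DeltaPsi against the mature reference, local
rho variability, and a nonparametric group comparison.

Two synthetic populations are imaged: early myotubes (psi* = 163 deg, loose
actin meshwork) and mature muscle (psi* = 129 deg).  Masked-mean psi is
aggregated image -> hemithorax -> population and reported as
DeltaPsi = Psi - 129; the expected population difference is ~34 deg.
"""

import numpy as np

from actinorder import (
    AcquisitionConfig,
    SarcomereLatticeParams,
    compare_groups,
    compute_actin_mask,
    compute_modulation_coefficients,
    forward_simulate,
    invert_cone_model,
    make_sarcomere_scene,
    rho_variability,
    summarize_order,
)
from actinorder.synthetic import constant_psi


def image_population(psi_star, seed0, n_hemi=3, n_img=2):
    images, labels = [], []
    for h in range(n_hemi):
        for i in range(n_img):
            lat = SarcomereLatticeParams(
                period=3.0, mline_dip=0.0, zdisc_boost=0.0, n_fibrils=34,
                fibril_spacing=0.9, fibril_width=0.55,
                psi_band_profile=constant_psi(psi_star),
            )
            scene = make_sarcomere_scene(lat, shape=(192, 192))
            stack = forward_simulate(
                scene, AcquisitionConfig(noise="poisson", seed=seed0 + 10 * h + i)
            )
            coeffs = compute_modulation_coefficients(stack)
            order = invert_cone_model(coeffs)
            order.pixel_size = stack.pixel_size
            mask = compute_actin_mask(coeffs.a0, pixel_size=stack.pixel_size)
            images.append((order, mask))
            labels.append(f"h{h}")
    return images, labels


early_images, early_labels = image_population(163.0, seed0=100)
mature_images, mature_labels = image_population(129.0, seed0=200)

early = summarize_order(early_images, early_labels, psi_ref=129.0)
mature = summarize_order(mature_images, mature_labels, psi_ref=129.0)

print("early myotube population:  Psi = "
      f"{early.population_mean:.2f} deg, DeltaPsi = {early.delta_psi:+.2f} deg")
print("mature muscle population:  Psi = "
      f"{mature.population_mean:.2f} deg, DeltaPsi = {mature.delta_psi:+.2f} deg")
print(f"population difference:     {early.population_mean - mature.population_mean:.2f} deg"
      "  (expected ~34)")

rv = rho_variability(*mature_images[0], window=65)
print(f"local rho variability (65x65 window): {rv.per_image_mean:.2f} deg "
      "(shot-noise floor on a perfectly parallel lattice)")

report = compare_groups(
    {
        "early": early.per_hemithorax["psi"].tolist(),
        "mature": mature.per_hemithorax["psi"].tolist(),
    }
)
print(f"Mann-Whitney U = {report['statistic']:.0f}, two-sided p = {report['p_value']:.3f}, "
      f"n = {report['n']}")
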