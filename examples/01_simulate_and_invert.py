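"""Simulate a polarization stack and invert it to (rho, psi) maps.

Builds a mature-stage (90 h APF) sarcomere lattice with known per-pixel
ground truth, simulates the 10-angle polarized acquisition with Poisson
noise, and recovers the per-pixel mean dipole orientation rho and molecular
order angle psi by harmonic decomposition + cone-model inversion.
"""

import numpy as np

from actinorder import (
    AcquisitionConfig,
    compute_modulation_coefficients,
    forward_simulate,
    invert_cone_model,
    make_preset_scene,
)

scene = make_preset_scene("90h", shape=(192, 192), seed=0)
stack = forward_simulate(scene, AcquisitionConfig(noise="poisson", photon_budget=1e4, seed=1))
coeffs = compute_modulation_coefficients(stack)
order = invert_cone_model(coeffs)

on = scene.fibril_mask & order.valid
print(f"stack: {stack.n_angles} angles x {stack.shape} px, {stack.pixel_size:.0f} nm/px")
print(f"ground-truth psi* on fibrils: {scene.psi_true[on].mean():.2f} deg")
print(f"recovered psi on fibrils:     {order.psi[on].mean():.2f} +/- {order.psi[on].std():.2f} deg")
drho = (order.rho[on] - scene.rho_true[on] + 90) % 180 - 90
print(f"rho error on fibrils:         {drho.mean():+.3f} +/- {drho.std():.3f} deg")
# psi ~ 128-129 deg is the mature-muscle order angle: tight dipole alignment
# limited by probe wobble; the +/- spread is shot-noise at this photon budget.
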