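"""Render a brightfield core and unmix it back into stain channels.

Shows the Beer-Lambert forward model and the non-negative group-sparse
inversion: at zero noise and zero sparsity weight the recovered
concentrations equal the generator's ground truth almost exactly.
"""

import numpy as np

from periscore import (SimulationConfig, StainBasis, UnmixConfig,
                       render_brightfield, simulate_core,
                       stain_concentration_maps, unmix_core)

config = SimulationConfig(seed=3, core_diameter=600.0, pixel_size=1.0,
                          regions=("CT",))
scene = simulate_core(config, "P001", "CT")
basis = StainBasis()
img = render_brightfield(scene, basis, noise_sd=0.0)
print(f"rendered RGB core: {img.shape}, intensities "
      f"{img.min():.0f}..{img.max():.0f}")

# exact inversion (no sparsity, no background floor)
channels, resid = unmix_core(
    img, basis, UnmixConfig(lam=0.0, od_floor=0.0, tol=1e-10, max_iter=5000))
truth = stain_concentration_maps(scene)
err = np.abs(channels - truth).max() / truth.max()
print(f"max relative concentration error vs ground truth: {err:.2e}")

# production settings: lambda = 0.1 sparsifies the per-pixel stain support
sparse, _ = unmix_core(img, basis, UnmixConfig(lam=0.1))
for lam, ch in (("0.0", channels), ("0.1", sparse)):
    active = (ch > 1e-8).sum(axis=-1).mean()
    print(f"lambda={lam}: mean active stains per pixel {active:.3f}")
print(f"reconstruction residual (rms OD): {resid:.2e}")
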