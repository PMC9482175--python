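"""Simulate a small synthetic TMA cohort and look at its ground truth.

Builds 8 patients with tumour-centre cores, prints the realised stromal
cell counts and the latent prognostic groups that drive both the spatial
enrichment and the survival times.
"""

import numpy as np

from periscore import SimulationConfig, simulate_cohort

config = SimulationConfig(
    seed=1, n_patients=8, cores_per_patient=1, core_diameter=600.0,
    pixel_size=2.0, regions=("CT",),
    proximity_enrichment={"CD8": 3.0, "GZMB": 3.0},
    hazard_ratio_high_vs_low=0.25)

scenes, clinical, survival = simulate_cohort(config, panels=(1,))

print(f"{len(scenes)} cores, {len(clinical)} patients")
print(clinical[["patient_id", "tnm_stage", "pT", "density_group_true"]])
for scene in scenes[:4]:
    n_stromal = sum(1 for c in scene.cells if c.compartment == "stroma")
    n_cd8 = sum(1 for c in scene.cells if c.phenotype == "CD8")
    area = scene.stroma_mask.sum() * scene.pixel_size ** 2 / 1e6
    print(f"{scene.core_id}: {n_stromal} stromal cells "
          f"({n_cd8} CD8+, {n_cd8 / area:.0f}/mm^2 stroma)")
events = sum(r.event for r in survival)
print(f"survival: {events} events, median time "
      f"{np.median([r.time for r in survival]):.1f} months")
# High-group patients carry 3x CD8/GZMB density near the tumour and a
# 0.25 hazard ratio; the printed counts show the density contrast.
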