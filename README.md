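# periscore

Peritumoral immune-cell density scoring for multiplex brightfield IHC
tissue microarrays.

## The problem

In colorectal cancer, the density of cytotoxic T cells (CD8), their
effector state (granzyme B, GZMB) and macrophage populations (CD68,
CD163) in the stroma immediately around tumour cell areas carries
prognostic information. Quantifying it from brightfield triple stains
requires a chain of non-trivial steps: unmixing overlapping chromogens
into stain concentrations, segmenting tumour from stroma, detecting and
typing cells, measuring densities inside tumour-proximity (TP) zones —
the stroma within 10/25/50/100 µm of tumour — pooling cores per patient,
dichotomising at cohort medians, and running the association and
survival statistics. `periscore` implements that chain as a tested
Python library for analysts working on TMA-based immune-contexture
studies, together with a synthetic cohort generator so every stage can
be validated against known ground truth.

## The model in brief

* **Unmixing.** Beer–Lambert optical densities `od = D a` with four
  unit-norm stain vectors; per pixel solve
  `min_{a≥0} ½‖od − Da‖² + λ Σ_g ‖a_g‖` with one stain per group
  (λ = 0.1), i.e. a non-negative sparse decomposition, by coordinate
  descent. At λ = 0 it equals non-negative least squares.
* **Zones.** Exact Euclidean distance transform from the tumour mask;
  TP zone r = stromal pixels with distance in (0, r]; densities are
  stromal cell counts per zone area; patient values are area-weighted
  means over QC-passing cores (>10 stromal cells, >1% tumour area).
* **Scores.** *High* = density strictly above the cohort median;
  combined GZMB/CD68 is *high* iff both markers are *high*.
* **Statistics.** χ² with Yates correction (2×2) or exact Fisher when
  expected counts < 5; log(x+1) density transforms; Kaplan–Meier,
  log-rank, and a Newton–Raphson Cox model with Efron tie handling.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

Segment a rendered core and read CD8 density along the zone ladder
(`examples/03_segment_and_zones.py`):

```python
from periscore import (SimulationConfig, ThresholdSet, UnmixConfig, ZoneSpec,
                       apply_core_qc, quantify_core, render_brightfield,
                       segment_core, simulate_core, unmix_core)
from periscore.types import CoreScene

config = SimulationConfig(seed=9, core_diameter=600.0, pixel_size=1.0,
                          regions=("CT",), proximity_enrichment={"CD8": 3.0})
scene = simulate_core(config, "P001", "CT")
img = render_brightfield(scene, noise_sd=0.0)
channels, _ = unmix_core(img, config=UnmixConfig())
tissue, tumour, stroma, cells = segment_core(channels, ThresholdSet(),
                                             panel=1, pixel_size=1.0)
seg = CoreScene("P001", scene.core_id, "CT", 1, 1.0,
                tissue, tumour, stroma, cells)
for z in quantify_core(seg, ZoneSpec(), markers=("CD8",)):
    print(z.radius, z.cell_count, round(z.density_per_mm2, 1))
```

prints

```
detected 476 cells (374 stromal), tumour fraction 0.30, core included: True
TP10.0:   18 CD8+ cells on 0.0188 mm^2 ->    959.3 /mm^2
TP25.0:   44 CD8+ cells on 0.0469 mm^2 ->    938.6 /mm^2
TP50.0:   55 CD8+ cells on 0.0918 mm^2 ->    598.9 /mm^2
TP100.0:   85 CD8+ cells on 0.1619 mm^2 ->    525.1 /mm^2
TPtotal:   99 CD8+ cells on 0.1984 mm^2 ->    498.9 /mm^2
```

The core was generated with a 3× CD8 enrichment within 25 µm of the
tumour: the near-tumour zones show roughly twice the total-stroma
density, which is exactly the spatial signal the patient-level score is
built on. The other examples cover cohort simulation (`01`), unmixing
and its exactness (`02`), scoring plus Kaplan–Meier/log-rank/Cox on a
cohort with a known hazard ratio of 0.25 (`04` — the fitted HR comes out
at 0.256 [0.165, 0.398]), and the clinicopathological association
battery with the χ²/Fisher selection rule (`05`).

A thin CLI mirrors the stages:

```bash
periscore simulate --seed 1 --out cohort/
periscore unmix --in cohort/P001-CT-0-p1.png --lambda 0.1 --out P001.tiff
periscore run-all --seed 1 --out artifacts/
```

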