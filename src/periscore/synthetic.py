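"""Synthetic multiplex-IHC TMA cohort generator.

Produces circular TMA-core scenes with known ground truth — tissue,
tumour and stroma masks, cell positions and phenotypes — together with
brightfield renderings and patient-level clinical/survival tables.  Every
downstream stage (unmixing, segmentation, zone quantification, scoring,
statistics) can thereby be exercised end-to-end with a known answer.

The model, briefly:

* a core is a disc of configurable diameter (600 or 1000 um) rasterised
  at ``pixel_size`` um/pixel;
* the tumour compartment is a thresholded smooth Gaussian random field
  occupying ~``tumour_fraction`` of the tissue in tumour-centre and
  tumour-front cores, half of that in microenvironment cores and nothing
  in normal-epithelium cores (where a PanCK+ normal epithelium of the
  same construction takes its geometric place);
* stromal cells follow an inhomogeneous Poisson process whose intensity
  is ``base_densities[marker]``, multiplied by ``proximity_enrichment``
  within 25 um of the tumour;
* survival times are exponential with hazard
  ``baseline_hazard * hazard_ratio**1{latent group high}``; the latent
  group also switches proximity enrichment on or off, so the spatial and
  survival signals are linked as in a prognostic-biomarker study.

Determinism: a fixed (seed, config) pair yields byte-identical scenes,
images and tables; per-core seeds are derived from the global seed and
the core's identifiers via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import SimulationConfig
from .types import PANEL_CHROMOGEN, PANEL_MARKERS, Cell, CoreScene, SurvivalRecord
from .unmixing import StainBasis

#: Ground-truth stain concentration painted at a nucleus / chromogen disc.
NUCLEUS_CONC = 1.0
MARKER_CONC = 0.8
PANCK_CONC = 0.7
#: faint diffuse haematoxylin over all tissue (cytoplasm / matrix
#: background); high enough to survive the sparsity shrinkage of the
#: unmixer at its default lambda, well below the nucleus threshold
TISSUE_BG_CONC = 0.3
NUCLEUS_RADIUS_UM = 4.0
MARKER_RADIUS_UM = 5.0

# Marginal frequencies of the clinical covariates (stage I-IV cohort).
TNM_PROBS = {1: 0.175, 2: 0.392, 3: 0.237, 4: 0.196}
PT_PROBS = {3: 0.838, 4: 0.162}
VENOUS_P = 0.133
CHEMO_P = 0.5


def _subseed(seed: int, *parts: object) -> np.random.Generator:
    """Deterministic per-entity generator derived from the global seed."""
    tokens = [zlib.crc32(str(p).encode()) for p in parts]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *tokens]))


def _disc_mask(n: int) -> np.ndarray:
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    return (xx - c) ** 2 + (yy - c) ** 2 <= (n / 2.0) ** 2


def _blob_mask(rng: np.random.Generator, tissue: np.ndarray, fraction: float,
               pixel_size: float) -> np.ndarray:
    """Union of random smooth blobs covering ~fraction of the tissue disc."""
    if fraction <= 0:
        return np.zeros_like(tissue)
    sigma_px = max(50.0 / pixel_size, 2.0)
    g = ndimage.gaussian_filter(rng.standard_normal(tissue.shape), sigma_px)
    cut = np.quantile(g[tissue], 1.0 - fraction)
    return (g > cut) & tissue


def tumour_fraction_for_region(config: SimulationConfig, region: str) -> float:
    if region in ("CT", "FR"):
        return config.tumour_fraction
    if region == "ME":  # stroma-rich invasive margin
        return 0.5 * config.tumour_fraction
    return 0.0  # NE


def simulate_core(
    config: SimulationConfig,
    patient_id: str,
    region: str,
    core_index: int = 0,
    panel: int | None = None,
    enriched: bool | None = None,
) -> CoreScene:
    """Simulate one TMA core scene with ground-truth masks and cells.

    ``enriched`` switches the 25-um proximity enrichment on; by default it
    is on whenever ``config.proximity_enrichment`` is non-empty.  The mask
    geometry is seeded by (patient, region, core) only, so the two staining
    panels of the same core share geometry like sequential tissue cuts.
    """
    config.validate()
    panel = config.panel if panel is None else panel
    if panel not in PANEL_MARKERS:
        raise ValueError(f"unknown staining panel {panel!r}")
    if region not in config.regions:
        raise ValueError(f"region {region!r} not in configured regions")
    if enriched is None:
        enriched = bool(config.proximity_enrichment)

    n = int(round(config.core_diameter / config.pixel_size))
    tissue = _disc_mask(n)

    geom_rng = _subseed(config.seed, "geometry", patient_id, region, core_index)
    frac = tumour_fraction_for_region(config, region)
    epithelium = None
    if region == "NE":
        tumour = np.zeros_like(tissue)
        epithelium = _blob_mask(geom_rng, tissue, config.tumour_fraction, config.pixel_size)
        occupied = epithelium
    else:
        tumour = _blob_mask(geom_rng, tissue, frac, config.pixel_size)
        occupied = tumour
    stroma = tissue & ~occupied

    # distance (um) from stroma pixels to the proximity source
    if occupied.any():
        dist = ndimage.distance_transform_edt(~occupied) * config.pixel_size
    else:
        dist = np.full(tissue.shape, np.inf)

    near = stroma & (dist <= config.enrichment_radius)
    far = stroma & ~near
    px_area_mm2 = (config.pixel_size ** 2) / 1e6

    cells: list[Cell] = []
    cell_rng = _subseed(config.seed, "cells", patient_id, region, core_index, panel)
    markers = PANEL_MARKERS[panel] + ("double_negative",)
    for marker in markers:
        rate = config.base_densities.get(marker, 0.0)
        if rate <= 0:
            continue
        factor = config.proximity_enrichment.get(marker, 1.0) if enriched else 1.0
        for stratum, lam_factor in ((near, factor), (far, 1.0)):
            idx = np.flatnonzero(stratum)
            if idx.size == 0:
                continue
            area = idx.size * px_area_mm2
            count = cell_rng.poisson(rate * lam_factor * area)
            if count == 0:
                continue
            pick = cell_rng.choice(idx, size=count)
            rows, cols = np.unravel_index(pick, stratum.shape)
            jit = cell_rng.uniform(0.0, 1.0, size=(count, 2))
            xs = (cols + jit[:, 0]) * config.pixel_size
            ys = (rows + jit[:, 1]) * config.pixel_size
            for x, y in zip(xs, ys):
                cells.append(Cell(
                    x=float(x), y=float(y), compartment="stroma", phenotype=marker,
                    channel_intensities={"haematoxylin": NUCLEUS_CONC}
                    | ({} if marker == "double_negative"
                       else {PANEL_CHROMOGEN[panel][marker]: MARKER_CONC}),
                ))

    if tumour.any() and config.tumour_cell_density > 0:
        idx = np.flatnonzero(tumour)
        count = cell_rng.poisson(config.tumour_cell_density * idx.size * px_area_mm2)
        if count:
            pick = cell_rng.choice(idx, size=count)
            rows, cols = np.unravel_index(pick, tumour.shape)
            jit = cell_rng.uniform(0.0, 1.0, size=(count, 2))
            for c, r, (jx, jy) in zip(cols, rows, jit):
                cells.append(Cell(
                    x=float((c + jx) * config.pixel_size),
                    y=float((r + jy) * config.pixel_size),
                    compartment="tumour", phenotype="tumour",
                    channel_intensities={"haematoxylin": NUCLEUS_CONC},
                ))

    scene = CoreScene(
        patient_id=patient_id,
        core_id=f"{patient_id}-{region}-{core_index}",
        region=region, panel=panel, pixel_size=config.pixel_size,
        tissue_mask=tissue, tumour_mask=tumour, stroma_mask=stroma,
        cells=cells, epithelium_mask=epithelium,
    )
    scene.validate()
    return scene


def _stamp(channel: np.ndarray, x_um: float, y_um: float, amplitude: float,
           kernel: np.ndarray, pixel_size: float) -> None:
    """Add a radial stamp centred at a um position, clipped at the borders."""
    k = kernel.shape[0]
    half = k // 2
    col = int(np.floor(x_um / pixel_size))
    row = int(np.floor(y_um / pixel_size))
    r0, r1 = row - half, row + half + 1
    c0, c1 = col - half, col + half + 1
    kr0, kc0 = max(0, -r0), max(0, -c0)
    r0, c0 = max(0, r0), max(0, c0)
    r1, c1 = min(channel.shape[0], r1), min(channel.shape[1], c1)
    if r1 <= r0 or c1 <= c0:
        return
    sub = kernel[kr0:kr0 + (r1 - r0), kc0:kc0 + (c1 - c0)]
    np.maximum(channel[r0:r1, c0:c1], amplitude * sub, out=channel[r0:r1, c0:c1])


def _radial_kernel(radius_um: float, pixel_size: float) -> np.ndarray:
    """Smooth plateau disc: exp(-(r/r0)^4), truncated at 1.5 r0."""
    half = int(np.ceil(1.5 * radius_um / pixel_size))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    r = np.hypot(xx, yy) * pixel_size
    k = np.exp(-((r / radius_um) ** 4))
    k[k < 1e-4] = 0.0
    return k


def stain_concentration_maps(scene: CoreScene) -> np.ndarray:
    """Rasterise ground-truth stain concentrations, shape (H, W, 4).

    Channel order follows ``StainBasis.stains``: haematoxylin, DAB (PanCK),
    fast red, PermaGreen.  Chromogens are mutually exclusive per pixel —
    marker discs are clipped to the stromal compartment and, where the two
    marker chromogens would overlap, the stronger one wins — emulating the
    occlusive, non-linear behaviour of co-deposited brightfield chromogens.
    """
    h, w = scene.tissue_mask.shape
    conc = np.zeros((h, w, 4))
    px = scene.pixel_size
    nuc_kernel = _radial_kernel(NUCLEUS_RADIUS_UM, px)
    mark_kernel = _radial_kernel(MARKER_RADIUS_UM, px)

    conc[:, :, 0] = np.where(scene.tissue_mask, TISSUE_BG_CONC, 0.0)

    chromogen_channel = {"dab": 1, "fast_red": 2, "perma_green": 3}
    for cell in scene.cells:
        hx = cell.channel_intensities.get("haematoxylin", NUCLEUS_CONC)
        _stamp(conc[:, :, 0], cell.x, cell.y, hx, nuc_kernel, px)
        for chrom, ch in chromogen_channel.items():
            amp = cell.channel_intensities.get(chrom)
            if amp:
                _stamp(conc[:, :, ch], cell.x, cell.y, amp, mark_kernel, px)

    panck = scene.tumour_mask if scene.tumour_mask.any() else (
        scene.epithelium_mask if scene.epithelium_mask is not None
        else scene.tumour_mask)
    conc[:, :, 1] = np.where(panck, PANCK_CONC, 0.0)

    # chromogen exclusivity: markers only in stroma, one chromogen per pixel
    conc[:, :, 2] *= scene.stroma_mask
    conc[:, :, 3] *= scene.stroma_mask
    red_wins = conc[:, :, 2] >= conc[:, :, 3]
    conc[:, :, 2] *= red_wins
    conc[:, :, 3] *= ~red_wins
    return conc


def render_brightfield(
    scene: CoreScene,
    basis: StainBasis | None = None,
    noise_sd: float = 0.0,
    background_intensity: float = 255.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a brightfield RGB image of a scene via the Beer-Lambert law.

    Per pixel ``I_c = I0 * 10**(-sum_s a_s d_s,c)`` with Gaussian noise of
    sd ``noise_sd`` added on the optical density.  Returns a float RGB
    raster in ``[0, I0]``; quantisation to 8 bit happens only on file
    output, so a noiseless render is exactly invertible by the unmixer.
    """
    basis = basis or StainBasis()
    D = basis.matrix
    conc = stain_concentration_maps(scene)
    od = conc @ D.T
    if noise_sd > 0:
        rng = rng or _subseed(0, "render", scene.core_id)
        od = np.maximum(od + rng.normal(0.0, noise_sd, od.shape), 0.0)
    img = background_intensity * np.power(10.0, -od)
    return np.clip(img, 0.0, background_intensity)


def _categorical(rng: np.random.Generator, probs: dict, size: int) -> np.ndarray:
    keys = np.array(list(probs.keys()))
    p = np.array(list(probs.values()), dtype=float)
    return rng.choice(keys, size=size, p=p / p.sum())


def simulate_clinical(config: SimulationConfig, groups: np.ndarray) -> pd.DataFrame:
    """Patient-level clinical covariates at the stated marginal frequencies.

    Independent of the latent density group unless ``confound_covariates``
    is set, in which case high-density patients skew toward lower TNM.
    """
    rng = _subseed(config.seed, "clinical")
    n = len(groups)
    tnm = _categorical(rng, TNM_PROBS, n)
    if config.confound_covariates and n:
        shift = rng.random(n) < 0.5
        tnm = np.where((groups == "high") & shift, np.maximum(tnm - 1, 1), tnm)
    return pd.DataFrame({
        "patient_id": [f"P{i + 1:03d}" for i in range(n)],
        "cohort": 1,
        "age": np.round(rng.normal(69.0, 12.0, n), 1),
        "tnm_stage": tnm.astype(int),
        "pT": _categorical(rng, PT_PROBS, n).astype(int),
        "venous_invasion": (rng.random(n) < VENOUS_P).astype(int),
        "postop_chemo": (rng.random(n) < CHEMO_P).astype(int),
        "density_group_true": groups,
    })


def simulate_survival(config: SimulationConfig, groups: np.ndarray,
                      endpoint: str = "overall") -> list[SurvivalRecord]:
    """Exponential survival with a group-dependent hazard and censoring.

    Hazard is ``baseline_hazard`` for the low group and
    ``baseline_hazard * hazard_ratio_high_vs_low`` for the high group.
    Censoring is independent of the event time given the group: an
    exponential censoring clock with rate ``h * q / (1 - q)`` (q =
    ``censor_rate``), which censors a fraction q of each group in
    expectation; everyone still at risk at ``follow_up_horizon`` is
    administratively censored there.
    """
    rng = _subseed(config.seed, "survival")
    records = []
    q = config.censor_rate
    for i, g in enumerate(groups):
        hazard = config.baseline_hazard * (
            config.hazard_ratio_high_vs_low if g == "high" else 1.0)
        t = rng.exponential(1.0 / hazard)
        event = 1
        if q > 0:
            c = (rng.exponential((1.0 - q) / (hazard * q))
                 if q < 1 else 0.0)
            if c < t:
                t, event = c, 0
        if t >= config.follow_up_horizon:
            t, event = config.follow_up_horizon, 0
        records.append(SurvivalRecord(
            patient_id=f"P{i + 1:03d}", time=max(float(t), 1e-3),
            event=event, endpoint=endpoint))
    return records


def assign_latent_groups(config: SimulationConfig) -> np.ndarray:
    """Balanced low/high latent TP25-density groups, randomly permuted."""
    rng = _subseed(config.seed, "groups")
    n = config.n_patients
    g = np.array(["low"] * (n - n // 2) + ["high"] * (n // 2), dtype=object)
    return rng.permutation(g)


def simulate_cohort(
    config: SimulationConfig,
    panels: tuple = (1, 2),
    make_scenes: bool = True,
) -> tuple[list[CoreScene], pd.DataFrame, list[SurvivalRecord]]:
    """Simulate a full cohort: scenes per (patient, region, core, panel),
    a clinical table and survival records.

    Patients in the latent ``high`` group receive proximity-enriched
    scenes; ``low`` patients do not.  ``make_scenes=False`` skips the
    image-scale simulation for table-level studies.
    """
    config.validate()
    groups = assign_latent_groups(config)
    clinical = simulate_clinical(config, groups)
    survival = simulate_survival(config, groups)
    scenes: list[CoreScene] = []
    if make_scenes:
        for pid, grp in zip(clinical["patient_id"], groups):
            for region in config.regions:
                for k in range(config.cores_per_patient):
                    for panel in panels:
                        scenes.append(simulate_core(
                            config, pid, region, core_index=k, panel=panel,
                            enriched=(grp == "high")))
    return scenes, clinical, survival
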