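"""Tumour-proximity zones and stroma-restricted immune-cell densities.

A tumour-proximity (TP) zone of radius r is the set of stromal pixels
whose Euclidean distance to the nearest tumour pixel lies in (0, r];
``total`` is the whole stromal compartment.  Zones are cumulative discs,
so counts and areas are non-decreasing along the radius ladder
10 -> 25 -> 50 -> 100 -> total.  Per-core densities are pooled to the
patient level as area-weighted means (pooled counts over pooled areas).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import ZoneSpec
from .types import Cell, CoreQCResult, CoreScene, ZoneDensity

#: QC thresholds: a core enters the analysis only with more than this many
#: stromal cells and a tumour area share above this fraction of tissue.
QC_MIN_STROMAL_CELLS = 10
QC_MIN_TUMOUR_FRACTION = 0.01


def tumour_distance_map(tumour_mask: np.ndarray, pixel_size: float,
                        fallback_mask: np.ndarray | None = None) -> np.ndarray:
    """Euclidean distance (um) of every pixel to the nearest tumour pixel.

    Zero inside the tumour.  For cores without tumour (normal epithelium),
    distances are measured from ``fallback_mask`` (the epithelium) instead;
    with both empty an all-inf map is returned with a warning.
    """
    source = tumour_mask
    if not source.any() and fallback_mask is not None:
        source = fallback_mask
    if not source.any():
        warnings.warn("no tumour or epithelium pixels; zones undefined", stacklevel=2)
        return np.full(tumour_mask.shape, np.inf)
    return ndimage.distance_transform_edt(~source) * pixel_size


def zone_mask(distance_map: np.ndarray, stroma_mask: np.ndarray,
              radius: object) -> np.ndarray:
    """Stromal pixels within (0, radius] um of the tumour; ``"total"``
    selects the whole stroma."""
    if radius == "total":
        return stroma_mask.copy()
    if not (isinstance(radius, (int, float)) and radius > 0):
        raise ValueError(f"radius must be positive or 'total', got {radius!r}")
    return stroma_mask & (distance_map > 0) & (distance_map <= radius)


def cells_in_mask(cells: list[Cell], mask: np.ndarray, pixel_size: float) -> int:
    """Count cells whose centroid falls on a mask pixel (half-open pixel
    membership: floor(x / pixel_size))."""
    n = 0
    h, w = mask.shape
    for cell in cells:
        col = int(np.floor(cell.x / pixel_size))
        row = int(np.floor(cell.y / pixel_size))
        if 0 <= row < h and 0 <= col < w and mask[row, col]:
            n += 1
    return n


def zone_density(
    scene: CoreScene, zone: np.ndarray, marker: str, radius: object,
) -> ZoneDensity:
    """Density of one marker phenotype within a zone of one core."""
    stromal = [c for c in scene.cells
               if c.compartment == "stroma" and c.phenotype == marker]
    count = cells_in_mask(stromal, zone, scene.pixel_size)
    area_mm2 = float(zone.sum()) * scene.pixel_size ** 2 / 1e6
    if area_mm2 <= 0:
        warnings.warn(
            f"zone area is zero for {scene.core_id} r={radius}; density undefined",
            stacklevel=2)
    return ZoneDensity(
        patient_id=scene.patient_id, core_id=scene.core_id, region=scene.region,
        marker=marker, radius=radius, cell_count=count, zone_area_mm2=area_mm2)


def apply_core_qc(scene: CoreScene) -> CoreQCResult:
    """Core inclusion filter: more than 10 stromal cells and tumour area
    above 1% of tissue (both strict)."""
    n_stromal = sum(1 for c in scene.cells if c.compartment == "stroma")
    tissue_area = float(scene.tissue_mask.sum())
    tumour_frac = float(scene.tumour_mask.sum()) / tissue_area if tissue_area else 0.0
    ok_cells = n_stromal > QC_MIN_STROMAL_CELLS
    ok_tumour = tumour_frac > QC_MIN_TUMOUR_FRACTION
    reasons = []
    if not ok_cells:
        reasons.append(f"stromal cells {n_stromal} <= {QC_MIN_STROMAL_CELLS}")
    if not ok_tumour:
        reasons.append(f"tumour fraction {tumour_frac:.4f} <= {QC_MIN_TUMOUR_FRACTION}")
    return CoreQCResult(
        core_id=scene.core_id, stromal_cell_count=n_stromal,
        tumour_area_fraction=tumour_frac,
        included=ok_cells and ok_tumour, reason="; ".join(reasons))


def quantify_core(scene: CoreScene, zone_spec: ZoneSpec | None = None,
                  markers: tuple | None = None) -> list[ZoneDensity]:
    """All (marker, radius) densities of one core."""
    zone_spec = zone_spec or ZoneSpec()
    zone_spec.validate()
    if markers is None:
        markers = tuple(sorted({
            c.phenotype for c in scene.cells
            if c.compartment == "stroma" and c.phenotype != "double_negative"}))
    dmap = tumour_distance_map(scene.tumour_mask, scene.pixel_size,
                               fallback_mask=scene.epithelium_mask)
    out = []
    for radius in zone_spec.labels:
        zm = zone_mask(dmap, scene.stroma_mask, radius)
        for marker in markers:
            out.append(zone_density(scene, zm, marker, radius))
    return out


def densities_to_frame(densities: list[ZoneDensity]) -> pd.DataFrame:
    """Long-format density table (one row per core x marker x radius)."""
    return pd.DataFrame([{
        "patient_id": d.patient_id, "core_id": d.core_id, "region": d.region,
        "marker": d.marker, "radius": d.radius, "count": d.cell_count,
        "area_mm2": d.zone_area_mm2, "density_per_mm2": d.density_per_mm2,
    } for d in densities])


def pool_patient_density(densities: list[ZoneDensity]) -> float:
    """Area-weighted mean density over the included cores of one patient:
    pooled counts over pooled areas."""
    if not densities:
        raise ValueError("no included cores to pool")
    total_count = sum(d.cell_count for d in densities)
    total_area = sum(d.zone_area_mm2 for d in densities)
    if total_area <= 0:
        return float("nan")
    return total_count / total_area


def pool_patient_table(density_frame: pd.DataFrame,
                       included_cores: set | None = None) -> pd.DataFrame:
    """Patient-level weighted mean densities per (region, marker, radius).

    ``included_cores`` restricts to QC-passing cores; patients with no
    included core for a stratum are simply absent (missing at random).
    """
    df = density_frame
    if included_cores is not None:
        df = df[df["core_id"].isin(included_cores)]
    if df.empty:
        return pd.DataFrame(columns=[
            "patient_id", "region", "marker", "radius", "density_per_mm2"])
    grouped = (
        df.groupby(["patient_id", "region", "marker", "radius"], sort=True)
        .agg(count=("count", "sum"), area_mm2=("area_mm2", "sum"))
        .reset_index())
    grouped["density_per_mm2"] = np.where(
        grouped["area_mm2"] > 0, grouped["count"] / grouped["area_mm2"], np.nan)
    return grouped
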