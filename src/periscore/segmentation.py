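"""Tissue detection, tumour-stroma split, watershed cell detection and
phenotype classification on 4-channel stain-concentration images.

All thresholds live in :class:`periscore.config.ThresholdSet`; they are
manually tuned per cohort in practice because overall stain intensity
varies between staining runs.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation as sk_seg
from skimage.feature import peak_local_max

from .config import ConfigurationError, ThresholdSet
from .types import PANEL_CHROMOGEN, PANEL_MARKERS, Cell

#: channel order of unmixed images
CH_HX, CH_DAB, CH_RED, CH_GREEN = 0, 1, 2, 3


def _disc(radius_um: float, pixel_size: float) -> np.ndarray:
    r = max(int(round(radius_um / pixel_size)), 1)
    return morphology.disk(r)


def detect_tissue(channels: np.ndarray, thresholds: ThresholdSet,
                  pixel_size: float) -> np.ndarray:
    """Tissue mask: total stain concentration above threshold, closed and
    hole-filled (closing disc 5 um)."""
    total = channels.sum(axis=-1)
    mask = total >= thresholds.tissue_od_min
    if not mask.any():
        return mask
    mask = morphology.closing(mask, _disc(5.0, pixel_size))
    return ndimage.binary_fill_holes(mask)


def split_tumour_stroma(
    channels: np.ndarray, tissue_mask: np.ndarray, thresholds: ThresholdSet,
    pixel_size: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Tumour = PanCK(DAB) channel above threshold within tissue, closed
    with a 10 um disc to merge glands; stroma = remaining tissue."""
    panck = channels[:, :, CH_DAB] >= thresholds.panck_min
    tumour = panck & tissue_mask
    if tumour.any():
        tumour = morphology.closing(tumour, _disc(10.0, pixel_size)) & tissue_mask
    stroma = tissue_mask & ~tumour
    return tumour, stroma


def detect_cells_watershed(
    hx_channel: np.ndarray, tissue_mask: np.ndarray, thresholds: ThresholdSet,
    pixel_size: float,
) -> list[Cell]:
    """Marker-controlled watershed on the haematoxylin channel.

    Gaussian smoothing (sigma 1 um), nucleus threshold, Euclidean distance
    transform, local maxima at a minimum separation of 4 um as markers,
    watershed on the inverted distance map.  Objects outside the
    [min, max] nucleus-area window are discarded.  Centroids are reported
    in micrometres (pixel centre convention).
    """
    sigma_px = thresholds.smooth_sigma_um / pixel_size
    smooth = ndimage.gaussian_filter(np.asarray(hx_channel, dtype=float), sigma_px)
    nuclei = (smooth >= thresholds.nucleus_od_min) & tissue_mask
    if not nuclei.any():
        return []
    dist = ndimage.distance_transform_edt(nuclei)
    min_sep_px = max(int(round(thresholds.min_peak_separation_um / pixel_size)), 1)
    peaks = peak_local_max(dist, min_distance=min_sep_px, labels=nuclei,
                           exclude_border=False)
    if len(peaks) == 0:
        return []
    markers = np.zeros(nuclei.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = sk_seg.watershed(-dist, markers, mask=nuclei)

    px_area = pixel_size ** 2
    cells = []
    for prop in measure.regionprops(labels):
        area_um2 = prop.area * px_area
        if not (thresholds.min_nucleus_area <= area_um2 <= thresholds.max_nucleus_area):
            continue
        cy, cx = prop.centroid
        cells.append(Cell(
            x=(cx + 0.5) * pixel_size,
            y=(cy + 0.5) * pixel_size,
            area_um2=area_um2,
            solidity=float(prop.solidity),
        ))
    return cells


def _mean_in_disc(channel: np.ndarray, x_um: float, y_um: float,
                  radius_um: float, pixel_size: float) -> float:
    col = x_um / pixel_size
    row = y_um / pixel_size
    r_px = max(radius_um / pixel_size, 1.0)
    r0 = max(int(np.floor(row - r_px)), 0)
    r1 = min(int(np.ceil(row + r_px)) + 1, channel.shape[0])
    c0 = max(int(np.floor(col - r_px)), 0)
    c1 = min(int(np.ceil(col + r_px)) + 1, channel.shape[1])
    if r1 <= r0 or c1 <= c0:
        return 0.0
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = (yy + 0.5 - row) ** 2 + (xx + 0.5 - col) ** 2 <= r_px ** 2
    if not inside.any():
        return 0.0
    return float(channel[r0:r1, c0:c1][inside].mean())


def classify_cells(
    cells: list[Cell],
    channels: np.ndarray,
    tumour_mask: np.ndarray,
    thresholds: ThresholdSet,
    panel: int,
    pixel_size: float,
) -> list[Cell]:
    """Assign compartment (centroid-in-tumour-mask) and stromal phenotype.

    Stromal cells are compared against per-marker thresholds on the mean
    chromogen concentration in a 3 um disc around the centroid; if both
    markers exceed their threshold the one with the larger
    threshold-normalised intensity wins; neither gives ``double_negative``.
    """
    if panel not in PANEL_MARKERS:
        raise ConfigurationError(f"unknown staining panel {panel!r}")
    m1, m2 = PANEL_MARKERS[panel]
    ch_of = {"dab": CH_DAB, "fast_red": CH_RED, "perma_green": CH_GREEN}
    chan1 = ch_of[PANEL_CHROMOGEN[panel][m1]]
    chan2 = ch_of[PANEL_CHROMOGEN[panel][m2]]
    t1 = thresholds.marker_threshold(m1)
    t2 = thresholds.marker_threshold(m2)

    out = []
    for cell in cells:
        col = min(int(np.floor(cell.x / pixel_size)), tumour_mask.shape[1] - 1)
        row = min(int(np.floor(cell.y / pixel_size)), tumour_mask.shape[0] - 1)
        if tumour_mask[row, col]:
            comp, pheno = "tumour", "tumour"
            intens = {}
        else:
            comp = "stroma"
            i1 = _mean_in_disc(channels[:, :, chan1], cell.x, cell.y,
                               thresholds.measure_radius_um, pixel_size)
            i2 = _mean_in_disc(channels[:, :, chan2], cell.x, cell.y,
                               thresholds.measure_radius_um, pixel_size)
            pos1, pos2 = i1 >= t1, i2 >= t2
            if pos1 and pos2:
                pheno = m1 if i1 / t1 >= i2 / t2 else m2
            elif pos1:
                pheno = m1
            elif pos2:
                pheno = m2
            else:
                pheno = "double_negative"
            intens = {m1: i1, m2: i2}
        out.append(Cell(
            x=cell.x, y=cell.y, compartment=comp, phenotype=pheno,
            channel_intensities=intens,
            area_um2=cell.area_um2, solidity=cell.solidity,
        ))
    return out


def exclude_artefacts(cells: list[Cell], channels: np.ndarray,
                      thresholds: ThresholdSet, pixel_size: float) -> list[Cell]:
    """Rule-based artefact filter.

    Removes objects with saturated optical density in three or more
    channels (pigment, debris) or with nucleus solidity below 0.5
    (fragmented objects).  Deterministic stand-in for a trained object
    classifier; the rules are the two artefact modes the generator can
    plant.
    """
    kept = []
    for cell in cells:
        if cell.solidity is not None and cell.solidity < thresholds.min_solidity:
            continue
        col = min(int(np.floor(cell.x / pixel_size)), channels.shape[1] - 1)
        row = min(int(np.floor(cell.y / pixel_size)), channels.shape[0] - 1)
        n_sat = int(np.sum(channels[row, col, :] >= thresholds.saturation_od))
        if n_sat >= 3:
            continue
        kept.append(cell)
    return kept


def segment_core(
    channels: np.ndarray,
    thresholds: ThresholdSet,
    panel: int,
    pixel_size: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[Cell]]:
    """Full segmentation of one unmixed core.

    Returns (tissue_mask, tumour_mask, stroma_mask, classified cells with
    artefacts removed).
    """
    tissue = detect_tissue(channels, thresholds, pixel_size)
    tumour, stroma = split_tumour_stroma(channels, tissue, thresholds, pixel_size)
    cells = detect_cells_watershed(channels[:, :, CH_HX], tissue, thresholds, pixel_size)
    cells = classify_cells(cells, channels, tumour, thresholds, panel, pixel_size)
    cells = exclude_artefacts(cells, channels, thresholds, pixel_size)
    return tissue, tumour, stroma, cells
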