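"""Core record types shared across the pipeline.

Coordinates are core-local micrometres with the origin at the top-left of
the core raster, x increasing rightward (columns) and y downward (rows).
All masks are boolean rasters; ``pixel_size`` is carried alongside every
raster in micrometres per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Tumour regions sampled on the tissue microarray: tumour centre, tumour
#: front (tumour-rich invasive margin), microenvironment (stroma-rich
#: invasive margin) and normal colorectal epithelium.
REGIONS = ("CT", "FR", "ME", "NE")

#: Immune markers quantified in the stroma, by staining panel.
PANEL_MARKERS = {1: ("CD8", "CD68"), 2: ("GZMB", "CD163")}

#: Stain names per panel, in channel order of the unmixed image.
PANEL_STAINS = {
    1: ("haematoxylin", "dab", "fast_red", "perma_green"),
    2: ("haematoxylin", "dab", "fast_red", "perma_green"),
}

#: Which chromogen visualises which target, per panel.  DAB (brown) carries
#: pancytokeratin in both panels; fast red and PermaGreen carry the two
#: immune markers.
PANEL_CHROMOGEN = {
    1: {"PanCK": "dab", "CD8": "fast_red", "CD68": "perma_green"},
    2: {"PanCK": "dab", "GZMB": "fast_red", "CD163": "perma_green"},
}


@dataclass
class Cell:
    """A detected or simulated cell.

    ``phenotype`` is one of the panel's two markers, ``double_negative``
    for stromal cells negative for both, or ``tumour`` for epithelial
    (PanCK+) cells.  A cell has phenotype ``tumour`` exactly when its
    compartment is ``tumour``.
    """

    x: float
    y: float
    compartment: str = "stroma"  # {"tumour", "stroma"}
    phenotype: str = "double_negative"
    channel_intensities: dict = field(default_factory=dict)
    area_um2: Optional[float] = None
    solidity: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.phenotype == "tumour") != (self.compartment == "tumour"):
            raise ValueError(
                "phenotype 'tumour' if and only if compartment 'tumour' "
                f"(got phenotype={self.phenotype!r}, compartment={self.compartment!r})"
            )


@dataclass
class CoreScene:
    """One TMA core: masks, cells and identifiers.

    ``epithelium_mask`` is only populated for NE cores, where PanCK stains
    normal epithelium; proximity zones there are measured from it instead
    of the (empty) tumour mask.
    """

    patient_id: str
    core_id: str
    region: str
    panel: int
    pixel_size: float
    tissue_mask: np.ndarray
    tumour_mask: np.ndarray
    stroma_mask: np.ndarray
    cells: list = field(default_factory=list)
    epithelium_mask: Optional[np.ndarray] = None

    def validate(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if np.any(self.tumour_mask & self.stroma_mask):
            raise ValueError("tumour and stroma masks overlap")
        if np.any((self.tumour_mask | self.stroma_mask) & ~self.tissue_mask):
            raise ValueError("tumour/stroma extend outside tissue")

    @property
    def proximity_source_mask(self) -> np.ndarray:
        """Mask from which proximity distances are measured.

        The tumour mask, except in NE cores where the normal epithelium
        plays that role.
        """
        if self.tumour_mask.any() or self.epithelium_mask is None:
            return self.tumour_mask
        return self.epithelium_mask


@dataclass
class SurvivalRecord:
    """Time-to-event outcome for one patient with clinical covariates."""

    patient_id: str
    time: float  # months
    event: int  # 1 = event observed, 0 = censored
    endpoint: str = "overall"  # {"overall", "disease_free"}
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event flag must be 0 or 1")


@dataclass
class ZoneDensity:
    """Cell density of one marker in one tumour-proximity zone of one core."""

    patient_id: str
    core_id: str
    region: str
    marker: str
    radius: object  # radius in um, or the string "total"
    cell_count: int
    zone_area_mm2: float

    @property
    def density_per_mm2(self) -> float:
        if self.zone_area_mm2 <= 0:
            return float("nan")
        return self.cell_count / self.zone_area_mm2


@dataclass
class CoreQCResult:
    """Core-level inclusion decision.

    A core enters the analysis only when more than 10 cells were detected
    in the stroma and the tumour occupies more than 1% of the tissue area.
    """

    core_id: str
    stromal_cell_count: int
    tumour_area_fraction: float
    included: bool
    reason: str = ""


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    statistic: float
    p_value: float
    degrees_of_freedom: Optional[float] = None
    continuity_correction: bool = False
    flags: tuple = ()

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass
class CoxFit:
    """Fitted Cox proportional-hazards model.

    Per covariate: log-hazard coefficient, hazard ratio with Wald 95% CI
    and Wald p-value.
    """

    covariates: tuple
    coef: np.ndarray
    se: np.ndarray
    log_likelihood: float
    ties_method: str
    converged: bool
    n: int
    n_events: int
    flags: tuple = ()

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def conf_int(self) -> np.ndarray:
        """(k, 2) array of 95% CI bounds on the hazard-ratio scale."""
        lo = np.exp(self.coef - 1.959963984540054 * self.se)
        hi = np.exp(self.coef + 1.959963984540054 * self.se)
        return np.column_stack([lo, hi])

    @property
    def p_values(self) -> np.ndarray:
        from scipy import stats as _st

        z = self.coef / self.se
        return 2.0 * _st.norm.sf(np.abs(z))

    def summary(self):
        import pandas as pd

        ci = self.conf_int
        return pd.DataFrame(
            {
                "coef": self.coef,
                "HR": self.hazard_ratios,
                "HR_ci_lower": ci[:, 0],
                "HR_ci_upper": ci[:, 1],
                "p": self.p_values,
            },
            index=list(self.covariates),
        )
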