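"""Patient-level immune scores.

Densities are dichotomised at the cohort median (strictly above -> high;
ties at the median go to low, so the complement of "high" is "at least
one below the median").  The combined GZMB/CD68 score is high exactly
when both single-marker groups are high.  Ratio scores carry a +1 offset
on numerator and denominator to guard against zero densities, matching
the +1 offset convention used for log transforms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LOW, HIGH = "low", "high"


def dichotomize_at_median(densities: pd.Series) -> pd.Series:
    """Map patient -> {low, high} at the cohort median.

    The median is computed over non-missing patients only; a patient is
    ``high`` iff its density is strictly greater than that median.
    Missing densities stay missing.
    """
    valid = densities.dropna()
    if len(valid) < 1:
        raise ValueError("cannot dichotomize an all-missing density vector")
    med = float(np.median(valid.to_numpy(dtype=float)))
    out = pd.Series(pd.NA, index=densities.index, dtype=object)
    out[valid.index] = np.where(valid.to_numpy(dtype=float) > med, HIGH, LOW)
    return out


def combine_gzmb_cd68(gzmb_group: object, cd68_group: object) -> object:
    """Combined score: high iff both marker groups are high; missing if
    either group is missing."""
    if pd.isna(gzmb_group) or pd.isna(cd68_group):
        return pd.NA
    return HIGH if (gzmb_group == HIGH and cd68_group == HIGH) else LOW


def ratio_scores(cd8: float, gzmb: float, cd68: float, cd163: float) -> dict:
    """Effector-to-lineage ratio scores and the macrophage difference.

    Ratios use a +1 offset on both numerator and denominator; the
    difference is a plain subtraction in 1/mm^2.
    """
    return {
        "gzmb_cd8_ratio": (gzmb + 1.0) / (cd8 + 1.0),
        "cd68_cd163_ratio": (cd68 + 1.0) / (cd163 + 1.0),
        "cd68_minus_cd163": cd68 - cd163,
    }


def score_patients(
    pooled: pd.DataFrame,
    region: str = "CT",
    radius: object = 25.0,
    cohort_id: object = 1,
) -> pd.DataFrame:
    """Build the per-patient score table for one (cohort, region, radius).

    ``pooled`` is the patient-level weighted-mean density table
    (columns patient_id, region, marker, radius, density_per_mm2).
    Medians are computed within this stratum only.  Returns one row per
    patient with per-marker densities, low/high groups, the combined
    GZMB/CD68 group and the ratio scores.
    """
    sel = pooled[(pooled["region"] == region) & (pooled["radius"] == radius)]
    wide = sel.pivot_table(index="patient_id", columns="marker",
                           values="density_per_mm2", aggfunc="first")
    out = pd.DataFrame(index=wide.index)
    out["cohort_id"] = cohort_id
    out["region"] = region
    out["radius"] = radius
    for marker in ("CD8", "GZMB", "CD68", "CD163"):
        if marker in wide.columns:
            out[f"{marker}_density"] = wide[marker]
            out[f"{marker}_group"] = dichotomize_at_median(wide[marker])
    if "GZMB_group" in out.columns and "CD68_group" in out.columns:
        out["combined_gzmb_cd68"] = [
            combine_gzmb_cd68(g, c)
            for g, c in zip(out["GZMB_group"], out["CD68_group"])]
    if all(f"{m}_density" in out.columns for m in ("CD8", "GZMB", "CD68", "CD163")):
        scores = [
            ratio_scores(r["CD8_density"], r["GZMB_density"],
                         r["CD68_density"], r["CD163_density"])
            if not any(pd.isna(r[f"{m}_density"])
                       for m in ("CD8", "GZMB", "CD68", "CD163"))
            else {"gzmb_cd8_ratio": np.nan, "cd68_cd163_ratio": np.nan,
                  "cd68_minus_cd163": np.nan}
            for _, r in out.iterrows()]
        for key in ("gzmb_cd8_ratio", "cd68_cd163_ratio", "cd68_minus_cd163"):
            out[key] = [s[key] for s in scores]
    return out.reset_index()
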