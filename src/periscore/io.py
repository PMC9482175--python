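"""File-format dialects: cells/clinical/survival/density CSV, mask PNG,
brightfield PNG and multichannel TIFF.

All CSVs are comma-separated UTF-8 with a header row; coordinates are
micrometres written as decimals (round-trip precision well below
1e-3 um).  Masks are 8-bit PNGs with values 0/255.  Unmixed images are
32-bit multichannel TIFFs with stain names in the image description.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .types import Cell, SurvivalRecord

CELL_COLUMNS = ["patient_id", "core_id", "region", "x_um", "y_um",
                "compartment", "phenotype"]


class ParseError(ValueError):
    pass


def write_cells_csv(path, cells: list[Cell], patient_id: str = "",
                    core_id: str = "", region: str = "") -> None:
    intensity_keys = sorted({k for c in cells for k in c.channel_intensities})
    rows = []
    for c in cells:
        row = {
            "patient_id": patient_id, "core_id": core_id, "region": region,
            "x_um": c.x, "y_um": c.y,
            "compartment": c.compartment, "phenotype": c.phenotype,
        }
        for k in intensity_keys:
            row[f"intensity_{k}"] = c.channel_intensities.get(k, "")
        rows.append(row)
    cols = CELL_COLUMNS + [f"intensity_{k}" for k in intensity_keys]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.6f")


def read_cells_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse cells CSV {path}: {exc}") from exc
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def cells_from_frame(df: pd.DataFrame) -> list[Cell]:
    cells = []
    for i, row in df.iterrows():
        try:
            intens = {
                col.removeprefix("intensity_"): float(row[col])
                for col in df.columns
                if col.startswith("intensity_") and pd.notna(row[col])}
            cells.append(Cell(
                x=float(row["x_um"]), y=float(row["y_um"]),
                compartment=str(row["compartment"]),
                phenotype=str(row["phenotype"]),
                channel_intensities=intens))
        except (ValueError, KeyError) as exc:
            raise ParseError(f"bad cell row {i + 2}: {exc}") from exc
    return cells


def write_mask_png(path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)


def read_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path)) > 127


def write_rgb_png(path, rgb: np.ndarray) -> None:
    """8-bit brightfield output (rendering itself is float)."""
    arr = np.clip(np.round(np.asarray(rgb, dtype=float)), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def read_rgb_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"), dtype=float)


def write_channels_tiff(path, channels: np.ndarray, stain_names: tuple) -> None:
    arr = np.moveaxis(np.asarray(channels, dtype=np.float32), -1, 0)
    tifffile.imwrite(path, arr, photometric="minisblack",
                     description=json.dumps({"stains": list(stain_names)}))


def read_channels_tiff(path) -> tuple[np.ndarray, tuple]:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or "{}"
    try:
        stains = tuple(json.loads(desc).get("stains", ()))
    except json.JSONDecodeError:
        stains = ()
    return np.moveaxis(arr, 0, -1), stains


def write_survival_csv(path, records: list[SurvivalRecord]) -> None:
    cov_keys = sorted({k for r in records for k in r.covariates})
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "time_months": r.time,
               "event": r.event, "endpoint": r.endpoint}
        row.update({k: r.covariates.get(k, "") for k in cov_keys})
        rows.append(row)
    cols = ["patient_id", "time_months", "event", "endpoint"] + cov_keys
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_survival_csv(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path)
    needed = {"patient_id", "time_months", "event", "endpoint"}
    if not needed <= set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(needed - set(df.columns))}")
    extra = [c for c in df.columns if c not in needed]
    out = []
    for i, row in df.iterrows():
        try:
            out.append(SurvivalRecord(
                patient_id=str(row["patient_id"]),
                time=float(row["time_months"]), event=int(row["event"]),
                endpoint=str(row["endpoint"]),
                covariates={k: row[k] for k in extra if pd.notna(row[k])}))
        except (ValueError, KeyError) as exc:
            raise ParseError(f"bad survival row {i + 2}: {exc}") from exc
    return out


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
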