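"""Data model and I/O for single-cell spatial tables.

A *cell table* is a pandas DataFrame with one row per segmented cell:
``cell_id, sample_id, patient_id, x, y[, area], <marker columns>`` plus any
derived label columns (``phenotype``, ``rcn``).  A *clinical table* has one
row per patient with survival times/events and arbitrary categorical labels.
Coordinates are continuous pixel centroids in a single shared scale per
cohort; all internal geometry is Euclidean in pixels and micrometres appear
only in reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerPanel",
    "DEFAULT_PANEL",
    "CellTableError",
    "REQUIRED_CELL_COLUMNS",
    "validate_cell_table",
    "read_cell_table",
    "write_cell_table",
    "validate_clinical_table",
    "read_clinical_table",
    "write_clinical_table",
    "qc_filter_cells",
    "pixels_to_microns",
    "microns_label",
]

#: Columns every cell table must carry, in canonical order.
REQUIRED_CELL_COLUMNS = ("cell_id", "sample_id", "patient_id", "x", "y")

#: The 11 analysis markers of the panel (Tbet is excluded from analysis:
#: its immunofluorescence signal was too weak to be usable).
DEFAULT_MARKERS = (
    "CD20",
    "CD3",
    "CD4",
    "CD8",
    "Foxp3",
    "CD68",
    "CD163",
    "PD-1",
    "PD-L1",
    "CD96",
    "CD45",
)


class CellTableError(ValueError):
    """Raised when a cell or clinical table violates its schema."""


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered marker panel plus the pixel scale of the cohort.

    Parameters
    ----------
    markers
        Unique marker names; each must appear as an intensity column in the
        cell tables.
    microns_per_pixel
        Physical size of one pixel.  The default is 1/3 µm/px, the
        convention under which the reporting thresholds used throughout
        (60 px ↔ 20 µm, 400 px ↔ 133 µm, 800 px ↔ 267 µm) round exactly.
    """

    markers: tuple[str, ...] = DEFAULT_MARKERS
    microns_per_pixel: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise CellTableError("marker names must be unique")
        if "Tbet" in self.markers:
            raise CellTableError("Tbet is excluded from analysis panels")
        if not self.microns_per_pixel > 0:
            raise CellTableError("microns_per_pixel must be > 0")


DEFAULT_PANEL = MarkerPanel()


def _check_unique(values: pd.Series, what: str) -> None:
    dup = values[values.duplicated()]
    if len(dup):
        raise CellTableError(f"duplicate {what}: {dup.iloc[0]!r}")


def validate_cell_table(
    df: pd.DataFrame, panel: MarkerPanel = DEFAULT_PANEL, *, require_area: bool = False
) -> pd.DataFrame:
    """Validate a cell table against the schema; return it unchanged.

    Raises :class:`CellTableError` naming the offending column (and row where
    identifiable) on: missing required columns or marker columns, duplicate
    ``cell_id``, non-numeric or non-finite coordinates, negative
    coordinates, or non-finite marker intensities.
    """
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in df.columns]
    if require_area and "area" not in df.columns:
        missing.append("area")
    missing += [m for m in panel.markers if m not in df.columns]
    if missing:
        raise CellTableError(f"missing required column(s): {', '.join(missing)}")
    _check_unique(df["cell_id"], "cell_id")
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals.to_numpy(dtype=float))
        if bad.any():
            row = df.index[bad][0]
            raise CellTableError(f"non-numeric or non-finite {col} at row {row}")
        if (vals < 0).any():
            row = df.index[vals < 0][0]
            raise CellTableError(f"negative coordinate {col} at row {row}")
    for m in panel.markers:
        vals = pd.to_numeric(df[m], errors="coerce").to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            row = df.index[~np.isfinite(vals)][0]
            raise CellTableError(f"non-finite intensity in column {m!r} at row {row}")
        if (vals < 0).any():
            row = df.index[vals < 0][0]
            raise CellTableError(f"negative intensity in column {m!r} at row {row}")
    return df


def read_cell_table(
    path: str | Path, panel: MarkerPanel = DEFAULT_PANEL, **kwargs
) -> pd.DataFrame:
    """Read and validate a cell table from CSV (``.csv``) or Parquet.

    Extra columns are preserved.  A missing required column is fatal.
    """
    path = Path(path)
    if path.suffix in {".parquet", ".pq"}:
        df = pd.read_parquet(path, **kwargs)
    else:
        df = pd.read_csv(path, **kwargs)
    return validate_cell_table(df, panel)


def write_cell_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table to CSV or Parquet, chosen by file suffix.

    CSV floats are written with ``repr`` round-trip precision so that
    read(write(t)) reproduces t to better than 1e-12 relative.
    """
    path = Path(path)
    if path.suffix in {".parquet", ".pq"}:
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False, float_format="%.17g")


def validate_clinical_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate one-row-per-patient clinical metadata.

    Requires a unique ``patient_id``; any ``*_time`` column must be
    nonnegative and any ``*_event`` column binary (0/1).
    """
    if "patient_id" not in df.columns:
        raise CellTableError("missing required column(s): patient_id")
    _check_unique(df["patient_id"], "patient_id")
    for col in df.columns:
        if col.endswith("_time"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if (vals < 0).any() or vals.isna().any():
                raise CellTableError(f"column {col!r} must be nonnegative")
        if col.endswith("_event"):
            if not df[col].isin([0, 1]).all():
                raise CellTableError(f"column {col!r} must be binary 0/1")
    return df


def read_clinical_table(path: str | Path, **kwargs) -> pd.DataFrame:
    df = pd.read_csv(path, **kwargs)
    return validate_clinical_table(df)


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def qc_filter_cells(df: pd.DataFrame, min_area: float = 100.0) -> pd.DataFrame:
    """Remove cells with segmented area below ``min_area`` pixels.

    The rule is "area < min_area removed": a cell with area exactly equal to
    the threshold survives.  With ``min_area=0`` the table is returned
    unchanged (and an ``area`` column is then not required).
    """
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    if min_area == 0:
        return df
    if "area" not in df.columns:
        raise CellTableError("missing required column(s): area")
    keep = df["area"].to_numpy(dtype=float) >= min_area
    removed = int((~keep).sum())
    if removed:
        logger.info("qc_filter_cells: removed %d of %d cells (area < %g px)",
                    removed, len(df), min_area)
    return df.loc[keep].copy()


def pixels_to_microns(d, panel: MarkerPanel = DEFAULT_PANEL):
    """Convert pixel distances to micrometres (``d * microns_per_pixel``).

    Accepts scalars or arrays; negative distances are rejected.
    """
    arr = np.asarray(d, dtype=float)
    if (arr < 0).any():
        raise ValueError("distances must be nonnegative")
    out = arr * panel.microns_per_pixel
    return float(out) if np.isscalar(d) or arr.ndim == 0 else out


def microns_label(d_pixels: float, panel: MarkerPanel = DEFAULT_PANEL) -> int:
    """Reporting helper: pixel distance as the nearest whole micrometre."""
    return int(round(pixels_to_microns(d_pixels, panel)))
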