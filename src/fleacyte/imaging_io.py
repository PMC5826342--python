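"""Field-image containers and file I/O.

One microscope *field* is a pair of co-registered grayscale rasters — a
chlorophyll-autofluorescence channel used to locate and size cells, and an
ELFA channel carrying the phosphatase-activity signal — plus the acquisition
metadata (exposure time, fluorescence calibration factor, pixel size) needed
to turn gray levels into fluorescence units.

On disk a field is two single-channel 16-bit TIFFs and a JSON sidecar:

    <field_id>_chl.tif
    <field_id>_elfa.tif
    <field_id>_meta.json

Measurement tables are plain CSV with one row per cell.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

SPECIES = ("C_elongata", "C_silvae_gabretae")
VARIANTS = ("I1", "I2", "I3", "O1", "O2", "O3")


class FieldIOError(ValueError):
    """Raised when a field cannot be read or validated; names the offending file."""


@dataclass
class FieldImage:
    """Two co-registered channels of one microscope field plus metadata.

    Attributes
    ----------
    chl, elfa
        2-D integer rasters (row, col), chlorophyll and ELFA channels.
    exposure_ms_elfa
        ELFA-channel exposure time T_exp in milliseconds (> 0).
    calibration_factor
        Dimensionless fluorescence calibration factor F_cal (> 0).
    pixel_size_um
        Side of one pixel in micrometres (> 0); areas are pixel counts
        times ``pixel_size_um**2``.
    """

    chl: np.ndarray
    elfa: np.ndarray
    exposure_ms_elfa: float
    calibration_factor: float = 1.0
    pixel_size_um: float = 0.11
    field_id: str = "field_0"
    slide_id: str = "slide_0"

    def __post_init__(self) -> None:
        self.chl = np.asarray(self.chl)
        self.elfa = np.asarray(self.elfa)
        if self.chl.ndim != 2 or self.elfa.ndim != 2:
            raise FieldIOError(f"{self.field_id}: channels must be 2-D rasters")
        if self.chl.shape != self.elfa.shape:
            raise FieldIOError(
                f"{self.field_id}: channel shapes differ "
                f"(chl {self.chl.shape} vs elfa {self.elfa.shape})"
            )
        if np.issubdtype(self.chl.dtype, np.floating) or np.issubdtype(
            self.elfa.dtype, np.floating
        ):
            raise FieldIOError(f"{self.field_id}: rasters must be integer-typed")
        if (self.chl < 0).any() or (self.elfa < 0).any():
            raise FieldIOError(f"{self.field_id}: negative intensities")
        if not self.exposure_ms_elfa > 0:
            raise FieldIOError(
                f"{self.field_id}: exposure_ms_elfa must be > 0, got {self.exposure_ms_elfa}"
            )
        if not self.calibration_factor > 0:
            raise FieldIOError(
                f"{self.field_id}: calibration_factor must be > 0, got {self.calibration_factor}"
            )
        if not self.pixel_size_um > 0:
            raise FieldIOError(f"{self.field_id}: pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.chl.shape


@dataclass(frozen=True)
class SampleDesign:
    """One experimental replicate: species x treatment variant x replicate number."""

    species: str
    variant: str
    replicate: int

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}; expected one of {SPECIES}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


def write_field(field: FieldImage, directory: str | Path) -> dict[str, Path]:
    """Write a field as two 16-bit TIFFs plus a JSON metadata sidecar.

    Returns a dict with keys ``chl``, ``elfa``, ``sidecar`` mapping to the
    written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "chl": directory / f"{field.field_id}_chl.tif",
        "elfa": directory / f"{field.field_id}_elfa.tif",
        "sidecar": directory / f"{field.field_id}_meta.json",
    }
    tifffile.imwrite(paths["chl"], field.chl.astype(np.uint16))
    tifffile.imwrite(paths["elfa"], field.elfa.astype(np.uint16))
    meta = {
        "field_id": field.field_id,
        "slide_id": field.slide_id,
        "exposure_ms_elfa": field.exposure_ms_elfa,
        "calibration_factor": field.calibration_factor,
        "pixel_size_um": field.pixel_size_um,
    }
    paths["sidecar"].write_text(json.dumps(meta, indent=1))
    return paths


def read_field(
    chl_path: str | Path,
    elfa_path: str | Path,
    sidecar_path: str | Path,
) -> FieldImage:
    """Read one field from its two channel TIFFs and JSON sidecar.

    A sidecar without ``calibration_factor`` defaults to F_cal = 1 with a
    logged warning. Shape mismatches, non-positive exposure and unreadable
    files raise :class:`FieldIOError` naming the file.
    """
    try:
        chl = tifffile.imread(chl_path)
    except Exception as exc:  # noqa: BLE001 - re-raise typed
        raise FieldIOError(f"cannot read chlorophyll TIFF {chl_path}: {exc}") from exc
    try:
        elfa = tifffile.imread(elfa_path)
    except Exception as exc:  # noqa: BLE001
        raise FieldIOError(f"cannot read ELFA TIFF {elfa_path}: {exc}") from exc
    try:
        meta = json.loads(Path(sidecar_path).read_text())
    except Exception as exc:  # noqa: BLE001
        raise FieldIOError(f"cannot parse sidecar {sidecar_path}: {exc}") from exc
    if "calibration_factor" not in meta:
        logger.warning(
            "sidecar %s has no calibration_factor; defaulting to 1.0", sidecar_path
        )
    if chl.shape != elfa.shape:
        raise FieldIOError(
            f"shape mismatch between {chl_path} {chl.shape} and {elfa_path} {elfa.shape}"
        )
    exposure = float(meta.get("exposure_ms_elfa", -1.0))
    if not exposure > 0:
        raise FieldIOError(f"sidecar {sidecar_path}: exposure_ms_elfa must be > 0")
    return FieldImage(
        chl=chl,
        elfa=elfa,
        exposure_ms_elfa=exposure,
        calibration_factor=float(meta.get("calibration_factor", 1.0)),
        pixel_size_um=float(meta.get("pixel_size_um", 0.11)),
        field_id=str(meta.get("field_id", Path(str(chl_path)).stem)),
        slide_id=str(meta.get("slide_id", "slide_0")),
    )


def cells_to_frame(cells: Sequence) -> pd.DataFrame:
    """Flatten a homogeneous list of cell records (dataclasses) to a DataFrame."""
    if len(cells) == 0:
        return pd.DataFrame()
    first = type(cells[0])
    if not all(type(c) is first for c in cells):
        raise TypeError("cell records must be of a single type")
    rows = []
    for c in cells:
        d = dataclasses.asdict(c)
        # unpack 2-tuples like centroid_px into scalar columns
        for key in list(d):
            v = d[key]
            if isinstance(v, (tuple, list)) and len(v) == 2:
                d[f"{key}_row"], d[f"{key}_col"] = v
                del d[key]
        rows.append(d)
    return pd.DataFrame(rows)


def write_cell_table(cells: Sequence, path: str | Path, record_type=None) -> None:
    """Write per-cell records to CSV, one row per cell, stable column order.

    An empty list produces a header-only file when ``record_type`` (a record
    dataclass) is given, otherwise an empty file. Floats are written with
    shortest round-trip repr, so re-reading reproduces them exactly.
    """
    frame = cells_to_frame(cells)
    if frame.empty and record_type is not None:
        cols = []
        for f in dataclasses.fields(record_type):
            if "tuple" in str(f.type):
                cols += [f"{f.name}_row", f"{f.name}_col"]
            else:
                cols.append(f.name)
        frame = pd.DataFrame(columns=cols)
    frame.to_csv(path, index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
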