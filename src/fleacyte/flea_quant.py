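"""Cell-specific phosphatase activity and cell volume from measurements.

The cell-associated ELFA fluorescence, in relative fluorescence units (FU)
per cell per hour, is

    F_ELFA = Area * (MGrey - BgMGrey) / (T_exp * F_cal)

with Area the projected cell area (um^2), MGrey/BgMGrey the mean ELFA grays
of cell and background, T_exp the exposure time (ms) and F_cal a
dimensionless calibration factor. The printed formula contains no incubation
term — its output is declared to be per hour under the assay's fixed 3-h
incubation — so division by incubation time is off by default and available
for cross-protocol use. A rough molar rate uses the empirical conversion
0.1 fmol FU^-1.

Cell volume treats the cell as a prolate spheroid with circular
cross-section, the only ellipsoid determinable from length and projected
area alone: W = 4*Area/(pi*L), V = (pi/6)*L*W^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .cytometry import CellMeasurement
from .imaging_io import FieldImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuantConfig:
    """Quantification constants: FU-to-fmol conversion and incubation handling."""

    conversion_fmol_per_FU: float = 0.1
    incubation_h: float = 3.0
    normalize_by_incubation: bool = False

    def __post_init__(self) -> None:
        if self.conversion_fmol_per_FU <= 0 or self.incubation_h <= 0:
            raise ValueError("conversion factor and incubation time must be positive")


@dataclass(frozen=True)
class CellActivity:
    """Per-cell FLEA result: activity in FU and fmol, plus spheroid geometry."""

    cell_id: int
    field_id: str
    felfa_FU_per_cell_per_h: float
    activity_fmol_per_cell_per_h: float
    volume_um3: float
    length_um: float
    width_um: float
    area_um2: float
    centroid_px: tuple[float, float]

    def __post_init__(self) -> None:
        if self.felfa_FU_per_cell_per_h < 0:
            raise ValueError("F_ELFA must be nonnegative (clamped upstream)")
        if self.volume_um3 <= 0 or self.width_um <= 0:
            raise ValueError("volume and width must be positive")
        if self.width_um > self.length_um * (1 + 1e-12):
            raise ValueError("width must not exceed length")


def compute_felfa(
    m: CellMeasurement, field: FieldImage, cfg: QuantConfig | None = None
) -> float:
    """F_ELFA for one cell; negative net gray is clamped to zero.

    A cell cannot hydrolyse substrate negatively, so MGrey < BgMGrey (a
    background fluctuation) yields 0; callers batching cells should count
    clamps for QC (see :func:`quantify_cells`).
    """
    cfg = cfg or QuantConfig()
    if not field.exposure_ms_elfa > 0 or not field.calibration_factor > 0:
        raise ValueError("exposure and calibration factor must be positive")
    net = m.mean_gray_elfa - m.bg_mean_gray_elfa
    felfa = m.area_um2 * net / (field.exposure_ms_elfa * field.calibration_factor)
    if cfg.normalize_by_incubation:
        felfa /= cfg.incubation_h
    return max(0.0, felfa)


def to_fmol(felfa_FU: float, cfg: QuantConfig | None = None) -> float:
    """Convert FU cell^-1 h^-1 to fmol cell^-1 h^-1 (default 0.1 fmol FU^-1)."""
    if felfa_FU < 0:
        raise ValueError("F_ELFA must be nonnegative")
    cfg = cfg or QuantConfig()
    return felfa_FU * cfg.conversion_fmol_per_FU


def cell_volume(length_um: float, area_um2: float) -> float:
    """Prolate-spheroid volume (um^3) from cell length and projected area.

    The projected ellipse has area pi/4 * L * W, so W = 4*Area/(pi*L); the
    spheroid volume is (pi/6) * L * W^2. If the derived width exceeds the
    length (length was actually the minor axis), the axes are swapped with a
    warning.
    """
    if length_um <= 0 or area_um2 <= 0:
        raise ValueError("length and area must be positive")
    width = 4.0 * area_um2 / (math.pi * length_um)
    if width > length_um:
        logger.warning(
            "derived width %.3g exceeds length %.3g; swapping axes", width, length_um
        )
        length_um, width = width, length_um
    return math.pi / 6.0 * length_um * width**2


def quantify_cells(
    cells: list[CellMeasurement],
    field: FieldImage,
    cfg: QuantConfig | None = None,
) -> list[CellActivity]:
    """Quantify a field's measured cells; logs how many were clamped to zero."""
    cfg = cfg or QuantConfig()
    out: list[CellActivity] = []
    n_clamped = 0
    for m in cells:
        felfa = compute_felfa(m, field, cfg)
        if m.mean_gray_elfa < m.bg_mean_gray_elfa:
            n_clamped += 1
        width = 4.0 * m.area_um2 / (math.pi * m.length_um)
        length = m.length_um
        if width > length:
            length, width = width, length
        out.append(
            CellActivity(
                cell_id=m.cell_id,
                field_id=m.field_id,
                felfa_FU_per_cell_per_h=felfa,
                activity_fmol_per_cell_per_h=to_fmol(felfa, cfg),
                volume_um3=cell_volume(m.length_um, m.area_um2),
                length_um=length,
                width_um=width,
                area_um2=m.area_um2,
                centroid_px=m.centroid_px,
            )
        )
    if n_clamped:
        logger.info(
            "field %s: clamped %d/%d cells with MGrey < BgMGrey to zero",
            field.field_id,
            n_clamped,
            len(cells),
        )
    return out
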