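"""Cell segmentation and per-cell gray-level measurement.

Cells are located on the chlorophyll-autofluorescence channel (the study did
this by manual demarcation in imaging software; here it is automated with an
Otsu threshold and connected-component labelling, validated against synthetic
ground truth). Geometry and ELFA gray statistics are then measured per cell:
projected area, major-axis length, mean ELFA gray over the mask (MGrey), and
the per-field background gray (BgMGrey) from pixels outside all cell masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import dilation, disk
from skimage.segmentation import clear_border

from .imaging_io import FieldImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CellMeasurement:
    """Geometry and gray-level statistics of one segmented cell."""

    cell_id: int
    field_id: str
    area_um2: float
    length_um: float
    mean_gray_elfa: float
    bg_mean_gray_elfa: float
    centroid_px: tuple[float, float]

    def __post_init__(self) -> None:
        if self.area_um2 <= 0 or self.length_um <= 0:
            raise ValueError("area and length must be positive")
        if self.mean_gray_elfa < 0 or self.bg_mean_gray_elfa < 0:
            raise ValueError("gray levels must be nonnegative")


def segment_cells(
    field: FieldImage,
    min_equiv_diameter_um: float = 2.0,
    border_policy: str = "exclude",
    threshold: str | float = "otsu",
) -> np.ndarray:
    """Label cells on the chlorophyll channel.

    Thresholds the chlorophyll raster (Otsu by default, or a fixed absolute
    value), labels connected components, drops objects whose area-equivalent
    diameter is below ``min_equiv_diameter_um`` (default 2 um — the sample
    filters retain nothing smaller) and, under the default border policy,
    removes objects touching the image border. Returns a label raster with
    labels 1..n; an all-flat image yields an empty labelling.
    """
    img = field.chl
    if img.size == 0:
        raise ValueError("empty chlorophyll raster")
    if border_policy not in ("exclude", "keep"):
        raise ValueError(f"unknown border policy {border_policy!r}")
    if img.min() == img.max():
        return np.zeros(field.shape, dtype=np.int32)
    if threshold == "otsu":
        thr = threshold_otsu(img)
    else:
        thr = float(threshold)
    mask = img > thr
    if border_policy == "exclude":
        mask = clear_border(mask)
    labels = cc_label(mask, connectivity=2)
    min_area_px = np.pi / 4.0 * (min_equiv_diameter_um / field.pixel_size_um) ** 2
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for p in regionprops(labels):
        keep[p.label] = p.area >= min_area_px
    mask_keep = keep[labels]
    return cc_label(mask_keep, connectivity=2).astype(np.int32)


def measure_cells(
    field: FieldImage,
    labels: np.ndarray,
    background: str = "median",
    bg_exclusion_dilation_px: int = 2,
) -> list[CellMeasurement]:
    """Measure geometry and ELFA grays for every labelled cell.

    Per cell: projected area (pixel count x pixel_size^2, um^2), length
    (major axis of the moment-matched ellipse, um) and MGrey (mean ELFA gray
    over the mask). BgMGrey is estimated once per field from ELFA pixels
    outside the union of all masks dilated by ``bg_exclusion_dilation_px``;
    the default statistic is the median (robust to stray fluorescent
    precipitates), with ``background="mean"`` available. Labels smaller than
    4 px are skipped with a warning.
    """
    labels = np.asarray(labels)
    if labels.shape != field.shape:
        raise ValueError("label raster does not match field shape")
    if background not in ("median", "mean"):
        raise ValueError(f"unknown background statistic {background!r}")

    bg_mask = ~dilation(labels > 0, disk(bg_exclusion_dilation_px))
    if not bg_mask.any():
        raise ValueError("no background pixels left after mask dilation")
    bg_pixels = field.elfa[bg_mask]
    bg_gray = float(np.median(bg_pixels) if background == "median" else bg_pixels.mean())

    px = field.pixel_size_um
    out: list[CellMeasurement] = []
    for p in regionprops(labels, intensity_image=field.elfa):
        if p.area < 4:
            logger.warning(
                "field %s: label %d has %d px (<4); skipped", field.field_id, p.label, p.area
            )
            continue
        out.append(
            CellMeasurement(
                cell_id=int(p.label),
                field_id=field.field_id,
                area_um2=float(p.area) * px * px,
                length_um=float(p.axis_major_length) * px,
                mean_gray_elfa=float(p.intensity_mean),
                bg_mean_gray_elfa=bg_gray,
                centroid_px=(float(p.centroid[0]), float(p.centroid[1])),
            )
        )
    return out


def subsample_cells(
    cells: list[CellMeasurement],
    k_range: tuple[int, int] = (3, 6),
    seed: int = 0,
) -> list[CellMeasurement]:
    """Randomly keep 3-6 cells per field, as in the study's manual workflow.

    For each field a count k is drawn uniformly from ``k_range`` (truncated
    to the field's cell count) and that many cells are sampled without
    replacement. Reproducible for a fixed seed; field order and within-field
    order are preserved.
    """
    k_lo, k_hi = k_range
    if not 0 <= k_lo <= k_hi:
        raise ValueError("k_range must satisfy 0 <= min <= max")
    rng = np.random.default_rng(seed)
    by_field: dict[str, list[CellMeasurement]] = {}
    for c in cells:
        by_field.setdefault(c.field_id, []).append(c)
    out: list[CellMeasurement] = []
    for fid in by_field:
        group = by_field[fid]
        k = min(int(rng.integers(k_lo, k_hi + 1)), len(group))
        idx = sorted(rng.choice(len(group), size=k, replace=False))
        out.extend(group[i] for i in idx)
    return out
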