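"""Synthetic microscope fields and culture series with known ground truth.

The generator emulates the study system: unicellular green algae
(*Coccomyxa*) grown in six treatments — inorganic (I1-I3) or organic (O1-O3)
phosphorus at one replete and two depleted concentrations — labelled with the
fluorogenic phosphatase substrate ELF97 phosphate and imaged in two channels.
Cells are prolate spheroids rendered as filled ellipses on the chlorophyll
channel; the ELFA channel carries, over each cell mask, exactly the gray-level
signal that inverts the fluorescence equation

    F_ELFA = Area * (MGrey - BgMGrey) / (T_exp * F_cal)

to that cell's ground-truth activity (in relative fluorescence units, FU
cell^-1 h^-1). Integer gray levels are dithered across the mask so that the
mask *sum* equals the target to within half a gray level, making noise-free
fields an exact oracle for the downstream pipeline.

Growth series emulate semi-continuous culture: exponential growth between
evenly spaced dilution events that reset chlorophyll to its target level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm
from skimage.draw import ellipse as draw_ellipse

from .growth import GrowthSeries
from .imaging_io import FieldImage, write_field, write_cell_table

U16_MAX = 65535


class FieldTooCrowdedError(RuntimeError):
    """Non-overlapping cell placement failed within the retry budget."""


class SaturationError(ValueError):
    """Requested signal exceeds the 16-bit raster range; not silently clipped."""


@dataclass(frozen=True)
class TreatmentSpec:
    """Ground-truth description of one experimental treatment.

    ``activity_median_FU`` is the median single-cell activity of the whole
    population (zero-activity cells included) when ``zero_fraction`` < 0.5;
    when half or more of the cells are inactive the population median is 0 by
    construction, and the value instead gives the median of the active
    (lognormal) subpopulation.
    """

    code: str
    p_source: str
    p_conc_umol_L: float
    activity_median_FU: float
    activity_sigma_log: float
    zero_fraction: float
    cell_length_um_range: tuple[float, float]
    aspect_ratio_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.p_source not in ("inorganic", "organic"):
            raise ValueError(f"p_source must be inorganic|organic, got {self.p_source!r}")
        if not 0 <= self.zero_fraction <= 1:
            raise ValueError("zero_fraction must lie in [0, 1]")
        if self.activity_median_FU < 0 or self.activity_sigma_log < 0:
            raise ValueError("activity parameters must be nonnegative")
        if not 0 < self.cell_length_um_range[0] <= self.cell_length_um_range[1]:
            raise ValueError("cell length range must be positive with min <= max")
        if not 1 <= self.aspect_ratio_range[0] <= self.aspect_ratio_range[1]:
            raise ValueError("aspect ratios must be >= 1 with min <= max")
        if self.p_conc_umol_L <= 0:
            raise ValueError("P concentration must be positive")

    def lognormal_median(self) -> float:
        """Median of the active-cell lognormal component.

        For zero_fraction z < 0.5 the component median is back-calculated so
        that the population median of the zero/lognormal mixture equals
        ``activity_median_FU``: the population median is the lognormal
        quantile at p = (0.5 - z) / (1 - z).
        """
        z, m = self.zero_fraction, self.activity_median_FU
        if z >= 0.5 or m == 0:
            return m
        p = (0.5 - z) / (1.0 - z)
        return m * math.exp(-self.activity_sigma_log * norm.ppf(p))


@dataclass(frozen=True)
class GroundTruthRecord:
    """True geometry and activity of one synthetic cell."""

    field_id: str
    cell_id: int
    center_px: tuple[float, float]
    length_um: float
    width_um: float
    orientation_rad: float
    true_FU_per_cell_per_h: float


@dataclass(frozen=True)
class NoiseParams:
    """Acquisition noise: Poisson shot noise on counts plus Gaussian read noise.

    Both are off by default (noise-free fields are the ground-truth oracle).
    """

    poisson: bool = False
    read_noise_sd: float = 0.0


def default_treatments() -> list[TreatmentSpec]:
    """The six study treatments with activity and size defaults.

    Activity levels are calibrated so the pipeline recovers the study's
    reported medians: depleted variants I3 and O3 at 0.4 and 1.6 FU (0.04 and
    0.16 fmol cell^-1 h^-1 with the 0.1 fmol/FU conversion), and a 10-fold
    organic-over-inorganic ratio at matched depletion (O2 vs I2). P-replete
    cells are sized to a mean volume of ~27 um^3, P-depleted ~45 um^3.
    """
    replete_len, depleted_len = (5.0, 6.8), (6.0, 8.0)
    aspect = (1.8, 2.2)
    return [
        TreatmentSpec("I1", "inorganic", 858.0, 0.01, 0.6, 0.60, replete_len, aspect),
        TreatmentSpec("I2", "inorganic", 16.0, 0.25, 0.7, 0.15, depleted_len, aspect),
        TreatmentSpec("I3", "inorganic", 10.0, 0.40, 0.7, 0.10, depleted_len, aspect),
        TreatmentSpec("O1", "organic", 858.0, 0.05, 0.9, 0.80, replete_len, aspect),
        TreatmentSpec("O2", "organic", 16.0, 2.50, 0.8, 0.02, depleted_len, aspect),
        TreatmentSpec("O3", "organic", 10.0, 1.60, 0.8, 0.02, depleted_len, aspect),
    ]


def _place_cells(
    rng: np.random.Generator,
    n_cells: int,
    shape: tuple[int, int],
    radii_px: np.ndarray,
    margin_px: float = 6.0,
    max_tries: int = 200,
) -> np.ndarray:
    """Rejection-sample non-overlapping cell centres; error when too crowded."""
    centers = np.empty((n_cells, 2))
    for i in range(n_cells):
        r = radii_px[i] + margin_px
        lo = (r, r)
        hi = (shape[0] - r, shape[1] - r)
        if hi[0] <= lo[0] or hi[1] <= lo[1]:
            raise FieldTooCrowdedError(
                f"field {shape} too small for a cell of radius {radii_px[i]:.0f} px"
            )
        for _ in range(max_tries):
            cand = np.array([rng.uniform(lo[0], hi[0]), rng.uniform(lo[1], hi[1])])
            sep = radii_px[:i] + radii_px[i] + 4.0
            if i == 0 or np.all(
                np.hypot(*(centers[:i] - cand).T) >= sep
            ):
                centers[i] = cand
                break
        else:
            raise FieldTooCrowdedError(
                f"could not place cell {i + 1}/{n_cells} in field {shape} "
                f"after {max_tries} tries"
            )
    return centers


def generate_field(
    spec: TreatmentSpec,
    n_cells: int,
    image_shape: tuple[int, int] = (512, 512),
    noise: NoiseParams | None = None,
    seed: int = 0,
    *,
    pixel_size_um: float = 0.11,
    exposure_ms_elfa: float = 500.0,
    calibration_factor: float = 1.0,
    chl_background: int = 50,
    chl_foreground: int = 3000,
    elfa_background: int = 100,
    field_id: str = "field_0",
    slide_id: str = "slide_0",
) -> tuple[FieldImage, list[GroundTruthRecord]]:
    """Render one two-channel field with known per-cell ground truth.

    Cells are non-overlapping filled ellipses; the chlorophyll channel marks
    their extent, and on the ELFA channel each cell's background-subtracted
    gray-level sum is painted to invert the F_ELFA equation to that cell's
    sampled activity. With ``noise=None`` the field is noise-free and the
    pipeline's recovery is exact up to the half-gray-level rounding of the
    mask sum.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)

    lengths = rng.uniform(*spec.cell_length_um_range, size=n_cells)
    aspects = rng.uniform(*spec.aspect_ratio_range, size=n_cells)
    widths = lengths / aspects
    orientations = rng.uniform(0.0, np.pi, size=n_cells)
    active = rng.random(n_cells) >= spec.zero_fraction
    med = spec.lognormal_median()
    fus = np.where(
        active & (med > 0),
        np.exp(rng.normal(np.log(med) if med > 0 else 0.0, spec.activity_sigma_log, n_cells)),
        0.0,
    )

    chl = np.full(image_shape, chl_background, dtype=np.int64)
    elfa = np.full(image_shape, elfa_background, dtype=np.int64)
    records: list[GroundTruthRecord] = []

    if n_cells > 0:
        radii_px = lengths / 2.0 / pixel_size_um
        centers = _place_cells(rng, n_cells, image_shape, radii_px)
        px_area = pixel_size_um**2
        for i in range(n_cells):
            rr, cc = draw_ellipse(
                centers[i, 0],
                centers[i, 1],
                lengths[i] / 2.0 / pixel_size_um,
                widths[i] / 2.0 / pixel_size_um,
                shape=image_shape,
                rotation=orientations[i],
            )
            n_px = rr.size
            chl[rr, cc] = chl_foreground
            # paint the exact mask sum: FU = Area*(MGrey-Bg)/(Texp*Fcal)
            # => sum of net grays = FU*Texp*Fcal/px_area, dithered to integers
            total = int(round(fus[i] * exposure_ms_elfa * calibration_factor / px_area))
            q, r = divmod(total, n_px)
            if elfa_background + q + 1 > U16_MAX:
                raise SaturationError(
                    f"cell {i} needs gray level {elfa_background + q + 1} > {U16_MAX}; "
                    "reduce activity, calibration factor or exposure"
                )
            net = np.full(n_px, q, dtype=np.int64)
            net[:r] += 1
            elfa[rr, cc] += net
            records.append(
                GroundTruthRecord(
                    field_id=field_id,
                    cell_id=i,
                    center_px=(float(centers[i, 0]), float(centers[i, 1])),
                    length_um=float(lengths[i]),
                    width_um=float(widths[i]),
                    orientation_rad=float(orientations[i]),
                    true_FU_per_cell_per_h=float(fus[i]),
                )
            )

    if noise.poisson:
        chl = rng.poisson(chl)
        elfa = rng.poisson(elfa)
    if noise.read_noise_sd > 0:
        chl = np.rint(chl + rng.normal(0.0, noise.read_noise_sd, chl.shape)).astype(np.int64)
        elfa = np.rint(elfa + rng.normal(0.0, noise.read_noise_sd, elfa.shape)).astype(np.int64)
    for name, arr in (("chl", chl), ("elfa", elfa)):
        if (arr < 0).any():
            raise ValueError(
                f"noise parameters drove the {name} channel negative; clipping is "
                "not permitted — lower read_noise_sd or raise the background"
            )
        if arr.max() > U16_MAX:
            raise SaturationError(f"{name} channel exceeds 16-bit range after noise")

    field = FieldImage(
        chl=chl.astype(np.uint16),
        elfa=elfa.astype(np.uint16),
        exposure_ms_elfa=exposure_ms_elfa,
        calibration_factor=calibration_factor,
        pixel_size_um=pixel_size_um,
        field_id=field_id,
        slide_id=slide_id,
    )
    return field, records


def generate_slide(
    spec: TreatmentSpec,
    n_fields: int = 30,
    cells_per_field: int = 5,
    seed: int = 0,
    slide_id: str | None = None,
    noise: NoiseParams | None = None,
    **field_kwargs,
) -> tuple[list[FieldImage], list[GroundTruthRecord]]:
    """Generate a slide's worth of fields (the study imaged 30 per slide)."""
    slide_id = slide_id or f"slide_{spec.code}"
    rng = np.random.default_rng(seed)
    field_seeds = rng.integers(0, 2**31 - 1, size=n_fields)
    fields, records = [], []
    for k in range(n_fields):
        f, recs = generate_field(
            spec,
            cells_per_field,
            noise=noise,
            seed=int(field_seeds[k]),
            field_id=f"field_{k}",
            slide_id=slide_id,
            **field_kwargs,
        )
        fields.append(f)
        records.extend(recs)
    return fields, records


def write_slide(
    fields: Sequence[FieldImage],
    records: Sequence[GroundTruthRecord],
    directory: str | Path,
) -> Path:
    """Write paired TIFFs + sidecars per field and a ground-truth CSV manifest."""
    directory = Path(directory)
    for f in fields:
        write_field(f, directory)
    manifest = directory / "ground_truth.csv"
    write_cell_table(list(records), manifest)
    return manifest


def generate_growth_series(
    mu_per_day: float,
    chl_target_ug_L: float = 10.0,
    n_dilutions: int = 3,
    duration_days: float = 21.0,
    sampling_interval_days: float = 1.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> GrowthSeries:
    """Simulate a semi-continuously diluted culture's chlorophyll series.

    Between dilutions chlorophyll follows N(t) = N0 * exp(mu * t); at each of
    ``n_dilutions`` evenly spaced events the culture is diluted back to
    ``chl_target_ug_L`` (factor >= 1; no dilution is applied when the culture
    sits at or below target). Observation noise is multiplicative lognormal
    with the given coefficient of variation.
    """
    if any(math.isnan(x) for x in (mu_per_day, chl_target_ug_L, duration_days)):
        raise ValueError("NaN input")
    if duration_days <= 0 or sampling_interval_days <= 0:
        raise ValueError("duration and sampling interval must be positive")
    if n_dilutions < 0 or noise_cv < 0:
        raise ValueError("n_dilutions and noise_cv must be nonnegative")
    if chl_target_ug_L <= 0:
        raise ValueError("chlorophyll target must be positive")

    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_days + 1e-9, sampling_interval_days)
    dil_times = np.array(
        [duration_days * k / (n_dilutions + 1) for k in range(1, n_dilutions + 1)]
    )

    chl = np.empty_like(times)
    level = chl_target_ug_L  # state at the last processed event
    t_ref = 0.0
    applied_factors = []
    dil_iter = list(dil_times)
    next_dil = dil_iter.pop(0) if dil_iter else None
    for i, t in enumerate(times):
        while next_dil is not None and next_dil <= t:
            at_dil = level * math.exp(mu_per_day * (next_dil - t_ref))
            factor = max(1.0, at_dil / chl_target_ug_L)
            level = at_dil / factor
            t_ref = next_dil
            applied_factors.append(factor)
            next_dil = dil_iter.pop(0) if dil_iter else None
        chl[i] = level * math.exp(mu_per_day * (t - t_ref))
    # dilutions after the last sample never occur (times cover the duration)
    while len(applied_factors) < dil_times.size:
        at_dil = level * math.exp(mu_per_day * (dil_times[len(applied_factors)] - t_ref))
        applied_factors.append(max(1.0, at_dil / chl_target_ug_L))

    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        chl = chl * rng.lognormal(-0.5 * sigma**2, sigma, size=chl.size)

    return GrowthSeries(
        times_days=times,
        chl_ug_L=chl,
        dilution_times_days=dil_times,
        dilution_factors=np.asarray(applied_factors),
        conversion=None,
    )
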