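"""End-to-end composition: field images -> per-cell activities.

Thin glue over the cytometry and quantification modules, plus helpers used
by the validation workflow: simulating a whole treatment and matching the
recovered cells back to the generator's ground-truth manifest by centroid
proximity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cytometry import measure_cells, segment_cells, subsample_cells
from .flea_quant import QuantConfig, quantify_cells
from .imaging_io import FieldImage, cells_to_frame
from .synthetic_data import GroundTruthRecord, NoiseParams, TreatmentSpec, generate_slide


def quantify_field(
    field: FieldImage,
    cfg: QuantConfig | None = None,
    **segment_kwargs,
):
    """Segment, measure and quantify one field; returns list of CellActivity."""
    labels = segment_cells(field, **segment_kwargs)
    measured = measure_cells(field, labels)
    return quantify_cells(measured, field, cfg)


def simulate_treatment(
    spec: TreatmentSpec,
    n_fields: int = 30,
    cells_per_field: int = 12,
    seed: int = 0,
    noise: NoiseParams | None = None,
    subsample: tuple[int, int] | None = None,
    cfg: QuantConfig | None = None,
    **field_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a treatment's slide and run the full recovery pipeline.

    Returns ``(recovered, truth)`` DataFrames; ``recovered`` holds one row
    per pipeline-quantified cell, ``truth`` one row per generated cell. With
    ``subsample=(k_lo, k_hi)`` only 3-6 cells per field are kept, mimicking
    the study's manual workflow.
    """
    fields, records = generate_slide(
        spec,
        n_fields=n_fields,
        cells_per_field=cells_per_field,
        seed=seed,
        noise=noise,
        **field_kwargs,
    )
    activities = []
    for f in fields:
        labels = segment_cells(f)
        measured = measure_cells(f, labels)
        if subsample is not None:
            measured = subsample_cells(measured, k_range=subsample, seed=seed)
        activities.extend(quantify_cells(measured, f, cfg))
    recovered = cells_to_frame(activities)
    truth = cells_to_frame(records)
    return recovered, truth


def match_to_ground_truth(
    recovered: pd.DataFrame, truth: pd.DataFrame, max_dist_px: float = 5.0
) -> pd.DataFrame:
    """Join recovered cells to ground truth by nearest centroid within a field.

    Returns the recovered table augmented with the matched truth columns
    (suffix ``_true``); raises if any recovered cell has no ground-truth
    partner within ``max_dist_px``.
    """
    out_rows = []
    for fid, group in recovered.groupby("field_id", sort=False):
        t = truth[truth["field_id"] == fid]
        if t.empty:
            raise ValueError(f"no ground truth for field {fid}")
        t_pos = t[["center_px_row", "center_px_col"]].to_numpy()
        for _, row in group.iterrows():
            d = np.hypot(
                t_pos[:, 0] - row["centroid_px_row"],
                t_pos[:, 1] - row["centroid_px_col"],
            )
            j = int(np.argmin(d))
            if d[j] > max_dist_px:
                raise ValueError(
                    f"cell at {row['centroid_px_row']:.0f},{row['centroid_px_col']:.0f} "
                    f"in {fid}: nearest ground truth {d[j]:.1f} px away"
                )
            merged = row.to_dict()
            merged.update({f"{k}_true": v for k, v in t.iloc[j].to_dict().items()})
            out_rows.append(merged)
    return pd.DataFrame(out_rows)
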