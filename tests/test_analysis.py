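"""Geometric-class distributions, factorial ANOVA and order statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fleacyte import (
    average_distributions,
    build_distribution,
    compare_treatments,
    summarize_activity,
)
from fleacyte.flea_quant import CellActivity


def make_activity(fu, cell_id=0):
    return CellActivity(
        cell_id=cell_id,
        field_id="f0",
        felfa_FU_per_cell_per_h=fu,
        activity_fmol_per_cell_per_h=0.1 * fu,
        volume_um3=30.0,
        length_um=7.0,
        width_um=3.5,
        area_um2=19.0,
        centroid_px=(0.0, 0.0),
    )


def make_design(values_fn, n_reps=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s, m, p in itertools.product(("sp_a", "sp_b"), ("I", "O"), ("1", "2", "3")):
        for _ in range(n_reps):
            rows.append(
                {"species": s, "medium": m, "p_level": p, "resp": values_fn(s, m, p, rng)}
            )
    return pd.DataFrame(rows)


class TestBuildDistribution:
    def test_all_zero_activities_fill_the_zero_class(self):
        dist = build_distribution([make_activity(0.0, i) for i in range(10)])
        assert dist.zero_class_pct == 100.0
        assert dist.underflow_pct == 0.0 and dist.bin_pcts.sum() == 0.0

    def test_single_cell_lands_in_expected_geometric_class(self):
        # 0.02 * 2^4 = 0.32 < 0.5 <= 0.64 = 0.02 * 2^5
        dist = build_distribution([make_activity(0.5)])
        k = int(np.nonzero(dist.bin_pcts)[0][0])
        assert (dist.bin_edges_FU[k], dist.bin_edges_FU[k + 1]) == (0.32, 0.64)
        assert dist.bin_pcts[k] == 100.0

    def test_edge_value_belongs_to_lower_class(self):
        # intervals are (edge_k, edge_{k+1}]: exactly 0.64 stays in (0.32, 0.64]
        dist = build_distribution([make_activity(0.64)], n_bins=6)
        k = int(np.nonzero(dist.bin_pcts)[0][0])
        assert dist.bin_edges_FU[k + 1] == pytest.approx(0.64)

    def test_sub_base_activity_goes_to_underflow_class(self):
        dist = build_distribution([make_activity(0.01)])
        assert dist.underflow_pct == 100.0

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=50.0, allow_nan=False), min_size=1, max_size=60
        )
    )
    def test_percentages_always_sum_to_100(self, values):
        acts = [make_activity(v, i) for i, v in enumerate(values)]
        dist = build_distribution(acts)
        assert dist.percentages().sum() == pytest.approx(100.0, abs=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.floats(min_value=1e-6, max_value=100.0),
        b=st.floats(min_value=1e-6, max_value=100.0),
    )
    def test_bin_assignment_is_order_preserving(self, a, b):
        lo, hi = sorted([a, b])
        dist = build_distribution([make_activity(lo, 0), make_activity(hi, 1)], n_bins=15)
        idx = np.nonzero(dist.bin_pcts)[0]
        edges = dist.bin_edges_FU
        bin_of = lambda v: int(np.searchsorted(edges, v, side="left") - 1)
        assert bin_of(hi) >= bin_of(lo)

    def test_averaging_replicate_distributions(self):
        reps = [
            build_distribution([make_activity(v, i) for i, v in enumerate(vals)], n_bins=8)
            for vals in ([0.0, 0.5, 0.5], [0.5, 0.5, 0.5], [0.0, 0.0, 0.5])
        ]
        edges, mean_pct, sd_pct = average_distributions(reps)
        assert mean_pct.sum() == pytest.approx(100.0)
        # zero class: mean of (33.3, 0, 66.7)
        assert mean_pct[0] == pytest.approx(100.0 / 3)
        assert sd_pct.shape == mean_pct.shape

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_distribution([])


class TestCompareTreatments:
    def test_degrees_of_freedom_of_full_factorial(self):
        tbl = make_design(lambda s, m, p, rng: rng.uniform(0.5, 1.5))
        rep = compare_treatments(tbl, "resp")
        assert rep.df_by_factor == (1, 1, 2, 1, 2, 2, 2)
        assert int(rep.anova.loc["Residual", "df"]) == 24

    def test_constant_response_has_no_effect_sums_of_squares(self):
        tbl = make_design(lambda s, m, p, rng: 1.0)
        rep = compare_treatments(tbl, "resp", tukey=False)
        assert np.allclose(rep.anova["sum_sq"][:7], 0.0, atol=1e-12)

    def test_planted_medium_effect_detected(self):
        tbl = make_design(
            lambda s, m, p, rng: rng.normal(1.0 if m == "I" else 3.0, 0.2), seed=3
        )
        rep = compare_treatments(tbl, "resp")
        assert rep.anova.loc["M", "p"] < 0.05
        assert rep.anova.loc["S", "p"] > 0.05
        # Tukey separates the medium groups at matched concentration
        sig = rep.tukey[rep.tukey["reject"]]
        assert {"I1", "O1"} in [set(x) for x in sig[["group1", "group2"]].to_numpy()]

    def test_missing_design_cells_listed(self):
        tbl = make_design(lambda s, m, p, rng: rng.uniform(0.5, 1.5))
        tbl = tbl[~((tbl.species == "sp_a") & (tbl.medium == "O") & (tbl.p_level == "2"))]
        with pytest.raises(ValueError, match="sp_a.*O.*2"):
            compare_treatments(tbl, "resp")

    def test_negative_response_rejected(self):
        tbl = make_design(lambda s, m, p, rng: -1.0)
        with pytest.raises(ValueError, match="nonnegative"):
            compare_treatments(tbl, "resp")


class TestSummarizeActivity:
    def test_constant_sample_collapses_all_quantiles(self):
        s = summarize_activity([make_activity(2.0, i) for i in range(20)])
        assert s["p10_FU"] == s["median_FU"] == s["p90_FU"] == 2.0

    def test_linear_interpolation_median_of_1_to_100(self):
        s = summarize_activity([make_activity(float(v), v) for v in range(1, 101)])
        assert s["median_FU"] == pytest.approx(50.5)
        assert s["q25_FU"] == pytest.approx(25.75)

    def test_fmol_median_is_scaled_fu_median(self):
        s = summarize_activity([make_activity(float(v), v) for v in range(1, 11)])
        assert s["median_fmol"] == pytest.approx(0.1 * s["median_FU"])
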