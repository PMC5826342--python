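"""Synthetic field and growth-series generators against closed-form oracles."""

import math

import numpy as np
import pytest

from fleacyte import (
    NoiseParams,
    TreatmentSpec,
    default_treatments,
    generate_field,
    generate_growth_series,
    growth_rate,
)
from fleacyte.synthetic_data import FieldTooCrowdedError, SaturationError


def make_spec(**over):
    base = dict(
        code="I3",
        p_source="inorganic",
        p_conc_umol_L=10.0,
        activity_median_FU=0.4,
        activity_sigma_log=0.7,
        zero_fraction=0.1,
        cell_length_um_range=(6.0, 8.0),
        aspect_ratio_range=(1.8, 2.2),
    )
    base.update(over)
    return TreatmentSpec(**base)


class TestGenerateField:
    def test_empty_field_is_flat_background(self):
        field, records = generate_field(make_spec(), 0, seed=0)
        assert records == []
        assert np.all(field.chl == field.chl.flat[0])
        assert np.all(field.elfa == field.elfa.flat[0])

    def test_all_inactive_cells_leave_elfa_at_background(self):
        field, records = generate_field(make_spec(zero_fraction=1.0), 8, seed=1)
        assert len(records) == 8
        assert all(r.true_FU_per_cell_per_h == 0 for r in records)
        assert np.all(field.elfa == field.elfa.flat[0])

    def test_painted_grays_invert_fluorescence_equation(self, uniform_spec):
        """Hand arithmetic on the raw rasters recovers true FU = 10 within 2%."""
        field, records = generate_field(
            uniform_spec, 1, seed=3, exposure_ms_elfa=500.0, calibration_factor=1.0
        )
        assert records[0].true_FU_per_cell_per_h == pytest.approx(10.0, rel=1e-12)
        mask = field.chl > field.chl.min()
        bg = np.median(field.elfa[~mask])
        area_um2 = mask.sum() * field.pixel_size_um**2
        mgrey = field.elfa[mask].mean()
        felfa = area_um2 * (mgrey - bg) / (500.0 * 1.0)
        assert felfa == pytest.approx(10.0, rel=0.02)

    def test_seed_determinism(self):
        spec = make_spec()
        f1, r1 = generate_field(spec, 6, seed=11)
        f2, r2 = generate_field(spec, 6, seed=11)
        assert np.array_equal(f1.chl, f2.chl) and np.array_equal(f1.elfa, f2.elfa)
        assert r1 == r2
        f3, _ = generate_field(spec, 6, seed=12)
        assert not np.array_equal(f1.chl, f3.chl)

    def test_painted_signal_linear_in_exposure(self, uniform_spec):
        f1, _ = generate_field(uniform_spec, 3, seed=5, exposure_ms_elfa=500.0)
        f2, _ = generate_field(uniform_spec, 3, seed=5, exposure_ms_elfa=1000.0)
        net1 = f1.elfa.astype(int) - 100
        net2 = f2.elfa.astype(int) - 100
        assert net2.sum() == pytest.approx(2 * net1.sum(), abs=3)

    def test_noise_determinism_and_nonnegativity(self):
        noise = NoiseParams(poisson=True, read_noise_sd=2.0)
        f1, _ = generate_field(make_spec(), 4, noise=noise, seed=9)
        f2, _ = generate_field(make_spec(), 4, noise=noise, seed=9)
        assert np.array_equal(f1.elfa, f2.elfa)

    def test_overcrowded_field_raises(self):
        with pytest.raises(FieldTooCrowdedError):
            generate_field(make_spec(), 50, image_shape=(128, 128), seed=0)

    def test_saturating_activity_raises_not_clips(self, uniform_spec):
        hot = make_spec(activity_median_FU=1e4, activity_sigma_log=0.0, zero_fraction=0.0)
        with pytest.raises(SaturationError):
            generate_field(hot, 1, seed=0)

    def test_noise_driving_raster_negative_is_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            generate_field(
                make_spec(), 2, noise=NoiseParams(read_noise_sd=60.0), seed=0
            )


class TestDefaultTreatments:
    def test_six_treatments_with_study_concentrations(self):
        specs = default_treatments()
        assert [s.code for s in specs] == ["I1", "I2", "I3", "O1", "O2", "O3"]
        assert {s.p_conc_umol_L for s in specs} == {858.0, 16.0, 10.0}
        assert all(
            s.p_source == ("inorganic" if s.code.startswith("I") else "organic")
            for s in specs
        )

    def test_depleted_medians_match_reported_fmol(self):
        specs = {s.code: s for s in default_treatments()}
        assert specs["I3"].activity_median_FU * 0.1 == pytest.approx(0.04)
        assert specs["O3"].activity_median_FU * 0.1 == pytest.approx(0.16)

    def test_organic_over_inorganic_depleted_ratio_is_tenfold(self):
        specs = {s.code: s for s in default_treatments()}
        assert specs["O2"].activity_median_FU / specs["I2"].activity_median_FU == 10

    def test_population_median_calibration(self):
        """Sampled zero/lognormal mixture has the spec'd population median."""
        spec = make_spec(activity_median_FU=0.4, zero_fraction=0.1)
        rng = np.random.default_rng(0)
        n = 200_000
        active = rng.random(n) >= spec.zero_fraction
        vals = np.where(
            active,
            rng.lognormal(np.log(spec.lognormal_median()), spec.activity_sigma_log, n),
            0.0,
        )
        assert np.median(vals) == pytest.approx(0.4, rel=0.01)


class TestGenerateGrowthSeries:
    def test_zero_growth_noise_free_is_constant(self):
        s = generate_growth_series(0.0, 10.0, 3, 21.0, 1.0, 0.0, seed=0)
        assert np.allclose(s.chl_ug_L, s.chl_ug_L[0])
        assert np.all(s.dilution_factors == 1.0)

    def test_density_ratio_follows_exponential_closed_form(self):
        # one dilution at day 7; growth from there for another 7 days
        s = generate_growth_series(0.17, 10.0, 1, 14.0, 1.0, 0.0, seed=0)
        i7 = int(np.argmin(np.abs(s.times_days - 7.0)))
        i14 = int(np.argmin(np.abs(s.times_days - 14.0)))
        assert s.chl_ug_L[i14] / s.chl_ug_L[i7] == pytest.approx(math.exp(0.17 * 7))

    def test_dilution_factors_reset_to_target(self):
        s = generate_growth_series(0.17, 10.0, 3, 21.0, 0.25, 0.0, seed=0)
        # factor for an inter-dilution gap of 21/4 days
        assert np.allclose(s.dilution_factors, math.exp(0.17 * 21 / 4))

    def test_negative_growth_declines_without_dilution(self):
        s = generate_growth_series(-0.1, 10.0, 2, 12.0, 1.0, 0.0, seed=0)
        assert np.all(np.diff(s.chl_ug_L) < 0)
        assert np.all(s.dilution_factors == 1.0)

    def test_seeded_noise_is_reproducible(self):
        a = generate_growth_series(0.1, 10.0, 3, 21.0, 1.0, 0.2, seed=4)
        b = generate_growth_series(0.1, 10.0, 3, 21.0, 1.0, 0.2, seed=4)
        assert np.array_equal(a.chl_ug_L, b.chl_ug_L)

    def test_nan_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_growth_series(float("nan"), 10.0, 3, 21.0, 1.0, 0.0, seed=0)

    def test_generated_series_feeds_growth_estimator(self):
        s = generate_growth_series(0.17, 10.0, 3, 21.0, 1.0, 0.0, seed=0)
        assert growth_rate(s) == pytest.approx(0.17, abs=1e-12)
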