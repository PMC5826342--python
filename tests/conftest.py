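import pytest

from fleacyte import TreatmentSpec, default_treatments, generate_slide


@pytest.fixture(scope="session")
def treatments():
    return {s.code: s for s in default_treatments()}


@pytest.fixture(scope="session")
def uniform_spec():
    """Deterministic activity: every cell at exactly 10 FU, no zeros."""
    return TreatmentSpec(
        code="I3",
        p_source="inorganic",
        p_conc_umol_L=10.0,
        activity_median_FU=10.0,
        activity_sigma_log=0.0,
        zero_fraction=0.0,
        cell_length_um_range=(6.0, 6.0),
        aspect_ratio_range=(2.0, 2.0),
    )


@pytest.fixture(scope="session")
def small_slide(treatments):
    """Five noise-free fields of the high-P-depletion inorganic treatment."""
    return generate_slide(treatments["I3"], n_fields=5, cells_per_field=5, seed=7)
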