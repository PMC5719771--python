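"""Shared fixtures.  Monte Carlo fixtures are session-scoped so expensive
runs are computed once and reused across test modules."""

import numpy as np
import pytest

from lungpdd.comparison import normalize_pdd
from lungpdd.mc_engine import (
    BeamConfig,
    PhantomStack,
    TransportOptions,
    default_scoring_radius,
    homogeneous_beam_data,
    simulate_depth_dose,
)
from lungpdd.synthetic_data import make_reference_phantom, synthesize_spectrum


@pytest.fixture(scope="session")
def spectrum15():
    return synthesize_spectrum(15.0)


@pytest.fixture(scope="session")
def reference_phantom():
    return make_reference_phantom()


@pytest.fixture(scope="session")
def water_phantom():
    return PhantomStack((("water", 30.0),))


@pytest.fixture(scope="session")
def beam_10x10(spectrum15):
    return BeamConfig(spectrum=spectrum15, square_side_cm=10.0)


@pytest.fixture(scope="session")
def beam_1x1(spectrum15):
    return BeamConfig(spectrum=spectrum15, square_side_cm=1.0)


@pytest.fixture(scope="session")
def hom_10x10_profile(water_phantom, beam_10x10):
    """Homogeneous-water 10x10 cm^2 run, wide scoring cylinder."""
    opts = TransportOptions(n_histories=800_000, seed=421,
                            scoring_radius_cm=2.8)
    return simulate_depth_dose(water_phantom, beam_10x10, opts)


@pytest.fixture(scope="session")
def mc_beam_data_small(beam_1x1):
    """MC beam data covering the small-field radii (for 1x1 corrections)."""
    return homogeneous_beam_data(
        beam_1x1, TransportOptions(n_histories=500_000, seed=422),
        field_sides_cm=(0.25, 0.5, 1.0),
    )


@pytest.fixture(scope="session")
def mc_beam_data_clinical(beam_10x10):
    """MC beam data on clinically sized fields (2, 5, 10 cm sides)."""
    return homogeneous_beam_data(
        beam_10x10, TransportOptions(n_histories=400_000, seed=425),
        field_sides_cm=(2.0, 5.0, 10.0),
    )


@pytest.fixture(scope="session")
def het_1x1_pdd(reference_phantom, beam_1x1):
    """Heterogeneous-phantom 1x1 cm^2 PDD, chip-area scoring."""
    opts = TransportOptions(n_histories=800_000, seed=423)
    return normalize_pdd(simulate_depth_dose(reference_phantom, beam_1x1, opts))


@pytest.fixture(scope="session")
def hom_1x1_pdd(water_phantom, beam_1x1):
    opts = TransportOptions(
        n_histories=800_000, seed=424,
        scoring_radius_cm=default_scoring_radius(beam_1x1.equivalent_radius_cm),
    )
    return normalize_pdd(simulate_depth_dose(water_phantom, beam_1x1, opts))
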