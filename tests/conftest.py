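"""Shared fixtures: one ground-truthed synthetic landscape per session."""

import pytest

from landconvert.synthetic import (
    SyntheticScenario,
    attach_overlay_truth,
    generate_conservation_layers,
    generate_landscape,
    generate_species_ranges,
)
from landconvert.transitions import detect_transitions


@pytest.fixture(scope="session")
def scenario():
    return SyntheticScenario(
        grid_shape=(80, 80),
        cell_size=100.0,
        nodata_fraction=0.02,
        n_pas=6,
        n_kbas=3,
        n_zones=3,
        n_species=25,
        seed=11,
    )


@pytest.fixture(scope="session")
def landscape(scenario):
    return generate_landscape(scenario)


@pytest.fixture(scope="session")
def layers(scenario, landscape):
    t0, _, _ = landscape
    pas, kbas, zones = generate_conservation_layers(scenario, t0)
    species = generate_species_ranges(scenario, t0)
    return pas, kbas, zones, species


@pytest.fixture(scope="session")
def truth(scenario, landscape, layers):
    t0, t1, gt = landscape
    pas, _, _, species = layers
    return attach_overlay_truth(gt, t0, t1, pas=pas, species=species)


@pytest.fixture(scope="session")
def transition(landscape):
    t0, t1, _ = landscape
    return detect_transitions(t0, t1)
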