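import pytest

from trophicast.core import Guild, SpeciesProfile, Tissue
from trophicast.synthetic import (
    generate_environment,
    generate_foodweb,
    noise_free_scenario,
)


@pytest.fixture(scope="session")
def scenario():
    """Four-country zero-sum noise-free scenario with exact truth."""
    return noise_free_scenario(seed=0)


@pytest.fixture(scope="session")
def environment(scenario):
    return generate_environment(scenario)


@pytest.fixture(scope="session")
def foodweb(scenario):
    return generate_foodweb(scenario)


@pytest.fixture(scope="session")
def roster(scenario):
    return dict(scenario.species_profiles)


@pytest.fixture
def magnifying_roster():
    """Roster with BTF·IR > 1 at every link, so burdens grow up the chain."""
    return {
        "vole": SpeciesProfile(
            species="vole", guild=Guild.HERBIVORE, bw_kg=0.03, ir_kg_per_day=0.5,
            lipid_fraction=0.05,
            btf_by_tissue={Tissue.LIVER: 4.0, Tissue.MUSCLE: 3.0, Tissue.FAT: 6.0},
            tissue_weights={Tissue.MUSCLE: 0.6, Tissue.FAT: 0.4},
        ),
        "stoat": SpeciesProfile(
            species="stoat", guild=Guild.CARNIVORE, bw_kg=0.3, ir_kg_per_day=0.9,
            lipid_fraction=0.07,
            btf_by_tissue={Tissue.LIVER: 4.0, Tissue.MUSCLE: 3.0, Tissue.FAT: 6.0},
            tissue_weights={Tissue.MUSCLE: 0.6, Tissue.FAT: 0.4},
        ),
    }
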