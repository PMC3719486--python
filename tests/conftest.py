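import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def species_tree():
    from famwave.trees import default_species_tree

    return default_species_tree()


@pytest.fixture(scope="session")
def toy_species_tree():
    """Four species, two clades: ((M1,M2)NM,(E1,E2)NE)R."""
    from famwave.trees import SpeciesTree

    return SpeciesTree.from_newick("((M1:1,M2:1)NM:1,(E1:1,E2:1)NE:1)R;")
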