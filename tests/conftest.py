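import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phosflow.model import PhosphoSite
from phosflow.simulate import SimConfig, simulate_study

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_study():
    """The default-size synthetic study (~2300 sites, 20 kinases, 5 planted
    activity shifts) shared by the heavier recovery tests."""
    return simulate_study(SimConfig(seed=101))


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for fast structural tests."""
    return simulate_study(SimConfig(seed=7, n_proteins=250))


def dummy_site(protein_id: str, position: int, residue: str) -> PhosphoSite:
    """A site with an all-padding window, for count-only statistics."""
    return PhosphoSite(protein_id, position, residue, "_" * 6 + residue + "_" * 6)
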