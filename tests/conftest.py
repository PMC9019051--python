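import numpy as np
import pytest

from prochir.dynamics import FSSHParams, run_swarm
from prochir.fixtures import make_fixtures
from prochir.pes import preset
from prochir.wigner import PhaseSpaceEnsemble, model_well_modes, sample_wigner, subselect


@pytest.fixture(scope="session")
def stilbene():
    return preset("stilbene")


@pytest.fixture(scope="session")
def stiff_stilbene():
    return preset("stiff_stilbene")


@pytest.fixture(scope="session")
def fixture_set():
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def p_ensemble(stilbene):
    """30 Wigner ICs subselected from 500 around the P well."""
    modes = model_well_modes(stilbene, "P")
    return subselect(sample_wigner(modes, 500, seed=42), 30, seed=43)


def mirror_ensemble(ens):
    return PhaseSpaceEnsemble(
        positions=-ens.positions,
        momenta=-ens.momenta,
        seed=ens.seed,
        provenance={**ens.provenance, "mirrored": True},
    )


@pytest.fixture(scope="session")
def p_swarm(stilbene, p_ensemble):
    """Shared 30-trajectory P-well swarm at default FSSH parameters."""
    return run_swarm(p_ensemble, stilbene, FSSHParams(seed=0), seed_base=7)
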