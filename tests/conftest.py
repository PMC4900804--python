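import numpy as np
import pytest

from allokit import MechanismParams, Protocol
from allokit.synthetic import reference_spectra


@pytest.fixture(scope="session")
def refs():
    return reference_spectra()


@pytest.fixture(scope="session")
def capping_params():
    """Slow-dissociating orthosteric ligand at 100x its K, with a fast,
    strongly negative (alpha = 1000) modulator: the regime in which the
    order in which the two ligands are added controls equilibration."""
    return MechanismParams(k_l=1e-10, k_a=1e-5, alpha=1000.0,
                           k_off_l=5e-4, k_off_a=10.0)


@pytest.fixture(scope="session")
def simultaneous_protocol():
    return Protocol(mode="simultaneous", l_conc=1e-8, post_incubation=1260.0)


def random_mechanism(rng: np.random.Generator) -> MechanismParams:
    """A physically plausible random parameter draw for property suites."""
    return MechanismParams(
        k_l=10.0 ** rng.uniform(-10, -7),
        k_a=10.0 ** rng.uniform(-7, -4),
        alpha=10.0 ** rng.uniform(-1, 2),
        k_off_l=10.0 ** rng.uniform(-3, 0),
        k_off_a=10.0 ** rng.uniform(0, 2),
        j=int(rng.integers(0, 4)),
    )
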