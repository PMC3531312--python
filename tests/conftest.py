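import dataclasses

import pytest

from vaxdss.core import ImmunizationProtocol, Inoculation, Store, VectorRecord
from vaxdss.synthgen import SynthConfig, synth_experiment


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study bundle (noisy), shared read-only."""
    return synth_experiment(SynthConfig(seed=20))


@pytest.fixture(scope="session")
def noiseless_bundle():
    return synth_experiment(SynthConfig(seed=21).noiseless())


@pytest.fixture()
def fresh_bundle():
    """A mutable bundle for tests that revise or import."""
    return synth_experiment(SynthConfig(seed=22))


@pytest.fixture(scope="session")
def light_config():
    """Config without expression data, for cheap replicated simulations."""
    return dataclasses.replace(SynthConfig(), n_genes=0, n_planted=0)


@pytest.fixture()
def store():
    """Minimal store with one protocol, no experiments."""
    s = Store()
    s.add_vector(VectorRecord("V1", "test vector"))
    s.add_immunization_protocol(
        ImmunizationProtocol("P1", "prime only", [Inoculation(0, "V1")])
    )
    return s
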