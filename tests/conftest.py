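import numpy as np
import pytest

from foldbind.exchange import ExchangeScheme, MixtureComposition
from foldbind.forward import CestExperiment, ResidueSpinSystem


@pytest.fixture
def study_scheme() -> ExchangeScheme:
    """Globally fitted 4-site rates of the study."""
    return ExchangeScheme(kon=7.3e5, koff=56.0, k_ab=72.0, k_ba=64.0,
                          k_bc=89.0, k_cb=94.0)


@pytest.fixture
def cest_composition() -> MixtureComposition:
    """CEST sample: 500 uM IDP, 100 uM partner, Kd = 24 uM."""
    return MixtureComposition(p0=500.0, r0=100.0, kd=24.0)


@pytest.fixture
def cw_experiment() -> CestExperiment:
    return CestExperiment(
        b1=20.5, tsat=0.4, offsets=np.arange(-800.0, 800.0, 8.0),
        scheme="cw", larmor_15n=96.3, carrier=118.5,
    )


@pytest.fixture
def example_spin() -> ResidueSpinSystem:
    return ResidueSpinSystem(
        residue_id=330, shift_f=119.2, dw_fa=2.0, dw_fb=2.0, dw_fc=2.3,
        r1=1.5, r2_f=5.0, r2_b=25.0, r2_c=30.0, r2_a=25.0,
    )


def random_spin_and_scheme(rng: np.random.Generator):
    """Random physically plausible 4-site instance for property tests."""
    scheme = ExchangeScheme(
        kon=10 ** rng.uniform(4, 6),
        koff=10 ** rng.uniform(0.5, 2.5),
        k_ab=10 ** rng.uniform(0.5, 2.5),
        k_ba=10 ** rng.uniform(0.5, 2.5),
        k_bc=10 ** rng.uniform(0.5, 2.5),
        k_cb=10 ** rng.uniform(0.5, 2.5),
    )
    spin = ResidueSpinSystem(
        residue_id=1,
        shift_f=rng.uniform(110, 127),
        dw_fa=rng.uniform(-5, 5),
        dw_fb=rng.uniform(-5, 5),
        dw_fc=rng.uniform(-5, 5),
        r1=rng.uniform(0.5, 3),
        r2_f=rng.uniform(2, 15),
        r2_b=rng.uniform(10, 60),
        r2_c=rng.uniform(10, 60),
        r2_a=rng.uniform(5, 40),
    )
    return spin, scheme
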