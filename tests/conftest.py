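import numpy as np
import pytest

from pleiokit.mixture import MixtureParams
from pleiokit.simulate import SimConfig, simulate_genotypes


def make_config(**overrides) -> SimConfig:
    base = dict(
        m_snps=600,
        n1=20_000,
        n2=20_000,
        n_ref=400,
        block_size=20,
        rho=0.5,
        mixture=MixtureParams.from_h2(0.3, 0.2, 600, pi1=0.02, pi2=0.02,
                                      pi12=0.05, rho12=0.5),
        n_chrom=2,
        seed=7,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return make_config()


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return simulate_genotypes(small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
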