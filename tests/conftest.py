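import numpy as np
import pytest

from fstenrich.synthetic import SyntheticConfig, write_bundle


@pytest.fixture(scope="session")
def demo_config() -> SyntheticConfig:
    """Small planted-promoter-divergence study used across integration tests."""
    return SyntheticConfig(
        seed=11,
        n_chromosomes=2,
        chrom_length=2_000_000,
        n_genes=60,
        n_sites=8_000,
        f_background=0.2,
        f_by_class={"promoter": 0.6},
        missing_rate=0.02,
    )


@pytest.fixture(scope="session")
def demo_bundle(demo_config, tmp_path_factory):
    """Full synthetic bundle (files + in-memory objects) written once."""
    out = tmp_path_factory.mktemp("bundle")
    return write_bundle(demo_config, out)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
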