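import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_karyotype():
    from dosagex.karyotype import Karyotype

    return Karyotype(
        lengths={"I": 2_000_000, "X": 1_500_000},
        copy_number={"I": 2, "X": 2},
    )


@pytest.fixture(scope="session")
def small_annotation(small_karyotype):
    from dosagex.simulate import gen_genome_annotation

    return gen_genome_annotation(small_karyotype, genes_per_mb=30.0, seed=11)
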