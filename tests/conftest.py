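import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitocr import SyntheticSpec, build_mock_mitogenome

settings.register_profile(
    "suite", derandomize=True, max_examples=60, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Table 2 of the five-genome cohort: printed %A, %T, %G, %C, A+T%, AT-skew,
#: GC-skew per species (inputs for the desk-scale checks).
COHORT_TABLE = {
    "peguensis":    (29.4, 21.5, 16.1, 33.1, 50.8, 0.1552, -0.3455),
    "thirakhupti":  (30.4, 21.5, 15.3, 32.8, 52.0, 0.1715, -0.3638),
    "auribalteatus": (31.1, 21.1, 15.0, 32.9, 52.1, 0.1916, -0.3737),
    "chanhomeae":   (31.2, 23.3, 15.6, 29.9, 54.5, 0.1450, -0.3143),
    "tigroides":    (30.3, 21.5, 15.6, 32.6, 51.8, 0.1699, -0.3527),
}


@pytest.fixture(scope="session")
def default_genome():
    """One deterministic Type I mock genome shared by read-only tests."""
    return build_mock_mitogenome(SyntheticSpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_dna(rng, n, p=(0.3, 0.22, 0.16, 0.32)):
    return "".join(rng.choice(list("ATGC"), size=n, p=np.asarray(p) / sum(p)))
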