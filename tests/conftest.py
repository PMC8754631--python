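import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from atcen.composition import AnnotatedSequence

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20211220)


@pytest.fixture
def random_sequence(rng):
    """A 2 kb random sequence biased toward A+T, as AnnotatedSequence."""
    bases = rng.choice(list("ACGT"), size=2000, p=[0.35, 0.15, 0.15, 0.35])
    return AnnotatedSequence(id="rand2k", residues="".join(bases))
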