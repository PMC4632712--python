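import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mirsnp import MiRNARecord, SeedCatalog

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def let7_like():
    # mature sequence of a let-7-family-like miRNA; seed 2-8 = GAGGUAG
    return MiRNARecord("let-7-like", "UGAGGUAGUAGGUUGUAUAGUU")


@pytest.fixture
def small_catalog(let7_like):
    other = MiRNARecord("mir-other", "UGGAGUGUGACAAUGGUGUUUG")
    return SeedCatalog((let7_like, other))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
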