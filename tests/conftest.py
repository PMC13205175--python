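import pytest
from hypothesis import HealthCheck, settings

import regevol as rv

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def exonic():
    return rv.load_fixture("exonic_silencer")


@pytest.fixture(scope="session")
def silencer_b():
    return rv.load_fixture("silencer_b")


@pytest.fixture(scope="session")
def full_silencer():
    return rv.load_fixture("full_silencer")


@pytest.fixture(scope="session")
def enhancer3():
    return rv.load_fixture("enhancer3")


def make_seq(residues, **kw):
    return rv.AnnotatedSequence(id=kw.pop("id", "seq"), residues=residues, **kw)
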