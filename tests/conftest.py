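import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from fungevolve.trees import parse_newick


@pytest.fixture
def species_abc():
    """Three taxa, fully resolved: ((A,B)X,C)R."""
    return parse_newick("((A,B)X,C)R;")


@pytest.fixture
def species_abcd():
    return parse_newick("((A,B)n1,(C,D)n2)r;")


@pytest.fixture
def species_polytomy():
    """Unresolved root: (A,B,C)R."""
    return parse_newick("(A,B,C)R;")
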