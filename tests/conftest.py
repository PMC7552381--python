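import pytest
from hypothesis import HealthCheck, settings

from mirsig import GeneSet, TargetDatabase

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def toy_db() -> TargetDatabase:
    """Four genes, three families with overlapping target sets."""
    return TargetDatabase(
        genes=frozenset({"A", "B", "C", "D"}),
        targets={
            "famX": frozenset({"A", "B", "C"}),
            "famY": frozenset({"C", "D"}),
            "famZ": frozenset({"D"}),
        })


@pytest.fixture
def toy_risk() -> GeneSet:
    return GeneSet.from_symbols("RISK", ["B", "C", "D"])
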