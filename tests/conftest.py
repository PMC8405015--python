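import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    max_examples=40,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def model():
    from xenorisk import BinaryTraitModel

    return BinaryTraitModel.from_ratio(1.0, theta=0.01)


@pytest.fixture
def three_taxon_pattern():
    from xenorisk import TraitCounts

    return TraitCounts.from_pattern({"A": 1, "B": 1, "C": 0})
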