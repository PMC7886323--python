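import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def small_protocol():
    from nontransim.simcore import SerialTransferProtocol

    return SerialTransferProtocol(dilution_factor=1024, bottleneck_size=1000)


@pytest.fixture
def toy_orf():
    """ATG AAA TAA: start, lysine, stop."""
    from nontransim.seqstats import ORFAnnotation

    return ORFAnnotation("ATGAAATAA", subunits=(("alpha", 1, 3),))
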