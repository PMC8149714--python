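import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from deinodel.genome_io import GenomeElement  # noqa: E402


@pytest.fixture
def toy_ref() -> GenomeElement:
    """16-mer with an ACGT direct repeat flanking a CCCC segment."""
    return GenomeElement(id="toy", seq="TTACGTCCCCACGTGG")
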