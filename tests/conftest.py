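import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_transcriptome():
    """Three hand-written transcripts exercising DRACH presence/absence."""
    from sgrecover.formats_io import Transcript

    return [
        Transcript("tx1", "g1", "GG" + "GGACT" * 2 + "C" * 93),  # two DRACH sites
        Transcript("tx2", "g2", "C" * 80),  # no A at all
        Transcript("tx3", "g3", "ACGT" * 30),
    ]
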