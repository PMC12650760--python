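import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from riboprox import AnalysisParams, TranscriptModel

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def params() -> AnalysisParams:
    return AnalysisParams()


@pytest.fixture
def transcript() -> TranscriptModel:
    """900 nt transcript, CDS at 60..660 (200 codons, 199 aa protein)."""
    return TranscriptModel("GENE1", "TX1", 900, 60, 600)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250901)
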