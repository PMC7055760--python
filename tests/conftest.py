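import numpy as np
import pytest
from hypothesis import HealthCheck, settings

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
    return np.random.default_rng(20260922)


@pytest.fixture
def default_config():
    from mstriage import default_instrument

    return default_instrument()


@pytest.fixture
def tiny_config():
    """One three-item section with weight(level) = level, as a hand oracle."""
    from mstriage import CutoffPair, InstrumentConfig, ItemDef, SectionDef

    return InstrumentConfig(
        sections=(
            SectionDef(
                name="symptoms",
                items=tuple(
                    ItemDef(id=f"item{i}", weights=(0, 1, 2)) for i in range(3)
                ),
            ),
        ),
        include_edss=False,
        cutoffs=CutoffPair(lower=40, upper=60),
    )
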