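import pytest

from vmrscreen import (
    Q344X_PARAMS,
    Segment,
    StimulusProtocol,
    simulate_plate,
)


@pytest.fixture(scope="session")
def short_protocol() -> StimulusProtocol:
    """A compressed protocol preserving the dark / light / dark structure."""
    return StimulusProtocol(
        (
            Segment("dark", 60, 0.0),
            Segment("light", 60, 0.01),
            Segment("dark", 40, 0.0),
        )
    )


@pytest.fixture(scope="session")
def small_trace(short_protocol):
    """Two batches of eight Q344X larvae on the compressed protocol."""
    return simulate_plate(
        Q344X_PARAMS,
        short_protocol,
        n_batches=2,
        larvae_per_batch=8,
        genotype="Q344X",
        seed=7,
    )
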