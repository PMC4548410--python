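import numpy as np
import pytest

from sacphys import StimulusProtocol, SweepSet


@pytest.fixture
def paired_protocol() -> StimulusProtocol:
    return StimulusProtocol.paired()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_sweepset(
    traces: np.ndarray,
    sampling_rate_Hz: float = 20_000.0,
    protocol: StimulusProtocol | None = None,
    **meta,
) -> SweepSet:
    return SweepSet(
        traces=np.asarray(traces, dtype=float),
        sampling_rate_Hz=sampling_rate_Hz,
        protocol=protocol or StimulusProtocol.paired(),
        meta=meta,
    )
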