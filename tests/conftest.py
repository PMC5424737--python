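import numpy as np
import pytest

from zlepy import FrequencyTrack, NotchBankParams, Signal

FS = 100.0


@pytest.fixture
def fs() -> float:
    return FS


@pytest.fixture
def default_bank() -> NotchBankParams:
    return NotchBankParams()


@pytest.fixture
def white_noise():
    def make(n: int, seed: int = 0) -> Signal:
        return Signal(np.random.default_rng(seed).standard_normal(n), FS)

    return make


@pytest.fixture
def constant_track():
    def make(freq_hz: float, n: int) -> FrequencyTrack:
        return FrequencyTrack.constant(2 * np.pi * freq_hz / FS, n)

    return make


def lti_notch_sos(theta: float, params: NotchBankParams) -> np.ndarray:
    """Independent time-invariant reference cascade, built directly from the
    section formulas (scipy sos rows), for oracle comparisons."""
    rows = []
    for j in range(1, params.p + 1):
        r = 1.0 - j * params.delta
        c = np.cos(j * theta)
        k = (1.0 + r) / 2.0
        rows.append([k, -2.0 * k * c, k, 1.0, -(1.0 + r) * c, r])
    return np.asarray(rows)
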