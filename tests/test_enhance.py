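import numpy as np
import pytest
from scipy import signal as sps

from zlepy import (
    FrequencyTrack,
    NotchBankParams,
    Signal,
    acf_enhance,
    frequency_response,
    zle_enhance,
)

from .conftest import FS, lti_notch_sos

THETA_12 = 2 * np.pi * 1.2 / FS


def _integer_lag(a: np.ndarray, b: np.ndarray) -> int:
    """Lag (samples) of the cross-correlation peak between two sequences."""
    a = a - a.mean()
    b = b - b.mean()
    xc = np.correlate(a, b, mode="full")
    return int(np.argmax(xc)) - (len(b) - 1)


class TestConservation:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_input_equals_enhanced_plus_residual_bitexact(self, white_noise, seed):
        n = 2000
        u = white_noise(n, seed)
        rng = np.random.default_rng(seed + 50)
        track = FrequencyTrack(
            2 * np.pi * np.clip(1.2 + np.cumsum(rng.normal(0, 0.005, n)), 0.8, 2.5) / FS
        )
        y_acf, v = acf_enhance(u, track)
        y_zle, w = zle_enhance(u, track)
        # the defining identities y = u - v and y = u - w hold bit-exactly
        assert np.array_equal(y_acf.samples, u.samples - v.samples)
        assert np.array_equal(y_zle.samples, u.samples - w.samples)
        # re-summing reconstructs the input to the last bit or one ulp
        eps = np.finfo(float).eps
        assert np.max(np.abs(y_acf.samples + v.samples - u.samples)) <= 4 * eps * np.max(
            np.abs(u.samples)
        )
        assert np.max(np.abs(y_zle.samples + w.samples - u.samples)) <= 4 * eps * np.max(
            np.abs(u.samples)
        )


class TestACF:
    def test_recovers_pure_sinusoid_at_exact_track(self, constant_track):
        n = 6000
        t = np.arange(n) / FS
        u = Signal(np.sin(2 * np.pi * 1.2 * t), FS)
        y, _ = acf_enhance(u, constant_track(1.2, n), NotchBankParams(8, 0.02))
        steady = slice(1000, n)
        err = y.samples[steady] - u.samples[steady]
        assert np.sqrt(np.mean(err**2)) < 1e-3 * np.sqrt(np.mean(u.samples[steady] ** 2))

    def test_nonharmonic_component_attenuated_per_response(self, constant_track):
        """A tone at 0.37*theta is attenuated by |1 - H| while the fundamental
        passes; amplitudes measured by least squares on the steady state."""
        n = 6000
        params = NotchBankParams()
        k = np.arange(n)
        u = Signal(np.sin(THETA_12 * k) + 0.8 * np.sin(0.37 * THETA_12 * k), FS)
        y, _ = acf_enhance(u, constant_track(1.2, n), params)
        seg = np.arange(2000, n)
        design = np.column_stack(
            [
                np.sin(THETA_12 * seg),
                np.cos(THETA_12 * seg),
                np.sin(0.37 * THETA_12 * seg),
                np.cos(0.37 * THETA_12 * seg),
            ]
        )
        coef, *_ = np.linalg.lstsq(design, y.samples[seg], rcond=None)
        fund_amp = np.hypot(coef[0], coef[1])
        other_amp = np.hypot(coef[2], coef[3])
        h = frequency_response(THETA_12, params, np.array([0.37 * THETA_12]))[0]
        assert fund_amp == pytest.approx(1.0, rel=0.01)
        assert other_amp == pytest.approx(0.8 * abs(1 - h), rel=0.01)


class TestZLE:
    def test_constant_track_matches_forward_backward_lti_oracle(self, white_noise, constant_track):
        n = 4000
        u = white_noise(n, 9)
        params = NotchBankParams(8, 0.02)
        _, w = zle_enhance(u, constant_track(1.2, n), params)
        sos = lti_notch_sos(THETA_12, params)
        ref = sps.sosfilt(sos, sps.sosfilt(sos, u.samples)[::-1])[::-1]
        assert np.sqrt(np.mean((w.samples - ref) ** 2)) <= 1e-12 * np.std(ref)

    def test_zero_phase_passband_lag_is_zero_while_acf_lags(self, constant_track):
        n = 6000
        k = np.arange(n)
        u = Signal(np.sin(0.5 * THETA_12 * k), FS)
        track = constant_track(1.2, n)
        _, w = zle_enhance(u, track)
        _, v = acf_enhance(u, track)
        central = slice(n // 4, 3 * n // 4)
        assert _integer_lag(w.samples[central], u.samples[central]) == 0
        assert _integer_lag(v.samples[central], u.samples[central]) != 0

    def test_empirical_transfer_phase_is_zero(self, white_noise, constant_track):
        """Cross-spectral phase of u -> w below 0.02 rad wherever coherence
        exceeds 0.99 (constant track, long white-noise record)."""
        n = 2**17
        u = white_noise(n, 3)
        _, w = zle_enhance(u, constant_track(1.2, n))
        sl = slice(4000, n - 4000)
        _, pxy = sps.csd(u.samples[sl], w.samples[sl], fs=FS, nperseg=2048)
        _, coh = sps.coherence(u.samples[sl], w.samples[sl], fs=FS, nperseg=2048)
        mask = coh > 0.99
        assert mask.sum() > 100
        assert np.max(np.abs(np.angle(pxy[mask]))) < 0.02

    def test_empirical_magnitude_is_squared_response(self, white_noise, constant_track):
        n = 2**17
        params = NotchBankParams()
        u = white_noise(n, 3)
        _, w = zle_enhance(u, constant_track(1.2, n), params)
        sl = slice(4000, n - 4000)
        f, pxy = sps.csd(u.samples[sl], w.samples[sl], fs=FS, nperseg=2048)
        _, pxx = sps.welch(u.samples[sl], fs=FS, nperseg=2048)
        transfer = np.abs(pxy / pxx)
        h2 = np.abs(frequency_response(THETA_12, params, 2 * np.pi * f / FS)) ** 2
        away = h2 > 0.5  # off the notch dips
        assert np.max(np.abs(transfer[away] - h2[away]) / h2[away]) < 0.02
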