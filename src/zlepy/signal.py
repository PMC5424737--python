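"""Core containers: uniformly sampled signals and fundamental-frequency tracks.

A :class:`Signal` is a real-valued, uniformly sampled sequence with a sampling
rate in Hz.  A :class:`FrequencyTrack` carries the per-sample instantaneous
fundamental frequency θ(n) in rad/sample (the instantaneous heart rate for a
PPG) and always belongs to a signal of the same length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Signal", "FrequencyTrack", "time_reverse"]


@dataclass
class Signal:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    samples : array_like
        Sample values (arbitrary amplitude units). Must be finite, length >= 1.
    fs : float
        Sampling frequency in Hz, > 0.
    valid_from : int, optional
        Index of the first sample considered valid for analysis.  Preprocessing
        sets this to flag an initial burn-in (e.g. frequency-estimator
        convergence) without dropping samples from the record.
    """

    samples: np.ndarray
    fs: float
    valid_from: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")
        self.fs = float(self.fs)
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if not (0 <= self.valid_from <= self.samples.size):
            raise ValueError("valid_from outside record")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n) / self.fs

    def copy(self) -> "Signal":
        return Signal(self.samples.copy(), self.fs, self.valid_from)


@dataclass
class FrequencyTrack:
    """Per-sample fundamental frequency θ(n), rad/sample.

    Invariant: 0 < θ(n) < π for every sample.  ``converged`` is cleared by the
    frequency estimator when the input carried no usable oscillation (e.g. an
    all-zero record) and the track is pinned at the initial guess.
    """

    theta: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=np.float64)
        if self.theta.ndim != 1 or self.theta.size < 1:
            raise ValueError("theta must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("theta contains non-finite values")
        if np.any(self.theta <= 0) or np.any(self.theta >= np.pi):
            raise ValueError("theta must lie strictly inside (0, pi) rad/sample")

    @property
    def n(self) -> int:
        return self.theta.size

    def hz(self, fs: float) -> np.ndarray:
        """Track in Hz for a given sampling rate."""
        return self.theta * fs / (2.0 * np.pi)

    @classmethod
    def constant(cls, theta: float, n: int) -> "FrequencyTrack":
        return cls(np.full(n, float(theta)))

    @classmethod
    def from_hz(cls, freq_hz: np.ndarray | float, fs: float, n: int | None = None) -> "FrequencyTrack":
        f = np.asarray(freq_hz, dtype=np.float64)
        if f.ndim == 0:
            if n is None:
                raise ValueError("n is required for a scalar frequency")
            f = np.full(n, float(f))
        return cls(2.0 * np.pi * f / fs)


def time_reverse(s: Signal) -> Signal:
    """Reverse the order of the time sequence: output[n] = input[N-1-n]."""
    return Signal(s.samples[::-1].copy(), s.fs)
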