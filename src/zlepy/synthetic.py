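"""Synthetic quasi-periodic PPG, colored motion-artifact noise, SNR mixing.

The clean pulse waveform is a harmonic sum

    s(n) = sum_k A_k sin(k * phi(n) + phi_k),    k = 1..K,

where phi(n) is the phase integral of a seeded heart-rate random walk
reflected inside a physiologic band, so beat-to-beat period varies the way a
resting heart rate does.  Motion artifact is emulated by colored noise whose
power is confined to the 0.5–2 Hz band where real limb-movement artifact
concentrates — precisely overlapping the feasible heart-rate range, which is
what makes single-input artifact reduction hard.  ``mix_at_snr`` scales the
noise so the clean-to-noise variance ratio hits a requested SNR exactly.

Everything is deterministic given its seed; the Monte Carlo harness derives
per-repetition seeds from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal import FrequencyTrack, Signal

__all__ = ["PPGModel", "SimulationConfig", "generate_ppg", "colored_noise", "mix_at_snr"]


@dataclass(frozen=True)
class PPGModel:
    """Generative model of a clean PPG-like record.

    amplitudes
        Per-harmonic amplitudes A_1..A_K (arbitrary units).  The default
        [1, 0.5, 0.2] mimics the decaying harmonic envelope of a pulse wave.
    hr_mean
        Mean heart rate, Hz.
    hr_walk_std
        Random-walk standard deviation of the instantaneous heart rate,
        Hz/sqrt(s); the walk is reflected at ``hr_band``.
    phases
        Per-harmonic phase offsets, rad (defaults to zeros).
    wander_amp / wander_freq_hz
        Optional additive sinusoidal baseline wander.
    """

    duration: float = 60.0
    fs: float = 100.0
    hr_mean: float = 1.2
    hr_walk_std: float = 0.05
    hr_band: tuple[float, float] = (0.8, 2.5)
    amplitudes: tuple[float, ...] = (1.0, 0.5, 0.2)
    phases: tuple[float, ...] | None = None
    wander_amp: float = 0.0
    wander_freq_hz: float = 0.15

    def __post_init__(self) -> None:
        if not (0.5 <= self.hr_mean <= 3.0):
            raise ValueError("mean heart rate must be in [0.5, 3] Hz")
        if len(self.amplitudes) < 1:
            raise ValueError("need at least one harmonic")
        if self.phases is not None and len(self.phases) != len(self.amplitudes):
            raise ValueError("phases and amplitudes must have equal length")
        k = len(self.amplitudes)
        if not (self.fs > 2 * k * self.hr_band[1]):
            raise ValueError(
                f"fs = {self.fs} Hz too low for {k} harmonics up to {self.hr_band[1]} Hz"
            )
        if not (self.hr_band[0] <= self.hr_mean <= self.hr_band[1]):
            raise ValueError("mean heart rate outside the reflection band")
        if self.hr_walk_std < 0 or self.duration <= 0:
            raise ValueError("invalid duration or walk std")


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo sweep: SNR grid (dB), repetitions per SNR, noise band, seed."""

    snr_grid_db: tuple[float, ...] = (-5.0, 0.0, 5.0, 10.0)
    reps: int = 100
    noise_band_hz: tuple[float, float] = (0.5, 2.0)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not (0 < self.noise_band_hz[0] < self.noise_band_hz[1]):
            raise ValueError("invalid noise band")


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    # reflect values into [lo, hi] (billiard boundary for the random walk)
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    return lo + np.where(y > span, 2 * span - y, y)


def generate_ppg(model: PPGModel | None = None, seed: int = 0):
    """Generate one clean record.

    Returns ``(clean, true_theta, true_peaks)``: the clean :class:`Signal`,
    the exact per-sample fundamental as a :class:`FrequencyTrack`, and the
    per-cycle waveform maxima as sample indices.
    """
    if model is None:
        model = PPGModel()
    rng = np.random.default_rng(seed)
    n = int(round(model.duration * model.fs))
    dt = 1.0 / model.fs
    steps = rng.normal(0.0, model.hr_walk_std * np.sqrt(dt), n)
    steps[0] = 0.0
    f_inst = _reflect(model.hr_mean + np.cumsum(steps), *model.hr_band)
    phi = 2.0 * np.pi * np.cumsum(f_inst) * dt
    phases = model.phases or (0.0,) * len(model.amplitudes)
    x = np.zeros(n)
    for k, (a, p) in enumerate(zip(model.amplitudes, phases), start=1):
        x += a * np.sin(k * phi + p)
    if model.wander_amp:
        t = np.arange(n) * dt
        x += model.wander_amp * np.sin(2 * np.pi * model.wander_freq_hz * t)
    # per-cycle maxima: argmax of the waveform within each complete 2*pi span of phi
    cycle = np.floor((phi - phi[0]) / (2.0 * np.pi)).astype(int)
    peaks = []
    for c in range(cycle[0], cycle[-1]):  # exclude the trailing partial cycle
        idx = np.nonzero(cycle == c)[0]
        if idx.size:
            peaks.append(int(idx[np.argmax(x[idx])]))
    theta = FrequencyTrack(2.0 * np.pi * f_inst / model.fs)
    return Signal(x, model.fs), theta, np.asarray(peaks, dtype=int)


def colored_noise(
    duration: float,
    fs: float,
    band: tuple[float, float] = (0.5, 2.0),
    seed: int = 0,
    order: int = 6,
) -> Signal:
    """Band-limited colored noise emulating motion artifact.

    Seeded white Gaussian noise is band-pass filtered into ``band`` with a
    zero-phase (forward-backward) Butterworth filter, then mean-removed.
    """
    if not (0 < band[0] < band[1] < fs / 2):
        raise ValueError(f"noise band {band} must lie inside (0, fs/2)")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    x = x - x.mean()
    return Signal(x, fs)


def mix_at_snr(clean: Signal, noise: Signal, snr_db: float) -> Signal:
    """clean + g*noise with g set so var(clean)/var(g*noise) equals snr_db exactly.

    ``snr_db = numpy.inf`` is the no-noise sentinel and returns a copy of the
    clean signal.
    """
    if np.isposinf(snr_db):
        return clean.copy()
    if clean.n != noise.n or clean.fs != noise.fs:
        raise ValueError("clean and noise must share length and sampling rate")
    var_noise = float(np.var(noise.samples))
    if var_noise == 0.0:
        raise ValueError("noise has zero variance")
    g = np.sqrt(float(np.var(clean.samples)) / (var_noise * 10.0 ** (snr_db / 10.0)))
    return Signal(clean.samples + g * noise.samples, clean.fs)
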