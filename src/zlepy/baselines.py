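"""Single-input baseline artifact-reduction methods: wavelet de-noising and
cycle-by-cycle Fourier series analysis (CFSA).

Wavelet de-noising decomposes the record into 7 levels with a biorthogonal
wavelet, zeroes the coarsest approximation (low-frequency artifact lives
there: at fs = 100 Hz level 7 covers roughly 0–0.4 Hz) and hard-thresholds
the detail coefficients with the universal threshold sigma*sqrt(2 ln N).

CFSA segments the record at cycle boundaries and reconstructs each cycle from
a truncated Fourier series (mean + n_harmonics sine/cosine pairs over that
cycle); components that do not complete an integer number of periods within
one cycle — in particular slow artifact — are partially cancelled by the
coefficient integrals, but within-cycle drift survives, which is its known
weakness against low-frequency artifact.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt
from scipy import signal as sps

from .signal import Signal

__all__ = ["wavelet_denoise", "cfsa", "auto_cycle_marks"]


def wavelet_denoise(
    u: Signal,
    levels: int = 7,
    wavelet_name: str = "bior3.9",
    threshold_rule: str = "hard",
    threshold: float | None = None,
    zero_coarsest: bool = True,
) -> Signal:
    """Wavelet de-noising with coarsest-level suppression.

    Parameters
    ----------
    threshold
        Detail-coefficient threshold; ``None`` selects the universal
        threshold sigma*sqrt(2 ln N) with sigma estimated from the median
        absolute deviation of the finest detail level.
    zero_coarsest
        Zero the level-``levels`` approximation coefficients (the
        low-frequency artifact band).
    """
    wavelet = pywt.Wavelet(wavelet_name)
    max_level = pywt.dwt_max_level(u.n, wavelet.dec_len)
    if max_level < levels:
        min_len = (wavelet.dec_len - 1) * 2**levels + 1
        raise ValueError(
            f"signal of {u.n} samples too short for a {levels}-level '{wavelet_name}' "
            f"decomposition; need at least {min_len} samples"
        )
    coeffs = pywt.wavedec(u.samples, wavelet, level=levels, mode="periodization")
    if threshold is None:
        sigma = float(np.median(np.abs(coeffs[-1]))) / 0.6745
        threshold = sigma * np.sqrt(2.0 * np.log(u.n))
    if zero_coarsest:
        coeffs[0] = np.zeros_like(coeffs[0])
    if threshold > 0:
        coeffs[1:] = [pywt.threshold(c, threshold, mode=threshold_rule) for c in coeffs[1:]]
    out = pywt.waverec(coeffs, wavelet, mode="periodization")[: u.n]
    return Signal(out, u.fs, u.valid_from)


def cfsa(u: Signal, cycle_marks: np.ndarray, n_harmonics: int = 8) -> Signal:
    """Cycle-by-cycle Fourier series reconstruction.

    Each cycle [m_i, m_{i+1}) is replaced by its truncated Fourier series over
    that cycle (discrete sums, rectangle rule); samples before the first and
    after the last mark pass through unchanged.
    """
    marks = np.asarray(cycle_marks, dtype=int)
    if marks.size < 2:
        return u.copy()
    if np.any(np.diff(marks) <= 0):
        raise ValueError("cycle marks must be strictly increasing")
    if marks[0] < 0 or marks[-1] > u.n:
        raise ValueError("cycle marks outside the record")
    out = u.samples.copy()
    for a, b in zip(marks[:-1], marks[1:]):
        seg = u.samples[a:b]
        length = b - a
        if length < 2 * n_harmonics + 1:
            raise ValueError(
                f"cycle [{a},{b}) has {length} samples; need >= {2 * n_harmonics + 1} "
                f"for {n_harmonics} harmonics"
            )
        t = 2.0 * np.pi * np.arange(length) / length
        recon = np.full(length, seg.mean())
        for h in range(1, n_harmonics + 1):
            c = np.cos(h * t)
            s = np.sin(h * t)
            recon += (2.0 / length) * (seg @ c) * c + (2.0 / length) * (seg @ s) * s
        out[a:b] = recon
    return Signal(out, u.fs, u.valid_from)


def auto_cycle_marks(
    u: Signal,
    band_hz: tuple[float, float] = (0.5, 3.0),
    min_distance_s: float = 0.33,
    min_separation_s: float = 0.25,
) -> np.ndarray:
    """Detect cycle boundaries as the troughs preceding each detected peak.

    The record is band-pass filtered into the heart-rate band (zero-phase,
    so the marks are not delayed), peaks are found with a minimum-distance
    guard, and each mark is the interior local minimum between consecutive
    peaks.  Marks closer than ``min_separation_s`` to the previous kept mark
    are spurious at physiologic heart rates (min cycle 1/3 s) and dropped.
    Returns an empty array (with a warning) when no cycles are detectable.
    """
    if np.ptp(u.samples) == 0:
        warnings.warn("no detectable cycles in a constant signal", stacklevel=2)
        return np.empty(0, dtype=int)
    sos = sps.butter(2, band_hz, btype="bandpass", fs=u.fs, output="sos")
    bp = sps.sosfiltfilt(sos, u.samples)
    peaks, _ = sps.find_peaks(bp, distance=max(1, int(round(min_distance_s * u.fs))))
    if peaks.size == 0:
        warnings.warn("no detectable cycles", stacklevel=2)
        return np.empty(0, dtype=int)
    candidates = []
    prev = 0
    for p in peaks:
        if p - prev >= 3:
            m = prev + int(np.argmin(bp[prev:p]))
            # boundary minima are segmentation artifacts, not true troughs
            if prev < m < p - 1:
                candidates.append(m)
        prev = p
    min_sep = int(round(min_separation_s * u.fs))
    marks: list[int] = []
    for m in candidates:
        if not marks or m - marks[-1] >= min_sep:
            marks.append(m)
    return np.asarray(marks, dtype=int)
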