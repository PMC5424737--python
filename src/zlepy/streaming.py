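"""Real-time blockwise zero-phase enhancement via a moving window.

Forward-backward filtering needs the whole record, so the real-time variant
processes overlapping windows: each window is batch-enhanced, its leading and
trailing ``transient_len`` samples (filter edge transients) are discarded and
only the central ``filter_len``-sample filtering period is emitted.  Because
transients occur at both window ends, consecutive windows overlap by
2 x transient_len and the hop equals filter_len, so the kept segments tile
the interior of the record exactly.  Latency is one window length.

The frequency estimator is causal and runs continuously over the stream
(state carried across windows); only the notch filtering is windowed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enhance import zle_enhance
from .freq import EstimatorConfig, FrequencyTracker
from .notch import NotchBankParams
from .signal import FrequencyTrack, Signal

__all__ = ["WindowScheme", "window_plan", "windowed_zle", "ZLEStream"]


@dataclass(frozen=True)
class WindowScheme:
    """Moving-window geometry: transient and filtering period lengths, samples.

    window length = filter_len + 2*transient_len; overlap = 2*transient_len;
    hop = filter_len.  Defaults are 100-sample transients and 300-sample
    filtering periods (1 s / 3 s at fs = 100 Hz).
    """

    transient_len: int = 100
    filter_len: int = 300

    def __post_init__(self) -> None:
        if self.transient_len < 1 or self.filter_len < 1:
            raise ValueError("transient_len and filter_len must be positive")

    @property
    def overlap(self) -> int:
        return 2 * self.transient_len

    @property
    def window_len(self) -> int:
        return self.filter_len + 2 * self.transient_len


def window_plan(
    n_samples: int, scheme: WindowScheme
) -> list[tuple[int, int, int, int]]:
    """Window/keep intervals ``(window_start, window_end, keep_start, keep_end)``.

    Kept intervals are disjoint, contiguous and each sits transient_len inside
    its window.  Trailing samples that cannot fill a final full window are not
    emitted, so every emitted sample is protected by full transients.
    """
    if n_samples < scheme.window_len:
        raise ValueError(
            f"record of {n_samples} samples shorter than one window "
            f"({scheme.window_len} samples)"
        )
    plan = []
    start = 0
    while start + scheme.window_len <= n_samples:
        plan.append(
            (
                start,
                start + scheme.window_len,
                start + scheme.transient_len,
                start + scheme.transient_len + scheme.filter_len,
            )
        )
        start += scheme.filter_len
    return plan


def windowed_zle(
    u: Signal,
    scheme: WindowScheme | None = None,
    est_config: EstimatorConfig | None = None,
    params: NotchBankParams | None = None,
    track: FrequencyTrack | None = None,
) -> Signal:
    """Blockwise zero-phase enhancement of a full record.

    Output sample i corresponds to input sample ``scheme.transient_len + i``;
    the record's first/last transients and any trailing partial window are not
    emitted.  Pass a precomputed ``track`` to reuse a frequency estimate.
    """
    scheme = scheme or WindowScheme()
    params = params or NotchBankParams()
    if track is None:
        tracker = FrequencyTracker(est_config or EstimatorConfig(), u.fs)
        track = FrequencyTrack(tracker.process(u.samples), converged=tracker.any_signal)
    elif track.n != u.n:
        raise ValueError("track length must match the signal")
    pieces = []
    for ws, we, ks, ke in window_plan(u.n, scheme):
        win = Signal(u.samples[ws:we], u.fs)
        win_track = FrequencyTrack(track.theta[ws:we], converged=track.converged)
        y, _ = zle_enhance(win, win_track, params)
        pieces.append(y.samples[ks - ws : ke - ws])
    return Signal(np.concatenate(pieces), u.fs)


class ZLEStream:
    """Push-based streaming interface.

    The caller pushes sample chunks of any size; :meth:`push` returns the list
    of newly emitted output blocks (possibly empty).  Output is identical to
    :func:`windowed_zle` on the concatenated input.
    """

    def __init__(
        self,
        fs: float,
        scheme: WindowScheme | None = None,
        est_config: EstimatorConfig | None = None,
        params: NotchBankParams | None = None,
    ) -> None:
        self.fs = float(fs)
        self.scheme = scheme or WindowScheme()
        self.params = params or NotchBankParams()
        self._tracker = FrequencyTracker(est_config or EstimatorConfig(), fs)
        self._buf = np.empty(0)
        self._theta = np.empty(0)

    def push(self, chunk: np.ndarray) -> list[np.ndarray]:
        """Feed samples; return any output blocks completed by this chunk."""
        chunk = np.asarray(chunk, dtype=np.float64)
        if chunk.size:
            self._buf = np.concatenate([self._buf, chunk])
            self._theta = np.concatenate([self._theta, self._tracker.process(chunk)])
        out = []
        wl = self.scheme.window_len
        t = self.scheme.transient_len
        fl = self.scheme.filter_len
        while self._buf.size >= wl:
            win = Signal(self._buf[:wl], self.fs)
            track = FrequencyTrack(self._theta[:wl], converged=self._tracker.any_signal)
            y, _ = zle_enhance(win, track, self.params)
            out.append(y.samples[t : t + fl])
            self._buf = self._buf[fl:]
            self._theta = self._theta[fl:]
        return out
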