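"""Quasi-periodic component enhancers built on the harmonic notch bank.

The notch bank removes the heart-rate fundamental and its harmonics, so its
output is an estimate of the motion artifact; subtracting it from the input
recovers the clean pulse waveform.

* ``acf_enhance`` — adaptive comb filter: a single causal forward pass,
  y = u - v.  On-line capable but phase-distorting when the frequency track
  is imperfect.
* ``zle_enhance`` — zero-phase line enhancer: forward pass, time reversal,
  second pass with the reversed track, final reversal; the u → w map then has
  squared magnitude |H|² and zero phase for a constant track.  y = u - w.
  This is a batch operation (the whole record is needed); see
  :mod:`zlepy.streaming` for the real-time windowed variant.
"""

from __future__ import annotations

from .freq import reverse_track
from .notch import NotchBankParams, apply_time_variant_notch
from .signal import FrequencyTrack, Signal, time_reverse

__all__ = ["acf_enhance", "zle_enhance", "time_reverse"]


def acf_enhance(
    u: Signal, track: FrequencyTrack, params: NotchBankParams | None = None
) -> tuple[Signal, Signal]:
    """Adaptive comb filter. Returns (y, v) with y + v = u sample-exact."""
    if params is None:
        params = NotchBankParams()
    v = apply_time_variant_notch(u, track, params, direction="forward")
    y = Signal(u.samples - v.samples, u.fs, u.valid_from)
    return y, v


def zle_enhance(
    u: Signal, track: FrequencyTrack, params: NotchBankParams | None = None
) -> tuple[Signal, Signal]:
    """Zero-phase line enhancer. Returns (y, w) with y + w = u sample-exact.

    w is the artifact estimate from the four-step forward-backward chain;
    the filter state is zeroed at the start of each pass.
    """
    if params is None:
        params = NotchBankParams()
    v = apply_time_variant_notch(u, track, params, direction="forward")
    p = time_reverse(v)
    q = apply_time_variant_notch(p, reverse_track(track), params, direction="backward")
    w = time_reverse(q)
    y = Signal(u.samples - w.samples, u.fs, u.valid_from)
    return y, w
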