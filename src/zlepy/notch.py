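"""Harmonic IIR notch filter bank with per-sample time-varying coefficients.

The bank is a cascade of P second-order notch sections.  Section j places a
unit-circle zero pair at the j-th harmonic jθ of the fundamental θ and a pole
pair at the same angle contracted by r_j = 1 - j·δ, so higher harmonics get
progressively wider notches (instantaneous heart rate is noisier at high
harmonic order).  With

    a1_j = (1 + r_j) cos(jθ(n)),  a2_j = -r_j,
    b1_j = -2 cos(jθ(n)),         k_j  = (1 + r_j) / 2,

each section is the transfer function

    H_j(z, θ) = k_j (1 + b1_j z^-1 + z^-2) / (1 - a1_j z^-1 - a2_j z^-2),

realized in direct form 2 with the coefficients recomputed at every sample
from the frequency track.  For a constant track this reduces exactly to an
ordinary time-invariant biquad cascade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .signal import FrequencyTrack, Signal

__all__ = [
    "NotchBankParams",
    "SectionCoefficients",
    "contraction_factors",
    "section_coefficients",
    "frequency_response",
    "apply_time_variant_notch",
]


@dataclass(frozen=True)
class NotchBankParams:
    """Number of harmonic sections P and pole-zero contraction increment δ.

    Stability of every section requires r_j = 1 - j·δ in (0, 1), i.e. P·δ < 1.
    Defaults: P = 8 sections, δ = 0.03 (mid-range of the typical 0.02–0.04).
    """

    p: int = 8
    delta: float = 0.03

    def __post_init__(self) -> None:
        if int(self.p) != self.p or self.p < 1:
            raise ValueError(f"P must be an integer >= 1, got {self.p}")
        if not (self.delta > 0):
            raise ValueError(f"delta must be positive, got {self.delta}")
        if self.p * self.delta >= 1:
            raise ValueError(
                f"P*delta = {self.p * self.delta:g} >= 1: contraction factor of the "
                "highest section would leave (0, 1) and the bank would be unstable"
            )


@dataclass(frozen=True)
class SectionCoefficients:
    """Coefficients of one second-order notch section (direct form 2)."""

    a1: float
    a2: float
    b1: float
    k: float


def contraction_factors(params: NotchBankParams) -> np.ndarray:
    """Pole-zero contraction factors r_j = 1 - j*delta for j = 1..P."""
    j = np.arange(1, params.p + 1)
    return 1.0 - j * params.delta


def section_coefficients(theta: float, j: int, r: float) -> SectionCoefficients:
    """Coefficients of the j-th harmonic section at fundamental theta (rad/sample)."""
    if not 0 < r < 1:
        raise ValueError(f"contraction factor must be in (0,1), got {r}")
    w = j * theta
    if not 0 < w < np.pi:
        raise ValueError(
            f"harmonic notch frequency j*theta = {w:g} rad/sample outside (0, pi): "
            "the section would alias past Nyquist"
        )
    c = math.cos(w)
    return SectionCoefficients(a1=(1.0 + r) * c, a2=-r, b1=-2.0 * c, k=(1.0 + r) / 2.0)


def bank_sos(theta: float, params: NotchBankParams) -> np.ndarray:
    """Second-order-section matrix (scipy convention) of the bank frozen at theta.

    Rows are [b0, b1, b2, a0, a1, a2] with the numerator gain k folded in; usable
    directly with :func:`scipy.signal.sosfilt` as an independent LTI reference.
    """
    rows = []
    for j, r in zip(range(1, params.p + 1), contraction_factors(params)):
        c = section_coefficients(theta, j, r)
        rows.append([c.k, c.k * c.b1, c.k, 1.0, -c.a1, -c.a2])
    return np.asarray(rows)


def frequency_response(
    theta: float, params: NotchBankParams, omega_grid: np.ndarray
) -> np.ndarray:
    """H(e^{iω}, θ): product of all P section responses on the given ω grid (rad/sample)."""
    omega = np.asarray(omega_grid, dtype=np.float64)
    z1 = np.exp(-1j * omega)
    z2 = np.exp(-2j * omega)
    h = np.ones_like(z1)
    for j, r in zip(range(1, params.p + 1), contraction_factors(params)):
        c = section_coefficients(theta, j, r)
        h *= c.k * (1.0 + c.b1 * z1 + z2) / (1.0 - c.a1 * z1 - c.a2 * z2)
    return h


def _run_section(x: list, cos_jtheta: list, r: float) -> list:
    # Direct form 2 biquad with per-sample coefficients; plain-float loop keeps
    # the scalar recursion fast without compiled helpers.
    k = (1.0 + r) / 2.0
    one_r = 1.0 + r
    s1 = 0.0
    s2 = 0.0
    out = []
    append = out.append
    for xn, cn in zip(x, cos_jtheta):
        s = xn + one_r * cn * s1 - r * s2
        append(k * (s - 2.0 * cn * s1 + s2))
        s2 = s1
        s1 = s
    return out


def apply_time_variant_notch(
    u: Signal,
    track: FrequencyTrack,
    params: NotchBankParams,
    direction: str = "forward",
) -> Signal:
    """Run the P-section time-variant notch bank over a signal.

    The sections are cascaded in ascending harmonic order j = 1..P, each with
    its internal delay line zeroed at the start of the pass.  ``direction`` is
    a label used only in error messages (the backward pass of the zero-phase
    enhancer runs this same routine on a time-reversed signal and track).
    """
    if track.n != u.n:
        raise ValueError(
            f"frequency track length {track.n} != signal length {u.n} ({direction} pass)"
        )
    theta_max = float(np.max(track.theta))
    if params.p * theta_max >= np.pi:
        raise ValueError(
            f"highest harmonic P*max(theta) = {params.p * theta_max:g} rad/sample "
            f"reaches Nyquist ({direction} pass); lower P or the track band"
        )
    x = u.samples.tolist()
    theta = track.theta
    for j, r in zip(range(1, params.p + 1), contraction_factors(params)):
        x = _run_section(x, np.cos(j * theta).tolist(), float(r))
    return Signal(np.asarray(x), u.fs)
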