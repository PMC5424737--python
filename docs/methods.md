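# Methods

This note records the models, numerical choices and known limitations of the
toolkit, in the spirit of a package vignette.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal model and problem

A PPG is quasi-periodic at the heart rate f₀ ∈ [0.5, 3] Hz with a decaying
harmonic envelope.  Motion artifact is broadband but concentrates in
0.5–2 Hz, overlapping the fundamental band, so separation must exploit the
*harmonic structure* of the pulse rather than a frequency band: everything at
jθ(n), j = 1..P, is pulse; the rest is artifact.

## Harmonic notch bank

Each of the P = 8 sections is a constrained second-order notch with unit
circle zeros at ±jθ and poles contracted by r_j = 1 − jδ.  Properties used
throughout the tests: |H| = 0 exactly at every jθ, and unity gain at DC and
Nyquist (each section's numerator and denominator coincide at z = ±1 after
the k_j = (1+r_j)/2 normalization).  The growth of notch bandwidth with j
(δ > 0) deliberately wastes bandwidth at high harmonics to absorb the j-fold
amplification of heart-rate tracking error.

Numerical realization: direct form 2, coefficients recomputed every sample
from θ(n); sections cascade in ascending j with per-section state zeroed at
the start of a pass.  For piecewise-constant θ this recursion coincides with
the frozen-coefficient LTI cascade (verified to 1e−12 relative RMS against an
independently coded second-order-section filter); for time-varying θ the
recursion is the definition of the system — a frozen-time convolution
description only holds approximately.  Internal frequencies are rad/sample;
Hz enter only at API boundaries (ω = 2πf/fs).  Any jθ(n) ≥ π raises an error
rather than silently wrapping past Nyquist; with P = 8, fs = 100 Hz and heart
rates ≤ 3 Hz the bound is never approached (8 · 2π·3/100 ≈ 1.51 rad/sample,
about half of π).

δ defaults to 0.03, the middle of the useful 0.02–0.04 range: smaller δ
sharpens the notches (better noise rejection, less robustness to tracking
error), larger δ the reverse.

## Enhancers

ACF: y = u − notch(u).  Causal; the enhanced signal inherits the phase error
of 1 − H wherever θ̂ ≠ θ.

ZLE: the artifact estimate w is produced by forward filtering, time reversal,
filtering with the *reversed* track θ(N−1−n), and a final reversal; y = u − w.
For constant θ the u → w transfer is |H(e^{jω}, θ)|² — real and nonnegative,
hence zero-phase — which the suite verifies empirically (cross-spectral phase
< 0.02 rad at coherence > 0.99; integer cross-correlation lag of a passband
tone exactly 0 samples, where the single-pass ACF shows a lag of tens of
samples).  The backward pass reuses the forward-estimated track reversed —
re-estimating on the reversed signal would break the θ(−n) symmetry and is
not attempted.  Both passes start from zero state; edge transients are the
streaming module's concern.

Conservation: y is *defined* as u − v (or u − w), so that identity is
bit-exact.  Note that re-summing y + v reproduces u only to one unit in the
last place per sample, because floating-point addition does not exactly
invert subtraction.

## Heart-rate tracker

A second-order constrained notch in lattice form, notch transfer
(1 − 2c z⁻¹ + z⁻²)/(1 − (1+ρ)c z⁻¹ + ρ z⁻²) with the single adapted
parameter c = cos θ̂.  The update minimizes the squared notch output by the
*exact recursive gradient* ∂e/∂c propagated through the filter state, with
the step normalized by a running estimate of the gradient power (NLMS): the
raw gradient scales roughly with θ², so an unnormalized step that converges
at mid-band stalls completely at heart-rate frequencies (θ ≈ 0.05–0.2
rad/sample at fs = 100 Hz).

Defaults (fs = 100 Hz): step 0.02, ρ = 0.95, initial guess 1.5 Hz, feasible
band [0.5, 3] Hz, trailing 100-sample moving average on θ̂, causal
exponential mean/power input normalization with a 2 s time constant.  The
step/contraction pair was chosen against two failure modes observed while
developing the tracker on multi-harmonic input:

* **harmonic capture** — with a narrow notch and a slow step the tracker can
  lose a wandering fundamental and re-lock on 2f₀; a faster normalized step
  holds lock (no capture over 60 stress records at 10 dB);
* **harmonic pull** — a notch much wider than the harmonic spacing (ρ ≲ 0.9)
  overlaps the 2nd harmonic at low heart rates and biases θ̂ upward by
  several percent; ρ = 0.95 keeps the bias ≤ ~1.5%.

The tracker is strictly causal (θ(n) depends on u[0..n] only) and clamps its
output to the feasible band; constant input leaves the track pinned at the
initial guess with a cleared `converged` flag.  Accuracy achieved under the
suite's conditions: median error ~0.03% on stationary tones at 10 dB SNR
(contract: < 1%), ≤ 2.2% on a 1.0→1.5 Hz chirp (contract: < 5%), and a few
percent on clean wandering-heart-rate records — a causal tracker cannot beat
the random walk's innovation over its own effective lag, so the wandering
case is held to the same 5% tolerance as the chirp.  Comb (harmonic-locked)
tracking, which would cancel the residual harmonic pull, is out of scope.

## Real-time windowed scheme

Window length = filtering period + 2 × transients (defaults 300 + 2·100
samples); hop = filtering period, so consecutive windows overlap by exactly
two transients and the kept segments tile the interior without gaps or
duplicates.  The first window's leading transient, the last window's trailing
transient, and any trailing samples that cannot fill a complete window are
never emitted — every emitted sample is protected by full transients on both
sides.  The heart-rate tracker runs continuously across windows (it is
causal; restarting it per window would re-incur its ~10 s convergence); only
the notch filtering is windowed.  Latency is one window (5 s at defaults).
Measured agreement with the batch enhancer on 60 s contaminated records is
~4–5% relative RMS at the default transient and falls monotonically as the
transient grows (≈0.2% at 300 samples), the residual being the decay r₁ⁿ of
the per-window zero-state transient.

## Baselines

*Wavelet*: 7-level `bior3.9` decomposition (periodized, so reconstruction is
exact when nothing is thresholded), coarsest approximation zeroed (0–0.39 Hz
at fs = 100 Hz — the slow-artifact band), details hard-thresholded at the
universal threshold σ√(2 ln N) with σ from the MAD of the finest level.
Family, rule and threshold are configurable.

*CFSA*: each cycle between consecutive marks is replaced by its truncated
Fourier series (mean + 8 sine/cosine pairs, discrete rectangle-rule sums —
exact for periodic band-limited cycles).  Its documented weakness is
retained faithfully: low-frequency artifact that drifts *within* one cycle
survives the per-cycle integrals.  Cycle marks come from troughs of the
0.5–3 Hz band-passed record; boundary argmins and marks closer than 0.25 s
(sub-physiologic) are discarded as segmentation artifacts.

## Synthetic data

Clean records are Σ_k A_k sin(kφ(n) + φ_k), K = 3, A = (1, 0.5, 0.2) — a
plausible pulse-harmonic decay, configurable — with φ the phase integral of a
heart-rate random walk (std 0.05 Hz/√s, reflected at [0.8, 2.5] Hz, mean
1.2 Hz).  Motion artifact is white noise band-passed to 0.5–2 Hz by a
zero-phase 6th-order Butterworth (in-band power fraction > 0.95); mixtures
hit the requested SNR exactly by construction.  Truth (per-sample fundamental
and per-cycle waveform maxima) is emitted alongside.

What the generator does *not* emulate: real pulse morphology (dicrotic
notch, asymmetric systolic upstroke), amplitude modulation by respiration,
sensor saturation, and accelerometer-correlated artifact.  Passing the
simulation suite therefore demonstrates the *algorithmic* claims (zero
phase, superiority under in-band colored noise), not clinical performance.

## Evaluation harness

Peaks: strict local maxima with a 0.33 s minimum-distance guard (max
physiologic rate 3 Hz), no prominence threshold.  Matching: greedy
nearest-first one-to-one within ±75 ms, ties toward the earlier index.
Se/PPV/F1 in percent, MAE in ms over matched pairs; with no true positives
Se = F1 = 0 while PPV/MAE are reported missing (NaN) with a warning, keeping
Monte Carlo aggregation well-defined.  Correlation is Pearson's r.

The Monte Carlo harness runs 100 repetitions per SNR ∈ {−5, 0, 5, 10} dB on
60 s records — a deliberate reduction from exhaustive sweeps (1000 × 21 SNRs)
that keeps the full comparison within tens of seconds while leaving the
paired tests overwhelming (p < 10⁻⁵ throughout); repetition seeds derive
deterministically from one master seed.  Scoring excludes the first 10 s
(tracker burn-in) and last 5 s (backward-pass edge transient) of each record.
Inference is by one-tailed paired t-tests of the ZLE against each baseline
per SNR (greater correlation/F1, smaller MAE), with incomplete pairs dropped.
A method that fails on a repetition is recorded as missing, not fatal.

## I/O and preprocessing

CSV only (two-column time,value or single column + declared rate), written at
full precision (`%.17g`) and parsed with correctly rounded float conversion
so round trips are lossless.  The standard preprocessing is a *causal*
third-order Butterworth band-pass, 0.5–10 Hz: the zero-phase property belongs
to the enhancer, and a causal front-end keeps the streaming path realizable.
The first 10 s are flagged (not dropped) as tracker burn-in.

## Known limitations

* The ZLE needs the whole record (or a window): minimum latency is one
  window length.
* Tracker accuracy, not notch design, limits enhancement quality at high
  SNR; the residual few-percent heart-rate error costs ~0.02 of correlation.
* All defaults assume fs ≈ 100 Hz and adult resting heart rates; other
  regimes require retuning the feasible band and window lengths.
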