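# zlepy — single-input PPG motion-artifact reduction

Photoplethysmogram (PPG) recordings from wearable sensors are routinely
corrupted by motion artifact (MA) whose spectrum (~0.5–2 Hz) overlaps the
feasible heart-rate band, so a plain band-pass cannot separate them.  `zlepy`
implements a **zero-phase line enhancer (ZLE)**: a single-channel method that
tracks the instantaneous heart rate and removes everything *except* the
quasi-periodic pulse component with a time-variant harmonic IIR notch filter
run forward *and* backward in time, which cancels the phase distortion that
plagues the causal adaptive comb filter (ACF).

## Method

The core is a cascade of P second-order notch sections at the harmonics jθ of
the instantaneous fundamental θ(n) (rad/sample):

    H(z, θ) = ∏_{j=1..P} k_j (1 + b1_j z⁻¹ + z⁻²) / (1 − a1_j z⁻¹ − a2_j z⁻²)

    a1_j = (1 + r_j) cos(jθ),  a2_j = −r_j,  b1_j = −2 cos(jθ),  k_j = (1 + r_j)/2

with contraction factors r_j = 1 − jδ (δ ≈ 0.02–0.04) so that higher
harmonics, whose frequency jitter grows with j, get proportionally wider
notches.  The coefficients are recomputed every sample from a heart-rate
track θ(n) produced by an adaptive notch frequency tracker (lattice-form,
normalized recursive-gradient adaptation).

* **ACF** (causal): v = notch(u), enhanced output y = u − v.  On-line, but
  any error in θ(n) produces phase distortion.
* **ZLE** (batch): w = reverse(notch(reverse(notch(u)), reversed θ)),
  y = u − w.  For constant θ the u → w map is |H|² with exactly zero phase.
* **Real-time ZLE**: overlapping windows (default 100-sample transients +
  300-sample filtering period, overlap = 2 × transient); each window is
  batch-enhanced, edge transients are discarded, and the kept filtering
  periods tile the record.

Baselines for comparison: 7-level biorthogonal wavelet de-noising (coarsest
level zeroed, hard universal threshold) and cycle-by-cycle Fourier series
analysis (CFSA).  A synthetic generator produces clean harmonic PPG with a
random-walk heart rate plus 0.5–2 Hz colored noise mixed at an exact SNR, and
an evaluation harness scores correlation with the clean record and
peak-detection metrics (Se/PPV/F1 with ±75 ms matching, MAE in ms).

## Worked example

```python
import numpy as np
from zlepy import (generate_ppg, colored_noise, mix_at_snr,
                   estimate_fundamental, zle_enhance, acf_enhance,
                   wavelet_denoise, correlation, Signal)

clean, true_theta, true_peaks = generate_ppg(seed=42)   # 60 s @ 100 Hz
noise = colored_noise(60.0, 100.0, seed=43)
contaminated = mix_at_snr(clean, noise, snr_db=0.0)     # SNR 0 dB

track = estimate_fundamental(contaminated)              # causal HR track
y_zle, _ = zle_enhance(contaminated, track)
y_acf, _ = acf_enhance(contaminated, track)
y_wav = wavelet_denoise(contaminated)

sl = slice(1000, 5500)   # skip estimator burn-in and edge transients
for name, y in [("zle", y_zle), ("acf", y_acf), ("wavelet", y_wav)]:
    c = correlation(Signal(y.samples[sl], 100.0), Signal(clean.samples[sl], 100.0))
    print(f"{name:8s} corr = {c:.4f}")
```

Output:

```
zle      corr = 0.7516
acf      corr = 0.6992
wavelet  corr = 0.7302
```

At 0 dB the zero-phase enhancer recovers the clean waveform best; the causal
comb filter trails even wavelet de-noising because its phase distortion
misaligns the recovered pulses, while the wavelet leaves in-band noise behind.
Averaged over 100 seeded repetitions the gaps are decisive (mean correlation
0.794 vs 0.716/0.715/0.688, paired p < 10⁻¹⁹; see below).  The same comparison is available from a shell:

```bash
zlepy simulate --duration 60 --snr 0 --seed 42 --out rec.csv
zlepy enhance rec.csv --method zle --out enhanced.csv
zlepy montecarlo --snrs -5,0,5,10 --reps 100 --seed 1 --out-prefix mc
```

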