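# pesodenoise

Removal of cardiogenic oscillations from esophageal pressure signals
by singular spectrum analysis.

## The problem

Esophageal pressure (P_eso, in cmH2O) is the standard minimally
invasive surrogate for pleural pressure in mechanically ventilated
patients: it is what clinicians use to read end-expiratory pressure
(P_ee), the per-breath pressure swing (ΔP), the pressure–time product
(PTP) and the work of breathing (WOB). Because the heart beats against
the esophagus, every P_eso record is contaminated by the cardiogenic
oscillation (CGO) — a quasi-periodic pressure artifact with its
fundamental in the heart-rate band, 0.8–4 Hz. The breathing waveform
occupies 0.17–0.67 Hz, so the two bands are separated by barely
0.13 Hz and plain fixed filters either leave artifact in or cut breath
content out. This package is aimed at respiratory-physiology and
ventilation researchers who need CGO-free P_eso traces and the derived
effort metrics.

## The method

The record `P` (length `L`, rate `fs`) is denoised in five steps:

1. Estimate the CGO fundamental `F_CGO` as the largest DFT amplitude
   at or above 0.8 Hz (mean removed first; ties go to the lowest bin).
2. Embed `P` in an `M x N` Hankel trajectory matrix with the
   sampling-rate-adaptive window `N = 1.5 fs` (one breath at the
   fastest physiological rate, 40 breaths/min), `M = L − N + 1`.
3. Thin SVD: `P_traj = Σ_i σ_i u_i v_iᵀ` with `λ_i = σ_i²`
   non-increasing; anti-diagonal averaging of each rank-one term gives
   reconstructed components RC_i with `Σ_i RC_i = P` exactly.
4. Filter every RC with a zero-phase 4th-order Butterworth bandpass
   (0.17–1.4 Hz) followed by a zero-phase band-stop at
   `F_CGO ± 0.05 Hz`.
5. Weight the filtered components by percent energy,
   `W(n) = 100 · Σ_i filRC_n(i)² / Σ_n Σ_i filRC_n(i)²`, and sum them
   in eigenvalue order until the cumulative weight reaches
   `Th_W = 99.99 %`. The sum (plus the input mean, so P_ee survives)
   is the denoised trace; `CGO = input − denoised`.

Reconstruction quality is scored by the percent RMS difference
`PRD = 100 · sqrt(Σ(ref−est)² / Σ ref²)` (≤2 % "very good", 2–9 %
"good"). Because no public P_eso recordings exist, the package ships a
seeded synthetic generator (active/passive breath morphologies, model
CGO, amplitude-referenced mixing `SynPeso = Peso + CGO/max|CGO| ·
max|Peso| · F`, optional white noise at a set SNR) so every stage is
exercisable end to end. See `docs/methods.md` for assumptions,
parameter rationale and limitations.

## Worked example

```python
import numpy as np
from pesodenoise import (BreathSpec, CgoSpec, MixSpec, SynthSpec,
                         SsaDenoiser, gen_synpeso, prd, snr_db)

spec = SynthSpec(breath=BreathSpec(mode="active", rr=18, swing=8.0),
                 cgo=CgoSpec(heart_rate=1.3), mix=MixSpec(f=0.5))
clean, cgo, noisy = gen_synpeso(spec, fs=100.0, duration=60.0, seed=3)

res = SsaDenoiser(noisy).fit()
print(res.summary())
print(f"PRD(noisy    vs clean) = {prd(clean, noisy):.2f}%")
print(f"PRD(denoised vs clean) = {prd(clean, res.denoised):.2f}%")
print(f"SNR improvement: {snr_db(clean, noisy):.2f} -> {snr_db(clean, res.denoised):.2f} dB")
```

prints

```
SSA cardiogenic-oscillation removal
===================================================
Samples (L)                                    6000
Sampling rate (Hz)                              100
Window length (N)                               150
CGO fundamental (Hz)                         1.3000
Th_W (%)                                    99.9900
Components kept (n_opt)                          10
Components total                                150
Cumulative weight (%)                     99.998996
Baseline preserved                             True
---------------------------------------------------
Leading component weights (%):
  45.7276  43.2451  0.3295  0.6739  9.6635  0.0191  0.2102  0.0099
PRD(noisy    vs clean) = 66.56%
PRD(denoised vs clean) = 9.59%
SNR improvement: 3.54 -> 20.36 dB
```

The detector found the injected 1.3 Hz heart rate exactly; ten of the
150 components carry 99.999 % of the filtered energy, and summing just
those removes an artifact whose peak equalled half the breath swing
(F=0.5), taking the record from 66.6 % to 9.6 % PRD — i.e. from
unusable to the edge of the "good" reconstruction band (heavier
contamination than the F=0.3 study condition, which averages ~7–9 %).

The same chain is available from a shell:

```bash
pesodenoise simulate --mode active --rr 18 --heart-rate 1.3 --f 0.5 \
    --seed 3 --out clean.csv --out-noisy noisy.csv
pesodenoise denoise --input noisy.csv --output denoised.csv --export-cgo cgo.csv
pesodenoise evaluate --clean clean.csv --denoised denoised.csv --noisy noisy.csv
```

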