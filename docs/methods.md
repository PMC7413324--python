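# Methods

## Problem

Esophageal pressure (Peso, cmH2O) is the standard minimally invasive
surrogate for pleural pressure in mechanically ventilated patients.
Because the heart beats directly against the esophagus, every Peso
record carries a quasi-periodic cardiac pressure artifact — the
cardiogenic oscillation (CGO) — whose fundamental lies in the
heart-rate band, 0.8 Hz (48 beats/min) to 4 Hz (240 beats/min). The
breathing waveform itself occupies roughly 0.17–0.67 Hz. The two bands
are separated by only ~0.13 Hz, so fixed filters either leave artifact
or clip breath content; the clinically scored features (end-expiratory
pressure P_ee, pressure swing ΔP, effort indices PTP and WOB) are
sensitive to both failure modes.

## Denoising chain

Given a record `P` of length `L` at sampling rate `fs`:

1. **CGO fundamental.** Remove the mean, take the DFT of the whole
   record (rectangular window, no zero-padding; resolution `fs/L`),
   and pick the largest amplitude at or above `f_min = 0.8` Hz. Ties
   go to the lowest qualifying bin. The winning frequency `F_CGO`
   becomes the notch centre. If no peak exists (constant record) the
   notch is skipped with a warning by default — CGO-free records, such
   as those captured from cadavers, should pass through nearly
   unchanged.
2. **Embedding.** Window length `N = round(1.5 fs)` — one full breath
   at the fastest physiological respiratory rate (40 breaths/min) — so
   each lagged vector spans at least one complete respiratory effort.
   The trajectory matrix is `M x N` Hankel, `M = L - N + 1`; at least
   `N + 1` samples are required (`M >= 2`).
3. **Decomposition.** Thin SVD of the trajectory matrix (numerically
   safer than forming `P^T P`; eigenvalues are the squared singular
   values, sorted non-increasing). Anti-diagonal averaging of each
   rank-one term yields `min(M, N)` reconstructed components (RCs)
   that sum pointwise to the input. The averaging is computed as
   `sigma * convolve(u, v) / counts`, which is algebraically identical
   to Hankelising the rank-one matrix and costs O(L log L) per
   component.
4. **Component filtering.** Every RC passes a zero-phase 4th-order
   Butterworth bandpass, 0.17–1.4 Hz, then a zero-phase 4th-order
   Butterworth band-stop at `F_CGO ± 0.05` Hz. Both are realised as
   cascaded second-order sections and applied forward–backward.
5. **Selection.** Filtered components are weighted by percent energy
   share (weights sum to 100) and summed *in eigenvalue order* until
   the cumulative weight reaches `Th_W = 99.99 %`; the count at the
   stop is `n_opt`. The running sum — plus the input mean if baseline
   preservation is on — is the denoised trace; the extracted CGO is
   the pointwise residual, so denoised + extracted always reconstructs
   the input exactly.

Note an algebraic fact that shapes the whole design: filtering is
linear, so the sum of *all* filtered components equals the bandpass +
notch of the raw signal. Everything the decomposition adds over direct
filtering therefore enters through the selection step, which discards
trailing components; those carry the broadband residue (filter-leaked
artifact, sensor noise) that fixed filters cannot touch.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `f_min` | 0.8 | Hz | lower edge of the physiological heart-rate band |
| bandpass | 0.17–1.4 | Hz | breathing band plus headroom below the common heart-rate range |
| filter order | 4 | – | Butterworth design order per stage, applied forward–backward |
| notch half-width | 0.05 | Hz | narrow enough to spare breath harmonics, wide enough for heart-rate drift within a record |
| `Th_W` | 99.99 | % | grid search over {90, 95, 99, 99.9, 99.99, 100} on the synthetic ensemble places the PRD minimum here; at 100 % the CGO-dominated trailing components re-enter |
| `N` | 1.5·fs | samples | one breath at 40 breaths/min; round-half-up when fractional |
| baseline preservation | on | – | re-add the input mean after selection (below) |

**Baseline.** The 0.17 Hz high-pass removes the DC level of every
component, yet end-expiratory pressure is a clinical feature. The
chain therefore re-adds the input mean to the selected sum by default.
This restores the record-average level; it does not restore sub-0.17 Hz
drift, which is genuinely outside the passband.

**Edge handling.** A zero-phase IIR pass needs edge extension, and the
settling of a 0.17 Hz edge is several seconds. We pad with the
boundary value over three periods of the low cutoff
(`min(L-1, 3 fs / band_lo)` samples, ~18 s at fs=100); short reflective
padding of a few dozen samples was measured to leave start/end
transients worth several PRD points on minute-long records. The first
and last `edge_samples` (reported in result metadata) remain the least
trustworthy part of any output.

**Rank tolerance.** Eigenvalues below `1e-12 · lambda_1` count as zero
for the rank diagnostic. With `M < N` (short windows) only `min(M, N)`
components exist; the remainder are identically zero and are not
materialised.

## Streaming

The same chain applies to successive windows of `chunk >= N + 1`
samples, re-estimating `F_CGO` per window so the notch follows
heart-rate drift. Windows are non-overlapping by default. An optional
`overlap` margin processes `±overlap` context samples around each
window and emits only the interior, moving the per-window filter
transients into discarded samples; with 10 s windows and a 5 s margin
at fs=100 the streamed output stays within 1.5x of the batch
reconstruction error, while plain non-overlapping windows can triple
it. A final partial window is reflect-padded to the minimum length,
denoised, trimmed, and flagged in metadata.

## Synthetic test bed

No public Peso recordings exist, so evaluation runs on a seeded
parametric generator.

* **Breaths**: baseline `pee` plus one raised-cosine deflection per
  cycle over the inspiratory fraction (`duty`, default 0.35) —
  negative-going for active (spontaneous) breathing, positive-going
  for passive (ventilator-driven) insufflation. Cycle periods are
  jittered multiplicatively (default 2 %, quasi-periodic like real
  breathing). The deflection train is then low-pass filtered to the
  0.67 Hz physiological band edge (8th-order zero-phase Butterworth)
  and rescaled so the peak deflection equals `swing`. The band
  limiting is essential, not cosmetic: real Peso traces carry almost
  no energy in the cardiac band, and that separation is the premise
  the method rests on. An unfiltered pulse train would spray
  harmonics above 0.8 Hz that can out-vote a weak CGO line in the
  detector — a failure mode of the *generator*, not of the method.
* **CGO**: harmonic stack at the heart rate (default 3 harmonics,
  amplitude ratio 0.5, seeded phases), optional slow (0.1 Hz)
  amplitude modulation mimicking respiratory modulation of the
  cardiac signal (off by default), zero mean.
* **Mixing**: `SynPeso = Peso + (CGO / max|CGO|) · (max|Peso| · F)`,
  so `F` is the artifact peak as a fraction of the clean-signal peak.
* **Noise**: optional white Gaussian noise at a prescribed SNR
  (realised within 0.1 dB).

**Study conditions** used by the tests and the acceptance script:
active breathing, fs=100 Hz, 60 s records, respiratory rate drawn
uniformly from 12–35 breaths/min, swing 5–15 cmH2O, heart rate
0.9–2.5 Hz, F=0.3 for the headline figure. Twenty records keep the
ensemble computation in seconds while the seed-to-seed spread of the
mean PRD stays under ~1 percentage point.

What the generator does *not* emulate: heart-rate drift and
beat-to-beat variability, non-stationary breathing patterns, ventilator
asynchronies, balloon-catheter dynamics, and the exact morphology of
bench-simulator waveforms. Passing results on this bed show the chain
removes a band-separated quasi-periodic artifact with small distortion;
they do not certify performance on pathological clinical morphologies.

## What the numbers mean

* **PRD** (percent RMS difference vs the clean original): ≤2 % "very
  good", 2–9 % "good". Under the study conditions the chain averages
  ~7–9 % at F=0.3, inside the "good" band. The floor is set not by
  residual artifact (the notch leaves <0.5 % of it) but by the
  bandpass itself: a 0.17 Hz high-pass attenuates the breathing
  fundamental noticeably when the rate is near 12 breaths/min
  (0.2 Hz). That cost is inherent to the published cutoffs.
* **Th_W grid**: over F ∈ {0.1…1.0} × seeds, the mean PRD is minimised
  at 99.99 %, with 100 % slightly worse (trailing components re-admit
  filter-leaked artifact and noise) and ≤99 % clearly worse (real
  breath energy is discarded).
* **Fixed-filter comparison**: on inputs with amplitude-modulated CGO
  and 20 dB sensor noise the SSA chain's median PRD beats direct
  bandpass+notch filtering of the same records. On a *purely*
  narrowband synthetic artifact the two coincide by the linearity
  argument above — the comparison is only meaningful when the input
  has the broadband content real records have.
* **MOS utilities** aggregate expert 1–5 ratings into mean opinion
  scores and percent errors (≤15 % "very good", 15–35 % "good"); the
  package implements only the arithmetic, not the survey.
* **PTP** (cmH2O·s) integrates the rectified inspiratory deflection
  below the window-start baseline (trapezoidal rule); the chest-wall
  recoil bound (tidal volume × chest-wall elastance, ramped linearly
  over the inspiratory fraction) is a configurable concretisation and
  is off by default so simple geometric examples are exact. **WOB**
  (J/L) is the shoelace area of the sampled pressure–volume loop,
  converted at 1 cmH2O·L = 0.0981 J, divided by tidal volume.
  Inspiratory windows are explicit inputs — effort-onset detection is
  a manual clinical step, not part of this package.

## Numerical choices and degenerate inputs

* Thin SVD via LAPACK (`scipy.linalg.svd`); tied eigenvalues keep the
  solver's ordering, and no operation depends on order within a tied
  block.
* Cumulative-weight comparison uses a 1e-9 tolerance so `Th_W = 100`
  matches the full sum despite rounding.
* A threshold unreachable from the weights (pathological) returns all
  components with a warning rather than failing.
* Constant records: rank-1 decomposition, no spectral peak (warn +
  skip notch), DC passes through via baseline preservation.
* Filters are designed per call and rejected if any pole reaches the
  unit circle.
* Separability: two sinusoids group cleanly only when their spacing
  exceeds the window resolution `fs/N` Hz *and* their amplitudes
  differ; equal amplitudes produce near-degenerate eigenvalue pairs
  whose singular vectors mix the two modes — an intrinsic limitation
  of the decomposition, demonstrated in the tests in both directions.

## Known limitations

* A single global notch per record (batch mode) assumes a steady heart
  rate; use streaming mode when drift matters.
* Breathing rates below ~14 breaths/min push the fundamental toward
  the 0.17 Hz cutoff and raise distortion regardless of contamination.
* If the true heart rate falls below 0.8 Hz (severe bradycardia) the
  detector cannot find it; `f_min` is configurable.
* EDF input is not supported; I/O is delimited text only.
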