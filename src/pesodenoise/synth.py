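"""Seeded synthetic Peso / CGO generator.

Real esophageal-pressure recordings from ICU patients are not publicly
shareable, so this module provides a parametric test bed: clean breath
waveforms in both clinical morphologies, a quasi-periodic cardiogenic
oscillation model, amplitude-referenced mixing, and white-Gaussian-noise
injection at a prescribed SNR.

* **Active breathing** (spontaneous effort): the respiratory muscles
  contract during inspiration, so the Peso trace deflects *downward*
  from its end-expiratory baseline.
* **Passive breathing** (ventilator insufflation): positive pressure
  drives the breath, so the trace deflects *upward*.

Breath deflections are raised-cosine pulses over the inspiratory
fraction of each cycle, low-pass filtered to the physiological Peso
band (upper edge 0.67 Hz) and rescaled so the peak deflection equals
``swing``. The band-limiting matters: the whole premise of notch-based
CGO removal is that breathing energy lives below ~0.67 Hz while the
cardiac artifact's fundamental sits at or above 0.8 Hz, and a raw pulse
train would spray harmonics into the cardiac band that no real Peso
trace has. Cycle lengths are perturbed multiplicatively by seeded
jitter, making records quasi-periodic like real breathing.

The CGO model is a harmonic series at the heart rate (fundamental plus
optional decaying overtones, seeded phases) with optional slow
amplitude modulation mimicking respiratory modulation of the cardiac
signal.

Mixing follows the amplitude-referenced rule used for building
contaminated test signals: the CGO is normalised to unit peak and
scaled to a fraction ``F`` of the clean signal's peak amplitude,

    SynPeso = Peso + (CGO / max|CGO|) * (max|Peso| * F),

so ``F = 1`` means the artifact peak equals the clean-signal peak.
Every generator is a pure function of (spec, fs, duration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .exceptions import InvalidArgumentError
from .signal import PressureSignal

__all__ = [
    "BreathSpec", "CgoSpec", "MixSpec", "SynthSpec",
    "gen_peso", "gen_cgo", "mix", "add_wgn", "gen_synpeso",
]


@dataclass(frozen=True)
class BreathSpec:
    """Clean-breath parameters.

    rr : respiratory rate, breaths/min (10-40, the design envelope of
        the SSA window length).
    pee : end-expiratory pressure baseline, cmH2O.
    swing : deflection magnitude per breath, cmH2O (> 0).
    duty : inspiratory fraction of each cycle (0-1).
    jitter : relative cycle-to-cycle period variability (>= 0);
        2% keeps records quasi-periodic like real breathing.
    normalize : rescale the finished record to peak |1| (the convention
        of bench-simulator test signals normalised to ±1).
    """

    mode: str = "active"
    rr: float = 15.0
    pee: float = 0.0
    swing: float = 8.0
    duty: float = 0.35
    jitter: float = 0.02
    normalize: bool = False

    def validate(self) -> None:
        if self.mode not in ("active", "passive"):
            raise InvalidArgumentError(f"mode must be active|passive, got {self.mode!r}")
        if not (10.0 <= self.rr <= 40.0):
            raise InvalidArgumentError(
                f"respiratory rate {self.rr} breaths/min outside the 10-40 envelope")
        if self.swing <= 0:
            raise InvalidArgumentError("pressure swing must be positive")
        if not (0 < self.duty < 1):
            raise InvalidArgumentError("duty must lie in (0, 1)")
        if self.jitter < 0:
            raise InvalidArgumentError("jitter must be non-negative")


@dataclass(frozen=True)
class CgoSpec:
    """Cardiogenic-oscillation parameters.

    heart_rate : fundamental in Hz (0.8-4.0, i.e. 48-240 beats/min).
    n_harmonics : number of harmonic partials (>= 1).
    harmonic_decay : amplitude ratio between successive harmonics (0-1).
    am_depth : depth of a slow (0.1 Hz) amplitude modulation (0-1);
        0 disables it.
    """

    heart_rate: float = 1.2
    n_harmonics: int = 3
    harmonic_decay: float = 0.5
    am_depth: float = 0.0

    def validate(self, fs: float) -> None:
        if not (0.8 <= self.heart_rate <= 4.0):
            raise InvalidArgumentError(
                f"heart rate {self.heart_rate} Hz outside the 0.8-4 Hz band")
        if self.n_harmonics < 1:
            raise InvalidArgumentError("need at least one harmonic")
        if not (0 <= self.harmonic_decay <= 1):
            raise InvalidArgumentError("harmonic decay must lie in [0, 1]")
        if not (0 <= self.am_depth <= 1):
            raise InvalidArgumentError("AM depth must lie in [0, 1]")
        if self.n_harmonics * self.heart_rate >= fs / 2:
            raise InvalidArgumentError(
                f"highest harmonic {self.n_harmonics * self.heart_rate} Hz "
                f"is at or above Nyquist ({fs / 2} Hz)")


@dataclass(frozen=True)
class MixSpec:
    """Contamination parameters: CGO scaling factor and optional WGN SNR."""

    f: float = 0.5
    wgn_snr_db: float | None = None

    def validate(self) -> None:
        if not (0 <= self.f <= 1):
            raise InvalidArgumentError(f"scaling factor F must lie in [0, 1], got {self.f}")


@dataclass(frozen=True)
class SynthSpec:
    """Full recipe for one contaminated synthetic record."""

    breath: BreathSpec = BreathSpec()
    cgo: CgoSpec = CgoSpec()
    mix: MixSpec = MixSpec()


def _raised_cosine_pulse(n: int) -> np.ndarray:
    # unit-peak smooth bump: 0.5 * (1 - cos(2 pi k / n)), zero at both ends
    k = np.arange(n)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * k / max(n, 1)))


#: upper band edge of the physiological Peso waveform, Hz
PESO_BAND_HI = 0.67


def gen_peso(spec: BreathSpec, fs: float, duration: float, seed: int) -> PressureSignal:
    """Generate a clean Peso record.

    Baseline ``pee`` plus one raised-cosine deflection per cycle over
    the inspiratory fraction — negative-going in active mode,
    positive-going in passive mode — zero-phase low-pass filtered to
    the 0.67 Hz Peso band edge and rescaled so the peak deflection
    equals ``swing``. Deterministic per ``(spec, fs, duration, seed)``.
    """
    spec.validate()
    if fs <= 0:
        raise InvalidArgumentError("sampling rate must be positive")
    mean_period = 60.0 / spec.rr
    if duration < 2 * mean_period:
        raise InvalidArgumentError(
            f"duration {duration} s is under two breath cycles ({2 * mean_period:.1f} s)")
    rng = np.random.default_rng(seed)
    n_total = int(round(duration * fs))
    x = np.full(n_total, float(spec.pee))
    sign = -1.0 if spec.mode == "active" else 1.0
    start = 0.0
    while start < n_total:
        period = mean_period * (1.0 + spec.jitter * rng.standard_normal())
        period = max(period, 0.25 * mean_period)
        n_insp = int(round(spec.duty * period * fs))
        i0 = int(round(start))
        i1 = min(i0 + n_insp, n_total)
        if i1 > i0 and n_insp >= 2:
            x[i0:i1] += sign * spec.swing * _raised_cosine_pulse(n_insp)[: i1 - i0]
        start += period * fs
    # confine the waveform to the physiological breathing band; the
    # fundamental (rr/60 <= 0.67 Hz) always survives, while content in
    # the cardiac band (>= 0.8 Hz) is suppressed hard — the band
    # separation is a premise of the denoising method, so the clean
    # waveform must honour it the way real Peso traces do
    if fs / 2 > PESO_BAND_HI:
        sos = scipy.signal.butter(8, PESO_BAND_HI, btype="lowpass", fs=fs, output="sos")
        deflection = scipy.signal.sosfiltfilt(sos, x - spec.pee)
        peak = np.max(np.abs(deflection))
        if peak > 0:
            deflection *= spec.swing / peak
        x = spec.pee + deflection
    if spec.normalize:
        peak = np.max(np.abs(x))
        if peak > 0:
            x = x / peak
    return PressureSignal(samples=x, fs=fs, label=f"synthetic {spec.mode} Peso")


def gen_cgo(spec: CgoSpec, fs: float, duration: float, seed: int) -> PressureSignal:
    """Generate a model cardiogenic oscillation.

    ``sum_k decay**(k-1) sin(2 pi k h t + phi_k)`` with seeded phases,
    optionally amplitude-modulated at 0.1 Hz; the output has zero mean.
    """
    if fs <= 0:
        raise InvalidArgumentError("sampling rate must be positive")
    spec.validate(fs)
    rng = np.random.default_rng(seed)
    n_total = int(round(duration * fs))
    t = np.arange(n_total) / fs
    x = np.zeros(n_total)
    for k in range(1, spec.n_harmonics + 1):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x += spec.harmonic_decay ** (k - 1) * np.sin(2.0 * np.pi * k * spec.heart_rate * t + phase)
    if spec.am_depth > 0:
        am_phase = rng.uniform(0.0, 2.0 * np.pi)
        x *= 1.0 + spec.am_depth * np.sin(2.0 * np.pi * 0.1 * t + am_phase)
    x -= x.mean()
    return PressureSignal(samples=x, fs=fs, label="synthetic CGO")


def mix(peso: PressureSignal, cgo: PressureSignal, f: float) -> PressureSignal:
    """Amplitude-referenced contamination of a clean record.

    ``SynPeso = peso + (cgo / max|cgo|) * (max|peso| * f)`` with the
    maxima taken over the whole record.
    """
    if not (0 <= f <= 1):
        raise InvalidArgumentError(f"scaling factor F must lie in [0, 1], got {f}")
    if len(peso) != len(cgo) or peso.fs != cgo.fs:
        raise InvalidArgumentError("peso and cgo must share length and sampling rate")
    if f == 0:
        return peso.with_samples(peso.samples.copy(), label=peso.label)
    peak_cgo = np.max(np.abs(cgo.samples))
    if peak_cgo == 0:
        raise InvalidArgumentError("CGO has zero peak amplitude; cannot normalise")
    peak_peso = np.max(np.abs(peso.samples))
    mixed = peso.samples + (cgo.samples / peak_cgo) * (peak_peso * f)
    return peso.with_samples(mixed, label=f"{peso.label} + CGO (F={f})")


def add_wgn(signal: PressureSignal, snr_db: float | None, seed: int) -> PressureSignal:
    """Add seeded white Gaussian noise at a prescribed SNR.

    ``snr_db=None`` is the no-noise sentinel and returns the input
    unchanged. Otherwise the noise power is scaled so
    ``10 log10(P_signal / P_noise) = snr_db``.
    """
    if snr_db is None:
        return signal
    power = np.mean(signal.samples ** 2)
    if power <= 0:
        raise InvalidArgumentError("signal has zero power; SNR undefined")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(len(signal))
    noise_power_target = power / (10.0 ** (snr_db / 10.0))
    noise *= np.sqrt(noise_power_target / np.mean(noise ** 2))
    return signal.with_samples(signal.samples + noise,
                               label=f"{signal.label} + WGN ({snr_db} dB)")


def gen_synpeso(spec: SynthSpec, fs: float, duration: float, seed: int
                ) -> tuple[PressureSignal, PressureSignal, PressureSignal]:
    """Generate (clean, cgo, contaminated) as one seeded bundle.

    Sub-seeds for the breath, CGO and noise generators are derived from
    ``seed`` so the three stages are independent but jointly
    reproducible.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    clean = gen_peso(spec.breath, fs, duration, sub[0])
    cgo = gen_cgo(spec.cgo, fs, duration, sub[1])
    spec.mix.validate()
    noisy = mix(clean, cgo, spec.mix.f)
    if spec.mix.wgn_snr_db is not None:
        noisy = add_wgn(noisy, spec.mix.wgn_snr_db, sub[2])
    return clean, cgo, noisy
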