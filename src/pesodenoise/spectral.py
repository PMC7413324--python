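"""Cardiogenic-oscillation fundamental-frequency estimation.

The heart's pressure artifact (CGO) has its fundamental in the
0.8-4 Hz band (48-240 beats/min), above the 0.17-0.67 Hz band of the
breathing waveform itself. The fundamental ``F_CGO`` is therefore read
off the amplitude spectrum of the contaminated signal as the largest
peak at or above a frequency floor (default 0.8 Hz); it later becomes
the notch-filter centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError, NoPeakError
from .signal import PressureSignal

__all__ = ["SpectrumEstimate", "estimate_fcgo", "DEFAULT_F_MIN"]

#: lower edge of the physiological heart-rate band (48 beats/min)
DEFAULT_F_MIN = 0.8


@dataclass(frozen=True)
class SpectrumEstimate:
    """Amplitude spectrum with the detected CGO fundamental.

    ``freqs``/``amplitudes`` cover 0..fs/2 at the record's native
    resolution fs/L; ``f_cgo`` is the frequency of the largest
    amplitude at or above the floor used for the search.
    """

    freqs: np.ndarray
    amplitudes: np.ndarray
    f_cgo: float
    peak_amplitude: float
    f_min: float

    def to_text(self) -> str:
        """Two-column (frequency, amplitude) delimited text for plotting."""
        lines = ["frequency,amplitude"]
        lines += [f"{f:.8g},{a:.8g}" for f, a in zip(self.freqs, self.amplitudes)]
        return "\n".join(lines) + "\n"


def estimate_fcgo(
    signal: PressureSignal,
    f_min: float = DEFAULT_F_MIN,
    window: str | None = None,
) -> SpectrumEstimate:
    """Estimate the CGO fundamental from the DFT of the whole record.

    The mean is removed before the transform so the DC lobe cannot mask
    nearby peaks; no zero-padding, so the grid resolution is ``fs/L``.
    Ties are broken toward the lowest qualifying frequency.

    Parameters
    ----------
    signal : PressureSignal
    f_min : float
        Search floor in Hz (default 0.8, the low edge of the heart-rate
        band). Must be below Nyquist.
    window : {None, "hann"}
        Taper applied before the transform. Default is rectangular
        (none), matching a raw DFT readout.

    Raises
    ------
    NoPeakError
        If the signal is constant (zero spectrum above DC).
    InvalidArgumentError
        If ``f_min`` is at or above Nyquist.
    """
    fs = signal.fs
    if fs / 2 <= f_min:
        raise InvalidArgumentError(
            f"Nyquist frequency {fs / 2} Hz must exceed the search floor {f_min} Hz")
    x = signal.samples - signal.samples.mean()
    length = x.size
    if length / fs < 2.0:
        warnings.warn(
            f"record is only {length / fs:.2f} s long; frequency resolution "
            f"{fs / length:.2f} Hz may be too coarse for reliable CGO detection",
            stacklevel=2)
    if window == "hann":
        x = x * np.hanning(length)
    elif window is not None:
        raise InvalidArgumentError(f"unknown window {window!r}")
    amplitudes = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(length, d=1.0 / fs)
    f_cgo, peak = pick_peak(freqs, amplitudes, f_min)
    return SpectrumEstimate(
        freqs=freqs,
        amplitudes=amplitudes,
        f_cgo=f_cgo,
        peak_amplitude=peak,
        f_min=float(f_min),
    )


def pick_peak(freqs: np.ndarray, amplitudes: np.ndarray, f_min: float
              ) -> tuple[float, float]:
    """Largest amplitude at or above ``f_min``; ties go to the lowest bin."""
    band = freqs >= f_min
    if not band.any():
        raise InvalidArgumentError(f"no DFT bins at or above {f_min} Hz")
    band_amp = amplitudes[band]
    peak = band_amp.max()
    if peak <= 0:
        raise NoPeakError("signal is constant: no spectral peak above the floor")
    # argmax returns the first maximal bin and freqs are ascending, which
    # realises the lowest-frequency tie-break deterministically
    i_abs = int(np.flatnonzero(band)[int(np.argmax(band_amp))])
    return float(freqs[i_abs]), float(peak)
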