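"""Pressure-signal container and delimited-text I/O.

Esophageal pressure (Peso) records are single-channel, uniformly sampled
traces in cmH2O. :class:`PressureSignal` is the in-memory container used
throughout the package; on disk the accepted dialect is delimited text
with either one ``pressure`` column or two ``time,pressure`` columns
(header line optional), the form typically exported by ventilator and
acquisition software.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, InvalidInputError

__all__ = ["PressureSignal", "read_signal", "write_signal"]

#: maximum allowed relative jitter of the time column for rate inference
_UNIFORMITY_RTOL = 1e-6


@dataclass(frozen=True)
class PressureSignal:
    """A uniformly sampled pressure trace.

    Parameters
    ----------
    samples : array-like of float
        Pressure values in cmH2O. Must be finite and contain at least
        two samples.
    fs : float
        Sampling rate in Hz, strictly positive.
    label : str, optional
        Free-text description carried through processing.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    #: metadata accumulated by processing stages (edge flags, padding notes)
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1:
            raise InvalidInputError(f"samples must be 1-D, got shape {arr.shape}")
        if arr.size < 2:
            raise InvalidArgumentError(f"need at least 2 samples, got {arr.size}")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("samples contain non-finite values")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise InvalidArgumentError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.samples.size / self.fs

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray, label: str | None = None,
                     meta: dict | None = None) -> "PressureSignal":
        """Return a copy carrying new samples at the same rate."""
        return PressureSignal(
            samples=np.asarray(samples, dtype=float),
            fs=self.fs,
            label=self.label if label is None else label,
            meta=dict(self.meta) if meta is None else meta,
        )


def read_signal(path_or_buf, fs: float | None = None, label: str | None = None) -> PressureSignal:
    """Read a pressure trace from delimited text.

    Accepts one-column (``pressure``) or two-column (``time,pressure``)
    files, comma/tab/whitespace separated, with or without a header line.
    With a time column the sampling rate is inferred and the column is
    checked for uniformity; otherwise ``fs`` must be given.

    Parameters
    ----------
    path_or_buf : path or file-like
    fs : float, optional
        Sampling rate in Hz. Required for one-column files; if given for
        a two-column file it overrides the inferred rate (still checked
        for uniformity).
    """
    df = pd.read_csv(path_or_buf, sep=r"[\s,;]+", engine="python", header=None,
                     comment="#", skip_blank_lines=True)
    # drop a header row if the first row is non-numeric
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    df = df.apply(pd.to_numeric, errors="raise")
    if df.shape[1] == 1:
        if fs is None:
            raise InvalidArgumentError(
                "one-column file: sampling rate must be supplied via fs")
        samples = df.iloc[:, 0].to_numpy(dtype=float)
        rate = float(fs)
    elif df.shape[1] == 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        samples = df.iloc[:, 1].to_numpy(dtype=float)
        dt = np.diff(t)
        if dt.size == 0 or np.any(dt <= 0):
            raise InvalidInputError("time column must be strictly increasing")
        mean_dt = dt.mean()
        if np.max(np.abs(dt - mean_dt)) > _UNIFORMITY_RTOL * mean_dt:
            raise InvalidInputError(
                "time column is not uniform within 1e-6 relative tolerance")
        rate = float(fs) if fs is not None else 1.0 / mean_dt
    else:
        raise InvalidInputError(
            f"expected 1 or 2 columns, got {df.shape[1]}")
    if label is None:
        label = os.fspath(path_or_buf) if isinstance(path_or_buf, (str, os.PathLike)) else ""
    return PressureSignal(samples=samples, fs=rate, label=label)


def write_signal(signal: PressureSignal, path_or_buf, include_time: bool = True) -> None:
    """Write a trace as delimited text (``time,pressure`` by default)."""
    if include_time:
        df = pd.DataFrame({"time": signal.time, "pressure": signal.samples})
    else:
        df = pd.DataFrame({"pressure": signal.samples})
    df.to_csv(path_or_buf, index=False)


def signal_to_text(signal: PressureSignal) -> str:
    """Render a trace in the on-disk dialect as a string."""
    buf = io.StringIO()
    write_signal(signal, buf)
    return buf.getvalue()
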