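"""Singular spectrum analysis core: embedding, SVD, reconstruction.

SSA decomposes a length-``L`` series into additive components by

1. *embedding* — arranging lagged copies of the signal into an
   ``M x N`` Hankel trajectory matrix (``M = L - N + 1``, window
   length ``N`` columns);
2. *decomposition* — thin SVD of the trajectory matrix into rank-one
   elementary matrices ``sqrt(lambda_i) u_i v_i^T`` with eigenvalues
   ``lambda_i = sigma_i**2`` of ``S = P^T P`` sorted non-increasing;
3. *reconstruction* — anti-diagonal (Hankel) averaging of each
   elementary matrix back into a length-``L`` reconstructed component
   (RC). The RCs sum pointwise to the original signal.

The window length is tied to respiratory physiology: the fastest human
respiratory rate on record is 40 breaths/min, so a window of
``60 * fs / 40 = 1.5 * fs`` samples spans at least one full breath at
any physiological rate, which is what lets the leading eigentriples
capture the breathing waveform while cardiogenic oscillations fall into
later components.

Anti-diagonal averaging is implemented as a linear convolution of the
scaled singular vectors (``sigma * convolve(u, v) / counts``), which is
algebraically identical to averaging the anti-diagonals of the rank-one
matrix but runs in O(L log L) per component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.signal

from .exceptions import InvalidArgumentError, InvalidInputError, TooShortSignalError
from .signal import PressureSignal

__all__ = [
    "window_length",
    "embed",
    "decompose",
    "reconstruct_components",
    "reconstruct_group",
    "TrajectoryMatrix",
    "SsaDecomposition",
]

#: fastest human respiratory rate (breaths per minute) anchoring the window
MAX_BREATHS_PER_MIN = 40

#: eigenvalues below RANK_RTOL * lambda_1 are treated as numerically zero
RANK_RTOL = 1e-12


def window_length(fs: float) -> int:
    """Window length (samples) for a given sampling rate.

    ``N = round(60 * fs / 40) = round(1.5 * fs)``, one full breath at
    the fastest physiological respiratory rate. Rounding is half-up.

    >>> window_length(200)
    300
    """
    if not (np.isfinite(fs) and fs > 0):
        raise InvalidArgumentError(f"sampling rate must be positive, got {fs}")
    n = int(np.floor(60.0 * fs / MAX_BREATHS_PER_MIN + 0.5))  # round half-up
    return max(n, 2)


@dataclass(frozen=True)
class TrajectoryMatrix:
    """Hankel matrix of lagged signal copies.

    ``values`` is ``M x N`` with column ``j`` equal to the signal
    delayed by ``j`` samples, truncated to ``M = L - N + 1`` samples;
    every anti-diagonal is constant.
    """

    values: np.ndarray
    n_window: int

    @property
    def m_lagged(self) -> int:
        return self.values.shape[0]

    @property
    def signal_length(self) -> int:
        return self.values.shape[0] + self.n_window - 1


def embed(signal: PressureSignal | np.ndarray, n_window: int) -> TrajectoryMatrix:
    """Embed a signal into its trajectory matrix.

    Requires ``n_window >= 2`` and at least ``n_window + 1`` samples so
    the matrix has at least two rows (the streaming minimum-length rule).
    """
    x = signal.samples if isinstance(signal, PressureSignal) else np.asarray(signal, float)
    if n_window < 2:
        raise InvalidArgumentError(f"window length must be >= 2, got {n_window}")
    length = x.size
    if length < n_window + 1:
        raise TooShortSignalError(
            f"signal has {length} samples but the window length {n_window} "
            f"requires at least {n_window + 1}")
    m = length - n_window + 1
    # stride trick then copy: column j = x[j : j + m]
    values = np.lib.stride_tricks.sliding_window_view(x, m).T.copy()
    return TrajectoryMatrix(values=values, n_window=n_window)


@dataclass(frozen=True)
class SsaDecomposition:
    """Result of the SVD step plus reconstructed components.

    Attributes
    ----------
    eigenvalues : (K,) ndarray
        ``lambda_i = sigma_i**2``, non-increasing, ``K = min(M, N)``.
    left_vectors : (M, K) ndarray
        Left singular vectors ``u_i`` (columns).
    right_vectors : (N, K) ndarray
        Right singular vectors ``v_i`` (columns).
    rcs : (K, L) ndarray
        Reconstructed components; ``rcs.sum(axis=0)`` equals the
        original signal. Components beyond ``min(M, N)`` are exactly
        zero and not materialised.
    """

    eigenvalues: np.ndarray
    left_vectors: np.ndarray
    right_vectors: np.ndarray
    n_window: int
    signal_length: int

    @property
    def singular_values(self) -> np.ndarray:
        return np.sqrt(self.eigenvalues)

    @property
    def rank(self) -> int:
        """Number of eigenvalues above ``RANK_RTOL * lambda_1``."""
        if self.eigenvalues.size == 0 or self.eigenvalues[0] <= 0:
            return 0
        return int(np.sum(self.eigenvalues > RANK_RTOL * self.eigenvalues[0]))

    @property
    def rcs(self) -> np.ndarray:
        return reconstruct_components(self)


def decompose(traj: TrajectoryMatrix) -> SsaDecomposition:
    """Thin SVD of the trajectory matrix.

    The eigenvalues of ``S = P^T P`` are the squared singular values of
    ``P``; computing the SVD of ``P`` directly avoids the conditioning
    loss of forming ``S`` explicitly.
    """
    values = traj.values
    if not np.all(np.isfinite(values)):
        raise InvalidInputError("trajectory matrix contains non-finite entries")
    u, s, vt = scipy.linalg.svd(values, full_matrices=False)
    return SsaDecomposition(
        eigenvalues=s ** 2,
        left_vectors=u,
        right_vectors=vt.T,
        n_window=traj.n_window,
        signal_length=traj.signal_length,
    )


def _antidiagonal_counts(m: int, n: int) -> np.ndarray:
    # number of (row, col) pairs on each anti-diagonal of an m x n matrix
    return np.convolve(np.ones(m), np.ones(n))


def reconstruct_components(dec: SsaDecomposition) -> np.ndarray:
    """Hankelise every elementary matrix into a length-``L`` component.

    ``RC_i[k]`` is the mean over the anti-diagonal ``l + m = k`` of
    ``sigma_i u_i v_i^T``; computed as
    ``sigma_i * convolve(u_i, v_i) / counts``.
    """
    m = dec.left_vectors.shape[0]
    n = dec.right_vectors.shape[0]
    counts = _antidiagonal_counts(m, n)
    k = dec.eigenvalues.size
    out = np.empty((k, dec.signal_length))
    sigmas = dec.singular_values
    for i in range(k):
        conv = scipy.signal.fftconvolve(dec.left_vectors[:, i], dec.right_vectors[:, i])
        # fftconvolve can leave tiny imaginary dust only for complex input;
        # inputs are real so conv is real. Trim any length excess from fft rounding.
        out[i] = sigmas[i] * conv[: dec.signal_length] / counts
    return out


def reconstruct_group(dec: SsaDecomposition, indices) -> np.ndarray:
    """Reconstruct the series for a group of eigentriple indices.

    Equivalent to summing the individual RCs of the group; used for
    eigenpair grouping (e.g. separating two oscillatory modes).
    """
    idx = np.atleast_1d(np.asarray(indices, dtype=int))
    if idx.size == 0:
        return np.zeros(dec.signal_length)
    m = dec.left_vectors.shape[0]
    n = dec.right_vectors.shape[0]
    counts = _antidiagonal_counts(m, n)
    total = np.zeros(dec.signal_length)
    for i in idx:
        conv = scipy.signal.fftconvolve(dec.left_vectors[:, i], dec.right_vectors[:, i])
        total += dec.singular_values[i] * conv[: dec.signal_length]
    return total / counts
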