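"""Reconstruction-quality and respiratory-effort metrics.

Quantitative quality: percent root-mean-square difference (PRD) between
a reference trace and a reconstruction, the standard figure for
processed biosignals (0-2% "very good", 2-9% "good"), and an SNR in dB
for noise-injection experiments.

Qualitative aggregation: mean opinion score (MOS) over an evaluators x
features table of 1-5 ratings, with per-feature and overall MOS errors
(percent deviation from a perfect 5) categorised as "very good"
(<= 15%) or "good" (15-35%).

Respiratory effort: pressure-time product (PTP) per breath and per
minute, and work of breathing (WOB) from the pressure-volume loop.
These are the clinical quantities whose values cardiac artifacts
distort, hence the point of denoising.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError, UndefinedMetricError
from .signal import PressureSignal

__all__ = [
    "prd", "snr_db", "quality_category",
    "MosRatings", "MosResult", "mos",
    "EffortInputs", "ptp_breath", "ptp_minute", "wob",
    "JOULE_PER_CMH2O_L",
]

#: 1 cmH2O * 1 L expressed in joules (98.1 Pa * 1e-3 m^3)
JOULE_PER_CMH2O_L = 0.0981


def _as_array(x) -> np.ndarray:
    return x.samples if isinstance(x, PressureSignal) else np.asarray(x, dtype=float)


def prd(reference, estimate) -> float:
    """Percent root-mean-square difference.

    ``100 * sqrt( sum (ref - est)^2 / sum ref^2 )``.
    """
    ref = _as_array(reference)
    est = _as_array(estimate)
    if ref.shape != est.shape:
        raise InvalidArgumentError("reference and estimate must have equal length")
    denom = np.sum(ref ** 2)
    if denom <= 0:
        raise UndefinedMetricError("reference has zero energy; PRD undefined")
    return float(100.0 * np.sqrt(np.sum((ref - est) ** 2) / denom))


def snr_db(clean, noisy_or_denoised) -> float:
    """Signal-to-residual ratio in dB: ``10 log10(sum clean^2 / sum res^2)``.

    Returns ``+inf`` when the residual is exactly zero.
    """
    ref = _as_array(clean)
    sig = _as_array(noisy_or_denoised)
    if ref.shape != sig.shape:
        raise InvalidArgumentError("signals must have equal length")
    p_clean = np.sum(ref ** 2)
    if p_clean <= 0:
        raise UndefinedMetricError("clean signal has zero power; SNR undefined")
    p_res = np.sum((sig - ref) ** 2)
    if p_res == 0:
        return math.inf
    return float(10.0 * np.log10(p_clean / p_res))


def quality_category(prd_percent: float) -> str:
    """Standard PRD quality bands: [0,2] very_good, (2,9] good, else other."""
    if prd_percent < 0:
        raise InvalidArgumentError(f"PRD cannot be negative, got {prd_percent}")
    if prd_percent <= 2.0:
        return "very_good"
    if prd_percent <= 9.0:
        return "good"
    return "other"


# --------------------------------------------------------------------------
# mean opinion score


@dataclass(frozen=True)
class MosRatings:
    """Evaluators x features table of integer quality ratings 1-5."""

    ratings: np.ndarray

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.ratings, dtype=float))
        if arr.size == 0:
            raise InvalidArgumentError("ratings table is empty")
        if not np.all(np.isin(arr, [1, 2, 3, 4, 5])):
            raise InvalidArgumentError("all ratings must be integers in 1..5")
        object.__setattr__(self, "ratings", arr)

    @property
    def n_evaluators(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_features(self) -> int:
        return self.ratings.shape[1]


@dataclass(frozen=True)
class MosResult:
    """Aggregated MOS with per-feature scores and error percentages."""

    mos: float                     # grand mean of all ratings
    mos_per_feature: np.ndarray    # mean over evaluators, one per feature
    error_per_feature: np.ndarray  # (1 - MOS(f)/5) * 100, percent
    error_overall: float           # (1 - MOS/5) * 100, percent
    category: str                  # from the overall error


def _mos_category(error_percent: float) -> str:
    if error_percent <= 15.0:
        return "very_good"
    if error_percent <= 35.0:
        return "good"
    return "other"


def mos(ratings: MosRatings | np.ndarray) -> MosResult:
    """Aggregate a ratings table into MOS scores and error percentages."""
    if not isinstance(ratings, MosRatings):
        ratings = MosRatings(ratings)
    table = ratings.ratings
    grand = float(table.mean())
    per_feature = table.mean(axis=0)
    err_feature = (1.0 - per_feature / 5.0) * 100.0
    err_overall = (1.0 - grand / 5.0) * 100.0
    return MosResult(
        mos=grand,
        mos_per_feature=per_feature,
        error_per_feature=err_feature,
        error_overall=float(err_overall),
        category=_mos_category(err_overall),
    )


# --------------------------------------------------------------------------
# respiratory-effort parameters


@dataclass(frozen=True)
class EffortInputs:
    """Inputs for PTP / WOB computation.

    insp_windows are (start, end) sample intervals (end exclusive)
    marking each inspiratory effort; effort onset detection is manual
    in clinical practice, so the windows are an explicit input.
    chest_wall_elastance (cmH2O/L) and tidal_volume (L) bound the
    inspiratory integral by the chest-wall recoil pressure when the
    recoil schedule is enabled.
    """

    peso: PressureSignal
    insp_windows: tuple
    respiratory_rate: float = 0.0
    volume: np.ndarray | None = None
    chest_wall_elastance: float = 0.0
    tidal_volume: float = 0.0

    def __post_init__(self) -> None:
        for (start, end) in self.insp_windows:
            if not (0 <= start < end <= len(self.peso)):
                raise InvalidArgumentError(
                    f"window ({start}, {end}) outside record of {len(self.peso)} samples")


def ptp_breath(inputs: EffortInputs, window_index: int, apply_recoil: bool = False) -> float:
    """Pressure-time product of one breath, in cmH2O*s.

    Trapezoidal integral over the inspiratory window of
    ``max(0, baseline - Peso(t))`` where the baseline is the pressure at
    the window start (the negative inspiratory deflection, rectified).
    With ``apply_recoil``, the chest-wall recoil pressure — tidal volume
    times chest-wall elastance, ramped linearly over the inspiratory
    fraction elapsed — is subtracted before rectification, bounding the
    effort estimate by the recoil load.
    """
    try:
        start, end = inputs.insp_windows[window_index]
    except IndexError:
        raise InvalidArgumentError(
            f"window index {window_index} out of range "
            f"({len(inputs.insp_windows)} windows)") from None
    x = inputs.peso.samples[start:end]
    baseline = x[0]
    deflection = baseline - x
    if apply_recoil:
        recoil = inputs.tidal_volume * inputs.chest_wall_elastance
        frac = np.linspace(0.0, 1.0, x.size)
        deflection = deflection - recoil * frac
    deflection = np.clip(deflection, 0.0, None)
    return float(np.trapezoid(deflection, dx=1.0 / inputs.peso.fs))


def ptp_minute(inputs: EffortInputs, apply_recoil: bool = False) -> float:
    """Mean per-breath PTP times the respiratory rate (cmH2O*s/min)."""
    if not inputs.insp_windows:
        raise InvalidArgumentError("at least one inspiratory window is required")
    per_breath = [ptp_breath(inputs, i, apply_recoil=apply_recoil)
                  for i in range(len(inputs.insp_windows))]
    return float(np.mean(per_breath) * inputs.respiratory_rate)


#: loops with shoelace area below this (cmH2O*L) are treated as degenerate
_LOOP_AREA_TOL = 1e-12


def wob(inputs: EffortInputs) -> float:
    """Work of breathing in J/L from the pressure-volume loop.

    For each breath window the enclosed area of the sampled
    (volume, pressure) polygon is computed by the shoelace formula
    (cmH2O*L), converted to joules (1 cmH2O*L = 0.0981 J), divided by
    the tidal volume, and averaged over breaths. Degenerate (open or
    collinear) loops contribute zero area with a warning.
    """
    if inputs.volume is None:
        raise InvalidArgumentError("a synchronized volume series is required for WOB")
    if inputs.tidal_volume <= 0:
        raise InvalidArgumentError("tidal volume must be positive")
    vol = np.asarray(inputs.volume, dtype=float)
    if vol.shape != inputs.peso.samples.shape:
        raise InvalidArgumentError("volume and pressure series must be the same length")
    per_breath = []
    for (start, end) in inputs.insp_windows:
        p = inputs.peso.samples[start:end]
        v = vol[start:end]
        area = _shoelace(v, p)
        if area < _LOOP_AREA_TOL:
            warnings.warn(
                f"degenerate pressure-volume loop in window ({start}, {end}); "
                f"area set to 0", stacklevel=2)
            area = 0.0
        per_breath.append(area * JOULE_PER_CMH2O_L / inputs.tidal_volume)
    return float(np.mean(per_breath))


def _shoelace(x: np.ndarray, y: np.ndarray) -> float:
    """Absolute polygon area of the closed (x, y) loop."""
    return float(0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))
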