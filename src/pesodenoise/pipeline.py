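"""End-to-end CGO removal: model/results API, batch and streaming modes.

The chain is: estimate the CGO fundamental from the DFT of the
contaminated record; embed the record into its trajectory matrix with
the sampling-rate-adaptive window ``N = 1.5 * fs``; SVD; reconstruct
the components by anti-diagonal averaging; zero-phase bandpass + notch
filter every component; weight the filtered components by energy; and
sum them in eigenvalue order until the cumulative weight reaches
``Th_W`` (99.99% by default). The running sum is the denoised Peso
trace and the residual ``input - denoised`` is the extracted CGO.

Two calling styles are provided:

* ``SsaDenoiser(signal, config).fit()`` — a model object built from
  the data whose ``fit`` returns :class:`SsaDenoiseResults` carrying
  the denoised trace, the detected fundamental, ``n_opt``, the
  component weights and a ``summary()`` table. Refitting with a
  different ``th_w`` reuses the cached decomposition.
* ``denoise(signal, config)`` — a functional one-shot wrapper.

Streaming: the same algorithm applied iteratively on windows of at
least ``N + 1`` samples (the minimum needed to form the trajectory
matrix), re-estimating the CGO fundamental per window so the notch
follows heart-rate drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import filtering, spectral, ssa
from .exceptions import InvalidArgumentError, NoPeakError, TooShortSignalError
from .filtering import DEFAULT_TH_W, FilterSpec
from .signal import PressureSignal
from .spectral import DEFAULT_F_MIN

__all__ = [
    "DenoiseConfig",
    "SsaDenoiser",
    "SsaDenoiseResults",
    "denoise",
    "extract_cgo",
    "denoise_stream",
]


@dataclass(frozen=True)
class DenoiseConfig:
    """Tunable parameters of the denoising chain.

    th_w : cumulative-weight threshold in percent (0, 100]. 99.99
        keeps essentially all breath energy while dropping the
        CGO-dominated trailing components.
    f_min : lower edge of the CGO search band, Hz.
    band_lo, band_hi, filter_order, notch_halfwidth : see
        :class:`~pesodenoise.filtering.FilterSpec`.
    preserve_baseline : re-add the input mean to the selected sum so
        the clinically scored end-expiratory pressure level survives
        the 0.17 Hz high-pass.
    on_no_cgo : "warn" skips the notch with a warning when no spectral
        peak is found (CGO-free records pass through nearly unchanged);
        "error" raises instead.
    stream_mode, chunk : process in successive windows of ``chunk``
        samples (default ``N + 1``) instead of the whole record at once.
    overlap : extra context samples carried on each side of a streaming
        window; only the window interior is emitted, so filter edge
        transients fall in the discarded margin. 0 (default) means
        plain non-overlapping iteration.
    """

    th_w: float = DEFAULT_TH_W
    f_min: float = DEFAULT_F_MIN
    band_lo: float = 0.17
    band_hi: float = 1.4
    filter_order: int = 4
    notch_halfwidth: float = 0.05
    preserve_baseline: bool = True
    on_no_cgo: str = "warn"
    spectral_window: str | None = None
    stream_mode: bool = False
    chunk: int | None = None
    overlap: int = 0

    def validate(self) -> None:
        if not (0 < self.th_w <= 100):
            raise InvalidArgumentError(f"th_w must be in (0, 100], got {self.th_w}")
        if self.on_no_cgo not in ("warn", "error"):
            raise InvalidArgumentError("on_no_cgo must be 'warn' or 'error'")

    def filter_spec(self, notch_center: float | None) -> FilterSpec:
        return FilterSpec(
            band_lo=self.band_lo,
            band_hi=self.band_hi,
            order=self.filter_order,
            notch_center=notch_center,
            notch_halfwidth=self.notch_halfwidth,
        )

    @classmethod
    def from_file(cls, path) -> "DenoiseConfig":
        """Load a flat key/value YAML config (same names as CLI flags)."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - valid
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class SsaDenoiser:
    """SSA-based CGO-removal model for one pressure record.

    Parameters
    ----------
    signal : PressureSignal
        The contaminated record. Must have at least ``N + 1`` samples,
        ``N = round(1.5 * fs)``.
    config : DenoiseConfig, optional

    Notes
    -----
    The expensive stages (spectrum, SVD, component filtering and
    weighting) are computed once on first ``fit`` and cached; fitting
    again with a different ``th_w`` only repeats the selection step.
    """

    def __init__(self, signal: PressureSignal, config: DenoiseConfig | None = None):
        self.signal = signal
        self.config = config or DenoiseConfig()
        self.config.validate()
        self.n_window = ssa.window_length(signal.fs)
        if len(signal) < self.n_window + 1:
            raise TooShortSignalError(
                f"signal has {len(signal)} samples; fs={signal.fs} Hz requires "
                f"at least {self.n_window + 1} (window length {self.n_window} + 1)")
        self._prepared = False
        self.f_cgo: float | None = None
        self.decomposition: ssa.SsaDecomposition | None = None
        self._filrcs: np.ndarray | None = None
        self._weights: np.ndarray | None = None

    @classmethod
    def from_dataframe(cls, df, pressure: str = "pressure", time: str | None = "time",
                       fs: float | None = None,
                       config: DenoiseConfig | None = None) -> "SsaDenoiser":
        """Build from a DataFrame with a pressure column and a time column or fs."""
        samples = np.asarray(df[pressure], dtype=float)
        if fs is None:
            if time is None or time not in df:
                raise InvalidArgumentError("supply fs or a time column")
            dt = np.diff(np.asarray(df[time], dtype=float))
            if np.any(dt <= 0):
                raise InvalidArgumentError("time column must be strictly increasing")
            fs = 1.0 / dt.mean()
        return cls(PressureSignal(samples=samples, fs=fs), config=config)

    # -- internal pipeline stages ------------------------------------------

    def _estimate_fcgo(self) -> float | None:
        cfg = self.config
        try:
            est = spectral.estimate_fcgo(self.signal, f_min=cfg.f_min,
                                         window=cfg.spectral_window)
            return est.f_cgo
        except NoPeakError:
            if cfg.on_no_cgo == "error":
                raise
            warnings.warn(
                "no CGO spectral peak detected; notch filter skipped",
                stacklevel=3)
            return None

    def _prepare(self) -> None:
        if self._prepared:
            return
        cfg = self.config
        self.f_cgo = self._estimate_fcgo()
        traj = ssa.embed(self.signal, self.n_window)
        self.decomposition = ssa.decompose(traj)
        rcs = ssa.reconstruct_components(self.decomposition)
        spec = cfg.filter_spec(self.f_cgo)
        self._filrcs = filtering.filter_components(rcs, spec, self.signal.fs)
        self._weights = filtering.compute_weights(self._filrcs)
        self._prepared = True

    # -- public API ---------------------------------------------------------

    def fit(self, th_w: float | None = None) -> "SsaDenoiseResults":
        """Run the chain and return the results object.

        ``th_w`` overrides the configured threshold for this fit only;
        the cached decomposition is reused.
        """
        cfg = self.config
        if cfg.stream_mode:
            return self._fit_streamed(th_w)
        self._prepare()
        threshold = cfg.th_w if th_w is None else th_w
        summed, n_opt = filtering.select_components(self._filrcs, self._weights, threshold)
        if cfg.preserve_baseline:
            summed = summed + self.signal.samples.mean()
        edge = filtering.edge_padlen(cfg.filter_spec(self.f_cgo), self.signal.fs,
                                     len(self.signal))
        denoised = self.signal.with_samples(
            summed, label=f"denoised {self.signal.label}".strip(),
            meta={"edge_samples": edge})
        return SsaDenoiseResults(
            model=self,
            denoised=denoised,
            f_cgo=self.f_cgo,
            n_opt=n_opt,
            n_window=self.n_window,
            weights=self._weights.copy(),
            th_w=threshold,
            config=cfg,
        )

    def _fit_streamed(self, th_w: float | None = None) -> "SsaDenoiseResults":
        cfg = self.config
        threshold = cfg.th_w if th_w is None else th_w
        chunk = cfg.chunk if cfg.chunk is not None else self.n_window + 1
        if chunk < self.n_window + 1:
            raise InvalidArgumentError(
                f"chunk {chunk} is below the minimum window of "
                f"{self.n_window + 1} samples")
        if cfg.overlap < 0:
            raise InvalidArgumentError("overlap must be non-negative")
        batch_cfg = replace(cfg, stream_mode=False, chunk=None, th_w=threshold)
        pieces = []
        meta: dict = {"stream_chunks": 0}
        x = self.signal.samples
        fs = self.signal.fs
        weights = None
        f_cgo_last = None
        n_opt_last = 0
        for start in range(0, x.size, chunk):
            lead = min(cfg.overlap, start)
            window = x[start - lead:start + chunk + cfg.overlap]
            valid = min(chunk, x.size - start)
            if valid < chunk:
                meta["partial_final_window"] = True
                meta["partial_final_valid_samples"] = int(valid)
            if window.size < self.n_window + 1:
                # final partial window below the minimum: reflective padding
                window = _reflect_pad(window, self.n_window + 1)
            res = SsaDenoiser(PressureSignal(window, fs), batch_cfg).fit()
            pieces.append(res.denoised.samples[lead:lead + valid])
            weights = res.weights
            f_cgo_last = res.f_cgo
            n_opt_last = res.n_opt
            meta["stream_chunks"] += 1
        denoised = self.signal.with_samples(np.concatenate(pieces), meta=meta)
        return SsaDenoiseResults(
            model=self,
            denoised=denoised,
            f_cgo=f_cgo_last,
            n_opt=n_opt_last,
            n_window=self.n_window,
            weights=weights,
            th_w=threshold,
            config=cfg,
        )


@dataclass(frozen=True)
class SsaDenoiseResults:
    """Fitted results: denoised trace, detected CGO parameters, weights.

    ``extracted_cgo`` is the pointwise residual ``input - denoised``,
    so ``denoised + extracted_cgo`` reconstructs the input exactly.
    """

    model: SsaDenoiser
    denoised: PressureSignal
    f_cgo: float | None
    n_opt: int
    n_window: int
    weights: np.ndarray
    th_w: float
    config: DenoiseConfig = field(repr=False)

    @property
    def extracted_cgo(self) -> PressureSignal:
        return extract_cgo(self.model.signal, self.denoised)

    def refit(self, th_w: float) -> "SsaDenoiseResults":
        """Re-run only the component-selection step at a new threshold."""
        return self.model.fit(th_w=th_w)

    def summary(self) -> str:
        """Human-readable fit report."""
        sig = self.model.signal
        lines = [
            "SSA cardiogenic-oscillation removal",
            "=" * 51,
            f"{'Samples (L)':<28}{len(sig):>23}",
            f"{'Sampling rate (Hz)':<28}{sig.fs:>23.6g}",
            f"{'Window length (N)':<28}{self.n_window:>23}",
            f"{'CGO fundamental (Hz)':<28}"
            + (f"{self.f_cgo:>23.4f}" if self.f_cgo is not None else f"{'not detected':>23}"),
            f"{'Th_W (%)':<28}{self.th_w:>23.4f}",
            f"{'Components kept (n_opt)':<28}{self.n_opt:>23}",
            f"{'Components total':<28}{self.weights.size:>23}",
            f"{'Cumulative weight (%)':<28}{np.sum(self.weights[:self.n_opt]):>23.6f}",
            f"{'Baseline preserved':<28}{str(self.config.preserve_baseline):>23}",
            "-" * 51,
            "Leading component weights (%):",
        ]
        head = self.weights[: min(8, self.weights.size)]
        lines.append("  " + "  ".join(f"{w:.4f}" for w in head))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay the contaminated and denoised traces (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        sig = self.model.signal
        ax.plot(sig.time, sig.samples, color="black", lw=0.8, label="contaminated")
        ax.plot(sig.time, self.denoised.samples, color="red", lw=0.9, label="denoised")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("pressure (cmH2O)")
        ax.legend(loc="best")
        return ax


def denoise(signal: PressureSignal, config: DenoiseConfig | None = None) -> SsaDenoiseResults:
    """One-shot functional interface: build the model and fit it."""
    return SsaDenoiser(signal, config=config).fit()


def extract_cgo(noisy: PressureSignal, denoised: PressureSignal) -> PressureSignal:
    """Pointwise residual: the CGO is what denoising removed."""
    if len(noisy) != len(denoised) or noisy.fs != denoised.fs:
        raise InvalidArgumentError(
            "noisy and denoised signals must share length and sampling rate")
    return noisy.with_samples(noisy.samples - denoised.samples, label="extracted CGO")


def denoise_stream(feed, fs: float, config: DenoiseConfig | None = None):
    """Generator form of streaming denoising.

    Consumes an iterable of samples, buffers windows of ``config.chunk``
    samples (default ``N + 1``) and yields each denoised window as an
    ndarray as soon as it completes. A final partial window is padded by
    reflection, denoised, and trimmed back before being yielded. An
    empty feed yields nothing.
    """
    cfg = config or DenoiseConfig()
    n_window = ssa.window_length(fs)
    chunk = cfg.chunk if cfg.chunk is not None else n_window + 1
    if chunk < n_window + 1:
        raise InvalidArgumentError(
            f"chunk {chunk} is below the minimum window of {n_window + 1} samples")
    batch_cfg = replace(cfg, stream_mode=False, chunk=None)
    buffer: list[float] = []
    for sample in feed:
        buffer.append(float(sample))
        if len(buffer) == chunk:
            window = np.asarray(buffer)
            buffer.clear()
            yield SsaDenoiser(PressureSignal(window, fs), batch_cfg).fit().denoised.samples
    if buffer:
        valid = len(buffer)
        window = np.asarray(buffer)
        if valid < n_window + 1:
            window = _reflect_pad(window, n_window + 1)
            warnings.warn(
                f"final partial window of {valid} samples padded by reflection "
                f"to {window.size}", stacklevel=2)
        yield SsaDenoiser(PressureSignal(window, fs), batch_cfg).fit().denoised.samples[:valid]


def _reflect_pad(x: np.ndarray, target: int) -> np.ndarray:
    """Extend ``x`` to ``target`` samples by (repeated) end reflection."""
    if x.size < 2:
        raise TooShortSignalError(
            f"cannot reflect-pad a {x.size}-sample window")
    while x.size < target:
        take = min(x.size - 1, target - x.size)
        x = np.concatenate([x, x[-2:-2 - take:-1]])
    return x
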