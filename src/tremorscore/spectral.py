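"""Windowed spectral estimation with fractal/oscillatory separation (IRASA).

The pipeline slices each channel into 50%-overlapping 8-s windows and, per
window, estimates three spectra:

* the *mixed* spectrum — an ordinary one-sided power spectral density of
  the detrended, Hann-tapered window, containing both scale-free (1/f-like)
  and rhythmic content;
* the *fractal* spectrum — the scale-free part, estimated by the method of
  irregular resampling (IRASA): for each non-integer factor ``h`` the window
  is resampled by ``h`` and ``1/h``, the PSDs of the two resampled series
  (evaluated against the original sampling rate, so that rhythmic peaks
  shift to ``f0/h`` and ``f0*h`` while self-similar 1/f^beta content is
  invariant) are combined bin-wise by geometric mean, and the bin-wise
  median across the whole factor set is taken;
* the *oscillatory ratio* — mixed divided bin-wise by fractal, a unitless
  spectrum that is ~1 wherever the window is purely fractal and rises above
  1 at rhythmic peaks.  Because the gain of the raw signal cancels in the
  division, everything downstream of this ratio is amplitude-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .exceptions import DataError, ParameterError

__all__ = [
    "Spectrum",
    "SpectralConfig",
    "segment_windows",
    "mixed_spectrum",
    "fractal_spectrum",
    "oscillatory_ratio",
    "spectrogram",
]

# Relative floor applied to the fractal denominator to avoid blow-ups at
# near-zero bins (e.g. DC after linear detrending).
EPS_REL = 1e-12


def _default_hset() -> tuple[float, ...]:
    # 1.10, 1.15, ..., 1.90 — 17 non-integer resampling factors
    return tuple(round(1.10 + 0.05 * i, 2) for i in range(17))


@dataclass(frozen=True)
class Spectrum:
    """A one-sided spectrum on a uniform frequency grid.

    ``kind`` is one of ``mixed`` (power spectral density), ``fractal``
    (IRASA estimate of the scale-free PSD) or ``ratio`` (mixed / fractal,
    unitless).
    """

    freqs: np.ndarray
    values: np.ndarray
    kind: str
    window_start: float = 0.0
    channel: str = ""

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "values", values)
        if self.kind not in ("mixed", "fractal", "ratio"):
            raise ParameterError(f"unknown spectrum kind {self.kind!r}")
        if freqs.shape != values.shape:
            raise ParameterError("freqs and values must have the same shape")
        if freqs.size >= 2 and not np.all(np.diff(freqs) > 0):
            raise ParameterError("frequency grid must be strictly increasing")
        if np.any(values < 0):
            raise ParameterError("spectral values must be nonnegative")

    @property
    def df(self) -> float:
        """Frequency resolution of the grid in Hz."""
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class SpectralConfig:
    """Windowing and IRASA settings.

    window_length : s, length of each analysis window (default 8).
    overlap_fraction : fractional overlap of consecutive windows (default
        0.5, i.e. a 4-s hop for 8-s windows).
    hset : irregular-resampling factors; all must exceed 1.
    detrend / taper : per-window detrending and taper passed to the PSD
        estimator.
    """

    window_length: float = 8.0
    overlap_fraction: float = 0.5
    hset: tuple[float, ...] = field(default_factory=_default_hset)
    detrend: str = "linear"
    taper: str = "hann"

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ParameterError("window_length must be positive")
        if not 0 <= self.overlap_fraction < 1:
            raise ParameterError("overlap_fraction must lie in [0, 1)")
        if not self.hset or any(h <= 1 for h in self.hset):
            raise ParameterError("all resampling factors must exceed 1")
        object.__setattr__(self, "hset", tuple(float(h) for h in self.hset))

    def to_dict(self) -> dict:
        return {
            "window_length": self.window_length,
            "overlap_fraction": self.overlap_fraction,
            "hset": list(self.hset),
            "detrend": self.detrend,
            "taper": self.taper,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralConfig":
        d = dict(d)
        if "hset" in d:
            d["hset"] = tuple(d["hset"])
        return cls(**d)


def segment_windows(
    samples: np.ndarray, rate: float, config: SpectralConfig | None = None
) -> list[tuple[float, np.ndarray]]:
    """Slice a channel into overlapping fixed-length windows.

    Returns ``(window_start_seconds, block)`` pairs; blocks are exactly
    ``window_length * rate`` samples and a trailing partial window is
    dropped.
    """
    config = config or SpectralConfig()
    samples = np.asarray(samples, dtype=float)
    nper = round(config.window_length * rate)
    hop = round(config.window_length * (1 - config.overlap_fraction) * rate)
    if samples.size < nper:
        raise DataError(
            f"input too short: {samples.size} samples, "
            f"need at least {nper} ({config.window_length} s at {rate} Hz)"
        )
    out = []
    start = 0
    while start + nper <= samples.size:
        out.append((start / rate, samples[start : start + nper]))
        start += hop
    return out


def _periodogram(block: np.ndarray, rate: float, config: SpectralConfig):
    return sps.periodogram(
        block, fs=rate, window=config.taper, detrend=config.detrend
    )


def mixed_spectrum(
    block: np.ndarray,
    rate: float,
    config: SpectralConfig | None = None,
    *,
    window_start: float = 0.0,
    channel: str = "",
) -> Spectrum:
    """One-sided PSD of a detrended, tapered window (``kind='mixed'``)."""
    config = config or SpectralConfig()
    freqs, psd = _periodogram(np.asarray(block, dtype=float), rate, config)
    return Spectrum(freqs, psd, "mixed", window_start, channel)


def _resample_linear(x: np.ndarray, m: int) -> np.ndarray:
    """Linearly interpolate x onto m evenly spaced points over its support."""
    n = x.size
    return np.interp(np.linspace(0.0, n - 1, m), np.arange(n), x)


def fractal_spectrum(
    block: np.ndarray,
    rate: float,
    config: SpectralConfig | None = None,
    *,
    window_start: float = 0.0,
    channel: str = "",
) -> Spectrum:
    """IRASA estimate of the scale-free PSD of a window (``kind='fractal'``).

    The block is resampled by each factor h and its reciprocal; each
    resampled series is analysed against the *original* sampling rate, so a
    rhythmic peak at f0 migrates to f0/h and f0*h while 1/f^beta content
    stays put (the h-dependent amplitude factors cancel in the geometric
    mean).  The median across factors removes the displaced peaks.
    """
    config = config or SpectralConfig()
    block = np.asarray(block, dtype=float)
    n = block.size
    freqs0, _ = _periodogram(block, rate, config)
    acc = np.empty((len(config.hset), freqs0.size))
    for i, h in enumerate(config.hset):
        per_h = []
        for m in (round(n * h), round(n / h)):
            f_r, p_r = _periodogram(_resample_linear(block, m), rate, config)
            per_h.append(np.interp(freqs0, f_r, p_r))
        acc[i] = np.sqrt(per_h[0] * per_h[1])
    fractal = np.median(acc, axis=0)
    return Spectrum(freqs0, fractal, "fractal", window_start, channel)


def oscillatory_ratio(mixed: Spectrum, fractal: Spectrum) -> Spectrum:
    """Bin-wise mixed/fractal ratio (``kind='ratio'``, unitless).

    The fractal denominator is floored at ``EPS_REL`` times its maximum so
    near-zero bins (DC after detrending) cannot blow up the ratio.
    """
    if mixed.kind != "mixed" or fractal.kind != "fractal":
        raise ParameterError("expected a mixed and a fractal spectrum")
    if mixed.freqs.shape != fractal.freqs.shape or not np.allclose(
        mixed.freqs, fractal.freqs
    ):
        raise ParameterError("mixed and fractal spectra are on different grids")
    peak = fractal.values.max()
    floor = EPS_REL * peak if peak > 0 else np.finfo(float).tiny
    denom = np.maximum(fractal.values, floor)
    return Spectrum(
        mixed.freqs,
        mixed.values / denom,
        "ratio",
        mixed.window_start,
        mixed.channel,
    )


def window_ratio(
    block: np.ndarray,
    rate: float,
    config: SpectralConfig | None = None,
    *,
    window_start: float = 0.0,
    channel: str = "",
) -> Spectrum:
    """Convenience: oscillatory ratio of a single window."""
    config = config or SpectralConfig()
    kw = dict(window_start=window_start, channel=channel)
    return oscillatory_ratio(
        mixed_spectrum(block, rate, config, **kw),
        fractal_spectrum(block, rate, config, **kw),
    )


def spectrogram(recording, config: SpectralConfig | None = None) -> list[Spectrum]:
    """Oscillatory-ratio spectra of all windows of all channels.

    Ordered by (channel, window_start), channels in the recording's
    canonical order.
    """
    config = config or SpectralConfig()
    out = []
    for name in recording.channel_names:
        for start, block in segment_windows(
            recording.channels[name], recording.rate, config
        ):
            out.append(
                window_ratio(
                    block,
                    recording.rate,
                    config,
                    window_start=start,
                    channel=name,
                )
            )
    return out
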