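"""Per-window tremor indices and the aggregated per-recording score.

Each window's oscillatory-ratio spectrum is smoothed with a Gaussian kernel
(sigma = 1 Hz), and the maximum of the smoothed ratio inside the tremor
band (3.5-10 Hz) is that window's tremor index.  All (window, channel)
indices of a recording are pooled, the top third is kept, and the median of
the kept values is the recording's tremor index I.  For comparison across
subjects the index can be expressed in decibels relative to the mean index
of a control population:

    I_dB = 10 * log10(I / <I_CTRL>)

so a control subject scores ~0 dB and a patient with a ten-fold larger
index scores +10 dB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .exceptions import DataError, ParameterError
from .spectral import SpectralConfig, Spectrum, spectrogram

__all__ = [
    "IndexConfig",
    "WindowIndex",
    "TremorScore",
    "smooth_spectrum",
    "window_index",
    "aggregate_score",
    "to_decibel",
    "score_recording",
]


@dataclass(frozen=True)
class IndexConfig:
    """Scoring settings.

    band : Hz, the tremor search band (default 3.5-10).
    smooth_sigma : Hz, standard deviation of the Gaussian smoothing kernel.
    top_fraction : fraction of pooled window indices kept before the median
        (default 1/3; k = ceil(top_fraction * n) so short recordings never
        lose their single best window).
    """

    band: tuple[float, float] = (3.5, 10.0)
    smooth_sigma: float = 1.0
    top_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ParameterError("band must satisfy 0 < low < high")
        if self.smooth_sigma <= 0:
            raise ParameterError("smooth_sigma must be positive")
        if not 0 < self.top_fraction <= 1:
            raise ParameterError("top_fraction must lie in (0, 1]")
        object.__setattr__(self, "band", (float(lo), float(hi)))

    def to_dict(self) -> dict:
        return {
            "band": list(self.band),
            "smooth_sigma": self.smooth_sigma,
            "top_fraction": self.top_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IndexConfig":
        d = dict(d)
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)


@dataclass(frozen=True)
class WindowIndex:
    """Tremor index of one (window, channel): in-band maximum of the
    smoothed oscillatory ratio, with the frequency at which it occurred."""

    value: float
    peak_freq: float
    window_start: float
    channel: str


@dataclass(frozen=True)
class TremorScore:
    """Aggregated per-recording tremor score.

    ``index`` is the median of the top-fraction window indices; ``db`` is
    set only after normalization against a control reference.
    ``dominant_freq`` (median peak frequency of the kept windows) is
    diagnostic metadata and does not enter the score.
    """

    index: float
    n_windows_total: int
    n_windows_used: int
    dominant_freq: float
    db: float | None = None
    control_mean: float | None = None

    def to_json_dict(self) -> dict:
        return {
            "index": self.index,
            "db": self.db,
            "control_mean": self.control_mean,
            "n_windows_total": self.n_windows_total,
            "n_windows_used": self.n_windows_used,
            "dominant_freq_hz": self.dominant_freq,
        }


def smooth_spectrum(spectrum: Spectrum, sigma: float) -> Spectrum:
    """Convolve spectral values with a unit-sum Gaussian of sd `sigma` Hz.

    The kernel is truncated at +-3 sigma and the spectrum is reflected at
    its edges; the frequency grid is unchanged.
    """
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    steps = np.diff(spectrum.freqs)
    if not np.allclose(steps, steps[0]):
        raise ParameterError("smoothing requires a uniform frequency grid")
    sigma_bins = sigma / spectrum.df
    smoothed = ndimage.gaussian_filter1d(
        spectrum.values, sigma=sigma_bins, mode="reflect", truncate=3.0
    )
    # reflection can produce tiny negatives from float cancellation; clip
    smoothed = np.maximum(smoothed, 0.0)
    return Spectrum(
        spectrum.freqs,
        smoothed,
        spectrum.kind,
        spectrum.window_start,
        spectrum.channel,
    )


def window_index(ratio: Spectrum, config: IndexConfig | None = None) -> WindowIndex:
    """In-band maximum of the smoothed ratio spectrum (ties -> lowest freq)."""
    config = config or IndexConfig()
    if ratio.kind != "ratio":
        raise ParameterError(f"expected a ratio spectrum, got {ratio.kind!r}")
    lo, hi = config.band
    smoothed = smooth_spectrum(ratio, config.smooth_sigma)
    mask = (smoothed.freqs >= lo) & (smoothed.freqs <= hi)
    if not mask.any():
        raise ParameterError(
            f"band {config.band} lies outside the frequency grid "
            f"[{ratio.freqs[0]}, {ratio.freqs[-1]}] Hz"
        )
    in_band = smoothed.values[mask]
    in_freqs = smoothed.freqs[mask]
    k = int(np.argmax(in_band))  # argmax returns the first (lowest) frequency
    return WindowIndex(
        value=float(in_band[k]),
        peak_freq=float(in_freqs[k]),
        window_start=ratio.window_start,
        channel=ratio.channel,
    )


def aggregate_score(
    indices: list[WindowIndex], config: IndexConfig | None = None
) -> TremorScore:
    """Pool all (window, channel) indices; median of the top fraction.

    k = ceil(top_fraction * n) values are kept after sorting descending;
    the median uses the midpoint convention for even k.  The dominant
    frequency is the median peak frequency of the kept windows.
    """
    config = config or IndexConfig()
    if not indices:
        raise DataError("cannot aggregate an empty list of window indices")
    n = len(indices)
    k = math.ceil(config.top_fraction * n)
    values = np.array([w.value for w in indices])
    order = np.argsort(-values, kind="stable")[:k]
    kept = values[order]
    kept_freqs = np.array([indices[i].peak_freq for i in order])
    return TremorScore(
        index=float(np.median(kept)),
        n_windows_total=n,
        n_windows_used=k,
        dominant_freq=float(np.median(kept_freqs)),
    )


def to_decibel(score: TremorScore, control) -> TremorScore:
    """Express a score in dB relative to the control-population mean index."""
    mean = float(control.mean_index if hasattr(control, "mean_index") else control)
    if score.index <= 0:
        raise ParameterError("tremor index must be positive")
    if mean <= 0:
        raise ParameterError("control mean index must be positive")
    return replace(
        score,
        db=10.0 * math.log10(score.index / mean),
        control_mean=mean,
    )


def score_recording(
    recording,
    spectral_config: SpectralConfig | None = None,
    index_config: IndexConfig | None = None,
    control=None,
) -> TremorScore:
    """Full pipeline: spectrogram -> per-window indices -> aggregate
    (-> dB against a control reference, if one is given)."""
    index_config = index_config or IndexConfig()
    ratios = spectrogram(recording, spectral_config)
    indices = [window_index(r, index_config) for r in ratios]
    score = aggregate_score(indices, index_config)
    if control is not None:
        score = to_decibel(score, control)
    return score
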