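"""Sliding-window Hanning spectrogram, band powers, coastline, normalization.

PSD convention: one-sided periodogram per window with Hanning taper and
taper-power compensation, so that the integral of the PSD over frequency
equals the windowed segment's variance (Parseval consistency). Units are
uV^2/Hz on the frequency grid with spacing 1/window_length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .signal_core import ChannelTrace

__all__ = [
    "SpectralParams",
    "Spectrogram",
    "BandPowerSummary",
    "NormalizedSpectrum",
    "DEFAULT_BANDS",
    "spectrogram",
    "band_power",
    "coastline",
    "windowed_coastline",
    "normalize_to_pretreatment",
]

DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 80.0),
)


@dataclass(frozen=True)
class SpectralParams:
    window_length: float = 10.0
    step: float = 5.0
    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        if self.step > self.window_length:
            raise ValueError("step must be <= window_length")
        for name, lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band {name!r} edges must increase")


@dataclass(frozen=True)
class Spectrogram:
    """Per-window one-sided PSD: times are window centers (s)."""

    times: np.ndarray
    frequencies: np.ndarray
    power: np.ndarray  # shape (n_windows, n_frequencies), uV^2/Hz

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


@dataclass(frozen=True)
class BandPowerSummary:
    """Mean per-band PSD over the analysis interval plus mean coastline."""

    band_power: dict[str, float]  # uV^2/Hz, mean over windows
    log10_power: dict[str, float]
    coastline: float  # uV, mean per window
    log10_coastline: float


@dataclass(frozen=True)
class NormalizedSpectrum:
    """Window-mean and SD of PSD per frequency, in % of pretreatment maximum."""

    frequencies: np.ndarray
    mean_pct: np.ndarray
    sd_pct: np.ndarray


def spectrogram(
    channel: ChannelTrace, rate: float, params: SpectralParams = SpectralParams()
) -> Spectrogram:
    """Sliding Hanning-window one-sided PSD of one channel.

    Windows of ``window_length`` seconds advance by ``step`` seconds; the last
    partial window is dropped. Frequency resolution is 1/window_length.
    """
    nper = int(round(params.window_length * rate))
    nstep = int(round(params.step * rate))
    x = channel.samples
    if x.size < nper:
        raise ValueError(
            f"trace of {x.size / rate:.3g} s shorter than one {params.window_length} s window"
        )
    taper = get_window("hann", nper)
    # normalization so that sum(psd) * df == variance of the tapered segment
    scale = 1.0 / (rate * np.sum(taper**2))

    n_windows = (x.size - nper) // nstep + 1
    starts = np.arange(n_windows) * nstep
    freqs = np.fft.rfftfreq(nper, d=1.0 / rate)

    power = np.empty((n_windows, freqs.size))
    for w, s in enumerate(starts):
        seg = x[s : s + nper]
        seg = seg - seg.mean()
        spec = np.fft.rfft(seg * taper)
        psd = scale * np.abs(spec) ** 2
        psd[1:-1] *= 2.0  # one-sided: fold negative frequencies
        if nper % 2:
            psd[-1] *= 2.0
        power[w] = psd

    times = (starts + nper / 2.0) / rate
    return Spectrogram(times=times, frequencies=freqs, power=power)


def _band_slice(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    mask = (freqs >= lo) & (freqs < hi)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}) Hz contains no frequency bins")
    return mask


def band_power(
    spec: Spectrogram,
    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS,
    coastline_per_window: np.ndarray | None = None,
) -> BandPowerSummary:
    """Mean PSD per half-open band [lo, hi), averaged over all windows."""
    bp: dict[str, float] = {}
    logp: dict[str, float] = {}
    for name, lo, hi in bands:
        mask = _band_slice(spec.frequencies, lo, hi)
        val = float(spec.power[:, mask].mean())
        bp[name] = val
        logp[name] = float(np.log10(val)) if val > 0 else float("nan")
    if coastline_per_window is not None and coastline_per_window.size:
        cl = float(np.mean(coastline_per_window))
    else:
        cl = float("nan")
    return BandPowerSummary(
        band_power=bp,
        log10_power=logp,
        coastline=cl,
        log10_coastline=float(np.log10(cl)) if cl > 0 else float("nan"),
    )


def coastline(channel: ChannelTrace, window: tuple[float, float] | None = None, rate: float | None = None) -> float:
    """Line length: sum of |x[i+1] - x[i]| over the window (whole trace if None)."""
    x = channel.samples
    if window is not None:
        if rate is None:
            raise ValueError("rate required when a window is given")
        i0 = int(round(window[0] * rate))
        i1 = int(round(window[1] * rate))
        x = x[i0:i1]
    if x.size < 2:
        raise ValueError("coastline needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def windowed_coastline(
    channel: ChannelTrace, rate: float, params: SpectralParams = SpectralParams()
) -> np.ndarray:
    """Coastline per sliding window, aligned with :func:`spectrogram` windows."""
    nper = int(round(params.window_length * rate))
    nstep = int(round(params.step * rate))
    x = channel.samples
    if x.size < nper:
        raise ValueError("trace shorter than one window")
    n_windows = (x.size - nper) // nstep + 1
    return np.array(
        [np.sum(np.abs(np.diff(x[s : s + nper]))) for s in np.arange(n_windows) * nstep]
    )


def normalize_to_pretreatment(
    pre: Spectrogram, post: Spectrogram
) -> tuple[NormalizedSpectrum, NormalizedSpectrum]:
    """Express both spectra as % of the pretreatment window-mean maximum.

    The normalizer is the maximum over frequency of the pretreatment
    window-mean PSD; that bin maps to 100% in the pre spectrum.
    """
    if pre.frequencies.shape != post.frequencies.shape or not np.allclose(
        pre.frequencies, post.frequencies
    ):
        raise ValueError("pre and post spectrograms must share a frequency grid")
    pre_mean = pre.power.mean(axis=0)
    m = float(pre_mean.max())
    if m <= 0:
        raise ValueError("pretreatment maximum is zero; cannot normalize")

    def norm(s: Spectrogram) -> NormalizedSpectrum:
        return NormalizedSpectrum(
            frequencies=s.frequencies,
            mean_pct=s.power.mean(axis=0) / m * 100.0,
            sd_pct=s.power.std(axis=0, ddof=0) / m * 100.0,
        )

    return norm(pre), norm(post)
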