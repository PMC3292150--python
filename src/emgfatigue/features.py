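"""Per-window fatigue feature extractors and the rolling-SD composite feature.

Five per-second feature streams are produced from the band-passed sEMG:

* ``imdf`` - median frequency of the window periodogram (first grid frequency
  at which cumulative power reaches half the total; no interpolation).
* ``bandpower`` - trapezoidal integral of the Welch PSD over its full grid.
* the unified stream - per-trial z-scored band power minus per-trial z-scored
  median frequency.  The raw streams are in incommensurable units (mV^2 vs
  Hz); standardizing before subtracting makes the difference dimensionless
  and signs it so the unified value rises as fatigue develops (power up,
  median frequency down).  This normalization is an interpretation: the
  subtraction itself is the defined operation, the scaling is ours.
* ``fi2`` - spectral-moment ratio (order -1 over order X) on 8-500 Hz.
* ``wavelet_db3`` - mean squared value, per second, of the level-12
  approximation of the whole filtered trial (a 1-s window cannot support 12
  decomposition levels, so the decomposition runs on the full signal and the
  per-window statistic is taken on the reconstructed approximation).

The headline feature is the causal 3-window rolling sample SD of the unified
stream; for comparability every other feature is reported through the same
rolling-SD transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from . import _dwt
from .core import FeatureSeries, Trial, ValidationError
from .preprocess import bandpass_filter, segment_windows

__all__ = [
    "PsdWindow",
    "SpectralMomentSpec",
    "welch_psd",
    "imdf",
    "total_band_power",
    "unify_1d_spectro",
    "rolling_std",
    "spectro_1d",
    "spectro_std",
    "fi_nsm",
    "wavelet_feature",
    "extract_all",
]


@dataclass
class PsdWindow:
    """One window's power spectral density on a discrete frequency grid."""

    freqs: np.ndarray   # Hz, strictly increasing, non-negative
    power: np.ndarray   # mV^2/Hz
    t: float = 0.0      # window start time, s

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValidationError("freqs and power must be equally long")
        if self.freqs.size and (self.freqs[0] < 0 or np.any(np.diff(self.freqs) <= 0)):
            raise ValidationError("freqs must be non-negative and strictly increasing")
        if np.any(self.power < 0):
            raise ValidationError("power must be non-negative")


@dataclass(frozen=True)
class SpectralMomentSpec:
    """Moment order and band for the spectral fatigue index."""

    X: int = 2
    f1: float = 8.0
    f2: float = 500.0

    def __post_init__(self) -> None:
        if self.X not in (2, 3, 4, 5):
            raise ValidationError(f"moment order X must be in 2..5; got {self.X}")
        if not 0 < self.f1 < self.f2:
            raise ValidationError("need 0 < f1 < f2")


def welch_psd(window: np.ndarray, fs: float, seg_len: int = 256,
              overlap: float = 0.5, t: float = 0.0) -> PsdWindow:
    """Welch PSD (Hamming taper, density scaling): integral approximates the
    window's variance."""
    window = np.asarray(window, dtype=float)
    if window.size < seg_len:
        raise ValidationError(
            f"window of {window.size} samples is shorter than seg_len={seg_len}"
        )
    freqs, power = sps.welch(
        window, fs=fs, window="hamming", nperseg=seg_len,
        noverlap=int(round(seg_len * overlap)), detrend="constant",
        scaling="density",
    )
    return PsdWindow(freqs=freqs, power=power, t=t)


def _periodogram(window: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    return sps.periodogram(window, fs=fs, window="boxcar", detrend=False)


def imdf(window: np.ndarray, fs: float) -> float:
    """Median frequency of the window's periodogram.

    Returns the smallest grid frequency at which cumulative power reaches
    half the total power (no interpolation between bins).
    """
    window = np.asarray(window, dtype=float)
    if not np.any(window != 0.0):
        raise ValidationError("median frequency undefined for an all-zero window")
    freqs, power = _periodogram(window, fs)
    csum = np.cumsum(power)
    # tolerance keeps exact-half ties (e.g. two equal spectral lines) on the
    # lower bin despite floating-point rounding
    half = csum[-1] * 0.5 * (1.0 - 1e-9)
    idx = int(np.searchsorted(csum, half))
    return float(freqs[idx])


def total_band_power(window: np.ndarray, fs: float, seg_len: int = 256,
                     overlap: float = 0.5) -> float:
    """Trapezoidal integral of the Welch PSD over its full frequency grid (mV^2)."""
    psd = welch_psd(window, fs, seg_len=seg_len, overlap=overlap)
    return float(np.trapezoid(psd.power, psd.freqs))


def _zscore(values: np.ndarray, name: str) -> np.ndarray:
    sd = values.std(ddof=1)
    if sd == 0.0:
        raise ValidationError(f"cannot standardize zero-variance series {name!r}")
    return (values - values.mean()) / sd


def unify_1d_spectro(power: FeatureSeries, mdf: FeatureSeries) -> FeatureSeries:
    """Unify band power and median frequency into one dimensionless stream.

    Both series are standardized over the trial (mean 0, sample SD 1) and the
    standardized median frequency is subtracted from the standardized power,
    so the unified value rises as fatigue develops.
    """
    if len(power) != len(mdf) or not np.allclose(power.times, mdf.times):
        raise ValidationError("power and mdf series must share timestamps")
    if len(power) < 2:
        raise ValidationError("need at least two windows to standardize")
    values = _zscore(power.values, power.name) - _zscore(mdf.values, mdf.name)
    return FeatureSeries(name="spectro_1d", times=power.times.copy(),
                         values=values, window_duration=power.window_duration)


def rolling_std(series: FeatureSeries, span: int = 3) -> FeatureSeries:
    """Causal sliding sample SD over ``span`` consecutive values (step 1).

    The output value at time ``t`` summarizes the ``span`` windows ending at
    ``t``, so it uses no future data.  ``span=1`` yields all zeros (the SD of
    a singleton is defined as 0).
    """
    if span < 1:
        raise ValidationError("span must be >= 1")
    n = len(series)
    if n < span:
        raise ValidationError(f"series of length {n} is shorter than span {span}")
    if span == 1:
        values = np.zeros(n)
        times = series.times.copy()
    else:
        values = np.lib.stride_tricks.sliding_window_view(
            series.values, span
        ).std(axis=1, ddof=1)
        times = series.times[span - 1:].copy()
    return FeatureSeries(name=f"{series.name}_std{span}", times=times,
                         values=values, window_duration=series.window_duration)


def _emg_signal(trial: Trial, channel: int | str) -> np.ndarray:
    if channel in (1, 2):
        return trial.emg[int(channel) - 1]
    if channel == "mean":
        return trial.emg.mean(axis=0)
    raise ValidationError(f"channel must be 1, 2 or 'mean'; got {channel!r}")


def _windowed(trial: Trial, channel: int | str, filter_params: dict | None):
    params = {"low": 1.0, "high": 500.0, "order": 5}
    params.update(filter_params or {})
    filtered = bandpass_filter(_emg_signal(trial, channel), trial.fs_emg, **params)
    windows = segment_windows(filtered, trial.fs_emg, 1.0)
    times = np.arange(windows.shape[0], dtype=float)
    return windows, times, filtered


def spectro_1d(trial: Trial, channel: int | str = 1,
               filter_params: dict | None = None) -> FeatureSeries:
    """The unified per-second stream: z(band power) - z(median frequency)."""
    windows, times, _ = _windowed(trial, channel, filter_params)
    fs = trial.fs_emg
    mdf = FeatureSeries("imdf", times, [imdf(w, fs) for w in windows])
    power = FeatureSeries("bandpower", times, [total_band_power(w, fs) for w in windows])
    return unify_1d_spectro(power, mdf)


def spectro_std(trial: Trial, span: int = 3, channel: int | str = 1,
                filter_params: dict | None = None) -> FeatureSeries:
    """The headline feature: rolling sample SD of the unified stream."""
    if trial.duration_s < span:
        raise ValidationError(f"trial shorter than {span} s")
    series = rolling_std(spectro_1d(trial, channel, filter_params), span)
    series.name = "spectro_std"
    return series


def fi_nsm(window: np.ndarray, fs: float,
           spec: SpectralMomentSpec = SpectralMomentSpec()) -> float:
    """Spectral fatigue index: (-1)-order over X-order spectral moment.

    Moments are trapezoidal integrals of ``f**k * PSD(f)`` over
    ``[f1, f2]`` on the periodogram grid.  Dimensionless in amplitude
    (scaling the signal cancels); rises as the spectrum compresses downward.
    """
    freqs, power = _periodogram(np.asarray(window, dtype=float), fs)
    if freqs[-1] < spec.f2:
        raise ValidationError(
            f"periodogram grid tops out at {freqs[-1]} Hz; cannot cover f2={spec.f2}"
        )
    mask = (freqs >= spec.f1) & (freqs <= spec.f2)
    if mask.sum() < 2:
        raise ValidationError("fewer than two grid points inside [f1, f2]")
    f = freqs[mask]
    p = power[mask]
    numerator = np.trapezoid(p / f, f)
    denominator = np.trapezoid(p * f ** spec.X, f)
    if denominator == 0.0:
        raise ValidationError("zero X-order spectral moment; index undefined")
    return float(numerator / denominator)


def wavelet_feature(trial: Trial, wavelet: str = "db3", level: int = 12,
                    channel: int | str = 1,
                    filter_params: dict | None = None) -> FeatureSeries:
    """Per-second mean squared value of the deep wavelet approximation.

    The full-length filtered signal is decomposed ``level`` times (symmetric
    padding); the approximation band is reconstructed to signal length and
    its mean square is taken per 1-s window.
    """
    if wavelet not in _dwt.SUPPORTED_WAVELETS:
        raise ValidationError(
            f"unsupported wavelet {wavelet!r}; supported: "
            f"{sorted(_dwt.SUPPORTED_WAVELETS)}"
        )
    _, times, filtered = _windowed(trial, channel, filter_params)
    approx = _dwt.approx_reconstruction(filtered, wavelet, level)
    windows = segment_windows(approx, trial.fs_emg, 1.0)
    values = (windows ** 2).mean(axis=1)
    return FeatureSeries(name=f"wavelet_{wavelet}", times=times, values=values)


def extract_all(trial: Trial, span: int = 3, channel: int | str = 1,
                fi_moments: tuple[int, ...] = (2,), wavelet: str = "db3",
                level: int = 12,
                filter_params: dict | None = None) -> dict[str, FeatureSeries]:
    """All comparison-ready features on identical timestamps.

    Returns ``spectro_std`` plus every comparison feature passed through the
    same ``span``-window rolling SD (``imdf_std3``, ``bandpower_std3``,
    ``fi2_std3``, ``wavelet_db3_std3`` for the defaults).  Higher-order
    moment indices are included when requested via ``fi_moments``.
    """
    windows, times, filtered = _windowed(trial, channel, filter_params)
    fs = trial.fs_emg
    if windows.shape[0] < span:
        raise ValidationError(f"trial shorter than {span} windows")

    mdf = FeatureSeries("imdf", times, [imdf(w, fs) for w in windows])
    power = FeatureSeries("bandpower", times, [total_band_power(w, fs) for w in windows])
    unified = unify_1d_spectro(power, mdf)

    out: dict[str, FeatureSeries] = {}
    headline = rolling_std(unified, span)
    headline.name = "spectro_std"
    out["spectro_std"] = headline
    out[f"imdf_std{span}"] = rolling_std(mdf, span)
    out[f"bandpower_std{span}"] = rolling_std(power, span)
    for x in fi_moments:
        spec = SpectralMomentSpec(X=x)
        fi = FeatureSeries(f"fi{x}", times, [fi_nsm(w, fs, spec) for w in windows])
        out[f"fi{x}_std{span}"] = rolling_std(fi, span)
    approx = _dwt.approx_reconstruction(filtered, wavelet, level)
    awin = segment_windows(approx, fs, 1.0)
    wseries = FeatureSeries(f"wavelet_{wavelet}", times, (awin ** 2).mean(axis=1))
    out[f"wavelet_{wavelet}_std{span}"] = rolling_std(wseries, span)
    return out
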