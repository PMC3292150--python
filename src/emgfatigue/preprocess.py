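"""Acquisition-matched filtering and windowing, plus the angular-oscillation signal.

All sEMG enters feature extraction through a zero-phase (forward-backward)
5th-order Butterworth band-pass of 1-500 Hz.  The goniometer oscillation
signal is the sample standard deviation of the angle over non-overlapping
4-second blocks, expanded back to per-sample length by zero-order hold.
Sample (n-1) standard deviation is the single convention used package-wide.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import ValidationError

__all__ = ["bandpass_filter", "segment_windows", "gonio_oscillation"]


def bandpass_filter(
    x: np.ndarray,
    fs: float,
    low: float = 1.0,
    high: float = 500.0,
    order: int = 5,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass; output length equals input length."""
    x = np.asarray(x, dtype=float)
    if not 0 < low < high:
        raise ValidationError(f"need 0 < low < high; got low={low}, high={high}")
    if high >= fs / 2:
        raise ValidationError(
            f"high edge {high} Hz must be below the Nyquist frequency {fs / 2} Hz"
        )
    if x.size <= 3 * (order + 1):
        raise ValidationError(
            f"signal too short to filter: {x.size} samples <= {3 * (order + 1)}"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    padlen = min(x.size - 1, 6 * order + 3)
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def segment_windows(x: np.ndarray, fs: float, window_s: float = 1.0) -> np.ndarray:
    """Split into non-overlapping, contiguous windows; drop the remainder.

    Returns an array of shape ``(floor(n / (fs * window_s)), fs * window_s)``.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot window an empty signal")
    w = int(round(fs * window_s))
    if w < 2:
        raise ValidationError("window must contain at least 2 samples")
    count = x.size // w
    if count == 0:
        raise ValidationError(
            f"signal of {x.size} samples is shorter than one {window_s}-s window"
        )
    return x[: count * w].reshape(count, w)


def gonio_oscillation(
    angle: np.ndarray, fs: float, window_s: float = 4.0
) -> np.ndarray:
    """Per-sample angular oscillation (degrees SD) from non-overlapping blocks.

    The sample SD is computed in ``window_s``-second blocks and expanded back
    to the input length by zero-order hold; trailing samples beyond the last
    full block take the last block's value.
    """
    angle = np.asarray(angle, dtype=float)
    w = int(round(fs * window_s))
    if angle.size < w:
        raise ValidationError(
            f"angle trace of {angle.size} samples is shorter than one "
            f"{window_s}-s block ({w} samples)"
        )
    k = angle.size // w
    sds = angle[: k * w].reshape(k, w).std(axis=1, ddof=1)
    out = np.repeat(sds, w)
    if out.size < angle.size:
        out = np.concatenate([out, np.full(angle.size - out.size, sds[-1])])
    return out
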