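"""Zero-phase Butterworth filters shared by the voltage and trace modules."""

from __future__ import annotations

import numpy as np
from scipy import signal


def butter_sos(band: tuple[float | None, float | None], fs: float, order: int) -> np.ndarray:
    """Second-order sections for a Butterworth filter.

    ``band`` is ``(low, high)``; a ``None`` edge degrades to low-/high-pass.
    Raises ``ValueError`` when an edge reaches the Nyquist frequency.
    """
    low, high = band
    nyq = fs / 2.0
    if high is not None and high >= nyq:
        raise ValueError(f"upper band edge {high} Hz is at or above Nyquist ({nyq} Hz)")
    if low is not None and low <= 0:
        raise ValueError("lower band edge must be positive")
    if low is not None and high is not None:
        return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    if low is not None:
        return signal.butter(order, low, btype="highpass", fs=fs, output="sos")
    if high is not None:
        return signal.butter(order, high, btype="lowpass", fs=fs, output="sos")
    raise ValueError("at least one band edge required")


def filtfilt_sos(x: np.ndarray, band, fs: float, order: int = 2, axis: int = -1) -> np.ndarray:
    """Forward-backward (zero-phase) Butterworth filtering along ``axis``."""
    sos = butter_sos(band, fs, order)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=axis)


def minmax_scale(x: np.ndarray, axis=None) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant input maps to all zeros."""
    x = np.asarray(x, dtype=float)
    lo = x.min(axis=axis, keepdims=axis is not None)
    hi = x.max(axis=axis, keepdims=axis is not None)
    rng = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(rng > 0, (x - lo) / np.where(rng == 0, 1.0, rng), 0.0)
    return out
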