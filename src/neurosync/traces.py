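"""Trace quality control, network activity traces, peak detection, and
pharmacological response quantification.

All traces are min-max normalized single-cell fluorescence time series at
the 2-Hz imaging rate. Quality control removes traces whose 0.0013–0.02 Hz
band-passed component fluctuates too much (sd > 0.05, "noisy") and traces
lacking a >= 10 % fluorescence rise under high potassium ("inactive or
non-neuronal"). The network activity trace is the normalized sum of
band-passed (0.005–0.2 Hz), individually normalized traces; activity peaks
are local maxima with topographic prominence above 0.025 and carry height,
prominence, width (full width at half prominence) and timing. Per-epoch
metrics compare agent applications against baseline as absolute and
relative changes; the excitatory GABA response of a cell is the difference
of its 0.024-Hz low-passed trace summed over the GABA epoch versus
baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from ._filters import filtfilt_sos, minmax_scale
from .protocol import Epoch, PharmacologyProtocol


@dataclass
class TraceParams:
    qc_band_hz: tuple[float, float] = (0.0013, 0.02)
    qc_sd_max: float = 0.05
    #: segment the noisiness QC is evaluated on: "baseline" epoch (default;
    #: evoked pharmacological responses are signal, not noise) or "full"
    qc_sd_window: str = "baseline"
    kplus_min_rise: float = 0.10
    #: seconds before K+ onset used as the pre-application reference level
    kplus_reference_s: float = 30.0
    network_band_hz: tuple[float, float] = (0.005, 0.2)
    peak_prominence_network: float = 0.025
    peak_prominence_single: float = 0.025
    gaba_lowpass_hz: float = 0.024
    filter_order: int = 2
    hist_bin_prominence: float = 0.005
    hist_bin_interval_s: float = 1.0
    hist_bin_change: float = 0.05
    #: analysis window at the end of the CBX epoch (slow-acting blocker)
    cbx_window_s: float = 180.0
    #: duration-normalize epoch sums to this reference when epoch lengths differ
    gaba_reference_duration_s: float | None = 180.0

    def __post_init__(self) -> None:
        for band in (self.qc_band_hz, self.network_band_hz):
            if not 0 < band[0] < band[1]:
                raise ValueError("filter bands must satisfy 0 < low < high")
        if self.peak_prominence_network <= 0 or self.peak_prominence_single <= 0:
            raise ValueError("prominences must be positive")


@dataclass(frozen=True)
class ActivityPeak:
    """One detected activity event."""

    time_s: float
    height: float
    prominence: float
    width_s: float


@dataclass
class EpochMetrics:
    """Peak statistics for one epoch compared against baseline."""

    epoch_label: str
    peaks: list[ActivityPeak]
    median_prominence: float
    intervals_s: np.ndarray
    median_interval_s: float
    prominence_change: float
    prominence_relative_change: float
    interval_change_s: float
    interval_relative_change: float


# -------------------------------------------------------------------- helpers
def _as_frame(traces) -> pd.DataFrame:
    if isinstance(traces, pd.DataFrame):
        return traces
    return pd.DataFrame(np.asarray(traces).T)


def _epoch_slice(epoch: Epoch, n: int, dt: float) -> slice:
    i0 = int(np.ceil(epoch.start_s / dt))
    i1 = int(np.ceil(epoch.end_s / dt))
    return slice(max(0, i0), min(n, i1))


# ------------------------------------------------------------------------- QC
def qc_filter(
    traces,
    protocol: PharmacologyProtocol,
    params: TraceParams | None = None,
    frame_interval_s: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove noisy and unresponsive traces.

    A trace is "noisy" when the standard deviation of its 0.0013–0.02 Hz
    band-passed component (over the baseline epoch by default) exceeds
    ``qc_sd_max``, and "inactive" when its normalized fluorescence rises by
    less than ``kplus_min_rise`` during the K+ epoch relative to the level
    just before application. Returns ``(kept, removal_log)`` where the log
    has columns ``cell`` and ``reason``.
    """
    params = params or TraceParams()
    df = _as_frame(traces)
    if df.shape[1] == 0:
        return df, pd.DataFrame(columns=["cell", "reason"])
    fs = 1.0 / frame_interval_s
    n = len(df)

    # The QC band-pass is applied to the segment the sd is evaluated on:
    # with the very low 0.0013-Hz high-pass edge the filter response spans
    # hundreds of seconds, so filtering the full trace would smear evoked
    # steps (K+, glutamate) far back into the baseline.
    arr = df.to_numpy().T
    if params.qc_sd_window == "baseline" and protocol.epoch("baseline") is not None:
        seg = arr[:, _epoch_slice(protocol.require("baseline"), n, frame_interval_s)]
    else:
        seg = arr
    sd = filtfilt_sos(seg, params.qc_band_hz, fs, order=params.filter_order, axis=1).std(axis=1)

    kplus = protocol.epoch("K+")
    if kplus is None:
        warnings.warn("protocol has no K+ epoch; skipping the viability filter")
        rise = np.full(len(df.columns), np.inf)
    else:
        sl = _epoch_slice(kplus, n, frame_interval_s)
        ref0 = max(0, int((kplus.start_s - params.kplus_reference_s) / frame_interval_s))
        ref1 = max(ref0 + 1, int(kplus.start_s / frame_interval_s))
        arr = df.to_numpy().T
        rise = arr[:, sl].max(axis=1) - np.median(arr[:, ref0:ref1], axis=1)

    removals = []
    keep = []
    for k, cell in enumerate(df.columns):
        if sd[k] > params.qc_sd_max:
            removals.append((cell, "noisy"))
        elif rise[k] < params.kplus_min_rise:
            removals.append((cell, "inactive"))
        else:
            keep.append(cell)
    log = pd.DataFrame(removals, columns=["cell", "reason"])
    return df[keep], log


# ----------------------------------------------------------------------- peaks
def find_peaks(trace, min_prominence: float, dt: float = 0.5, t0: float = 0.0) -> list[ActivityPeak]:
    """Local maxima with topographic prominence >= ``min_prominence``.

    Prominence is the height of a peak above the higher of the two flanking
    minima separating it from higher terrain; width is measured at half
    prominence. Times are ``t0 + index * dt``.
    """
    x = np.asarray(trace, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("trace contains non-finite values")
    idx, props = signal.find_peaks(x, prominence=min_prominence, width=0, rel_height=0.5)
    return [
        ActivityPeak(
            time_s=t0 + i * dt,
            height=float(x[i]),
            prominence=float(p),
            width_s=float(w * dt),
        )
        for i, p, w in zip(idx, props["prominences"], props["widths"])
    ]


def peak_times(peaks: list[ActivityPeak]) -> np.ndarray:
    return np.asarray([p.time_s for p in peaks])


# --------------------------------------------------------------- network trace
def network_trace(
    traces, params: TraceParams | None = None, frame_interval_s: float = 0.5, normalize: bool = True
) -> np.ndarray:
    """Network activity trace in [0, 1].

    Each trace is band-passed (0.005–0.2 Hz) and min-max normalized, the
    traces summed, and the sum min-max normalized again. Synchronous
    transients reinforce in the sum while asynchronous activity averages
    out, so network events stand out as prominent peaks. ``normalize=False``
    returns the raw sum, whose amplitude scales with the number of
    synchronously active cells.
    """
    params = params or TraceParams()
    df = _as_frame(traces)
    if df.shape[1] == 0:
        raise ValueError("need at least one trace")
    fs = 1.0 / frame_interval_s
    filtered = filtfilt_sos(df.to_numpy().T, params.network_band_hz, fs, order=params.filter_order, axis=1)
    summed = minmax_scale(filtered, axis=1).sum(axis=0)
    return minmax_scale(summed) if normalize else summed


# --------------------------------------------------------------- epoch metrics
def _peaks_in(peaks: list[ActivityPeak], start: float, end: float) -> list[ActivityPeak]:
    return [p for p in peaks if start <= p.time_s < end]


def _median_or_nan(values) -> float:
    values = np.asarray(values, dtype=float)
    return float(np.median(values)) if values.size else float("nan")


def _relative(change: float, baseline: float) -> float:
    if not np.isfinite(change) or baseline == 0 or not np.isfinite(baseline):
        return float("nan")
    return change / baseline


def epoch_metrics(
    trace,
    peaks: list[ActivityPeak],
    protocol: PharmacologyProtocol,
    epoch_label: str,
    baseline_label: str = "baseline",
    params: TraceParams | None = None,
) -> EpochMetrics:
    """Median peak prominence and inter-peak interval of an epoch, with
    change and relative change versus baseline.

    For the slow-acting gap-junction blocker (CBX) only the final
    ``cbx_window_s`` (default 3 min) of the application window is analysed.
    Epochs without peaks yield NaN metrics (flagged by NaN, never infinity).
    """
    params = params or TraceParams()
    base_ep = protocol.require(baseline_label)
    ep = protocol.require(epoch_label)
    start, end = ep.start_s, ep.end_s
    if epoch_label == "CBX":
        start = max(start, end - params.cbx_window_s)

    ep_peaks = _peaks_in(peaks, start, end)
    base_peaks = _peaks_in(peaks, base_ep.start_s, base_ep.end_s)

    ep_prom = _median_or_nan([p.prominence for p in ep_peaks])
    base_prom = _median_or_nan([p.prominence for p in base_peaks])
    intervals = np.diff(peak_times(ep_peaks))
    base_intervals = np.diff(peak_times(base_peaks))
    ep_int = _median_or_nan(intervals)
    base_int = _median_or_nan(base_intervals)

    prom_change = ep_prom - base_prom
    int_change = ep_int - base_int
    return EpochMetrics(
        epoch_label=epoch_label,
        peaks=ep_peaks,
        median_prominence=ep_prom,
        intervals_s=intervals,
        median_interval_s=ep_int,
        prominence_change=prom_change,
        prominence_relative_change=_relative(prom_change, base_prom),
        interval_change_s=int_change,
        interval_relative_change=_relative(int_change, base_int),
    )


# ---------------------------------------------------------------- GABA scoring
def gaba_excitatory_response(
    trace,
    protocol: PharmacologyProtocol,
    params: TraceParams | None = None,
    frame_interval_s: float = 0.5,
) -> float:
    """Excitatory GABA response of one cell.

    The trace is low-pass filtered at 0.024 Hz and summed over the GABA and
    baseline epochs; the response is the GABA sum minus the baseline sum.
    Positive values mean depolarization, negative inhibition. Because the
    baseline epoch is typically much longer than the application, each sum
    is duration-normalized by default: per-sample mean times
    ``gaba_reference_duration_s``; set that parameter to ``None`` for the
    raw sums.
    """
    params = params or TraceParams()
    base_ep = protocol.require("baseline")
    gaba_ep = protocol.require("GABA")
    x = np.asarray(trace, dtype=float)
    fs = 1.0 / frame_interval_s
    low = filtfilt_sos(x, (None, params.gaba_lowpass_hz), fs, order=params.filter_order)

    def epoch_sum(ep: Epoch) -> float:
        seg = low[_epoch_slice(ep, len(low), frame_interval_s)]
        if seg.size == 0:
            raise ValueError(f"epoch {ep.agent!r} lies outside the trace")
        if params.gaba_reference_duration_s is None:
            return float(seg.sum())
        return float(seg.mean() * params.gaba_reference_duration_s * fs)

    return epoch_sum(gaba_ep) - epoch_sum(base_ep)


# ------------------------------------------------------------------ histograms
def response_histograms(values, bin_width: float, direction: str = "cumulative") -> pd.DataFrame:
    """Histogram of responses as % of neurons with a (reverse-)cumulative sum.

    Bins are multiples of ``bin_width`` covering the data range. The
    cumulative column is monotone non-decreasing and ends at 100 %
    (``direction="cumulative"``) or starts at 100 % and is non-increasing
    (``direction="reverse"``).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if direction not in ("cumulative", "reverse"):
        raise ValueError("direction must be 'cumulative' or 'reverse'")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "percent", "cumulative_percent"])
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    percent = 100.0 * counts / values.size
    if direction == "cumulative":
        cum = np.cumsum(percent)
    else:
        cum = np.cumsum(percent[::-1])[::-1]
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "percent": percent, "cumulative_percent": cum}
    )
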