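"""Network-level statistics: activity-pattern classification, paired
nonparametric comparisons, correlations, and report tables.

The activity-pattern label (synchronous / loosely synchronous /
asynchronous) operationalizes what is usually judged by eye from aligned
trace rasters. The rule is declared, configurable, and always reported
together with its three diagnostic quantities: the network-peak rate, the
mean fraction of cells participating in each network event, and the ratio
of single-cell activity inside versus outside network events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .protocol import PharmacologyProtocol
from .traces import ActivityPeak, TraceParams, _as_frame, find_peaks, network_trace, peak_times


@dataclass
class ClassifyParams:
    #: fewer network peaks than this per 5 minutes -> asynchronous
    min_peaks_per_5min: float = 2.0
    #: mean event participation below this -> asynchronous
    min_participation: float = 0.2
    #: participation at or above this (with the ratio below) -> synchronous
    sync_participation: float = 0.5
    #: in-event / out-of-event single-cell activity ratio for synchrony
    sync_activity_ratio: float = 3.0
    #: half-width (s) of the window around a network peak counted as in-event
    event_half_width_s: float = 2.0
    #: minimum prominence (on the [0, 1] network trace) for a peak to define
    #: an event window for the participation / activity-ratio diagnostics;
    #: min-max normalization guarantees ripple peaks on any trace, so event
    #: windows come from the prominent ones only
    event_prominence: float = 0.3
    #: band (Hz) matched to the calcium-transient timescale used for the
    #: single-cell activity diagnostics; faster than the network band so
    #: that filter ringing between events does not count as activity
    activity_band_hz: tuple[float, float] = (0.05, 0.5)
    #: a cell participates in an event when its activity-band signal exceeds
    #: this many robust noise standard deviations inside the event window
    participation_sigma: float = 5.0
    #: extra seconds after each event window counted as in-event for the
    #: activity-ratio power mask (covers the calcium transient decay tail)
    event_tail_s: float = 8.0
    #: fewer traces than this -> "undetermined"
    min_traces: int = 10


@dataclass
class NetworkClassification:
    label: str
    peaks_per_5min: float
    mean_participation: float
    activity_ratio: float
    n_traces: int
    network_peaks: list[ActivityPeak] = field(default_factory=list)


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    n: int
    r: float | None = None
    flag: str | None = None


def classify_network(
    traces,
    network_peaks: list[ActivityPeak] | None = None,
    params: ClassifyParams | None = None,
    trace_params: TraceParams | None = None,
    frame_interval_s: float = 0.5,
    protocol: PharmacologyProtocol | None = None,
    analysis_epoch: str = "baseline",
) -> NetworkClassification:
    """Label a recording's activity pattern from its QC-passed traces.

    Diagnostics: network peaks (prominence 0.025 on the network trace);
    per-event participation (fraction of cells whose transient-band signal
    within ``event_half_width_s`` of a prominent network peak exceeds
    ``participation_sigma`` robust noise standard deviations); and the
    pooled in-event / out-of-event power ratio of that band. Default rule:
    asynchronous when the network trace has fewer than 2 peaks per 5 min or
    mean participation < 0.2; synchronous when participation >= 0.5 and the
    in/out activity ratio >= 3; loosely synchronous otherwise.

    When a protocol is given the classification is computed on the
    ``analysis_epoch`` segment (baseline by default): spontaneous activity
    patterns are a baseline property, and evoked steps elsewhere in the
    recording would dominate the per-trace normalization.
    """
    params = params or ClassifyParams()
    trace_params = trace_params or TraceParams()
    df = _as_frame(traces)
    if protocol is not None and protocol.epoch(analysis_epoch) is not None:
        ep = protocol.require(analysis_epoch)
        i0 = int(np.ceil(ep.start_s / frame_interval_s))
        i1 = int(np.ceil(ep.end_s / frame_interval_s))
        df = df.iloc[i0:i1].reset_index(drop=True)
    n_traces = df.shape[1]
    duration = len(df) * frame_interval_s
    if network_peaks is None:
        net = network_trace(df, trace_params, frame_interval_s)
        network_peaks = find_peaks(net, trace_params.peak_prominence_network, dt=frame_interval_s)

    peaks_per_5min = len(network_peaks) / duration * 300.0 if duration else 0.0

    # Single-cell activity is judged on a transient-timescale band so that
    # neither frame-to-frame noise nor slow filter ringing between events
    # counts as activity. A cell participates in an event when its
    # band-passed signal inside the event window exceeds 5 robust noise
    # standard deviations (sigma = median(|x|) / 0.6745 per cell).
    from ._filters import filtfilt_sos

    arr = df.to_numpy().T
    act = filtfilt_sos(arr, params.activity_band_hz, 1.0 / frame_interval_s, order=trace_params.filter_order, axis=1)
    sigma = np.median(np.abs(act), axis=1) / 0.6745
    sigma = np.maximum(sigma, 1e-12)

    ev = peak_times([p for p in network_peaks if p.prominence >= params.event_prominence])
    w = params.event_half_width_s
    t_frames = np.arange(arr.shape[1]) * frame_interval_s
    if len(ev) and n_traces:
        per_event = []
        for e in ev:
            win = np.abs(t_frames - e) <= w
            per_event.append(np.mean(act[:, win].max(axis=1) >= params.participation_sigma * sigma))
        mean_participation = float(np.mean(per_event))
    else:
        mean_participation = 0.0

    # in-event / out-of-event activity: pooled mean square of the band-passed
    # traces inside versus outside the event windows
    tail = params.event_tail_s
    in_mask = (
        np.any((t_frames[:, None] >= ev[None, :] - w) & (t_frames[:, None] <= ev[None, :] + w + tail), axis=1)
        if len(ev)
        else np.zeros(arr.shape[1], bool)
    )
    power = act**2
    in_power = float(power[:, in_mask].mean()) if in_mask.any() else 0.0
    out_power = float(power[:, ~in_mask].mean()) if (~in_mask).any() else 0.0
    activity_ratio = in_power / out_power if out_power > 0 else (np.inf if in_power > 0 else 0.0)

    if n_traces < params.min_traces:
        label = "undetermined"
    elif peaks_per_5min < params.min_peaks_per_5min or mean_participation < params.min_participation:
        label = "asynchronous"
    elif mean_participation >= params.sync_participation and activity_ratio >= params.sync_activity_ratio:
        label = "synchronous"
    else:
        label = "loosely_synchronous"
    return NetworkClassification(
        label=label,
        peaks_per_5min=peaks_per_5min,
        mean_participation=mean_participation,
        activity_ratio=float(activity_ratio),
        n_traces=n_traces,
        network_peaks=network_peaks,
    )


# ------------------------------------------------------------------ statistics
def wilcoxon_signed_rank(paired_before, paired_after) -> GroupComparison:
    """Paired two-tailed Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's original procedure); the exact
    null distribution is used for up to 25 nonzero differences and the
    normal approximation above that. All-zero differences yield an
    undefined p, flagged rather than raised.
    """
    x = np.asarray(paired_before, dtype=float)
    y = np.asarray(paired_after, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = y - x
    nz = int(np.count_nonzero(d))
    if nz == 0:
        return GroupComparison(statistic=float("nan"), p_value=float("nan"), n=0, flag="all differences zero")
    method = "exact" if nz <= 25 else "approx"
    res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided", method=method)
    return GroupComparison(statistic=float(res.statistic), p_value=float(res.pvalue), n=nz)


def pearson_correlation(x, y) -> GroupComparison:
    """Pearson product-moment correlation with a two-tailed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return GroupComparison(statistic=float("nan"), p_value=float("nan"), n=x.size, r=None, flag="constant input")
    res = stats.pearsonr(x, y)
    return GroupComparison(statistic=float(res.statistic), p_value=float(res.pvalue), n=x.size, r=float(res.statistic))


# --------------------------------------------------------------------- reports
def roi_totals(per_group_counts: pd.DataFrame, count_columns=None) -> pd.DataFrame:
    """Append a ``Total`` row summing per-group analyzed-ROI counts."""
    df = per_group_counts.copy()
    cols = count_columns or [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    total = {c: df[c].sum() if c in cols else "Total" for c in df.columns}
    df.loc["Total"] = pd.Series(total)
    return df


def classification_proportions(labels) -> pd.DataFrame:
    """Counts and percentages (rounded to whole %) per activity label."""
    s = pd.Series(list(labels), dtype="object")
    counts = s.value_counts()
    out = pd.DataFrame({"count": counts})
    out["fraction"] = out["count"] / out["count"].sum()
    out["percent"] = (100 * out["fraction"]).round().astype(int)
    return out


def classification_counts_by_timepoint(records: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint label counts and within-timepoint percentages.

    ``records`` needs columns ``timepoint`` and ``label``. Percentages per
    timepoint sum to 100 (up to rounding of the displayed column).
    """
    counts = records.groupby(["timepoint", "label"]).size().rename("count").reset_index()
    totals = counts.groupby("timepoint")["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    counts["percent"] = (100 * counts["fraction"]).round().astype(int)
    return counts


def build_report(networks: list[dict], out_dir=None) -> dict[str, pd.DataFrame]:
    """Assemble machine-readable report tables for a cohort of recordings.

    ``networks`` is a list of per-recording summaries with keys
    ``name``, ``timepoint``, ``classification`` (a NetworkClassification),
    and optionally ``epoch_metrics`` (label -> EpochMetrics) and
    ``gaba_responses`` (array of per-cell scores). Returns a dict of tables
    and, when ``out_dir`` is given, writes each as CSV.
    """
    from .traces import response_histograms

    rows = []
    for net in networks:
        cl = net["classification"]
        rows.append(
            {
                "name": net.get("name", ""),
                "timepoint": net.get("timepoint", ""),
                "label": cl.label,
                "peaks_per_5min": cl.peaks_per_5min,
                "mean_participation": cl.mean_participation,
                "activity_ratio": cl.activity_ratio,
                "n_traces": cl.n_traces,
            }
        )
    summary = pd.DataFrame(rows)
    tables: dict[str, pd.DataFrame] = {
        "network_summary": summary,
        "classification_proportions": classification_proportions(summary["label"]) if len(summary) else pd.DataFrame(),
    }
    if len(summary) and summary["timepoint"].astype(str).str.len().gt(0).any():
        tables["classification_by_timepoint"] = classification_counts_by_timepoint(summary)

    metric_rows = []
    for net in networks:
        for label, m in (net.get("epoch_metrics") or {}).items():
            metric_rows.append(
                {
                    "name": net.get("name", ""),
                    "epoch": label,
                    "median_prominence": m.median_prominence,
                    "median_interval_s": m.median_interval_s,
                    "prominence_change": m.prominence_change,
                    "prominence_relative_change": m.prominence_relative_change,
                    "interval_change_s": m.interval_change_s,
                    "interval_relative_change": m.interval_relative_change,
                }
            )
    if metric_rows:
        tables["epoch_metrics"] = pd.DataFrame(metric_rows)

    all_gaba = [np.asarray(net["gaba_responses"]) for net in networks if net.get("gaba_responses") is not None]
    if all_gaba:
        pooled = np.concatenate(all_gaba)
        tables["gaba_reverse_cumulative"] = response_histograms(pooled, bin_width=1.0, direction="reverse")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in tables.items():
            tab.to_csv(out / f"{name}.csv", index=False)
    return tables


def response_map(centroids, responses, path=None, dot_size: float = 30.0):
    """Pseudo-colored spatial map of per-cell responses (green = excited,
    black = no response, red = inhibited)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap, TwoSlopeNorm

    centroids = np.asarray(centroids, dtype=float)
    responses = np.asarray(responses, dtype=float)
    cmap = LinearSegmentedColormap.from_list("gaba", ["red", "black", "green"])
    vmax = max(np.abs(responses).max(), 1e-9)
    norm = TwoSlopeNorm(vmin=-vmax, vcenter=0.0, vmax=vmax)
    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(centroids[:, 1], centroids[:, 0], c=responses, cmap=cmap, norm=norm, s=dot_size)
    ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    fig.colorbar(sc, ax=ax, label="GABA response")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
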