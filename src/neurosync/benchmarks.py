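"""Self-contained ground-truth benchmarks of the full pipeline.

Each benchmark generates synthetic recordings at the package's standard
benchmark scale, runs the relevant analysis stages, and scores the result
against the generator's ground truth. They back both the test suite and
the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import ca_track, mea, synth, traces
from .protocol import qc_protocol


def qc_retention(
    n_seeds: int = 20,
    n_cells: int = 200,
    noise_sd: float = 0.02,
    duration_s: float = 640.0,
    seed: int = 0,
) -> dict:
    """Trace retention of the two QC filters on default synthetic movies.

    For each seed: render a synchronous movie of responsive neurons with a
    baseline + K+ protocol, segment, track, extract traces, and apply the
    in-band-sd and K+-rise filters. Returns per-seed retention percentages
    plus their minimum and the total number of traces that entered QC.
    """
    protocol = qc_protocol()
    retentions = []
    total = 0
    for k in range(n_seeds):
        movie_seed = int((seed * 100_003 + k) % 2**31)
        movie, _ = synth.simulate_recording(
            "synchronous",
            duration_s=duration_s,
            n_cells=n_cells,
            protocol=protocol,
            noise_sd=noise_sd,
            seed=movie_seed,
        )
        traces_df, _, _ = ca_track.track_movie(movie)
        kept, _ = traces.qc_filter(traces_df, protocol)
        total += traces_df.shape[1]
        retentions.append(100.0 * kept.shape[1] / max(1, traces_df.shape[1]))
    return {
        "per_seed_percent": retentions,
        "min_percent": float(min(retentions)),
        "mean_percent": float(np.mean(retentions)),
        "n_traces": total,
    }


def spike_detection(
    duration_s: float = 300.0,
    n_electrodes: int = 60,
    sampling_rate_hz: float = 10_000.0,
    amplitude_sigma: float = 10.0,
    noise_sd: float = 3.0,
    match_tol_s: float = 3e-4,
    seed: int = 0,
    common_mode: bool = False,
) -> dict:
    """Spike-detector recall/precision against inserted ground-truth spikes.

    Renders a synchronous-event MEA recording with template spikes at
    ``amplitude_sigma`` times the noise sd, optionally adds a 7-Hz 100-uV
    common-mode waveform to every electrode, median-references, band-passes
    and detects. Returns pooled recall/precision and the per-electrode spike
    counts (for the common-mode invariance check).
    """
    rng = np.random.default_rng(seed)
    schedule = synth.generate_event_schedule(
        "synchronous", duration_s, n_cells=1, seed=int(rng.integers(2**31))
    )
    cm = None
    if common_mode:
        t = np.arange(int(duration_s * sampling_rate_hz)) / sampling_rate_hz
        cm = 100.0 * np.sin(2 * np.pi * 7.0 * t)
    rec, truth = synth.render_mea_recording(
        schedule,
        n_electrodes=n_electrodes,
        sampling_rate_hz=sampling_rate_hz,
        spike_amplitude_uv=amplitude_sigma * noise_sd,
        noise_sd=noise_sd,
        common_mode_waveform=cm,
        seed=int(rng.integers(2**31)),
    )
    params = mea.MeaParams()
    st = mea.detect_spikes(mea.bandpass_voltage(mea.median_reference(rec), params), params)

    hits = n_detected = n_true = 0
    for e in range(n_electrodes):
        det = st.timestamps[e]
        n_detected += len(det)
        n_true += len(truth[e])
        for t_true in truth[e]:
            if len(det) and np.min(np.abs(det - t_true)) <= match_tol_s:
                hits += 1
    return {
        "recall": hits / n_true if n_true else float("nan"),
        "precision": hits / n_detected if n_detected else float("nan"),
        "n_true": n_true,
        "timestamps": st.timestamps,
    }


def interval_recovery(n_seeds: int = 20, n_cells: int = 50, duration_s: float = 600.0, seed: int = 0) -> dict:
    """Recovery of the generator's network event interval from the pipeline.

    Per seed: generate a synchronous schedule, render the per-cell temporal
    traces, build the network trace, detect prominence-0.025 peaks, and
    compare the median detected inter-peak interval with the generator's
    median inter-event interval.
    """
    errors = []
    for k in range(n_seeds):
        s = int((seed * 99_991 + k) % 2**31)
        sched = synth.generate_event_schedule(
            "synchronous", duration_s, n_cells=n_cells, seed=s, **synth.default_schedule_params("synchronous")
        )
        gt = synth.make_ground_truth(sched, seed=s + 1)
        rng = np.random.default_rng(s + 2)
        raw = synth.render_cell_traces(gt, None) + rng.normal(0, 0.003, (n_cells, int(duration_s * 2)))
        from ._filters import minmax_scale

        net = traces.network_trace(minmax_scale(raw, axis=1))
        peaks = traces.find_peaks(net, traces.TraceParams().peak_prominence_network)
        detected = np.median(np.diff(traces.peak_times(peaks)))
        errors.append(abs(detected / sched.median_interval_s() - 1.0))
    return {
        "per_seed_relative_error": errors,
        "median_relative_error": float(np.median(errors)),
        "n_seeds": n_seeds,
    }
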