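"""Synthetic paired calcium-imaging and MEA recordings with known ground truth.

The generator emulates the statistical structure of developing stem-cell-
derived neural cultures as seen by the analysis pipeline:

* an event schedule in one of three network modes — ``synchronous``
  (network-wide events, jittered per-cell copies with partial participation),
  ``loosely_synchronous`` (the same plus substantial independent per-cell
  activity), and ``asynchronous`` (independent per-cell activity only);
* soma-sized fluorescent blobs whose intensity follows event-driven calcium
  transients (linear rise, exponential decay) on top of a resting level;
* per-cell pharmacological response classes, from strongly GABA-depolarized
  to GABA-inhibited, plus a sustained high-K+ depolarization used by the
  viability filter;
* extracellular spike waveforms (biphasic, ~1 ms) inserted into Gaussian
  noise on 60 electrodes, dense around network events and sparse elsewhere,
  with an optional common-mode perfusion artifact on all electrodes.

Everything is reproducible: a fixed seed yields bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import FluorescenceMovie
from .mea import VoltageRecording
from .protocol import PharmacologyProtocol, default_protocol, qc_protocol

MODES = ("synchronous", "loosely_synchronous", "asynchronous")


class UnknownModeError(ValueError):
    """Raised for an unrecognized network activity mode."""


# ------------------------------------------------------------------ schedules
@dataclass
class EventSchedule:
    """Network and per-cell event times for one recording."""

    mode: str
    duration_s: float
    network_events: np.ndarray
    per_cell_events: dict[int, np.ndarray]

    @property
    def n_cells(self) -> int:
        return len(self.per_cell_events)

    def median_interval_s(self) -> float:
        """Median interval between consecutive network events."""
        if len(self.network_events) < 2:
            return float("nan")
        return float(np.median(np.diff(self.network_events)))


def _renewal_times(rng, duration_s: float, rate_hz: float, spread: float) -> np.ndarray:
    """Event times of a renewal process with uniform intervals around 1/rate.

    Intervals are drawn from U((1-spread)/rate, (1+spread)/rate); with the
    default network rate of 0.03 Hz and spread 0.45 the intervals span
    roughly 18–48 s, reproducing the irregular-but-not-Poisson pacing of
    developmental network events.
    """
    if rate_hz <= 0:
        return np.empty(0)
    mean = 1.0 / rate_hz
    times = []
    t = rng.uniform(0, mean)
    while t < duration_s:
        times.append(t)
        t += rng.uniform((1 - spread) * mean, (1 + spread) * mean)
    return np.asarray(times)


def _poisson_times(rng, duration_s: float, rate_hz: float) -> np.ndarray:
    if rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0, duration_s, n))


def generate_event_schedule(
    mode: str,
    duration_s: float,
    network_rate_hz: float = 0.03,
    participation_prob: float = 0.8,
    jitter_s: float = 0.5,
    per_cell_rate_hz: float = 0.02,
    n_cells: int = 50,
    seed: int | None = None,
    interval_spread: float = 0.45,
) -> EventSchedule:
    """Draw an event schedule for one recording.

    In ``synchronous`` mode each cell keeps every network event with
    probability ``participation_prob``, jittered by at most ``jitter_s``;
    ``loosely_synchronous`` adds independent per-cell Poisson events at
    ``per_cell_rate_hz``; ``asynchronous`` cells share no common schedule.
    """
    if mode not in MODES:
        raise UnknownModeError(f"unknown mode {mode!r}; expected one of {MODES}")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if network_rate_hz < 0 or per_cell_rate_hz < 0:
        raise ValueError("rates must be non-negative")
    if not 0 <= participation_prob <= 1:
        raise ValueError("participation_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    network = (
        _renewal_times(rng, duration_s, network_rate_hz, interval_spread)
        if mode != "asynchronous"
        else np.empty(0)
    )
    per_cell: dict[int, np.ndarray] = {}
    for cell in range(n_cells):
        events = np.empty(0)
        if mode != "asynchronous" and len(network):
            keep = rng.random(len(network)) < participation_prob
            kept = network[keep] + rng.uniform(-jitter_s, jitter_s, int(keep.sum()))
            events = kept
        if mode != "synchronous":
            events = np.concatenate([events, _poisson_times(rng, duration_s, per_cell_rate_hz)])
        events = np.sort(events)
        per_cell[cell] = events[(events >= 0) & (events < duration_s)]
    return EventSchedule(mode=mode, duration_s=duration_s, network_events=network, per_cell_events=per_cell)


def default_schedule_params(mode: str) -> dict:
    """Mode-specific generator defaults (participation, jitter, rates)."""
    if mode == "synchronous":
        return dict(network_rate_hz=0.03, participation_prob=0.8, jitter_s=0.5, per_cell_rate_hz=0.0)
    if mode == "loosely_synchronous":
        return dict(network_rate_hz=0.03, participation_prob=0.4, jitter_s=2.0, per_cell_rate_hz=0.02)
    if mode == "asynchronous":
        return dict(network_rate_hz=0.0, participation_prob=0.0, jitter_s=0.0, per_cell_rate_hz=0.02)
    raise UnknownModeError(f"unknown mode {mode!r}; expected one of {MODES}")


# ------------------------------------------------------------- response class
@dataclass(frozen=True)
class ResponseClass:
    """Phenomenological per-cell pharmacological response.

    ``baseline_shift`` is the signed sustained fluorescence change during the
    GABA epoch as a fraction of the cell's dynamic range;
    ``participation_multiplier`` scales event transients occurring during the
    GABA epoch (strongly depolarized cells drop out of network events).
    """

    label: str
    baseline_shift: float
    participation_multiplier: float = 1.0


RESPONSE_CLASSES: dict[str, ResponseClass] = {
    "strongly_depolarized": ResponseClass("strongly_depolarized", 0.5, 0.0),
    "weakly_depolarized": ResponseClass("weakly_depolarized", 0.15, 1.0),
    "no_response": ResponseClass("no_response", 0.0, 1.0),
    "inhibited": ResponseClass("inhibited", -0.08, 0.0),
}

CLASS_ORDER = ("strongly_depolarized", "weakly_depolarized", "no_response", "inhibited")

#: Default class mixture for a synchronously active network: few strongly
#: depolarized cells, a spread from weak depolarization to inhibition.
DEFAULT_CLASS_PROPORTIONS = (0.05, 0.25, 0.45, 0.25)


def assign_response_classes(
    n_cells: int, class_proportions=DEFAULT_CLASS_PROPORTIONS, seed: int | None = None
) -> list[ResponseClass]:
    """Multinomial draw of response classes in ``CLASS_ORDER``."""
    p = np.asarray(class_proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("class proportions must be non-negative")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("class proportions must sum to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(CLASS_ORDER), size=n_cells, p=p)
    return [RESPONSE_CLASSES[CLASS_ORDER[i]] for i in labels]


# --------------------------------------------------------------- ground truth
@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows and the analysis must recover."""

    centroids: np.ndarray  # (n_cells, 2) as (row, col) pixels
    radii: np.ndarray  # soma profile scale per cell, px
    gains: np.ndarray  # per-cell brightness factor
    response_classes: list[ResponseClass]
    schedule: EventSchedule
    event_amplitudes: dict[int, np.ndarray]  # per-cell, aligned to events
    is_neuron: np.ndarray  # bool; non-neurons lack the K+ response
    rise_time_s: float = 1.0
    decay_tau_s: float = 4.0
    kplus_amplitude: float = 0.3

    @property
    def n_cells(self) -> int:
        return len(self.centroids)

    def to_dict(self) -> dict:
        return {
            "centroids": self.centroids.tolist(),
            "radii": self.radii.tolist(),
            "gains": self.gains.tolist(),
            "response_classes": [rc.label for rc in self.response_classes],
            "mode": self.schedule.mode,
            "duration_s": self.schedule.duration_s,
            "network_events": self.schedule.network_events.tolist(),
            "per_cell_events": {str(k): v.tolist() for k, v in self.schedule.per_cell_events.items()},
            "event_amplitudes": {str(k): v.tolist() for k, v in self.event_amplitudes.items()},
            "is_neuron": self.is_neuron.tolist(),
            "rise_time_s": self.rise_time_s,
            "decay_tau_s": self.decay_tau_s,
            "kplus_amplitude": self.kplus_amplitude,
        }


def make_ground_truth(
    schedule: EventSchedule,
    width_px: int = 448,
    height_px: int = 400,
    soma_sigma_px: float = 5.0,
    class_proportions=DEFAULT_CLASS_PROPORTIONS,
    transient_amplitude: float = 0.12,
    neuron_fraction: float = 1.0,
    seed: int | None = None,
) -> SyntheticGroundTruth:
    """Place cells on a jittered grid and draw per-cell rendering parameters.

    Cells are laid out with enough spacing that somata never overlap, as in
    a sparsely plated monolayer imaged at 10x.
    """
    rng = np.random.default_rng(seed)
    n_cells = schedule.n_cells
    margin = int(np.ceil(3 * soma_sigma_px)) + 2
    spacing = 5 * soma_sigma_px
    cols = max(1, int((width_px - 2 * margin) // spacing) + 1)
    rows = max(1, int((height_px - 2 * margin) // spacing) + 1)
    if rows * cols < n_cells:
        raise ValueError(
            f"frame {width_px}x{height_px} fits at most {rows * cols} non-overlapping cells, got {n_cells}"
        )
    grid = [(margin + r * spacing, margin + c * spacing) for r in range(rows) for c in range(cols)]
    chosen = rng.choice(len(grid), size=n_cells, replace=False)
    jitter = rng.uniform(-0.8 * soma_sigma_px, 0.8 * soma_sigma_px, size=(n_cells, 2))
    centroids = np.asarray([grid[i] for i in chosen], dtype=float).reshape(-1, 2) + jitter

    radii = soma_sigma_px * rng.uniform(0.85, 1.15, n_cells)
    gains = rng.uniform(0.7, 1.0, n_cells)
    classes = assign_response_classes(n_cells, class_proportions, seed=rng.integers(2**31))
    amplitudes = {
        cell: transient_amplitude * rng.uniform(0.6, 1.0, len(events))
        for cell, events in schedule.per_cell_events.items()
    }
    is_neuron = rng.random(n_cells) < neuron_fraction
    return SyntheticGroundTruth(
        centroids=centroids,
        radii=radii,
        gains=gains,
        response_classes=classes,
        schedule=schedule,
        event_amplitudes=amplitudes,
        is_neuron=is_neuron,
    )


# ------------------------------------------------------------------ rendering
def transient_kernel(t: np.ndarray, rise_s: float = 1.0, tau_s: float = 4.0) -> np.ndarray:
    """Calcium transient: linear rise over ``rise_s``, exponential decay."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    rising = (t >= 0) & (t < rise_s)
    out[rising] = t[rising] / rise_s
    decaying = t >= rise_s
    out[decaying] = np.exp(-(t[decaying] - rise_s) / tau_s)
    return out


def render_cell_traces(
    ground_truth: SyntheticGroundTruth,
    protocol: PharmacologyProtocol | None,
    frame_interval_s: float = 0.5,
    resting_level: float = 0.45,
) -> np.ndarray:
    """Noise-free temporal fluorescence components, shape (n_cells, n_frames).

    These are the signals the blobs in the rendered movie follow: resting
    level plus event transients, the class-specific sustained shift during
    the GABA epoch, and the sustained K+ depolarization (neurons only).
    """
    gt = ground_truth
    n_frames = int(round(gt.schedule.duration_s / frame_interval_s))
    t = np.arange(n_frames) * frame_interval_s
    traces = np.full((gt.n_cells, n_frames), resting_level)

    gaba = protocol.epoch("GABA") if protocol else None
    kplus = protocol.epoch("K+") if protocol else None
    for cell in range(gt.n_cells):
        rc = gt.response_classes[cell]
        for ev, amp in zip(gt.schedule.per_cell_events[cell], gt.event_amplitudes[cell]):
            if gaba is not None and gaba.contains(ev):
                amp = amp * rc.participation_multiplier
            if amp == 0:
                continue
            traces[cell] += amp * transient_kernel(t - ev, gt.rise_time_s, gt.decay_tau_s)
        if gaba is not None:
            traces[cell, (t >= gaba.start_s) & (t < gaba.end_s)] += rc.baseline_shift
        if kplus is not None and gt.is_neuron[cell]:
            traces[cell, (t >= kplus.start_s) & (t < kplus.end_s)] += gt.kplus_amplitude
    return np.clip(traces, 0.0, None)


def soma_profile(radius_px: float, patch_half: int) -> np.ndarray:
    """Flat-top (super-Gaussian, exponent 4) soma intensity profile.

    Real somata appear as bright discs with a fairly flat interior and a
    sharp rim rather than as point-spread-limited Gaussians; the flat top is
    also what makes their regional intensity maxima plateau-like, which the
    marker pipeline relies on.
    """
    ax = np.arange(-patch_half, patch_half + 1, dtype=float)
    d2 = ax[:, None] ** 2 + ax[None, :] ** 2
    return np.exp(-0.5 * (d2 / radius_px**2) ** 2)


def render_calcium_movie(
    ground_truth: SyntheticGroundTruth,
    width_px: int = 448,
    height_px: int = 400,
    frame_interval_s: float = 0.5,
    protocol: PharmacologyProtocol | None = None,
    noise_sd: float = 0.02,
    baseline_intensity: float = 0.2,
    clip_max: float = 1.5,
    seed: int | None = None,
) -> FluorescenceMovie:
    """Render the ground truth into a fluorescence movie.

    Each cell contributes ``gain * profile(x, y) * trace(t)`` on top of a
    uniform background at ``baseline_intensity``; i.i.d. Gaussian noise of
    ``noise_sd`` is added per pixel and frame and values clipped to
    ``[0, clip_max]``.
    """
    gt = ground_truth
    if width_px <= 0 or height_px <= 0 or frame_interval_s <= 0:
        raise ValueError("geometry and frame interval must be positive")
    if len(gt.centroids) and (
        (gt.centroids[:, 0] < 0).any()
        or (gt.centroids[:, 1] < 0).any()
        or (gt.centroids[:, 0] >= height_px).any()
        or (gt.centroids[:, 1] >= width_px).any()
    ):
        raise ValueError("cell centroids fall outside the frame")

    rng = np.random.default_rng(seed)
    traces = render_cell_traces(gt, protocol, frame_interval_s)
    n_frames = traces.shape[1] if gt.n_cells else int(round(gt.schedule.duration_s / frame_interval_s))
    # float32 throughout: a movie is hundreds of MB and the noise floor is
    # far above float32 resolution
    movie = rng.standard_normal(size=(n_frames, height_px, width_px), dtype=np.float32)
    movie *= np.float32(noise_sd)
    movie += np.float32(baseline_intensity)

    for cell in range(gt.n_cells):
        half = int(np.ceil(2.2 * gt.radii[cell]))
        patch = (gt.gains[cell] * soma_profile(gt.radii[cell], half)).astype(np.float32)
        r0, c0 = np.round(gt.centroids[cell]).astype(int)
        rs, re = max(0, r0 - half), min(height_px, r0 + half + 1)
        cs, ce = max(0, c0 - half), min(width_px, c0 + half + 1)
        sub = patch[rs - (r0 - half) : re - (r0 - half), cs - (c0 - half) : ce - (c0 - half)]
        movie[:, rs:re, cs:ce] += traces[cell].astype(np.float32)[:, None, None] * sub[None, :, :]

    np.clip(movie, 0.0, np.float32(clip_max), out=movie)
    return FluorescenceMovie(data=movie, frame_interval_s=frame_interval_s, protocol=protocol)


# ------------------------------------------------------------------ MEA side
def biphasic_template(sampling_rate_hz: float, width_ms: float = 1.0) -> np.ndarray:
    """Biphasic ~1-ms extracellular spike waveform, negative peak = -1.

    Modeled as the first derivative of a Gaussian: a sharp negative
    deflection followed by a positive rebound, the classic extracellular
    signature of a nearby action potential.
    """
    n = max(5, int(round(width_ms * 1e-3 * sampling_rate_hz)) | 1)
    t = np.linspace(-2.5, 2.5, n)
    w = -t * np.exp(-(t**2) / 2)
    return w / abs(w.min()) if w.min() < 0 else w / w.max()


def render_mea_recording(
    event_schedule: EventSchedule,
    n_electrodes: int = 60,
    sampling_rate_hz: float = 10_000.0,
    spike_template: np.ndarray | None = None,
    spike_amplitude_uv: float = 30.0,
    spikes_per_event_per_electrode: float = 20.0,
    background_rate_hz: float = 0.1,
    noise_sd: float = 3.0,
    event_spread_s: float = 0.5,
    common_mode_waveform: np.ndarray | None = None,
    reference_index: int = 0,
    seed: int | None = None,
) -> tuple[VoltageRecording, dict[int, np.ndarray]]:
    """Insert template spikes into Gaussian noise on all non-reference
    electrodes: Poisson bursts around each network event plus a sparse
    Poisson background. Returns the recording and the true spike times.
    """
    template = biphasic_template(sampling_rate_hz) if spike_template is None else np.asarray(spike_template, float)
    if sampling_rate_hz < 4 * 1000.0:  # template bandwidth ~ 1 kHz for the 1-ms waveform
        raise ValueError("sampling rate must be at least 4x the template bandwidth (>= 4 kHz)")
    n_samples = int(round(event_schedule.duration_s * sampling_rate_hz))
    if len(template) > n_samples:
        raise ValueError("spike template longer than the recording")
    ext = int(np.argmax(np.abs(template)))
    rng = np.random.default_rng(seed)

    # float32 end to end: a 60-electrode 300-s recording is ~0.7 GB
    voltages = rng.standard_normal(size=(n_electrodes, n_samples), dtype=np.float32)
    voltages *= np.float32(noise_sd)
    true_spikes: dict[int, np.ndarray] = {}
    t_lo = ext / sampling_rate_hz
    t_hi = (n_samples - (len(template) - ext)) / sampling_rate_hz
    for elec in range(n_electrodes):
        if elec == reference_index:
            true_spikes[elec] = np.empty(0)
            continue
        times = [
            _poisson_times(rng, event_schedule.duration_s, background_rate_hz)
        ]
        for ev in event_schedule.network_events:
            k = rng.poisson(spikes_per_event_per_electrode)
            times.append(ev + rng.normal(0.0, event_spread_s, k))
        t = np.sort(np.concatenate(times))
        t = t[(t >= t_lo) & (t < t_hi)]
        true_spikes[elec] = t
        idx = np.round(t * sampling_rate_hz).astype(int) - ext
        for i in idx:
            voltages[elec, i : i + len(template)] += spike_amplitude_uv * template

    if common_mode_waveform is not None:
        cm = np.asarray(common_mode_waveform, dtype=np.float32)
        if len(cm) != n_samples:
            raise ValueError("common-mode waveform length must match the recording")
        voltages += cm[None, :]

    rec = VoltageRecording(
        voltages=voltages,
        sampling_rate=sampling_rate_hz,
        reference_index=reference_index,
    )
    return rec, true_spikes


# ------------------------------------------------------------------ top level
def simulate_recording(
    mode: str = "synchronous",
    duration_s: float = 640.0,
    n_cells: int = 200,
    width_px: int = 448,
    height_px: int = 400,
    protocol: PharmacologyProtocol | None = None,
    noise_sd: float = 0.02,
    with_mea: bool = False,
    mea_sampling_rate_hz: float = 10_000.0,
    seed: int | None = None,
    **schedule_overrides,
):
    """One-call generation of a movie (and optionally an MEA recording).

    Returns ``(movie, ground_truth)`` or ``(movie, recording, true_spikes,
    ground_truth)`` when ``with_mea`` is set. All randomness derives from
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    params = default_schedule_params(mode)
    params.update(schedule_overrides)
    schedule = generate_event_schedule(
        mode, duration_s, n_cells=n_cells, seed=int(rng.integers(2**31)), **params
    )
    gt = make_ground_truth(schedule, width_px=width_px, height_px=height_px, seed=int(rng.integers(2**31)))
    if protocol is None:
        # Full application series when the recording is long enough to hold
        # it, otherwise the compact baseline + K+ protocol.
        full = default_protocol()
        protocol = full if duration_s >= full.end_s else qc_protocol()
        if protocol.end_s > duration_s:
            raise ValueError("recording too short for the default protocols; pass one explicitly")
    movie = render_calcium_movie(
        gt,
        width_px=width_px,
        height_px=height_px,
        protocol=protocol,
        noise_sd=noise_sd,
        seed=int(rng.integers(2**31)),
    )
    if not with_mea:
        return movie, gt
    rec, spikes = render_mea_recording(
        schedule, sampling_rate_hz=mea_sampling_rate_hz, seed=int(rng.integers(2**31))
    )
    return movie, rec, spikes, gt
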