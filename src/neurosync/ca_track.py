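"""Frame-to-frame cell linking and fluorescence trace extraction.

Per-block segmentations are linked into cell tracks by minimum-cost
assignment (Munkres/Hungarian) on centroid distances with a gating rule:
distances above the gating threshold (20 px) receive a prohibitive gating
cost (5000) and a detection/track is left unlinked at a non-assignment cost
of 500. Tracks shorter than 20 segmentation steps or visible in fewer than
half of their steps are discarded. Each surviving track yields a
full-frame-rate fluorescence intensity trace (mean over its region, carried
forward over missing steps) normalized to [0, 1], so intensity 1 is the
cell's maximum over the recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from ._filters import minmax_scale
from .ca_seg import SegParams, Segmentation
from .containers import FluorescenceMovie

_LARGE = 1e12  # forbidden-assignment sentinel in the augmented matrix


@dataclass
class TrackParams:
    gating_threshold: float = 20.0  # px
    gating_cost: float = 5000.0
    cost_non_assignment: float = 500.0
    min_track_age: int = 20  # segmentation steps
    min_visibility: float = 0.5  # fraction of steps with a detection

    def __post_init__(self) -> None:
        if not self.gating_cost > self.cost_non_assignment > 0:
            raise ValueError("require gating_cost > cost_non_assignment > 0")
        if not 0 < self.min_visibility <= 1:
            raise ValueError("min_visibility must lie in (0, 1]")


@dataclass
class CellTrack:
    """A tracked cell: per-step centroid (or None) and region ownership."""

    track_id: int
    first_step: int
    centroids: list  # per step since first_step: (row, col) or None
    regions: list  # per step since first_step: (seg_step, region_id) or None

    @property
    def age(self) -> int:
        return len(self.centroids)

    @property
    def visible_steps(self) -> int:
        return sum(c is not None for c in self.centroids)

    @property
    def visibility(self) -> float:
        return self.visible_steps / self.age if self.age else 0.0

    def last_centroid(self):
        for c in reversed(self.centroids):
            if c is not None:
                return c
        return None


@dataclass
class CalciumTrace:
    """Normalized fluorescence intensity per frame for one tracked cell."""

    cell_id: int
    intensity: np.ndarray
    frame_interval_s: float


def build_cost_matrix(prev_centroids, new_centroids, params: TrackParams | None = None) -> np.ndarray:
    """Gated Euclidean-distance cost matrix, |prev| x |new|.

    Entry (i, j) is the centroid distance when it does not exceed the gating
    threshold and the gating cost otherwise.
    """
    params = params or TrackParams()
    prev = np.asarray(prev_centroids, dtype=float).reshape(-1, 2)
    new = np.asarray(new_centroids, dtype=float).reshape(-1, 2)
    if len(prev) == 0 or len(new) == 0:
        return np.zeros((len(prev), len(new)))
    d = cdist(prev, new)
    return np.where(d <= params.gating_threshold, d, params.gating_cost)


def assign_tracks(
    cost_matrix: np.ndarray, params: TrackParams | None = None
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Optimal gated assignment with explicit non-assignment.

    Minimizes total cost where every unlinked row or column incurs
    ``cost_non_assignment``; a pair whose cost exceeds the non-assignment
    cost is never linked. Returns ``(matches, unmatched_rows,
    unmatched_cols)``.
    """
    params = params or TrackParams()
    cost = np.asarray(cost_matrix, dtype=float)
    n, m = cost.shape
    if n == 0 or m == 0:
        return [], list(range(n)), list(range(m))
    cna = params.cost_non_assignment
    augmented = np.full((n + m, m + n), _LARGE)
    augmented[:n, :m] = np.where(cost <= cna, cost, _LARGE)
    augmented[:n, m:] = np.where(np.eye(n, dtype=bool), cna, _LARGE)
    augmented[n:, :m] = np.where(np.eye(m, dtype=bool), cna, _LARGE)
    augmented[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(augmented)
    matches = [(int(i), int(j)) for i, j in zip(rows, cols) if i < n and j < m]
    matched_rows = {i for i, _ in matches}
    matched_cols = {j for _, j in matches}
    return (
        matches,
        [i for i in range(n) if i not in matched_rows],
        [j for j in range(m) if j not in matched_cols],
    )


def track_segmentations(
    segmentations: list[Segmentation], params: TrackParams | None = None
) -> list[CellTrack]:
    """Link a sequence of segmentations into cell tracks.

    Unmatched new detections open new tracks; unmatched existing tracks
    persist invisibly (their last centroid keeps competing for future
    detections) until the final visibility filter.
    """
    params = params or TrackParams()
    tracks: list[CellTrack] = []
    for step, seg in enumerate(segmentations):
        active = list(tracks)  # every track keeps its last centroid, so all compete
        prev = [t.last_centroid() for t in active]
        new = seg.centroids
        cost = build_cost_matrix(prev, new, params) if len(prev) and len(new) else np.zeros((len(prev), len(new)))
        matches, unmatched_prev, unmatched_new = assign_tracks(cost, params)
        for i, j in matches:
            t = active[i]
            t.centroids.append(tuple(new[j]))
            t.regions.append((step, int(seg.region_ids[j])))
        for i in unmatched_prev:
            active[i].centroids.append(None)
            active[i].regions.append(None)
        for j in unmatched_new:
            tracks.append(
                CellTrack(
                    track_id=len(tracks),
                    first_step=step,
                    centroids=[tuple(new[j])],
                    regions=[(step, int(seg.region_ids[j]))],
                )
            )
    return tracks


def filter_tracks(
    tracks: list[CellTrack], params: TrackParams | None = None, n_steps: int | None = None
) -> list[CellTrack]:
    """Keep tracks with age >= min_track_age and visibility >= min_visibility."""
    params = params or TrackParams()
    return [t for t in tracks if t.age >= params.min_track_age and t.visibility >= params.min_visibility]


def extract_traces(
    movie: FluorescenceMovie,
    tracks: list[CellTrack],
    segmentations: list[Segmentation],
    seg_params: SegParams | None = None,
) -> list[CalciumTrace]:
    """Per-frame mean region intensity for each track, normalized to [0, 1].

    The region owning a frame comes from the segmentation step covering that
    frame; steps without a detection reuse the last known region (or the
    first, before a track's creation step). Normalization is min-max per
    trace; a constant trace maps to zeros.
    """
    seg_params = seg_params or SegParams()
    stride = seg_params.stride or seg_params.frames_to_average
    n_steps = len(segmentations)
    n_frames = movie.n_frames
    out: list[CalciumTrace] = []
    for t in tracks:
        known = [r for r in t.regions if r is not None]
        if not known:
            raise ValueError(f"track {t.track_id} has no region in any step")
        # region used at each global segmentation step (carry forward/backward)
        per_step: list[tuple[int, int]] = []
        current = known[0]
        for step in range(n_steps):
            local = step - t.first_step
            if 0 <= local < len(t.regions) and t.regions[local] is not None:
                current = t.regions[local]
            per_step.append(current)
        trace = np.empty(n_frames)
        for step in range(n_steps):
            seg_step, region_id = per_step[step]
            rows, cols = segmentations[seg_step].region_pixels(region_id)
            f0 = step * stride
            f1 = n_frames if step == n_steps - 1 else min(n_frames, (step + 1) * stride)
            trace[f0:f1] = movie.data[f0:f1, rows, cols].mean(axis=1)
        out.append(CalciumTrace(cell_id=t.track_id, intensity=minmax_scale(trace), frame_interval_s=movie.frame_interval_s))
    return out


def traces_to_frame(traces: list[CalciumTrace]) -> pd.DataFrame:
    """Trace list as a frames x cells DataFrame (columns = cell ids)."""
    return pd.DataFrame({tr.cell_id: tr.intensity for tr in traces})


def track_movie(
    movie: FluorescenceMovie,
    seg_params: SegParams | None = None,
    track_params: TrackParams | None = None,
):
    """Segment, track, filter, and extract traces in one call.

    Returns ``(traces_df, kept_tracks, segmentations)``.
    """
    from .ca_seg import segment_movie

    seg_params = seg_params or SegParams()
    track_params = track_params or TrackParams()
    segmentations = segment_movie(movie, seg_params)
    tracks = track_segmentations(segmentations, track_params)
    kept = filter_tracks(tracks, track_params, n_steps=len(segmentations))
    traces = extract_traces(movie, kept, segmentations, seg_params)
    return traces_to_frame(traces), kept, segmentations
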