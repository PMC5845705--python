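"""Shared in-memory containers for imaging data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import PharmacologyProtocol


@dataclass
class FluorescenceMovie:
    """Frames x height x width fluorescence stack with epoch annotations.

    ``data`` holds intensities on an arbitrary non-negative scale (the
    analysis min-max normalizes everything downstream); ``frame_interval_s``
    is the time between frames (0.5 s at the standard 2-Hz imaging rate).
    """

    data: np.ndarray
    frame_interval_s: float = 0.5
    protocol: PharmacologyProtocol | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("movie data must be frames x height x width")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s
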