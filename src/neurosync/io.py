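"""Reading and writing the pipeline's on-disk formats.

Movies travel as multi-page 16-bit TIFF stacks, voltage recordings as HDF5
(electrodes x samples, float32, with sampling_rate and reference_index
attributes), protocols as YAML, ground truth as JSON, traces and spike
trains as delimited text.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .containers import FluorescenceMovie
from .mea import SpikeTrain, VoltageRecording
from .protocol import PharmacologyProtocol

#: intensity corresponding to the full 16-bit scale in exported TIFFs
TIFF_SCALE = 1.5


def write_movie(movie: FluorescenceMovie, path) -> None:
    """Write a movie as a multi-page 16-bit TIFF (intensity 0..TIFF_SCALE)."""
    scaled = np.clip(movie.data / TIFF_SCALE, 0, 1) * np.iinfo(np.uint16).max
    tifffile.imwrite(path, scaled.astype(np.uint16), photometric="minisblack")


def read_movie(path, frame_interval_s: float = 0.5, protocol: PharmacologyProtocol | None = None) -> FluorescenceMovie:
    data = tifffile.imread(path).astype(np.float32)
    if data.ndim == 2:
        data = data[None]
    if data.dtype.kind != "f" or data.max() > TIFF_SCALE:
        data = data.astype(np.float32) * (TIFF_SCALE / np.iinfo(np.uint16).max)
    return FluorescenceMovie(data=data, frame_interval_s=frame_interval_s, protocol=protocol)


def write_recording(recording: VoltageRecording, path) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("voltages", data=recording.voltages.astype(np.float32), compression="gzip")
        ds.attrs["sampling_rate"] = recording.sampling_rate
        ds.attrs["reference_index"] = recording.reference_index
        if recording.positions is not None:
            f.create_dataset("positions", data=recording.positions)


def read_recording(path) -> VoltageRecording:
    with h5py.File(path, "r") as f:
        ds = f["voltages"]
        return VoltageRecording(
            voltages=ds[:],
            sampling_rate=float(ds.attrs["sampling_rate"]),
            reference_index=int(ds.attrs["reference_index"]),
            positions=f["positions"][:] if "positions" in f else None,
        )


def write_ground_truth(ground_truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(ground_truth.to_dict(), fh)


def write_spiketrain(spiketrain: SpikeTrain, table_path, cutout_path=None) -> None:
    rows = [
        (elec, t)
        for elec, times in enumerate(spiketrain.timestamps)
        for t in times
    ]
    pd.DataFrame(rows, columns=["electrode", "timestamp_s"]).to_csv(table_path, index=False)
    if cutout_path is not None:
        with h5py.File(cutout_path, "w") as f:
            for elec, c in enumerate(spiketrain.cutouts):
                f.create_dataset(f"electrode_{elec}", data=c.astype(np.float32))


def write_raster_png(gray: np.ndarray, path) -> None:
    """Write an 8-bit grayscale raster image (electrodes x bins)."""
    iio.imwrite(path, np.asarray(gray, dtype=np.uint8))


def write_traces(traces_df: pd.DataFrame, path) -> None:
    traces_df.to_csv(path, index=False)


def read_traces(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_track_table(tracks, path) -> None:
    """Track summary table: id, creation step, age, visible steps."""
    rows = [
        {
            "track_id": t.track_id,
            "first_step": t.first_step,
            "age_steps": t.age,
            "visible_steps": t.visible_steps,
        }
        for t in tracks
    ]
    pd.DataFrame(rows, columns=["track_id", "first_step", "age_steps", "visible_steps"]).to_csv(
        path, index=False
    )


def write_labels_tiff(labels: np.ndarray, path) -> None:
    tifffile.imwrite(path, labels.astype(np.uint16), photometric="minisblack")


def write_region_table(segmentation, path) -> None:
    areas = np.bincount(segmentation.labels.ravel())
    rows = [
        {
            "id": int(rid),
            "centroid_row": float(c[0]),
            "centroid_col": float(c[1]),
            "area_px": int(areas[rid]) if rid < len(areas) else 0,
        }
        for rid, c in zip(segmentation.region_ids, segmentation.centroids)
    ]
    pd.DataFrame(rows, columns=["id", "centroid_row", "centroid_col", "area_px"]).to_csv(path, index=False)
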