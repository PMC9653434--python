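"""Readers and writers for the formats the pipelines exchange.

Movies and labelled ROI masks travel as multi-frame TIFF (tifffile); trial
tables and response/distance tables as CSV (pandas); trace sets and
photometry sessions as HDF5 (h5py) with a ``rate`` attribute.
"""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np
import pandas as pd
import tifffile

from .imaging import Movie, ResponseStat, RoiSet, TraceSet
from .photometry import PhotometrySession
from .trials import read_trial_table, write_trial_table  # re-exported

__all__ = [
    "read_movie",
    "write_movie",
    "read_roi_masks",
    "write_roi_masks",
    "read_trial_table",
    "write_trial_table",
    "read_traces",
    "write_traces",
    "read_photometry_session",
    "write_photometry_session",
    "response_table",
    "write_response_table",
]


def read_movie(path, frame_rate: float, pixel_size_um: float | None = None) -> Movie:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return Movie(frames=frames.astype(float), frame_rate=frame_rate, pixel_size_um=pixel_size_um)


def write_movie(movie: Movie, path) -> None:
    tifffile.imwrite(path, movie.frames.astype(np.float32))


def read_roi_masks(path) -> RoiSet:
    return RoiSet(masks=tifffile.imread(path).astype(int))


def write_roi_masks(rois: RoiSet, path) -> None:
    tifffile.imwrite(path, rois.masks.astype(np.uint16))


def write_traces(traces: TraceSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=traces.traces)
        f.create_dataset("roi_labels", data=np.asarray(traces.roi_labels))
        if traces.interpolated_frames is not None:
            f.create_dataset("interpolated_frames", data=traces.interpolated_frames)
        f.attrs["rate"] = traces.frame_rate


def read_traces(path) -> TraceSet:
    with h5py.File(path, "r") as f:
        interp = f["interpolated_frames"][:] if "interpolated_frames" in f else None
        return TraceSet(
            traces=f["traces"][:],
            frame_rate=float(f.attrs["rate"]),
            roi_labels=f["roi_labels"][:],
            interpolated_frames=interp,
        )


def write_photometry_session(session: PhotometrySession, h5_path, trials_csv_path) -> None:
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("fluorescence", data=session.fluorescence)
        if session.reflection is not None:
            f.create_dataset("reflection", data=session.reflection)
        f.attrs["rate"] = session.rate
    write_trial_table(session.trials, trials_csv_path)


def read_photometry_session(h5_path, trials_csv_path) -> PhotometrySession:
    trials = read_trial_table(trials_csv_path)
    with h5py.File(h5_path, "r") as f:
        reflection = f["reflection"][:] if "reflection" in f else None
        return PhotometrySession(
            fluorescence=f["fluorescence"][:],
            reflection=reflection,
            rate=float(f.attrs["rate"]),
            trials=trials,
        )


def response_table(stats: dict[tuple, ResponseStat]) -> pd.DataFrame:
    """Flatten {(cell, stimulus): ResponseStat} into a tidy DataFrame."""
    rows = []
    for (cell, stimulus), stat in stats.items():
        row = {"cell": cell, "stimulus": stimulus}
        row.update(dataclasses.asdict(stat))
        rows.append(row)
    return pd.DataFrame(rows)


def write_response_table(stats: dict[tuple, ResponseStat], path) -> None:
    response_table(stats).to_csv(path, index=False)
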