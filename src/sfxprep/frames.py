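"""Simple HDF5 frame-stack container used by the CLI and examples.

One file holds a raw-layout frame stack at ``/frames`` (n, rows, cols), the
per-event ids at ``/event_id`` and the scalar beam metadata (wavelength in
ångström, detector distance in metres) as file attributes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

__all__ = ["FrameStack", "write_frame_stack", "read_frame_stack"]


@dataclass
class FrameStack:
    frames: np.ndarray  # (n, rows, cols)
    event_ids: np.ndarray  # (n,) int64
    wavelength: float | None = None  # ångström
    detector_distance: float | None = None  # metres

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n, rows, cols)")
        if len(self.event_ids) != len(self.frames):
            raise ValueError("one event id per frame required")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return zip(self.event_ids.tolist(), self.frames)


def write_frame_stack(stack: FrameStack, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=stack.frames, track_times=False)
        f.create_dataset("event_id", data=np.asarray(stack.event_ids, dtype=np.int64),
                         track_times=False)
        if stack.wavelength is not None:
            f.attrs["wavelength_A"] = stack.wavelength
        if stack.detector_distance is not None:
            f.attrs["detector_distance_m"] = stack.detector_distance
    return path


def read_frame_stack(path) -> FrameStack:
    with h5py.File(path, "r") as f:
        if "frames" not in f:
            raise ValueError(f"{path}: no /frames dataset; found {sorted(f.keys())}")
        frames = f["frames"][()]
        ids = f["event_id"][()] if "event_id" in f else np.arange(len(frames), dtype=np.int64)
        wl = float(f.attrs["wavelength_A"]) if "wavelength_A" in f.attrs else None
        dist = float(f.attrs["detector_distance_m"]) if "detector_distance_m" in f.attrs else None
    return FrameStack(frames=frames, event_ids=np.asarray(ids, dtype=np.int64),
                      wavelength=wl, detector_distance=dist)
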