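"""File readers/writers for the pipeline's standard artifacts.

Tables are CSV (pandas), arrays are HDF5 (h5py), images/videos are TIFF
(tifffile).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .core import EVENT_TYPES, BehaviorSession, DffMatrix, Epoch, Trajectory


def write_session_csv(session: BehaviorSession, path: str | Path) -> None:
    df = pd.DataFrame({"frame": np.arange(session.n_frames), "t": session.imaging_t})
    for ev in EVENT_TYPES:
        df[f"B_{ev}"] = session.vectors.get(ev, np.zeros(session.n_frames, dtype=np.uint8))
    df["B_NE"] = session.ne_vector()
    stage_col = np.array([""] * session.n_frames, dtype=object)
    for name, sl in session.stage_slices.items():
        stage_col[sl] = name
    df["stage"] = stage_col
    df.to_csv(path, index=False)


def read_session_csv(path: str | Path, imaging_rate: float,
                     epochs: list[Epoch] | None = None) -> BehaviorSession:
    from .core import STAGES

    df = pd.read_csv(path)
    n = len(df)
    vectors = {ev: df[f"B_{ev}"].to_numpy(np.uint8) for ev in EVENT_TYPES}
    stage_slices: dict[str, slice] = {}
    if "stage" in df.columns:
        stages = df["stage"].astype(str).to_numpy()
        for name in STAGES:
            idx = np.flatnonzero(stages == name)
            stage_slices[name] = (slice(int(idx[0]), int(idx[-1]) + 1)
                                  if idx.size else slice(0, 0))
    else:
        stage_slices = {name: slice(0, n) for name in STAGES}
    return BehaviorSession(imaging_t=df["t"].to_numpy(), vectors=vectors,
                           stage_slices=stage_slices, epochs=epochs or [],
                           imaging_rate=imaging_rate)


def write_epochs_csv(epochs: list[Epoch], path: str | Path) -> None:
    pd.DataFrame([
        {"event": e.event, "start": e.start, "end": e.end,
         "start_t": e.start_t, "end_t": e.end_t}
        for e in epochs
    ]).to_csv(path, index=False)


def read_epochs_csv(path: str | Path) -> list[Epoch]:
    df = pd.read_csv(path)
    return [Epoch(event=r.event, start=int(r.start), end=int(r.end),
                  start_t=float(r.start_t), end_t=float(r.end_t))
            for r in df.itertuples()]


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y}).to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(t=df["t"].to_numpy(), x=df["x"].to_numpy(), y=df["y"].to_numpy())


def write_dff_h5(dff: DffMatrix, path: str | Path, truth=None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("dff", data=dff.C)
        f.create_dataset("t", data=dff.t)
        f.attrs["rate"] = dff.rate
        f.create_dataset("neuron_ids", data=np.asarray(dff.neuron_ids))
        if truth is not None:
            g = f.create_group("ground_truth")
            g.create_dataset("classes",
                             data=np.array([str(c) for c in truth.classes], dtype="S"))
            g.create_dataset("kernel", data=truth.kernel)
            g.create_dataset("activations", data=truth.activations)
            g.attrs["kernel_rise"] = truth.kernel_rise
            g.attrs["kernel_decay"] = truth.kernel_decay


def read_dff_h5(path: str | Path) -> DffMatrix:
    with h5py.File(path, "r") as f:
        return DffMatrix(C=f["dff"][()], t=f["t"][()], rate=float(f.attrs["rate"]),
                         neuron_ids=f["neuron_ids"][()])


def write_video_tiff(video: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(video))


def read_video_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_label_tiff(label_image: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, label_image.astype(np.int32))
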