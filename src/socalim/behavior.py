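"""Trajectory smoothing, exploration-epoch detection and clock alignment.

Turns head-position tracks into smoothed trajectories, distance-threshold
exploration epochs, binary behavior vectors on the imaging timebase and
occupancy summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Epoch, Trajectory

DEFAULT_DISTANCE_THRESHOLD_CM = 3.0
DEFAULT_MIN_DURATION_S = 0.5
DEFAULT_MEDIAN_WINDOW = 5


@dataclass(frozen=True)
class AlignmentStats:
    """Timestamp-matching error between the two clocks (seconds)."""

    mean_abs_dt: float
    sd_abs_dt: float
    max_abs_dt: float


def smooth_trajectory(traj: Trajectory, window: int = DEFAULT_MEDIAN_WINDOW) -> Trajectory:
    """Coordinatewise running median; endpoints use a shrinking window.

    Parameters
    ----------
    traj : Trajectory
    window : odd int >= 1
        Number of behavior frames in the median window.

    Returns
    -------
    Trajectory with identical timestamps and median-filtered coordinates.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > len(traj):
        raise ValueError(
            f"window ({window}) exceeds trajectory length ({len(traj)})"
        )
    if window == 1:
        return Trajectory(traj.t.copy(), traj.x.copy(), traj.y.copy(),
                          None if traj.valid is None else traj.valid.copy())
    # center=True + min_periods=1 gives the shrinking-window median at edges
    xs = pd.Series(traj.x).rolling(window, center=True, min_periods=1).median()
    ys = pd.Series(traj.y).rolling(window, center=True, min_periods=1).median()
    return Trajectory(traj.t.copy(), xs.to_numpy(), ys.to_numpy(),
                      None if traj.valid is None else traj.valid.copy())


def distance_to_target(traj: Trajectory, target_xy: tuple[float, float]) -> np.ndarray:
    """Per-frame Euclidean distance (cm) between the head and a target."""
    tx, ty = target_xy
    return np.hypot(traj.x - tx, traj.y - ty)


def detect_epochs(
    traj: Trajectory,
    target_xy: tuple[float, float],
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD_CM,
    min_duration: float = DEFAULT_MIN_DURATION_S,
    event: str = "mouse",
) -> tuple[list[Epoch], np.ndarray]:
    """Maximal below-threshold runs of head-target distance.

    A frame belongs to an epoch when ``distance < distance_threshold``; runs
    shorter than ``min_duration`` seconds are dropped.  No gap-merging is
    performed.  Returned epochs are on the *behavior* clock (frame indices
    into ``traj``); use :func:`align_to_imaging` to move them onto the
    imaging timebase.

    Returns
    -------
    (epochs, distances)
    """
    if distance_threshold <= 0:
        raise ValueError("distance_threshold must be > 0")
    d = distance_to_target(traj, target_xy)
    below = d < distance_threshold
    if traj.valid is not None:
        below &= traj.valid
    edges = np.flatnonzero(np.diff(np.concatenate(([0], below.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    out: list[Epoch] = []
    n = len(traj)
    for s, e in zip(starts, ends):
        if e < n:
            end_t = float(traj.t[e])
        else:
            dt = float(traj.t[-1] - traj.t[-2]) if n > 1 else 0.0
            end_t = float(traj.t[-1]) + dt
        if end_t - traj.t[s] + 1e-12 < min_duration:
            continue
        out.append(Epoch(event=event, start=int(s), end=int(e),
                         start_t=float(traj.t[s]), end_t=end_t))
    return out, d


def align_to_imaging(
    behavior_t: np.ndarray,
    values: np.ndarray,
    imaging_t: np.ndarray,
) -> tuple[np.ndarray, AlignmentStats]:
    """Resample a behavior-clock vector onto the imaging clock.

    Each imaging frame takes the value of the *nearest* behavior timestamp.
    Also reports statistics of the |dt| between matched stamps.

    Raises
    ------
    ValueError if the two clocks do not overlap at all.
    """
    behavior_t = np.asarray(behavior_t, dtype=float)
    imaging_t = np.asarray(imaging_t, dtype=float)
    values = np.asarray(values)
    if behavior_t.size == 0 or imaging_t.size == 0:
        raise ValueError("empty clock")
    if behavior_t[-1] < imaging_t[0] or imaging_t[-1] < behavior_t[0]:
        raise ValueError("behavior and imaging clocks do not overlap")
    idx = np.searchsorted(behavior_t, imaging_t)
    idx = np.clip(idx, 1, behavior_t.size - 1)
    left = behavior_t[idx - 1]
    right = behavior_t[idx]
    nearest = np.where(imaging_t - left <= right - imaging_t, idx - 1, idx)
    dt = np.abs(behavior_t[nearest] - imaging_t)
    stats = AlignmentStats(
        mean_abs_dt=float(dt.mean()),
        sd_abs_dt=float(dt.std()),
        max_abs_dt=float(dt.max()),
    )
    return values[nearest], stats


def epochs_to_imaging(
    epochs: list[Epoch],
    behavior_t: np.ndarray,
    imaging_t: np.ndarray,
) -> tuple[list[Epoch], AlignmentStats]:
    """Carry behavior-clock epochs onto the imaging clock via a binary vector.

    Epochs shorter than one imaging frame may vanish.
    """
    from .core import epochs_to_vector, vector_to_epochs

    by_event: dict[str, list[Epoch]] = {}
    for e in epochs:
        by_event.setdefault(e.event, []).append(e)
    out: list[Epoch] = []
    stats = None
    for event, evs in by_event.items():
        vec = epochs_to_vector(evs, len(behavior_t))
        aligned, stats = align_to_imaging(behavior_t, vec, imaging_t)
        out.extend(vector_to_epochs(aligned, imaging_t, event))
    if stats is None:
        _, stats = align_to_imaging(behavior_t, np.zeros(len(behavior_t)), imaging_t)
    out.sort(key=lambda e: (e.start, e.event))
    return out, stats


def exploration_ratio(
    epochs: list[Epoch],
    side_events: tuple[str, str] = ("mouse", "object"),
) -> dict[str, float]:
    """Per-side direct-exploration time ratios.

    ratio_side = time exploring that side's target / total direct-exploration
    time across both targets; the two ratios sum to 1.

    Raises
    ------
    ValueError when neither side was explored at all.
    """
    times = {ev: sum(e.duration_s for e in epochs if e.event == ev)
             for ev in side_events}
    total = sum(times.values())
    if total <= 0:
        raise ValueError("zero total exploration time; ratio undefined")
    return {ev: times[ev] / total for ev in side_events}
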