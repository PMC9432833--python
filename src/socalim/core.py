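"""Shared domain types for the social-ensemble calcium analysis pipeline.

The whole pipeline works on two clocks: a behavior clock (~30 Hz trajectory
samples) and an imaging clock (~9.76 Hz fluorescence frames).  All epoch and
vector bookkeeping downstream of alignment lives on the imaging clock, with
0-based frames and half-open ``[start, end)`` intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The five direct-exploration event types, in canonical order.
EVENT_TYPES: tuple[str, ...] = ("cage", "object", "mouse", "new", "old")

#: The three session stages, in temporal order.
STAGES: tuple[str, ...] = ("habituation", "sociability", "novelty")

#: Which event types can occur in which stage.
STAGE_EVENTS: dict[str, tuple[str, ...]] = {
    "habituation": ("cage",),
    "sociability": ("object", "mouse"),
    "novelty": ("new", "old"),
}

#: Event types counted as social interaction (used for the social vector B_M
#: and for inactivation of tonic neurons).
SOCIAL_EVENTS: tuple[str, ...] = ("mouse", "new", "old")


@dataclass(frozen=True)
class Epoch:
    """One contiguous exploration event on the imaging clock.

    ``start``/``end`` are imaging frame indices, half-open; ``start_t`` and
    ``end_t`` are the corresponding times in seconds on the session clock.
    """

    event: str
    start: int
    end: int
    start_t: float
    end_t: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"epoch end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def n_frames(self) -> int:
        return self.end - self.start

    @property
    def duration_s(self) -> float:
        return self.end_t - self.start_t


@dataclass
class Trajectory:
    """Head-position track on the behavior clock.

    t is in seconds and strictly increasing; x, y in cm.  ``valid`` marks
    frames where tracking succeeded (all-valid when omitted).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have identical shapes")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("trajectory timestamps must be strictly increasing")
        if self.valid is None:
            ok = slice(None)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            ok = self.valid
        if not (np.all(np.isfinite(self.x[ok])) and np.all(np.isfinite(self.y[ok]))):
            raise ValueError("coordinates must be finite where valid")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class BehaviorSession:
    """Binary behavior vectors on the imaging timebase plus raw trajectory.

    ``vectors`` maps each event type to a uint8 vector over imaging frames;
    ``stage_slices`` maps stage names to frame slices.  The nonexploration
    (NE) vector is derived, never stored: it is 1 exactly where every event
    vector is 0.
    """

    imaging_t: np.ndarray
    vectors: dict[str, np.ndarray]
    stage_slices: dict[str, slice]
    epochs: list[Epoch]
    imaging_rate: float
    trajectory: Trajectory | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.imaging_t = np.asarray(self.imaging_t, dtype=float)
        n = self.imaging_t.size
        for ev, v in self.vectors.items():
            v = np.asarray(v, dtype=np.uint8)
            if v.size != n:
                raise ValueError(f"vector for {ev!r} has wrong length")
            if not np.all((v == 0) | (v == 1)):
                raise ValueError(f"vector for {ev!r} is not binary")
            self.vectors[ev] = v

    @property
    def n_frames(self) -> int:
        return self.imaging_t.size

    def event_vector(self, event: str) -> np.ndarray:
        return self.vectors[event]

    def ne_vector(self) -> np.ndarray:
        """1 where no exploration event of any type is active."""
        any_event = np.zeros(self.n_frames, dtype=np.uint8)
        for v in self.vectors.values():
            any_event |= v
        return (1 - any_event).astype(np.uint8)

    def social_vector(self, events: tuple[str, ...] = SOCIAL_EVENTS) -> np.ndarray:
        """Union of the social event vectors (the B_M of the classifier)."""
        out = np.zeros(self.n_frames, dtype=np.uint8)
        for ev in events:
            if ev in self.vectors:
                out |= self.vectors[ev]
        return out

    def epochs_of(self, event: str) -> list[Epoch]:
        return [e for e in self.epochs if e.event == event]


@dataclass
class DffMatrix:
    """Neurons x frames matrix of dF/F with its imaging timestamps."""

    C: np.ndarray
    t: np.ndarray
    rate: float
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.t = np.asarray(self.t, dtype=float)
        if self.C.shape[1] != self.t.size:
            raise ValueError("column count must equal number of timestamps")
        if not np.all(np.isfinite(self.C)):
            raise ValueError("dF/F matrix contains non-finite values")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.C.shape[0])

    @property
    def n_neurons(self) -> int:
        return self.C.shape[0]

    @property
    def n_frames(self) -> int:
        return self.C.shape[1]


def epochs_to_vector(epochs: list[Epoch], n_frames: int) -> np.ndarray:
    """Binary vector that is 1 inside any of the given (half-open) epochs."""
    v = np.zeros(n_frames, dtype=np.uint8)
    for e in epochs:
        v[max(e.start, 0) : min(e.end, n_frames)] = 1
    return v


def vector_to_epochs(
    vector: np.ndarray, t: np.ndarray, event: str
) -> list[Epoch]:
    """Maximal runs of 1s in a binary vector, as half-open epochs."""
    v = np.asarray(vector).astype(np.int8)
    if v.size == 0:
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], v, [0]))))
    starts, ends = edges[::2], edges[1::2]
    out = []
    for s, e in zip(starts, ends):
        end_t = t[e] if e < t.size else t[-1] + (t[-1] - t[-2] if t.size > 1 else 0.0)
        out.append(Epoch(event=event, start=int(s), end=int(e),
                         start_t=float(t[s]), end_t=float(end_t)))
    return out
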