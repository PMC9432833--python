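"""Event-associated neuron detection and social-cue-preference set logic.

Per neuron and event type E, the mean dF/F during E frames is contrasted
with the mean during that stage's nonexploration (NE) frames; the neuron is
event-associated (EAN) when the difference strictly exceeds beta times the
NE noise level.  NewPN/OldPN labels then follow by set difference over the
five EAN flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import HP_CUTOFF_HZ, HP_ORDER, event_average_trace, noise_highpass
from .core import EVENT_TYPES, STAGE_EVENTS, STAGES, BehaviorSession, DffMatrix

DEFAULT_BETA = 0.5

#: Stage each event type is tested in (with that stage's NE as contrast).
EVENT_STAGE = {ev: stage for stage, evs in STAGE_EVENTS.items() for ev in evs}

#: EAN flag names per event type.
FLAG_NAMES = {"cage": "CageN", "object": "ON", "mouse": "MN",
              "new": "NewN", "old": "OldN"}


def mean_state_amplitude(
    c_i: np.ndarray,
    b_e: np.ndarray,
    normalization: str = "active",
) -> float:
    """Mean amplitude of the trace during a binary state.

    ``active`` (default): conditional mean over frames where the state is 1.
    ``full``: masked sum divided by the full trace length (conflates tuning
    with event frequency; provided for comparison).
    Returns NaN when the state has no active frame.
    """
    c_i = np.asarray(c_i, dtype=float)
    b_e = np.asarray(b_e)
    active = int(b_e.sum())
    if active == 0:
        return float("nan")
    masked = float(c_i[b_e == 1].sum())
    if normalization == "active":
        return masked / active
    if normalization == "full":
        return masked / c_i.size
    raise ValueError(f"unknown normalization {normalization!r}")


def noise_ne(
    c_i: np.ndarray,
    b_ne: np.ndarray,
    rate: float,
    order: int = HP_ORDER,
    cutoff: float = HP_CUTOFF_HZ,
) -> float:
    """Noise level of the NE-spliced trace (high-pass SD).

    NE frames are concatenated in time order into one signal, then the
    50-order / 1 Hz high-pass SD estimator is applied.
    """
    c_i = np.asarray(c_i, dtype=float)
    spliced = c_i[np.asarray(b_ne) == 1]
    if spliced.size <= order:
        raise ValueError(
            f"only {spliced.size} NE frames; need more than the filter "
            f"order ({order})"
        )
    return noise_highpass(spliced, rate, order, cutoff)


def detect_ean(c_e: float, c_ne: float, noise: float,
               beta: float = DEFAULT_BETA) -> bool:
    """Strict threshold test: c_E - c_NE > beta * noise_NE."""
    if np.isnan(c_e) or np.isnan(c_ne):
        return False
    return bool(c_e - c_ne > beta * noise)


def preferred_labels(flags: dict[str, bool]) -> str:
    """NewPN/OldPN/none by set difference over the five EAN flags.

    NewPN: NewN and none of CageN, ON, MN, OldN.  OldPN: OldN and none of
    CageN, ON, MN, NewN.  The two are mutually exclusive by construction.
    """
    missing = set(FLAG_NAMES.values()) - set(flags)
    if missing:
        raise ValueError(f"missing flags: {sorted(missing)}")
    others = flags["CageN"] or flags["ON"] or flags["MN"]
    if flags["NewN"] and not flags["OldN"] and not others:
        return "NewPN"
    if flags["OldN"] and not flags["NewN"] and not others:
        return "OldPN"
    return "none"


@dataclass
class TuningProfile:
    """Per-neuron tuning summary over the five event types."""

    neuron_id: int
    c_e: dict[str, float]          # mean dF/F during each event type
    c_ne: dict[str, float]         # stage NE mean, keyed by event type
    noise_ne: dict[str, float]     # stage NE noise, keyed by event type
    flags: dict[str, bool]         # CageN/ON/MN/NewN/OldN
    beta: float
    preferred: str                 # NewPN / OldPN / none

    @property
    def c_e_minus_ne(self) -> dict[str, float]:
        return {ev: self.c_e[ev] - self.c_ne[ev] for ev in self.c_e}


def compute_tuning(
    dff: DffMatrix,
    session: BehaviorSession,
    beta: float = DEFAULT_BETA,
    normalization: str = "active",
) -> list[TuningProfile]:
    """EAN flags and preferred labels for every neuron.

    Each event type is tested inside its own stage, against that stage's NE
    frames (cage in habituation; object/mouse in sociability; new/old in
    novelty).
    """
    ne = session.ne_vector()
    profiles: list[TuningProfile] = []

    # per-stage NE masks and noise depend only on the session, compute once
    stage_ne: dict[str, np.ndarray] = {}
    for stage in STAGES:
        sl = session.stage_slices[stage]
        stage_ne[stage] = ne[sl]

    for i in range(dff.n_neurons):
        c_e: dict[str, float] = {}
        c_ne: dict[str, float] = {}
        nz: dict[str, float] = {}
        flags: dict[str, bool] = {}
        for ev in EVENT_TYPES:
            stage = EVENT_STAGE[ev]
            sl = session.stage_slices[stage]
            trace = dff.C[i, sl]
            b_e = session.vectors[ev][sl]
            c_e[ev] = mean_state_amplitude(trace, b_e, normalization)
            c_ne[ev] = mean_state_amplitude(trace, stage_ne[stage], normalization)
            nz[ev] = noise_ne(trace, stage_ne[stage], dff.rate)
            flags[FLAG_NAMES[ev]] = detect_ean(c_e[ev], c_ne[ev], nz[ev], beta)
        profiles.append(TuningProfile(
            neuron_id=int(dff.neuron_ids[i]), c_e=c_e, c_ne=c_ne, noise_ne=nz,
            flags=flags, beta=beta, preferred=preferred_labels(flags),
        ))
    return profiles


def ean_counts(profiles: list[TuningProfile]) -> dict[str, int]:
    """Counts of each EAN flag plus NewPN/OldPN over a profile list."""
    out = {name: 0 for name in FLAG_NAMES.values()}
    out["NewPN"] = out["OldPN"] = 0
    for p in profiles:
        for name, on in p.flags.items():
            out[name] += int(on)
        if p.preferred != "none":
            out[p.preferred] += 1
    return out


def behavior_correlation_matrix(
    dff: DffMatrix,
    session: BehaviorSession,
    neuron_indices: np.ndarray | list[int],
    mode: str = "event_average",
    half_window_s: float = 4.0,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Average states x states Pearson correlation matrix of an ensemble.

    Per neuron, a response profile is built for each event type and the
    profiles are correlated pairwise; matrices are then averaged over the
    ensemble (NaN-aware).  ``event_average`` profiles are the onset-aligned
    8 s event-average traces; ``concat`` profiles are the spliced raw event
    frames truncated to the shortest state.  Zero-variance profiles yield
    NaN entries.
    """
    ne = session.ne_vector()
    states = EVENT_TYPES
    mats = []
    for i in neuron_indices:
        profiles: dict[str, np.ndarray | None] = {}
        for ev in states:
            if mode == "event_average":
                tr = event_average_trace(
                    dff.C[i], session.epochs_of(ev), session.vectors[ev], ne,
                    dff.rate, mode="onset", half_window_s=half_window_s)
                profiles[ev] = None if tr is None else tr.trace
            elif mode == "concat":
                sel = dff.C[i, session.vectors[ev] == 1]
                profiles[ev] = sel if sel.size >= 2 else None
            else:
                raise ValueError(f"unknown mode {mode!r}")
        if mode == "concat":
            lens = [p.size for p in profiles.values() if p is not None]
            if lens:
                m = min(lens)
                profiles = {ev: (None if p is None else p[:m])
                            for ev, p in profiles.items()}
        mat = np.full((len(states), len(states)), np.nan)
        for a, eva in enumerate(states):
            for b, evb in enumerate(states):
                pa, pb = profiles[eva], profiles[evb]
                if pa is None or pb is None:
                    continue
                if a == b:
                    mat[a, b] = 1.0
                    continue
                if pa.std() == 0 or pb.std() == 0:
                    continue
                mat[a, b] = float(np.corrcoef(pa, pb)[0, 1])
        mats.append(mat)
    if not mats:
        raise ValueError("empty ensemble")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN entries
        avg = np.nanmean(np.stack(mats), axis=0)
    return avg, states
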