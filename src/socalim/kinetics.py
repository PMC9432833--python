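"""Socially activated epoch detection and transient kinetics.

An epoch is *activated* for a neuron when the peak of its calcium signal in
the 4 s before and after epoch onset falls strictly after the onset.  Epochs
shorter than 4 s, or with less than 4 s of event-free time before onset, are
discarded.  Per-neuron summaries are the activation probability P_up and the
mean rise time / amplitude over activated epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Epoch

DEFAULT_WINDOW_S = 4.0

ACTIVATED = "activated"
NONACTIVATED = "nonactivated"
DISCARDED = "discarded"


@dataclass
class EpochStatus:
    epoch: Epoch
    status: str
    peak_frame: int | None = None     # absolute frame of the peak
    peak_value: float | None = None


@dataclass
class EpochKinetics:
    """Per-neuron kinetic summary over one cue's epochs."""

    p_up: float                    # activated / (activated + nonactivated)
    rise_time_s: float             # mean over activated epochs (NaN if none)
    amplitude: float               # mean peak - baseline over activated epochs
    statuses: list[EpochStatus]
    n_activated: int
    n_nonactivated: int
    n_discarded: int


def epoch_status(
    c_i: np.ndarray,
    epoch: Epoch,
    prev_end: int | None,
    rate: float,
    window_s: float = DEFAULT_WINDOW_S,
) -> EpochStatus:
    """Status of one epoch for one trace.

    ``prev_end`` is the end frame of the preceding epoch in the list (None
    when there is none); the pre-onset gap must cover at least ``window_s``
    seconds or the epoch is discarded.  The peak is the first argmax over
    the inclusive frame window [start - w, start + w]; a peak exactly at the
    start frame (or before) counts as nonactivated.
    """
    c_i = np.asarray(c_i, dtype=float)
    w = int(round(window_s * rate))
    s = epoch.start
    if epoch.duration_s < window_s:
        return EpochStatus(epoch, DISCARDED)
    if s - w < 0 or s + w >= c_i.size:
        return EpochStatus(epoch, DISCARDED)
    if prev_end is not None and s - prev_end < w:
        return EpochStatus(epoch, DISCARDED)
    win = c_i[s - w : s + w + 1]
    peak_rel = int(np.argmax(win))           # earliest frame on ties
    peak = s - w + peak_rel
    status = ACTIVATED if peak > s else NONACTIVATED
    return EpochStatus(epoch, status, peak_frame=peak, peak_value=float(win[peak_rel]))


def kinetic_summary(
    c_i: np.ndarray,
    epochs: list[Epoch],
    rate: float,
    window_s: float = DEFAULT_WINDOW_S,
) -> EpochKinetics:
    """P_up, mean rise time and mean amplitude over a sorted epoch list.

    Baseline for the amplitude is the minimum of the trace in the 4 s before
    epoch onset.  Rise time is peak time minus onset time.  Means are taken
    over activated epochs only; they are NaN when no epoch is activated, and
    P_up is NaN when every epoch was discarded.
    """
    c_i = np.asarray(c_i, dtype=float)
    w = int(round(window_s * rate))
    epochs = sorted(epochs, key=lambda e: e.start)
    statuses: list[EpochStatus] = []
    rises: list[float] = []
    amps: list[float] = []
    prev_end: int | None = None
    for ep in epochs:
        st = epoch_status(c_i, ep, prev_end, rate, window_s)
        statuses.append(st)
        prev_end = ep.end
        if st.status == ACTIVATED:
            rises.append((st.peak_frame - ep.start) / rate)
            baseline = float(c_i[ep.start - w : ep.start].min())
            amps.append(st.peak_value - baseline)
    n_act = sum(s.status == ACTIVATED for s in statuses)
    n_non = sum(s.status == NONACTIVATED for s in statuses)
    n_dis = sum(s.status == DISCARDED for s in statuses)
    valid = n_act + n_non
    return EpochKinetics(
        p_up=n_act / valid if valid else float("nan"),
        rise_time_s=float(np.mean(rises)) if rises else float("nan"),
        amplitude=float(np.mean(amps)) if amps else float("nan"),
        statuses=statuses,
        n_activated=n_act,
        n_nonactivated=n_non,
        n_discarded=n_dis,
    )
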