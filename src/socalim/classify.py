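"""Permutation-null classification of neurons against a behavior vector.

A neuron's similarity to the binary social vector B is

    S = B . C / (|B|^2 + |C|^2)

and its label comes from comparing S to a null distribution built by fully
shuffling B k times.  Also here: ensemble signal-behavior correlation,
peri-event average traces, high-pass noise estimation and engagement
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import firwin, lfilter

from .core import DffMatrix, Epoch

DEFAULT_K = 1000
DEFAULT_UPPER_PCT = 99.17
DEFAULT_LOWER_PCT = 0.83
HP_ORDER = 50
HP_CUTOFF_HZ = 1.0


def similarity(b: np.ndarray, c: np.ndarray) -> float:
    """S = b.c / (|b|^2 + |c|^2); errors when both vectors are all-zero."""
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    if b.shape != c.shape:
        raise ValueError("vectors must have equal length")
    denom = float(b @ b + c @ c)
    if denom == 0.0:
        raise ValueError("similarity undefined: both vectors are zero")
    return float(b @ c) / denom


def permutation_null(
    b: np.ndarray,
    c: np.ndarray,
    k: int = DEFAULT_K,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """k similarities of fully shuffled copies of b against c.

    The shuffle is a full random permutation of b, so the null ignores the
    autocorrelation of the behavior vector by design.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    denom = float(b @ b + c @ c)
    if denom == 0.0:
        raise ValueError("similarity undefined: both vectors are zero")
    # shuffle a compact copy when b is binary; the matmul stays float64
    src = b.astype(np.uint8) if np.all((b == 0) | (b == 1)) else b
    perms = rng.permuted(np.broadcast_to(src, (k, b.size)).copy(), axis=1)
    return (perms.astype(np.float64) @ c) / denom


def classify_neuron(
    s: float,
    null_samples: np.ndarray,
    upper_pct: float = DEFAULT_UPPER_PCT,
    lower_pct: float = DEFAULT_LOWER_PCT,
) -> str:
    """SAN / SIN / Other by strict comparison with null percentiles.

    Percentiles use linear interpolation between order statistics; ties at
    either threshold yield "Other".
    """
    null_samples = np.asarray(null_samples, dtype=float)
    if null_samples.size == 0:
        raise ValueError("null_samples must be nonempty")
    hi = np.percentile(null_samples, upper_pct)
    lo = np.percentile(null_samples, lower_pct)
    if s > hi:
        return "SAN"
    if s < lo:
        return "SIN"
    return "Other"


@dataclass
class SimilarityResult:
    neuron_id: int
    s: float
    threshold_lo: float
    threshold_hi: float
    label: str
    null_samples: np.ndarray | None = None


def classify_population(
    b: np.ndarray,
    dff: DffMatrix,
    k: int = DEFAULT_K,
    upper_pct: float = DEFAULT_UPPER_PCT,
    lower_pct: float = DEFAULT_LOWER_PCT,
    rng: np.random.Generator | None = None,
    keep_null: bool = False,
) -> list[SimilarityResult]:
    """Classify every row of a dF/F matrix against one behavior vector."""
    rng = np.random.default_rng() if rng is None else rng
    out: list[SimilarityResult] = []
    for i in range(dff.n_neurons):
        c = dff.C[i]
        s = similarity(b, c)
        null = permutation_null(b, c, k=k, rng=rng)
        hi = float(np.percentile(null, upper_pct))
        lo = float(np.percentile(null, lower_pct))
        label = "SAN" if s > hi else ("SIN" if s < lo else "Other")
        out.append(SimilarityResult(
            neuron_id=int(dff.neuron_ids[i]), s=s, threshold_lo=lo,
            threshold_hi=hi, label=label,
            null_samples=null if keep_null else None,
        ))
    return out


def signal_behavior_correlation(results: list[SimilarityResult]) -> dict[str, float]:
    """Ensemble mean similarity per label; empty ensembles come back as NaN."""
    out: dict[str, float] = {}
    for label in ("SAN", "SIN"):
        vals = [r.s for r in results if r.label == label]
        out[label] = float(np.mean(vals)) if vals else float("nan")
    return out


# ---------------------------------------------------------------------------
# event-average traces


def moving_average(x: np.ndarray, span: int = 5) -> np.ndarray:
    """Centered moving average with a window that shrinks at the edges."""
    if span < 1:
        raise ValueError("span must be >= 1")
    if span == 1:
        return np.asarray(x, dtype=float).copy()
    x = np.asarray(x, dtype=float)
    c = np.concatenate(([0.0], np.cumsum(x)))
    h = span // 2
    n = x.size
    lo = np.clip(np.arange(n) - h, 0, n)
    hi = np.clip(np.arange(n) + h + 1, 0, n)
    return (c[hi] - c[lo]) / (hi - lo)


@dataclass
class EventAverageTrace:
    """Peri-event average over an 8 s window centered on onset or offset."""

    time: np.ndarray      # seconds relative to the alignment point
    trace: np.ndarray     # mean dF/F, same length as time
    n_events: int
    mode: str             # "onset" or "offset"
    relative: bool = False


def _valid_fragments(
    epochs: list[Epoch],
    b_event: np.ndarray,
    b_ne: np.ndarray,
    half_frames: int,
    n_frames: int,
    mode: str,
) -> list[int]:
    """Alignment points with a clean NE half and a clean E half.

    Onset mode: the ``half_frames`` before the start are all NE and the
    ``half_frames`` from the start are all inside the event.  Offset mode is
    the mirror image around the epoch end.
    """
    points: list[int] = []
    for ep in epochs:
        if mode == "onset":
            p = ep.start
            pre_ok = p - half_frames >= 0 and np.all(b_ne[p - half_frames : p] == 1)
            post_ok = p + half_frames <= n_frames and np.all(b_event[p : p + half_frames] == 1)
        elif mode == "offset":
            p = ep.end
            pre_ok = p - half_frames >= 0 and np.all(b_event[p - half_frames : p] == 1)
            post_ok = p + half_frames <= n_frames and np.all(b_ne[p : p + half_frames] == 1)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if pre_ok and post_ok:
            points.append(p)
    return points


def event_average_trace(
    c_i: np.ndarray,
    epochs: list[Epoch],
    b_event: np.ndarray,
    b_ne: np.ndarray,
    rate: float,
    mode: str = "onset",
    relative: bool = False,
    half_window_s: float = 4.0,
    span: int = 5,
) -> EventAverageTrace | None:
    """Average the smoothed trace over all valid 8 s peri-event fragments.

    A valid onset fragment has 4 s of pure NE before the epoch start and 4 s
    of pure event after it (mirrored for offsets).  The trace is smoothed by
    a span-``span`` moving average before alignment.  The ``relative``
    variant first subtracts the neuron's mean dF/F over all NE frames.
    Returns None when no fragment is valid.
    """
    c_i = np.asarray(c_i, dtype=float)
    half = int(round(half_window_s * rate))
    points = _valid_fragments(epochs, np.asarray(b_event), np.asarray(b_ne),
                              half, c_i.size, mode)
    if not points:
        return None
    x = c_i.copy()
    if relative:
        ne_frames = np.asarray(b_ne) == 1
        if not ne_frames.any():
            raise ValueError("no NE frames for the relative baseline")
        x = x - x[ne_frames].mean()
    x = moving_average(x, span)
    frags = np.stack([x[p - half : p + half] for p in points])
    time = (np.arange(2 * half) - half) / rate
    return EventAverageTrace(time=time, trace=frags.mean(axis=0),
                             n_events=len(points), mode=mode, relative=relative)


def ensemble_event_average(traces: list[EventAverageTrace | None]) -> EventAverageTrace | None:
    """Mean of per-neuron event-triggered signals (None entries skipped)."""
    kept = [t for t in traces if t is not None]
    if not kept:
        return None
    return EventAverageTrace(
        time=kept[0].time.copy(),
        trace=np.mean([t.trace for t in kept], axis=0),
        n_events=sum(t.n_events for t in kept),
        mode=kept[0].mode,
        relative=kept[0].relative,
    )


# ---------------------------------------------------------------------------
# noise and engagement


def highpass_taps(rate: float, order: int = HP_ORDER,
                  cutoff: float = HP_CUTOFF_HZ) -> np.ndarray:
    """FIR high-pass taps: given order, Hamming window, cutoff in Hz."""
    return firwin(order + 1, cutoff, fs=rate, pass_zero=False, window="hamming")


def noise_highpass(
    c_i: np.ndarray,
    rate: float,
    order: int = HP_ORDER,
    cutoff: float = HP_CUTOFF_HZ,
) -> float:
    """SD of the mean-subtracted trace after forward high-pass filtering.

    The first ``order`` output samples (filter start-up) are excluded from
    the SD.  Raises when the trace is not longer than the filter order.
    """
    c_i = np.asarray(c_i, dtype=float)
    if c_i.size <= order:
        raise ValueError(
            f"trace length {c_i.size} must exceed filter order {order}"
        )
    taps = highpass_taps(rate, order, cutoff)
    y = lfilter(taps, 1.0, c_i - c_i.mean())
    return float(y[order:].std())


@dataclass
class EngagementStats:
    """Engagement of an ensemble in discrete events.

    consistency[i]: engaged events / total events for neuron i;
    percentage[j]: engaged neurons / ensemble size for event j;
    engaged: (n_neurons, n_events) bool; noise: per-neuron noise level.
    """

    engaged: np.ndarray
    consistency: np.ndarray
    percentage: np.ndarray
    noise: np.ndarray
    n: int = 10
    factor: float = 3.0


def engagement(
    dff: DffMatrix,
    epochs: list[Epoch],
    n: int = 10,
    factor: float = 3.0,
) -> EngagementStats:
    """Event engagement by the n-points-over-3-sigma rule.

    A neuron is engaged in an event when at least ``n`` samples inside the
    event exceed ``factor`` times its noise level (high-pass SD of the whole
    trace).  Events with fewer than ``n`` frames can never be engaged.
    """
    noise = np.array([noise_highpass(dff.C[i], dff.rate)
                      for i in range(dff.n_neurons)])
    engaged = np.zeros((dff.n_neurons, len(epochs)), dtype=bool)
    for j, ep in enumerate(epochs):
        seg = dff.C[:, ep.start : ep.end]
        counts = (seg > factor * noise[:, None]).sum(axis=1)
        engaged[:, j] = counts >= n
    n_events = max(len(epochs), 1)
    consistency = engaged.sum(axis=1) / n_events
    percentage = engaged.mean(axis=0) if dff.n_neurons else np.zeros(len(epochs))
    return EngagementStats(engaged=engaged, consistency=consistency,
                           percentage=percentage, noise=noise, n=n, factor=factor)
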