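"""Synthetic sessions with planted ground truth.

Generates three things, each deterministic under a seed:

* behavior sessions — binary exploration-event vectors on the imaging
  timebase plus a matching 30 Hz trajectory whose head-target distance dips
  below threshold during each planted epoch;
* dF/F matrices — GCaMP6s-like transients (fast rise, slow decay) riding on
  white baseline noise, with per-neuron planted tuning classes;
* rendered fluorescence videos — disk somata plus a shared multiplicative
  neuropil field, for exercising the annular-ring-subtraction extractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .core import (
    EVENT_TYPES,
    STAGE_EVENTS,
    STAGES,
    BehaviorSession,
    DffMatrix,
    Epoch,
    Trajectory,
)

#: Event types each planted class responds to with transients.  Preferred
#: classes (NewPN/OldPN) respond to exactly one event type; the plain
#: event-associated classes NewN/OldN deliberately respond to several so the
#: set-difference logic downstream has something to exclude.  SIN is tonic
#: (elevated baseline suppressed during social epochs), null is noise only.
CLASS_RESPONSES: dict[str, tuple[str, ...]] = {
    "SAN": ("mouse", "new", "old"),
    "SIN": (),
    "CageN": ("cage",),
    "ON": ("object",),
    "MN": ("mouse",),
    "NewN": ("new", "mouse"),
    "OldN": ("old", "mouse"),
    "NewPN": ("new",),
    "OldPN": ("old",),
    "null": (),
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic session generator."""

    imaging_rate: float = 9.76
    behavior_rate: float = 30.0
    stage_durations: tuple[float, float, float] = (300.0, 300.0, 300.0)
    n_neurons: int = 50
    class_counts: dict[str, int] = field(default_factory=dict)
    response_gain: float = 1.0
    response_prob: float = 0.8
    kernel_rise: float = 0.2
    kernel_decay: float = 1.8
    baseline_noise_sd: float = 0.2
    epoch_rate: float = 2.0
    epoch_duration_range: tuple[float, float] = (4.5, 8.0)
    epoch_min_gap: float = 5.0
    n_epochs: dict[str, int] | None = None
    arena_size: tuple[float, float] = (40.0, 40.0)
    distance_threshold: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.imaging_rate <= 0 or self.behavior_rate <= 0:
            raise ValueError("rates must be > 0")
        if any(d < 0 for d in self.stage_durations):
            raise ValueError("stage durations must be >= 0")
        if self.n_neurons < 0:
            raise ValueError("n_neurons must be >= 0")
        unknown = set(self.class_counts) - set(CLASS_RESPONSES)
        if unknown:
            raise ValueError(f"unknown planted classes: {sorted(unknown)}")
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        if sum(self.class_counts.values()) > self.n_neurons:
            raise ValueError("class counts sum exceeds n_neurons")
        lo, hi = self.epoch_duration_range
        if lo <= 0 or hi < lo:
            raise ValueError("epoch durations must be positive and ordered")
        if self.epoch_rate < 0:
            raise ValueError("epoch_rate must be >= 0")

    @property
    def total_duration(self) -> float:
        return float(sum(self.stage_durations))


@dataclass
class GroundTruth:
    """What was planted: classes, kernel, and per-epoch activation flags."""

    classes: np.ndarray              # (n_neurons,) of class-name strings
    kernel: np.ndarray               # sampled response kernel, peak 1
    kernel_rise: float
    kernel_decay: float
    #: (n_neurons, n_epochs) int8: 1 planted response, 0 planted no-response,
    #: -1 epoch not of a type this neuron responds to.
    activations: np.ndarray

    def neurons_of(self, cls: str) -> np.ndarray:
        return np.flatnonzero(self.classes == cls)


#: Target positions per event type (cm, arena coordinates scaled to size).
_TARGET_FRAC = {
    "cage": (0.2, 0.5),
    "object": (0.2, 0.5),
    "mouse": (0.8, 0.5),
    "new": (0.2, 0.5),
    "old": (0.8, 0.5),
}


def target_positions(config: SimulationConfig) -> dict[str, tuple[float, float]]:
    w, h = config.arena_size
    return {ev: (fx * w, fy * h) for ev, (fx, fy) in _TARGET_FRAC.items()}


def _requested_epochs(config: SimulationConfig, stage: str, rng: np.random.Generator):
    """(event, duration) pairs to place in one stage."""
    dur = config.stage_durations[STAGES.index(stage)]
    items: list[tuple[str, float]] = []
    lo, hi = config.epoch_duration_range
    for ev in STAGE_EVENTS[stage]:
        if config.n_epochs is not None:
            n = int(config.n_epochs.get(ev, 0))
        else:
            n = int(round(config.epoch_rate * dur / 60.0))
        for _ in range(n):
            items.append((ev, float(rng.uniform(lo, hi))))
    return items


def _place_epochs(
    items: list[tuple[str, float]],
    stage_start: float,
    stage_duration: float,
    min_gap: float,
    rng: np.random.Generator,
) -> list[tuple[str, float, float]]:
    """Randomly order and place non-overlapping epochs with min gaps."""
    if not items:
        return []
    order = rng.permutation(len(items))
    items = [items[i] for i in order]
    n = len(items)
    total = sum(d for _, d in items)
    slack = stage_duration - total - min_gap * (n + 1)
    if slack < 0:
        raise ValueError(
            f"stage of {stage_duration:.1f} s too short to place {n} epochs "
            f"totalling {total:.1f} s with {min_gap:.1f} s gaps"
        )
    cuts = np.sort(rng.uniform(0.0, slack, size=n + 1))
    extra = np.diff(np.concatenate(([0.0], cuts)))  # n+1 nonneg, sum <= slack
    t = stage_start
    placed = []
    for (ev, d), x in zip(items, extra[:-1]):
        t += min_gap + x
        placed.append((ev, t, t + d))
        t += d
    return placed


def simulate_behavior(
    config: SimulationConfig, seed: int | None = None
) -> BehaviorSession:
    """Generate a three-stage behavior session with planted epochs.

    Cage epochs occur only in habituation, object/mouse only in sociability,
    new/old only in novelty.  Epochs within a stage are jointly
    non-overlapping with at least ``epoch_min_gap`` seconds between them.
    The returned session carries a 30 Hz trajectory whose distance to the
    active target dips below ``distance_threshold`` during each epoch.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    n_frames = int(round(config.total_duration * config.imaging_rate))
    imaging_t = np.arange(n_frames) / config.imaging_rate

    # place epochs stage by stage
    placed: list[tuple[str, float, float]] = []
    stage_start = 0.0
    stage_slices: dict[str, slice] = {}
    for stage, dur in zip(STAGES, config.stage_durations):
        items = _requested_epochs(config, stage, rng)
        placed.extend(_place_epochs(items, stage_start, dur, config.epoch_min_gap, rng))
        f0 = int(np.searchsorted(imaging_t, stage_start, side="left"))
        f1 = int(np.searchsorted(imaging_t, stage_start + dur, side="left"))
        stage_slices[stage] = slice(f0, f1)
        stage_start += dur

    epochs: list[Epoch] = []
    for ev, t0, t1 in sorted(placed, key=lambda p: p[1]):
        s = int(np.searchsorted(imaging_t, t0, side="left"))
        e = int(np.searchsorted(imaging_t, t1, side="left"))
        if e > s:  # epochs shorter than one imaging frame vanish
            epochs.append(Epoch(event=ev, start=s, end=e, start_t=t0, end_t=t1))

    vectors = {ev: np.zeros(n_frames, dtype=np.uint8) for ev in EVENT_TYPES}
    for e in epochs:
        vectors[e.event][e.start : e.end] = 1

    traj = _simulate_trajectory(config, placed, rng)

    return BehaviorSession(
        imaging_t=imaging_t,
        vectors=vectors,
        stage_slices=stage_slices,
        epochs=epochs,
        imaging_rate=config.imaging_rate,
        trajectory=traj,
        meta={"seed": config.seed if seed is None else seed},
    )


def _simulate_trajectory(
    config: SimulationConfig,
    placed: list[tuple[str, float, float]],
    rng: np.random.Generator,
) -> Trajectory:
    """Ornstein-Uhlenbeck walk pulled toward the active target during epochs.

    During an epoch the position is additionally clamped inside 0.8x the
    detection threshold so distance-threshold epoching recovers the planted
    epochs; outside epochs it is pushed beyond 1.5x threshold of all targets.
    """
    dt = 1.0 / config.behavior_rate
    nb = int(round(config.total_duration * config.behavior_rate))
    tb = np.arange(nb) / config.behavior_rate
    w, h = config.arena_size
    center = np.array([w / 2.0, h / 2.0])
    targets = target_positions(config)
    thr = config.distance_threshold

    # per behavior frame: index of active epoch target (or None)
    active_target = np.full(nb, -1, dtype=int)
    tkeys = list(targets)
    for ev, t0, t1 in placed:
        i0, i1 = np.searchsorted(tb, [t0, t1])
        active_target[i0:i1] = tkeys.index(ev)

    theta_in, theta_out, sigma = 8.0, 1.0, 5.0
    pos = center.copy()
    xy = np.empty((nb, 2))
    noise = rng.normal(0.0, sigma * np.sqrt(dt), size=(nb, 2))
    for i in range(nb):
        k = active_target[i]
        if k >= 0:
            mu = np.asarray(targets[tkeys[k]])
            theta = theta_in
        else:
            mu = center
            theta = theta_out
        pos = pos + theta * (mu - pos) * dt + noise[i]
        if k >= 0:
            d = np.hypot(*(pos - mu))
            if d > 0.8 * thr:
                pos = mu + (pos - mu) * (0.8 * thr / d)
        else:
            for txy in targets.values():
                txy = np.asarray(txy)
                d = np.hypot(*(pos - txy))
                if d < 1.5 * thr:
                    pos = txy + (pos - txy) * (1.5 * thr / max(d, 1e-9))
        pos = np.clip(pos, [0.0, 0.0], [w, h])
        xy[i] = pos
    return Trajectory(t=tb, x=xy[:, 0], y=xy[:, 1])


def response_kernel(rise: float, decay: float, rate: float) -> np.ndarray:
    """Double-exponential transient kernel sampled at the imaging rate.

    k(t) = exp(-t/decay) - exp(-t/rise), normalized to unit peak.
    """
    if not 0 < rise < decay:
        raise ValueError("need 0 < rise < decay")
    n = max(int(np.ceil(8.0 * decay * rate)), 2)
    t = np.arange(n) / rate
    k = np.exp(-t / decay) - np.exp(-t / rise)
    return k / k.max()


def kernel_time_to_peak(rise: float, decay: float) -> float:
    """Analytic argmax of the double-exponential kernel, in seconds."""
    return rise * decay / (decay - rise) * np.log(decay / rise)


def assign_classes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    labels: list[str] = []
    for cls in CLASS_RESPONSES:
        labels.extend([cls] * int(config.class_counts.get(cls, 0)))
    labels.extend(["null"] * (config.n_neurons - len(labels)))
    labels_arr = np.array(labels, dtype=object)
    return labels_arr[rng.permutation(config.n_neurons)]


def simulate_dff(
    config: SimulationConfig,
    session: BehaviorSession,
    seed: int | None = None,
) -> tuple[DffMatrix, GroundTruth]:
    """Plant tuning classes into a dF/F matrix aligned with ``session``.

    For a neuron whose class responds to event type E, every E epoch
    independently triggers (probability ``response_prob``) a transient of
    ``response_gain`` times the unit-peak kernel at epoch onset.  SINs carry
    a tonic component of ``response_gain`` that is suppressed during social
    epochs.  All neurons ride on white Gaussian baseline noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n, T = config.n_neurons, session.n_frames
    kernel = response_kernel(config.kernel_rise, config.kernel_decay, config.imaging_rate)
    classes = assign_classes(config, rng)
    social = session.social_vector().astype(float)

    C = rng.normal(0.0, config.baseline_noise_sd, size=(n, T)) \
        if config.baseline_noise_sd > 0 else np.zeros((n, T))
    activations = np.full((n, len(session.epochs)), -1, dtype=np.int8)

    for i in range(n):
        cls = classes[i]
        events = CLASS_RESPONSES[cls]
        if cls == "SIN":
            C[i] += config.response_gain * (1.0 - social)
            continue
        for j, ep in enumerate(session.epochs):
            if ep.event not in events:
                continue
            fire = rng.random() < config.response_prob
            activations[i, j] = int(fire)
            if fire:
                stop = min(ep.start + kernel.size, T)
                C[i, ep.start : stop] += config.response_gain * kernel[: stop - ep.start]

    truth = GroundTruth(
        classes=classes,
        kernel=kernel,
        kernel_rise=config.kernel_rise,
        kernel_decay=config.kernel_decay,
        activations=activations,
    )
    return DffMatrix(C=C, t=session.imaging_t.copy(), rate=config.imaging_rate), truth


# ---------------------------------------------------------------------------
# video rendering


@dataclass
class SomaLayout:
    """Where the somata sit in the rendered frame."""

    shape: tuple[int, int] = (128, 128)
    centers: list[tuple[float, float]] = field(default_factory=list)  # (row, col)
    radius_px: float = 4.0
    soma_f0: float = 2000.0          # soma brightness scale (counts)
    soma_baseline: float = 1.0       # baseline fraction added to dF/F
    offset: float = 100.0            # camera offset (counts)

    @classmethod
    def grid(cls, n: int, shape: tuple[int, int] = (128, 128),
             radius_px: float = 4.0, margin_px: int = 16, **kw) -> "SomaLayout":
        """n somata on a jittered square grid, guaranteed non-overlapping."""
        side = int(np.ceil(np.sqrt(n)))
        rows = np.linspace(margin_px, shape[0] - margin_px, side)
        cols = np.linspace(margin_px, shape[1] - margin_px, side)
        centers = [(float(r), float(c)) for r in rows for c in cols][:n]
        return cls(shape=shape, centers=centers, radius_px=radius_px, **kw)


@dataclass
class VideoGroundTruth:
    """Masks and neuropil components planted in a rendered video."""

    masks: np.ndarray                # (n, H, W) bool soma footprints
    label_image: np.ndarray          # (H, W) int, 0 = background
    neuropil_spatial: np.ndarray     # (H, W)
    neuropil_temporal: np.ndarray    # (T,)
    layout: SomaLayout


def _disk_masks(layout: SomaLayout) -> np.ndarray:
    H, W = layout.shape
    rr, cc = np.mgrid[0:H, 0:W]
    masks = np.empty((len(layout.centers), H, W), dtype=bool)
    for i, (r, c) in enumerate(layout.centers):
        masks[i] = (rr - r) ** 2 + (cc - c) ** 2 <= layout.radius_px**2
    return masks


def render_video(
    dff: DffMatrix,
    layout: SomaLayout,
    neuropil_gain: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, VideoGroundTruth]:
    """Render a uint16 fluorescence video from planted dF/F traces.

    Pixel model: ``offset + soma * f0 * (baseline + dF/F) + neuropil_gain *
    spatial(x,y) * temporal(t) + noise``, clipped to [0, 65535].  The
    neuropil field is a smooth positive spatial profile modulated by a
    shared slow temporal trace (mean 1), so a ring-mean trace tracks the
    planted temporal component.

    Raises
    ------
    ValueError when the layout has fewer centers than neurons or any two
    soma footprints overlap (planted truth must stay identifiable).
    """
    if len(layout.centers) != dff.n_neurons:
        raise ValueError(
            f"layout has {len(layout.centers)} centers for {dff.n_neurons} neurons"
        )
    masks = _disk_masks(layout)
    if masks.any(axis=0).sum() != masks.sum():
        raise ValueError("soma footprints overlap")
    H, W = layout.shape
    T = dff.n_frames
    rng = np.random.default_rng(seed)

    label = np.zeros((H, W), dtype=np.int32)
    for i, m in enumerate(masks):
        label[m] = i + 1

    spatial = gaussian_filter(rng.gamma(2.0, 1.0, size=(H, W)), sigma=H / 10.0)
    spatial /= spatial.mean()
    temporal = gaussian_filter1d(rng.normal(0.0, 1.0, size=T), sigma=20.0)
    sd = temporal.std()
    temporal = 1.0 + 0.3 * (temporal / sd if sd > 0 else temporal)
    temporal = np.clip(temporal, 0.0, None)

    video = np.empty((T, H * W), dtype=np.float32)
    video[:] = layout.offset
    video += neuropil_gain * np.outer(temporal, spatial.ravel()).astype(np.float32)
    soma_pix = np.flatnonzero(label.ravel())
    owner = label.ravel()[soma_pix] - 1
    video[:, soma_pix] += (
        layout.soma_f0 * (layout.soma_baseline + dff.C[owner, :].T)
    ).astype(np.float32)
    if noise_sd > 0:
        video += rng.normal(0.0, noise_sd, size=video.shape).astype(np.float32)
    out = np.clip(video, 0.0, 65535.0).astype(np.uint16).reshape(T, H, W)
    truth = VideoGroundTruth(
        masks=masks,
        label_image=label,
        neuropil_spatial=spatial,
        neuropil_temporal=temporal,
        layout=layout,
    )
    return out, truth
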