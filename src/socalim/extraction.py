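"""Soma identification, trace extraction and annular-ring-subtraction dF/F.

The extraction chain is:

1. ``segment_somata`` — temporal-activity feature image, blob detection plus
   adaptive thresholding, SNR/area filtering;
2. ``make_ring`` / ``extract_traces`` — soma-mean, ring-mean and background
   traces;
3. ``ars_dff`` — background subtraction, neuropil (ring) subtraction at
   contamination degree alpha, normalization by the mean corrected trace.

Input video is assumed motion-registered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import blob_log
from skimage.filters import threshold_local

from .core import DffMatrix

#: Field of view 420 um across a 512 px frame.
DEFAULT_PIXEL_SIZE_UM = 420.0 / 512.0

DEFAULT_RING_GAP_PX = 2
DEFAULT_RING_WIDTH_PX = 4

MATCH_MAX_CENTROID_UM = 3.0
MATCH_MIN_OVERLAP = 0.75


@dataclass
class Roi:
    """One soma: footprint mask, its annulus, and the centroid."""

    mask: np.ndarray                      # (H, W) bool
    centroid_px: tuple[float, float]      # (row, col)
    ring: np.ndarray | None = None        # (H, W) bool

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class RoiSet:
    rois: list[Roi]
    shape: tuple[int, int]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __len__(self) -> int:
        return len(self.rois)

    def centroids_um(self) -> np.ndarray:
        return np.array([r.centroid_px for r in self.rois]) * self.pixel_size_um

    def any_soma_mask(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for r in self.rois:
            out |= r.mask
        return out

    def label_image(self) -> np.ndarray:
        lab = np.zeros(self.shape, dtype=np.int32)
        for i, r in enumerate(self.rois):
            lab[r.mask] = i + 1
        return lab


@dataclass
class RawTraceBundle:
    """Per-neuron soma and ring traces plus the background baseline.

    ``f_raw`` and ``f_ring`` are (n, T); ``f_b`` is (T,) (per-frame
    background) or a scalar-broadcastable (1,) array (global mode).
    """

    f_raw: np.ndarray
    f_ring: np.ndarray
    f_b: np.ndarray

    def __post_init__(self) -> None:
        self.f_raw = np.atleast_2d(np.asarray(self.f_raw, dtype=float))
        self.f_ring = np.atleast_2d(np.asarray(self.f_ring, dtype=float))
        self.f_b = np.asarray(self.f_b, dtype=float)
        if self.f_raw.shape != self.f_ring.shape:
            raise ValueError("f_raw and f_ring shapes differ")


def background_trace(video: np.ndarray, mode: str = "per_frame") -> np.ndarray:
    """Background baseline from the stack minima.

    ``per_frame`` (default): one value per frame, the minimum pixel of that
    frame.  ``global``: a single scalar, the minimum over the whole stack,
    broadcast to all frames.
    """
    video = np.asarray(video)
    if video.size == 0:
        raise ValueError("empty video")
    if mode == "per_frame":
        return video.reshape(video.shape[0], -1).min(axis=1).astype(float)
    if mode == "global":
        return np.full(video.shape[0], float(video.min()))
    raise ValueError(f"unknown background mode {mode!r}")


def make_ring(
    soma: np.ndarray,
    gap_px: int = DEFAULT_RING_GAP_PX,
    width_px: int = DEFAULT_RING_WIDTH_PX,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Annulus around a soma: pixels at boundary distance in (gap, gap+width].

    ``exclude`` is the union of all soma footprints; any pixel of any soma is
    never part of a ring.  Raises when the ring is empty after exclusions.
    """
    if gap_px < 1 or width_px < 1:
        raise ValueError("gap_px and width_px must be >= 1")
    soma = np.asarray(soma, dtype=bool)
    dist = ndimage.distance_transform_edt(~soma)
    ring = (dist > gap_px) & (dist <= gap_px + width_px)
    if exclude is not None:
        ring &= ~np.asarray(exclude, dtype=bool)
    else:
        ring &= ~soma
    if not ring.any():
        raise ValueError("ring empty after exclusions")
    return ring


def attach_rings(
    rois: RoiSet,
    gap_px: int = DEFAULT_RING_GAP_PX,
    width_px: int = DEFAULT_RING_WIDTH_PX,
) -> RoiSet:
    """Compute and attach an annulus for every ROI (in place); returns rois."""
    all_somata = rois.any_soma_mask()
    for i, r in enumerate(rois.rois):
        try:
            r.ring = make_ring(r.mask, gap_px, width_px, exclude=all_somata)
        except ValueError as exc:
            raise ValueError(f"neuron {i}: {exc}") from exc
    return rois


def extract_traces(
    video: np.ndarray,
    rois: RoiSet,
    background_mode: str = "per_frame",
) -> RawTraceBundle:
    """Mean soma / ring intensity per frame plus the background trace."""
    video = np.asarray(video, dtype=float)
    T = video.shape[0]
    flat = video.reshape(T, -1)
    f_raw = np.empty((len(rois), T))
    f_ring = np.empty((len(rois), T))
    for i, r in enumerate(rois.rois):
        if r.ring is None:
            raise ValueError(f"neuron {i}: ring not attached (call attach_rings)")
        f_raw[i] = flat[:, r.mask.ravel()].mean(axis=1)
        f_ring[i] = flat[:, r.ring.ravel()].mean(axis=1)
    f_b = background_trace(video, background_mode)
    return RawTraceBundle(f_raw=f_raw, f_ring=f_ring, f_b=f_b)


def ars_dff(
    bundle: RawTraceBundle,
    alpha: float = 1.0,
    t: np.ndarray | None = None,
    rate: float = 9.76,
    convention: str = "ratio",
) -> DffMatrix:
    """Annular-ring-subtraction dF/F.

    F_ROI = F_raw - F_b;  F_con = F_ring - F_b;  F_sig = F_ROI - alpha*F_con;
    F_0 = mean(F_ROI);  dF/F = F_sig / F_0.

    ``convention="ratio"`` (default) is the formula as stated, whose baseline
    sits near 1.  ``convention="relative"`` returns the conventional
    (F_sig - F_0)/F_0, baseline near 0.  Raises when any neuron has
    F_0 = 0, naming the neuron.
    """
    f_roi = bundle.f_raw - bundle.f_b
    f_con = bundle.f_ring - bundle.f_b
    f_sig = f_roi - alpha * f_con
    f0 = f_roi.mean(axis=1)
    bad = np.flatnonzero(f0 == 0)
    if bad.size:
        raise ValueError(f"F_0 is zero for neuron(s) {bad.tolist()}")
    if convention == "ratio":
        C = f_sig / f0[:, None]
    elif convention == "relative":
        C = (f_sig - f0[:, None]) / f0[:, None]
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if t is None:
        t = np.arange(C.shape[1]) / rate
    return DffMatrix(C=C, t=t, rate=rate)


# ---------------------------------------------------------------------------
# segmentation


def activity_image(video: np.ndarray) -> np.ndarray:
    """Per-pixel temporal activity score: mean squared positive z-score.

    Amplifies pixels with transient activity over static background.
    """
    video = np.asarray(video, dtype=np.float32)
    mu = video.mean(axis=0)
    sd = video.std(axis=0)
    sd = np.maximum(sd, 1e-6)
    z = (video - mu) / sd
    np.maximum(z, 0.0, out=z)
    return np.mean(z * z, axis=0)


def _trace_snr(trace: np.ndarray) -> float:
    """Peak-over-noise of a raw trace, robust to slow transients."""
    med = np.median(trace)
    mad = np.median(np.abs(trace - med))
    noise = 1.4826 * mad
    if noise <= 0:
        noise = max(trace.std(), 1e-9)
    return float((trace.max() - med) / noise)


def segment_somata(
    video: np.ndarray,
    snr_min: float = 5.0,
    area_range_px: tuple[int, int] = (10, 400),
    soma_sigma_px: float = 3.0,
    block_size: int = 51,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> RoiSet:
    """Detect blob-like active somata in a registered video.

    Candidate regions come from adaptive (local) thresholding of the
    activity image, retained when they contain a Laplacian-of-Gaussian blob
    center, have area within ``area_range_px`` and mean-trace SNR at least
    ``snr_min``.  ROIs are ordered row-major by centroid; the empty set is a
    valid result.
    """
    video = np.asarray(video)
    feat = activity_image(video)
    span = float(feat.max() - feat.min())
    if span <= 0:
        return RoiSet(rois=[], shape=feat.shape, pixel_size_um=pixel_size_um)
    norm = (feat - feat.min()) / span

    blobs = blob_log(norm, min_sigma=soma_sigma_px * 0.5,
                     max_sigma=soma_sigma_px * 2.0, num_sigma=5, threshold=0.1)
    local = threshold_local(norm, block_size=block_size, method="gaussian")
    binary = norm > np.maximum(local, norm.mean() + 2.0 * norm.std())
    labels, _ = ndimage.label(binary)

    keep: dict[int, tuple[float, float]] = {}
    for r, c, _s in blobs:
        lab = labels[int(round(r)), int(round(c))]
        if lab > 0:
            keep.setdefault(lab, (r, c))

    T = video.shape[0]
    flat = video.reshape(T, -1).astype(np.float32)
    rois: list[Roi] = []
    for lab in keep:
        mask = labels == lab
        area = int(mask.sum())
        if not (area_range_px[0] <= area <= area_range_px[1]):
            continue
        trace = flat[:, mask.ravel()].mean(axis=1)
        if _trace_snr(trace) < snr_min:
            continue
        rr, cc = np.nonzero(mask)
        rois.append(Roi(mask=mask, centroid_px=(float(rr.mean()), float(cc.mean()))))
    rois.sort(key=lambda r: r.centroid_px)
    return RoiSet(rois=rois, shape=feat.shape, pixel_size_um=pixel_size_um)


# ---------------------------------------------------------------------------
# cross-day matching


def _shift_mask(mask: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.zeros_like(mask)
    H, W = mask.shape
    ys, xs = np.nonzero(mask)
    ys = ys + dy
    xs = xs + dx
    ok = (ys >= 0) & (ys < H) & (xs >= 0) & (xs < W)
    out[ys[ok], xs[ok]] = True
    return out


def match_across_days(
    rois_a: RoiSet,
    rois_b: RoiSet,
    displacement_px: tuple[float, float] = (0.0, 0.0),
    max_centroid_um: float = MATCH_MAX_CENTROID_UM,
    min_overlap: float = MATCH_MIN_OVERLAP,
) -> list[tuple[int, int]]:
    """One-to-one cross-session neuron matching.

    ``displacement_px`` (dy, dx) maps B's coordinates into A's frame.  A pair
    matches when the displaced centroid distance is below ``max_centroid_um``
    AND the Jaccard overlap of the (displaced) footprints exceeds
    ``min_overlap``.  Pairs are resolved greedily, smallest centroid distance
    first.
    """
    dy, dx = displacement_px
    px = rois_a.pixel_size_um
    ca = np.array([r.centroid_px for r in rois_a.rois]) if len(rois_a) else np.empty((0, 2))
    cb = np.array([r.centroid_px for r in rois_b.rois]) if len(rois_b) else np.empty((0, 2))
    if len(rois_a) == 0 or len(rois_b) == 0:
        return []
    cb = cb + np.array([dy, dx])
    idy, idx = int(round(dy)), int(round(dx))

    candidates = []
    for i in range(len(rois_a)):
        for j in range(len(rois_b)):
            d_um = float(np.hypot(*(ca[i] - cb[j]))) * px
            if d_um >= max_centroid_um:
                continue
            mb = _shift_mask(rois_b.rois[j].mask, idy, idx)
            ma = rois_a.rois[i].mask
            inter = np.logical_and(ma, mb).sum()
            union = np.logical_or(ma, mb).sum()
            if union == 0:
                continue
            jacc = inter / union
            if jacc > min_overlap:
                candidates.append((d_um, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _d, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    return pairs
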