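"""Scored quantities: angle counts, interlock geometry, openings, tremor.

Angle counting follows the velocity premise of drawing kinematics: pen speed
rises along each edge and falls to (near) zero at each change of direction,
so a figure's angle count equals its velocity peak count unless the figure
was already identified as a pentagon by segmentation match percentage.
Openings are found from the dispersion of k-means clusters of zero-velocity
samples: a closed corner is a tight dwell blob, while a contour gap splits a
corner into two dwell blobs whose merged cluster is wide.  Tremor is the
count of pen-up immediately followed by pen-down events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from sklearn.cluster import KMeans

from .config import PeakParams, RunConfig
from .sensor_io import FigureSplit, SensorTrace, VelocitySeries, figure_means

RATIO_SENTINEL = float("inf")  # |dx/dy| when dy = 0 and dx != 0


@dataclass
class FeatureSet:
    """Every quantity entering the score assignment."""

    NA1: int
    NA2: int
    Np1: int
    Np2: int
    pf1: float
    pf2: float
    pL: float
    dL_cm: float
    ratio: float
    O1: int               # 1 = opening present in figure 1
    O2: int
    tremor_count1: int
    tremor_count2: int
    T1: int               # 1 = tremor present in figure 1
    T2: int
    degenerate: list[str] = field(default_factory=list)

    def to_record(self) -> dict[str, float]:
        rec = {
            k: getattr(self, k)
            for k in (
                "NA1", "NA2", "Np1", "Np2", "pf1", "pf2", "pL",
                "dL_cm", "ratio", "O1", "O2",
                "tremor_count1", "tremor_count2", "T1", "T2",
            )
        }
        return {k: float(v) for k, v in rec.items()}


@dataclass
class ClusterResult:
    """k-means clustering of zero-velocity samples of one figure."""

    labels: np.ndarray
    centers_px: np.ndarray
    dispersions_cm: np.ndarray  # mean member-to-center distance per cluster
    k_used: int
    degenerate: bool = False


def clean_velocity(v: np.ndarray, tol: float) -> np.ndarray:
    """Zero out isolated single-sample speed spikes.

    A sample whose speed exceeds the zero tolerance and is more than eight
    times both neighbours is a positional discontinuity (e.g. the restart
    after an undrawn contour gap), not pen motion a 50 Hz stylus could
    record; the pen is effectively at rest there.
    """
    vv = np.asarray(v, dtype=float).copy()
    if len(vv) < 3:
        return vv
    spikes = np.zeros(len(vv), dtype=bool)
    spikes[1:-1] = (
        (vv[1:-1] > tol) & (vv[1:-1] > 8 * vv[:-2]) & (vv[1:-1] > 8 * vv[2:])
    )
    vv[spikes] = 0.0
    return vv


def detect_velocity_peaks(v: np.ndarray | VelocitySeries, params: PeakParams, dt: float) -> int:
    """Count velocity peaks separated by near-zero troughs.

    The raw speed series is first cleaned of isolated single-sample spikes
    (speed above the zero tolerance with both neighbours below it), which a
    physical pen cannot produce at 50 Hz, then smoothed with a short moving
    average.  Local maxima of the smoothed series at or above
    ``min_height_frac`` of the segment maximum are grouped: maxima with no
    zero-speed sample between them count as one peak.
    """
    v = np.asarray(v.v if isinstance(v, VelocitySeries) else v, dtype=float)
    if len(v) < 3:
        return 0
    tol = params.zero_vel_px_per_sample / dt
    vv = clean_velocity(v, tol)
    w = max(1, int(params.smooth_window))
    vp = np.pad(vv, (w // 2, w - 1 - w // 2), mode="edge")
    vs = np.convolve(vp, np.ones(w) / w, mode="valid")
    vmax = float(vs.max())
    if vmax < tol:
        return 0
    # a dip to a few percent of the stroke's top speed is a stop, even when
    # sensor jitter keeps the raw samples just above the absolute zero floor
    zero = vv < max(tol, params.trough_frac * vmax)
    pk, _ = find_peaks(vs, height=params.min_height_frac * vmax)
    if len(pk) == 0:
        return 0
    count = 1
    for a, b in zip(pk[:-1], pk[1:]):
        if zero[a + 1 : b].any():
            count += 1
    return count


def count_angles(pf: float, peak_count: int, pth1: float) -> int:
    """Angle count: 5 when the figure matches the pentagon model, else the
    velocity peak count."""
    return 5 if pf >= pth1 else int(peak_count)


def interlock_distance(
    trace: SensorTrace,
    n1: int,
    n2: int,
    cm_per_px: float,
    left_tip_is_n1: bool = True,
) -> float:
    """Signed tip-to-tip distance in cm: negative when the figures overlap.

    Overlap means the left figure's rightmost sample lies to the right of the
    right figure's leftmost sample; ``left_tip_is_n1`` says which endpoint
    belongs to the left-positioned figure (figure 1 in the standard
    left-first drawing order).
    """
    dx = trace.x[n1] - trace.x[n2]
    d = float(np.hypot(dx, trace.y[n1] - trace.y[n2])) * cm_per_px
    x_left = trace.x[n1] if left_tip_is_n1 else trace.x[n2]
    x_right = trace.x[n2] if left_tip_is_n1 else trace.x[n1]
    return -d if x_left > x_right else d


def aspect_ratio(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """|dx/dy| of the two interlock endpoints; a rhombus-shaped interlock has
    a wide, flat tip pair (large ratio).  dy = 0 yields an infinite sentinel
    (compares >= any finite threshold) unless dx = 0 too."""
    dx = abs(p1[0] - p2[0])
    dy = abs(p1[1] - p2[1])
    if dy == 0:
        return 0.0 if dx == 0 else RATIO_SENTINEL
    return dx / dy


def cluster_dispersions(
    points_px: np.ndarray,
    k: int,
    seed: int,
    cm_per_px: float,
) -> ClusterResult:
    """k-means of zero-velocity sample positions; dispersion per cluster.

    With fewer distinct points than k the cluster count is reduced and the
    result flagged degenerate.
    """
    pts = np.asarray(points_px, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return ClusterResult(
            labels=np.empty(0, dtype=int),
            centers_px=np.empty((0, 2)),
            dispersions_cm=np.empty(0),
            k_used=0,
            degenerate=True,
        )
    n_distinct = len(np.unique(pts, axis=0))
    k_used = min(k, n_distinct)
    degenerate = k_used < k
    km = KMeans(n_clusters=k_used, n_init=10, random_state=seed).fit(pts)
    disp = np.array(
        [
            np.mean(np.linalg.norm(pts[km.labels_ == j] - km.cluster_centers_[j], axis=1))
            for j in range(k_used)
        ]
    )
    return ClusterResult(
        labels=km.labels_,
        centers_px=km.cluster_centers_,
        dispersions_cm=disp * cm_per_px,
        k_used=k_used,
        degenerate=degenerate,
    )


def opening_flag(dispersions_cm: np.ndarray, delta_th_cm: float) -> int:
    """1 iff any cluster dispersion exceeds the closed-corner threshold."""
    d = np.asarray(dispersions_cm, dtype=float)
    return int(bool((d > delta_th_cm).any()))


def count_updown_transitions(e: np.ndarray) -> int:
    """Number of pen-up samples immediately followed by pen-down samples."""
    e = np.asarray(e)
    if len(e) < 2:
        return 0
    return int(np.sum((e[:-1] == 1) & (e[1:] == -1)))


def tremor_flag(count: int, eth: int) -> int:
    """1 iff the up->down transition count reaches the tremor threshold."""
    return int(count >= eth)


def zero_velocity_points(
    trace: SensorTrace,
    v: np.ndarray,
    lo: int,
    hi: int,
    params: PeakParams,
    dt: float,
) -> np.ndarray:
    """Positions of touching samples with near-zero speed in [lo, hi]."""
    tol = params.zero_vel_px_per_sample / dt
    vv = clean_velocity(v, tol)
    idx = np.arange(lo, hi + 1)
    sel = (vv[idx] < tol) & (trace.e[idx] != 1)
    return np.column_stack([trace.x[idx[sel]], trace.y[idx[sel]]])


def extract_features(
    trace: SensorTrace,
    velocity: VelocitySeries,
    split: FigureSplit,
    pf1: float,
    pf2: float,
    pL: float,
    cfg: RunConfig,
) -> FeatureSet:
    """Compute the full feature set for a split trace with known percentages."""
    v = velocity.v
    dt = cfg.sample_dt
    th = cfg.thresholds

    v1 = v[: split.nf1 + 1]
    v2 = v[split.nf2 :].copy()
    if len(v2):
        v2[0] = 0.0  # the hop from the inter-figure pause is not a stroke
    np1 = detect_velocity_peaks(v1, cfg.peaks, dt)
    np2 = detect_velocity_peaks(v2, cfg.peaks, dt)
    na1 = count_angles(pf1, np1, th.pth1)
    na2 = count_angles(pf2, np2, th.pth1)

    m1, m2 = figure_means(trace, split)
    dl = interlock_distance(trace, split.n1, split.n2, cfg.cm_per_px, left_tip_is_n1=m1 <= m2)
    ratio = aspect_ratio(
        (trace.x[split.n1], trace.y[split.n1]),
        (trace.x[split.n2], trace.y[split.n2]),
    )

    degenerate: list[str] = []
    flags = []
    for name, (lo, hi), k in (
        ("figure1", (0, split.nf1), na1),
        ("figure2", (split.nf2, len(trace) - 1), na2),
    ):
        pts = zero_velocity_points(trace, v, lo, hi, cfg.peaks, dt)
        res = cluster_dispersions(pts, max(k, 1), cfg.seed, cfg.cm_per_px)
        if res.degenerate:
            degenerate.append(name)
        flags.append(opening_flag(res.dispersions_cm, th.delta_cm))
    o1, o2 = flags

    c1 = count_updown_transitions(trace.e[: split.nf1 + 1])
    c2 = count_updown_transitions(trace.e[split.nf2 :])

    return FeatureSet(
        NA1=na1,
        NA2=na2,
        Np1=np1,
        Np2=np2,
        pf1=pf1,
        pf2=pf2,
        pL=pL,
        dL_cm=dl,
        ratio=ratio,
        O1=o1,
        O2=o2,
        tremor_count1=c1,
        tremor_count2=c2,
        T1=tremor_flag(c1, th.eth),
        T2=tremor_flag(c2, th.eth),
        degenerate=degenerate,
    )
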