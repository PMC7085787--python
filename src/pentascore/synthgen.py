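"""Synthetic pen-trace generator for interlocking-polygon drawings.

Emulates the phenomena the scorer measures, with ground truth attached:

* two regular polygons drawn sequentially, separated by a long pen-up pause;
* per-edge triangular speed profile — the pen accelerates along an edge and
  comes to rest at every corner, so a perfect n-gon produces exactly n
  velocity peaks and n tight clusters of zero-velocity samples;
* an interlock whose overlap region is (or is not) rhombus-shaped, or
  figures merely touching, or separated by a configurable gap;
* contour openings: a short arc on each side of one corner is left undrawn,
  so the corner's zero-velocity cluster splits into two dwell blobs whose
  dispersion exceeds the closed-corner regime;
* tremor: isolated pen-up/pen-down event pairs injected mid-edge.

The first figure ends at its interlock tip with a small outward closure
overshoot and the second figure starts at its tip with a small outward
pre-stroke, which is what pins the arg-extremal x samples (the interlock
endpoints) to the tips and keeps the interlock sub-trace confined to the
overlap region, as in careful human drawings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon

from .config import RunConfig, Thresholds
from .sensor_io import SensorTrace

INTERLOCK_MODES = ("rhombus", "non_rhombus", "touching", "gap")

# layout defaults (centimetres; converted via RunConfig.cm_per_px)
_R_DEFAULT_CM = 1.52          # circumradius of each figure
_DEPTH_CM = {"rhombus": 0.9, "non_rhombus": 0.6}   # tip overlap depth
_TIP_DY_CM = {"rhombus": 0.15, "non_rhombus": 0.7}  # vertical tip offset
# tip separation in "touching" mode: the 2 px closure overshoot on each side
# leaves a measured pen-to-pen gap of about one pixel (within spatial accuracy)
_TOUCH_SEP_CM = 0.02
_OVERSHOOT_PX = 2.0           # closure overshoot / pre-stroke length
_OPENING_TRIM_CM = 0.25       # undrawn arc length on each side of the corner
_MARGIN_PX = 30
_GAP_RUN_SAMPLES = 25         # pen-up pause between the figures


class SpecError(ValueError):
    """The drawing specification is internally inconsistent."""


@dataclass
class DrawingSpec:
    """Parameters of one synthetic drawing."""

    vertices_fig1: int = 5
    vertices_fig2: int = 5
    interlock_mode: str = "rhombus"
    gap_cm: float = 0.0
    opening_fig1: bool = False
    opening_fig2: bool = False
    tremor_fig1: int = 0
    tremor_fig2: int = 0
    corner_dwell_samples: int = 3
    samples_per_edge: int = 22
    noise_px: float = 0.3
    right_first: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.vertices_fig1 < 3 or self.vertices_fig2 < 3:
            raise SpecError("figures need at least 3 vertices")
        if self.gap_cm < 0:
            raise SpecError("gap_cm must be non-negative")
        if self.corner_dwell_samples < 1:
            raise SpecError("corner_dwell_samples must be >= 1")
        if self.interlock_mode not in INTERLOCK_MODES:
            raise SpecError(f"unknown interlock_mode {self.interlock_mode!r}")
        if self.interlock_mode != "gap" and self.gap_cm > 0:
            raise SpecError(f"{self.interlock_mode} interlock is incompatible with gap_cm > 0")
        if self.interlock_mode == "gap" and self.gap_cm <= 0:
            raise SpecError("gap mode requires gap_cm > 0")
        if self.tremor_fig1 < 0 or self.tremor_fig2 < 0:
            raise SpecError("tremor counts must be non-negative")


@dataclass
class GroundTruth:
    """Construction-time truth for a synthetic drawing."""

    sub_scores: dict[str, int]
    total: int
    na1: int                      # true angle count entering the score rule
    na2: int
    is_pentagon1: bool
    is_pentagon2: bool
    vertices_fig1: np.ndarray     # polygon vertices, canvas pixels
    vertices_fig2: np.ndarray
    interlock_polygon: np.ndarray | None  # true overlap region, canvas pixels
    opening_fig1: bool
    opening_fig2: bool
    tremor_count1: int
    tremor_count2: int
    dl_cm: float                  # signed tip distance by construction
    spec: DrawingSpec | None = None

    def to_json(self) -> str:
        d = {
            "sub_scores": self.sub_scores,
            "total": self.total,
            "na1": self.na1,
            "na2": self.na2,
            "is_pentagon1": self.is_pentagon1,
            "is_pentagon2": self.is_pentagon2,
            "vertices_fig1": np.asarray(self.vertices_fig1).tolist(),
            "vertices_fig2": np.asarray(self.vertices_fig2).tolist(),
            "interlock_polygon": (
                None if self.interlock_polygon is None
                else np.asarray(self.interlock_polygon).tolist()
            ),
            "opening_fig1": self.opening_fig1,
            "opening_fig2": self.opening_fig2,
            "tremor_count1": self.tremor_count1,
            "tremor_count2": self.tremor_count2,
            "dl_cm": self.dl_cm,
            "spec": None if self.spec is None else asdict(self.spec),
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "GroundTruth":
        d = json.loads(s)
        spec = d.pop("spec")
        return cls(
            sub_scores={k: int(v) for k, v in d["sub_scores"].items()},
            total=int(d["total"]),
            na1=int(d["na1"]),
            na2=int(d["na2"]),
            is_pentagon1=bool(d["is_pentagon1"]),
            is_pentagon2=bool(d["is_pentagon2"]),
            vertices_fig1=np.asarray(d["vertices_fig1"], float),
            vertices_fig2=np.asarray(d["vertices_fig2"], float),
            interlock_polygon=(
                None if d["interlock_polygon"] is None
                else np.asarray(d["interlock_polygon"], float)
            ),
            opening_fig1=bool(d["opening_fig1"]),
            opening_fig2=bool(d["opening_fig2"]),
            tremor_count1=int(d["tremor_count1"]),
            tremor_count2=int(d["tremor_count2"]),
            dl_cm=float(d["dl_cm"]),
            spec=None if spec is None else DrawingSpec(**spec),
        )


# ---------------------------------------------------------------- geometry


def _polygon_vertices(cx: float, cy: float, r: float, n: int, tip_angle_deg: float) -> np.ndarray:
    """Regular n-gon with one vertex (the interlock tip) at ``tip_angle_deg``.

    Screen coordinates: y grows downward, so the mathematical angle is
    mirrored; traversal order is the listed order.
    """
    ang = np.deg2rad(tip_angle_deg + 360.0 * np.arange(n) / n)
    return np.column_stack([cx + r * np.cos(ang), cy - r * np.sin(ang)])


def _tip_wedge_deg(n: int) -> float:
    """Half the interior angle at a regular n-gon vertex."""
    return 90.0 - 180.0 / n


def _layout(spec: DrawingSpec, cfg: RunConfig) -> dict:
    px = 1.0 / cfg.cm_per_px
    if spec.interlock_mode in ("rhombus", "non_rhombus"):
        sep = -_DEPTH_CM[spec.interlock_mode] * px
        if spec.interlock_mode == "rhombus":
            dy = _TIP_DY_CM["rhombus"] * px
        else:
            # tips must sit inside the opposite figure (tip distance ratio
            # |dx/dy| >= cot of the narrower corner wedge) while the ratio
            # stays below the rhombus threshold
            w_min = min(_tip_wedge_deg(spec.vertices_fig1), _tip_wedge_deg(spec.vertices_fig2))
            r_target = max(0.85, 1.02 / np.tan(np.deg2rad(w_min)))
            if r_target >= 0.93 * cfg.thresholds.rth:
                raise SpecError(
                    "non-rhombus interlock is infeasible for these vertex counts"
                )
            dy = -sep / r_target
    elif spec.interlock_mode == "touching":
        sep = _TOUCH_SEP_CM * px
        dy = 0.0
    else:
        sep = spec.gap_cm * px
        dy = 0.0
    r = min(_R_DEFAULT_CM * px, (cfg.canvas_w - 2 * _MARGIN_PX - max(sep, 0.0)) / 4.0)
    if r < 40:
        raise SpecError("canvas too small for the requested layout")
    cx1 = _MARGIN_PX + r
    tip1x = cx1 + r
    tip2x = tip1x + sep
    cx2 = tip2x + r
    cy1 = cfg.canvas_h / 2.0 - dy / 2.0
    cy2 = cy1 + dy
    left = _polygon_vertices(cx1, cy1, r, spec.vertices_fig1 if not spec.right_first else spec.vertices_fig2, 0.0)
    right = _polygon_vertices(cx2, cy2, r, spec.vertices_fig2 if not spec.right_first else spec.vertices_fig1, 180.0)
    return {"left": left, "right": right, "r": r,
            "tip_left": np.array([tip1x, cy1]), "tip_right": np.array([tip2x, cy2])}


def _interlock_polygon(left: np.ndarray, right: np.ndarray) -> np.ndarray | None:
    inter = Polygon(left).intersection(Polygon(right))
    if inter.is_empty or inter.area <= 0 or inter.geom_type != "Polygon":
        return None
    return np.asarray(inter.exterior.coords[:-1], float)


# ---------------------------------------------------------------- kinematics


def _ramp_points(p: np.ndarray, q: np.ndarray, n: int) -> np.ndarray:
    """n points from just after p to exactly q, triangular speed profile."""
    k = np.arange(1, n + 1, dtype=float)
    w = np.minimum(k, n + 1 - k)          # triangular step weights
    f = np.cumsum(w) / np.sum(w)
    return p[None, :] + (q - p)[None, :] * f[:, None]


def _figure_samples(
    vertices: np.ndarray,
    *,
    role_first: bool,
    opening: bool,
    opening_vertex: int,
    trim_px: float,
    dwell: int,
    n_per_edge: int,
    edge_ref_px: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample path of one figure.

    Returns (points, mid_edge_mask); the mask marks samples eligible for
    tremor injection (interior of long ramps).  ``role_first`` figures end at
    the tip (vertex 0) with an outward overshoot; second figures begin with
    an outward pre-stroke into the tip.
    """
    m = len(vertices)
    tip = vertices[0]
    outward = tip - vertices.mean(axis=0)
    outward = outward / np.linalg.norm(outward)

    # stop list: (position, dwell_count, ramp_from_previous)
    stops: list[tuple[np.ndarray, int, bool]] = []
    if not role_first:
        stops.append((tip + outward * _OVERSHOOT_PX, dwell, True))
    order = list(range(m)) + [0]
    for k, vi in enumerate(order):
        v = vertices[vi]
        if opening and k > 0 and order[k] == opening_vertex % m and vi != 0:
            prev = vertices[order[k - 1]]
            nxt = vertices[order[k + 1]]
            e_in = (v - prev) / np.linalg.norm(v - prev)
            e_out = (nxt - v) / np.linalg.norm(nxt - v)
            stops.append((v - e_in * trim_px, dwell, True))    # break point
            stops.append((v + e_out * trim_px, dwell, False))  # restart (gap)
        else:
            stops.append((v, dwell, True))
    if role_first:
        stops.append((tip + outward * _OVERSHOOT_PX, dwell, True))

    pts: list[np.ndarray] = []
    eligible: list[bool] = []
    pos = stops[0][0]
    pts.extend([pos] * stops[0][1])
    eligible.extend([False] * stops[0][1])
    for target, dw, ramp in stops[1:]:
        if ramp:
            dist = np.linalg.norm(target - pos)
            n = max(2, int(round(n_per_edge * dist / edge_ref_px)))
            seg = _ramp_points(pos, target, n)
            pts.extend(seg)
            elig = [False] * n
            if n >= 8:
                for i in range(2, n - 2):
                    elig[i] = True
            eligible.extend(elig)
        # gap: no ramp samples; the pen path simply restarts at `target`
        pts.extend([target] * dw)
        eligible.extend([False] * dw)
        pos = target
    return np.asarray(pts), np.asarray(eligible, bool)


def _inject_tremors(e: np.ndarray, eligible: np.ndarray, count: int, rng: np.random.Generator) -> int:
    """Replace `count` eligible 0-event pairs by (up, down); returns injected."""
    cand = np.where(eligible[:-1] & eligible[1:])[0]
    rng.shuffle(cand)
    taken: list[int] = []
    for i in cand:
        if len(taken) == count:
            break
        if all(abs(i - j) >= 3 for j in taken):
            taken.append(i)
    for i in taken:
        e[i] = 1
        e[i + 1] = -1
    return len(taken)


# ---------------------------------------------------------------- truth


def _angle_subscore(na1: int, na2: int, pent1: bool, pent2: bool) -> int:
    if pent1 and pent2:
        return 4
    s = na1 + na2
    if s in (9, 11):
        return 3
    if s in (8, 12):
        return 2
    if 5 <= s <= 7:
        return 1
    return 0


def _intersection_subscore(mode: str, gap_cm: float) -> int:
    if mode == "rhombus":
        return 4
    if mode == "non_rhombus":
        return 3
    if mode == "touching":
        return 2
    return 1 if gap_cm < 1.0 else 0


def _ground_truth(spec: DrawingSpec, lay: dict, th: Thresholds, cfg: RunConfig) -> GroundTruth:
    first_is_left = not spec.right_first
    fig1_poly = lay["left"] if first_is_left else lay["right"]
    fig2_poly = lay["right"] if first_is_left else lay["left"]
    pent1 = spec.vertices_fig1 == 5
    pent2 = spec.vertices_fig2 == 5
    na1 = 5 if pent1 else spec.vertices_fig1
    na2 = 5 if pent2 else spec.vertices_fig2
    o1, o2 = int(spec.opening_fig1), int(spec.opening_fig2)
    t1 = int(spec.tremor_fig1 >= th.eth)
    t2 = int(spec.tremor_fig2 >= th.eth)
    tip_sep = lay["tip_right"] - lay["tip_left"]
    dl = float(np.hypot(*tip_sep)) * cfg.cm_per_px
    if spec.interlock_mode in ("rhombus", "non_rhombus"):
        dl = -dl
    sub = {
        "angles": _angle_subscore(na1, na2, pent1, pent2),
        "intersection": _intersection_subscore(spec.interlock_mode, spec.gap_cm),
        "closure": 2 - (o1 + o2),
        "tremor": int(t1 == 0 and t2 == 0),
    }
    inter = (
        _interlock_polygon(lay["left"], lay["right"])
        if spec.interlock_mode in ("rhombus", "non_rhombus")
        else None
    )
    if spec.interlock_mode in ("rhombus", "non_rhombus") and inter is None:
        raise SpecError("interlock requested but the figures do not overlap")
    return GroundTruth(
        sub_scores=sub,
        total=sum(sub.values()),
        na1=na1,
        na2=na2,
        is_pentagon1=pent1,
        is_pentagon2=pent2,
        vertices_fig1=fig1_poly,
        vertices_fig2=fig2_poly,
        interlock_polygon=inter,
        opening_fig1=spec.opening_fig1,
        opening_fig2=spec.opening_fig2,
        tremor_count1=spec.tremor_fig1,
        tremor_count2=spec.tremor_fig2,
        dl_cm=dl,
        spec=spec,
    )


# ---------------------------------------------------------------- generator


def generate_trace(spec: DrawingSpec, cfg: RunConfig | None = None) -> tuple[SensorTrace, GroundTruth]:
    """Generate one synthetic drawing trace with its ground truth.

    Deterministic given ``spec.seed`` and the configuration.
    """
    spec.validate()
    cfg = cfg or RunConfig()
    rng = np.random.default_rng(spec.seed)
    lay = _layout(spec, cfg)
    truth = _ground_truth(spec, lay, cfg.thresholds, cfg)

    trim_px = _OPENING_TRIM_CM / cfg.cm_per_px
    edge_ref = 2.0 * lay["r"] * np.sin(np.pi / 5)

    def build(vertices: np.ndarray, n_vert: int, opening: bool, role_first: bool):
        edge_len = 2.0 * lay["r"] * np.sin(np.pi / n_vert)
        trim = min(trim_px, 0.3 * edge_len)
        return _figure_samples(
            vertices,
            role_first=role_first,
            opening=opening,
            opening_vertex=2,
            trim_px=trim,
            dwell=spec.corner_dwell_samples,
            n_per_edge=spec.samples_per_edge,
            edge_ref_px=edge_ref,
        )

    pts1, elig1 = build(truth.vertices_fig1, spec.vertices_fig1, spec.opening_fig1, True)
    pts2, elig2 = build(truth.vertices_fig2, spec.vertices_fig2, spec.opening_fig2, False)

    e1 = np.zeros(len(pts1), dtype=int)
    e1[0] = -1
    e2 = np.zeros(len(pts2), dtype=int)
    e2[0] = -1
    inj1 = _inject_tremors(e1, elig1, spec.tremor_fig1, rng)
    inj2 = _inject_tremors(e2, elig2, spec.tremor_fig2, rng)
    if inj1 != spec.tremor_fig1 or inj2 != spec.tremor_fig2:
        raise SpecError("not enough mid-edge samples to inject the requested tremors")

    gap_pts = np.repeat(pts1[-1][None, :], _GAP_RUN_SAMPLES, axis=0)
    gap_e = np.ones(_GAP_RUN_SAMPLES, dtype=int)
    tail_pts = np.repeat(pts2[-1][None, :], 2, axis=0)
    tail_e = np.ones(2, dtype=int)

    pts = np.vstack([pts1, gap_pts, pts2, tail_pts])
    e = np.concatenate([e1, gap_e, e2, tail_e])
    if spec.noise_px > 0:
        pts = pts + rng.normal(0.0, spec.noise_px, size=pts.shape)
    pts[:, 0] = np.clip(pts[:, 0], 0, cfg.canvas_w - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, cfg.canvas_h - 1)
    t = np.arange(len(pts)) * cfg.sample_dt
    trace = SensorTrace(t, pts[:, 0], pts[:, 1], e)
    trace.validate(cfg.canvas_w, cfg.canvas_h)
    return trace, truth


# ---------------------------------------------------------------- datasets


@dataclass
class SynthItem:
    trace: SensorTrace
    image: np.ndarray          # 128x128 binary drawing
    mask_pentagons: np.ndarray  # union of true pentagon bands
    mask_interlock: np.ndarray  # true interlock region (dilated fill)
    truth: GroundTruth
    spec: DrawingSpec = field(repr=False, default=None)


def random_spec(rng: np.random.Generator, seed: int) -> DrawingSpec:
    """Draw one spec from the documented study distribution."""
    def n_vertices() -> int:
        return int(rng.choice([5, 4, 6], p=[0.6, 0.3, 0.1]))

    mode = str(rng.choice(INTERLOCK_MODES, p=[0.4, 0.2, 0.2, 0.2]))
    gap = 0.0
    if mode == "gap":
        gap = float(rng.uniform(0.2, 0.8) if rng.random() < 0.5 else rng.uniform(1.1, 1.9))

    def tremor() -> int:
        if rng.random() < 0.2:
            return int(rng.integers(5, 15))
        return int(rng.choice([0, 1, 2], p=[0.7, 0.2, 0.1]))

    return DrawingSpec(
        vertices_fig1=n_vertices(),
        vertices_fig2=n_vertices(),
        interlock_mode=mode,
        gap_cm=gap,
        opening_fig1=bool(rng.random() < 0.2),
        opening_fig2=bool(rng.random() < 0.2),
        tremor_fig1=tremor(),
        tremor_fig2=tremor(),
        right_first=bool(rng.random() < 0.1),
        seed=seed,
    )


def generate_dataset(
    n: int,
    seed: int,
    cfg: RunConfig | None = None,
    spec_factory=None,
) -> list[SynthItem]:
    """Generate ``n`` drawings with images, true masks and ground truth."""
    from . import segmentation  # local import to avoid a cycle at import time

    cfg = cfg or RunConfig()
    rng = np.random.default_rng(seed)
    items: list[SynthItem] = []
    for i in range(n):
        item_seed = int(rng.integers(0, 2**31 - 1))
        spec = (spec_factory or random_spec)(rng, item_seed)
        trace, truth = generate_trace(spec, cfg)
        image = segmentation.rasterize_trace(trace, cfg)
        masks = segmentation.oracle_segment(truth, cfg)
        mask5 = masks.mask_fig1 | masks.mask_fig2
        items.append(SynthItem(trace, image, mask5, masks.mask_interlock, truth, spec))
    return items


def write_dataset(items: list[SynthItem], outdir: str | Path) -> None:
    """Emit a dataset to disk: trace files, PNG images/masks, labels table."""
    from PIL import Image

    from .sensor_io import save_trace

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, item in enumerate(items):
        stem = f"item_{i:04d}"
        save_trace(item.trace, outdir / f"{stem}_trace.csv")
        for suffix, arr in (
            ("image", item.image),
            ("mask5", item.mask_pentagons),
            ("masklock", item.mask_interlock),
        ):
            Image.fromarray((np.asarray(arr) > 0).astype(np.uint8) * 255).save(
                outdir / f"{stem}_{suffix}.png"
            )
        (outdir / f"{stem}_truth.json").write_text(item.truth.to_json())
        rows.append(
            {
                "item": stem,
                **{f"score_{k}": v for k, v in item.truth.sub_scores.items()},
                "total": item.truth.total,
            }
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(outdir / "labels.tsv", sep="\t", index=False)
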