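"""Pen-trace I/O, validation, velocities, and figure/interlock splitting.

A trace is the primary sensor record of one drawing session: per 20 ms sample
a timestamp ``t`` (seconds), pen coordinates ``x``/``y`` (pixels, origin
top-left, y down), and a touch event ``e`` in {-1, 0, 1} (-1 pen-down onset,
0 move while touching, 1 pen-up).  The file dialect is delimited text with a
header row ``t_sec, x_px, y_px, event``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

TRACE_COLUMNS = ("t_sec", "x_px", "y_px", "event")
VALID_EVENTS = (-1, 0, 1)


class TraceValidationError(ValueError):
    """A trace violates the sensor-data contract; message names the row."""


class SingleFigureError(ValueError):
    """The trace contains no interior pen-up run: only one figure was drawn."""


@dataclass
class SensorTrace:
    """Primary sensor data of one drawing."""

    t: np.ndarray  # seconds, strictly increasing after dedup
    x: np.ndarray  # pixels
    y: np.ndarray  # pixels
    e: np.ndarray  # touch events in {-1, 0, 1}

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.e = np.asarray(self.e, dtype=int)

    def __len__(self) -> int:
        return len(self.t)

    def validate(self, canvas_w: int | None = None, canvas_h: int | None = None) -> None:
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.e) == n):
            raise TraceValidationError("t, x, y, e must have equal length")
        if n < 2:
            raise TraceValidationError("trace must have at least 2 samples")
        bad = np.where(~np.isin(self.e, VALID_EVENTS))[0]
        if bad.size:
            raise TraceValidationError(
                f"row {bad[0]}: event value {self.e[bad[0]]} outside {{-1, 0, 1}}"
            )
        dt = np.diff(self.t)
        neg = np.where(dt < 0)[0]
        if neg.size:
            raise TraceValidationError(
                f"row {neg[0] + 1}: time {self.t[neg[0] + 1]} decreases"
            )
        if canvas_w is not None:
            if (self.x < 0).any() or (self.x > canvas_w).any():
                raise TraceValidationError("x coordinate outside canvas bounds")
        if canvas_h is not None:
            if (self.y < 0).any() or (self.y > canvas_h).any():
                raise TraceValidationError("y coordinate outside canvas bounds")

    def dedup_timestamps(self) -> "SensorTrace":
        """Merge consecutive samples sharing a timestamp, keeping the last.

        Guarantees strictly increasing ``t`` so velocities are well defined.
        """
        keep = np.ones(len(self.t), dtype=bool)
        keep[:-1] = np.diff(self.t) > 0
        return SensorTrace(self.t[keep], self.x[keep], self.y[keep], self.e[keep])


@dataclass
class VelocitySeries:
    """Per-step pen speed in pixels/second; v[0] = 0 by convention."""

    v: np.ndarray

    def __len__(self) -> int:
        return len(self.v)


@dataclass
class FigureSplit:
    """Sample indices separating the two figures and their interlock tips.

    nf1: last sample of figure 1; nf2: first sample of figure 2;
    n1/n2: interlock endpoint in figure 1 / figure 2 (filled by
    :func:`interlock_endpoints`).
    """

    nf1: int
    nf2: int
    n1: int | None = None
    n2: int | None = None


def load_trace(path: str | Path) -> SensorTrace:
    """Read a delimited trace file and return a validated :class:`SensorTrace`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceValidationError(f"trace file missing columns {missing}")
    if df[list(TRACE_COLUMNS)].isna().any().any():
        row = int(df[list(TRACE_COLUMNS)].isna().any(axis=1).idxmax())
        raise TraceValidationError(f"row {row}: malformed or missing value")
    ev = df["event"].to_numpy()
    if not np.all(np.isin(ev, VALID_EVENTS)):
        row = int(np.where(~np.isin(ev, VALID_EVENTS))[0][0])
        raise TraceValidationError(f"row {row}: event value {ev[row]} outside {{-1, 0, 1}}")
    trace = SensorTrace(
        df["t_sec"].to_numpy(float),
        df["x_px"].to_numpy(float),
        df["y_px"].to_numpy(float),
        ev.astype(int),
    )
    trace.validate()
    return trace


def save_trace(trace: SensorTrace, path: str | Path) -> None:
    """Write a trace in the delimited dialect (lossless round trip)."""
    df = pd.DataFrame(
        {"t_sec": trace.t, "x_px": trace.x, "y_px": trace.y, "event": trace.e}
    )
    df.to_csv(path, index=False)


def compute_velocity(trace: SensorTrace) -> VelocitySeries:
    """Pen speed per inter-sample step: Euclidean step length over time step.

    Consecutive duplicate timestamps are merged beforehand by callers via
    :meth:`SensorTrace.dedup_timestamps`; a residual zero dt raises.
    """
    dt = np.diff(trace.t)
    if (dt <= 0).any():
        raise TraceValidationError("non-increasing timestamps; dedup the trace first")
    step = np.hypot(np.diff(trace.x), np.diff(trace.y))
    v = np.empty(len(trace), dtype=float)
    v[0] = 0.0
    v[1:] = step / dt
    return VelocitySeries(v)


def _interior_up_runs(e: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) inclusive index pairs of runs of 1s strictly inside e."""
    runs: list[tuple[int, int]] = []
    n = len(e)
    i = 0
    while i < n:
        if e[i] == 1:
            j = i
            while j + 1 < n and e[j + 1] == 1:
                j += 1
            if i > 0 and j < n - 1:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def split_figures(trace: SensorTrace) -> FigureSplit:
    """Locate the figure boundary at the longest interior pen-up run.

    The drawing pause between the two figures is the longest chain of 'up'
    events; ``nf1`` is the sample immediately before that run, ``nf2`` the
    first sample after it.  Ties are broken by the earliest run.
    """
    runs = _interior_up_runs(trace.e)
    if not runs:
        raise SingleFigureError(
            "no interior pen-up run found: trace contains a single figure"
        )
    start, end = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    return FigureSplit(nf1=start - 1, nf2=end + 1)


def figure_means(trace: SensorTrace, split: FigureSplit) -> tuple[float, float]:
    """Mean x of figure 1 and figure 2 (used to normalize left/right roles)."""
    return (
        float(np.mean(trace.x[: split.nf1 + 1])),
        float(np.mean(trace.x[split.nf2:])),
    )


def interlock_endpoints(trace: SensorTrace, split: FigureSplit) -> tuple[int, int]:
    """Interlock tip sample of each figure.

    The left-positioned figure contributes its rightmost sample (argmax x),
    the right-positioned one its leftmost sample (argmin x); positions are
    normalized by mean x so the convention also holds when the right figure
    was drawn first.  First occurrence wins on ties.  Returns ``(n1, n2)``
    with ``n1 <= nf1`` and ``n2 >= nf2``.
    """
    m1, m2 = figure_means(trace, split)
    x1 = trace.x[: split.nf1 + 1]
    x2 = trace.x[split.nf2:]
    if m1 <= m2:  # figure 1 sits left
        n1 = int(np.argmax(x1))
        n2 = split.nf2 + int(np.argmin(x2))
    else:
        n1 = int(np.argmin(x1))
        n2 = split.nf2 + int(np.argmax(x2))
    split.n1, split.n2 = n1, n2
    return n1, n2
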