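"""Score assignment: four integer sub-scores and the 0-11 total.

The rules transcribe the published assignment table, with two documented
resolutions: the interlocked-non-rhombus rule does not require a low
interlock percentage (the worked examples score high-percentage non-rhombus
interlocks as 3), and an angle-count sum of 13 scores 0 ("greater than 12").
All threshold comparisons are inclusive (>= / <=).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import Thresholds
from .features import FeatureSet

MAX_SUBSCORES = {"angles": 4, "intersection": 4, "closure": 2, "tremor": 1}


@dataclass
class ScoreReport:
    """Sub-scores, total, and full provenance of one scored drawing."""

    angles_score: int
    intersection_score: int
    closure_score: int
    tremor_score: int
    total: int
    features: FeatureSet | None = None
    thresholds: Thresholds | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def sub_scores(self) -> dict[str, int]:
        return {
            "angles": self.angles_score,
            "intersection": self.intersection_score,
            "closure": self.closure_score,
            "tremor": self.tremor_score,
        }

    def to_record(self) -> dict[str, float]:
        rec = {f"score_{k}": float(v) for k, v in self.sub_scores.items()}
        rec["total"] = float(self.total)
        if self.features is not None:
            rec.update(self.features.to_record())
        return rec

    def to_text(self) -> str:
        lines = ["pentagon drawing test score"]
        if self.features is not None:
            f = self.features
            lines += [
                f"  figure match      pf1={f.pf1:.2f}%  pf2={f.pf2:.2f}%",
                f"  angle counts      NA1={f.NA1}  NA2={f.NA2}  (peaks {f.Np1}/{f.Np2})",
                f"  interlock         pL={f.pL:.2f}%  dL={f.dL_cm:+.3f} cm  |dx/dy|={f.ratio:.2f}",
                f"  openings          figure1={f.O1}  figure2={f.O2}",
                f"  tremor            counts {f.tremor_count1}/{f.tremor_count2}  flags {f.T1}/{f.T2}",
            ]
        lines += [
            f"  angles score        {self.angles_score} / 4",
            f"  intersection score  {self.intersection_score} / 4",
            f"  closure score       {self.closure_score} / 2",
            f"  tremor score        {self.tremor_score} / 1",
            f"  TOTAL               {self.total} / 11",
        ]
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)


def score_angles(pf1: float, pf2: float, na1: int, na2: int, th: Thresholds) -> int:
    """0-4 points for the number of angles."""
    if pf1 >= th.pth1 and pf2 >= th.pth1:
        return 4
    s = na1 + na2
    if s in (9, 11):
        return 3
    if s in (8, 12):
        return 2
    if 5 <= s <= 7:
        return 1
    return 0


def score_intersection(pL: float, dL_cm: float, ratio: float, th: Thresholds) -> int:
    """0-4 points for distance/intersection of the two figures.

    Rules are tested most-specific first: rhombus interlock, any interlock,
    contact, near miss, separation.
    """
    if pL >= th.pth2 and dL_cm < -th.eps_cm and ratio >= th.rth:
        return 4
    if dL_cm < -th.eps_cm:
        return 3
    if abs(dL_cm) <= th.eps_cm:
        return 2
    if dL_cm < 1.0:
        return 1
    return 0


def score_closure(o1: int, o2: int) -> int:
    """2 points when both contours close, 1 when one has an opening, else 0."""
    return 2 - (int(o1) + int(o2))


def score_tremor(t1: int, t2: int) -> int:
    """1 point only when neither figure shows tremor."""
    return int(not t1 and not t2)


def total_score(
    features: FeatureSet,
    th: Thresholds | None = None,
    warnings: list[str] | None = None,
) -> ScoreReport:
    """Assemble the full report from a feature set."""
    th = th or Thresholds()
    a = score_angles(features.pf1, features.pf2, features.NA1, features.NA2, th)
    i = score_intersection(features.pL, features.dL_cm, features.ratio, th)
    c = score_closure(features.O1, features.O2)
    t = score_tremor(features.T1, features.T2)
    return ScoreReport(
        angles_score=a,
        intersection_score=i,
        closure_score=c,
        tremor_score=t,
        total=a + i + c + t,
        features=features,
        thresholds=th,
        warnings=list(warnings or []),
    )
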