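"""Run configuration: canvas geometry, thresholds and detector parameters.

Every threshold carries the published default of the scoring protocol; all
values are overridable from a YAML file so that a deployment can re-calibrate
against its own expert raters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class Thresholds:
    """Decision thresholds of the scoring protocol.

    pth1/pth2 are percentages in (0, 100); rth is dimensionless; eps_cm and
    delta_cm are centimetres; eth is a transition count.  All comparisons in
    the scorer use >= (equivalently <= on the negative side), the convention
    of the score-assignment table.
    """

    pth1: float = 75.0   # pentagon identification: minimum figure match %
    pth2: float = 75.0   # rhombus interlock: minimum interlock match %
    rth: float = 1.12    # rhombus interlock: minimum |dx/dy| of the tip pair
    eps_cm: float = 0.01  # "touching" tolerance on |dL| (2 px diagonal)
    delta_cm: float = 0.1  # opening: maximum closed-corner cluster dispersion
    eth: int = 5         # tremor: minimum up->down transition count

    def validate(self) -> None:
        if not (0 < self.pth1 < 100 and 0 < self.pth2 < 100):
            raise ValueError("percentage thresholds must lie in (0, 100)")
        if min(self.rth, self.eps_cm, self.delta_cm, self.eth) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class PeakParams:
    """Velocity peak detector parameters (counts one peak per drawn edge)."""

    smooth_window: int = 5          # moving-average window, samples
    min_height_frac: float = 0.2    # peak height as fraction of segment max
    zero_vel_px_per_sample: float = 1.0  # |v|*dt below this counts as zero
    trough_frac: float = 0.05       # peak-separating dip, fraction of segment max


@dataclass
class RunConfig:
    """Full pipeline configuration."""

    canvas_w: int = 1600
    canvas_h: int = 1320
    cm_per_px: float = 0.004
    line_width_px: int = 20
    image_size: int = 128
    sample_dt: float = 0.02
    # mask post-processing at image_size resolution
    figure_mask_dilate_px: int = 2
    interlock_mask_dilate_px: int = 3
    thresholds: Thresholds = field(default_factory=Thresholds)
    peaks: PeakParams = field(default_factory=PeakParams)
    seed: int = 0
    deep5_path: str | None = None
    deeplock_path: str | None = None

    def validate(self) -> None:
        self.thresholds.validate()
        if self.canvas_w <= 0 or self.canvas_h <= 0 or self.image_size <= 0:
            raise ValueError("canvas and image sizes must be positive")
        if self.cm_per_px <= 0 or self.sample_dt <= 0:
            raise ValueError("cm_per_px and sample_dt must be positive")

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "thresholds" in d:
            d["thresholds"] = Thresholds(**d["thresholds"])
        if "peaks" in d:
            d["peaks"] = PeakParams(**d["peaks"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
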