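"""End-to-end scoring: trace in, 0-11 score report out."""

from __future__ import annotations

import logging
import time

from . import features as feat
from . import segmentation as seg
from . import sensor_io as sio
from .config import RunConfig
from .scoring import ScoreReport, total_score
from .synthgen import GroundTruth

log = logging.getLogger("pentascore")


def score_trace(
    trace: sio.SensorTrace,
    cfg: RunConfig | None = None,
    *,
    oracle_truth: GroundTruth | None = None,
    deep5: seg.TrainedModel | None = None,
    deeplock: seg.TrainedModel | None = None,
) -> ScoreReport:
    """Run split -> rasterize -> segment -> features -> score.

    Segmentation masks come either from the geometric oracle (synthetic data
    with ground truth) or from the two trained models.
    """
    if oracle_truth is None and (deep5 is None or deeplock is None):
        raise ValueError("provide oracle_truth or both trained models")
    cfg = cfg or RunConfig()
    cfg.validate()

    t0 = time.perf_counter()
    trace.validate(cfg.canvas_w, cfg.canvas_h)
    trace = trace.dedup_timestamps()
    velocity = sio.compute_velocity(trace)
    split = sio.split_figures(trace)
    sio.interlock_endpoints(trace, split)
    log.info("split: nf1=%d nf2=%d n1=%d n2=%d", split.nf1, split.nf2, split.n1, split.n2)

    if oracle_truth is not None:
        masks = seg.oracle_segment(oracle_truth, cfg)
    else:
        masks = seg.predicted_masks(trace, split, cfg, deep5, deeplock)
    segres = seg.compute_segmentation(trace, split, cfg, masks)
    log.info("segmentation: pf1=%.2f pf2=%.2f pL=%.2f", segres.pf1, segres.pf2, segres.pL)

    fs = feat.extract_features(trace, velocity, split, segres.pf1, segres.pf2, segres.pL, cfg)
    report = total_score(fs, cfg.thresholds, warnings=segres.warnings)
    log.info("scored %d/11 in %.3f s", report.total, time.perf_counter() - t0)
    return report
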