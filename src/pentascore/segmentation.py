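"""Rasterization, segmentation masks (learned and oracle) and overlap scores.

The drawing is inked on the full canvas with the configured line width while
the pen is touching, then downsampled to the 128x128 analysis resolution.
Figure match percentages compare the drawn pixels of each figure against a
segmentation mask: the learned masks come from the two U-Net models (one for
pentagon-shaped figures, one for the interlock region); the oracle masks are
rasterized from the generator's true geometry and provide a deterministic
stand-in for the learned models when ground truth exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from skimage.morphology import dilation as binary_dilation, disk as disk_struct
from skimage.transform import resize

from . import nn
from .config import RunConfig
from .sensor_io import FigureSplit, SensorTrace
from .synthgen import GroundTruth

_BINARIZE = 0.15  # ink threshold after area downsampling


class EmptyReferenceError(ValueError):
    """The reference pixel set of an overlap percentage is empty."""


@dataclass
class UNetConfig:
    """Architecture and training settings for the segmentation network."""

    input_size: int = 128
    base_channels: int = 16
    depth: int = 4
    out_channels: int = 1
    epochs: int = 6
    batch_size: int = 4
    learning_rate: float = 1e-3
    pos_weight: float = 4.0
    loss: str = "weighted_bce"

    def validate(self) -> None:
        if self.base_channels <= 0 or self.depth <= 0 or self.out_channels <= 0:
            raise ValueError("channels/depth must be positive")
        if self.input_size % (2**self.depth) != 0:
            raise ValueError("input size must be divisible by 2**depth")


@dataclass
class SegmentationMasks:
    """Binary masks at analysis resolution for both figures and the interlock."""

    mask_fig1: np.ndarray
    mask_fig2: np.ndarray
    mask_interlock: np.ndarray


@dataclass
class SegmentationResult:
    """Masks, drawn-pixel references, and the three match percentages."""

    masks: SegmentationMasks
    ref_fig1: np.ndarray
    ref_fig2: np.ndarray
    ref_interlock: np.ndarray   # drawn pixels between the interlock endpoints
    pf1: float
    pf2: float
    pL: float
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------- raster


def _draw_thick_path(canvas: np.ndarray, pts: np.ndarray, drawn: np.ndarray, radius: float) -> None:
    """Ink round-capped thick segments for steps flagged in ``drawn``."""
    h, w = canvas.shape
    pts = np.asarray(pts, float)
    stamped = np.zeros(len(pts), dtype=bool)

    def stamp(i: int) -> None:
        if not stamped[i]:
            rr, cc = draw_disk((pts[i, 1], pts[i, 0]), radius, shape=(h, w))
            canvas[rr, cc] = True
            stamped[i] = True

    for n in range(1, len(pts)):
        if not drawn[n]:
            continue
        stamp(n - 1)
        stamp(n)
        p, q = pts[n - 1], pts[n]
        d = q - p
        length = np.hypot(*d)
        if length > 0.5:
            perp = np.array([-d[1], d[0]]) / length * radius
            corners = np.array([p + perp, q + perp, q - perp, p - perp])
            rr, cc = draw_polygon(corners[:, 1], corners[:, 0], shape=(h, w))
            canvas[rr, cc] = True


def _downsample(canvas: np.ndarray, size: int) -> np.ndarray:
    small = resize(canvas.astype(np.float32), (size, size), order=1, anti_aliasing=True)
    return small > _BINARIZE


def rasterize_trace(
    trace: SensorTrace,
    cfg: RunConfig,
    idx_range: tuple[int, int] | None = None,
    *,
    full_resolution: bool = False,
) -> np.ndarray:
    """Binary drawing image of (part of) a trace.

    A step from sample n-1 to n is inked unless the pen was up at n-1, so
    pen-up travel leaves no ink.  ``idx_range`` restricts to steps inside the
    inclusive sample window (used for per-figure and interlock references).
    Returns the analysis-resolution image unless ``full_resolution``.
    """
    canvas = np.zeros((cfg.canvas_h, cfg.canvas_w), dtype=bool)
    e = trace.e
    drawn = np.zeros(len(e), dtype=bool)
    drawn[1:] = e[:-1] != 1
    if idx_range is not None:
        lo, hi = idx_range
        mask = np.zeros(len(e), dtype=bool)
        mask[lo + 1 : hi + 1] = True
        drawn &= mask
        # ink the endpoint caps even if the window contains no moving step
        if lo <= hi and e[lo] != 1:
            rr, cc = draw_disk(
                (trace.y[lo], trace.x[lo]), cfg.line_width_px / 2.0,
                shape=canvas.shape,
            )
            canvas[rr, cc] = True
    pts = np.column_stack([trace.x, trace.y])
    _draw_thick_path(canvas, pts, drawn, cfg.line_width_px / 2.0)
    if full_resolution:
        return canvas
    return _downsample(canvas, cfg.image_size)


def rasterize_polygon_outline(vertices: np.ndarray, cfg: RunConfig) -> np.ndarray:
    """Closed polygon contour with the drawing line width, at analysis size."""
    canvas = np.zeros((cfg.canvas_h, cfg.canvas_w), dtype=bool)
    pts = np.vstack([vertices, vertices[:1]])
    drawn = np.ones(len(pts), dtype=bool)
    _draw_thick_path(canvas, pts, drawn, cfg.line_width_px / 2.0)
    return _downsample(canvas, cfg.image_size)


def rasterize_polygon_fill(vertices: np.ndarray, cfg: RunConfig) -> np.ndarray:
    canvas = np.zeros((cfg.canvas_h, cfg.canvas_w), dtype=bool)
    rr, cc = draw_polygon(vertices[:, 1], vertices[:, 0], shape=canvas.shape)
    canvas[rr, cc] = True
    return _downsample(canvas, cfg.image_size)


# ---------------------------------------------------------------- oracle


def oracle_segment(truth: GroundTruth, cfg: RunConfig) -> SegmentationMasks:
    """Deterministic masks rasterized from the true geometry.

    A figure's pentagon mask is its contour band (dilated a little to absorb
    resampling error) when the figure truly has five vertices, else empty;
    the interlock mask is the filled true overlap polygon, dilated so that
    tip strokes straddling the region boundary are matched.
    """
    size = cfg.image_size
    empty = np.zeros((size, size), dtype=bool)

    def band(vertices: np.ndarray, is_pentagon: bool) -> np.ndarray:
        if not is_pentagon:
            return empty.copy()
        m = rasterize_polygon_outline(np.asarray(vertices, float), cfg)
        return binary_dilation(m, disk_struct(cfg.figure_mask_dilate_px))

    if truth.interlock_polygon is None:
        lock = empty.copy()
    else:
        lock = rasterize_polygon_fill(np.asarray(truth.interlock_polygon, float), cfg)
        lock = binary_dilation(lock, disk_struct(cfg.interlock_mask_dilate_px))
    return SegmentationMasks(
        mask_fig1=band(truth.vertices_fig1, truth.is_pentagon1),
        mask_fig2=band(truth.vertices_fig2, truth.is_pentagon2),
        mask_interlock=lock,
    )


# ---------------------------------------------------------------- learned


def build_unet(config: UNetConfig, seed: int = 0) -> nn.UNet:
    """Construct the segmentation network; validates the 23-conv contract."""
    config.validate()
    net = nn.UNet(
        base_channels=config.base_channels,
        depth=config.depth,
        out_channels=config.out_channels,
        seed=seed,
    )
    expected = 4 * config.depth + 2 + config.depth + 1
    if net.conv_layer_count() != expected:
        raise RuntimeError("constructed network violates the conv-layer contract")
    return net


@dataclass
class TrainedModel:
    """A trained segmentation network plus its training history."""

    net: nn.UNet
    config: UNetConfig
    history: list[dict]

    def predict(self, images: np.ndarray) -> np.ndarray:
        """images (N, H, W) in [0,1] -> binary masks (N, H, W)."""
        single = images.ndim == 2
        if single:
            images = images[None]
        prob = self.net.predict_proba(np.asarray(images, np.float32))
        out = prob >= 0.5
        return out[0] if single else out

    def save(self, path) -> None:
        self.net.save(path)

    @classmethod
    def load(cls, path, config: UNetConfig | None = None) -> "TrainedModel":
        return cls(nn.UNet.load(path), config or UNetConfig(), history=[])


def train_model(
    images: np.ndarray,
    masks: np.ndarray,
    config: UNetConfig,
    seed: int = 0,
    val_images: np.ndarray | None = None,
    val_masks: np.ndarray | None = None,
) -> TrainedModel:
    """Train the U-Net on binary images/masks (N, H, W); seeded and CPU-sized."""
    if len(images) == 0:
        raise ValueError("empty dataset")
    net = build_unet(config, seed=seed)
    history = nn.train_unet(
        net,
        np.asarray(images, np.float32),
        np.asarray(masks, np.float32),
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr=config.learning_rate,
        pos_weight=config.pos_weight,
        seed=seed,
        val_images=None if val_images is None else np.asarray(val_images, np.float32),
        val_masks=None if val_masks is None else np.asarray(val_masks, np.float32),
    )
    return TrainedModel(net, config, history)


# ---------------------------------------------------------------- overlap


def overlap_percentage(mask: np.ndarray, reference: np.ndarray) -> float:
    """100 * |mask intersect reference| / |reference|."""
    mask = np.asarray(mask, bool)
    reference = np.asarray(reference, bool)
    if mask.shape != reference.shape:
        raise ValueError("mask and reference must have the same shape")
    ref_n = int(reference.sum())
    if ref_n == 0:
        raise EmptyReferenceError("reference pixel set is empty")
    return 100.0 * int((mask & reference).sum()) / ref_n


def compute_segmentation(
    trace: SensorTrace,
    split: FigureSplit,
    cfg: RunConfig,
    masks: SegmentationMasks,
) -> SegmentationResult:
    """Assemble references from the trace and score them against the masks."""
    if split.n1 is None or split.n2 is None:
        raise ValueError("interlock endpoints missing; call interlock_endpoints first")
    ref1 = rasterize_trace(trace, cfg, (0, split.nf1))
    ref2 = rasterize_trace(trace, cfg, (split.nf2, len(trace) - 1))
    refL = rasterize_trace(trace, cfg, (split.n1, split.n2))
    warnings: list[str] = []

    def pct(mask: np.ndarray, ref: np.ndarray, name: str) -> float:
        try:
            return overlap_percentage(mask, ref)
        except EmptyReferenceError:
            warnings.append(f"{name}: empty reference, percentage treated as 0")
            return 0.0

    return SegmentationResult(
        masks=masks,
        ref_fig1=ref1,
        ref_fig2=ref2,
        ref_interlock=refL,
        pf1=pct(masks.mask_fig1, ref1, "pf1"),
        pf2=pct(masks.mask_fig2, ref2, "pf2"),
        pL=pct(masks.mask_interlock, refL, "pL"),
        warnings=warnings,
    )


def predicted_masks(
    trace: SensorTrace,
    split: FigureSplit,
    cfg: RunConfig,
    deep5: TrainedModel,
    deeplock: TrainedModel,
) -> SegmentationMasks:
    """Masks from the trained models, with the pentagon prediction assigned to
    figures via the sample-index split (pixels near each figure's samples)."""
    image = rasterize_trace(trace, cfg)
    pent = deep5.predict(image.astype(np.float32))
    lock = deeplock.predict(image.astype(np.float32))
    struct = disk_struct(max(2, cfg.figure_mask_dilate_px + 2))
    region1 = binary_dilation(rasterize_trace(trace, cfg, (0, split.nf1)), struct)
    region2 = binary_dilation(
        rasterize_trace(trace, cfg, (split.nf2, len(trace) - 1)), struct
    )
    return SegmentationMasks(
        mask_fig1=pent & region1, mask_fig2=pent & region2, mask_interlock=lock
    )
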