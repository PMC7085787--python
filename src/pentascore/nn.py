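"""A small NumPy implementation of the U-Net used for drawing segmentation.

Encoder–decoder with skip connections: four contracting levels of two 3x3
convolutions + ReLU followed by 2x2 max pooling, a two-convolution
bottleneck, four expanding levels of a learnable 2x2 up-convolution,
skip concatenation and two 3x3 convolutions, and a final 1x1 convolution
producing one logit map.  Feature channels double per contracting level
starting from 16, so the final feature vectors have 16 components.  Counting
the up-convolutions and the final 1x1, the network has 23 convolutional
layers.

Training uses Adam on a positively-weighted binary cross-entropy with
logits; everything is float32 and deterministic given the seed.  3x3
convolutions run as im2col + GEMM; their data gradient is the same-padded
convolution of the output gradient with spatially flipped, channel-swapped
kernels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

F32 = np.float32


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


class Conv:
    """k x k same-padded convolution with stride 1 (k in {1, 3}) + bias."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int, k: int = 3):
        assert k in (1, 3)
        self.k = k
        self.cin, self.cout = cin, cout
        self.W = _he_init(rng, (cout, cin * k * k), cin * k * k)
        self.b = np.zeros(cout, dtype=F32)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if self.k == 1:
            return x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (n,c,h,w,3,3)
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = np.ascontiguousarray(self._im2col(x))
        out = cols @ self.W.T + self.b
        self._cols, self._shape = cols, (n, c, h, w)
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout)
        self.dW = (dflat.T @ self._cols).astype(F32)
        self.db = dflat.sum(axis=0).astype(F32)
        if self.k == 1:
            dx = dflat @ self.W
            return dx.reshape(n, h, w, c).transpose(0, 3, 1, 2)
        # data gradient: same-pad conv of dout with flipped, transposed kernels
        Wk = self.W.reshape(self.cout, self.cin, 3, 3)
        Wflip = Wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.cin, self.cout * 9)
        dp = np.pad(dout, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(dp, (3, 3), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, self.cout * 9)
        dx = cols @ Wflip.T
        self._cols = None
        return dx.reshape(n, h, w, self.cin).transpose(0, 3, 1, 2).astype(F32)

    def params(self):
        return {"W": self.W, "b": self.b}


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2 (input sides must be even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        xf = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._arg = xf.argmax(axis=-1)  # ties routed to one element only
        self._shape = x.shape
        return np.take_along_axis(xf, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        d = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
        np.put_along_axis(d, self._arg[..., None], dout[..., None].astype(F32), axis=-1)
        d = d.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return d.reshape(n, c, h, w)


class UpConv2:
    """Learnable 2x2 up-convolution (transposed conv, stride 2)."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int):
        self.cin, self.cout = cin, cout
        self.W = _he_init(rng, (cin, cout, 2, 2), cin)
        self.b = np.zeros(cout, dtype=F32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._x = x
        y = np.einsum("ncij,cfab->nfiajb", x, self.W, optimize=True)
        y = y.reshape(n, self.cout, 2 * h, 2 * w) + self.b[None, :, None, None]
        return y.astype(F32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, H, W_ = dout.shape
        d = dout.reshape(n, f, H // 2, 2, W_ // 2, 2)
        self.dW = np.einsum("ncij,nfiajb->cfab", self._x, d, optimize=True).astype(F32)
        self.db = dout.sum(axis=(0, 2, 3)).astype(F32)
        dx = np.einsum("nfiajb,cfab->ncij", d, self.W, optimize=True)
        self._x = None
        return dx.astype(F32)

    def params(self):
        return {"W": self.W, "b": self.b}


def bce_with_logits(z: np.ndarray, y: np.ndarray, pos_weight: float = 1.0):
    """Weighted binary cross-entropy; returns (loss, dloss/dz)."""
    w = np.where(y > 0.5, F32(pos_weight), F32(1.0))
    # stable: max(z,0) - z*y + log(1 + exp(-|z|))
    loss_map = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    wsum = w.sum()
    loss = float((w * loss_map).sum() / wsum)
    sig = expit(z)
    dz = (w * (sig - y) / wsum).astype(F32)
    return loss, dz


class Adam:
    def __init__(self, layers, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if hasattr(l, "params")]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params().items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params().items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        for i, l in enumerate(self.layers):
            for k, p in l.params().items():
                g = getattr(l, "d" + k)
                m = self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                v = self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                mh = m / (1 - self.b1**self.t)
                vh = v / (1 - self.b2**self.t)
                p -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(F32)


class UNet:
    """The 23-conv-layer segmentation network."""

    def __init__(self, base_channels: int = 16, depth: int = 4, in_channels: int = 1,
                 out_channels: int = 1, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.base_channels, self.depth = base_channels, depth
        self.in_channels, self.out_channels = in_channels, out_channels
        c = base_channels
        self.enc: list[list] = []
        cin = in_channels
        self.channel_progression = []
        for _ in range(depth):
            self.enc.append([Conv(rng, cin, c), ReLU(), Conv(rng, c, c), ReLU()])
            self.channel_progression.append(c)
            cin, c = c, c * 2
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = [Conv(rng, cin, c), ReLU(), Conv(rng, c, c), ReLU()]
        self.channel_progression.append(c)
        self.dec: list[dict] = []
        for _ in range(depth):
            cskip = c // 2
            up = UpConv2(rng, c, cskip)
            convs = [Conv(rng, 2 * cskip, cskip), ReLU(), Conv(rng, cskip, cskip), ReLU()]
            self.dec.append({"up": up, "convs": convs})
            c = cskip
        self.final = Conv(rng, c, out_channels, k=1)

    # -- architecture introspection ----------------------------------

    def conv_layer_count(self) -> int:
        n = sum(1 for blk in self.enc for l in blk if isinstance(l, Conv))
        n += sum(1 for l in self.bottleneck if isinstance(l, Conv))
        n += sum(1 + sum(1 for l in d["convs"] if isinstance(l, Conv)) for d in self.dec)
        return n + 1  # final 1x1

    def layers(self):
        out = []
        for blk in self.enc:
            out.extend(blk)
        out.extend(self.pools)
        out.extend(self.bottleneck)
        for d in self.dec:
            out.append(d["up"])
            out.extend(d["convs"])
        out.append(self.final)
        return out

    # -- forward / backward ------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, C, H, W) float32 -> logits (N, out, H, W)."""
        h = x.astype(F32)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            for l in blk:
                h = l.forward(h)
            skips.append(h)
            h = pool.forward(h)
        for l in self.bottleneck:
            h = l.forward(h)
        self._skip_channels = [s.shape[1] for s in skips]
        for d, skip in zip(self.dec, reversed(skips)):
            h = d["up"].forward(h)
            h = np.concatenate([skip, h], axis=1)
            for l in d["convs"]:
                h = l.forward(h)
        return self.final.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.final.backward(dlogits)
        dskip_rev = []
        for d_blk in reversed(self.dec):
            for l in reversed(d_blk["convs"]):
                d = l.backward(d)
            cskip = d.shape[1] // 2
            dskip_rev.append(d[:, :cskip])
            d = d_blk["up"].backward(d[:, cskip:])
        for l in reversed(self.bottleneck):
            d = l.backward(d)
        # dec[0] consumed the deepest skip, so its gradient is dskip_rev[-1]
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskip_rev)):
            d = pool.backward(d) + dskip
            for l in reversed(blk):
                d = l.backward(d)

    def predict_proba(self, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """images: (N, H, W) -> probabilities (N, H, W)."""
        outs = []
        for i in range(0, len(images), batch_size):
            x = images[i : i + batch_size].astype(F32)[:, None]
            z = self.forward(x)
            outs.append(expit(z[:, 0]))
        return np.concatenate(outs, axis=0)

    # -- persistence ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {}
        for i, l in enumerate(self.layers()):
            if hasattr(l, "params"):
                for k, v in l.params().items():
                    arrays[f"l{i}_{k}"] = v
        meta = json.dumps(
            {
                "base_channels": self.base_channels,
                "depth": self.depth,
                "in_channels": self.in_channels,
                "out_channels": self.out_channels,
            }
        )
        np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            net = cls(**meta)
            for i, l in enumerate(net.layers()):
                if hasattr(l, "params"):
                    for k in l.params():
                        setattr(l, k, data[f"l{i}_{k}"].copy())
        return net


def train_unet(
    net: UNet,
    images: np.ndarray,
    masks: np.ndarray,
    *,
    epochs: int = 6,
    batch_size: int = 4,
    lr: float = 1e-3,
    pos_weight: float = 4.0,
    seed: int = 0,
    val_images: np.ndarray | None = None,
    val_masks: np.ndarray | None = None,
) -> list[dict]:
    """Mini-batch Adam training; returns one history record per epoch."""
    if len(images) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    opt = Adam(net.layers(), lr=lr)
    history = []
    n = len(images)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            x = images[idx].astype(F32)[:, None]
            y = masks[idx].astype(F32)[:, None]
            z = net.forward(x)
            loss, dz = bce_with_logits(z, y, pos_weight)
            net.backward(dz)
            opt.step()
            losses.append(loss)
        rec = {"epoch": epoch + 1, "loss": float(np.mean(losses))}
        if val_images is not None:
            p = net.predict_proba(val_images)
            rec["val_pixel_accuracy"] = float(np.mean((p >= 0.5) == (val_masks > 0.5)))
        history.append(rec)
    return history


def pixel_accuracy(prob: np.ndarray, mask: np.ndarray) -> float:
    return float(np.mean((prob >= 0.5) == (mask > 0.5)))


def iou(pred: np.ndarray, mask: np.ndarray) -> float:
    p = pred >= 0.5
    m = mask > 0.5
    union = np.logical_or(p, m).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, m).sum() / union)
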