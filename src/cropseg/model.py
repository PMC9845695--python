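"""The two-branch segmentation network.

The master branch is a five-level U-Net encoder / four-stage bilinear
decoder.  Every encoder level is a double 3x3 conv + batch norm + activation
block; levels 2-5 halve the resolution with 2x2 max pooling and double the
channels.  Efficient channel attention (ECA: global average pooling, a
bias-free size-3 1-D convolution across channels, a sigmoid, and a
channel-wise rescale) is applied to the encoder outputs of levels 1-4 before
they are used as skip connections; the attended map keeps the shape of its
input.  Each decoder stage bilinearly upsamples the running feature 2x,
concatenates the attended skip at that resolution, and applies a double-conv
block; the final 64-channel map goes through a 1x1 convolution to per-class
logits.

The point-constraint branch re-classifies the hardest pixels: per-pixel
difficulty is the top-1 minus top-2 softmax margin, the k smallest-margin
valid pixels are selected (k = 8096 on a 256x256 patch, ~12.35% of pixels;
scaled by the same fraction for other sizes), their feature vectors are
bilinearly sampled from the upsampled level-2 encoder map (after ECA by
default), concatenated with the master softmax scores at those pixels, and
passed through a shared MLP.  The MLP's argmax overrides the master label
map at exactly the selected pixels.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

CP_PIXEL_FRACTION = 8096 / (256 * 256)  # ~0.1235 of each patch


@dataclasses.dataclass
class NetConfig:
    in_bands: int = 4
    n_classes: int = 4
    encoder_channels: tuple = (64, 128, 256, 512, 1024)
    eca_kernel: int = 3
    eca_levels: int = 4
    activation: str = "prelu"
    prelu_init: float = 0.25
    cp_enabled: bool = True
    cp_k: int = 8096
    cp_source_level: int = 2
    cp_after_eca: bool = True
    cp_hidden: tuple = (256, 256)

    def __post_init__(self):
        if self.eca_kernel % 2 == 0:
            raise ValueError("eca_kernel must be odd")
        if self.cp_k < 1:
            raise ValueError("cp_k must be >= 1")
        if not 1 <= self.cp_source_level <= 5:
            raise ValueError("cp_source_level must be in 1..5")
        if len(self.encoder_channels) != 5:
            raise ValueError("encoder_channels must have 5 levels")
        if self.activation not in ("prelu", "relu"):
            raise ValueError("activation must be 'prelu' or 'relu'")

    @classmethod
    def scaled(cls, base_width: int, **kwargs) -> "NetConfig":
        """Config with encoder widths (w, 2w, 4w, 8w, 16w)."""
        channels = tuple(base_width * (2 ** i) for i in range(5))
        return cls(encoder_channels=channels, **kwargs)


@dataclasses.dataclass
class PointSelection:
    """The k hardest pixels of each image in a batch."""

    indices: np.ndarray        # [N, k] flat pixel indices, unique per image
    margins: np.ndarray        # [N, k] top1 - top2 softmax margins
    features: np.ndarray       # [N, k, C_src] sampled encoder features
    master_scores: np.ndarray  # [N, k, n_classes] master softmax at the points


@dataclasses.dataclass
class Prediction:
    master_logits: np.ndarray          # [N, C, H, W]
    master_probs: np.ndarray           # [N, C, H, W]
    label_map: np.ndarray              # [N, H, W]; overridden at selected points
    selection: PointSelection | None
    cp_logits: np.ndarray | None       # [N, k, C]
    probs_t: Tensor | None = None      # autodiff handles for training
    cp_logits_t: Tensor | None = None


def point_difficulty(scores: np.ndarray) -> np.ndarray:
    """Margin map: top-1 minus top-2 class probability per pixel.

    Low margin = hard pixel.  Accepts [C,H,W] or [N,C,H,W].
    """
    scores = np.asarray(scores)
    axis = 0 if scores.ndim == 3 else 1
    if scores.shape[axis] < 2:
        raise ValueError("need at least 2 classes for a margin")
    part = np.partition(scores, scores.shape[axis] - 2, axis=axis)
    top1 = np.take(part, -1, axis=axis)
    top2 = np.take(part, -2, axis=axis)
    return top1 - top2


def select_topk(margins: np.ndarray, valid: np.ndarray | None, k: int) -> np.ndarray:
    """Flat indices of the k valid pixels with smallest margin.

    Ties break by ascending flat index (stable sort), so selection is fully
    deterministic.  Returns min(k, #valid) indices in ascending-margin order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    m = np.asarray(margins, dtype=float).ravel()
    if valid is not None:
        v = np.asarray(valid, dtype=bool).ravel()
        n_valid = int(v.sum())
        if n_valid == 0:
            raise ValueError("no valid pixels to select from")
        m = np.where(v, m, np.inf)
    else:
        n_valid = m.size
    order = np.argsort(m, kind="stable")
    return order[:min(k, n_valid)]


def effective_k(cfg: NetConfig, h: int, w: int) -> int:
    """cp_k on a 256x256 patch; the same ~12.35% pixel fraction elsewhere."""
    if (h, w) == (256, 256):
        return cfg.cp_k
    return max(1, int(round(CP_PIXEL_FRACTION * h * w)))


def sample_point_features(feature_map, indices: np.ndarray,
                          out_hw: tuple[int, int]) -> Tensor:
    """Bilinearly upsample a feature map to ``out_hw`` and gather pixel vectors.

    ``feature_map`` is [N, C, h, w]; ``indices`` are [N, k] flat indices on the
    full-resolution grid.  Sampling uses the pixel-centre convention (corners
    not aligned), so gathering after upsampling equals bilinear interpolation
    at the pixel centres.
    """
    feature_map = ad.as_tensor(feature_map)
    h, w = out_hw
    up = ad.upsample_bilinear(feature_map, h, w)
    return ad.gather_pixels(up, indices)


class DoubleConv(nn.Module):
    """(3x3 conv -> BN -> activation) twice, spatial size preserved."""

    def __init__(self, in_ch: int, out_ch: int, activation: str, prelu_init: float,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.act1 = nn.make_activation(activation, out_ch, prelu_init)
        self.conv2 = nn.Conv2d(out_ch, out_ch, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.act2 = nn.make_activation(activation, out_ch, prelu_init)

    def forward(self, x):
        x = self.act1(self.bn1(self.conv1(x)))
        return self.act2(self.bn2(self.conv2(x)))


class ECA(nn.Module):
    """Efficient channel attention: GAP -> 1-D conv (no bias) -> sigmoid -> scale."""

    def __init__(self, kernel: int = 3, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = nn.Parameter(rng.normal(0.0, np.sqrt(1.0 / kernel), size=kernel))

    def forward(self, x):
        pooled = ad.gap2d(x)
        w = ad.sigmoid(ad.conv1d_channels(pooled, self.weight))
        return ad.channel_scale(x, w)


class MLP(nn.Module):
    def __init__(self, in_f: int, hidden: tuple, out_f: int, activation: str,
                 prelu_init: float, rng: np.random.Generator):
        super().__init__()
        dims = [in_f, *hidden]
        self.layers = [nn.Linear(dims[i], dims[i + 1], rng=rng) for i in range(len(hidden))]
        self.acts = [nn.make_activation(activation, dims[i + 1], prelu_init)
                     for i in range(len(hidden))]
        self.out = nn.Linear(dims[-1], out_f, rng=rng)

    def forward(self, x):
        for layer, act in zip(self.layers, self.acts):
            x = act(layer(x))
        return self.out(x)


class CropSegNet(nn.Module):
    """Attention-augmented U-Net with optional point-constraint refinement."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = cfg.encoder_channels
        self.inc = DoubleConv(cfg.in_bands, ch[0], cfg.activation, cfg.prelu_init, rng)
        self.downs = [DoubleConv(ch[i], ch[i + 1], cfg.activation, cfg.prelu_init, rng)
                      for i in range(4)]
        self.ecas = [ECA(cfg.eca_kernel, rng=rng) for _ in range(cfg.eca_levels)]
        # decoder stage i consumes upsampled ch[4-i] + skip ch[3-i], emits ch[3-i]
        self.ups = [DoubleConv(ch[4 - i] + ch[3 - i], ch[3 - i],
                               cfg.activation, cfg.prelu_init, rng)
                    for i in range(4)]
        self.outc = nn.Conv2d(ch[0], cfg.n_classes, kernel=1, padding=0, rng=rng)
        if cfg.cp_enabled:
            c_src = ch[cfg.cp_source_level - 1]
            self.cp_head = MLP(c_src + cfg.n_classes, cfg.cp_hidden, cfg.n_classes,
                               cfg.activation, cfg.prelu_init, rng)

    # -- pieces ------------------------------------------------------------

    def encode(self, x) -> tuple[list[Tensor], list[Tensor]]:
        """Five-level feature pyramid plus the attended skip copies."""
        x = ad.as_tensor(x)
        n, c, h, w = x.shape
        if h % 16 or w % 16:
            raise ValueError(f"input spatial dims must be divisible by 16, got {h}x{w}")
        levels = [self.inc(x)]
        for block in self.downs:
            levels.append(block(ad.maxpool2x2(levels[-1])))
        attended = [self.ecas[i](levels[i]) if i < self.cfg.eca_levels else levels[i]
                    for i in range(4)]
        return levels, attended

    def decode(self, levels: list[Tensor], attended: list[Tensor]) -> Tensor:
        d = levels[4]
        for i, block in enumerate(self.ups):
            skip = attended[3 - i]
            _, _, sh, sw = skip.shape
            d = ad.upsample_bilinear(d, sh, sw)
            d = block(ad.concat_channels(skip, d))
        return self.outc(d)

    # -- full forward ------------------------------------------------------

    def forward(self, images: np.ndarray, valid: np.ndarray | None = None) -> Prediction:
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 3:
            images = images[None]
        n, _, h, w = images.shape
        levels, attended = self.encode(Tensor(images))
        logits = self.decode(levels, attended)
        probs = ad.softmax_channel(logits)
        label_map = probs.data.argmax(axis=1).astype(np.uint8)

        selection = None
        cp_logits_t = None
        if self.cfg.cp_enabled:
            margins = point_difficulty(probs.data)
            if valid is None:
                valid = np.ones((n, h, w), dtype=bool)
            counts = valid.reshape(n, -1).sum(axis=1)
            if (counts == 0).any():
                raise ValueError("an image in the batch has no valid pixels")
            k = min(effective_k(self.cfg, h, w), int(counts.min()))
            idx = np.stack([select_topk(margins[i], valid[i], k) for i in range(n)])
            src_pool = attended if self.cfg.cp_after_eca else levels
            source = src_pool[self.cfg.cp_source_level - 1]
            feats = ad.gather_pixels(ad.upsample_bilinear(source, h, w), idx)
            scores = ad.gather_pixels(probs, idx)
            flat = ad.reshape(ad.concat_channels(
                ad.reshape(feats, (n * k, -1, 1, 1)),
                ad.reshape(scores, (n * k, -1, 1, 1))), (n * k, -1))
            cp_logits_t = ad.reshape(self.cp_head(flat), (n, k, self.cfg.n_classes))
            mrows = np.take_along_axis(margins.reshape(n, -1), idx, axis=1)
            selection = PointSelection(
                indices=idx, margins=mrows,
                features=feats.data, master_scores=scores.data)
            cp_labels = cp_logits_t.data.argmax(axis=2).astype(np.uint8)
            flat_map = label_map.reshape(n, -1)
            np.put_along_axis(flat_map, idx, cp_labels, axis=1)
            label_map = flat_map.reshape(n, h, w)

        return Prediction(
            master_logits=logits.data, master_probs=probs.data,
            label_map=label_map, selection=selection,
            cp_logits=None if cp_logits_t is None else cp_logits_t.data,
            probs_t=probs, cp_logits_t=cp_logits_t)

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))
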