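"""U-net for binary lumen segmentation of 2D axial slices.

The network is the classic encoder–decoder with skip connections: each
contracting level applies two 3×3 convolutions + ReLU then 2×2 max pooling,
halving the spatial size and doubling the feature channels; the expansive
path mirrors it with 2×2 transposed convolutions and concatenates the
same-level encoder features; a final 1×1 convolution + sigmoid produces a
per-pixel lumen probability. Convolutions use same padding so a 512×512
input yields a 512×512 mask. Training minimizes binary cross-entropy with
Adam.

Also houses the training-mask preparation steps: Gaussian smoothing of hand
masks (2.0 μm kernel), contour interpolation between sparse z-slices via
signed-distance transforms, and the seeded 80/20 train/validation split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import nn

__all__ = [
    "UNetSpec",
    "TrainSpec",
    "UNet",
    "build_unet",
    "train",
    "predict",
    "predict_padded",
    "threshold",
    "split_train_val",
    "preprocess_mask",
    "interpolate_contours",
    "save_model",
    "load_model",
]


@dataclass
class UNetSpec:
    """Architecture hyperparameters.

    ``input_size`` A must be a power of two divisible by 2**depth; the
    full-scale configuration is A=512, depth 4, 64 base features; the
    reduced desk-scale profile is A=128, depth 3, 8 base features.
    """

    input_size: int = 512
    in_channels: int = 1
    depth: int = 4
    base_features: int = 64

    def __post_init__(self) -> None:
        a = self.input_size
        if a < 2 or (a & (a - 1)) != 0:
            raise ValueError(f"input_size must be a power of two, got {a}")
        if self.depth < 1 or self.base_features < 1 or self.in_channels < 1:
            raise ValueError("depth, base_features and in_channels must be positive")
        if a % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {a} not divisible by 2^depth = {2**self.depth}"
            )

    @classmethod
    def reduced(cls) -> "UNetSpec":
        """Desk-scale profile: 128×128 input, depth 3, 8 base features."""
        return cls(input_size=128, depth=3, base_features=8)


@dataclass
class TrainSpec:
    """Training hyperparameters; loss is binary cross-entropy, optimizer Adam."""

    epochs: int = 40
    batch_size: int = 8
    learning_rate: float = 1e-3
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training hyperparameters")


class _DoubleConv:
    """Two 3×3 conv + ReLU blocks (one U-net level)."""

    def __init__(self, c_in, c_out, rng):
        self.layers = [
            nn.Conv2d(c_in, c_out, 3, rng),
            nn.ReLU(),
            nn.Conv2d(c_out, c_out, 3, rng),
            nn.ReLU(),
        ]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, g, need_dx=True):
        for l in reversed(self.layers[1:]):
            g = l.backward(g)
        return self.layers[0].backward(g, need_dx=need_dx)


class UNet:
    """Encoder–decoder with skip connections; ``forward`` returns logits."""

    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        f, d = spec.base_features, spec.depth
        self.enc = []
        c = spec.in_channels
        for j in range(d):
            self.enc.append(_DoubleConv(c, f * 2**j, rng))
            c = f * 2**j
        self.pools = [nn.MaxPool2() for _ in range(d)]
        self.bottleneck = _DoubleConv(f * 2 ** (d - 1), f * 2**d, rng)
        self.ups = []
        self.dec = []
        for j in reversed(range(d)):
            self.ups.append(nn.UpConv2(f * 2 ** (j + 1), f * 2**j, rng))
            self.dec.append(_DoubleConv(f * 2 ** (j + 1), f * 2**j, rng))
        self.head = nn.Conv2d(f, 1, 1, rng)
        self._skip_channels = None

    def params(self):
        ps = []
        for block in [*self.enc, self.bottleneck, *self.ups, *self.dec, self.head]:
            ps.extend(block.params())
        return ps

    def cast(self, dtype) -> None:
        """Convert all parameters in place (float64 used by gradient tests)."""
        for block in [*self.enc, self.bottleneck, *self.ups, *self.dec, self.head]:
            if hasattr(block, "cast"):
                block.cast(dtype)
            elif hasattr(block, "layers"):
                for l in block.layers:
                    if hasattr(l, "cast"):
                        l.cast(dtype)

    def level_ledger(self) -> list[dict]:
        """Per-level (channels, spatial size) of the contracting path.

        Level j in 1..depth has base_features·2^j channels at spatial size
        A/2^j — the doubling/halving contract of the architecture.
        """
        a, f = self.spec.input_size, self.spec.base_features
        return [
            {"level": j, "channels": f * 2**j, "spatial": a // 2**j}
            for j in range(1, self.spec.depth + 1)
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = [s.shape[-1] for s in skips]
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([skip, x], axis=-1)
            x = dec.forward(x)
        return self.head.forward(x)

    def backward(self, g: np.ndarray) -> None:
        g = self.head.backward(g)
        g_skips = []
        for up, dec, c_skip in zip(
            reversed(self.ups), reversed(self.dec), self._skip_channels
        ):
            g = dec.backward(g)
            g_skip, g = g[..., :c_skip], g[..., c_skip:]
            g_skips.append(g_skip)
            g = up.backward(g)
        g = self.bottleneck.backward(g)
        for block, pool, g_skip in zip(
            reversed(self.enc), reversed(self.pools), reversed(g_skips)
        ):
            g = pool.backward(g)
            g = g + g_skip
            g = block.backward(g, need_dx=block is not self.enc[0])


def build_unet(spec: UNetSpec, seed: int = 0) -> UNet:
    """Construct a U-net with He-initialized weights from ``seed``."""
    return UNet(spec, seed=seed)


# ---------------------------------------------------------------------------
# training and inference


def _as_float01(images: np.ndarray) -> np.ndarray:
    """Normalize 8-bit input to [0, 1] float32; pass float input through."""
    images = np.asarray(images)
    if images.dtype == np.uint8:
        return images.astype(np.float32) / 255.0
    images = images.astype(np.float32, copy=False)
    if images.size and images.max() > 1.0 + 1e-6:
        images = images / 255.0
    return images


def train(
    model: UNet,
    images: np.ndarray,
    masks: np.ndarray,
    spec: TrainSpec,
) -> tuple[UNet, list[float]]:
    """Train in place; returns the model and the per-epoch mean loss history.

    ``images``: (n, A, A) grayscale, 8-bit or [0, 1] float; ``masks``:
    (n, A, A) binary. Shuffling and batching are seeded from ``spec.seed``.
    """
    images = _as_float01(images)
    masks = np.asarray(masks)
    if images.shape[0] != masks.shape[0]:
        raise ValueError(
            f"{images.shape[0]} images but {masks.shape[0]} masks"
        )
    if images.shape[1:] != masks.shape[1:]:
        raise ValueError("image and mask shapes differ")
    a = model.spec.input_size
    if images.ndim != 3 or images.shape[1:] != (a, a):
        raise ValueError(
            f"expected (n, {a}, {a}) input for this model, got {images.shape}"
        )
    y = (masks > 0).astype(np.float32)[..., None]
    x = images[..., None]
    rng = np.random.default_rng(spec.seed)
    opt = nn.Adam(model.params(), lr=spec.learning_rate)
    history: list[float] = []
    n = x.shape[0]
    for _epoch in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            logits = model.forward(x[idx])
            loss, grad = nn.bce_with_logits(logits, y[idx])
            model.backward(grad)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def predict(model: UNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel lumen probability for a 2D slice or an (m, H, W) stack.

    The network is fully convolutional: any H, W divisible by 2^depth is
    accepted. Deterministic given fixed weights.
    """
    image = _as_float01(image)
    squeeze = image.ndim == 2
    if squeeze:
        image = image[None]
    if image.ndim != 3:
        raise ValueError(f"expected a 2D slice or (m, H, W) stack, got {image.shape}")
    div = 2**model.spec.depth
    h, w = image.shape[1:]
    if h % div or w % div:
        raise ValueError(f"spatial size {(h, w)} not divisible by 2^depth = {div}")
    probs = []
    for start in range(0, image.shape[0], 8):
        logits = model.forward(image[start : start + 8, ..., None])
        probs.append(nn.sigmoid(logits)[..., 0])
    out = np.concatenate(probs)
    return out[0] if squeeze else out


def predict_padded(model: UNet, image: np.ndarray, border: int = 24) -> np.ndarray:
    """Probability maps for slices that may be smaller than the training field.

    Reflect-pads each slice by ``border`` pixels (so structures touching the
    frame edge get the background context the network was trained with),
    rounds the padded size up to a multiple of 2^depth, predicts, and crops
    back to the input geometry.
    """
    image = np.asarray(image)
    squeeze = image.ndim == 2
    if squeeze:
        image = image[None]
    div = 2**model.spec.depth
    h, w = image.shape[1:]
    ph = border + (-(h + 2 * border)) % div
    pw = border + (-(w + 2 * border)) % div
    padded = np.pad(image, ((0, 0), (border, ph), (border, pw)), mode="reflect")
    prob = predict(model, padded)[:, border : border + h, border : border + w]
    return prob[0] if squeeze else prob


def threshold(prob: np.ndarray, tau: float = 0.5) -> np.ndarray:
    """Binarize a probability map: mask = prob ≥ τ."""
    return np.asarray(prob) >= tau


# ---------------------------------------------------------------------------
# training-mask preparation


def preprocess_mask(mask: np.ndarray, pixel_pitch: float) -> np.ndarray:
    """Smooth a binary hand mask with a 2.0 μm Gaussian and re-binarize.

    σ = 2.0 μm / pixel_pitch in pixels; the result is thresholded at 0.5 so
    large regions keep their boundary (a symmetric blur preserves the 0.5
    crossing of a step) while single-pixel specks vanish.
    """
    if pixel_pitch <= 0:
        raise ValueError("pixel pitch must be positive")
    mask = np.asarray(mask)
    if set(np.unique(mask)) - {0, 1, True, False}:
        raise ValueError("preprocess_mask expects a binary mask")
    sigma = 2.0 / pixel_pitch
    smoothed = ndimage.gaussian_filter(mask.astype(np.float32), sigma=sigma)
    return smoothed >= 0.5


_BIG = 1e6


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Positive outside, negative inside; ±large for empty/full masks."""
    mask = mask.astype(bool)
    if not mask.any():
        return np.full(mask.shape, _BIG, dtype=np.float32)
    if mask.all():
        return np.full(mask.shape, -_BIG, dtype=np.float32)
    outside = ndimage.distance_transform_edt(~mask)
    inside = ndimage.distance_transform_edt(mask)
    return (outside - inside).astype(np.float32)


def interpolate_contours(
    slices: Sequence[np.ndarray], z_positions: Sequence[int]
) -> np.ndarray:
    """Fill unsegmented slices between sparse hand-segmented ones.

    Intermediate slices are obtained by linearly interpolating the signed
    distance transforms of the two flanking segmented slices and thresholding
    at zero. Returns a dense binary stack spanning
    [min(z_positions), max(z_positions)] inclusive.
    """
    if len(slices) < 2:
        raise ValueError("need at least 2 segmented slices to interpolate")
    if len(slices) != len(z_positions):
        raise ValueError("slices and z_positions length mismatch")
    order = np.argsort(z_positions)
    zs = [int(z_positions[i]) for i in order]
    ms = [np.asarray(slices[i]).astype(bool) for i in order]
    if len(set(zs)) != len(zs):
        raise ValueError("duplicate z positions")
    if len({m.shape for m in ms}) != 1:
        raise ValueError("all slices must share one shape")
    z0, z1 = zs[0], zs[-1]
    out = np.zeros((z1 - z0 + 1, *ms[0].shape), dtype=bool)
    for (za, ma), (zb, mb) in zip(zip(zs, ms), zip(zs[1:], ms[1:])):
        sda, sdb = _signed_distance(ma), _signed_distance(mb)
        for z in range(za, zb + 1):
            w = (z - za) / (zb - za)
            out[z - z0] = (1.0 - w) * sda + w * sdb < 0
    return out


def split_train_val(
    pairs: Sequence, fraction: float = 0.8, seed: int = 0
) -> tuple[list, list]:
    """Seeded shuffle into disjoint, exhaustive train/validation subsets.

    |train| = round(fraction × total), clamped so neither side is empty.
    """
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 pairs to split")
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    train_set = [pairs[i] for i in order[:n_train]]
    val_set = [pairs[i] for i in order[n_train:]]
    return train_set, val_set


# ---------------------------------------------------------------------------
# persistence


def save_model(model: UNet, directory: str | Path) -> None:
    """Store weights (.npz) plus a JSON of the architecture spec."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": p for i, (p, _g) in enumerate(model.params())}
    np.savez(directory / "weights.npz", **arrays)
    (directory / "unet_spec.json").write_text(json.dumps(asdict(model.spec), indent=2))


def load_model(directory: str | Path) -> UNet:
    directory = Path(directory)
    spec = UNetSpec(**json.loads((directory / "unet_spec.json").read_text()))
    model = UNet(spec, seed=0)
    with np.load(directory / "weights.npz") as data:
        for i, (p, _g) in enumerate(model.params()):
            p[...] = data[f"p{i}"]
    return model
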