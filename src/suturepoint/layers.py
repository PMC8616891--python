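"""The suture detector: U-Net backbone plus the two differentiable heatmap layers.

The network maps a 3-channel RGB image to a single-channel likelihood map
through a standard U-Net (two 3x3 conv + ReLU per level, 2x max-pool /
transposed-conv resampling, skip connections, final 1x1 conv + sigmoid).
Two custom layers follow the sigmoid:

* a differentiable Gaussian filter of spread ``sigma2`` (output stage 1),
  which encourages a smooth likelihood distribution around each predicted
  location, and
* a convolutional 2-D spatial soft-argmax (output stage 2): each pixel is
  replaced by the softmax-weighted average of its ``window x window``
  neighbourhood (stride 1, zero padding), which acts as a differentiable
  local non-maximum suppression — pixels that are not local maxima are
  pulled towards zero relative to their dominating neighbours.

Both stages are supervised during training; see :mod:`suturepoint.losses`.
All tensors are channels-first ``(N, C, H, W)`` float64 numpy arrays.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "ModelConfig",
    "StageOutputs",
    "Detector",
    "build_detector",
    "gaussian_kernel_2d",
    "gaussian_filter_layer",
    "conv_soft_argmax_layer",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Detector hyper-parameters.

    ``input_height`` and ``input_width`` must be divisible by
    ``2 ** (depth - 1)`` so that every encoder level can be pooled.
    ``sigma2`` is the spread (px) of the differentiable Gaussian layer,
    ``softargmax_window`` the (odd) local NMS window and
    ``softargmax_temperature`` its softmax temperature. ``variant`` selects
    which stage-2 supervision the losses use (1: heatmap, 2: binary mask).
    """

    input_height: int = 288
    input_width: int = 512
    input_channels: int = 3
    depth: int = 5
    base_filters: int = 64
    sigma2: float = 1.0
    softargmax_window: int = 3
    softargmax_temperature: float = 1.0
    variant: int = 1

    def __post_init__(self):
        factor = 2 ** (self.depth - 1)
        if self.input_height % factor or self.input_width % factor:
            raise ValueError(
                f"input size {self.input_height}x{self.input_width} not divisible "
                f"by 2**(depth-1) = {factor}")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.softargmax_window % 2 == 0:
            raise ValueError("softargmax_window must be odd")
        if self.softargmax_temperature <= 0:
            raise ValueError("softargmax_temperature must be positive")
        if self.variant not in (1, 2):
            raise ValueError("variant must be 1 or 2")


class StageOutputs(NamedTuple):
    """The two supervised outputs of a forward pass (values in [0, 1])."""

    stage1: Tensor  # Gaussian-filtered sigmoid map, (N, 1, H, W)
    stage2: Tensor  # after convolutional soft-argmax, (N, 1, H, W)


# ---------------------------------------------------------------------------
# parameterised building blocks
# ---------------------------------------------------------------------------

class Conv2d:
    """k x k convolution, stride 1, 'same' zero padding, via unfold + matmul."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator):
        fan_in = cin * ksize * ksize
        scale = math.sqrt(2.0 / fan_in)  # He init for the ReLU trunk
        self.weight = ag.parameter(rng.normal(0.0, scale, size=(cout, fan_in)))
        self.bias = ag.parameter(np.zeros((cout, 1)))
        self.ksize = ksize
        self.cin = cin
        self.cout = cout

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {c}")
        if self.ksize == 1:
            col = x.reshape(n, c, h * w)
        else:
            col = ag.unfold(x, self.ksize, (self.ksize - 1) // 2)
            col = col.reshape(n, c * self.ksize * self.ksize, h * w)
        y = ag.matmul(self.weight, col) + self.bias
        return y.reshape(n, self.cout, h, w)

    def parameters(self):
        return [self.weight, self.bias]


class ConvTranspose2x2:
    """2x2 transposed convolution with stride 2 (learned 2x upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / cin)
        self.weight = ag.parameter(rng.normal(0.0, scale, size=(cout * 4, cin)))
        self.bias = ag.parameter(np.zeros((cout * 4, 1)))
        self.cin = cin
        self.cout = cout

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        y = ag.matmul(self.weight, x.reshape(n, c, h * w)) + self.bias
        y = y.reshape(n, self.cout, 2, 2, h, w)
        y = y.transpose(0, 1, 4, 2, 5, 3)  # (N, Cout, H, 2, W, 2)
        return y.reshape(n, self.cout, 2 * h, 2 * w)

    def parameters(self):
        return [self.weight, self.bias]


class DoubleConv:
    """Two 3x3 convolutions, each followed by ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, 3, rng)
        self.conv2 = Conv2d(cout, cout, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.relu(self.conv2(ag.relu(self.conv1(x))))

    def parameters(self):
        return self.conv1.parameters() + self.conv2.parameters()


class UNet:
    """Encoder-decoder with skip connections and a sigmoid single-channel head."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        d, f = config.depth, config.base_filters
        self.encoders = [DoubleConv(config.input_channels, f, rng)]
        for i in range(1, d):
            self.encoders.append(DoubleConv(f * 2 ** (i - 1), f * 2 ** i, rng))
        self.upsamples = []
        self.decoders = []
        for i in range(d - 1, 0, -1):
            self.upsamples.append(ConvTranspose2x2(f * 2 ** i, f * 2 ** (i - 1), rng))
            self.decoders.append(DoubleConv(f * 2 ** i, f * 2 ** (i - 1), rng))
        self.head = Conv2d(f, 1, 1, rng)
        # neutral head start: zero weights and a negative bias put the sigmoid
        # output at a flat map near the background rate.  on extremely sparse
        # targets a random 0.5-level start either collapses to all-background
        # (saturating the sigmoid) or stalls, depending on the seed; the
        # neutral start removes that seed dependence
        self.head.weight.data[:] = 0.0
        self.head.bias.data[:] = -2.0

    def __call__(self, x: Tensor) -> Tensor:
        skips = []
        for enc in self.encoders[:-1]:
            x = enc(x)
            skips.append(x)
            x = ag.maxpool2x2(x)
        x = self.encoders[-1](x)
        for up, dec, skip in zip(self.upsamples, self.decoders, reversed(skips)):
            x = dec(ag.concat([skip, up(x)], axis=1))
        return ag.sigmoid(self.head(x))

    def parameters(self):
        params = []
        for block in self.encoders + self.upsamples + self.decoders + [self.head]:
            params.extend(block.parameters())
        return params


# ---------------------------------------------------------------------------
# the two differentiable heatmap layers
# ---------------------------------------------------------------------------

def gaussian_kernel_2d(sigma: float) -> np.ndarray:
    """Isotropic 2-D Gaussian kernel, truncated at 3 sigma, sum-normalised.

    Kernel size is ``2 * ceil(3 sigma) + 1``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    radius = int(math.ceil(3.0 * sigma))
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma ** 2))
    return g / g.sum()


def gaussian_filter_layer(x: Tensor | np.ndarray, sigma2: float) -> Tensor:
    """Convolve each channel with a unit-mass Gaussian (reflect padding).

    Differentiable; a sum-normalised kernel with reflect padding preserves
    constants and (on interior-supported inputs) total mass, so [0, 1]
    inputs stay in [0, 1].
    """
    x = ag.tensor(x) if not isinstance(x, Tensor) else x
    kernel = gaussian_kernel_2d(sigma2)
    k = kernel.shape[0]
    n, c, h, w = x.shape
    col = ag.unfold(x, k, (k - 1) // 2, pad_mode="reflect")  # (N, C, k*k, H*W)
    weighted = col * ag.tensor(kernel.reshape(1, 1, k * k, 1))
    return weighted.sum(axis=2).reshape(n, c, h, w)


def conv_soft_argmax_layer(x: Tensor | np.ndarray, window: int = 3,
                           temperature: float = 1.0) -> Tensor:
    """Convolutional 2-D spatial soft-argmax (local NMS), stride 1.

    Each output pixel is ``sum_q w_q x_q`` over its ``window x window``
    zero-padded neighbourhood with ``w = softmax(x / temperature)``, so the
    output never exceeds the local window maximum and spatial size is
    preserved.
    """
    if window % 2 == 0:
        raise ValueError(f"soft-argmax window must be odd, got {window}")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    x = ag.tensor(x) if not isinstance(x, Tensor) else x
    n, c, h, w = x.shape
    col = ag.unfold(x, window, (window - 1) // 2)  # zero padding
    weights = ag.softmax(col * ag.tensor(1.0 / temperature), axis=2)
    return (weights * col).sum(axis=2).reshape(n, c, h, w)


# ---------------------------------------------------------------------------
# the assembled detector
# ---------------------------------------------------------------------------

class Detector:
    """U-Net followed by the Gaussian filter and conv soft-argmax layers."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.unet = UNet(config, np.random.default_rng(seed))

    def parameters(self) -> list[Tensor]:
        return self.unet.parameters()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, images: np.ndarray | Tensor) -> StageOutputs:
        """Run a batch of RGB images (N, 3, H, W) through both output stages."""
        x = images if isinstance(images, Tensor) else ag.tensor(np.asarray(images))
        cfg = self.config
        if x.ndim != 4 or x.shape[1] != cfg.input_channels \
                or x.shape[2] != cfg.input_height or x.shape[3] != cfg.input_width:
            raise ValueError(
                f"expected images of shape (N, {cfg.input_channels}, "
                f"{cfg.input_height}, {cfg.input_width}), got {x.shape}")
        raw = self.unet(x)
        stage1 = gaussian_filter_layer(raw, cfg.sigma2)
        stage2 = conv_soft_argmax_layer(stage1, cfg.softargmax_window,
                                        cfg.softargmax_temperature)
        return StageOutputs(stage1, stage2)

    __call__ = forward

    # -- persistence ---------------------------------------------------------
    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state does not match the detector's parameters")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {arr.shape}")
            p.data = np.asarray(arr, dtype=np.float64).copy()


def build_detector(config: ModelConfig, seed: int = 0) -> Detector:
    """Construct a seeded detector from a validated configuration."""
    return Detector(config, seed=seed)


def save_checkpoint(detector: Detector, path, manifest_extra: dict | None = None) -> None:
    """Save parameters (.npz) plus a JSON manifest with the config next to it."""
    from pathlib import Path

    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    state = detector.state_dict()
    np.savez(path, **{f"p{i}": arr for i, arr in enumerate(state)})
    manifest = {"config": asdict(detector.config),
                "n_parameters": detector.n_parameters()}
    manifest.update(manifest_extra or {})
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path) -> Detector:
    """Rebuild a detector from :func:`save_checkpoint` output."""
    from pathlib import Path

    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    manifest = json.loads(path.with_suffix(".json").read_text())
    detector = Detector(ModelConfig(**manifest["config"]))
    with np.load(path) as data:
        state = [data[f"p{i}"] for i in range(len(data.files))]
    detector.load_state_dict(state)
    return detector
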