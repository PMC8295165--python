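"""Capsule layers and full encoder-decoder segmentation networks.

Two architectures are provided:

* :class:`CapsuleUNet` — a U-Net-shaped matrix-capsule network.  Every
  "pixel" of a feature grid holds one capsule per *capsule type* (the
  analogue of a feature-map channel), each capsule consisting of a pose
  matrix and an appearance matrix.  Layers couple child capsules inside a
  small spatial window to parent capsules by locally constrained routing;
  stride-2 windows downsample, transposed (input-dilated) windows upsample,
  and skip connections concatenate capsule types across the encoder-decoder
  mirror.  The output layer turns the final ``classes`` capsule types into
  per-class activations via the product of the pose and appearance
  Frobenius norms.

* :class:`UNetRes` — a parameter-matched residual-block U-Net baseline
  producing per-pixel class probabilities.

Grids are ``[height, width, types, side, side]``; images are ``[H, W]``
single-channel arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor, astensor
from .capsule_math import (PoseTreatment, RoutingSpec, _flat_activate,
                           normalize_pose, route_dual, route_dynamic, squash)
from .nn import Module, count_parameters
from .window_ops import (capsule_transform, window_agreement,
                         window_weighted_sum)

__all__ = [
    "CapsuleGrid", "ArchitectureConfig", "UNetResConfig",
    "initial_embedding", "conv_capsule_layer", "concat_types",
    "class_activations", "build_capsule_unet", "build_unet_res",
    "CapsuleUNet", "UNetRes", "count_parameters",
    "capsule_presets", "matched_unet_config", "matched_pairs",
]


# --------------------------------------------------------------------------
# containers and configuration
# --------------------------------------------------------------------------

@dataclass
class CapsuleGrid:
    """Spatial grid of matrix capsules: pose ``[H,W,T,pP,pP]`` and
    appearance ``[H,W,T,pA,pA]`` sharing height, width and type count."""

    pose: Tensor
    appearance: Tensor

    def __post_init__(self):
        self.pose = astensor(self.pose)
        self.appearance = astensor(self.appearance)
        if self.pose.ndim != 5 or self.appearance.ndim != 5:
            raise ValueError("pose and appearance must be 5-dimensional")
        if self.pose.shape[:3] != self.appearance.shape[:3]:
            raise ValueError(
                f"pose grid {self.pose.shape[:3]} and appearance grid "
                f"{self.appearance.shape[:3]} disagree on height/width/types")

    @property
    def height(self) -> int:
        return self.pose.shape[0]

    @property
    def width(self) -> int:
        return self.pose.shape[1]

    @property
    def types(self) -> int:
        return self.pose.shape[2]


@dataclass(frozen=True)
class ArchitectureConfig:
    """All tunable axes of the capsule network.

    ``shape`` lists the capsule-type count per encoder level (the decoder
    mirrors it); the optimized network doubles types per level:
    ``(3, 6, 12, 24, 48)`` with a 5x5 routing window, 4x4 pose and 5x5
    appearance matrices and dual routing with three iterations.
    """

    shape: tuple[int, ...] = (3, 6, 12, 24, 48)
    layers_per_level: int = 2
    window: int = 5
    pose_size: int = 4
    appearance_size: int = 5
    routing: RoutingSpec = field(default_factory=RoutingSpec)
    pose_treatment: PoseTreatment = field(default_factory=PoseTreatment)
    classes: int = 3
    initial_features: int | None = None   # default: shape[0] * appearance_size**2
    initial_kernel: int = 5
    matrix_bias: bool = False             # full-matrix appearance bias variant

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if len(self.shape) < 2:
            raise ValueError("shape: need at least two encoder levels")
        if any(s < 1 for s in self.shape):
            raise ValueError("shape: all capsule-type counts must be >= 1")
        if self.layers_per_level < 1:
            raise ValueError("layers_per_level must be >= 1")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be a positive odd integer")
        if self.pose_size < 1 or self.appearance_size < 1:
            raise ValueError("pose_size and appearance_size must be >= 1")
        if self.classes < 1:
            raise ValueError("classes must be >= 1")

    @property
    def levels(self) -> int:
        return len(self.shape)

    def features(self) -> int:
        if self.initial_features is not None:
            return self.initial_features
        return self.shape[0] * self.appearance_size ** 2


@dataclass(frozen=True)
class UNetResConfig:
    """Residual U-Net baseline: ``round(base_channels * 2**level)`` channels
    per level (non-integer bases allow fine-grained parameter budgets)."""

    base_channels: float = 16
    depth: int = 4
    classes: int = 3

    def __post_init__(self):
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.classes < 1:
            raise ValueError("classes must be >= 1")

    def channels(self) -> list[int]:
        return [max(1, round(self.base_channels * 2 ** l)) for l in range(self.depth)]


# --------------------------------------------------------------------------
# functional capsule operations
# --------------------------------------------------------------------------

def _coord_offsets(h: int, w: int, p: int, scale: float, dtype) -> np.ndarray:
    """Offset array adding scaled normalized (row, col) coordinates of each
    grid position to the first two entries of the last pose column."""
    rows = np.arange(h, dtype=dtype) / max(h - 1, 1)
    cols = np.arange(w, dtype=dtype) / max(w - 1, 1)
    off = np.zeros((h, w, 1, 1, p, p), dtype=dtype)
    off[:, :, 0, 0, 0, -1] = scale * rows[:, None]
    off[:, :, 0, 0, 1, -1] = scale * cols[None, :]
    return off


def _transform_children(grid: CapsuleGrid,
                        pose_w: Tensor, app_w: Tensor, app_b: Tensor,
                        treatment: PoseTreatment):
    """Per-position child transforms shared across window offsets.

    Returns ``(pose_hat, app_hat)`` of shape ``[H, W, Ti, To, side, side]``
    with pose treatment (transform/pose normalization + scaled coordinate
    addition at each child's own grid position) already applied.
    """
    p = grid.pose.shape[-1]
    if treatment.normalizes_transform:
        pose_w = normalize_pose(pose_w)
    pose_hat = capsule_transform(grid.pose, pose_w)
    if treatment.normalizes_pose:
        pose_hat = normalize_pose(pose_hat)
    if treatment.adds_coordinates and treatment.coord_scale != 0.0:
        off = _coord_offsets(grid.height, grid.width, p,
                             treatment.coord_scale, pose_hat.dtype)
        pose_hat = pose_hat + off
    # (A + b) W = A W + b (1 W): the bias term is the transform's column
    # sums scaled by the scalar bias, broadcast over rows
    app_hat = capsule_transform(grid.appearance, app_w)
    col_sums = ad.tsum(app_w, axis=-2, keepdims=True)     # [Ti,To,1,pA]
    app_hat = app_hat + _bias_term(app_b, app_w, col_sums)
    return pose_hat, app_hat


def _bias_term(app_b: Tensor, app_w: Tensor, col_sums: Tensor) -> Tensor:
    if app_b.shape[-2:] == (1, 1):        # scalar bias per (child, parent) pair
        return app_b * col_sums
    # full-matrix bias: (B W) shared across positions
    return ad.matmul(app_b, app_w)


def _route_windows(pose_hat: Tensor, app_hat: Tensor,
                   spec: RoutingSpec, stride: int, transposed: bool):
    """Unfold transformed children into routing windows and route them.

    Pose and appearance streams are flattened into one child vector per
    (position, type) pair so padding, window extraction and the routing
    contractions each run once; the stream is split again for the
    Psquash/squash nonlinearities inside the routing loop (dual) or squashed
    whole (dynamic).
    """
    h, w, ti, to, p = pose_hat.shape[:5]
    q = app_hat.shape[-1]
    d = p * p + q * q
    flat = ad.concatenate([ad.reshape(pose_hat, (h, w, ti, to, p * p)),
                           ad.reshape(app_hat, (h, w, ti, to, q * q))], axis=-1)
    k = spec.window
    if transposed:
        flat = ad.dilate2d(flat, 2)
        stride = 1
    padded = ad.pad2d(flat, (k - 1) // 2)
    n_children = k * k * ti
    pose_entries = p * p if spec.algorithm == "dual" else None

    # First iteration: coefficients are softmax of zero logits, i.e. exactly
    # uniform, so the weighted sum reduces to a window sum over the compact
    # tensor.  Later iterations need child-specific coefficients; their
    # contractions run as fused window kernels against the compact padded
    # tensor, so the k^2-times-larger windowed child tensor never exists.
    s = ad.shiftsum2d(ad.tsum(padded, axis=2), k, stride) * (1.0 / to)
    parents = _flat_activate(s, pose_entries)              # [Ho,Wo,To,D]
    ho, wo = parents.shape[:2]
    logits = None
    coeffs = None
    for _ in range(spec.iterations - 1):
        agree = window_agreement(padded, parents, k, stride)
        logits = agree if logits is None else logits + agree
        coeffs = ad.softmax(logits, axis=-1)               # [Ho,Wo,k,k,Ti,To]
        s = window_weighted_sum(padded, coeffs, stride)
        parents = _flat_activate(s, pose_entries)
    if coeffs is None:
        coeffs = Tensor(np.full((ho, wo, n_children, to), 1.0 / to,
                                dtype=parents.dtype))
    else:
        coeffs = ad.reshape(coeffs, (ho, wo, n_children, to))
    pose_out = ad.reshape(ad.narrow(parents, 0, p * p), (ho, wo, to, p, p))
    app_out = ad.reshape(ad.narrow(parents, p * p, d), (ho, wo, to, q, q))
    return CapsuleGrid(pose_out, app_out), coeffs


def conv_capsule_layer(grid: CapsuleGrid, pose_transforms, appearance_transforms,
                       appearance_bias, spec: RoutingSpec,
                       treatment: PoseTreatment | None = None,
                       stride: int | None = None,
                       transposed: bool = False) -> CapsuleGrid:
    """Locally constrained routing layer (functional form).

    For every output position the children are all capsules of all types in
    the ``window x window`` neighbourhood (same-padding; output size
    ``ceil(H / stride)``).  Transform banks are shared across positions and
    window offsets: ``pose_transforms [Ti,To,pP,pP]``,
    ``appearance_transforms [Ti,To,pA,pA]``, ``appearance_bias`` broadcastable
    to ``[Ti,To,1,1]``.  With ``transposed=True`` the layer is the stride-2
    transposed counterpart: each child contributes to a ``window x window``
    neighbourhood of parents and the spatial size doubles.
    """
    if treatment is None:
        treatment = PoseTreatment()
    stride = spec.stride if stride is None else stride
    if not transposed and min(grid.height, grid.width) + (spec.window - 1) < spec.window:
        raise ValueError("routing window larger than padded grid")
    pose_w = astensor(pose_transforms)
    app_w = astensor(appearance_transforms)
    app_b = astensor(appearance_bias)
    if app_b.ndim == 2:  # scalar bias per (child type, parent type) pair
        app_b = ad.reshape(app_b, app_b.shape + (1, 1))
    pose_hat, app_hat = _transform_children(grid, pose_w, app_w, app_b, treatment)
    out, _ = _route_windows(pose_hat, app_hat, spec, stride, transposed)
    return out


def upsample_capsule_layer(grid: CapsuleGrid, pose_transforms,
                           appearance_transforms, appearance_bias,
                           spec: RoutingSpec,
                           treatment: PoseTreatment | None = None) -> CapsuleGrid:
    """Transposed routing layer: spatial size doubles."""
    return conv_capsule_layer(grid, pose_transforms, appearance_transforms,
                              appearance_bias, spec, treatment, transposed=True)


def concat_types(a: CapsuleGrid, b: CapsuleGrid) -> CapsuleGrid:
    """Concatenate capsule types of two grids (``a``'s types first)."""
    if b.types == 0:
        return a
    if a.types == 0:
        return b
    if (a.height, a.width) != (b.height, b.width):
        raise ValueError(f"spatial sizes differ: {(a.height, a.width)} vs "
                         f"{(b.height, b.width)}")
    if a.pose.shape[3:] != b.pose.shape[3:] or \
            a.appearance.shape[3:] != b.appearance.shape[3:]:
        raise ValueError("matrix sizes differ between grids")
    return CapsuleGrid(ad.concatenate([a.pose, b.pose], axis=2),
                       ad.concatenate([a.appearance, b.appearance], axis=2))


def class_activations(grid: CapsuleGrid, classes: int | None = None) -> Tensor:
    """Per-pixel, per-class activation: product of the Frobenius norms of
    the pose and the appearance matrix of each class capsule."""
    if classes is not None and grid.types != classes:
        raise ValueError(f"grid has {grid.types} types, expected {classes} classes")
    eps = 1e-12
    pn = ad.sqrt(ad.tsum(ad.square(grid.pose), axis=(-2, -1)) + eps)
    an = ad.sqrt(ad.tsum(ad.square(grid.appearance), axis=(-2, -1)) + eps)
    return pn * an


# --------------------------------------------------------------------------
# capsule network modules
# --------------------------------------------------------------------------

class ConvCapsuleLayer(Module):
    """Learnable locally constrained routing layer."""

    def __init__(self, in_types: int, out_types: int, config: ArchitectureConfig,
                 stride: int = 1, transposed: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        p, q = config.pose_size, config.appearance_size
        self.in_types, self.out_types = in_types, out_types
        self.stride, self.transposed = stride, transposed
        self.spec = replace(config.routing, window=config.window, stride=stride)
        self.treatment = config.pose_treatment
        eye = np.eye(p, dtype=np.float32)
        self.pose_w = Parameter(
            (eye + 0.1 * rng.standard_normal((in_types, out_types, p, p)))
            .astype(np.float32))
        fan = q * in_types * config.window ** 2 / max(out_types, 1)
        std = float(np.clip(1.0 / np.sqrt(fan), 0.05, 1.0))
        self.app_w = Parameter(
            (std * rng.standard_normal((in_types, out_types, q, q)))
            .astype(np.float32))
        bias_shape = ((in_types, out_types, q, q) if config.matrix_bias
                      else (in_types, out_types, 1, 1))
        self.app_b = Parameter(np.zeros(bias_shape, dtype=np.float32))

    def forward(self, grid: CapsuleGrid) -> CapsuleGrid:
        if grid.types != self.in_types:
            raise ValueError(f"expected {self.in_types} input types, got {grid.types}")
        pose_hat, app_hat = _transform_children(
            grid, self.pose_w, self.app_w, self.app_b, self.treatment)
        out, _ = _route_windows(pose_hat, app_hat, self.spec,
                                self.stride, self.transposed)
        return out


class InitialEmbedding(Module):
    """Ordinary convolution forming the first capsule grid.

    The convolution produces ``initial_features = shape[0] * pA**2``
    rectified feature maps which are reshaped per pixel into the appearance
    matrices of the first ``shape[0]`` capsule types (then squashed to the
    sub-unit Frobenius ball); pose matrices start at the identity.
    """

    def __init__(self, config: ArchitectureConfig,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.config = config
        k = config.initial_kernel
        feats = config.features()
        std = np.sqrt(2.0 / (k * k))
        self.weight = Parameter(
            (std * rng.standard_normal((k, k, feats))).astype(np.float32))
        self.bias = Parameter(np.zeros(feats, dtype=np.float32))

    def forward(self, image) -> CapsuleGrid:
        t = astensor(image)
        if t.ndim != 2:
            raise ValueError(f"expected a single-channel [H, W] image, got "
                             f"shape {t.shape}")
        cfg = self.config
        k = cfg.initial_kernel
        win = ad.unfold2d(ad.pad2d(t, (k - 1) // 2), k, 1)
        feats = ad.relu(ad.einsum("hwij,ijf->hwf", win, self.weight) + self.bias)
        h, w = feats.shape[:2]
        t0, q, p = cfg.shape[0], cfg.appearance_size, cfg.pose_size
        n = cfg.features()
        need = t0 * q * q
        if n < need:   # zero-pad feature vector up to t0 * pA^2 entries
            feats = ad.concatenate(
                [feats, Tensor(np.zeros((h, w, need - n), dtype=feats.dtype))],
                axis=-1)
        elif n > need:  # truncate
            feats = feats[:, :, :need]
        appearance = squash(ad.reshape(feats, (h, w, t0, q, q)), axis=(-2, -1))
        pose = Tensor(np.broadcast_to(
            np.eye(p, dtype=appearance.dtype), (h, w, t0, p, p)).copy())
        return CapsuleGrid(pose, appearance)


def initial_embedding(image, config: ArchitectureConfig,
                      weight=None, bias=None,
                      rng: np.random.Generator | None = None) -> CapsuleGrid:
    """Functional form of :class:`InitialEmbedding` (optionally with given
    convolution weights)."""
    layer = InitialEmbedding(config, rng=rng)
    if weight is not None:
        layer.weight = Parameter(np.asarray(weight, dtype=np.float32))
    if bias is not None:
        layer.bias = Parameter(np.asarray(bias, dtype=np.float32))
    return layer(image)


class CapsuleUNet(Module):
    """Encoder-decoder matrix-capsule segmentation network.

    ``layers_per_level`` routing layers per level, stride-2 routing windows
    between levels, a mirrored decoder with transposed routing windows and
    skip concatenations, and a final routing layer onto ``classes`` capsule
    types whose Frobenius-norm products are the class activations.
    """

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        shape = config.shape
        self.embed = InitialEmbedding(config, rng=rng)
        self.encoder: list[list[ConvCapsuleLayer]] = []
        self.down: list[ConvCapsuleLayer] = []
        for lvl, types in enumerate(shape):
            block = []
            in_t = types
            for _ in range(config.layers_per_level):
                block.append(ConvCapsuleLayer(in_t, types, config, rng=rng))
                in_t = types
            self.encoder.append(block)
            if lvl < len(shape) - 1:
                self.down.append(
                    ConvCapsuleLayer(types, shape[lvl + 1], config, stride=2, rng=rng))
        self.up: list[ConvCapsuleLayer] = []
        self.decoder: list[list[ConvCapsuleLayer]] = []
        for lvl in range(len(shape) - 2, -1, -1):
            self.up.append(ConvCapsuleLayer(shape[lvl + 1], shape[lvl], config,
                                            transposed=True, rng=rng))
            block = []
            in_t = 2 * shape[lvl]   # skip concatenation doubles the types
            for _ in range(config.layers_per_level):
                block.append(ConvCapsuleLayer(in_t, shape[lvl], config, rng=rng))
                in_t = shape[lvl]
            self.decoder.append(block)
        self.head = ConvCapsuleLayer(shape[0], config.classes, config, rng=rng)

    def _check_size(self, h: int, w: int) -> None:
        div = 2 ** (len(self.config.shape) - 1)
        if h % div or w % div:
            raise ValueError(
                f"input size {(h, w)} must be divisible by {div} "
                f"(2**(levels-1)) for this architecture")

    def forward(self, image) -> Tensor:
        """Image ``[H, W]`` to activation map ``[H, W, classes]``."""
        t = astensor(image)
        self._check_size(*t.shape[:2])
        grid = self.embed(t)
        skips = []
        for lvl, block in enumerate(self.encoder):
            for layer in block:
                grid = layer(grid)
            if lvl < len(self.encoder) - 1:
                skips.append(grid)
                grid = self.down[lvl](grid)
        for i, block in enumerate(self.decoder):
            grid = self.up[i](grid)
            grid = concat_types(grid, skips.pop())
            for layer in block:
                grid = layer(grid)
        grid = self.head(grid)
        return class_activations(grid, self.config.classes)

    def predict(self, image) -> np.ndarray:
        """Per-pixel argmax class labels (inference mode, no graph)."""
        with ad.no_grad():
            acts = self.forward(image)
        return np.argmax(acts.data, axis=-1).astype(np.int64)


def build_capsule_unet(config: ArchitectureConfig, seed: int = 0) -> CapsuleUNet:
    return CapsuleUNet(config, seed=seed)


# --------------------------------------------------------------------------
# residual U-Net baseline
# --------------------------------------------------------------------------

class Conv2d(Module):
    def __init__(self, cin, cout, kernel, rng, stride=1):
        std = np.sqrt(2.0 / (kernel * kernel * cin))
        self.weight = Parameter(
            (std * rng.standard_normal((kernel, kernel, cin, cout)))
            .astype(np.float32))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))
        self.kernel, self.stride = kernel, stride

    def forward(self, x):  # x: [H, W, Cin]
        k = self.kernel
        win = ad.unfold2d(ad.pad2d(x, (k - 1) // 2), k, self.stride)
        return ad.einsum("hwijc,ijcf->hwf", win, self.weight) + self.bias


class ChannelNorm(Module):
    """Per-channel spatial normalization with learnable scale and shift."""

    def __init__(self, channels):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x):
        mu = ad.tmean(x, axis=(0, 1), keepdims=True)
        var = ad.tmean(ad.square(x - mu), axis=(0, 1), keepdims=True)
        return (x - mu) / ad.sqrt(var + 1e-5) * self.gamma + self.beta


class ResBlock(Module):
    """Two 3x3 convolutions with normalization and a (projected) shortcut."""

    def __init__(self, cin, cout, rng):
        self.conv1 = Conv2d(cin, cout, 3, rng)
        self.norm1 = ChannelNorm(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng)
        self.norm2 = ChannelNorm(cout)
        self.proj = Conv2d(cin, cout, 1, rng) if cin != cout else None

    def forward(self, x):
        h = ad.relu(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        shortcut = x if self.proj is None else self.proj(x)
        return ad.relu(h + shortcut)


class UNetRes(Module):
    """Residual-block U-Net producing per-pixel class probabilities."""

    def __init__(self, config: UNetResConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        ch = config.channels()
        self.stem = Conv2d(1, ch[0], 3, rng)
        self.enc = [ResBlock(ch[l], ch[l], rng) for l in range(config.depth)]
        self.down = [Conv2d(ch[l], ch[l + 1], 3, rng, stride=2)
                     for l in range(config.depth - 1)]
        self.upconv = [Conv2d(ch[l + 1], ch[l], 3, rng)
                       for l in range(config.depth - 2, -1, -1)]
        self.dec = [ResBlock(2 * ch[l], ch[l], rng)
                    for l in range(config.depth - 2, -1, -1)]
        self.headconv = Conv2d(ch[0], config.classes, 1, rng)

    def _check_size(self, h, w):
        div = 2 ** (self.config.depth - 1)
        if h % div or w % div:
            raise ValueError(f"input size {(h, w)} must be divisible by {div}")

    def forward(self, image) -> Tensor:
        """Image ``[H, W]`` to probability map ``[H, W, classes]``."""
        t = astensor(image)
        if t.ndim != 2:
            raise ValueError("expected a single-channel [H, W] image")
        self._check_size(*t.shape)
        x = ad.reshape(t, t.shape + (1,))
        x = self.stem(x)
        skips = []
        for l in range(self.config.depth):
            x = self.enc[l](x)
            if l < self.config.depth - 1:
                skips.append(x)
                x = ad.relu(self.down[l](x))
        for i in range(self.config.depth - 1):
            x = self.upconv[i](ad.repeat2d(x, 2))
            x = ad.concatenate([x, skips.pop()], axis=-1)
            x = self.dec[i](x)
        return ad.softmax(self.headconv(x), axis=-1)

    def predict(self, image) -> np.ndarray:
        with ad.no_grad():
            probs = self.forward(image)
        return np.argmax(probs.data, axis=-1).astype(np.int64)


def build_unet_res(config: UNetResConfig, seed: int = 0) -> UNetRes:
    return UNetRes(config, seed=seed)


# --------------------------------------------------------------------------
# presets and parameter-budget matching
# --------------------------------------------------------------------------

def capsule_presets() -> dict[str, ArchitectureConfig]:
    """Capsule architecture presets at three parameter-budget tiers.

    ``large`` is the optimized type-doubling architecture; ``medium`` and
    ``small`` are the non-doubling shapes used as budget-reduction steps.
    """
    return {
        "small": ArchitectureConfig(shape=(3, 4, 5, 6)),
        "medium": ArchitectureConfig(shape=(3, 5, 7, 9)),
        "large": ArchitectureConfig(shape=(3, 6, 12, 24, 48)),
    }


def matched_unet_config(target_params: int, classes: int = 3,
                        tolerance: float | None = 0.05) -> UNetResConfig:
    """Find a baseline whose parameter count matches ``target_params``.

    Scans depths 3-5 and fractional channel bases; raises if no candidate
    lands within ``tolerance`` (relative).  ``tolerance=None`` returns the
    closest achievable configuration (tiny budgets are quantized by the
    minimum channel widths).
    """
    best = None
    for depth in (3, 4, 5):
        lo, hi = 1.0, 64.0
        # parameter count is monotone in base at fixed depth: bisect
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            n = count_parameters(UNetRes(UNetResConfig(mid, depth, classes)))
            if n < target_params:
                lo = mid
            else:
                hi = mid
        for base in (lo, hi):
            cfg = UNetResConfig(base, depth, classes)
            n = count_parameters(UNetRes(cfg))
            err = abs(n - target_params) / target_params
            if best is None or err < best[0]:
                best = (err, cfg)
    err, cfg = best
    if tolerance is not None and err > tolerance:
        raise ValueError(f"no baseline within {tolerance:.0%} of "
                         f"{target_params} parameters (best: {err:.1%})")
    return cfg


def matched_pairs(classes: int = 3) -> dict[str, tuple[ArchitectureConfig, UNetResConfig]]:
    """Capsule/baseline preset pairs with parameter budgets matched < 5%."""
    pairs = {}
    for name, caps_cfg in capsule_presets().items():
        target = count_parameters(CapsuleUNet(caps_cfg))
        pairs[name] = (caps_cfg, matched_unet_config(target, classes))
    return pairs
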