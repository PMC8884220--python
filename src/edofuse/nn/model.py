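"""Encoder / residual / max-fusion / decoder network for focal-stack fusion.

The model maps a z-stack of D RGB planes (each scaled to [-1, 1]) to a single
fused image:

    O = tanh( decode( max_i( res( encode(I_i) ) ) ) )

One shared encoder (NL stride-2 convolution stages) turns every plane into a
feature tensor of shape (H / 2^NL, W / 2^NL, Ed); a chain of residual blocks
transforms those features; an elementwise maximum across the plane axis fuses
them into one tensor, and a transposed-convolution decoder maps it back to an
RGB image through a tanh.  Because the encoder weights are shared and the
maximum is symmetric, the parameter count is independent of D and one trained
model fuses stacks of any depth in any plane order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..stack import EDoFImage, ZStack, normalize_for_network
from . import autograd as ag
from .autograd import Tensor

__all__ = ["FusionNetConfig", "ModelParams", "init_params", "encode",
           "residual_transform", "fuse_max", "decode", "forward",
           "fuse_stack_cnn", "save_params", "load_params"]


@dataclass
class FusionNetConfig:
    """Architecture and training hyperparameters.

    nl            : number of stride-2 encoder stages (spatial downsampling 2^nl)
    ed            : feature channels at the bottleneck
    n_res_blocks  : residual blocks between encoder and fusion (default 5)
    kernel_size   : encoder / residual convolution kernel (decoder upsampling
                    stages use kernel 4 so stride-2 transposed convolutions
                    double the size exactly)
    patch_size    : training crop edge in pixels; must be divisible by 2^nl
    loss_weights  : (λ1, λ2, λ3) for the MAE / SSIM / spectral loss terms
    """

    nl: int = 2
    ed: int = 64
    n_res_blocks: int = 5
    kernel_size: int = 3
    patch_size: int = 256
    loss_weights: tuple[float, float, float] = (1.0, 0.1, 0.5)
    learning_rate: float = 1e-4
    batch_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nl < 1:
            raise ValueError("nl must be >= 1")
        if self.n_res_blocks < 1:
            raise ValueError("n_res_blocks must be >= 1")
        if self.patch_size % (2**self.nl) != 0:
            raise ValueError(
                f"patch_size {self.patch_size} not divisible by 2^nl = {2**self.nl}"
            )
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss weights must be non-negative")

    def encoder_channels(self) -> list[int]:
        """Channel progression 3 -> ... -> ed over the nl encoder stages."""
        return [3] + [max(1, self.ed // 2 ** (self.nl - 1 - m))
                      for m in range(self.nl)]


@dataclass
class ModelParams:
    """Learnable parameters plus the configuration they were built with."""

    config: FusionNetConfig
    tensors: dict[str, Tensor] = field(default_factory=dict)

    def parameters(self) -> list[Tensor]:
        return list(self.tensors.values())

    def zero_grad(self) -> None:
        for t in self.tensors.values():
            t.grad = None

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.tensors.values())


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), shape), requires_grad=True)


def init_params(cfg: FusionNetConfig, zero_residual: bool = False) -> ModelParams:
    """He-initialised parameters from the config seed.

    With ``zero_residual=True`` the residual blocks start as exact identity
    maps (their convolutions are zeroed), which is also a useful structural
    test hook.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.kernel_size
    p = ModelParams(config=cfg)
    chans = cfg.encoder_channels()
    for m in range(cfg.nl):
        ci, co = chans[m], chans[m + 1]
        p.tensors[f"enc{m}_w"] = _he(rng, (co, ci, k, k), ci * k * k)
        p.tensors[f"enc{m}_b"] = Tensor(np.zeros(co), requires_grad=True)
    for r in range(cfg.n_res_blocks):
        for half in (0, 1):
            w = _he(rng, (cfg.ed, cfg.ed, k, k), cfg.ed * k * k)
            if zero_residual:
                w.data[:] = 0.0
            p.tensors[f"res{r}_{half}_w"] = w
            p.tensors[f"res{r}_{half}_b"] = Tensor(np.zeros(cfg.ed),
                                                   requires_grad=True)
    dec_chans = list(reversed(chans))  # ed -> ... -> 3
    for m in range(cfg.nl):
        ci, co = dec_chans[m], dec_chans[m + 1]
        w = _he(rng, (ci, co, 4, 4), ci * 16)
        if m == cfg.nl - 1:
            # start the tanh pre-activations near zero so early optimiser
            # steps cannot saturate the output nonlinearity
            w.data *= 0.1
        p.tensors[f"dec{m}_w"] = w
        p.tensors[f"dec{m}_b"] = Tensor(np.zeros(co), requires_grad=True)
    return p


def encode(planes: Tensor, params: ModelParams) -> Tensor:
    """Shared encoder: (N, 3, H, W) -> (N, ed, H / 2^nl, W / 2^nl)."""
    cfg = params.config
    h, w = planes.shape[2], planes.shape[3]
    if h % 2**cfg.nl or w % 2**cfg.nl:
        raise ValueError(
            f"plane size {(h, w)} not divisible by 2^nl = {2**cfg.nl}; pad upstream"
        )
    pad = cfg.kernel_size // 2
    x = planes
    for m in range(cfg.nl):
        x = ag.conv2d(x, params.tensors[f"enc{m}_w"],
                      params.tensors[f"enc{m}_b"], stride=2, pad=pad)
        x = ag.leaky_relu(x)
    return x


def residual_transform(features: Tensor, params: ModelParams) -> Tensor:
    """Chain of shape-preserving residual blocks: x -> x + conv(act(conv(x)))."""
    cfg = params.config
    pad = cfg.kernel_size // 2
    x = features
    for r in range(cfg.n_res_blocks):
        y = ag.conv2d(x, params.tensors[f"res{r}_0_w"],
                      params.tensors[f"res{r}_0_b"], stride=1, pad=pad)
        y = ag.leaky_relu(y)
        y = ag.conv2d(y, params.tensors[f"res{r}_1_w"],
                      params.tensors[f"res{r}_1_b"], stride=1, pad=pad)
        x = ag.add(x, y)
    return x


def fuse_max(features: Tensor) -> Tensor:
    """Elementwise maximum over the leading plane axis: (D, N, C, h, w) -> (N, C, h, w)."""
    if features.shape[0] == 1:
        return ag.reshape(features, features.shape[1:])
    return ag.max_over_axis(features, axis=0)


def decode(fused: Tensor, params: ModelParams) -> Tensor:
    """Transposed-convolution decoder back to (N, 3, H, W), tanh-bounded."""
    cfg = params.config
    x = fused
    for m in range(cfg.nl):
        x = ag.conv_transpose2d(x, params.tensors[f"dec{m}_w"],
                                params.tensors[f"dec{m}_b"], stride=2, pad=1)
        if m < cfg.nl - 1:
            x = ag.leaky_relu(x)
    return ag.tanh(x)


def forward(planes: np.ndarray | Tensor, params: ModelParams) -> Tensor:
    """Full network on a batch of stacks shaped (D, N, 3, H, W) in [-1, 1]."""
    x = planes if isinstance(planes, Tensor) else Tensor(np.asarray(planes))
    D, N, C, H, W = x.shape
    flat = ag.reshape(x, (D * N, C, H, W))
    feats = residual_transform(encode(flat, params), params)
    _, ed, h, w = feats.shape
    fused = fuse_max(ag.reshape(feats, (D, N, ed, h, w)))
    return decode(fused, params)


def fuse_stack_cnn(stack: ZStack, params: ModelParams) -> EDoFImage:
    """Fuse a z-stack with the trained network into an EDoF image in [0, 1].

    Planes are mapped to [-1, 1], padded symmetrically to a multiple of
    2^nl, fused, cropped back and unmapped to [0, 1].
    """
    cfg = params.config
    norm = normalize_for_network(stack)
    planes = norm.planes  # (D, H, W, 3) in [-1, 1]
    h, w = planes.shape[1:3]
    mult = 2**cfg.nl
    ph, pw = (-h) % mult, (-w) % mult
    if ph or pw:
        planes = np.pad(planes, ((0, 0), (0, ph), (0, pw), (0, 0)),
                        mode="symmetric")
    x = planes.transpose(0, 3, 1, 2)[:, None]  # (D, 1, 3, H, W)
    out = forward(x, params).data[0].transpose(1, 2, 0)[:h, :w]
    return EDoFImage(
        image=np.clip((out + 1.0) / 2.0, 0.0, 1.0),
        method="cnn",
        source_planes=stack.n_planes,
        source_step=stack.axial_step,
    )


def save_params(params: ModelParams, path) -> None:
    """Write a checkpoint: arrays plus the config, in one npz archive."""
    cfg = params.config
    meta = dict(nl=cfg.nl, ed=cfg.ed, n_res_blocks=cfg.n_res_blocks,
                kernel_size=cfg.kernel_size, patch_size=cfg.patch_size,
                lw1=cfg.loss_weights[0], lw2=cfg.loss_weights[1],
                lw3=cfg.loss_weights[2], learning_rate=cfg.learning_rate,
                batch_size=cfg.batch_size, seed=cfg.seed)
    arrays = {f"param_{k}": t.data for k, t in params.tensors.items()}
    np.savez(path, _meta=np.array([list(meta.items())], dtype=object),
             **arrays)


def load_params(path) -> ModelParams:
    with np.load(path, allow_pickle=True) as archive:
        meta = dict(archive["_meta"][0])
        cfg = FusionNetConfig(
            nl=int(meta["nl"]), ed=int(meta["ed"]),
            n_res_blocks=int(meta["n_res_blocks"]),
            kernel_size=int(meta["kernel_size"]),
            patch_size=int(meta["patch_size"]),
            loss_weights=(float(meta["lw1"]), float(meta["lw2"]),
                          float(meta["lw3"])),
            learning_rate=float(meta["learning_rate"]),
            batch_size=int(meta["batch_size"]), seed=int(meta["seed"]),
        )
        params = ModelParams(config=cfg)
        for key in archive.files:
            if key.startswith("param_"):
                params.tensors[key[6:]] = Tensor(archive[key],
                                                 requires_grad=True)
    return params
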