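"""Patch-based training of the fusion network with Adam.

Training pairs are random co-located crops from (undersampled stack, EDoF
target) couples; every source of randomness (initialisation, pair order,
crop positions) is derived from the config seed, so identical seeds give
identical loss histories.
"""

from __future__ import annotations

import numpy as np

from ..stack import EDoFImage, ZStack
from .autograd import Tensor
from .losses import combined_loss_terms
from .model import FusionNetConfig, ModelParams, forward, init_params

__all__ = ["Adam", "sample_patches", "train"]


class Adam:
    """Adam with global gradient-norm clipping over a list of parameters."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 max_grad_norm: float | None = 1.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.max_grad_norm = max_grad_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        if self.max_grad_norm is not None:
            norm = np.sqrt(sum(float(np.sum(p.grad**2)) for p in self.params
                               if p.grad is not None))
            if norm > self.max_grad_norm:
                scale = self.max_grad_norm / norm
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _target_image(target) -> np.ndarray:
    if isinstance(target, EDoFImage):
        return target.image
    return np.asarray(target, dtype=np.float64)


def sample_patches(stack_pair: tuple[ZStack, EDoFImage | np.ndarray],
                   patch_size: int, n: int, seed: int,
                   ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw ``n`` co-located crops from a (stack, target) pair.

    Each crop shares one uniformly random (y, x) window across all focal
    planes and the target; positions are reproducible from ``seed``.  Returns
    pairs of ``(planes (D, p, p, 3), target (p, p, 3))`` in [0, 1].
    """
    stack, target = stack_pair
    planes = stack.as_float01()
    tgt = _target_image(target)
    h, w = planes.shape[1:3]
    if h < patch_size or w < patch_size:
        raise ValueError(f"stack {(h, w)} smaller than patch size {patch_size}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        y = int(rng.integers(0, h - patch_size + 1))
        x = int(rng.integers(0, w - patch_size + 1))
        out.append((planes[:, y : y + patch_size, x : x + patch_size],
                    tgt[y : y + patch_size, x : x + patch_size]))
    return out


def train(dataset: list[tuple[ZStack, EDoFImage | np.ndarray]],
          cfg: FusionNetConfig, n_steps: int,
          params: ModelParams | None = None,
          ) -> tuple[ModelParams, list[float]]:
    """Run ``n_steps`` Adam updates of the combined loss on random patches.

    Parameters are initialised from ``cfg.seed`` unless ``params`` is given
    (resume).  Returns the trained parameters and the per-step loss history.
    Raises if the dataset is empty or the loss becomes non-finite.
    """
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    if params is None:
        params = init_params(cfg)
    # cache [-1, 1] copies once; crops below are views into these
    planes_cache = [s.as_float01() * 2.0 - 1.0 for s, _ in dataset]
    target_cache = [_target_image(t) * 2.0 - 1.0 for _, t in dataset]
    ps = cfg.patch_size
    for pl in planes_cache:
        if pl.shape[1] < ps or pl.shape[2] < ps:
            raise ValueError(f"stack planes {pl.shape[1:3]} smaller than "
                             f"patch size {ps}")
    depths = {pl.shape[0] for pl in planes_cache}
    if len(depths) > 1:
        raise ValueError(f"all stacks in a batch-trained dataset must share "
                         f"the same plane count, got {sorted(depths)}")

    rng = np.random.default_rng((cfg.seed, 0xED0F))
    opt = Adam(params.parameters(), lr=cfg.learning_rate)
    history: list[float] = []
    for _ in range(n_steps):
        idx = rng.integers(0, len(dataset), size=cfg.batch_size)
        xs, ts = [], []
        for i in idx:
            pl, tg = planes_cache[i], target_cache[i]
            y = int(rng.integers(0, pl.shape[1] - ps + 1))
            x = int(rng.integers(0, pl.shape[2] - ps + 1))
            xs.append(pl[:, y : y + ps, x : x + ps].transpose(0, 3, 1, 2))
            ts.append(tg[y : y + ps, x : x + ps].transpose(2, 0, 1))
        batch_x = np.stack(xs, axis=1)  # (D, B, 3, p, p)
        batch_t = np.stack(ts, axis=0)  # (B, 3, p, p)
        out = forward(batch_x, params)
        loss, _ = combined_loss_terms(out, batch_t, cfg.loss_weights)
        value = loss.item()
        if not np.isfinite(value):
            raise RuntimeError(f"non-finite loss at step {len(history)}: {value}")
        params.zero_grad()
        loss.backward()
        opt.step()
        history.append(value)
    return params, history
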