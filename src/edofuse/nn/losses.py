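"""Composite reconstruction loss: weighted MAE + (1 - SSIM) + spectral MAE.

All terms operate on network-space images in [-1, 1] (NCHW); each is zero iff
output equals target, so the weighted sum l = λ1·lMAE + λ2·lSSIM + λ3·lFFT is
non-negative with its optimum at exact reconstruction.  Default weights are
(1.0, 0.1, 0.5).
"""

from __future__ import annotations

import numpy as np

from ..metrics import gaussian_window
from . import autograd as ag
from .autograd import Tensor

__all__ = ["loss_mae", "loss_ssim", "loss_fft", "combined_loss",
           "combined_loss_terms"]

_SSIM_WIN = gaussian_window(11, 1.5)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def loss_mae(output: Tensor, target) -> Tensor:
    """Mean absolute error over all pixels and channels."""
    target = _as_tensor(target)
    if output.shape != target.shape:
        raise ValueError(f"shape mismatch {output.shape} vs {target.shape}")
    return ag.mean(ag.absolute(ag.sub(output, target)))


def loss_ssim(output: Tensor, target, data_range: float = 2.0) -> Tensor:
    """1 - mean SSIM, Gaussian-windowed (11x11, σ=1.5), valid windows only.

    Uses the standard constants C1 = (0.01 L)², C2 = (0.03 L)² with
    L = ``data_range`` (2 for images in [-1, 1]).  Lies in [0, 2] and equals
    0 iff the images are identical.
    """
    target = _as_tensor(target)
    if output.shape != target.shape:
        raise ValueError(f"shape mismatch {output.shape} vs {target.shape}")
    if min(output.shape[-2:]) < _SSIM_WIN.shape[0]:
        raise ValueError("images smaller than the 11x11 SSIM window")
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mu_x = ag.correlate_valid(output, _SSIM_WIN)
    mu_y = ag.correlate_valid(target, _SSIM_WIN)
    sxx = ag.sub(ag.correlate_valid(ag.mul(output, output), _SSIM_WIN),
                 ag.mul(mu_x, mu_x))
    syy = ag.sub(ag.correlate_valid(ag.mul(target, target), _SSIM_WIN),
                 ag.mul(mu_y, mu_y))
    sxy = ag.sub(ag.correlate_valid(ag.mul(output, target), _SSIM_WIN),
                 ag.mul(mu_x, mu_y))
    num = ag.mul(ag.scalar_add(ag.scalar_mul(ag.mul(mu_x, mu_y), 2.0), c1),
                 ag.scalar_add(ag.scalar_mul(sxy, 2.0), c2))
    den = ag.mul(ag.scalar_add(ag.add(ag.mul(mu_x, mu_x), ag.mul(mu_y, mu_y)), c1),
                 ag.scalar_add(ag.add(sxx, syy), c2))
    return ag.scalar_add(ag.neg(ag.mean(ag.div(num, den))), 1.0)


def loss_fft(output: Tensor, target) -> Tensor:
    """Mean absolute difference of the 2-D DFTs of output and target.

    Computed on the modulus of the complex difference (so phase errors are
    penalised too), averaged over all frequency bins and channels.
    """
    target = np.asarray(target.data if isinstance(target, Tensor) else target,
                        dtype=np.float64)
    if output.shape != target.shape:
        raise ValueError(f"shape mismatch {output.shape} vs {target.shape}")
    return ag.fft_mae(output, target)


def combined_loss_terms(output: Tensor, target,
                        weights: tuple[float, float, float] = (1.0, 0.1, 0.5),
                        ) -> tuple[Tensor, dict[str, float]]:
    """Weighted sum of the three terms plus their unweighted values."""
    if any(w < 0 for w in weights):
        raise ValueError("loss weights must be non-negative")
    target = _as_tensor(target)
    l1 = loss_mae(output, target)
    l2 = loss_ssim(output, target)
    l3 = loss_fft(output, target)
    total = ag.add(ag.add(ag.scalar_mul(l1, weights[0]),
                          ag.scalar_mul(l2, weights[1])),
                   ag.scalar_mul(l3, weights[2]))
    return total, {"mae": l1.item(), "ssim": l2.item(), "fft": l3.item()}


def combined_loss(output: Tensor, target,
                  weights: tuple[float, float, float] = (1.0, 0.1, 0.5)) -> Tensor:
    total, _ = combined_loss_terms(output, target, weights)
    return total
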