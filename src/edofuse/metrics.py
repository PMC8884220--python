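"""Full-reference image similarity metrics: SSIM, Pearson correlation, HaarPSI.

These are the three scores used to compare fused extended-depth-of-field
images against their full-stack ground truth.  SSIM follows the original
windowed formulation (11x11 Gaussian window, σ = 1.5, K1 = 0.01, K2 = 0.03);
HaarPSI follows its defining reference (two fine Haar scales for local
similarity, the third scale for weights, C = 30 and α = 4.2 on the [0, 255]
scale, YIQ chroma terms for colour images).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

from .stack import EDoFImage

__all__ = ["MetricReport", "gaussian_window", "luminance", "ssim",
           "pearson_corr", "hpsi", "evaluate_pair", "evaluate_batch",
           "write_report", "gradient_energy", "sharpest_plane"]

#: Rec.709 luma weights
LUMA_709 = np.array([0.2126, 0.7152, 0.0722])


def luminance(image: np.ndarray) -> np.ndarray:
    """Rec.709 luminance of an (H, W, 3) image; 2-D input passes through."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return image
    return image @ LUMA_709


def gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    """Normalised 2-D Gaussian window."""
    r = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(r**2) / (2.0 * sigma**2))
    w = np.outer(g, g)
    return w / w.sum()


@dataclass
class MetricReport:
    """Similarity of one test image against one reference image."""

    ssim: float
    corr: float
    hpsi: float
    reference_id: str = ""
    test_id: str = ""


def ssim(x: np.ndarray, y: np.ndarray, data_range: float = 1.0) -> float:
    """Structural similarity index of two grayscale images.

    Mean over all complete 11x11 Gaussian-weighted windows (σ = 1.5) of

        (2 µx µy + C1)(2 σxy + C2) / ((µx² + µy² + C1)(σx² + σy² + C2))

    with C1 = (0.01 L)², C2 = (0.03 L)², L = ``data_range``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    if x.ndim != 2:
        raise ValueError("ssim expects 2-D (grayscale / luminance) images")
    win = gaussian_window(11, 1.5)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mu_x = fftconvolve(x, win, mode="valid")
    mu_y = fftconvolve(y, win, mode="valid")
    sxx = fftconvolve(x * x, win, mode="valid") - mu_x**2
    syy = fftconvolve(y * y, win, mode="valid") - mu_y**2
    sxy = fftconvolve(x * y, win, mode="valid") - mu_x * mu_y
    num = (2 * mu_x * mu_y + c1) * (2 * sxy + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (sxx + syy + c2)
    return float(np.mean(num / den))


def pearson_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient over flattened pixel values."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("Pearson correlation undefined for a constant image",
                      stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


# ------------------------------------------------------------------ HaarPSI

def _haar_filter(scale: int) -> np.ndarray:
    size = 2**scale
    f = np.full((size, size), 2.0**-scale)
    f[: size // 2] *= -1.0
    return f


def _conv_same(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    return fftconvolve(x, k, mode="same")


def _subsample(x: np.ndarray) -> np.ndarray:
    return _conv_same(x, np.full((2, 2), 0.25))[::2, ::2]


def _similarity(a: np.ndarray, b: np.ndarray, c: float) -> np.ndarray:
    return (2.0 * a * b + c) / (a**2 + b**2 + c)


def hpsi(x: np.ndarray, y: np.ndarray, c: float = 30.0,
         alpha: float = 4.2) -> float:
    """Haar wavelet-based perceptual similarity index in [0, 1].

    Inputs are grayscale ``(H, W)`` or RGB ``(H, W, 3)`` images on the
    [0, 255] scale.  Local similarity comes from the magnitudes of the first
    two Haar wavelet scales in the horizontal and vertical orientations,
    logistic-mapped with constant ``c``; the third-scale magnitude provides
    the weights; colour images add a chroma (IQ) mean-similarity channel.
    The weighted logistic average is inverted and squared (exponent α).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    color = x.ndim == 3
    if color:
        yx = x @ [0.299, 0.587, 0.114]
        yy = y @ [0.299, 0.587, 0.114]
        ix = x @ [0.596, -0.274, -0.322]
        iy = y @ [0.596, -0.274, -0.322]
        qx = x @ [0.211, -0.523, 0.312]
        qy = y @ [0.211, -0.523, 0.312]
        ix, iy, qx, qy = map(_subsample, (ix, iy, qx, qy))
    else:
        yx, yy = x, y
    yx = _subsample(yx)
    yy = _subsample(yy)

    n_channels = 3 if color else 2
    sims = []
    weights = []
    for orientation in range(2):  # 0: horizontal edges, 1: vertical
        coefs_x = []
        coefs_y = []
        for scale in (1, 2, 3):
            f = _haar_filter(scale)
            if orientation == 1:
                f = f.T
            coefs_x.append(np.abs(_conv_same(yx, f)))
            coefs_y.append(np.abs(_conv_same(yy, f)))
        local = (_similarity(coefs_x[0], coefs_y[0], c)
                 + _similarity(coefs_x[1], coefs_y[1], c)) / 2.0
        sims.append(local)
        weights.append(np.maximum(coefs_x[2], coefs_y[2]))
    if color:
        mf = np.full((2, 2), 0.25)
        ai, bi = np.abs(_conv_same(ix, mf)), np.abs(_conv_same(iy, mf))
        aq, bq = np.abs(_conv_same(qx, mf)), np.abs(_conv_same(qy, mf))
        sims.append((_similarity(ai, bi, c) + _similarity(aq, bq, c)) / 2.0)
        weights.append((weights[0] + weights[1]) / 2.0)

    sims = np.stack(sims[:n_channels])
    weights = np.stack(weights[:n_channels])
    logistic = 1.0 / (1.0 + np.exp(-alpha * sims))
    pooled = (logistic * weights).sum() / weights.sum()
    pooled = np.clip(pooled, 1e-12, 1.0 - 1e-12)
    return float((np.log(pooled / (1.0 - pooled)) / alpha) ** 2)


def evaluate_pair(reference: EDoFImage | np.ndarray,
                  test: EDoFImage | np.ndarray,
                  reference_id: str = "", test_id: str = "") -> MetricReport:
    """All three metrics of a test image against a reference.

    SSIM and Pearson correlation are computed on Rec.709 luminance in [0, 1];
    HaarPSI on RGB scaled to [0, 255].
    """
    ref = reference.image if isinstance(reference, EDoFImage) else np.asarray(reference)
    tst = test.image if isinstance(test, EDoFImage) else np.asarray(test)
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch {ref.shape} vs {tst.shape}")
    ref_l = luminance(ref)
    tst_l = luminance(tst)
    return MetricReport(
        ssim=ssim(ref_l, tst_l, data_range=1.0),
        corr=pearson_corr(ref_l, tst_l),
        hpsi=hpsi(ref * 255.0, tst * 255.0),
        reference_id=reference_id,
        test_id=test_id,
    )


def evaluate_batch(references, tests) -> list[MetricReport]:
    """Order-preserving pairwise evaluation of two equally long image sets."""
    references = list(references)
    tests = list(tests)
    if len(references) != len(tests):
        raise ValueError(
            f"set sizes differ: {len(references)} references, {len(tests)} tests"
        )
    return [evaluate_pair(r, t, reference_id=str(i), test_id=str(i))
            for i, (r, t) in enumerate(zip(references, tests))]


def gradient_energy(image: np.ndarray) -> float:
    """Mean squared gradient magnitude of a 2-D image — a simple focus measure."""
    gy, gx = np.gradient(np.asarray(image, dtype=np.float64))
    return float(np.mean(gx**2 + gy**2))


def sharpest_plane(planes: np.ndarray) -> int:
    """Index of the plane with the highest luminance gradient energy.

    ``planes`` is ``(D, H, W, 3)`` or ``(D, H, W)``; ties go to the lowest index.
    """
    planes = np.asarray(planes, dtype=np.float64)
    energies = [gradient_energy(luminance(p)) for p in planes]
    return int(np.argmax(energies))


def write_report(reports: list[MetricReport], path: str | Path) -> None:
    """One CSV row per (reference, test) pair."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["reference_id", "test_id", "ssim", "corr", "hpsi"])
        for r in reports:
            writer.writerow([r.reference_id, r.test_id,
                             f"{r.ssim:.6f}", f"{r.corr:.6f}", f"{r.hpsi:.6f}"])
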