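"""Classical wavelet multi-scale-decomposition (MSD) fusion of focal stacks.

Each plane is decomposed with a separable discrete wavelet transform; at every
detail band the coefficient from the plane with the strongest local response
is kept (sharp structure produces large detail coefficients), the coarsest
approximation band is averaged, and the inverse transform yields a single
all-in-focus image.  This is the reference extended-depth-of-field method the
learned fusion is trained against and compared with.

The wavelet family, level count and selection rule are configurable; the
defaults (``sym4``, 4 levels, 3x3 local-energy selection with a radius-1
majority consistency filter) are a documented choice of this package, not a
canonical standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

from .stack import EDoFImage, ZStack

__all__ = [
    "WaveletFusionConfig",
    "decompose",
    "reconstruct",
    "select_coefficients",
    "consistency_filter",
    "fuse_stack_wavelet",
]

#: Rec.709 luma weights used when fusion is guided by a single luminance channel
LUMA_709 = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class WaveletFusionConfig:
    wavelet_name: str = "sym4"
    levels: int = 4
    selection: str = "max_local_energy"  # or "max_abs"
    consistency_radius: int = 1
    color_mode: str = "luminance_guided"  # or "per_channel"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.selection not in ("max_abs", "max_local_energy"):
            raise ValueError(f"unknown selection rule {self.selection!r}")
        if not 0 <= self.consistency_radius <= 5:
            raise ValueError("consistency_radius must be in [0, 5]")
        if self.color_mode not in ("luminance_guided", "per_channel"):
            raise ValueError(f"unknown color mode {self.color_mode!r}")


def decompose(image: np.ndarray, cfg: WaveletFusionConfig) -> list:
    """Multi-level 2-D DWT of a grayscale image (symmetric extension).

    Returns the usual pyramid ``[cA_L, (cH_L, cV_L, cD_L), ..., (cH_1, cV_1, cD_1)]``.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"decompose expects a 2-D image, got shape {image.shape}")
    if min(image.shape) < 2**cfg.levels:
        raise ValueError(
            f"image of shape {image.shape} too small for {cfg.levels} levels"
        )
    with warnings.catch_warnings():
        # boundary-effect notice for deep levels on small images; symmetric
        # extension still reconstructs perfectly, which is all fusion needs
        warnings.simplefilter("ignore", UserWarning)
        return pywt.wavedec2(image, cfg.wavelet_name, level=cfg.levels,
                             mode="symmetric")


def reconstruct(pyramid: list, cfg: WaveletFusionConfig,
                shape: tuple[int, int] | None = None) -> np.ndarray:
    """Inverse of :func:`decompose`; optionally crops to the original shape."""
    image = pywt.waverec2(pyramid, cfg.wavelet_name, mode="symmetric")
    if shape is not None:
        image = image[: shape[0], : shape[1]]
    return image


def consistency_filter(selection_map: np.ndarray, radius: int) -> np.ndarray:
    """Majority-vote filter on a plane-index map.

    Every entry is replaced by the most frequent index within its
    ``(2r+1) x (2r+1)`` neighbourhood (windows are clipped at the borders);
    when the majority is not unique the original value is kept.  ``radius=0``
    is the identity.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    selection_map = np.asarray(selection_map)
    if radius == 0:
        return selection_map.copy()
    labels = np.unique(selection_map)
    size = 2 * radius + 1
    counts = np.stack([
        ndimage.correlate(
            (selection_map == lab).astype(np.float64),
            np.ones((size, size)),
            mode="constant",
            cval=0.0,
        )
        for lab in labels
    ])
    counts = np.rint(counts).astype(np.int64)
    best = counts.max(axis=0)
    n_best = (counts == best).sum(axis=0)
    winner = labels[np.argmax(counts, axis=0)]
    return np.where(n_best > 1, selection_map, winner)


def _activity(coef: np.ndarray, selection: str) -> np.ndarray:
    if selection == "max_abs":
        return np.abs(coef)
    # local energy in a 3x3 window
    return ndimage.uniform_filter(coef * coef, size=3, mode="nearest")


def select_coefficients(pyramids: list[list], cfg: WaveletFusionConfig
                        ) -> tuple[list, list]:
    """Fuse congruent per-plane pyramids coefficient-wise.

    Detail coefficients are taken from the plane maximising the activity
    criterion (ties go to the lowest plane index, which is what ``argmax``
    yields); the coarsest approximation is the pixelwise mean across planes.

    Returns ``(fused_pyramid, selection_maps)`` where ``selection_maps`` is a
    list over levels of ``(mapH, mapV, mapD)`` integer arrays recording the
    winning plane index per coefficient (after consistency filtering).
    """
    if len(pyramids) < 1:
        raise ValueError("need at least one pyramid")
    ref = pyramids[0]
    for p in pyramids[1:]:
        if len(p) != len(ref) or any(
            p[0].shape != ref[0].shape
            or any(pb.shape != rb.shape for pb, rb in zip(p[lev], ref[lev]))
            for lev in range(1, len(ref))
        ):
            raise ValueError("pyramids are not congruent")

    fused: list = [np.mean([p[0] for p in pyramids], axis=0)]
    maps: list = []
    for lev in range(1, len(ref)):
        fused_bands = []
        map_bands = []
        for band in range(3):
            coefs = np.stack([p[lev][band] for p in pyramids])
            activity = np.stack([_activity(c, cfg.selection) for c in coefs])
            sel = np.argmax(activity, axis=0)
            sel = consistency_filter(sel, cfg.consistency_radius)
            fused_bands.append(np.take_along_axis(coefs, sel[None], axis=0)[0])
            map_bands.append(sel)
        fused.append(tuple(fused_bands))
        maps.append(tuple(map_bands))
    return fused, maps


def _apply_selection(pyramids: list[list], maps: list) -> list:
    """Gather coefficients according to precomputed selection maps."""
    fused: list = [np.mean([p[0] for p in pyramids], axis=0)]
    for lev in range(1, len(pyramids[0])):
        bands = []
        for band in range(3):
            coefs = np.stack([p[lev][band] for p in pyramids])
            sel = maps[lev - 1][band]
            bands.append(np.take_along_axis(coefs, sel[None], axis=0)[0])
        fused.append(tuple(bands))
    return fused


def _pad_to_multiple(image: np.ndarray, multiple: int) -> np.ndarray:
    h, w = image.shape[:2]
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph == 0 and pw == 0:
        return image
    pad = [(0, ph), (0, pw)] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pad, mode="symmetric")


def fuse_stack_wavelet(stack: ZStack, cfg: WaveletFusionConfig | None = None
                       ) -> EDoFImage:
    """Fuse a full z-stack into one extended-depth-of-field image.

    In ``luminance_guided`` mode the selection maps are computed once on the
    Rec.709 luminance channel and applied identically to all three colour
    channels, which avoids colour fringing at selection boundaries.
    """
    if cfg is None:
        cfg = WaveletFusionConfig()
    planes = stack.as_float01()
    h, w = planes.shape[1:3]
    levels = min(cfg.levels,
                 max(1, pywt.dwt_max_level(min(h, w),
                                           pywt.Wavelet(cfg.wavelet_name))))
    if levels < cfg.levels:
        cfg = WaveletFusionConfig(cfg.wavelet_name, levels, cfg.selection,
                                  cfg.consistency_radius, cfg.color_mode)
    padded = np.stack([_pad_to_multiple(p, 2**cfg.levels) for p in planes])

    if cfg.color_mode == "luminance_guided":
        luma = padded @ LUMA_709
        _, maps = select_coefficients([decompose(l, cfg) for l in luma], cfg)
        channels = []
        for c in range(3):
            pyrs = [decompose(p[..., c], cfg) for p in padded]
            fused_pyr = _apply_selection(pyrs, maps)
            channels.append(reconstruct(fused_pyr, cfg, shape=(h, w)))
        fused_img = np.stack(channels, axis=-1)
    else:
        channels = []
        for c in range(3):
            pyrs = [decompose(p[..., c], cfg) for p in padded]
            fused_pyr, _ = select_coefficients(pyrs, cfg)
            channels.append(reconstruct(fused_pyr, cfg, shape=(h, w)))
        fused_img = np.stack(channels, axis=-1)

    return EDoFImage(
        image=np.clip(fused_img, 0.0, 1.0),
        method="wavelet",
        source_planes=stack.n_planes,
        source_step=stack.axial_step,
    )
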