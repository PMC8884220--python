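"""Focal-plane stack data model, TIFF I/O, white balancing and axial decimation.

A :class:`ZStack` holds the D focal planes of a brightfield z-stack acquired at
successive axial positions (plane 0 is the shallowest; plane ``i`` sits at
``i * axial_step`` micrometres from the first plane).  All fusion code in this
package consumes and produces these stacks, so the declared pixel value range
is carried explicitly on the object rather than re-inferred per operation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

__all__ = [
    "ZStack",
    "EDoFImage",
    "StackFormatError",
    "read_stack",
    "write_stack",
    "white_balance",
    "decimate_stack",
    "normalize_for_network",
    "denormalize_from_network",
]

#: default pixel pitch (µm/px) of the nominal 100x acquisition geometry
DEFAULT_PIXEL_SIZE = 0.065


class StackFormatError(ValueError):
    """Raised when a file or array does not form a valid focal-plane stack."""


def _infer_range(dtype: np.dtype) -> tuple[float, float]:
    if np.issubdtype(dtype, np.integer):
        return (0.0, 255.0)
    return (0.0, 1.0)


@dataclass
class ZStack:
    """Ordered focal planes plus acquisition metadata.

    Parameters
    ----------
    planes
        Array of shape ``(D, H, W, 3)``; index 0 is the shallowest plane.
    axial_step
        Distance between consecutive planes in micrometres (> 0).
    pixel_size
        Lateral pixel pitch in µm/px; used only by the simulator, never by
        the fusion mathematics.
    white_ref
        Optional empty-field white reference, shape ``(H, W, 3)``.
    value_range
        Declared pixel range, ``(0, 1)`` for float data or ``(0, 255)`` for
        8-bit integer data.
    """

    planes: np.ndarray
    axial_step: float
    pixel_size: float = DEFAULT_PIXEL_SIZE
    white_ref: np.ndarray | None = None
    value_range: tuple[float, float] | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 4 or self.planes.shape[-1] != 3:
            raise StackFormatError(
                f"planes must have shape (D, H, W, 3), got {self.planes.shape}"
            )
        if self.planes.shape[0] < 1:
            raise StackFormatError("a stack needs at least one plane")
        if not self.axial_step > 0:
            raise ValueError(f"axial_step must be > 0, got {self.axial_step}")
        if self.value_range is None:
            self.value_range = _infer_range(self.planes.dtype)
        if self.white_ref is not None:
            self.white_ref = np.asarray(self.white_ref)
            if self.white_ref.shape != self.planes.shape[1:]:
                raise StackFormatError(
                    "white reference shape does not match plane shape"
                )

    @property
    def n_planes(self) -> int:
        return int(self.planes.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of every plane."""
        return self.planes.shape[1], self.planes.shape[2]

    @property
    def axial_span(self) -> float:
        """Distance (µm) between first and last plane: ``(D - 1) * axial_step``."""
        return (self.n_planes - 1) * self.axial_step

    def plane_depths(self) -> np.ndarray:
        """Axial coordinate of each plane, in µm from the first plane."""
        return np.arange(self.n_planes) * self.axial_step

    def as_float01(self) -> np.ndarray:
        """Planes linearly mapped from the declared range to float64 [0, 1]."""
        lo, hi = self.value_range
        return (self.planes.astype(np.float64) - lo) / (hi - lo)


@dataclass
class EDoFImage:
    """A single fused extended-depth-of-field image with provenance."""

    image: np.ndarray  # (H, W, 3) float in [0, 1]
    method: str  # one of {"wavelet", "cnn", "plane_select"}
    source_planes: int
    source_step: float

    def __post_init__(self) -> None:
        self.image = np.clip(np.asarray(self.image, dtype=np.float64), 0.0, 1.0)
        if self.image.ndim != 3 or self.image.shape[-1] != 3:
            raise ValueError(f"image must be (H, W, 3), got {self.image.shape}")


def read_stack(path: str | Path, axial_step: float, **kwargs: Any) -> ZStack:
    """Read a multi-page TIFF into a :class:`ZStack` (page order = axial order)."""
    with tifffile.TiffFile(str(path)) as tif:
        if len(tif.pages) == 0:
            raise StackFormatError(f"{path}: TIFF contains no pages")
        shapes = {p.shape for p in tif.pages}
        if len(shapes) > 1:
            raise StackFormatError(f"{path}: pages have mixed shapes {shapes}")
        data = tif.asarray()
    if data.ndim == 3:  # single page
        data = data[None]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise StackFormatError(f"{path}: expected RGB pages, got shape {data.shape}")
    return ZStack(planes=data, axial_step=axial_step, **kwargs)


def write_stack(stack: ZStack, path: str | Path) -> None:
    """Write the stack as a multi-page RGB TIFF; round-trips integer data bit-exactly."""
    tifffile.imwrite(str(path), stack.planes, photometric="rgb")


def white_balance(plane: np.ndarray, reference: np.ndarray,
                  value_range: tuple[float, float] = (0.0, 1.0)) -> np.ndarray:
    """Flat-field white balance: divide by the mean-normalised empty-field reference.

    Each channel of ``reference`` is divided by its own spatial mean so a
    uniform reference is the identity; the plane is then divided elementwise
    and clipped back to the declared range.  Zero-valued reference pixels are
    clamped to a small epsilon (with a warning) to keep the division finite.
    """
    plane = np.asarray(plane, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if plane.shape != reference.shape:
        raise ValueError(
            f"plane shape {plane.shape} != reference shape {reference.shape}"
        )
    eps = 1e-6 * max(abs(value_range[1]), 1.0)
    if np.any(reference <= 0):
        warnings.warn("white reference contains non-positive pixels; clamping",
                      stacklevel=2)
        reference = np.maximum(reference, eps)
    gain = reference / reference.mean(axis=(0, 1), keepdims=True)
    out = plane / np.maximum(gain, eps)
    return np.clip(out, value_range[0], value_range[1])


def decimate_stack(stack: ZStack, factor: int) -> ZStack:
    """Emulate a coarser axial sampling rate by keeping every ``factor``-th plane.

    Retains planes at indices ``factor-1, 2*factor-1, ...`` so the output has
    ``floor(D / factor)`` planes — the rule consistent with reducing a 14-plane
    0.5 µm stack to 7 planes at 1 µm (factor 2) and 3 planes at 2 µm (factor 4).
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError(f"decimation factor must be a positive integer, got {factor}")
    if factor > stack.n_planes:
        raise ValueError(
            f"decimation factor {factor} exceeds plane count {stack.n_planes}"
        )
    kept = stack.planes[factor - 1 :: factor]
    return ZStack(
        planes=kept.copy(),
        axial_step=stack.axial_step * factor,
        pixel_size=stack.pixel_size,
        white_ref=None if stack.white_ref is None else stack.white_ref.copy(),
        value_range=stack.value_range,
        meta={**stack.meta, "decimated_by": factor},
    )


def normalize_for_network(stack: ZStack) -> ZStack:
    """Map the declared pixel range linearly onto [-1, 1] (the tanh output range).

    The inverse mapping is recorded under ``meta["normalize"]`` so outputs can
    be unmapped with :func:`denormalize_from_network`.
    """
    lo, hi = stack.value_range
    data = stack.planes.astype(np.float64)
    scaled = 2.0 * (data - lo) / (hi - lo) - 1.0
    meta = {**stack.meta, "normalize": {"lo": float(lo), "hi": float(hi)}}
    return ZStack(
        planes=scaled,
        axial_step=stack.axial_step,
        pixel_size=stack.pixel_size,
        white_ref=stack.white_ref,
        value_range=(-1.0, 1.0),
        meta=meta,
    )


def denormalize_from_network(data: np.ndarray,
                             norm: dict[str, float] | None = None) -> np.ndarray:
    """Invert :func:`normalize_for_network` on an array in [-1, 1]."""
    if norm is None:
        norm = {"lo": 0.0, "hi": 1.0}
    lo, hi = norm["lo"], norm["hi"]
    return (np.asarray(data, dtype=np.float64) + 1.0) / 2.0 * (hi - lo) + lo
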