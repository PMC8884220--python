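"""Acquisition-geometry arithmetic for high-NA brightfield z-stacks.

At high magnification the depth of field of an oil-immersion objective
(``DoF = lambda / NA**2``) is far thinner than a blood film, so a z-stack of
``Np = ceil(St * NA**2 / (2 * lambda))`` focal planes is needed to sample a
slab of thickness ``St`` at Nyquist along the optical axis.  These helpers
turn a geometry into the plane counts the rest of the package works with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["AcquisitionGeometry", "depth_of_field", "required_planes"]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Optical parameters of a z-stack acquisition.

    wavelength : emission wavelength in µm (green light ≈ 0.53)
    na         : numerical aperture of the objective (≤ 1.5 for oil immersion)
    sample_thickness : axial extent of the specimen slab in µm
    """

    wavelength: float
    na: float
    sample_thickness: float

    def __post_init__(self) -> None:
        if self.wavelength <= 0 or self.na <= 0 or self.sample_thickness <= 0:
            raise ValueError("all geometry parameters must be strictly positive")
        if self.na > 1.5:
            raise ValueError(f"NA {self.na} exceeds the oil-immersion limit 1.5")


def depth_of_field(geom: AcquisitionGeometry) -> float:
    """Depth of field in µm: ``lambda / NA**2``."""
    return geom.wavelength / geom.na**2


def required_planes(geom: AcquisitionGeometry) -> int:
    """Number of focal planes to cover the sample slab: ``ceil(St * NA**2 / (2*lambda))``."""
    return math.ceil(geom.sample_thickness * geom.na**2 / (2.0 * geom.wavelength))
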