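"""Closed-form cone geometry for pile growth and particle shape.

A powder pile poured from a point source is idealized as a right circular
cone whose flank makes the static angle of repose ``alpha`` with the
horizontal.  With the apex angle fixed, every dimension of the cone follows
from its height ``h``::

    r = h / tan(alpha)                     (base radius)
    V = pi * h**3 / (3 * tan(alpha)**2)    (volume)

Inverting the volume relation gives the height as a power law of the fed
volume, ``h = (3/pi)^(1/3) * tan(alpha)^(2/3) * V^(1/3)``.  Because the
fed volume grows linearly in time at constant feed rate, the projected
pile height — and hence the bright area of a fixed image slice — grows as
``t^(1/3)`` in the ideal-cone limit.  That exponent is the anchor for the
power-law flow-curve model fitted elsewhere in this package.

Note on conventions: ``alpha`` is always the angle of repose measured from
the *horizontal*, in degrees at the API surface (converted to radians
internally).  The radius is ``h / tan(alpha)``, the only reading consistent
with the volume relation above and with steep piles being narrow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "ConeState",
    "GeometryCoefficients",
    "OrificeFlowParams",
    "sphericity_index",
    "cone_radius",
    "cone_volume",
    "cone_height",
    "geometry_coefficients",
    "brown_richards_rate",
]


def _check_alpha(alpha: float) -> float:
    """Validate an angle of repose (degrees) and return it in radians."""
    if not 0.0 < alpha < 90.0:
        raise ValueError(
            f"angle of repose must be in (0, 90) degrees, got {alpha!r}"
        )
    return math.radians(alpha)


def _check_positive(**values: float) -> None:
    for name, value in values.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class ConeState:
    """Geometric state of an ideal conical pile.

    Parameters
    ----------
    height : float
        Pile height, in pixels or mm (any consistent length unit).
    alpha : float
        Static angle of repose in degrees, measured from the horizontal.
    """

    height: float
    alpha: float

    def __post_init__(self) -> None:
        _check_positive(height=self.height)
        _check_alpha(self.alpha)

    @property
    def radius(self) -> float:
        return cone_radius(self.height, self.alpha)

    @property
    def volume(self) -> float:
        return cone_volume(self.height, self.alpha)


@dataclass(frozen=True)
class GeometryCoefficients:
    """Unit-scale power-law coefficients implied by cone geometry.

    ``b_geom`` is the proportionality factor of ``h = b_geom * V^(1/3)``;
    the exponent ``c_geom`` is exactly 1/3 for any cone.  Converting
    ``b_geom`` into flow-curve units (pixels per second^(1/3)) requires the
    pixel/volume calibration of the rig, which is left to the caller.
    """

    b_geom: float
    c_geom: float = 1.0 / 3.0


@dataclass(frozen=True)
class OrificeFlowParams:
    """Inputs of the Brown–Richards orifice discharge rate.

    Attributes
    ----------
    K : float
        Dimensionless material constant.
    A : float
        Outlet cross-section area (mm^2).
    h_bed : float
        Powder bed height above the outlet (mm).
    rho_t : float
        Powder density (g/mm^3).
    g : float
        Gravitational acceleration (mm/s^2).
    """

    K: float
    A: float
    h_bed: float
    rho_t: float
    g: float = 9810.0

    def __post_init__(self) -> None:
        _check_positive(
            K=self.K, A=self.A, h_bed=self.h_bed, rho_t=self.rho_t, g=self.g
        )


def sphericity_index(projected_area: float, perimeter: float) -> float:
    """Isoperimetric sphericity ``4*pi*A / P**2`` of a 2-D silhouette.

    Equals 1 for a perfect circle and decreases with elongation or
    roughness.  Values marginally above 1, which can arise when the
    perimeter of a pixelated shape is slightly under-estimated, are clamped
    to 1 with a warning.

    Parameters
    ----------
    projected_area : float
        2-D projected area of the particle (px^2 or any length^2).
    perimeter : float
        Perimeter in matching length units (typically a Crofton estimate).
    """
    _check_positive(projected_area=projected_area, perimeter=perimeter)
    psi = 4.0 * math.pi * projected_area / perimeter**2
    if psi > 1.0:
        warnings.warn(
            f"sphericity {psi:.6g} > 1 from discretized input; clamped to 1",
            stacklevel=2,
        )
        return 1.0
    return psi


def cone_radius(height: float, alpha: float) -> float:
    """Base radius of a cone of given height and angle of repose (degrees)."""
    _check_positive(height=height)
    return height / math.tan(_check_alpha(alpha))


def cone_volume(height: float, alpha: float) -> float:
    """Volume ``pi*h^3 / (3*tan(alpha)^2)`` of an ideal conical pile."""
    _check_positive(height=height)
    return math.pi * height**3 / (3.0 * math.tan(_check_alpha(alpha)) ** 2)


def cone_height(volume: float, alpha: float) -> float:
    """Height of the cone holding ``volume``; inverse of :func:`cone_volume`.

    ``h = (3 V tan(alpha)^2 / pi)^(1/3)``, strictly increasing in ``V``.
    """
    _check_positive(volume=volume)
    return (3.0 * volume * math.tan(_check_alpha(alpha)) ** 2 / math.pi) ** (
        1.0 / 3.0
    )


def geometry_coefficients(alpha: float) -> GeometryCoefficients:
    """Power-law coefficients of cone growth at constant volumetric feed.

    Returns ``b_geom = (3/pi)^(1/3) * tan(alpha)^(2/3)`` (unit volume scale)
    and ``c_geom = 1/3`` exactly.  ``b_geom`` increases with alpha: steeper
    material builds height faster for the same fed volume.
    """
    rad = _check_alpha(alpha)
    b_geom = (3.0 / math.pi) ** (1.0 / 3.0) * math.tan(rad) ** (2.0 / 3.0)
    return GeometryCoefficients(b_geom=b_geom)


def brown_richards_rate(params: OrificeFlowParams) -> float:
    """Brown–Richards mass discharge rate through an orifice.

    ``Q = K * A * sqrt(2 * g * h_bed) * rho_t`` — the standard funnel-flow
    correlation; used as the simulator's default feed rate.
    """
    p = params
    return p.K * p.A * math.sqrt(2.0 * p.g * p.h_bed) * p.rho_t
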