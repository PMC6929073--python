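"""Ray optics of a trapezoidal ATR prism and evanescent-field sampling.

In attenuated total reflection (ATR) spectroscopy the infrared beam is
coupled into a high-index crystal (here ZnS, n ~ 2.2 at 10 um) through a
slanted entry facet, undergoes a series of total internal reflections
between the parallel top and bottom facets, and exits through the opposite
slanted facet.  At every reflection on the facet that carries the sample an
evanescent field leaks into the medium; its 1/e decay length d_p (Harrick
formula) sets the effective optical pathlength through the sample:

    d_p = lambda / (2 pi n1 sqrt(sin^2(theta) - (n2/n1)^2))

with lambda the in-vacuo wavelength, n1/n2 the crystal/sample indices and
theta the internal angle of incidence.  The quantity actually probed by an
absorbance measurement is an *effective sampling depth*, conventionally a
small multiple of d_p, times the number of sample-facet reflections.

This module provides a 2-D specular ray tracer for the trapezoid cross
section (replacing a commercial 3-D ray tracer: the prism is translationally
invariant along its width, so the bounce pattern is planar) and the
evanescent-depth calculator used by the instrument simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "PrismGeometry",
    "RayTraceResult",
    "EvanescentResult",
    "TotalInternalReflectionError",
    "RayGeometryError",
    "trace_prism",
    "penetration_depth",
    "sampling_profile",
    "DEFAULT_DEPTH_FACTOR",
]

#: Effective-sampling-depth multiplier applied to the Harrick d_p.  With
#: n1 = 2.2, n2 = 1.3 and 45 deg incidence this places the sampling depth at
#: 4.0 um (1200 cm-1) to 5.2 um (925 cm-1), i.e. inside the 4-5.4 um band
#: expected for this crystal, and the 5-reflection interaction length at
#: 20-26 um.  Calibration choice, not a first-principles constant.
DEFAULT_DEPTH_FACTOR = 2.6

_EPS = 1e-9


class TotalInternalReflectionError(ValueError):
    """Incidence angle at a sampling facet is at or below the critical angle."""


class RayGeometryError(ValueError):
    """A ray left the prism somewhere other than the exit facet."""


@dataclass(frozen=True)
class PrismGeometry:
    """Trapezoidal ATR prism cross section.

    The top facet (length ``top_facet_length``) carries the sample; the two
    slanted facets make ``facet_angle`` degrees with the horizontal and act
    as entry/exit windows.  Lengths in mm, angle in degrees.
    """

    top_facet_length: float = 24.0
    top_facet_width: float = 6.0
    height: float = 2.4
    facet_angle: float = 45.0
    refractive_index_prism: float = 2.2
    refractive_index_sample: float = 1.3

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("prism height must be positive")
        if not 0.0 < self.facet_angle < 90.0:
            raise ValueError("facet angle must lie strictly between 0 and 90 degrees")
        n1, n2 = self.refractive_index_prism, self.refractive_index_sample
        if not n1 > n2 > 0:
            raise ValueError("need refractive_index_prism > refractive_index_sample > 0")
        if self.top_facet_length <= 0 or self.top_facet_width <= 0:
            raise ValueError("facet dimensions must be positive")
        # bottom facet may degenerate to a point (triangular prism) but not invert
        if self.bottom_facet_length < -_EPS:
            raise ValueError(
                "slanted facets overlap: top facet shorter than 2*height/tan(angle)"
            )

    @property
    def facet_run(self) -> float:
        """Horizontal extent of each slanted facet, height / tan(angle)."""
        return self.height / math.tan(math.radians(self.facet_angle))

    @property
    def bottom_facet_length(self) -> float:
        return self.top_facet_length - 2.0 * self.facet_run

    @property
    def critical_angle(self) -> float:
        """Critical angle for total internal reflection, degrees from normal."""
        return math.degrees(
            math.asin(self.refractive_index_sample / self.refractive_index_prism)
        )


@dataclass(frozen=True)
class RayTraceResult:
    total_reflections: int
    top_facet_reflections: int
    bottom_facet_reflections: int
    propagation_length: float  # mm, central ray
    max_radial_pathlength_difference: float  # mm, worst marginal ray vs central


@dataclass(frozen=True)
class EvanescentResult:
    wavenumber: float  # cm-1
    wavelength: float  # um
    penetration_depth: float  # um, Harrick d_p
    sampling_depth: float  # um, effective_depth_factor * d_p
    interaction_length: float  # um, sampling_depth * top-facet reflections


def _segments(geom: PrismGeometry):
    """Facet segments as (name, (ax, ay), (bx, by)) in the trace frame.

    Origin at the top-left corner of the top facet; y downwards is negative,
    here we put the bottom facet at y=0 and the top facet at y=height with
    x in [0, top_facet_length].
    """
    h = geom.height
    L = geom.top_facet_length
    r = geom.facet_run
    return (
        ("top", (0.0, h), (L, h)),
        ("bottom", (r, 0.0), (L - r, 0.0)),
        ("entry", (0.0, h), (r, 0.0)),
        ("exit", (L - r, 0.0), (L, h)),
    )


def _next_hit(p, d, segs):
    """Nearest forward intersection of ray p + t d with the facet segments."""
    best = None
    for name, a, b in segs:
        ex, ey = b[0] - a[0], b[1] - a[1]
        denom = d[0] * (-ey) + d[1] * ex  # cross products for the 2x2 solve
        if abs(denom) < 1e-14:
            continue  # parallel
        rx, ry = a[0] - p[0], a[1] - p[1]
        t = (rx * (-ey) + ry * ex) / denom
        s = (d[0] * ry - d[1] * rx) / denom
        if t > _EPS and -_EPS <= s <= 1.0 + _EPS:
            if best is None or t < best[0]:
                best = (t, name, (p[0] + t * d[0], p[1] + t * d[1]))
    return best


def _trace_ray(geom: PrismGeometry, origin, direction, *, check_tir: bool = True):
    """Specular 2-D bounce trace from origin to the exit facet.

    Returns (top_count, bottom_count, path_length_mm).  Raises
    TotalInternalReflectionError when a top/bottom incidence falls below the
    critical angle, RayGeometryError when the ray re-exits the entry facet
    or fails to terminate.
    """
    segs = _segments(geom)
    sin_crit = geom.refractive_index_sample / geom.refractive_index_prism
    p = origin
    d = direction
    n_top = n_bottom = 0
    length = 0.0
    for _ in range(100000):
        hit = _next_hit(p, d, segs)
        if hit is None:
            raise RayGeometryError(
                f"ray escaped without hitting a facet (at {p}, direction {d})"
            )
        t, name, q = hit
        length += t
        if name == "exit":
            return n_top, n_bottom, length
        if name == "entry":
            raise RayGeometryError(
                f"ray returned to the entry facet at {q} after "
                f"{n_top + n_bottom} reflections"
            )
        # horizontal facet: incidence angle from the vertical normal
        if check_tir and abs(d[0]) <= sin_crit + 1e-12:
            theta = math.degrees(math.asin(min(1.0, abs(d[0]))))
            raise TotalInternalReflectionError(
                f"incidence angle {theta:.2f} deg at the {name} facet is below "
                f"the critical angle {geom.critical_angle:.2f} deg"
            )
        if name == "top":
            n_top += 1
        else:
            n_bottom += 1
        p = q
        d = (d[0], -d[1])
    raise RayGeometryError("ray failed to reach the exit facet (bounce limit)")


def _entry_ray(geom: PrismGeometry, offset_mm: float = 0.0, tilt_rad: float = 0.0):
    """Ray entering normal to the entry facet, offset along it from its midpoint.

    ``offset_mm`` is signed distance along the facet (positive towards the top
    corner); ``tilt_rad`` rotates the direction away from the facet normal.
    """
    phi = math.radians(geom.facet_angle)
    r = geom.facet_run
    h = geom.height
    # entry facet runs from (0, h) to (r, 0); unit vector pointing up-left
    ux, uy = -math.sin(phi), math.cos(phi)
    mx, my = r / 2.0, h / 2.0
    p = (mx + offset_mm * ux, my + offset_mm * uy)
    # inward facet normal
    base = math.atan2(math.cos(phi), math.sin(phi))  # angle of the normal (sin, cos)
    ang = base + tilt_rad
    d = (math.cos(ang), math.sin(ang))
    return p, d


def trace_prism(
    geometry: PrismGeometry,
    beam_diameter: float = 400.0,
    numerical_aperture: float = 0.0,
) -> RayTraceResult:
    """Trace the central ray (plus marginal rays) through the prism.

    The central ray enters at the midpoint of the entry facet at normal
    incidence, so it propagates undeviated at the facet angle.  With
    ``numerical_aperture`` > 0 and/or a finite ``beam_diameter`` (um),
    marginal rays at the internal divergence half-angle asin(NA/n1) and at
    the beam-edge offsets are traced as well and the largest propagation
    length difference relative to the central ray is reported.

    Raises
    ------
    TotalInternalReflectionError
        if any traced incidence on the top/bottom facets falls below the
        critical angle asin(n2/n1).
    RayGeometryError
        if a ray exits anywhere other than the exit facet.
    """
    if not 0.0 <= numerical_aperture < 1.0:
        raise ValueError("numerical_aperture must lie in [0, 1)")
    if beam_diameter < 0:
        raise ValueError("beam_diameter must be non-negative")

    p0, d0 = _entry_ray(geometry)
    n_top, n_bottom, length = _trace_ray(geometry, p0, d0)

    max_diff = 0.0
    half_angle = (
        math.asin(numerical_aperture / geometry.refractive_index_prism)
        if numerical_aperture > 0
        else 0.0
    )
    half_beam_mm = beam_diameter / 2.0 / 1000.0
    offsets = [o for o in (-half_beam_mm, 0.0, half_beam_mm) if o != 0.0 or True]
    tilts = [a for a in (-half_angle, 0.0, half_angle)]
    if half_angle > 0.0 or half_beam_mm > 0.0:
        for off in offsets:
            for tilt in tilts:
                if off == 0.0 and tilt == 0.0:
                    continue
                pm, dm = _entry_ray(geometry, off, tilt)
                _, _, lm = _trace_ray(geometry, pm, dm)
                max_diff = max(max_diff, abs(lm - length))

    return RayTraceResult(
        total_reflections=n_top + n_bottom,
        top_facet_reflections=n_top,
        bottom_facet_reflections=n_bottom,
        propagation_length=length,
        max_radial_pathlength_difference=max_diff,
    )


@lru_cache(maxsize=32)
def _top_reflections(geometry: PrismGeometry) -> int:
    return trace_prism(geometry, beam_diameter=0.0, numerical_aperture=0.0).top_facet_reflections


def penetration_depth(
    geometry: PrismGeometry,
    wavenumber: float,
    effective_depth_factor: float = DEFAULT_DEPTH_FACTOR,
    n_top_reflections: int | None = None,
) -> EvanescentResult:
    """Evanescent-field parameters at one wavenumber (cm-1).

    The Harrick penetration depth d_p is evaluated at the internal incidence
    angle (equal to the facet angle for normal entry), the sampling depth is
    ``effective_depth_factor * d_p``, and the interaction length multiplies
    the sampling depth by the number of top-facet (sample-side) reflections,
    traced from the geometry unless given explicitly.
    """
    if wavenumber <= 0:
        raise ValueError("wavenumber must be positive (cm-1)")
    n1 = geometry.refractive_index_prism
    n2 = geometry.refractive_index_sample
    theta = math.radians(geometry.facet_angle)
    disc = math.sin(theta) ** 2 - (n2 / n1) ** 2
    if disc <= 0:
        raise TotalInternalReflectionError(
            f"incidence angle {geometry.facet_angle:.2f} deg does not exceed the "
            f"critical angle {geometry.critical_angle:.2f} deg: no evanescent confinement"
        )
    wavelength = 1.0e4 / wavenumber  # um
    d_p = wavelength / (2.0 * math.pi * n1 * math.sqrt(disc))
    sampling = effective_depth_factor * d_p
    if n_top_reflections is None:
        n_top_reflections = _top_reflections(geometry)
    return EvanescentResult(
        wavenumber=float(wavenumber),
        wavelength=wavelength,
        penetration_depth=d_p,
        sampling_depth=sampling,
        interaction_length=sampling * n_top_reflections,
    )


def sampling_profile(
    geometry: PrismGeometry,
    wavenumbers: np.ndarray,
    effective_depth_factor: float = DEFAULT_DEPTH_FACTOR,
    n_top_reflections: int | None = None,
) -> np.ndarray:
    """Vectorised ATR interaction length (um) over a wavenumber array."""
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    if np.any(wavenumbers <= 0):
        raise ValueError("wavenumbers must be positive (cm-1)")
    n1 = geometry.refractive_index_prism
    n2 = geometry.refractive_index_sample
    theta = math.radians(geometry.facet_angle)
    disc = math.sin(theta) ** 2 - (n2 / n1) ** 2
    if disc <= 0:
        raise TotalInternalReflectionError(
            "incidence angle does not exceed the critical angle"
        )
    if n_top_reflections is None:
        n_top_reflections = _top_reflections(geometry)
    d_p = (1.0e4 / wavenumbers) / (2.0 * math.pi * n1 * math.sqrt(disc))
    return effective_depth_factor * d_p * n_top_reflections
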