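"""Vessel and aneurysm geometry, wall mechanics, and compliance summaries.

A vessel segment is an axisymmetric elastic tube whose healthy lumen radius
tapers linearly from inlet to outlet.  A fusiform aneurysm is an axisymmetric
outward bump added to the healthy radius; two families are supported:

* ``arc``    -- the laboratory shape: a central circular arc of radius ``R_A``
  tangentially conjugated to the straight wall through arcs of radius ``R_s``,
  so the profile is C1 everywhere;
* ``cosine`` -- the classic smooth bump
  ``a(x) = a0(x) + k * a0(x) * (1 - cos(2*pi*(x-x1)/L_A))/2``.

The aneurysm acts on long pulse waves as a lumped extra compliance.  Its two
scalar summaries are the excess volume compliance ``dC_A`` (m^3/Pa) and the
dimensionless ratio ``K`` of that excess to the compliance of an equally long
healthy vessel.  For a uniform-stiffness wall ``K`` depends on the lumen
profile only::

    K = (1/L_A) * integral( (a_A(x)/a_v(x))**3 - 1 ) dx

and the reflection time constant is ``tau = (L_A / 2 c0) * K``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from scipy.integrate import quad

__all__ = [
    "GeometryError",
    "FluidProperties",
    "AneurysmProfile",
    "VesselSegment",
    "ComplianceSummary",
    "plate_modulus",
    "wave_speed",
    "adan_wall_thickness",
    "arc_aneurysm_radius",
    "cosine_aneurysm_radius",
    "compute_K",
    "excess_compliance",
    "tau_from_geometry",
    "segment_compliance_summary",
]

#: Absolute quadrature tolerance, relative to the integrand scale.
QUAD_TOL = 1e-10


class GeometryError(ValueError):
    """Raised for physically impossible or infeasible geometry requests."""


@dataclass(frozen=True)
class FluidProperties:
    """Working-fluid density (kg/m^3) and dynamic viscosity (Pa s)."""

    density: float = 1000.0
    viscosity: float = 1.0e-3

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise GeometryError(f"density must be positive, got {self.density}")
        if self.viscosity < 0:
            raise GeometryError(f"viscosity must be >= 0, got {self.viscosity}")


def plate_modulus(E: float, poisson: float) -> float:
    """Plate/shell effective Young modulus ``E' = E / (1 - sigma^2)``."""
    if not 0.0 <= poisson < 1.0:
        raise GeometryError(f"Poisson ratio must be in [0, 1), got {poisson}")
    return E / (1.0 - poisson**2)


def wave_speed(a0, h, E: float, poisson: float = 0.5, rho: float = 1000.0):
    """Unperturbed pulse wave speed ``c0 = sqrt(h E' / (2 rho a0))`` (m/s).

    ``a0`` and ``h`` may be scalars or arrays (m); ``E`` in Pa.  This is the
    Moens-Korteweg-type speed of the pressure-area law
    ``p = p_ext + beta*(sqrt(A)-sqrt(A0))``, i.e. ``c0^2 = beta*sqrt(A0)/2rho``.
    """
    a0 = np.asarray(a0, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(a0 <= 0) or np.any(h <= 0) or E <= 0 or rho <= 0:
        raise GeometryError("wave_speed arguments must be positive")
    c = np.sqrt(h * plate_modulus(E, poisson) / (2.0 * rho * a0))
    return float(c) if c.ndim == 0 else c


def adan_wall_thickness(a0_cm):
    """Arterial wall thickness law ``h(a0)``, both in centimetres.

    ``h = a0 * (0.2802 exp(-5.053 a0) + 0.1324 exp(-0.1114 a0))`` with the
    radius expressed in cm (the convention of the source network model).  The
    unit is part of the signature on purpose: callers working in SI convert
    explicitly.
    """
    a0_cm = np.asarray(a0_cm, dtype=float)
    if np.any(a0_cm <= 0):
        raise GeometryError("radius must be positive")
    h = a0_cm * (0.2802 * np.exp(-5.053 * a0_cm) + 0.1324 * np.exp(-0.1114 * a0_cm))
    return float(h) if h.ndim == 0 else h


def arc_aneurysm_radius(a_v: float, D: float, L_A: float, R_s: float) -> Callable:
    """Laboratory arc-profile aneurysm radius function on ``[0, L_A]`` (m).

    The generatrix is a central outward circular arc of radius ``R_A``
    tangentially joined to the straight wall (radius ``a_v``) at both ends
    through conjugation arcs of radius ``R_s``.  Tangency between the two
    circles fixes the free parameter:

        R_A = ((L_A/2)^2 + d^2 - 2 d R_s) / (2 d),   d = D/2 - a_v.

    Returns a vectorised callable ``a_A(x)`` with ``a_A(0)=a_A(L_A)=a_v`` and
    peak ``D/2`` at ``L_A/2``.
    """
    if L_A <= 0 or R_s <= 0 or a_v <= 0:
        raise GeometryError("a_v, L_A and R_s must be positive")
    d = 0.5 * D - a_v
    if d < 0:
        raise GeometryError(f"peak diameter D={D} smaller than vessel diameter {2*a_v}")
    if d == 0.0:
        def flat(x):
            x = np.asarray(x, dtype=float)
            r = np.full_like(x, a_v)
            return float(r) if r.ndim == 0 else r
        return flat

    X = 0.5 * L_A
    R_A = (X * X + d * d - 2.0 * d * R_s) / (2.0 * d)
    if R_A <= 0:
        raise GeometryError(
            f"no tangent arc fits: D={D}, L_A={L_A}, R_s={R_s} (R_A={R_A:.3g} <= 0)"
        )
    # tangency point between conjugation and central circle, left half
    x_t = X * R_s / (R_s + R_A)
    y_cA = a_v + d - R_A          # centre height of the central circle

    def profile(x):
        x = np.asarray(x, dtype=float)
        xs = np.minimum(x, L_A - x)          # fold onto the left half
        r = np.full_like(xs, a_v)
        conj = (xs >= 0) & (xs < x_t)
        main = xs >= x_t
        r[conj] = a_v + R_s - np.sqrt(R_s**2 - xs[conj] ** 2)
        r[main] = y_cA + np.sqrt(np.maximum(R_A**2 - (xs[main] - X) ** 2, 0.0))
        r[xs < 0] = a_v
        return float(r) if r.ndim == 0 else r

    return profile


def cosine_aneurysm_radius(
    a0: Callable, k_delta: float, x1: float, L_A: float
) -> Callable:
    """Cosine-bump aneurysm: ``a = a0(x) (1 + k/2 (1 - cos(2 pi (x-x1)/L_A)))``.

    ``a0`` is the healthy radius function; outside ``[x1, x1+L_A]`` the healthy
    radius is returned unchanged.
    """
    if L_A <= 0:
        raise GeometryError("L_A must be positive")
    if k_delta < 0:
        raise GeometryError("k_delta must be >= 0")

    def profile(x):
        x = np.asarray(x, dtype=float)
        base = np.asarray(a0(x), dtype=float)
        inside = (x >= x1) & (x <= x1 + L_A)
        bump = np.zeros_like(base)
        xi = np.asarray(x, dtype=float)[inside]
        bump[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (xi - x1) / L_A))
        r = base * (1.0 + k_delta * bump)
        return float(r) if r.ndim == 0 else r

    return profile


def _as_function(f) -> Callable:
    if callable(f):
        return f
    val = float(f)
    return lambda x: np.full_like(np.asarray(x, dtype=float), val)


def compute_K(a_A, a_v, L_A: float) -> float:
    """Excess-compliance ratio ``K = (1/L_A) int ((a_A/a_v)^3 - 1) dx``.

    ``a_A`` and ``a_v`` are radius functions (or scalars) on ``[0, L_A]``.  The
    ratio is taken pointwise, which for tapered vessels generalises the
    constant-radius form consistently (the taper cancels when the bump is a
    multiple of the healthy radius).
    """
    if L_A <= 0:
        raise GeometryError("L_A must be positive")
    fA = _as_function(a_A)
    fv = _as_function(a_v)

    def integrand(x):
        av = float(np.asarray(fv(x)))
        if av <= 0:
            raise GeometryError(f"healthy radius must be positive at x={x}")
        return (float(np.asarray(fA(x))) / av) ** 3 - 1.0

    val, _ = quad(integrand, 0.0, L_A, epsabs=QUAD_TOL * L_A, epsrel=1e-12, limit=200)
    return val / L_A


def excess_compliance(a_A, a_v, Ep_A, h_A, Ep_v=None, h_v=None, L_A: float = None) -> float:
    """Excess volume compliance of the aneurysm over the healthy vessel.

    ``dC_A = int_0^L_A ( 2 pi a_A^3/(E'_A h_A) - 2 pi a_v^3/(E'_v h_v) ) dx``
    in m^3/Pa.  All profile arguments may be scalars or callables of x; the
    stiffness of the healthy wall defaults to that of the aneurysm wall.
    """
    if L_A is None or L_A <= 0:
        raise GeometryError("L_A must be positive")
    fA, fv = _as_function(a_A), _as_function(a_v)
    fEpA, fhA = _as_function(Ep_A), _as_function(h_A)
    fEpv = _as_function(Ep_v if Ep_v is not None else Ep_A)
    fhv = _as_function(h_v if h_v is not None else h_A)

    def integrand(x):
        eA = float(np.asarray(fEpA(x))) * float(np.asarray(fhA(x)))
        ev = float(np.asarray(fEpv(x))) * float(np.asarray(fhv(x)))
        if eA <= 0 or ev <= 0:
            raise GeometryError(f"wall stiffness must be positive at x={x}")
        return 2.0 * np.pi * (
            float(np.asarray(fA(x))) ** 3 / eA - float(np.asarray(fv(x))) ** 3 / ev
        )

    scale = 2.0 * np.pi * float(np.asarray(fv(0.0))) ** 3 / (
        float(np.asarray(fEpv(0.0))) * float(np.asarray(fhv(0.0)))
    )
    val, _ = quad(integrand, 0.0, L_A, epsabs=QUAD_TOL * scale * L_A, epsrel=1e-12,
                  limit=200)
    return val


def tau_from_geometry(L_A: float, c0: float, K: float) -> float:
    """Reflection time constant ``tau = (L_A / 2 c0) * K`` in seconds."""
    if L_A <= 0 or c0 <= 0:
        raise GeometryError("L_A and c0 must be positive")
    return 0.5 * L_A / c0 * K


@dataclass(frozen=True)
class AneurysmProfile:
    """Parametric description of one fusiform aneurysm bump.

    ``kind`` is ``"arc"`` (laboratory circular-arc generatrix; needs
    ``peak_diameter`` and ``conjugation_radius``) or ``"cosine"`` (needs the
    radius-increment scale ``k_delta``).  ``x1`` is the bump start measured
    from the host-segment inlet; ``length`` is the full bump footprint.  All
    lengths in metres.
    """

    kind: str
    x1: float
    length: float
    peak_diameter: Optional[float] = None
    conjugation_radius: Optional[float] = None
    k_delta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("arc", "cosine"):
            raise GeometryError(f"unknown aneurysm kind {self.kind!r}")
        if self.length <= 0:
            raise GeometryError("aneurysm length must be positive")
        if self.kind == "arc":
            if self.peak_diameter is None or self.conjugation_radius is None:
                raise GeometryError("arc aneurysm needs peak_diameter and conjugation_radius")
        elif self.k_delta is None:
            raise GeometryError("cosine aneurysm needs k_delta")

    def radius(self, healthy: Callable) -> Callable:
        """Radius function (full segment coordinate) given the healthy one."""
        if self.kind == "cosine":
            return cosine_aneurysm_radius(healthy, self.k_delta, self.x1, self.length)
        a_v = float(np.asarray(healthy(self.x1 + 0.5 * self.length)))
        bump = arc_aneurysm_radius(
            a_v, self.peak_diameter, self.length, self.conjugation_radius
        )

        def profile(x):
            x = np.asarray(x, dtype=float)
            base = np.asarray(healthy(x), dtype=float)
            inside = (x >= self.x1) & (x <= self.x1 + self.length)
            r = base.copy()
            r[inside] = np.maximum(bump(x[inside] - self.x1), base[inside])
            return float(r) if r.ndim == 0 else r

        return profile


@dataclass
class VesselSegment:
    """One elastic tube of the network.

    Lengths in m, moduli in Pa.  ``wall_thickness`` is a scalar (m), a callable
    ``h(x)`` in m, or the string ``"adan"`` for the radius-dependent arterial
    law (evaluated on the healthy radius).  ``dx_hint`` lets network builders
    mesh short stiff segments coarsely.
    """

    name: str
    length: float
    radius_in: float
    radius_out: float
    wall_thickness: Union[float, str, Callable] = 2.0e-3
    youngs_modulus: float = 2.8e6
    poisson: float = 0.5
    external_pressure: float = 0.0
    aneurysm: Optional[AneurysmProfile] = None
    dx_hint: Optional[float] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise GeometryError(f"{self.name}: length must be positive")
        if self.radius_in <= 0 or self.radius_out <= 0:
            raise GeometryError(f"{self.name}: radii must be positive")
        if self.youngs_modulus <= 0:
            raise GeometryError(f"{self.name}: Young modulus must be positive")
        if not 0.0 <= self.poisson <= 0.5:
            raise GeometryError(f"{self.name}: Poisson ratio must be in [0, 0.5]")
        if isinstance(self.wall_thickness, str) and self.wall_thickness != "adan":
            raise GeometryError(f"{self.name}: unknown thickness law {self.wall_thickness!r}")
        if isinstance(self.wall_thickness, (int, float)) and self.wall_thickness <= 0:
            raise GeometryError(f"{self.name}: wall thickness must be positive")
        if self.aneurysm is not None:
            a = self.aneurysm
            if a.x1 < 0 or a.x1 + a.length > self.length + 1e-12:
                raise GeometryError(f"{self.name}: aneurysm footprint outside segment")

    # -- radius / wall fields -------------------------------------------------

    def radius_healthy(self, x):
        """Healthy lumen radius: linear taper inlet -> outlet."""
        x = np.asarray(x, dtype=float)
        r = self.radius_in + (self.radius_out - self.radius_in) * x / self.length
        return float(r) if r.ndim == 0 else r

    def radius(self, x):
        """Actual lumen radius, including the aneurysm bump if present."""
        if self.aneurysm is None:
            return self.radius_healthy(x)
        return self.aneurysm.radius(self.radius_healthy)(x)

    def thickness(self, x):
        """Wall thickness h(x) in m (ADAN law evaluated on the healthy radius)."""
        x = np.asarray(x, dtype=float)
        if callable(self.wall_thickness):
            h = np.asarray(self.wall_thickness(x), dtype=float)
        elif self.wall_thickness == "adan":
            h = np.asarray(adan_wall_thickness(self.radius_healthy(x) * 100.0)) / 100.0
        else:
            h = np.full_like(x, float(self.wall_thickness))
        return float(h) if h.ndim == 0 else h

    @property
    def plate_modulus(self) -> float:
        return plate_modulus(self.youngs_modulus, self.poisson)

    def area0(self, x):
        r = np.asarray(self.radius(x), dtype=float)
        a = np.pi * r * r
        return float(a) if a.ndim == 0 else a

    def beta(self, x):
        """Wall stiffness ``beta = sqrt(pi) h E' / A0`` of the tube law."""
        b = np.sqrt(np.pi) * np.asarray(self.thickness(x)) * self.plate_modulus \
            / np.asarray(self.area0(x))
        b = np.asarray(b, dtype=float)
        return float(b) if b.ndim == 0 else b

    def wave_speed0(self, x, rho: float = 1000.0):
        """Local unperturbed wave speed from the actual (bumped) radius."""
        return wave_speed(self.radius(x), self.thickness(x), self.youngs_modulus,
                          self.poisson, rho)

    def mean_wave_speed(self, rho: float = 1000.0, n: int = 257) -> float:
        """Wave speed of the healthy vessel averaged along the segment."""
        x = np.linspace(0.0, self.length, n)
        c = wave_speed(self.radius_healthy(x), self.thickness(x),
                       self.youngs_modulus, self.poisson, rho)
        return float(np.mean(c))


@dataclass(frozen=True)
class ComplianceSummary:
    """Lumped aneurysm indicators: dC_A (m^3/Pa), K (-), tau and tau0 (s)."""

    excess_compliance: float
    K: float
    tau: float
    tau0: float

    def __post_init__(self) -> None:
        if self.K < -1e-12 or self.excess_compliance < -1e-18:
            raise GeometryError("negative aneurysm compliance")


def segment_compliance_summary(segment: VesselSegment, rho: float = 1000.0) -> ComplianceSummary:
    """K, dC_A, tau0 and tau of the aneurysm embedded in ``segment``.

    The reference healthy vessel is the segment's linear taper; ``c0`` used in
    ``tau0 = (L_A/2)/c0`` is the healthy wave speed averaged over the bump
    footprint.  Returns an all-zero summary for a healthy segment.
    """
    if segment.aneurysm is None:
        return ComplianceSummary(0.0, 0.0, 0.0, 0.0)
    an = segment.aneurysm
    bumped = an.radius(segment.radius_healthy)
    a_A = lambda s: bumped(s + an.x1)
    a_v = lambda s: segment.radius_healthy(s + an.x1)
    K = compute_K(a_A, a_v, an.length)
    Ep = segment.plate_modulus
    h = lambda s: segment.thickness(s + an.x1)
    dca = excess_compliance(a_A, a_v, Ep, h, Ep, h, an.length)
    x = np.linspace(an.x1, an.x1 + an.length, 257)
    c0 = float(np.mean(wave_speed(segment.radius_healthy(x), segment.thickness(x),
                                  segment.youngs_modulus, segment.poisson, rho)))
    tau0 = 0.5 * an.length / c0
    return ComplianceSummary(dca, K, tau0 * K, tau0)
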