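"""Forward model for projected 2D diameters of sectioned spheres.

A spherical particle of diameter D intersected by (or adjacent to) a
section of thickness T shows a circular profile of apparent diameter d.
Particles with their centre inside the section show d = D; particles
centred a distance dz above/below a surface (dz < D/2) show a cap with
d = sqrt(D^2 - 4 dz^2) and cap angle theta = asin(d/D). Caps with theta
below the cap-angle limit phi are lost (unobserved).

For a 3D diameter density F(d) the observed 2D diameter density is

    G(d) = (T/zeta) F(d) + (d/zeta) int_d^{d/sin(phi)} F(y)/sqrt(y^2-d^2) dy

with zeta = T + mu_D cos(phi), the mean axial depth containing the
centres of observed particles. At phi = 0 the upper limit is infinite
and the model reduces to the classical thick-section (Bach) solution,
further reducing to Wicksell's planar-section solution at T = 0; at
phi = 90 deg all caps are lost and G = F.

phi is in degrees at every API surface (converted internally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from numpy.polynomial.legendre import leggauss

from .distributions import SizeDistribution

__all__ = [
    "SectionSpec",
    "ProjectionModel",
    "zeta",
    "g_density",
    "g_curve",
    "g_cdf",
    "lost_cap_density",
]

# denominator guard used by the raw-integrand quadrature variant
_SINGULARITY_GUARD = 1e-7


@dataclass(frozen=True)
class SectionSpec:
    """Section thickness T (>= 0) with a units label."""

    T: float
    units: str = "u.d."

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("section thickness T must be >= 0")


@dataclass(frozen=True)
class ProjectionModel:
    """F(d) + section + cap-angle limit: everything G(d) depends on."""

    dist: SizeDistribution
    section: SectionSpec
    phi: float  # cap-angle limit, degrees, in [0, 90]

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 90.0:
            raise ValueError("phi must be in [0, 90] degrees")

    @property
    def zeta(self) -> float:
        return zeta(self.section, self.dist.mu_D, self.phi)


def zeta(section: SectionSpec | float, mu_D: float, phi: float) -> float:
    """Mean axial depth of observed particle centres: T + mu_D cos(phi)."""
    T = section.T if isinstance(section, SectionSpec) else float(section)
    if mu_D <= 0:
        raise ValueError("mu_D must be positive")
    if not 0.0 <= phi <= 90.0:
        raise ValueError("phi must be in [0, 90] degrees")
    # cos(90 deg) must be exactly 0 so the T = 0 degenerate case is caught
    cos_phi = 0.0 if phi == 90.0 else np.cos(np.deg2rad(phi))
    return T + mu_D * cos_phi


def _upper_limit(d: np.ndarray, phi: float, support_max: float) -> np.ndarray:
    """Largest sphere diameter whose cap can appear with apparent diameter d.

    Cap geometry: a sphere of diameter y shows a cap of apparent diameter
    d only if d >= y sin(phi), i.e. y <= d/sin(phi). The limit is capped
    at the support maximum of F (F ~ 0 beyond).
    """
    if phi <= 0.0:
        return np.full_like(d, support_max)
    return np.minimum(d / np.sin(np.deg2rad(phi)), support_max)


def _cap_integral_curve(
    dist: SizeDistribution, d: np.ndarray, phi: float, n_nodes: int = 120
) -> np.ndarray:
    """Vectorised I(d) = int_d^{ymax} F(y)/sqrt(y^2 - d^2) dy.

    The substitution u^2 = y^2 - d^2 removes the inverse-square-root
    singularity at y = d, giving int_0^U F(sqrt(u^2+d^2))/sqrt(u^2+d^2) du
    with a smooth integrand, evaluated by fixed-order Gauss-Legendre
    simultaneously for all grid points.
    """
    d = np.atleast_1d(np.asarray(d, dtype=float))
    support_max = dist.support[1]
    ymax = _upper_limit(d, phi, support_max)
    U = np.sqrt(np.maximum(ymax * ymax - d * d, 0.0))
    x, w = leggauss(n_nodes)  # nodes on [-1, 1]
    u = 0.5 * U[:, None] * (x[None, :] + 1.0)
    y = np.sqrt(u * u + d[:, None] ** 2)
    vals = dist.pdf(y) / y
    return 0.5 * U * (vals * w[None, :]).sum(axis=1)


def _cap_integral_scalar(
    dist: SizeDistribution, d: float, phi: float, method: str, epsrel: float = 1e-8
) -> float:
    """Adaptive-quadrature cap integral at a single d.

    method="substitution" (default) integrates the smooth substituted
    integrand; method="guard" integrates the raw integrand with the
    denominator floored at 1e-7 near y = d, replicating the guard used
    by earlier numerical treatments of this integral.
    """
    support_max = dist.support[1]
    ymax = float(_upper_limit(np.array([d]), phi, support_max)[0])
    if ymax <= d:
        return 0.0
    if method == "substitution":
        U = np.sqrt(ymax * ymax - d * d)

        def integrand(u: float) -> float:
            y = np.sqrt(u * u + d * d)
            return dist.pdf(y) / y

        val, _ = integrate.quad(integrand, 0.0, U, epsrel=epsrel, limit=200)
    elif method == "guard":

        def integrand(y: float) -> float:
            den = np.sqrt(max(y * y - d * d, 0.0))
            return dist.pdf(y) / max(den, _SINGULARITY_GUARD)

        val, _ = integrate.quad(
            integrand, d, ymax, epsrel=epsrel, limit=400, points=[d]
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(val)


def g_density(model: ProjectionModel, d: float, method: str = "substitution") -> float:
    """Projected 2D diameter density G(d) at a single diameter d > 0."""
    if d <= 0:
        raise ValueError("d must be positive")
    T = model.section.T
    z = model.zeta
    if z <= 0:
        raise ValueError("degenerate model: zeta = 0 (T = 0 and phi = 90 deg)")
    interior = T / z * float(model.dist.pdf(d))
    if model.phi >= 90.0:
        cap = 0.0
    else:
        cap = d / z * _cap_integral_scalar(model.dist, d, model.phi, method)
    return max(interior + cap, 0.0)


def g_curve(model: ProjectionModel, d_grid: np.ndarray, n_nodes: int = 120) -> np.ndarray:
    """Vectorised G(d) on a strictly increasing grid of positive diameters."""
    d = np.asarray(d_grid, dtype=float)
    if d.ndim != 1 or d.size == 0 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
        raise ValueError("d_grid must be a strictly increasing vector of positive d")
    T = model.section.T
    z = model.zeta
    if z <= 0:
        raise ValueError("degenerate model: zeta = 0 (T = 0 and phi = 90 deg)")
    out = T / z * np.asarray(model.dist.pdf(d), dtype=float)
    if model.phi < 90.0:
        out = out + d / z * _cap_integral_curve(model.dist, d, model.phi, n_nodes)
    return np.maximum(out, 0.0)


def g_cdf(model: ProjectionModel, d_grid: np.ndarray, n_nodes: int = 120) -> np.ndarray:
    """Cumulative G on a grid (trapezoid of g_curve), clipped to [0, 1]."""
    g = g_curve(model, d_grid, n_nodes=n_nodes)
    c = np.concatenate([[0.0], integrate.cumulative_trapezoid(g, d_grid)])
    return np.clip(c, 0.0, 1.0)


def lost_cap_density(
    dist: SizeDistribution, phi: float, d_grid: np.ndarray
) -> np.ndarray:
    """Distribution of lost caps L(d) on a grid for a planar section.

    L is the difference between the no-loss curve G(d, phi=0) and the
    lossy curve G(d, phi), both at T = 0, after rescaling the lossy curve
    so the two agree in the far tail. The grid must extend to 3 mu_D; the
    tail matching is applied analytically as the zeta(phi)/zeta(0) ratio,
    which is the exact factor by which the two curves differ wherever the
    cap integrals coincide (d >= sin(phi) * support max) and remains
    defined when both tails have vanished at the last grid point.
    """
    d = np.asarray(d_grid, dtype=float)
    if d[-1] < 3.0 * dist.mu_D - 1e-9:
        raise ValueError("d_grid must extend to 3 * mu_D for the tail anchor")
    section = SectionSpec(T=0.0, units=dist.units)
    g0 = g_curve(ProjectionModel(dist, section, 0.0), d)
    if phi <= 0.0:
        return np.zeros_like(g0)
    z0 = zeta(section, dist.mu_D, 0.0)
    zphi = zeta(section, dist.mu_D, phi)
    if phi >= 90.0:  # all caps lost: L is the whole no-loss curve
        return g0
    gphi = g_curve(ProjectionModel(dist, section, phi), d)
    return np.maximum(g0 - gphi * (zphi / z0), 0.0)
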