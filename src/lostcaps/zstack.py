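"""3D analysis of particle profiles tracked through z-stacks.

Particles outlined plane-by-plane in a z-stack yield per-particle
(z-index, radius) series. Fitting each series to an axially stretched
circle

    r = sqrt((D/2)^2 - (z/E)^2),   z = z_index * S_z - z0

recovers the particle's diameter D, axial centre z0 and elliptical
eccentricity E (E = 1 spherical, E > 1 z-elongated). Because axial
tissue shrinkage makes the plane spacing S_z uncertain, S_z can be
estimated by requiring the mean fitted E of an isotropically oriented
sample to equal 1. The smallest outline diameter near each pole
(delta_min) gives a direct per-pole measurement of the cap-angle limit
phi = asin(delta_min/D). Tomography resolution formulas (Crowther and
the tilt-increment variant, plus the missing-wedge axial elongation)
estimate the achievable in-plane and axial resolution of such stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ZProfile",
    "TomographyResolution",
    "fit_profile",
    "fit_profiles",
    "estimate_sz",
    "measure_phi",
    "dmin_vs_D_fit",
    "tomo_resolution",
]


class UnfitProfileError(ValueError):
    """Raised for profiles with too few or one-sided data points."""


@dataclass
class ZProfile:
    """One particle's fitted z-profile and per-pole cap-angle measures."""

    particle_id: int
    z_index: np.ndarray
    radius: np.ndarray
    D: float | None = None
    z0: float | None = None
    E: float | None = None
    residual: float | None = None
    phi_north: float | None = None  # degrees; None if pole not interior
    phi_south: float | None = None
    pole_north_interior: bool = True
    pole_south_interior: bool = True

    @property
    def d_volume(self) -> float:
        """Equivalent-volume sphere diameter of the fitted ellipsoid, D E^(1/3)."""
        return self.D * self.E ** (1.0 / 3.0)


@dataclass
class TomographyResolution:
    """Single-axis tomography acquisition geometry and derived resolutions."""

    T_tissue: float  # tissue thickness (nm)
    N_tilt: int  # number of tilt images
    total_angle: float  # total scan angle (degrees)
    alpha_max: float  # maximum tilt angle (degrees)
    rho_x_crowther: float | None = None
    rho_x_tilt: float | None = None
    delta_tilt: float | None = None  # tilt increment (degrees)
    e_xz: float | None = None
    rho_z: float | None = None

    def __post_init__(self) -> None:
        if self.N_tilt < 1:
            raise ValueError("N_tilt must be >= 1")
        if not 0.0 < self.alpha_max <= 90.0:
            raise ValueError("alpha_max must be in (0, 90] degrees")


def _ellipse_params_from_parabola(z: np.ndarray, r: np.ndarray):
    """Closed-form start values: r^2 is a downward parabola in physical z."""
    c2, c1, c0 = np.polyfit(z, r * r, 2)
    if c2 >= 0:
        return None
    E = 1.0 / np.sqrt(-c2)
    z0 = -c1 / (2.0 * c2)
    half2 = c0 - c2 * z0 * z0
    if half2 <= 0:
        return None
    return 2.0 * np.sqrt(half2), z0, E


def fit_profile(
    profile: pd.DataFrame | np.ndarray, S_z: float, refine: bool = True
) -> tuple[float, float, float, float]:
    """Fit (D, z0, E, residual) to one (z_index, radius) series; S_z fixed.

    The radius-squared series is an exact quadratic in physical z, which
    gives closed-form start values; a damped least-squares refinement on
    the radius residuals follows (skippable with refine=False). Requires
    >= 3 points spanning both sides of the profile maximum.
    """
    if isinstance(profile, pd.DataFrame):
        zi = profile["z_index"].to_numpy(dtype=float)
        r = profile["radius"].to_numpy(dtype=float)
    else:
        arr = np.asarray(profile, dtype=float)
        zi, r = arr[:, 0], arr[:, 1]
    if zi.size < 3:
        raise UnfitProfileError("profile needs at least 3 planes")
    imax = int(np.argmax(r))
    if imax == 0 or imax == zi.size - 1:
        raise UnfitProfileError("profile must span both sides of its maximum")
    z = zi * S_z
    start = _ellipse_params_from_parabola(z, r)
    if start is None:
        raise UnfitProfileError("profile is not concave in r^2; cannot fit an ellipse")
    D0, z00, E0 = start
    if not refine:
        res = r - _ellipse_radius(z, D0, z00, E0)
        return float(D0), float(z00), float(E0), float(np.sum(res**2))

    def residual(x):
        return r - _ellipse_radius(z, x[0], x[1], abs(x[2]))

    sol = optimize.least_squares(residual, [D0, z00, E0], method="lm", xtol=1e-12, ftol=1e-12)
    D, z0, E = sol.x[0], sol.x[1], abs(sol.x[2])
    return float(abs(D)), float(z0), float(E), float(2.0 * sol.cost)


def _ellipse_radius(z: np.ndarray, D: float, z0: float, E: float) -> np.ndarray:
    val = (D / 2.0) ** 2 - ((z - z0) / E) ** 2
    return np.sqrt(np.maximum(val, 0.0))


def fit_profiles(
    profiles: pd.DataFrame, S_z: float, min_planes: int = 3
) -> list[ZProfile]:
    """Fit every particle in a long-format profiles table; unfittable
    profiles (too few planes, one-sided) are skipped."""
    out: list[ZProfile] = []
    for pid, grp in profiles.groupby("particle_id"):
        grp = grp.sort_values("z_index")
        if len(grp) < min_planes:
            continue
        try:
            D, z0, E, resid = fit_profile(grp, S_z)
        except UnfitProfileError:
            continue
        out.append(
            ZProfile(
                particle_id=int(pid),
                z_index=grp["z_index"].to_numpy(),
                radius=grp["radius"].to_numpy(),
                D=D,
                z0=z0,
                E=E,
                residual=resid,
            )
        )
    return out


def estimate_sz(
    profiles: pd.DataFrame,
    initial_sz: float,
    tol: float = 0.005,
    bracket_factor: float = 4.0,
) -> tuple[float, float]:
    """Estimate the axial plane spacing from the isotropy condition mean E = 1.

    The fitted eccentricity of each profile scales linearly with the
    trial S_z, so mean(E) - 1 has a single root; it is bracketed around
    ``initial_sz`` and solved to |mean E - 1| <= tol. Returns (S_z,
    achieved mean E). Assumes isotropic particle orientation - for a
    systematically z-elongated sample the result absorbs the elongation
    into S_z and is biased accordingly.
    """
    n_profiles = profiles["particle_id"].nunique()
    if n_profiles < 30:
        raise ValueError("estimate_sz needs >= 30 profiles for a stable mean E")

    def mean_e(sz: float) -> float:
        fits = fit_profiles(profiles, sz)
        if not fits:
            raise ValueError("no fittable profiles")
        return float(np.mean([f.E for f in fits]))

    lo, hi = initial_sz / bracket_factor, initial_sz * bracket_factor
    flo, fhi = mean_e(lo) - 1.0, mean_e(hi) - 1.0
    if flo * fhi > 0:
        raise ValueError(
            "mean fitted E = 1 is not bracketed; widen bracket_factor or "
            "check the initial S_z"
        )
    sz = optimize.brentq(lambda s: mean_e(s) - 1.0, lo, hi, xtol=initial_sz * 1e-6)
    achieved = mean_e(sz)
    if abs(achieved - 1.0) > tol:
        raise ValueError(f"converged mean E {achieved} misses 1.0 by more than {tol}")
    return float(sz), achieved


def measure_phi(
    zp: ZProfile,
    S_z: float,
    stack_z_range: tuple[float, float] | None = None,
) -> ZProfile:
    """Per-pole cap-angle limits phi = asin(delta_min/D).

    delta_min on each side is the outline diameter at the extreme
    measured plane on that side of the fitted centre. A pole is skipped
    (phi None) unless its physical position z0 +/- E*D/2 lies strictly
    inside the stack's z range.
    """
    if zp.D is None:
        raise ValueError("fit the profile before measuring phi")
    z = zp.z_index * S_z
    if stack_z_range is None:
        stack_z_range = (-np.inf, np.inf)
    north_pole = zp.z0 + zp.E * zp.D / 2.0
    south_pole = zp.z0 - zp.E * zp.D / 2.0
    zp.pole_north_interior = stack_z_range[0] < north_pole < stack_z_range[1]
    zp.pole_south_interior = stack_z_range[0] < south_pole < stack_z_range[1]

    def pole_phi(side_mask: np.ndarray) -> float | None:
        if not side_mask.any():
            return None
        extreme = np.argmax(np.abs(z[side_mask] - zp.z0))
        delta_min = 2.0 * zp.radius[side_mask][extreme]
        if delta_min > zp.D * (1.0 + 1e-9):
            raise ValueError("delta_min exceeds the fitted diameter")
        return float(np.rad2deg(np.arcsin(min(delta_min / zp.D, 1.0))))

    zp.phi_north = pole_phi(z > zp.z0) if zp.pole_north_interior else None
    zp.phi_south = pole_phi(z < zp.z0) if zp.pole_south_interior else None
    return zp


def dmin_vs_D_fit(pairs: np.ndarray) -> tuple[float, float]:
    """Fit delta_min = D sin(phi) through the origin; returns (phi, rss).

    ``pairs`` is an (n, 2) array of (D, delta_min) pole measurements,
    n >= 10. The sine of the slope is the population cap-angle limit
    under the size-independent-phi model.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 10:
        raise ValueError("need at least 10 (D, delta_min) pairs")
    D, dmin = arr[:, 0], arr[:, 1]
    slope = float(np.sum(D * dmin) / np.sum(D * D))
    if not 0.0 <= slope <= 1.0:
        raise ValueError(f"fitted slope {slope} outside [0, 1]")
    rss = float(np.sum((dmin - slope * D) ** 2))
    return float(np.rad2deg(np.arcsin(slope))), rss


def tomo_resolution(tr: TomographyResolution) -> TomographyResolution:
    """Fill in the in-plane and axial resolution estimates.

    rho_x is reported both by the Crowther formula T_tissue * pi/N_tilt
    (which assumes a 180 deg scan) and by the tilt-increment variant
    T_tissue * Delta_tilt (Delta_tilt in radians, = total angle/N_tilt).
    The missing wedge elongates the axial resolution by

        e_xz = sqrt((a + sin a cos a)/(a - sin a cos a)),  a = alpha_max,

    which tends to 1 as the tilt range approaches +/- 90 deg;
    rho_z = rho_x(tilt-increment) * e_xz.
    """
    tr.rho_x_crowther = tr.T_tissue * np.pi / tr.N_tilt
    tr.delta_tilt = tr.total_angle / tr.N_tilt
    tr.rho_x_tilt = tr.T_tissue * np.deg2rad(tr.delta_tilt)
    a = np.deg2rad(tr.alpha_max)
    sc = np.sin(a) * np.cos(a)
    denominator = a - sc
    if denominator <= 0:
        raise ValueError("alpha_max too small: axial elongation undefined")
    tr.e_xz = float(np.sqrt((a + sc) / denominator))
    tr.rho_z = tr.rho_x_tilt * tr.e_xz
    return tr
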