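"""2D-to-3D conversion of particle counts, densities and area fractions.

The observed 2D number density lambda_2D of spherical particles relates
to the 3D number density lambda_3D through the mean axial sampling depth
zeta = T + mu_D cos(phi):

    lambda_3D = lambda_2D / zeta

Setting phi = 0 recovers the classical Abercrombie thick-section
correction (no lost caps); substituting theta_min = asin(d_min/mu_D)
for phi gives the minimum-observed-diameter (Konigsmark-style)
correction. The volume fraction follows as VF = lambda_3D * E[(pi/6)D^3]
and, independently, from the observed area fraction via VF = K_v * AF
(Weibel-Paumgartner), with K_v a function of the size spread, relative
section thickness g = T/mu_D and the lost-cap term X = 1 - cos(phi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import SizeDistribution
from .keiding import zeta

__all__ = [
    "DensityEstimate",
    "lambda2d",
    "lambda3d_phi_correction",
    "lambda3d_dmin_correction",
    "volume_fraction",
    "kv_factor",
    "vf_from_af",
    "correction_table",
    "theta_min",
]

_METHODS = ("phi_correction", "abercrombie", "dmin_correction", "af_based", "direct3D")


@dataclass
class DensityEstimate:
    """One 3D density/volume-fraction estimate plus its provenance."""

    lambda2D: float | None = None
    zeta: float | None = None
    lambda3D: float | None = None
    VF: float | None = None
    AF: float | None = None
    K_v: float | None = None
    method: str = "phi_correction"
    vf_flagged: bool = False  # VF > 1: model-violating input

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}")


def lambda2d(count: int, area: float) -> float:
    """Particles per unit area of the counting frame."""
    if area <= 0:
        raise ValueError("area must be positive")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / area


def theta_min(d_min: float, mu_D: float) -> float:
    """Cap angle equivalent of the smallest observed diameter, degrees."""
    if not 0.0 <= d_min <= mu_D:
        raise ValueError("d_min must lie in [0, mu_D]")
    return float(np.rad2deg(np.arcsin(d_min / mu_D)))


def lambda3d_phi_correction(
    lambda2D: float, T: float, mu_D: float, phi: float
) -> DensityEstimate:
    """3D density via the cap-angle correction lambda_3D = lambda_2D / zeta.

    phi = 0 reduces to the Abercrombie correction lambda_2D/(T + mu_D).
    """
    z = zeta(T, mu_D, phi)
    if z <= 0:
        raise ValueError("zeta must be positive (T = 0 with phi = 90 deg is degenerate)")
    method = "abercrombie" if phi == 0.0 else "phi_correction"
    return DensityEstimate(lambda2D=lambda2D, zeta=z, lambda3D=lambda2D / z, method=method)


def lambda3d_dmin_correction(
    lambda2D: float, T: float, mu_D: float, d_min: float
) -> DensityEstimate:
    """3D density with theta_min = asin(d_min/mu_D) substituted for phi."""
    est = lambda3d_phi_correction(lambda2D, T, mu_D, theta_min(d_min, mu_D))
    est.method = "dmin_correction"
    return est


def volume_fraction(lambda3D: float, dist: SizeDistribution) -> DensityEstimate:
    """VF = lambda_3D * mean particle volume; VF > 1 is returned but flagged."""
    if lambda3D < 0:
        raise ValueError("lambda3D must be >= 0")
    vf = lambda3D * dist.mean_sphere_volume()
    return DensityEstimate(lambda3D=lambda3D, VF=vf, method="direct3D", vf_flagged=vf > 1.0)


def kv_factor(mu_D: float, sigma_D: float, T: float, phi: float) -> float:
    """Area-fraction-to-volume-fraction factor K_v for Gaussian-spread spheres.

    K_v = 2 m3 / (2 m3 + 3 g m2 - 3 X^2 + X^3) with the dimensionless
    Gaussian moments m2 = 1 + CV^2, m3 = 1 + 3 CV^2, the relative
    thickness g = T/mu_D and the lost-cap term X = 1 - cos(phi).
    """
    if mu_D <= 0:
        raise ValueError("mu_D must be positive")
    if T < 0:
        raise ValueError("T must be >= 0")
    if not 0.0 <= phi <= 90.0:
        raise ValueError("phi must be in [0, 90] degrees")
    cv2 = (sigma_D / mu_D) ** 2
    m2 = 1.0 + cv2
    m3 = 1.0 + 3.0 * cv2
    g = T / mu_D
    X = 1.0 - np.cos(np.deg2rad(phi))
    return float(2.0 * m3 / (2.0 * m3 + 3.0 * g * m2 - 3.0 * X**2 + X**3))


def vf_from_af(AF: float, K_v: float) -> DensityEstimate:
    """VF = K_v * AF; AF > 1 (overlapping outlines) is permitted but flagged."""
    if AF < 0:
        raise ValueError("AF must be >= 0")
    vf = K_v * AF
    return DensityEstimate(AF=AF, K_v=K_v, VF=vf, method="af_based", vf_flagged=AF > 1.0 or vf > 1.0)


def correction_table(
    lambda2D: float,
    T: float,
    mu_D: float,
    phi: float,
    d_min: float,
    truth_lambda3D: float | None = None,
) -> pd.DataFrame:
    """Compare the phi, d_min and Abercrombie corrections side by side.

    Delta columns are percent differences 100 (X_method - X_ref)/X_ref,
    rounded to the nearest integer. The reference is the phi-correction
    row unless a directly measured 3D truth is supplied, in which case
    the reference zeta is lambda_2D/truth.
    """
    rows = []
    ests = [
        lambda3d_phi_correction(lambda2D, T, mu_D, phi),
        lambda3d_dmin_correction(lambda2D, T, mu_D, d_min),
        lambda3d_phi_correction(lambda2D, T, mu_D, 0.0),
    ]
    ests[2].method = "abercrombie"
    if truth_lambda3D is not None:
        ref_lambda, ref_zeta = truth_lambda3D, lambda2D / truth_lambda3D
    else:
        ref_lambda, ref_zeta = ests[0].lambda3D, ests[0].zeta
    for est in ests:
        rows.append(
            {
                "method": est.method,
                "zeta": est.zeta,
                "lambda3D": est.lambda3D,
                "delta_zeta_pct": round(100.0 * (est.zeta - ref_zeta) / ref_zeta),
                "delta_lambda3D_pct": round(
                    100.0 * (est.lambda3D - ref_lambda) / ref_lambda
                ),
            }
        )
    return pd.DataFrame(rows)
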