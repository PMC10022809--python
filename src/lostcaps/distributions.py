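"""Parametric families for the 3D diameter distribution F(d).

Three families are supported, matching the shapes commonly fitted to
particle-diameter data: a Gaussian, a chi distribution (which arises in
the classical lost-caps literature) and an offset gamma distribution.
Both chi and gamma converge to a Gaussian as their shape parameter f
grows, so a large fitted f signals a Gaussian-like size distribution.

All lengths are unit-agnostic; simulation defaults use "unit diameters"
(u.d.), the normalisation in which the mean 3D diameter is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats
from scipy.special import gammaln

__all__ = ["SizeDistribution", "pdf", "moments", "mean_sphere_volume"]

_FAMILIES = ("gaussian", "chi", "gamma")


def _chi_gamma_ratio(f: float) -> float:
    """gamma-function ratio Gamma(w + 1/2)/Gamma(w) with w = f/2.

    Computed via log-gamma differences so large f does not overflow.
    """
    w = 0.5 * f
    return float(np.exp(gammaln(w + 0.5) - gammaln(w)))


def _chi_f_from_cv(cv: float) -> float:
    """Invert the chi coefficient of variation for the dof parameter f.

    For a chi distribution cv^2 = f/(2 g^2) - 1 with g the gamma-function
    ratio; cv is strictly decreasing in f, so a bracketed root works.
    """
    if cv <= 0:
        raise ValueError("cv must be positive to invert a chi distribution")

    def h(logf: float) -> float:
        f = np.exp(logf)
        g = _chi_gamma_ratio(f)
        return f / (2.0 * g * g) - 1.0 - cv * cv

    # cv^2 ~ 1/(2f) for large f; bracket generously in log-space.
    lo, hi = np.log(1e-3), np.log(1e9)
    if h(lo) < 0:  # cv larger than any chi can produce
        raise ValueError(f"no chi distribution has cv={cv}")
    logf = optimize.brentq(h, lo, hi, xtol=1e-12, rtol=1e-14)
    return float(np.exp(logf))


@dataclass(frozen=True)
class SizeDistribution:
    """Parametric 3D diameter density F(d).

    Use the constructors :meth:`gaussian`, :meth:`chi`, :meth:`gamma` or
    :meth:`from_moments` rather than the raw dataclass.

    Parameters by family:

    * ``gaussian`` -- ``mu`` (mean, length), ``sigma`` (sd, length > 0)
    * ``chi``      -- ``f`` (degrees of freedom > 0), ``beta`` (scale > 0)
    * ``gamma``    -- ``f`` (shape > 0), ``beta`` (scale > 0),
      ``d0`` (x-offset, length)
    """

    family: str
    mu: float | None = None
    sigma: float | None = None
    f: float | None = None
    beta: float | None = None
    d0: float = 0.0
    units: str = "u.d."
    _frozen: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {_FAMILIES}")
        if self.family == "gaussian":
            if self.mu is None or self.sigma is None or self.sigma <= 0:
                raise ValueError("gaussian requires mu and sigma > 0")
            frozen = stats.norm(loc=self.mu, scale=self.sigma)
        elif self.family == "chi":
            if self.f is None or self.beta is None or self.f <= 0 or self.beta <= 0:
                raise ValueError("chi requires f > 0 and beta > 0")
            frozen = stats.chi(self.f, scale=np.sqrt(self.beta))
        else:  # gamma
            if self.f is None or self.beta is None or self.f <= 0 or self.beta <= 0:
                raise ValueError("gamma requires f > 0 and beta > 0")
            frozen = stats.gamma(self.f, loc=self.d0, scale=self.beta)
        object.__setattr__(self, "_frozen", frozen)

    # ------------------------------------------------------------------
    # constructors
    @classmethod
    def gaussian(cls, mu: float, sigma: float, units: str = "u.d.") -> "SizeDistribution":
        return cls(family="gaussian", mu=mu, sigma=sigma, units=units)

    @classmethod
    def chi(
        cls,
        f: float | None = None,
        beta: float | None = None,
        mu: float | None = None,
        sigma: float | None = None,
        units: str = "u.d.",
    ) -> "SizeDistribution":
        """Chi distribution from either (f, beta) or matched moments (mu, sigma)."""
        if f is None and beta is None:
            if mu is None or sigma is None:
                raise ValueError("chi requires either (f, beta) or (mu, sigma)")
            f = _chi_f_from_cv(sigma / mu)
            g = _chi_gamma_ratio(f)
            beta = (mu / g) ** 2 / 2.0
        return cls(family="chi", f=f, beta=beta, units=units)

    @classmethod
    def gamma(cls, f: float, beta: float, d0: float = 0.0, units: str = "u.d.") -> "SizeDistribution":
        return cls(family="gamma", f=f, beta=beta, d0=d0, units=units)

    @classmethod
    def from_moments(
        cls, family: str, mu: float, sigma: float, d0: float = 0.0, units: str = "u.d."
    ) -> "SizeDistribution":
        """Build a distribution of ``family`` with the given mean and sd.

        For gamma the offset d0 is held fixed and (f, beta) are solved
        from mu - d0 = f*beta, sigma^2 = f*beta^2.
        """
        if family == "gaussian":
            return cls.gaussian(mu, sigma, units=units)
        if family == "chi":
            return cls.chi(mu=mu, sigma=sigma, units=units)
        if family == "gamma":
            m = mu - d0
            if m <= 0:
                raise ValueError("gamma requires mu > d0")
            beta = sigma * sigma / m
            return cls.gamma(f=(m / sigma) ** 2, beta=beta, d0=d0, units=units)
        raise ValueError(f"unknown family {family!r}")

    # ------------------------------------------------------------------
    # moments
    @property
    def mu_D(self) -> float:
        if self.family == "gaussian":
            return float(self.mu)
        if self.family == "chi":
            return _chi_gamma_ratio(self.f) * float(np.sqrt(2.0 * self.beta))
        return self.d0 + self.f * self.beta

    @property
    def sigma_D(self) -> float:
        if self.family == "gaussian":
            return float(self.sigma)
        if self.family == "chi":
            g = _chi_gamma_ratio(self.f)
            return float(np.sqrt(self.beta * (self.f - 2.0 * g * g)))
        return float(np.sqrt(self.f) * self.beta)

    @property
    def cv_D(self) -> float:
        return self.sigma_D / self.mu_D

    @property
    def support(self) -> tuple[float, float]:
        """Effective support used for quadrature and simulation.

        The Gaussian is truncated to [max(0, mu - 6 sigma), mu + 6 sigma];
        for the size spreads this package targets (CV_D <= ~0.2) the
        clipped mass is < 1e-8. Chi/gamma use their exact lower bound and
        a far-tail upper quantile.
        """
        if self.family == "gaussian":
            return (max(0.0, self.mu - 6.0 * self.sigma), self.mu + 6.0 * self.sigma)
        lo = self.d0 if self.family == "gamma" else 0.0
        return (lo, float(self._frozen.isf(1e-12)))

    # ------------------------------------------------------------------
    def pdf(self, d):
        """Density at d; zero outside the support (d < 0, or d < d0 for gamma)."""
        d = np.asarray(d, dtype=float)
        if not np.all(np.isfinite(d)):
            raise ValueError("d must be finite")
        out = self._frozen.pdf(d)
        if self.family == "gaussian":
            out = np.where(d < 0, 0.0, out)
        return out if out.ndim else float(out)

    def cdf(self, d):
        return self._frozen.cdf(d)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n diameters; Gaussian draws are redrawn if negative (mass < 1e-8)."""
        x = self._frozen.rvs(size=n, random_state=rng)
        if self.family == "gaussian":
            while np.any(x <= 0):
                bad = x <= 0
                x[bad] = self._frozen.rvs(size=int(bad.sum()), random_state=rng)
        return x

    def mean_sphere_volume(self, method: str = "auto") -> float:
        """E[(pi/6) D^3], the mean particle volume.

        Gaussian uses the closed form (pi/6)(mu^3 + 3 mu sigma^2); other
        families integrate F(y) (pi/6) y^3 over the support.
        """
        if method not in ("auto", "closed_form", "quadrature"):
            raise ValueError(f"unknown method {method!r}")
        if self.family == "gaussian" and method in ("auto", "closed_form"):
            return np.pi / 6.0 * (self.mu**3 + 3.0 * self.mu * self.sigma**2)
        if method == "closed_form":
            raise ValueError("closed form only available for the gaussian family")
        lo, hi = self.support
        val, _ = integrate.quad(
            lambda y: self.pdf(y) * np.pi / 6.0 * y**3, lo, hi, epsrel=1e-10, limit=200
        )
        return float(val)

    def to_config(self) -> dict:
        """Plain key-value serialisation (family, parameters, units)."""
        cfg = {"family": self.family, "units": self.units}
        if self.family == "gaussian":
            cfg.update(mu=self.mu, sigma=self.sigma)
        elif self.family == "chi":
            cfg.update(f=self.f, beta=self.beta)
        else:
            cfg.update(f=self.f, beta=self.beta, d0=self.d0)
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "SizeDistribution":
        cfg = dict(cfg)
        family = cfg.pop("family")
        units = cfg.pop("units", "u.d.")
        return cls(family=family, units=units, **cfg)


# ----------------------------------------------------------------------
# functional aliases matching the operation-style surface


def pdf(dist: SizeDistribution, d):
    return dist.pdf(d)


def moments(dist: SizeDistribution) -> tuple[float, float]:
    return dist.mu_D, dist.sigma_D


def mean_sphere_volume(dist: SizeDistribution, method: str = "auto") -> float:
    return dist.mean_sphere_volume(method=method)
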