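"""Monte Carlo virtual sectioning of sphere packings.

Workflow: pack non-overlapping hard spheres with diameters drawn from a
size distribution into a periodic cuboid, cut virtual sections of
thickness T, project every intersecting particle to a circle (interiors
at full diameter, caps reduced by their axial offset), apply the
lost-cap rule (cap angle theta below the limit phi is unobserved) and,
optionally, semi-transparency (overlap sum Omega above psi hides a
particle) or opacity (strongly overlapping projections merge into one).
Observed projections then yield the simulated G(d), lambda_2D and AF
against which the analytic forward model and the density corrections
are validated, plus a physical-disector counting simulation.

Projection records are pandas DataFrames with one row per intersecting
particle and columns::

    particle_id, D, x, y, z, dz, d, theta, is_cap, depth, phi,
    omega, observed, merged_with

``depth`` is measured from the imaging surface (the z-max face of the
section); "higher in the section" means smaller depth. ``dz`` is the
signed centre offset from the nearest section face (0 for interiors,
positive above the top face). ``merged_with`` is the id of the higher
composite a projection was merged into under opacity, else -1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .distributions import SizeDistribution
from .fitting import DiameterHistogram, histogram_from_diameters
from .keiding import zeta

__all__ = [
    "PhiModel",
    "SimulationConfig",
    "ParticleSet",
    "ErrorStats",
    "pack_spheres",
    "project_section",
    "overlap_sums",
    "apply_transparency",
    "merge_opaque",
    "measure_projection",
    "sample_projected_diameters",
    "simulate_projections",
    "simulate_disector",
    "error_stats",
    "simulate_zstack",
]


@dataclass(frozen=True)
class PhiModel:
    """Cap-angle limit model: a fixed phi or a Gaussian phi per particle."""

    kind: str  # "fixed" | "gaussian"
    mu: float  # degrees
    cv: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "gaussian"):
            raise ValueError("phi model kind must be 'fixed' or 'gaussian'")
        if not 0.0 <= self.mu <= 90.0:
            raise ValueError("mean phi must be in [0, 90] degrees")
        if self.cv < 0:
            raise ValueError("CV of phi must be >= 0")

    @classmethod
    def fixed(cls, phi: float) -> "PhiModel":
        return cls(kind="fixed", mu=phi)

    @classmethod
    def gaussian(cls, mu: float, cv: float) -> "PhiModel":
        return cls(kind="gaussian", mu=mu, cv=cv)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "fixed" or self.cv == 0.0:
            return np.full(n, self.mu)
        return np.clip(rng.normal(self.mu, self.cv * self.mu, n), 0.0, 90.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Virtual-sectioning study conditions.

    Defaults reproduce the canonical study conditions: Gaussian F(d)
    with unit mean diameter and CV_D = 0.09, particle volume fraction
    0.40, ~500 observed particles per projection. The cuboid's xy square
    is sized from the expected lambda_2D so a projection holds about
    ``n_per_projection`` particles; the z extent holds ``n_sections``
    section slots. All boundaries are periodic.
    """

    dist: SizeDistribution = field(
        default_factory=lambda: SizeDistribution.gaussian(1.0, 0.09)
    )
    vf_target: float = 0.40
    T: float = 1.0
    n_per_projection: int = 500
    n_sections: int = 1
    phi_model: PhiModel = field(default_factory=lambda: PhiModel.fixed(0.0))
    psi: float = np.inf  # overlap limit; inf = fully transparent
    opaque: bool = False
    seed: int = 0
    arrangement: str = "hard"  # "hard" (non-overlapping) | "poisson"
    section_spacing: float | None = None  # z distance between section bottoms

    def __post_init__(self) -> None:
        if not 0.0 < self.vf_target < 0.74:
            raise ValueError("vf_target must be in (0, 0.74)")
        if self.arrangement not in ("hard", "poisson"):
            raise ValueError("arrangement must be 'hard' or 'poisson'")
        if self.T < 0:
            raise ValueError("T must be >= 0")

    @property
    def spacing(self) -> float:
        """Section-to-section z spacing (bottom to bottom)."""
        if self.section_spacing is not None:
            return self.section_spacing
        dmax = self.dist.support[1]
        return self.T + 1.2 * dmax  # sections effectively independent


@dataclass
class ParticleSet:
    """Packed spheres: centres in [0, box) with periodic boundaries."""

    centers: np.ndarray  # (N, 3)
    diameters: np.ndarray  # (N,)
    box: np.ndarray  # (3,) cuboid edge lengths
    realized_vf: float

    @property
    def n(self) -> int:
        return len(self.diameters)

    @property
    def area_xy(self) -> float:
        return float(self.box[0] * self.box[1])

    @property
    def lambda3d_true(self) -> float:
        return self.n / float(np.prod(self.box))


def _min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - np.round(delta / box) * box


def _relax(
    pos: np.ndarray,
    diam: np.ndarray,
    box: np.ndarray,
    rng: np.random.Generator,
    max_sweeps: int,
) -> tuple[np.ndarray, bool]:
    """Remove pair overlaps by pushing overlapping pairs apart.

    Deterministic pairwise separation with a slight overshoot; random
    directions only break exact-coincidence ties. Returns (positions,
    converged).
    """
    dmax = float(diam.max())
    for _ in range(max_sweeps):
        tree = cKDTree(pos, boxsize=box)
        pairs = tree.query_pairs(dmax, output_type="ndarray")
        if pairs.size == 0:
            return pos, True
        i, j = pairs.T
        delta = _min_image(pos[j] - pos[i], box)
        dist = np.linalg.norm(delta, axis=1)
        target = 0.5 * (diam[i] + diam[j])
        overlap = target - dist
        mask = overlap > 1e-12
        if not mask.any():
            return pos, True
        i, j = i[mask], j[mask]
        delta, dist, overlap = delta[mask], dist[mask], overlap[mask]
        unit = delta / np.maximum(dist, 1e-12)[:, None]
        degenerate = dist < 1e-12
        if degenerate.any():
            rd = rng.normal(size=(int(degenerate.sum()), 3))
            rd /= np.linalg.norm(rd, axis=1)[:, None]
            unit[degenerate] = rd
        shift = 0.55 * overlap[:, None] * unit
        disp = np.zeros_like(pos)
        np.add.at(disp, j, shift)
        np.add.at(disp, i, -shift)
        pos = np.mod(pos + disp, box)
    return pos, False


def pack_spheres(config: SimulationConfig, rng: np.random.Generator | None = None) -> ParticleSet:
    """Pack hard spheres at the target volume fraction in a periodic cuboid.

    Random insertion seeds the configuration at a reduced diameter scale;
    diameters are then inflated gradually towards full size with overlap
    relaxation after each step. With ``arrangement="poisson"`` centres
    stay independently uniform (no hard-core constraint) - appropriate
    whenever only the marginal axial geometry matters.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    dist = config.dist
    evol = dist.mean_sphere_volume()
    lam3 = config.vf_target / evol
    mu_D = dist.mu_D
    dmax = dist.support[1]

    z_eff = zeta(config.T, mu_D, config.phi_model.mu)
    area = config.n_per_projection / (lam3 * z_eff)
    L = float(np.sqrt(area))
    Lz = max(config.n_sections * config.spacing, 2.2 * dmax)
    box = np.array([L, L, Lz])
    volume = float(np.prod(box))

    # draw diameters until the summed sphere volume meets the target VF
    target_vol = config.vf_target * volume
    n_guess = max(int(target_vol / evol * 1.2), 16)
    D = dist.sample(n_guess, rng)
    vols = np.pi / 6.0 * D**3
    csum = np.cumsum(vols)
    while csum[-1] < target_vol:
        extra = dist.sample(n_guess, rng)
        D = np.concatenate([D, extra])
        vols = np.pi / 6.0 * D**3
        csum = np.cumsum(vols)
    n = int(np.searchsorted(csum, target_vol)) + 1
    D = D[:n]
    realized_vf = float(np.sum(np.pi / 6.0 * D**3) / volume)

    pos = rng.uniform(0.0, 1.0, size=(n, 3)) * box
    if config.arrangement == "poisson":
        return ParticleSet(pos, D, box, realized_vf)

    # start dilute enough that random insertion rarely overlaps, inflate up
    s0 = min((0.10 / config.vf_target) ** (1.0 / 3.0), 1.0)
    for s in np.linspace(s0, 1.0, 25):
        pos, _ = _relax(pos, s * D, box, rng, max_sweeps=80)
    pos, ok = _relax(pos, D, box, rng, max_sweeps=2000)
    if not ok:
        raise RuntimeError(
            f"sphere packing failed to converge at VF={config.vf_target}; "
            "lower vf_target or enlarge the box"
        )
    return ParticleSet(pos, D, box, realized_vf)


def project_section(
    particles: ParticleSet,
    z0: float,
    T: float,
    phi,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Project every particle intersecting the slab [z0, z0 + T] (z-periodic).

    ``phi`` is a scalar cap-angle limit in degrees, a per-particle array,
    or a :class:`PhiModel` (drawn with ``rng``). Interiors (centre inside
    the slab) get d = D, theta = 90; caps at axial offset dz < D/2 get
    d = sqrt(D^2 - 4 dz^2), theta = asin(d/D). A record is ``observed``
    iff theta >= its phi.
    """
    box = particles.box
    D = particles.diameters
    z = particles.centers[:, 2]
    w = np.mod(z - z0, box[2])  # position in the section frame, [0, Lz)
    interior = w <= T
    above = (w - T) <= (box[2] - w)
    dz = np.where(interior, 0.0, np.where(above, w - T, -(box[2] - w)))
    intersects = interior | (np.abs(dz) < D / 2.0)

    idx = np.nonzero(intersects)[0]
    Dk = D[idx]
    dzk = dz[idx]
    d = np.where(
        dzk == 0.0, Dk, np.sqrt(np.maximum(Dk**2 - 4.0 * dzk**2, 0.0))
    )
    theta = np.rad2deg(np.arcsin(np.clip(d / Dk, 0.0, 1.0)))
    # depth below the imaging surface (the z-max face of the section)
    depth = np.where(interior[idx], T - w[idx], np.where(dzk > 0, -dzk, T - dzk))

    if isinstance(phi, PhiModel):
        if rng is None and phi.kind == "gaussian":
            raise ValueError("a Gaussian phi model needs an rng")
        phik = phi.draw(idx.size, rng) if rng is not None else np.full(idx.size, phi.mu)
    else:
        phi = np.asarray(phi, dtype=float)
        phik = np.full(idx.size, float(phi)) if phi.ndim == 0 else phi[idx]

    return pd.DataFrame(
        {
            "particle_id": idx,
            "D": Dk,
            "x": particles.centers[idx, 0],
            "y": particles.centers[idx, 1],
            "z": z[idx],
            "dz": dzk,
            "d": d,
            "theta": theta,
            "is_cap": ~interior[idx],
            "depth": depth,
            "phi": phik,
            "omega": np.nan,
            "observed": theta >= phik,
            "merged_with": -1,
        }
    )


def _lens_area(r1, r2, dist):
    """Intersection area of two circles of radii r1, r2 at centre distance dist."""
    r1, r2, dist = np.asarray(r1, float), np.asarray(r2, float), np.asarray(dist, float)
    rmin, rmax = np.minimum(r1, r2), np.maximum(r1, r2)
    out = np.zeros_like(dist)
    contained = dist <= rmax - rmin
    out[contained] = np.pi * rmin[contained] ** 2
    partial = (~contained) & (dist < r1 + r2)
    if partial.any():
        d, a, b = dist[partial], r1[partial], r2[partial]
        t1 = a**2 * np.arccos(np.clip((d**2 + a**2 - b**2) / (2 * d * a), -1, 1))
        t2 = b**2 * np.arccos(np.clip((d**2 + b**2 - a**2) / (2 * d * b), -1, 1))
        s = 0.5 * np.sqrt(
            np.maximum((-d + a + b) * (d + a - b) * (d - a + b) * (d + a + b), 0.0)
        )
        out[partial] = t1 + t2 - s
    return out


def overlap_sums(records: pd.DataFrame, particles: ParticleSet) -> pd.DataFrame:
    """Fill Omega: summed fractional projection overlap with higher particles.

    For each record, Omega is the sum over particles higher in the
    section (smaller depth; ties broken by particle id) of the
    circle-circle intersection area divided by the record's own projected
    circle area. Omega > 1 flags a projection likely to be completely
    hidden. xy distances use the periodic minimum image.
    """
    rec = records.copy()
    n = len(rec)
    omega = np.zeros(n)
    if n > 1:
        box2 = particles.box[:2]
        xy = rec[["x", "y"]].to_numpy()
        r = rec["d"].to_numpy() / 2.0
        depth = rec["depth"].to_numpy()
        pid = rec["particle_id"].to_numpy()
        tree = cKDTree(np.mod(xy, box2), boxsize=box2)
        pairs = tree.query_pairs(float(2.0 * r.max()), output_type="ndarray")
        if pairs.size:
            i, j = pairs.T
            delta = _min_image(xy[j] - xy[i], box2)
            dist = np.linalg.norm(delta, axis=1)
            touching = dist < r[i] + r[j]
            i, j, dist = i[touching], j[touching], dist[touching]
            area = _lens_area(r[i], r[j], dist)
            # rank by (depth, id): the lower-ranked of each pair accumulates
            i_higher = (depth[i] < depth[j]) | (
                (depth[i] == depth[j]) & (pid[i] < pid[j])
            )
            lower = np.where(i_higher, j, i)
            own = np.pi * r[lower] ** 2
            np.add.at(omega, lower, area / own)
    rec["omega"] = omega
    return rec


def apply_transparency(records: pd.DataFrame, psi: float) -> pd.DataFrame:
    """Hide semi-transparent particles whose overlap sum exceeds psi."""
    rec = records.copy()
    if np.isfinite(psi):
        if rec["omega"].isna().any():
            raise ValueError("run overlap_sums before apply_transparency")
        rec["observed"] = rec["observed"] & (rec["omega"] <= psi)
    return rec


def _hilliard_alpha(d1: float, d2: float, d12: float) -> float:
    """Dimensionless pairwise-overlap parameter alpha = (4 d12^2 - d1^2 - d2^2)/(2 d1 d2).

    alpha = -1 at concentric equal circles or internal tangency, 0 < alpha
    for well-separated circles; -1 < alpha < 0 marks projections that
    visually coalesce.
    """
    return (4.0 * d12**2 - d1**2 - d2**2) / (2.0 * d1 * d2)


def merge_opaque(records: pd.DataFrame, particles: ParticleSet) -> pd.DataFrame:
    """Merge coalescing projections of opaque particles.

    Iterating from the particle closest to the imaging surface, any
    deeper observed projection whose alpha with the current composite
    lies in (-1, 0) is merged into it: the composite's area becomes the
    union of the two circles and the deeper record is marked unobserved
    with ``merged_with`` pointing at the composite. A projection fully
    contained in a higher one (alpha <= -1) is hidden outright (counted
    once through the composite).
    """
    rec = records.copy().reset_index(drop=True)
    order = np.lexsort((rec["particle_id"].to_numpy(), rec["depth"].to_numpy()))
    xy = rec[["x", "y"]].to_numpy().copy()
    area = np.pi * (rec["d"].to_numpy() / 2.0) ** 2
    deq = rec["d"].to_numpy().copy()  # equivalent diameter of composite
    observed = rec["observed"].to_numpy().copy()
    merged_with = np.full(len(rec), -1, dtype=int)
    box2 = particles.box[:2]

    for pos_k, k in enumerate(order):
        if not observed[k]:
            continue
        for m in order[pos_k + 1 :]:
            if not observed[m]:
                continue
            d12 = float(np.linalg.norm(_min_image(xy[m] - xy[k], box2)))
            alpha = _hilliard_alpha(deq[k], deq[m], d12)
            if alpha >= 0.0:
                continue
            if alpha <= -1.0:  # fully hidden behind the composite
                observed[m] = False
                merged_with[m] = int(rec["particle_id"].iloc[k])
                continue
            union = area[k] + area[m] - _lens_area(
                np.array([deq[k] / 2]), np.array([deq[m] / 2]), np.array([d12])
            )[0]
            # composite keeps the higher particle's centre, gains union area
            area[k] = union
            deq[k] = 2.0 * np.sqrt(union / np.pi)
            observed[m] = False
            merged_with[m] = int(rec["particle_id"].iloc[k])
    rec["d"] = deq
    rec["observed"] = observed
    rec["merged_with"] = merged_with
    return rec


def measure_projection(
    records: pd.DataFrame,
    area_xy: float,
    bin_width: float | None = None,
) -> tuple[float, float, DiameterHistogram | None]:
    """(lambda_2D, AF, G(d) histogram) of the observed records.

    AF sums each observed projection's area once (merged composites
    carry their union area). Returns histogram None when nothing is
    observed. Default bin width is 4% of the mean observed diameter.
    """
    obs = records[records["observed"]]
    lam2 = len(obs) / area_xy
    if len(obs) == 0:
        return 0.0, 0.0, None
    d = obs["d"].to_numpy()
    af = float(np.sum(np.pi * (d / 2.0) ** 2) / area_xy)
    h = bin_width if bin_width is not None else 0.04 * float(d.mean())
    return lam2, af, histogram_from_diameters(d, h)


def sample_projected_diameters(
    dist: SizeDistribution,
    T: float,
    phi_model: PhiModel | float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n observed projected diameters directly (no packing).

    Equivalent to projecting a Poisson sphere process: each candidate
    particle gets a diameter from F and a centre uniform over the axial
    window reachable by any particle; survivors of the slab-intersection
    and lost-cap rules contribute their projected diameter. The marginal
    law of d is identical to that of a full packed-section projection,
    which does not depend on in-plane correlations.
    """
    if not isinstance(phi_model, PhiModel):
        phi_model = PhiModel.fixed(float(phi_model))
    dmax = dist.support[1]
    out: list[np.ndarray] = []
    got = 0
    while got < n:
        m = max(int((n - got) * 2.5), 1000)
        D = dist.sample(m, rng)
        z = rng.uniform(-dmax / 2.0, T + dmax / 2.0, m)
        dz = np.where(z < 0, -z, np.where(z > T, z - T, 0.0))
        keep = dz < D / 2.0
        d = np.where(dz > 0, np.sqrt(np.maximum(D**2 - 4.0 * dz**2, 0.0)), D)
        theta = np.rad2deg(np.arcsin(np.clip(d / D, 0.0, 1.0)))
        keep &= theta >= phi_model.draw(m, rng)
        out.append(d[keep])
        got += int(keep.sum())
    return np.concatenate(out)[:n]


def simulate_projections(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ParticleSet, list[pd.DataFrame]]:
    """Pack once and project all configured sections.

    Sections sit at z = i * spacing for i in range(n_sections); each is
    projected with the configured phi model (per-section draws from a
    child RNG stream, so changing n_sections leaves earlier sections
    untouched), then the transparency/opacity rules are applied.
    """
    root = np.random.default_rng(config.seed) if rng is None else rng
    pack_rng, *section_seeds = root.spawn(config.n_sections + 1)
    particles = pack_spheres(config, pack_rng)
    sections = []
    for i in range(config.n_sections):
        srng = section_seeds[i]
        rec = project_section(particles, i * config.spacing, config.T, config.phi_model, srng)
        if np.isfinite(config.psi) or config.opaque:
            rec = overlap_sums(rec, particles)
        if np.isfinite(config.psi):
            rec = apply_transparency(rec, config.psi)
        if config.opaque:
            rec = merge_opaque(rec, particles)
        sections.append(rec)
    return particles, sections


def simulate_disector(
    config: SimulationConfig,
    phi_lookup: float,
    phi_bias: float = 0.0,
    T_ref: float = 0.3,
) -> dict:
    """Physical-disector counting with a blind-vs-nonblind detection bias.

    Adjacent reference/lookup section pairs of thickness T_ref tile the
    volume. A particle is counted for a pair iff it is observed in the
    reference projection (cap-angle limit phi_ref = phi_lookup +
    phi_bias, the blind detection) and not observed in the lookup
    projection (limit phi_lookup). lambda_3D = count/(Area_xy * T_ref)
    per pair; the packed set's true density is returned alongside.
    """
    cfg = replace(config, T=T_ref, section_spacing=2.0 * T_ref)
    rng = np.random.default_rng(cfg.seed)
    particles = pack_spheres(cfg, rng)
    phi_ref = min(phi_lookup + phi_bias, 180.0)
    estimates = []
    for i in range(cfg.n_sections):
        z_i = i * 2.0 * T_ref
        ref = project_section(particles, z_i, T_ref, min(phi_ref, 90.0))
        lookup = project_section(particles, z_i + T_ref, T_ref, phi_lookup)
        if phi_ref > 90.0:  # beyond 90 every cap is lost in the reference
            ref = ref.assign(observed=ref["observed"] & ~ref["is_cap"])
        in_lookup = set(lookup.loc[lookup["observed"], "particle_id"])
        counted = ref[ref["observed"] & ~ref["particle_id"].isin(in_lookup)]
        estimates.append(len(counted) / (particles.area_xy * T_ref))
    return {
        "lambda3D_estimates": np.array(estimates),
        "lambda3D_true": particles.lambda3d_true,
        "area_xy": particles.area_xy,
        "T_ref": T_ref,
        "phi_ref": phi_ref,
        "phi_lookup": phi_lookup,
    }


@dataclass
class ErrorStats:
    """Bias and spread of an estimation-error sample.

    Percent errors 100 (estimate - truth)/truth for sizes and densities,
    plain differences for angles. When the error sample is clearly
    skewed (|skew| > 0.5) the bias is the median and the spread is
    reported asymmetrically, computed separately above and below it.
    """

    parameter: str
    bias: float
    sigma_plus: float
    sigma_minus: float
    n_reps: int
    skew: float
    asymmetric: bool

    @property
    def sigma(self) -> float:
        return 0.5 * (self.sigma_plus + self.sigma_minus)


def error_stats(
    estimates: np.ndarray,
    truth: float,
    parameter: str = "value",
    mode: str = "percent",
) -> ErrorStats:
    est = np.asarray(estimates, dtype=float)
    if mode == "percent":
        delta = 100.0 * (est - truth) / truth
    elif mode == "absolute":
        delta = est - truth
    else:
        raise ValueError("mode must be 'percent' or 'absolute'")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        skew = float(stats.skew(delta)) if delta.size > 2 else 0.0
    if delta.size == 0:
        raise ValueError("empty estimate sample")
    if abs(skew) > 0.5:
        med = float(np.median(delta))
        hi = delta[delta > med] - med
        lo = med - delta[delta < med]
        sp = float(np.sqrt(np.mean(hi**2))) if hi.size else 0.0
        sm = float(np.sqrt(np.mean(lo**2))) if lo.size else 0.0
        return ErrorStats(parameter, med, sp, sm, int(delta.size), skew, True)
    sd = float(delta.std(ddof=0))
    return ErrorStats(parameter, float(delta.mean()), sd, sd, int(delta.size), skew, False)


def simulate_zstack(
    dist: SizeDistribution,
    S_z: float,
    phi_model: PhiModel,
    n_particles: int,
    rng: np.random.Generator,
    noise_sd: float = 0.0,
    eccentricity: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-particle (z-index, radius) profiles with truncated poles.

    Each particle gets a diameter from F, a continuous axial centre z0
    and an independent cap-angle limit per pole; planes where the local
    apparent diameter falls below D sin(phi_pole) are dropped (the lost
    caps). Radii optionally get additive Gaussian noise. Returns
    (profiles, truth): profiles has columns particle_id, z_index,
    radius; truth has particle_id, D, z0, phi_north, phi_south, E.
    """
    prof_rows = []
    truth_rows = []
    for pid in range(n_particles):
        D = float(dist.sample(1, rng)[0])
        z0 = float(rng.uniform(0.0, 1000.0 * S_z))
        phi_n, phi_s = phi_model.draw(2, rng)
        half = eccentricity * D / 2.0
        k_lo = int(np.ceil((z0 - half) / S_z))
        k_hi = int(np.floor((z0 + half) / S_z))
        ks = np.arange(k_lo, k_hi + 1)
        zrel = ks * S_z - z0
        r2 = (D / 2.0) ** 2 - (zrel / eccentricity) ** 2
        valid = r2 > 0.0
        ks, zrel, r2 = ks[valid], zrel[valid], r2[valid]
        r = np.sqrt(r2)
        d = 2.0 * r
        thresh = np.where(zrel >= 0, D * np.sin(np.deg2rad(phi_n)), D * np.sin(np.deg2rad(phi_s)))
        keep = d >= thresh
        ks, r = ks[keep], r[keep]
        if noise_sd > 0:
            r = np.maximum(r + rng.normal(0.0, noise_sd, r.size), 0.0)
        for k, rk in zip(ks, r):
            prof_rows.append((pid, int(k), float(rk)))
        truth_rows.append((pid, D, z0, phi_n, phi_s, eccentricity))
    profiles = pd.DataFrame(prof_rows, columns=["particle_id", "z_index", "radius"])
    truth = pd.DataFrame(
        truth_rows, columns=["particle_id", "D", "z0", "phi_north", "phi_south", "E"]
    )
    return profiles, truth
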