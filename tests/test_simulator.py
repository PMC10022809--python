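"""Virtual sectioning: packing, projection, overlap rules, disector, errors."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree
from scipy.stats import ks_2samp, skew

from lostcaps import (
    PhiModel,
    SimulationConfig,
    SizeDistribution,
    error_stats,
    pack_spheres,
    project_section,
    sample_projected_diameters,
    simulate_disector,
    simulate_projections,
    simulate_zstack,
)
from lostcaps.simulator import (
    ParticleSet,
    apply_transparency,
    measure_projection,
    merge_opaque,
    overlap_sums,
    _hilliard_alpha,
)


def min_pair_gap(p: ParticleSet) -> float:
    tree = cKDTree(p.centers, boxsize=p.box)
    pairs = tree.query_pairs(float(p.diameters.max()), output_type="ndarray")
    if pairs.size == 0:
        return np.inf
    i, j = pairs.T
    delta = p.centers[j] - p.centers[i]
    delta -= np.round(delta / p.box) * p.box
    return float(
        (np.linalg.norm(delta, axis=1) - 0.5 * (p.diameters[i] + p.diameters[j])).min()
    )


def single_sphere(D=1.0, z=0.0, box=(10.0, 10.0, 10.0)):
    return ParticleSet(
        centers=np.array([[5.0, 5.0, z % box[2]]]),
        diameters=np.array([D]),
        box=np.array(box),
        realized_vf=0.0,
    )


class TestPacking:
    cfg = SimulationConfig(
        T=1.0, vf_target=0.40, n_per_projection=150, n_sections=1, seed=7
    )

    def test_hard_core_and_realized_vf(self):
        p = pack_spheres(self.cfg)
        assert min_pair_gap(p) >= -1e-9
        assert abs(p.realized_vf - 0.40) < 0.01

    def test_determinism(self):
        p1 = pack_spheres(self.cfg)
        p2 = pack_spheres(self.cfg)
        assert np.array_equal(p1.centers, p2.centers)
        assert np.array_equal(p1.diameters, p2.diameters)

    def test_dilute_vf_succeeds(self):
        cfg = SimulationConfig(
            T=1.0, vf_target=0.15, n_per_projection=150, n_sections=1, seed=8
        )
        p = pack_spheres(cfg)
        assert min_pair_gap(p) >= -1e-9
        assert abs(p.realized_vf - 0.15) < 0.01

    def test_infeasible_vf_rejected_at_config(self):
        with pytest.raises(ValueError):
            SimulationConfig(vf_target=0.80)


class TestProjectSection:
    def test_interior_particle(self):
        p = single_sphere(D=1.0, z=0.5)
        rec = project_section(p, 0.0, 1.0, 0.0)
        assert len(rec) == 1
        assert not rec["is_cap"].iloc[0]
        assert rec["d"].iloc[0] == pytest.approx(1.0)
        assert rec["theta"].iloc[0] == pytest.approx(90.0)

    def test_cap_geometry(self):
        p = single_sphere(D=1.0, z=1.3)  # 0.3 above a [0, 1] section
        rec = project_section(p, 0.0, 1.0, 0.0)
        assert rec["is_cap"].iloc[0]
        assert rec["dz"].iloc[0] == pytest.approx(0.3)
        assert rec["d"].iloc[0] == pytest.approx(0.8)
        assert rec["theta"].iloc[0] == pytest.approx(53.13, abs=0.01)

    def test_lost_cap_excluded(self):
        p = single_sphere(D=1.0, z=1.45)  # theta = asin(sqrt(1-0.81)) ~ 25.8 deg
        rec = project_section(p, 0.0, 1.0, 30.0)
        assert not rec["observed"].iloc[0]
        rec = project_section(p, 0.0, 1.0, 20.0)
        assert rec["observed"].iloc[0]

    def test_matches_direct_sampler(self, unit_gaussian, rng):
        """Projecting a Poisson arrangement and the packing-free sampler
        draw from the same law."""
        cfg = SimulationConfig(
            T=1.0, n_per_projection=4000, n_sections=1,
            phi_model=PhiModel.fixed(30.0), seed=17, arrangement="poisson",
        )
        _, sections = simulate_projections(cfg)
        d_proj = sections[0].loc[sections[0]["observed"], "d"].to_numpy()
        d_direct = sample_projected_diameters(unit_gaussian, 1.0, 30.0, 4000, rng)
        assert ks_2samp(d_proj, d_direct).pvalue > 0.01


class TestOverlaps:
    def test_lone_particle_zero_omega(self):
        p = single_sphere(z=5.0)
        rec = overlap_sums(project_section(p, 4.5, 1.0, 0.0), p)
        assert rec["omega"].iloc[0] == 0.0

    def test_coaxial_full_overlap(self):
        p = ParticleSet(
            centers=np.array([[5.0, 5.0, 0.8], [5.0, 5.0, 0.2]]),
            diameters=np.array([1.0, 1.0]),
            box=np.array([10.0, 10.0, 10.0]),
            realized_vf=0.0,
        )
        rec = overlap_sums(project_section(p, 0.0, 1.0, 0.0), p)
        rec = rec.set_index("particle_id")
        # particle 0 sits higher (closer to the z-max face): Omega = 0
        assert rec.loc[0, "omega"] == 0.0
        assert rec.loc[1, "omega"] == pytest.approx(1.0)

    def test_omega_grows_with_depth(self):
        cfg = SimulationConfig(
            T=2.0, vf_target=0.45, n_per_projection=250, n_sections=1,
            phi_model=PhiModel.fixed(0.0), seed=31,
        )
        particles, sections = simulate_projections(cfg)
        rec = overlap_sums(sections[0], particles)
        shallow = rec[rec["depth"] < 0.7]["omega"].mean()
        deep = rec[rec["depth"] > 1.3]["omega"].mean()
        assert deep > shallow
        assert rec[rec["depth"] > 1.8]["omega"].mean() > 1.0


class TestTransparency:
    def test_infinite_psi_noop(self):
        p = single_sphere(z=5.0)
        rec = overlap_sums(project_section(p, 4.5, 1.0, 0.0), p)
        out = apply_transparency(rec, np.inf)
        assert out["observed"].equals(rec["observed"])

    def test_reduces_effective_depth(self):
        cfg = SimulationConfig(
            T=2.0, vf_target=0.30, n_per_projection=250, n_sections=2,
            phi_model=PhiModel.fixed(0.0), seed=32,
        )
        particles, sections = simulate_projections(cfg)
        for rec in sections:
            rec = overlap_sums(rec, particles)
            thinned = apply_transparency(rec, 0.25)
            ctrl_depth = rec.loc[rec["observed"], "depth"]
            surv_depth = thinned.loc[thinned["observed"], "depth"]
            # survivors concentrate near the imaging surface: the bulk of
            # the thinned sample stops well short of the section bottom
            assert surv_depth.quantile(0.9) < 2.0
            assert surv_depth.mean() < 0.6 * ctrl_depth.mean()

    def test_little_effect_on_gdist_shape(self):
        cfg = SimulationConfig(
            T=1.0, vf_target=0.30, n_per_projection=700, n_sections=2,
            phi_model=PhiModel.fixed(0.0), seed=33,
        )
        particles, sections = simulate_projections(cfg)
        control, thinned = [], []
        for rec in sections:
            rec = overlap_sums(rec, particles)
            obs = rec[rec["observed"]]
            control.append(obs["d"].to_numpy())
            surv = apply_transparency(rec, 0.25)
            thinned.append(surv.loc[surv["observed"], "d"].to_numpy())
        stat = ks_2samp(np.concatenate(control), np.concatenate(thinned)).statistic
        assert stat < 0.05


class TestOpaqueMerging:
    def test_alpha_disjoint_positive(self):
        assert _hilliard_alpha(1.0, 1.0, 1.2) > 0

    def test_alpha_concentric_equal_is_minus_one(self):
        assert _hilliard_alpha(1.0, 1.0, 0.0) == pytest.approx(-1.0)

    def test_disjoint_circles_not_merged(self):
        p = ParticleSet(
            centers=np.array([[2.0, 2.0, 0.8], [6.0, 6.0, 0.2]]),
            diameters=np.array([1.0, 1.0]),
            box=np.array([10.0, 10.0, 10.0]),
            realized_vf=0.0,
        )
        rec = merge_opaque(project_section(p, 0.0, 1.0, 0.0), p)
        assert rec["observed"].all()
        assert (rec["merged_with"] == -1).all()

    def test_concentric_counted_once_without_area_merge(self):
        p = ParticleSet(
            centers=np.array([[5.0, 5.0, 0.8], [5.0, 5.0, 0.2]]),
            diameters=np.array([1.0, 1.0]),
            box=np.array([10.0, 10.0, 10.0]),
            realized_vf=0.0,
        )
        rec = merge_opaque(project_section(p, 0.0, 1.0, 0.0), p)
        assert rec["observed"].sum() == 1
        # hidden, not coalesced: the surviving projection keeps its own size
        assert rec.loc[rec["observed"], "d"].iloc[0] == pytest.approx(1.0)

    def test_partial_overlap_merges_to_union_area(self):
        p = ParticleSet(
            centers=np.array([[5.0, 5.0, 0.8], [5.4, 5.0, 0.2]]),
            diameters=np.array([1.0, 1.0]),
            box=np.array([10.0, 10.0, 10.0]),
            realized_vf=0.0,
        )
        rec = merge_opaque(project_section(p, 0.0, 1.0, 0.0), p)
        assert rec["observed"].sum() == 1
        d_comp = rec.loc[rec["observed"], "d"].iloc[0]
        assert d_comp > 1.0  # union is bigger than either circle

    def test_opacity_creates_positive_skew(self):
        cfg = SimulationConfig(
            T=1.0, vf_target=0.30, n_per_projection=450, n_sections=1,
            phi_model=PhiModel.fixed(0.0), seed=34,
        )
        particles, sections = simulate_projections(cfg)
        rec = overlap_sums(sections[0], particles)
        transparent_d = rec.loc[rec["observed"], "d"].to_numpy()
        merged = merge_opaque(rec, particles)
        opaque_d = merged.loc[merged["observed"], "d"].to_numpy()
        assert len(opaque_d) < len(transparent_d)
        assert skew(opaque_d) > skew(transparent_d)


class TestMeasureProjection:
    def test_empty_projection(self):
        rec = pd.DataFrame(
            {"d": [], "observed": pd.Series([], dtype=bool), "x": [], "y": []}
        )
        lam2, af, hist = measure_projection(rec, 10.0)
        assert (lam2, af, hist) == (0.0, 0.0, None)

    def test_overprojection_in_thick_sections(self):
        cfg = SimulationConfig(
            T=1.0, vf_target=0.40, n_per_projection=300, n_sections=2,
            phi_model=PhiModel.fixed(0.0), seed=35,
        )
        particles, sections = simulate_projections(cfg)
        afs = [measure_projection(rec, particles.area_xy)[1] for rec in sections]
        assert np.mean(afs) > particles.realized_vf  # AF > VF: Holmes effect

    def test_periodic_count_equals_inclusive_exclusive_rule(self):
        """Center-in-frame counting with periodic wrap equals the
        inclusive/exclusive border rule applied to the replicated tile."""
        rng = np.random.default_rng(3)
        n = 200
        L = 20.0
        xy = rng.uniform(0, L, size=(n, 2))
        r = rng.uniform(0.2, 0.6, size=n)
        count = 0
        for dx in (-L, 0.0, L):
            for dy in (-L, 0.0, L):
                cx, cy = xy[:, 0] + dx, xy[:, 1] + dy
                intersects = (
                    (cx + r > 0) & (cx - r < L) & (cy + r > 0) & (cy - r < L)
                )
                # exclusive borders: the lines x = L and y = L
                touches_exclusive = (np.abs(cx - L) <= r) | (np.abs(cy - L) <= r)
                count += int(np.sum(intersects & ~touches_exclusive))
        assert count == n


class TestDisector:
    cfg = SimulationConfig(
        T=0.3, vf_target=0.40, n_per_projection=120, n_sections=12,
        phi_model=PhiModel.fixed(42.0), seed=41,
    )

    def test_unbiased_without_detection_bias(self):
        res = simulate_disector(self.cfg, phi_lookup=42.0, phi_bias=0.0)
        est, truth = res["lambda3D_estimates"], res["lambda3D_true"]
        sem = est.std(ddof=1) / np.sqrt(est.size)
        assert abs(est.mean() - truth) < 4 * sem + 0.02 * truth

    def test_detection_bias_undercounts(self):
        """A 20 deg blind-vs-nonblind bias at vesicle-like phi produces a
        tens-of-percent undercount."""
        res = simulate_disector(self.cfg, phi_lookup=42.0, phi_bias=20.0)
        delta = 100 * (res["lambda3D_estimates"].mean() - res["lambda3D_true"]) / res[
            "lambda3D_true"
        ]
        assert -60.0 < delta < -25.0


class TestErrorStats:
    def test_exact_estimates(self):
        st = error_stats(np.full(10, 5.0), 5.0, mode="percent")
        assert st.bias == 0.0 and st.sigma == 0.0 and not st.asymmetric

    def test_symmetric_sample_uses_mean(self, rng):
        sample = 1.0 + rng.normal(0, 0.02, 5000)
        st = error_stats(sample, 1.0, mode="percent")
        assert not st.asymmetric
        assert st.bias == pytest.approx(0.0, abs=0.15)
        assert st.sigma == pytest.approx(2.0, abs=0.2)

    def test_skew_threshold_triggers_asymmetric_reporting(self, rng):
        base = rng.normal(0, 1, 4000)
        mild = np.where(base > 0, base * 1.25, base)  # |skew| < 0.5
        strong = np.exp(rng.normal(0, 0.8, 4000))  # lognormal, skew >> 0.5
        st_mild = error_stats(1.0 + 0.01 * mild, 1.0)
        st_strong = error_stats(strong, 1.0)
        assert abs(st_mild.skew) < 0.5 and not st_mild.asymmetric
        assert st_strong.skew > 0.5 and st_strong.asymmetric
        assert st_strong.bias == pytest.approx(
            100 * (np.median(strong) - 1.0), rel=1e-9
        )
        assert st_strong.sigma_plus != st_strong.sigma_minus

    def test_absolute_mode_for_angles(self):
        st = error_stats(np.array([41.0, 43.0]), 40.0, parameter="phi", mode="absolute")
        assert st.bias == pytest.approx(2.0)


class TestZstackGenerator:
    def test_determinism(self, unit_gaussian):
        a = simulate_zstack(
            unit_gaussian, 0.02, PhiModel.fixed(40.0), 20, np.random.default_rng(5)
        )
        b = simulate_zstack(
            unit_gaussian, 0.02, PhiModel.fixed(40.0), 20, np.random.default_rng(5)
        )
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_profiles_respect_lost_cap_rule(self, unit_gaussian, rng):
        profiles, truth = simulate_zstack(
            unit_gaussian, 0.012, PhiModel.fixed(40.0), 30, rng
        )
        merged = profiles.merge(truth, on="particle_id")
        d_over_D = 2 * merged["radius"] / merged["D"]
        assert (d_over_D >= np.sin(np.deg2rad(40.0)) - 1e-9).all()
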