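"""Spring systems, correlated forces, relaxation, and axial offsets."""

import numpy as np
import pytest

from npcsim.errors import DegenerateGeometryError, ValidationError
from npcsim.feature_extraction import fit_ellipse_3d
from npcsim.npc_assembly import SimulationConfig, assemble
from npcsim.reference_models import bands_from_ru, make_synthetic_ru
from npcsim.simulate import simulate_npc
from npcsim.spring_deformation import (
    build_springs,
    deform_npc,
    force_covariance,
    radialize,
    relax,
    sample_axial_offsets,
    sample_scalar_forces,
)


@pytest.fixture
def ring_nodes(two_ring_model):
    return two_ring_model.coords[two_ring_model.band_nodes(0)]


class TestBuildSprings:
    def test_counts_default_h2(self, ring_nodes):
        sp = build_springs(ring_nodes, h=2)
        assert sp.n_nodes == 8
        assert len(sp.pairs) == 16  # s*h distinct circumferential springs
        assert np.all(sp.rest_radial > 0)

    def test_h_zero_radial_only(self, ring_nodes):
        sp = build_springs(ring_nodes, h=0)
        assert len(sp.pairs) == 0

    def test_stiffness_ordering(self, ring_nodes):
        """Shorter springs stiffer; radial weakest."""
        sp = build_springs(ring_nodes, h=2)
        by_order = sp.stiffness_by_order()
        assert by_order[1] > by_order[2]
        assert sp.k_radial < min(sp.k_circ)

    def test_h_out_of_range(self, ring_nodes):
        with pytest.raises(ValidationError):
            build_springs(ring_nodes, h=5)


class TestForceCovariance:
    def test_diagonal_is_dmag_third_squared(self, two_ring_model):
        cov = force_covariance(two_ring_model.coords, dmag=9.0, sigma_kernel=20.0)
        np.testing.assert_allclose(np.diag(cov), 9.0, atol=1e-12)  # (9/3)^2

    def test_zero_dmag_zero_matrix(self, two_ring_model):
        cov = force_covariance(two_ring_model.coords, dmag=0.0, sigma_kernel=20.0)
        np.testing.assert_array_equal(cov, 0.0)

    def test_monotone_decay_with_distance(self):
        pts = np.array([[50.0, 0.0, 0.0], [50.0, 0.0, 1.0], [50.0, 0.0, 30.0]])
        cov = force_covariance(pts, dmag=3.0, sigma_kernel=25.0)
        assert cov[0, 1] > cov[0, 2] > 0

    def test_radius_equalization(self):
        """Nodes at the same angle/z but different radii count as coincident."""
        pts = np.array([[40.0, 0.0, 0.0], [60.0, 0.0, 0.0]])
        cov = force_covariance(pts, dmag=3.0, sigma_kernel=25.0)
        assert cov[0, 1] == pytest.approx(cov[0, 0])

    def test_psd_and_symmetric(self, two_ring_model):
        cov = force_covariance(two_ring_model.coords, dmag=10.0, sigma_kernel=26.85)
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(cov).min() > -1e-8


class TestSampleForces:
    def test_zero_cov_zero_forces(self, two_ring_model, rng):
        cov = force_covariance(two_ring_model.coords, 0.0, 25.0)
        np.testing.assert_array_equal(sample_scalar_forces(cov, rng), 0.0)

    def test_marginal_sd_is_dmag_third(self, two_ring_model):
        rng = np.random.default_rng(0)
        cov = force_covariance(two_ring_model.coords, 10.0, 26.85)
        draws = np.array([sample_scalar_forces(cov, rng)[0] for _ in range(10_000)])
        assert draws.std(ddof=1) == pytest.approx(10.0 / 3.0, rel=0.05)

    def test_three_sigma_coverage(self, two_ring_model):
        """~99.7% of scalar forces fall within +-dmag."""
        rng = np.random.default_rng(1)
        dmag = 10.0
        cov = force_covariance(two_ring_model.coords, dmag, 26.85)
        draws = np.concatenate([sample_scalar_forces(cov, rng) for _ in range(7000)])
        frac = np.mean(np.abs(draws) <= dmag)
        assert frac == pytest.approx(0.997, abs=0.003)

    def test_empirical_covariance_matches(self, two_ring_model):
        rng = np.random.default_rng(2)
        cov = force_covariance(two_ring_model.coords, 10.0, 26.85)
        draws = np.array([sample_scalar_forces(cov, rng) for _ in range(20_000)])
        emp = np.cov(draws.T)
        # entrywise within 5 standard errors (SE ~ sqrt((c_ii c_jj + c_ij^2)/n))
        se = np.sqrt((np.outer(np.diag(cov), np.diag(cov)) + cov**2) / draws.shape[0])
        assert np.all(np.abs(emp - cov) < 5.0 * se)


class TestRadialize:
    def test_unit_example(self):
        vec = radialize(np.array([2.0]), np.array([[1.0, 0.0, 5.0]]))
        np.testing.assert_allclose(vec, [[2.0, 0.0, 0.0]], atol=1e-15)

    def test_zero_force_zero_vector(self, two_ring_model):
        vec = radialize(np.zeros(16), two_ring_model.coords)
        np.testing.assert_array_equal(vec, 0.0)

    def test_no_net_torque(self, two_ring_model, rng):
        f = rng.normal(size=16)
        vec = radialize(f, two_ring_model.coords)
        torque = np.sum(
            two_ring_model.coords[:, 0] * vec[:, 1] - two_ring_model.coords[:, 1] * vec[:, 0]
        )
        assert abs(torque) < 1e-9

    def test_axis_node_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            radialize(np.array([1.0]), np.array([[0.0, 0.0, 5.0]]))


class TestRelax:
    def test_zero_forces_rest_state(self, ring_nodes):
        sp = build_springs(ring_nodes, h=2)
        np.testing.assert_allclose(relax(sp, np.zeros((8, 3))), ring_nodes, atol=1e-9)

    def test_uniform_force_closed_form(self, ring_nodes):
        """h=0 oracle: uniform outward force f dilates every radius by f/k_r."""
        k_r = 2.0
        sp = build_springs(ring_nodes, h=0, k_radial=k_r)
        f = radialize(np.full(8, 3.0), ring_nodes)
        eq = relax(sp, f)
        r_new = np.hypot(eq[:, 0], eq[:, 1])
        np.testing.assert_allclose(r_new, 53.7 + 3.0 / k_r, atol=1e-7)

    def test_symmetric_forces_keep_symmetry(self, ring_nodes):
        sp = build_springs(ring_nodes, h=2)
        f = radialize(np.full(8, 5.0), ring_nodes)
        eq = relax(sp, f)
        r = np.hypot(eq[:, 0], eq[:, 1])
        assert r.max() - r.min() < 1e-6

    def test_equilibrium_residual_below_tolerance(self, ring_nodes, rng):
        from npcsim.spring_deformation import _potential_and_grad

        sp = build_springs(ring_nodes, h=2)
        f = radialize(rng.normal(0, 5, 8), ring_nodes)
        eq = relax(sp, f)
        _, grad = _potential_and_grad(eq[:, :2].ravel(), sp, f[:, :2])
        assert np.max(np.linalg.norm(grad.reshape(-1, 2), axis=1)) < 1e-6


class TestAxialOffsets:
    def test_zero_omag_identity(self, two_ring_model, rng):
        off = sample_axial_offsets(two_ring_model.coords, 0.0, 26.85, rng)
        np.testing.assert_array_equal(off.offsets, 0.0)

    def test_xy_bit_identical(self, two_ring_model, rng):
        off = sample_axial_offsets(two_ring_model.coords, 5.0, 26.85, rng)
        out = off.apply(two_ring_model.coords)
        assert np.array_equal(out[:, :2], two_ring_model.coords[:, :2])
        assert not np.array_equal(out[:, 2], two_ring_model.coords[:, 2])

    def test_default_omag_half_dmag(self):
        cfg = SimulationConfig(dmag=10.0)
        assert cfg.effective_omag == 5.0
        cfg2 = SimulationConfig(dmag=10.0, omag=1.0)
        assert cfg2.effective_omag == 1.0


class TestDeformNpc:
    def _rngs(self, seed):
        from npcsim import rng as rngmod

        return dict(
            rng_forces=rngmod.stream(seed, "forces", 0),
            rng_axial=rngmod.stream(seed, "axial", 0),
            rng_elongation=rngmod.stream(seed, "elongation", 0),
        )

    def test_no_variability_is_identity(self, two_ring_model):
        cfg = SimulationConfig(dmag=0.0)
        out = deform_npc(two_ring_model, cfg, **self._rngs(0))
        np.testing.assert_allclose(out.coords, two_ring_model.coords, atol=1e-9)

    def test_determinism_same_seed(self, two_ring_model):
        cfg = SimulationConfig(dmag=15.0, seed=9)
        a = deform_npc(two_ring_model, cfg, **self._rngs(9))
        b = deform_npc(two_ring_model, cfg, **self._rngs(9))
        assert np.array_equal(a.coords, b.coords)

    def test_no_band_overlap_across_seeds(self, two_ring_bands):
        """Strong correlation of nearby forces keeps adjacent bands apart."""
        for seed in range(40):
            m = simulate_npc(two_ring_bands, SimulationConfig(dmag=20.0, seed=seed))
            d = np.linalg.norm(m.coords[:, None] - m.coords[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            assert d.min() > 0.0

    def test_displacement_monotone_in_dmag(self, two_ring_bands):
        ref = assemble(two_ring_bands, s=8)
        means = []
        for dmag in (1.0, 5.0, 10.0, 20.0):
            disp = []
            for seed in range(60):
                m = simulate_npc(two_ring_bands, SimulationConfig(dmag=dmag, seed=seed))
                disp.append(np.linalg.norm(m.coords - ref.coords, axis=1).mean())
            means.append(np.mean(disp))
        assert means[0] < means[1] < means[2] < means[3]

    def test_band_concentricity_preserved(self, two_ring_bands):
        """Fitted band centers stay closer than half the mean displacement."""
        from npcsim.feature_extraction import fit_circle_3d

        ref = assemble(two_ring_bands, s=8)
        gaps, disps = [], []
        for seed in range(30):
            m = simulate_npc(two_ring_bands, SimulationConfig(dmag=10.0, seed=seed))
            c0 = fit_circle_3d(m.coords[m.band_nodes(0)]).center
            c1 = fit_circle_3d(m.coords[m.band_nodes(1)]).center
            gaps.append(np.linalg.norm(c0[:2] - c1[:2]))
            disps.append(np.linalg.norm((m.coords - ref.coords)[:, :2], axis=1).mean())
        assert np.mean(gaps) < 0.5 * np.mean(disps)

    def test_ellipse_rss_monotone_in_dmag(self, two_ring_bands):
        """Dmag feeds true irregularity: band ellipse RSS grows with it."""
        means = []
        for dmag in (1.0, 10.0, 20.0):
            rss = []
            for seed in range(40):
                m = simulate_npc(two_ring_bands, SimulationConfig(dmag=dmag, seed=seed))
                rss.append(fit_ellipse_3d(m.coords[m.band_nodes(0)]).rss)
            means.append(np.mean(rss))
        assert means[0] < means[1] < means[2]
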