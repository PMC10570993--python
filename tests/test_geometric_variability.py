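"""The seven geometric variability types and their parameter recovery."""

import numpy as np
import pytest

from npcsim.errors import InapplicableError, ValidationError
from npcsim.feature_extraction import (
    fit_circle_3d,
    fit_ellipse_3d,
    measure_height,
    measure_twist,
)
from npcsim.geometric_variability import (
    apply_shift,
    apply_tilt,
    change_symmetry,
    draw_parameter,
    elongation_forces,
    sample_vmf,
    set_height,
    set_mean_radius,
    set_twist,
    split_sides,
)
from npcsim.npc_assembly import assemble, mean_radius
from npcsim.reference_models import bands_from_ru, make_synthetic_ru
from npcsim.simulate import simulate_dataset
from npcsim.npc_assembly import SimulationConfig


class TestDrawParameter:
    def test_zero_sd_is_identity(self, rng):
        assert draw_parameter(10.0, 0.0, rng) == 10.0

    def test_gaussian_mean_clt_bound(self, rng):
        draws = np.array([draw_parameter(10.0, 2.0, rng) for _ in range(100_000)])
        assert abs(draws.mean() - 10.0) < 4.0 * 2.0 / np.sqrt(100_000)

    def test_negative_sd_rejected(self, rng):
        with pytest.raises(ValidationError):
            draw_parameter(1.0, -1.0, rng)


class TestSplitSides:
    def test_two_sides_no_sandwich(self, two_ring_model):
        split = split_sides(two_ring_model)
        assert split.applicable
        assert split.cs_bands == (0,) and split.ns_bands == (1,)
        assert split.sandwiched == ()
        np.testing.assert_allclose(split.weight, [1.0, 0.0])

    def test_sandwiched_band_midway(self, three_ring_model):
        split = split_sides(three_ring_model)
        assert split.sandwiched == (1,)
        assert split.weight[1] == pytest.approx(0.5)

    def test_single_subcomplex_flagged(self):
        bands = bands_from_ru(make_synthetic_ru(1, [0.0], [50.0], [0.0], ["CR"]))
        split = split_sides(assemble(bands, s=8))
        assert not split.applicable


class TestHeight:
    def test_identity_when_current(self, two_ring_model):
        out = set_height(two_ring_model, 50.0)
        np.testing.assert_allclose(out.coords, two_ring_model.coords, atol=1e-9)

    def test_target_height_reached(self, two_ring_model):
        out = set_height(two_ring_model, 30.0)
        assert measure_height(out) == pytest.approx(30.0)
        z = out.coords[:, 2]
        assert z[out.band == 0].mean() == pytest.approx(15.0)
        assert z[out.band == 1].mean() == pytest.approx(-15.0)
        np.testing.assert_array_equal(out.coords[:, :2], two_ring_model.coords[:, :2])

    def test_sandwiched_band_interpolates(self, three_ring_model):
        out = set_height(three_ring_model, 30.0)
        # IR sits midway, so its mean z stays at the centre
        assert out.coords[out.band == 1, 2].mean() == pytest.approx(0.0, abs=1e-12)

    def test_single_subcomplex_noop_with_warning(self):
        bands = bands_from_ru(make_synthetic_ru(1, [5.0], [50.0], [0.0], ["CR"]))
        model = assemble(bands, s=8)
        with pytest.warns(UserWarning):
            out = set_height(model, 30.0)
        np.testing.assert_array_equal(out.coords, model.coords)

    def test_nonpositive_height_rejected(self, two_ring_model):
        with pytest.raises(ValidationError):
            set_height(two_ring_model, 0.0)


class TestTilt:
    def test_huge_kappa_is_identity(self, two_ring_model, rng):
        # polar angle scales like 1/sqrt(kappa): at 1e12 the displacement of
        # a 53.7 nm ring is far below 1e-4 nm
        out = apply_tilt(two_ring_model, 1e12, rng)
        np.testing.assert_allclose(out.coords, two_ring_model.coords, atol=1e-4)

    def test_rigid_within_side(self, two_ring_model, rng):
        out = apply_tilt(two_ring_model, 20.0, rng)
        for j in range(2):
            a = two_ring_model.coords[two_ring_model.band == j]
            b = out.coords[out.band == j]
            d_a = np.linalg.norm(a[:, None] - a[None, :], axis=-1)
            d_b = np.linalg.norm(b[:, None] - b[None, :], axis=-1)
            np.testing.assert_allclose(d_a, d_b, atol=1e-9)

    def test_vmf_mean_resultant_length(self, rng):
        """Sampled axes match the closed-form coth(k) - 1/k resultant length."""
        kappa = 50.0
        draws = sample_vmf(kappa, rng, size=10_000)
        rbar = np.linalg.norm(draws.mean(axis=0))
        expected = 1.0 / np.tanh(kappa) - 1.0 / kappa
        assert rbar == pytest.approx(expected, abs=4.0 / np.sqrt(10_000))

    def test_nonpositive_kappa_rejected(self, two_ring_model, rng):
        with pytest.raises(ValidationError):
            apply_tilt(two_ring_model, 0.0, rng)


class TestShift:
    def test_zero_sd_identity(self, two_ring_model, rng):
        out = apply_shift(two_ring_model, 0.0, rng)
        np.testing.assert_array_equal(out.coords, two_ring_model.coords)

    def test_z_untouched_and_empirical_sd(self, two_ring_model):
        deltas = []
        for i in range(4000):
            r = np.random.default_rng(i)
            out = apply_shift(two_ring_model, 3.0, r)
            np.testing.assert_array_equal(out.coords[:, 2], two_ring_model.coords[:, 2])
            cs = out.band == 0
            deltas.append(out.coords[cs, 0].mean() - two_ring_model.coords[cs, 0].mean())
        sd = np.std(deltas, ddof=1)
        assert sd == pytest.approx(3.0, rel=0.1)


class TestTwist:
    def test_identity_at_current_twist(self, two_ring_model):
        theta0 = measure_twist(two_ring_model)
        out = set_twist(two_ring_model, theta0)
        np.testing.assert_allclose(out.coords, two_ring_model.coords, atol=1e-9)

    def test_fourteen_degrees_recovered(self, two_ring_model):
        out = set_twist(two_ring_model, np.radians(14.0))
        assert measure_twist(out) == pytest.approx(np.radians(14.0), abs=1e-9)

    def test_radii_and_z_unchanged(self, two_ring_model):
        out = set_twist(two_ring_model, 0.3)
        np.testing.assert_allclose(
            np.hypot(out.coords[:, 0], out.coords[:, 1]),
            np.hypot(two_ring_model.coords[:, 0], two_ring_model.coords[:, 1]),
            atol=1e-12,
        )
        np.testing.assert_array_equal(out.coords[:, 2], two_ring_model.coords[:, 2])

    def test_twist_invariant_under_global_rotation(self, two_ring_model):
        twisted = set_twist(two_ring_model, 0.25)
        rotated = twisted.copy()
        c, s = np.cos(1.1), np.sin(1.1)
        x, y = rotated.coords[:, 0].copy(), rotated.coords[:, 1].copy()
        rotated.coords[:, 0] = c * x - s * y
        rotated.coords[:, 1] = s * x + c * y
        assert measure_twist(rotated) == pytest.approx(measure_twist(twisted), abs=1e-12)

    def test_sandwiched_band_rotates_half(self, three_ring_model):
        theta0 = measure_twist(three_ring_model)
        out = set_twist(three_ring_model, theta0 + 0.2)
        ang_in = np.arctan2(three_ring_model.coords[:, 1], three_ring_model.coords[:, 0])
        ang_out = np.arctan2(out.coords[:, 1], out.coords[:, 0])
        d = np.angle(np.exp(1j * (ang_out - ang_in)))
        assert d[out.band == 1] == pytest.approx(0.1, abs=1e-9)


class TestRadius:
    def test_identity(self, two_ring_model):
        out = set_mean_radius(two_ring_model, mean_radius(two_ring_model))
        np.testing.assert_allclose(out.coords, two_ring_model.coords, atol=1e-9)

    def test_doubling(self, two_ring_model):
        out = set_mean_radius(two_ring_model, 107.4)
        np.testing.assert_allclose(
            np.hypot(out.coords[:, 0], out.coords[:, 1]),
            2.0 * np.hypot(two_ring_model.coords[:, 0], two_ring_model.coords[:, 1]),
            atol=1e-9,
        )
        np.testing.assert_array_equal(out.coords[:, 2], two_ring_model.coords[:, 2])

    def test_nonpositive_rejected(self, two_ring_model):
        with pytest.raises(ValidationError):
            set_mean_radius(two_ring_model, -5.0)


class TestElongation:
    def test_q_one_gives_zero_forces(self, two_ring_model, rng):
        f = elongation_forces(two_ring_model, 1.0, rng)
        np.testing.assert_array_equal(f, 0.0)

    def test_invalid_q_rejected(self, two_ring_model, rng):
        for q in (0.0, 1.5, -0.2):
            with pytest.raises(ValidationError):
                elongation_forces(two_ring_model, q, rng)

    def test_axis_ratio_monotone_in_q(self, two_ring_bands):
        """Fitted ellipse ratio decreases as q decreases (100-NPC means)."""
        means = []
        for q in (1.0, 0.9, 0.8):
            cfg = SimulationConfig(dmag=0.0, elongation_q=q, seed=11, n_npcs=30)
            models = simulate_dataset(two_ring_bands, cfg)
            ratios = [
                fit_ellipse_3d(m.coords[m.band_nodes(0)]).ratio for m in models
            ]
            means.append(np.mean(ratios))
        assert means[0] > means[1] > means[2]
        assert means[2] == pytest.approx(0.8, abs=0.05)

    def test_orientation_uniform_rayleigh(self, two_ring_bands):
        """Long-axis orientations are uniform: Rayleigh test on doubled angles."""
        cfg = SimulationConfig(dmag=0.0, elongation_q=0.7, seed=5, n_npcs=300)
        models = simulate_dataset(two_ring_bands, cfg)
        ang = np.array(
            [fit_ellipse_3d(m.coords[m.band_nodes(0)]).orientation for m in models]
        )
        doubled = 2.0 * ang
        n = len(doubled)
        rbar = np.hypot(np.cos(doubled).sum(), np.sin(doubled).sum()) / n
        z = n * rbar**2  # Rayleigh statistic; p ~ exp(-z)
        assert np.exp(-z) > 0.01


class TestSymmetry:
    def test_identity(self, two_ring_bands):
        assert change_symmetry(two_ring_bands, 8, 8) is two_ring_bands

    def test_nine_fold_arc_preserved(self):
        bands = bands_from_ru(
            make_synthetic_ru(2, [25.0, -25.0], [50.0, 56.0], [0.0, 0.0], ["CR", "NR"])
        )
        out = change_symmetry(bands, 8, 9)
        rbar_old = np.mean([b.r for b in bands.bands])
        rbar_new = np.mean([b.r for b in out.bands])
        # arc length between adjacent spokes is invariant
        assert 2 * np.pi * rbar_new / 9 == pytest.approx(2 * np.pi * rbar_old / 8)
        # band offsets from the mean radius are preserved
        assert out.bands[0].r - rbar_new == pytest.approx(bands.bands[0].r - rbar_old)
        for a, b in zip(bands.bands, out.bands):
            assert a.z == b.z and a.alpha == b.alpha

    def test_ninefold_has_larger_fitted_radius(self, two_ring_bands):
        m8 = assemble(two_ring_bands, s=8)
        m9 = assemble(change_symmetry(two_ring_bands, 8, 9), s=9)
        r8 = fit_circle_3d(m8.coords[m8.band_nodes(0)]).radius
        r9 = fit_circle_3d(m9.coords[m9.band_nodes(0)]).radius
        assert r9 > r8

    def test_invalid_target_symmetry(self, two_ring_bands):
        with pytest.raises(ValidationError):
            change_symmetry(two_ring_bands, 8, 2)


class TestNeutralIdentityAndOverlap:
    def test_neutral_parameters_are_identity(self, two_ring_bands):
        """The full pipeline with all-neutral parameters reproduces the assembly."""
        cfg = SimulationConfig(dmag=0.0, seed=3, n_npcs=1)
        model = simulate_dataset(two_ring_bands, cfg)[0]
        ref = assemble(two_ring_bands, s=8)
        np.testing.assert_allclose(model.coords, ref.coords, atol=1e-9)

    @pytest.mark.parametrize(
        "overrides",
        [
            {"mean_radius": 48.7},
            {"height": 40.0},
            {"twist": np.radians(14.0)},
            {"tilt_kappa": 50.0},
            {"shift_sd": 3.0},
            {"elongation_q": 0.8},
            {"s": 9},
        ],
    )
    def test_no_node_overlap_on_presets(self, two_ring_bands, overrides):
        cfg = SimulationConfig(seed=21, n_npcs=3, **overrides)
        for m in simulate_dataset(two_ring_bands, cfg):
            d = np.linalg.norm(m.coords[:, None] - m.coords[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            assert d.min() > 0.1
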