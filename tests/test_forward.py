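import numpy as np
import pytest

from dotslab.geometry import OpticalProperties, TumorSpec, make_slab_phantom, make_layout
from dotslab.forward import (
    DEFAULT_IMAGE_PAIRS,
    ForwardModelError,
    MeasurementSet,
    add_noise,
    boundary_reflection_parameter,
    born_perturbation,
    diffusion_params,
    infinite_medium_fluence,
    simulate_measurement,
    slab_fluence,
)

L = 23.7  # default slab thickness, mm


class TestDiffusionParams:
    def test_derived_quantities(self):
        op = OpticalProperties(mu_a=0.01, mu_s_prime=1.0)
        p = diffusion_params(op)
        assert p.D == pytest.approx(1.0 / (3 * 1.01))
        assert p.mu_eff == pytest.approx(np.sqrt(0.01 / p.D))
        assert p.z_b > 0 and p.z_0 == pytest.approx(1.0)

    def test_boundary_parameter_matched_and_tissue(self):
        assert boundary_reflection_parameter(1.0) == 1.0
        # tissue-air mismatch at n = 1.4
        assert boundary_reflection_parameter(1.4) == pytest.approx(2.95, abs=0.01)


class TestInfiniteMedium:
    def test_closed_form_value(self):
        # frozen from an independent high-precision evaluation of
        # exp(-mu_eff r) / (4 pi D r) at mu_a=0.01, mu_s'=1.0, r=10
        op = OpticalProperties(mu_a=0.01, mu_s_prime=1.0)
        assert infinite_medium_fluence(op, 10.0) == pytest.approx(
            4.2292261792981406e-3, rel=1e-12
        )

    def test_monotone_decay(self):
        op = OpticalProperties()
        r = np.linspace(1.0, 200.0, 300)
        phi = infinite_medium_fluence(op, r)
        assert np.all(np.diff(phi) < 0)

    def test_doubling_D_at_fixed_mu_eff_halves_fluence(self):
        op1 = OpticalProperties(mu_a=0.01, mu_s_prime=1.0)
        # same mu_eff, doubled D: mu_a2 = 2 mu_a1, mu_a2 + mu_s2' halved
        op2 = OpticalProperties(mu_a=0.02, mu_s_prime=0.485)
        p1, p2 = diffusion_params(op1), diffusion_params(op2)
        assert p2.D == pytest.approx(2 * p1.D)
        assert p2.mu_eff == pytest.approx(p1.mu_eff)
        assert infinite_medium_fluence(op2, 10.0) == pytest.approx(
            infinite_medium_fluence(op1, 10.0) / 2
        )

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            infinite_medium_fluence(OpticalProperties(), 0.0)


class TestSlabFluence:
    op = OpticalProperties()

    def test_reciprocity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.uniform((0, 0, 1), (220, 100, L - 1))
            b = rng.uniform((0, 0, 1), (220, 100, L - 1))
            f_ab = slab_fluence(self.op, L, a, b)
            f_ba = slab_fluence(self.op, L, b, a)
            assert f_ab == pytest.approx(f_ba, rel=1e-12)

    def test_positivity(self):
        rng = np.random.default_rng(4)
        a = rng.uniform((0, 0, 0.5), (220, 100, L - 0.5), size=(30, 3))
        b = rng.uniform((0, 0, 0.5), (220, 100, L - 0.5), size=(30, 3))
        assert np.all(slab_fluence(self.op, L, a, b) > 0)

    def test_infinite_medium_limit_thick_slab(self):
        a = np.array([50.0, 50.0, 100.0])
        b = np.array([55.0, 52.0, 110.0])
        f_slab = slab_fluence(self.op, 200.0, a, b)
        f_inf = infinite_medium_fluence(self.op, float(np.linalg.norm(a - b)))
        assert abs(f_slab - f_inf) / f_inf < 1e-3

    def test_image_truncation_converged(self):
        a = np.array([100.0, 50.0, 1.0])
        b = np.array([110.0, 55.0, L])
        f7 = slab_fluence(self.op, L, a, b, n_image_pairs=7)
        f15 = slab_fluence(self.op, L, a, b, n_image_pairs=15)
        assert abs(f7 - f15) / abs(f15) < 1e-6


class TestBornPerturbation:
    op = OpticalProperties()

    def test_zero_contrast_is_exactly_zero(self):
        tumor = TumorSpec(100.0, 50.0, 12.0, 5.0, self.op.mu_a)  # delta mu_a = 0
        p = born_perturbation(
            self.op, tumor, np.array([100.0, 50.0, 1.0]), np.array([100.0, 50.0, L]), L
        )
        assert p == 0.0

    def test_positive_contrast_dims_every_channel(self, phantom, small_layout):
        rng = np.random.default_rng(5)
        src = small_layout.source_positions + [0, 0, 1.0]
        det = small_layout.detector_positions
        for _ in range(5):
            tumor = TumorSpec(
                rng.uniform(30, 190), rng.uniform(30, 70), rng.uniform(6, 18),
                rng.uniform(2, 5), rng.uniform(2, 4) * self.op.mu_a,
            )
            p = born_perturbation(self.op, tumor, src, det, L)
            assert np.all(p < 0)

    def test_quadrature_refinement(self):
        tumor = TumorSpec(100.0, 50.0, 12.0, 2.0, 0.015)
        s = np.array([100.0, 50.0, 1.0])
        d = np.array([105.0, 52.0, L])
        p500 = born_perturbation(self.op, tumor, s, d, L, n_quadrature=500)
        p5000 = born_perturbation(self.op, tumor, s, d, L, n_quadrature=5000)
        assert abs(p500 - p5000) / abs(p5000) < 0.01

    def test_tumor_on_face_rejected(self):
        tumor = TumorSpec(100.0, 50.0, 1.0, 5.0, 0.015)
        with pytest.raises(ForwardModelError):
            born_perturbation(
                self.op, tumor, np.array([100, 50, 1.0]), np.array([100, 50, L]), L
            )


class TestSimulateMeasurement:
    def test_translational_symmetry_without_tumor(self, phantom, layout):
        # homogeneous slab, no tumor: co-axial channels all see the same value
        readings = simulate_measurement(phantom, None, layout).reshape(48, 54)
        src = layout.source_positions
        det = layout.detector_positions
        vals = []
        for i in range(48):
            j = np.argmin(np.linalg.norm(det[:, :2] - src[i, :2], axis=1))
            if np.linalg.norm(det[j, :2] - src[i, :2]) < 1e-9:
                vals.append(readings[i, j])
        assert len(vals) > 1
        np.testing.assert_allclose(vals, vals[0], rtol=1e-9)

    @staticmethod
    def _chord_distances(layout, tumor):
        dists = []
        for s in layout.source_positions:
            for d in layout.detector_positions:
                u = d - s
                t = np.clip(np.dot(tumor.center - s, u) / np.dot(u, u), 0, 1)
                dists.append(np.linalg.norm(s + t * u - tumor.center))
        return np.array(dists)

    def test_largest_dimming_on_channel_nearest_tumor(self, phantom, layout):
        # a tumor sitting on the one co-axial source-detector line of the
        # grid: the exhaustive channel scan must find that same channel both
        # nearest and most dimmed
        tumor = TumorSpec(10.0, 43.225, 12.0, 3.0, 0.015)
        base = simulate_measurement(phantom, None, layout)
        with_t = simulate_measurement(phantom, tumor, layout)
        frac = with_t / base - 1.0
        dists = self._chord_distances(layout, tumor)
        assert np.argmin(frac) == np.argmin(dists)

    def test_max_dimming_chord_intersects_mid_slab_tumor(self, phantom, layout):
        # mid-slab, many chords pass close; the most-dimmed channel must at
        # least be one whose line crosses the sphere
        tumor = TumorSpec(110.0, 50.0, 12.0, 6.0, 0.015)
        base = simulate_measurement(phantom, None, layout)
        with_t = simulate_measurement(phantom, tumor, layout)
        frac = with_t / base - 1.0
        dists = self._chord_distances(layout, tumor)
        assert dists[np.argmin(frac)] < tumor.radius

    def test_monotone_in_radius_and_contrast(self, phantom, small_layout):
        base_kwargs = dict(center_x=100.0, center_y=50.0, center_z=12.0)
        prev = None
        for r in (2.0, 3.0, 4.0, 5.0):
            cur = simulate_measurement(
                phantom, TumorSpec(radius=r, mu_a_tumor=0.012, **base_kwargs), small_layout
            )
            if prev is not None:
                assert np.all(cur <= prev)
            prev = cur
        prev = None
        for mua in (0.008, 0.012, 0.016, 0.02):
            cur = simulate_measurement(
                phantom, TumorSpec(radius=4.0, mu_a_tumor=mua, **base_kwargs), small_layout
            )
            if prev is not None:
                assert np.all(cur <= prev)
            prev = cur

    def test_deterministic(self, het_phantom, small_layout):
        tumor = TumorSpec(100.0, 50.0, 12.0, 4.0, 0.015)
        a = simulate_measurement(het_phantom, tumor, small_layout)
        b = simulate_measurement(het_phantom, tumor, small_layout)
        np.testing.assert_array_equal(a, b)

    def test_oversized_perturbation_rejected(self, phantom, layout):
        # a large, strongly absorbing central tumor leaves the linear regime
        tumor = TumorSpec(110.4, 51.45, 11.85, 11.0, 0.02)
        with pytest.raises(ForwardModelError):
            simulate_measurement(phantom, tumor, layout)


class TestNoise:
    def _mset(self, readings):
        return MeasurementSet(
            readings=readings,
            source_xyz=np.zeros((1, 3)),
            detector_xyz=np.zeros((readings.shape[1], 3)),
        )

    def test_zero_level_is_identity(self):
        m = self._mset(np.ones((3, 4)))
        out = add_noise(m, 0.0, seed=1)
        np.testing.assert_array_equal(out.readings, m.readings)

    def test_two_percent_noise_statistics(self):
        m = self._mset(np.ones((1000, 1000)))
        out = add_noise(m, 0.02, seed=2)
        eps = out.readings - 1.0
        assert np.std(eps) == pytest.approx(0.02, rel=0.01)
        assert np.mean(eps) == pytest.approx(0.0, abs=1e-4)

    def test_seeded_determinism_and_positivity(self):
        m = self._mset(np.full((5, 8), 1e-6))
        a = add_noise(m, 0.5, seed=3)
        b = add_noise(m, 0.5, seed=3)
        np.testing.assert_array_equal(a.readings, b.readings)
        assert np.all(a.readings > 0)

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            add_noise(self._mset(np.ones((1, 2))), -0.1, seed=0)
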