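"""Watson sampling, multi-tensor signals, Rician noise, population generation."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

import dwifuse as dw
from dwifuse.gradients import repulsion_energy

from conftest import random_rotation


class TestWatsonKappa:
    @pytest.mark.parametrize(
        "theta, expected",
        [(90.0, 2.0), (30.0, 8.0), (15.0, 2.0 / np.sin(np.radians(15.0)) ** 2)],
    )
    def test_closed_form(self, theta, expected):
        assert dw.watson_kappa(theta) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("theta", [0.0, -5.0, 90.1])
    def test_domain(self, theta):
        with pytest.raises(ValueError):
            dw.watson_kappa(theta)

    def test_strictly_decreasing(self):
        thetas = np.linspace(1.0, 90.0, 200)
        kappas = [dw.watson_kappa(t) for t in thetas]
        assert np.all(np.diff(kappas) < 0)


class TestWatsonSampling:
    def test_degenerate_concentration(self):
        axes = dw.sample_watson_axes([0.0, 0.0, 1.0], 1e9, 500, seed=3)
        ang = np.degrees(np.arccos(np.clip(axes @ [0, 0, 1], -1, 1)))
        assert ang.max() < 0.2

    def test_deviation_angle_distribution(self):
        """Empirical CDF of theta matches quadrature of exp(-k sin^2 t) sin t."""
        kappa = dw.watson_kappa(30.0)  # 8
        axes = dw.sample_watson_axes([0.0, 0.0, 1.0], kappa, 100_000, seed=11)
        theta = np.arccos(np.clip(axes[:, 2], -1, 1))
        grid = np.linspace(0, np.pi / 2, 20001)
        dens = np.exp(-kappa * np.sin(grid) ** 2) * np.sin(grid)
        cdf = cumulative_trapezoid(dens, grid, initial=0.0)
        cdf /= cdf[-1]
        emp = np.searchsorted(np.sort(theta), grid, side="right") / len(theta)
        assert np.max(np.abs(emp - cdf)) < 0.01

    def test_determinism_and_hemisphere(self):
        a = dw.sample_watson_axes([1.0, 1.0, 0.0], 5.0, 100, seed=4)
        b = dw.sample_watson_axes([1.0, 1.0, 0.0], 5.0, 100, seed=4)
        np.testing.assert_array_equal(a, b)
        assert np.all(a @ (np.array([1.0, 1.0, 0.0]) / np.sqrt(2)) >= 0)

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError):
            dw.sample_watson_axes([0.0, 0.0, 0.0], 5.0, 10, seed=0)


class TestMultiTensorSignal:
    def test_no_diffusion_weighting(self, scheme81):
        sch = dw.GradientScheme(scheme81.directions, 0.0)
        sig = dw.multi_tensor_signal(dw.named_fiber_config("single"), sch, S0=150.0)
        np.testing.assert_allclose(sig, 150.0)

    def test_parallel_perpendicular_closed_form(self):
        axis = np.array([0.0, 0.0, 1.0])
        dirs = np.array([[0, 0, 1.0], [1.0, 0, 0], [0, 1.0, 0]])
        sch = dw.GradientScheme(dirs, 3000.0)
        cfg = dw.FiberConfig(((axis, 1.0),))
        sig = dw.multi_tensor_signal(cfg, sch, S0=150.0, lambda_axial=1.7e-3, lambda_radial=3e-4)
        assert sig[0] == pytest.approx(150.0 * np.exp(-3000.0 * 1.7e-3), rel=1e-12)
        assert sig[1] == pytest.approx(150.0 * np.exp(-3000.0 * 3e-4), rel=1e-12)
        assert sig[2] == pytest.approx(sig[1], rel=1e-12)

    def test_rotation_invariance(self, scheme81, rng):
        """Noise-free signals are invariant under joint rotation of fibers and gradients."""
        cfg = dw.named_fiber_config("cross60eq")
        base = dw.multi_tensor_signal(cfg, scheme81)
        for _ in range(10):
            R = random_rotation(rng)
            sch_r = dw.GradientScheme(scheme81.directions @ R.T, scheme81.b_value)
            cfg_r = dw.FiberConfig(tuple((R @ a, w) for a, w in cfg.fibers))
            rot = dw.multi_tensor_signal(cfg_r, sch_r)
            assert np.max(np.abs(rot - base)) < 1e-10


class TestRicianNoise:
    def test_zero_noise_is_identity(self):
        sig = np.linspace(1, 100, 50)
        np.testing.assert_array_equal(dw.add_rician_noise(sig, 0.0, 150.0, seed=1), sig)

    def test_rayleigh_mean_at_zero_signal(self):
        """For S = 0 the magnitude is Rayleigh with mean sigma sqrt(pi/2)."""
        out = dw.add_rician_noise(np.zeros(1_000_000), 5.0, 150.0, seed=2)
        assert out.mean() == pytest.approx(7.5 * np.sqrt(np.pi / 2), rel=2e-3)

    def test_second_moment_identity(self):
        s = 40.0
        out = dw.add_rician_noise(np.full(1_000_000, s), 5.0, 150.0, seed=3)
        assert np.mean(out**2) == pytest.approx(s**2 + 2 * 7.5**2, rel=2e-3)


class TestMakePopulation:
    def test_degenerate_limit_equals_ground_truth(self, scheme81):
        sim = dw.SimulationConfig(
            theta_T=1e-9, noise_percent=0.0, population_size=5, grid_shape=(2, 2, 1), seed=0
        )
        pop = dw.make_population(sim, dw.named_fiber_config("cross90eq"), scheme81)
        for d in range(5):
            np.testing.assert_allclose(pop.signals[d], pop.ground_truth, atol=1e-9)

    def test_reproducible(self, scheme81):
        sim = dw.SimulationConfig(theta_T=30, noise_percent=5, population_size=4, seed=9)
        a = dw.make_population(sim, dw.named_fiber_config("single"), scheme81)
        b = dw.make_population(sim, dw.named_fiber_config("single"), scheme81)
        np.testing.assert_array_equal(a.signals, b.signals)
        assert a.sigma == 150.0 * 0.05

    def test_second_moment_across_subjects(self, scheme81):
        """E[S_noisy^2] = S^2 + 2 sigma^2, checked by a z-test per direction."""
        sim = dw.SimulationConfig(
            theta_T=1e-9, noise_percent=5, population_size=1000, grid_shape=(1, 1, 1), seed=7
        )
        pop = dw.make_population(sim, dw.named_fiber_config("single"), scheme81)
        gt = pop.ground_truth[0]
        expected = gt**2 + 2 * pop.sigma**2
        # Var(S_noisy^2) = 4 sigma^2 S^2 + 4 sigma^4 (noncentral chi-square, 2 dof)
        sd_mean = np.sqrt(4 * pop.sigma**2 * gt**2 + 4 * pop.sigma**4) / np.sqrt(1000)
        z = np.abs(np.mean(pop.signals**2, axis=(0, 1)) - expected) / sd_mean
        assert z.max() < 5.0


class TestDefaultScheme:
    def test_unit_norm_and_non_collinear(self, scheme81):
        assert scheme81.count == 81
        np.testing.assert_allclose(np.linalg.norm(scheme81.directions, axis=1), 1.0, atol=1e-12)

    def test_min_angle_near_15_degrees(self, scheme81):
        # 81 axes spread on the hemisphere pack at roughly 15 degrees
        assert 13.0 < scheme81.min_axis_angle() < 18.0

    def test_k6_reaches_icosahedral_optimum(self, scheme6):
        phi = (1 + np.sqrt(5)) / 2
        ico = np.array(
            [[-1, phi, 0], [1, phi, 0], [0, -1, phi], [0, 1, phi], [phi, 0, -1], [phi, 0, 1]],
            dtype=float,
        )
        ico /= np.linalg.norm(ico, axis=1, keepdims=True)
        assert repulsion_energy(scheme6.directions) <= repulsion_energy(ico) * 1.001

    def test_deterministic(self):
        a = dw.default_scheme(20, seed=3, n_iter=200)
        b = dw.default_scheme(20, seed=3, n_iter=200)
        np.testing.assert_array_equal(a.directions, b.directions)
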