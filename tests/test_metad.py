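"""Metadynamics engine: deposition rule, bias bookkeeping, Langevin dynamics,
FES reconstruction and basin thermodynamics."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from shp2meta.errors import ParameterError
from shp2meta.metad import (
    KB,
    BasinSpec,
    BiasState,
    FreeEnergySurface,
    KernelDeposit,
    Landscape,
    MetaDParams,
    basin_delta_g,
    bias_from_kernels,
    block_error,
    deposit,
    fes_from_bias,
    langevin_step,
    read_hills,
    run_wtmetad,
    write_hills,
)
from shp2meta.synthetic import double_well_landscape


def flat_landscape(width=4.0):
    return Landscape(
        dimension=1,
        energy=lambda s: 0.0,
        gradient=lambda s: np.zeros(1),
        box=np.array([[-width, width]]),
    )


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        {"w0": 0.0}, {"w0": -1.0}, {"sigma": 0.0}, {"stride": 0},
        {"bias_factor": 1.0}, {"temperature": -5.0},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            MetaDParams(**{"sigma": 0.1, **kwargs})

    def test_tempering_scale(self):
        p = MetaDParams(sigma=0.1, bias_factor=10.0, temperature=298.0)
        assert p.kb_delta_t == pytest.approx(KB * 9 * 298.0)


class TestLangevinStep:
    def test_flat_landscape_zero_noise_is_identity(self):
        s = langevin_step([0.7], flat_landscape(), None, dt=0.1, diffusion=0.1,
                          temperature=298.0, noise=np.zeros(1))
        assert s[0] == pytest.approx(0.7)

    def test_harmonic_zero_noise_geometric_decay(self):
        k = 2.0
        harmonic = Landscape(1, lambda s: 0.5 * k * float(s[0]) ** 2,
                             lambda s: np.array([k * float(s[0])]),
                             box=np.array([[-5.0, 5.0]]))
        dt, D, T = 0.05, 0.1, 298.0
        factor = 1.0 - D * dt * k / (KB * T)
        x = 1.0
        for _ in range(5):
            x_next = langevin_step([x], harmonic, None, dt, D, T, noise=np.zeros(1))[0]
            assert x_next == pytest.approx(factor * x, rel=1e-12)
            x = x_next

    def test_displacement_variance_matches_diffusion(self, rng):
        dt, D = 0.1, 0.05
        steps = 20_000
        land = flat_landscape(width=1e6)  # effectively unbounded
        x = 0.0
        disp = np.empty(steps)
        for i in range(steps):
            x_new = langevin_step([x], land, None, dt, D, 298.0, rng=rng)[0]
            disp[i] = x_new - x
            x = x_new
        assert np.var(disp) == pytest.approx(2 * D * dt, rel=0.05)

    def test_reflective_and_periodic_boundaries(self):
        land = flat_landscape(width=1.0)
        s = langevin_step([0.95], land, None, 0.1, 0.1, 298.0, noise=np.array([3.0]))
        assert -1.0 <= s[0] <= 1.0
        per = Landscape(1, lambda s: 0.0, lambda s: np.zeros(1),
                        box=np.array([[-180.0, 180.0]]), periodic=(True,))
        s = langevin_step([179.0], per, None, 0.1, 100.0, 298.0, noise=np.array([2.0]))
        assert -180.0 <= s[0] <= 180.0

    def test_invalid_dt_and_diffusion(self):
        with pytest.raises(ParameterError):
            langevin_step([0.0], flat_landscape(), None, 0.0, 0.1, 298.0, noise=np.zeros(1))
        with pytest.raises(ParameterError):
            langevin_step([0.0], flat_landscape(), None, 0.1, -0.1, 298.0, noise=np.zeros(1))


class TestDeposit:
    def test_first_height_is_w0(self):
        params = MetaDParams(sigma=0.1, w0=0.3)
        bias = BiasState(np.array([[-2.0, 2.0]]), sigma=0.1)
        deposit(bias, np.array([0.5]), params)
        assert bias.kernels[-1][1] == pytest.approx(0.3)

    def test_height_decays_by_e_at_v_equals_kb_delta_t(self):
        params = MetaDParams(sigma=0.1, w0=0.3, bias_factor=10.0, temperature=298.0)
        bias = BiasState(np.array([[-2.0, 2.0]]), sigma=0.1)
        # seed the bias with exactly kB·ΔT at a grid point
        center = np.array([bias.axes[0][40]])
        bias.add_kernel(center, params.kb_delta_t)
        deposit(bias, center, params)
        assert bias.kernels[-1][1] == pytest.approx(0.3 / math.e, rel=1e-6)

    def test_two_same_point_depositions_closed_form(self):
        params = MetaDParams(sigma=0.1, w0=0.3, bias_factor=8.0)
        bias = BiasState(np.array([[-2.0, 2.0]]), sigma=0.1)
        center = np.array([bias.axes[0][25]])
        deposit(bias, center, params)
        deposit(bias, center, params)
        expected = 0.3 + 0.3 * math.exp(-0.3 / params.kb_delta_t)
        assert bias.value(center) == pytest.approx(expected, rel=1e-3)

    def test_heights_non_increasing_at_revisited_point(self):
        params = MetaDParams(sigma=0.2, w0=0.5, bias_factor=5.0)
        bias = BiasState(np.array([[-2.0, 2.0]]), sigma=0.2)
        center = np.array([0.0])
        heights = []
        for _ in range(6):
            deposit(bias, center, params)
            heights.append(bias.kernels[-1][1])
        assert all(h2 < h1 for h1, h2 in zip(heights, heights[1:]))
        assert all(0 < h <= params.w0 for h in heights)

    def test_tempering_limits(self):
        center = np.array([0.0])
        # gamma -> large: heights stay near w0 (standard metadynamics)
        params = MetaDParams(sigma=0.2, w0=0.5, bias_factor=1e7)
        bias = BiasState(np.array([[-2.0, 2.0]]), sigma=0.2)
        for _ in range(5):
            deposit(bias, center, params)
        assert bias.kernels[-1][1] == pytest.approx(0.5, rel=1e-4)
        # gamma -> 1+: heights collapse immediately
        params = MetaDParams(sigma=0.2, w0=0.5, bias_factor=1.001)
        bias = BiasState(np.array([[-2.0, 2.0]]), sigma=0.2)
        deposit(bias, center, params)
        deposit(bias, center, params)
        assert bias.kernels[-1][1] < 1e-100


class TestBiasValue:
    def test_empty_bias_is_zero(self):
        bias = BiasState(np.array([[-3.0, 3.0]]), sigma=0.1)
        assert bias.value(np.array([1.234])) == 0.0

    def test_single_kernel_center_value(self):
        bias = BiasState(np.array([[-3.0, 3.0], [-3.0, 3.0]]), sigma=0.2)
        bias.add_kernel(np.array([0.5, -1.0]), 0.7)
        assert bias.value(np.array([0.5, -1.0])) == pytest.approx(0.7, rel=0.01)

    def test_grid_matches_kernel_sum_within_one_percent(self, rng):
        bias = BiasState(np.array([[-3.0, 3.0], [-2.0, 4.0]]), sigma=0.25)
        for _ in range(50):
            center = rng.uniform([-3.0, -2.0], [3.0, 4.0])
            bias.add_kernel(center, rng.uniform(0.05, 0.5))
        scale = float(np.max(bias.bias))
        for _ in range(20):
            probe = rng.uniform([-3.0, -2.0], [3.0, 4.0])
            grid = bias.value(probe)
            direct = bias.kernel_sum(probe)
            assert abs(grid - direct) <= 0.01 * scale

    def test_outside_box_rejected(self):
        bias = BiasState(np.array([[-3.0, 3.0]]), sigma=0.1)
        with pytest.raises(ValueError, match="outside"):
            bias.value(np.array([4.0]))

    def test_periodic_kernel_wraps_around_seam(self):
        bias = BiasState(np.array([[-180.0, 180.0]]), sigma=10.0, periodic=(True,))
        bias.add_kernel(np.array([175.0]), 1.0)
        # 10 degrees away across the seam
        assert bias.value(np.array([-175.0])) == pytest.approx(
            math.exp(-0.5), rel=0.02)


class TestRun:
    def test_bit_reproducible(self):
        land = double_well_landscape(h=2.0)
        params = MetaDParams(sigma=0.1, w0=0.25, stride=100, bias_factor=10.0)
        a = run_wtmetad(land, params, 20_000, dt=0.1, diffusion=0.03, seed=5,
                        initial=np.array([-1.0]))
        b = run_wtmetad(land, params, 20_000, dt=0.1, diffusion=0.03, seed=5,
                        initial=np.array([-1.0]))
        np.testing.assert_array_equal(a.trajectory, b.trajectory)
        assert [k.height for k in a.log] == [k.height for k in b.log]
        assert write_hills(a) == write_hills(b)

    def test_near_unbiased_limit_stays_in_deep_well(self):
        """Tiny kernels on a deep double well: no basin escape in a short run."""
        land = double_well_landscape(h=12.0)
        params = MetaDParams(sigma=0.1, w0=1e-6, stride=500, bias_factor=1e6)
        run = run_wtmetad(land, params, 50_000, dt=0.1, diffusion=0.03, seed=3,
                          initial=np.array([-1.0]), traj_stride=50)
        assert np.all(run.trajectory[:, 0] < 0)

    def test_double_well_run_visits_both_basins(self, short_reference_run):
        x = short_reference_run.run.trajectory[:, 0]
        assert np.mean(x < -0.3) >= 0.10
        assert np.mean(x > 0.3) >= 0.10

    def test_grid_force_path_consistent_with_langevin_step(self):
        """One deposition interval of the fast loop reproduces stepwise
        langevin_step updates driven by the same noise and grids."""
        land = double_well_landscape(h=2.0)
        params = MetaDParams(sigma=0.1, w0=0.25, stride=50, bias_factor=10.0)
        run = run_wtmetad(land, params, 50, dt=0.1, diffusion=0.03, seed=9,
                          initial=np.array([0.4]), traj_stride=1)
        rng = np.random.default_rng(9)
        noise = rng.standard_normal((50, 1))
        bias = BiasState(land.box, sigma=np.broadcast_to(params.sigma, (1,)))
        x = np.array([0.4])
        for k in range(50):
            # same integrator, but force from the analytic landscape gradient
            x = langevin_step(x, land, bias, 0.1, 0.03, params.temperature,
                              noise=noise[k])
        # grid interpolation of the gradient introduces only a small error
        assert run.trajectory[-1, 0] == pytest.approx(float(x[0]), abs=5e-3)


class TestFes:
    def test_uniform_bias_gives_flat_zero_fes(self):
        bias = BiasState(np.array([[-1.0, 1.0]]), sigma=0.1)
        bias.add_kernel(np.array([0.0]), 1e-12)  # non-empty kernel history
        bias.bias[:] = 3.7  # uniform accumulated bias
        fes = fes_from_bias(bias, MetaDParams(sigma=0.1))
        np.testing.assert_allclose(fes.F, 0.0, atol=1e-12)

    def test_single_kernel_inverted_scaled_gaussian(self):
        params = MetaDParams(sigma=0.2, w0=0.5, bias_factor=10.0)
        bias = BiasState(np.array([[-2.0, 2.0]]), sigma=0.2)
        bias.add_kernel(np.array([0.0]), 0.5)
        fes = fes_from_bias(bias, params)
        x = fes.axes[0]
        scale = 10.0 / 9.0
        expected = scale * 0.5 * (1.0 - np.exp(-0.5 * (x / 0.2) ** 2))
        inner = np.abs(x) <= 1.0  # inside the 6-sigma kernel truncation
        np.testing.assert_allclose(fes.F[inner], expected[inner], atol=1e-6)
        assert fes.F.min() == 0.0

    def test_empty_bias_rejected(self):
        bias = BiasState(np.array([[-1.0, 1.0]]), sigma=0.1)
        with pytest.raises(ValueError, match="empty"):
            fes_from_bias(bias, MetaDParams(sigma=0.1))

    def test_reference_run_recovers_double_well(self, short_reference_run):
        ref = short_reference_run
        fes = fes_from_bias(ref.run.bias, ref.params)
        x = fes.axes[0]
        U = ref.barrier_height * (x ** 2 - 1.0) ** 2
        U -= U.min()
        region = (np.abs(x) <= 1.3) & (U <= 6.0)
        rms = float(np.sqrt(np.mean((fes.F[region] - U[region]) ** 2)))
        assert rms <= 0.5


def _analytic_fes(h=4.0, tilt=0.0, n=1601):
    # exactly antisymmetric axis so mirror-image basins match point for point
    x = (np.arange(n) - (n - 1) / 2) * (3.2 / (n - 1))
    F = h * (x ** 2 - 1.0) ** 2 + tilt * x
    F -= F.min()
    return FreeEnergySurface(axes=[x], F=F, gamma=10.0)


class TestBasinDeltaG:
    LEFT = BasinSpec("left", box=[(-1.5, -0.2)])
    RIGHT = BasinSpec("right", box=[(0.2, 1.5)])

    def test_symmetric_wells_give_zero(self):
        fes = _analytic_fes()
        assert basin_delta_g(fes, self.LEFT, self.RIGHT, 298.0) == pytest.approx(
            0.0, abs=1e-9)

    def test_swap_flips_sign_exactly(self):
        fes = _analytic_fes(tilt=1.0)
        ab = basin_delta_g(fes, self.LEFT, self.RIGHT, 298.0)
        ba = basin_delta_g(fes, self.RIGHT, self.LEFT, 298.0)
        assert ab == pytest.approx(-ba, abs=1e-12)
        assert abs(ab) > 0.5

    def test_tilted_well_matches_direct_quadrature(self):
        h, tilt, T = 4.0, 1.0, 298.0
        fes = _analytic_fes(h=h, tilt=tilt, n=3201)
        beta = 1.0 / (KB * T)

        def boltz(x):
            u = h * (x ** 2 - 1.0) ** 2 + tilt * x
            return math.exp(-beta * u)

        za, _ = quad(boltz, -1.5, -0.2)
        zb, _ = quad(boltz, 0.2, 1.5)
        expected = -KB * T * math.log(zb / za)
        got = basin_delta_g(fes, self.LEFT, self.RIGHT, T)
        assert got == pytest.approx(expected, abs=0.05)

    def test_overlapping_or_empty_basins_rejected(self):
        fes = _analytic_fes()
        with pytest.raises(ValueError, match="overlap"):
            basin_delta_g(fes, BasinSpec("a", box=[(-1.0, 0.5)]),
                          BasinSpec("b", box=[(0.0, 1.0)]), 298.0)
        with pytest.raises(ValueError, match="no grid points"):
            basin_delta_g(fes, BasinSpec("a", box=[(7.0, 8.0)]), self.RIGHT, 298.0)


class TestBlockError:
    def test_converged_run_has_small_error(self, short_reference_run):
        ref = short_reference_run
        res = block_error(ref.run.log, ref.run.bias, ref.params,
                          ref.basin_left, ref.basin_right, n_blocks=5)
        assert res.error < 1.0
        assert res.delta_g == pytest.approx(ref.expected_delta_g, abs=3 * max(res.error, 0.05))

    def test_too_short_log_rejected(self, short_reference_run):
        ref = short_reference_run
        with pytest.raises(ValueError, match="too short"):
            block_error(ref.run.log[:5], ref.run.bias, ref.params,
                        ref.basin_left, ref.basin_right, n_blocks=5)


class TestHills:
    def test_round_trip_reproduces_bias(self, short_reference_run):
        ref = short_reference_run
        text = write_hills(ref.run)
        times, centers, sigmas, heights, biasf = read_hills(text)
        assert len(times) == len(ref.run.log)
        assert biasf == pytest.approx(ref.params.bias_factor)
        rebuilt = bias_from_kernels(centers, heights, sigmas[0],
                                    ref.landscape.box)
        probe = np.array([0.37])
        assert rebuilt.value(probe) == pytest.approx(
            ref.run.bias.value(probe), rel=1e-4, abs=1e-6)

    def test_landscape_gradient_self_consistency(self, rng):
        double_well_landscape(h=3.0, tilt=0.7).check_gradient(rng)
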