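"""NL-DCT reconstruction: slope fits, system assembly, TV inversion."""

import math

import numpy as np
import pytest
from scipy.optimize import nnls

from conftest import make_toy_tensor
from dcflow.forward_dcs import (
    AcquisitionFrame,
    CorrelationCurve,
    DelayGrid,
    NoiseConfig,
    simulate_acquisition,
    synth_g1,
)
from dcflow.nldct import (
    LinearSystem,
    RBFIMap,
    ReconConfig,
    SlopeVector,
    assemble_system,
    extract_slope,
    higher_order_correct,
    normalize_rbfi,
    reconstruct,
    solve_bregman_tv,
    sensitivity_row,
    _slopes_from_frame,
)
from dcflow.phantom import BFIMap, LesionSpec, OpticalProperties, VoxelGrid, make_phantom


def _curve(taus, vals):
    return CorrelationCurve("g1", np.asarray(taus), np.asarray(vals), (0, 0))


class TestExtractSlope:
    def test_flat_curve_gives_zero(self):
        taus = np.geomspace(1e-7, 1e-1, 64)
        assert extract_slope(_curve(taus, np.ones(64))) == 0.0

    def test_exact_linear_decay_recovered(self):
        taus = np.geomspace(1e-7, 1e-3, 64)
        c = 250.0
        assert extract_slope(_curve(taus, 1 - c * taus)) == pytest.approx(c, rel=1e-12)

    def test_exponential_slope_converges_to_rate(self):
        gamma = 1e4
        taus = np.geomspace(1e-9, 1e-2, 256)
        curve = _curve(taus, np.exp(-gamma * taus))
        b = extract_slope(curve, ReconConfig(window_level=0.05))
        assert b == pytest.approx(gamma, rel=0.02)

    def test_too_few_points_rejected(self):
        taus = np.array([1e-3, 2e-3, 4e-3])
        with pytest.raises(ValueError, match="3 usable"):
            extract_slope(_curve(taus, np.array([0.5, 0.4, 0.3])))  # all outside window


class TestAssembleSystem:
    def test_scalar_closed_form(self):
        grid = VoxelGrid(nx=1, ny=1, nz=1, voxel_edge=8.0)
        optics = OpticalProperties()
        s = 5.0
        sens = make_toy_tensor([[s]], [1.0], grid, optics)
        slopes = SlopeVector(np.array([1.0]), [(0, 0)], np.array([3]), np.array([0.0]))
        system = assemble_system(sens, optics, slopes)
        assert system.A[0, 0] == pytest.approx(2 * optics.k0**2 * s * optics.mus_prime)

    def test_first_order_matches_tau_to_zero_derivative(self, sens_std, optics, grid):
        """A @ alphaDb equals the finite-difference tau->0 slope of the exact
        forward model, pairwise to 0.5%."""
        les = LesionSpec(center=(4.25, 4.25, 0.75), diameter=1.2, contrast=10.0)
        bfi = make_phantom(grid, 4.5e-8, [les], seed=2)
        tau0 = 1e-10
        curves = synth_g1(sens_std, bfi, optics, DelayGrid(np.array([tau0, 2 * tau0])))
        for pair, c in curves.items():
            fd = (1.0 - c.values[0]) / tau0
            row = sensitivity_row(sens_std, optics, pair)
            assert row @ bfi.values == pytest.approx(fd, rel=5e-3)

    def test_missing_pair_rejected(self, sens_small, optics):
        slopes = SlopeVector(np.array([1.0]), [(99, 99)], np.array([3]), np.array([0.0]))
        with pytest.raises(ValueError, match="missing"):
            assemble_system(sens_small, optics, slopes)


class TestHigherOrder:
    @pytest.fixture()
    def scalar_setup(self):
        grid = VoxelGrid(nx=1, ny=1, nz=1, voxel_edge=8.0)
        optics = OpticalProperties()
        sens = make_toy_tensor([[5.0]], [1.0], grid, optics)
        return grid, optics, sens

    def test_zero_estimate_gives_zero_correction(self, scalar_setup):
        grid, optics, sens = scalar_setup
        bfi = BFIMap([4.5e-8], grid)
        frame = simulate_acquisition(sens, bfi, optics, noise=NoiseConfig(0.0), seed=0)
        corr = higher_order_correct(
            frame, sens, optics, BFIMap([0.0], grid), ReconConfig(order=3)
        )
        np.testing.assert_array_equal(corr[(0, 0)], 0.0)

    def test_scalar_taylor_remainder(self, scalar_setup):
        """With the true flow as estimate, corrected data equals the Taylor
        remainder of exp(-x) truncated at order N."""
        grid, optics, sens = scalar_setup
        alpha = 4.5e-8
        bfi = BFIMap([alpha], grid)
        taus = np.geomspace(1e-7, 1e-3, 32)
        frame = simulate_acquisition(
            sens, bfi, optics, DelayGrid(taus), NoiseConfig(0.0), seed=0
        )
        N = 3
        corr = higher_order_correct(frame, sens, optics, bfi, ReconConfig(order=N))
        x = 2 * taus * optics.k0**2 * alpha * 5.0 * optics.mus_prime
        expected = sum((-x) ** k / math.factorial(k) for k in range(2, N + 1))
        np.testing.assert_allclose(corr[(0, 0)], expected, rtol=0, atol=1e-10)
        # and it linearizes the data: (1 - g1) + correction = x + O(x^4)
        small = x < 0.2
        lin = (1 - np.exp(-x)) + corr[(0, 0)]
        np.testing.assert_allclose(lin[small], x[small], rtol=1e-3)

    def test_order3_residual_not_worse_on_extended_window(self, sens_small, optics, grid):
        bfi = make_phantom(grid, 4.5e-8, [], seed=0)
        frame = simulate_acquisition(sens_small, bfi, optics, noise=NoiseConfig(0.0), seed=0)
        cfg1 = ReconConfig(order=1, window_level=0.6)
        slopes1 = _slopes_from_frame(frame, cfg1)
        cfg3 = ReconConfig(order=3, window_level=0.6)
        corr = higher_order_correct(frame, sens_small, optics, bfi, cfg3)
        slopes3 = _slopes_from_frame(frame, cfg3, corr)
        assert slopes3.residual.mean() <= slopes1.residual.mean()


class TestBregmanTV:
    def test_zero_data_gives_zero_map(self):
        grid = VoxelGrid(nx=2, ny=2, nz=1, voxel_edge=1.0)
        system = LinearSystem(np.eye(4), np.zeros(4), [(0, j) for j in range(4)], grid)
        sol, diag = solve_bregman_tv(system)
        np.testing.assert_array_equal(sol.values, 0.0)

    def test_identity_fidelity_dominated_recovery(self):
        grid = VoxelGrid(nx=2, ny=2, nz=1, voxel_edge=1.0)
        x_true = np.array([1.0, 2.0, 3.0, 4.0])
        system = LinearSystem(np.eye(4), x_true, [(0, j) for j in range(4)], grid)
        cfg = ReconConfig(mu=1e8, bregman_iters=200, inner_tol=1e-10)
        sol, _ = solve_bregman_tv(system, cfg)
        np.testing.assert_allclose(sol.values, x_true, rtol=1e-3)

    def test_matches_nnls_oracle_at_weak_tv(self):
        rng = np.random.default_rng(5)
        grid = VoxelGrid(nx=3, ny=2, nz=1, voxel_edge=1.0)
        A = rng.uniform(0.5, 2.0, (10, 6)) + 3 * np.eye(10, 6)
        x_true = rng.uniform(0.5, 2.0, 6)
        b = A @ x_true
        system = LinearSystem(A, b, [(0, j) for j in range(10)], grid)
        cfg = ReconConfig(mu=1e9, bregman_iters=300, inner_tol=1e-12)
        sol, _ = solve_bregman_tv(system, cfg)
        oracle, _ = nnls(A, b)
        np.testing.assert_allclose(sol.values, oracle, rtol=0.01)

    def test_objective_nonincreasing(self, sens_std, optics, grid):
        les = LesionSpec(center=(4.25, 4.25, 0.75), diameter=1.2, contrast=10.0)
        bfi = make_phantom(grid, 4.5e-8, [les], seed=2)
        frame = simulate_acquisition(sens_std, bfi, optics, noise=NoiseConfig(0.0), seed=0)
        slopes = _slopes_from_frame(frame, ReconConfig())
        system = assemble_system(sens_std, optics, slopes)
        _, diag = solve_bregman_tv(system, ReconConfig())
        obj = np.array(diag["objective"])
        assert np.all(np.diff(obj) <= 1e-9 * np.abs(obj[:-1]) + 1e-12)


class TestNormalize:
    def test_uniform_maps_to_ones(self):
        grid = VoxelGrid(nx=2, ny=2, nz=1, voxel_edge=1.0)
        out = normalize_rbfi(BFIMap(np.full(4, 3.7e-8), grid))
        np.testing.assert_allclose(out.values, 1.0, atol=1e-15)

    def test_hand_arithmetic(self):
        grid = VoxelGrid(nx=2, ny=1, nz=1, voxel_edge=1.0)
        out = normalize_rbfi(BFIMap(np.array([1.0, 3.0]), grid))
        np.testing.assert_allclose(out.values, [0.5, 1.5], atol=1e-15)

    def test_mean_exactly_one_for_random_maps(self):
        grid = VoxelGrid()
        rng = np.random.default_rng(1)
        for _ in range(5):
            vals = rng.lognormal(0, 1, grid.n_voxels)
            out = normalize_rbfi(BFIMap(vals, grid))
            assert out.values.mean() == pytest.approx(1.0, abs=1e-12)

    def test_zero_map_rejected(self):
        grid = VoxelGrid(nx=2, ny=1, nz=1, voxel_edge=1.0)
        with pytest.raises(ValueError, match="degenerate"):
            normalize_rbfi(BFIMap(np.zeros(2), grid))


class TestReconstruct:
    def test_homogeneous_phantom_flat_rbfi(self, sens_std, optics, grid):
        bfi = make_phantom(grid, 4.5e-8, [], seed=0)
        frame = simulate_acquisition(sens_std, bfi, optics, noise=NoiseConfig(0.0), seed=0)
        rbfi, _ = reconstruct(frame, sens_std, optics)
        assert rbfi.as_volume().shape == (6, 16, 16)
        assert np.abs(rbfi.values - 1.0).max() < 0.15

    def test_linearization_consistency_on_true_phantom(self, sens_std, optics, grid):
        les = LesionSpec(center=(4.25, 4.25, 0.75), diameter=1.2, contrast=10.0)
        bfi = make_phantom(grid, 4.5e-8, [les], seed=2)
        frame = simulate_acquisition(sens_std, bfi, optics, noise=NoiseConfig(0.0), seed=0)
        slopes = _slopes_from_frame(frame, ReconConfig())
        system = assemble_system(sens_std, optics, slopes)
        rel = np.linalg.norm(system.A @ bfi.values - system.b) / np.linalg.norm(system.b)
        assert rel <= 0.05

    def test_higher_order_mode_runs_and_stays_close(self, sens_small, optics, grid):
        bfi = make_phantom(grid, 4.5e-8, [], seed=0)
        frame = simulate_acquisition(sens_small, bfi, optics, noise=NoiseConfig(0.0), seed=0)
        rbfi, diag = reconstruct(frame, sens_small, optics, ReconConfig(order=3))
        assert len(diag["outer"]) >= 2
        assert np.abs(rbfi.values - 1.0).max() < 0.15
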