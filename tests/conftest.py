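"""Shared fixtures: Monte Carlo sensitivity tensors are expensive, so the
suite shares one small (quick checks) and one standard-resolution tensor."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from dcflow.phantom import OpticalProperties, ProbeLayout, VoxelGrid, make_probe
from dcflow.photon_mc import (
    MonteCarloConfig,
    PairSensitivity,
    SensitivityTensor,
    run_monte_carlo,
)


@pytest.fixture(scope="session")
def grid() -> VoxelGrid:
    return VoxelGrid()


@pytest.fixture(scope="session")
def optics() -> OpticalProperties:
    return OpticalProperties()


@pytest.fixture(scope="session")
def probe() -> ProbeLayout:
    return make_probe()


@pytest.fixture(scope="session")
def sens_small(grid, optics, probe) -> SensitivityTensor:
    """Quick tensor (2e4 photons/source) for structural checks."""
    return run_monte_carlo(grid, optics, probe, MonteCarloConfig(n_photons=20_000, seed=1))


@pytest.fixture(scope="session")
def sens_std(grid, optics, probe) -> SensitivityTensor:
    """Standard tensor (1e5 photons/source) for reconstruction checks."""
    return run_monte_carlo(grid, optics, probe, MonteCarloConfig(n_photons=100_000, seed=1))


def make_toy_tensor(
    path_lengths: np.ndarray,
    weights: np.ndarray,
    grid: VoxelGrid,
    optics: OpticalProperties,
) -> SensitivityTensor:
    """Hand-built single-pair tensor: one row per photon, one column per voxel."""
    probe = ProbeLayout(
        source_positions=((0.0, 0.0),),
        detector_positions=((1.0, 0.0),),
        acceptance_radius=0.25,
    )
    weights = np.asarray(weights, dtype=float)
    csr = sp.csr_matrix(np.atleast_2d(np.asarray(path_lengths, dtype=float)))
    assert csr.shape == (weights.size, grid.n_voxels)
    pair = PairSensitivity(
        weights=weights / weights.sum(),
        pathlengths=csr,
        total_weight=float(weights.sum()),
        n_detected=weights.size,
    )
    return SensitivityTensor(
        pairs={(0, 0): pair},
        grid=grid,
        optics=optics,
        probe=probe,
        n_photons=weights.size,
        seed=0,
    )
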