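"""Shared fixtures: small geometries with exactly known structure.

Heavy objects (trajectories, random cells, fields) are session-scoped; all
randomness is seeded through the generator parameters so the suite is
deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

import fptcell as fc

D_DEFAULT = 10.0  # um^2/s


@pytest.fixture(scope="session")
def corridor3():
    """Corridor of 3 cytosol voxels (h=0.1): masks, operator, shell source."""
    grid = fc.corridor_grid(3)
    masks = fc.build_masks(grid)
    op = fc.assemble_operator(masks, D_DEFAULT)
    g = fc.uniform_shell_init(masks)  # the single far-end voxel
    return grid, masks, op, g


@pytest.fixture(scope="session")
def sphere_fixture():
    """Voxelized concentric spheres (a=0.5, R=1, h=0.1), shell release."""
    grid = fc.concentric_spheres_grid(0.5, 1.0, 0.1)
    masks = fc.build_masks(grid)
    op = fc.assemble_operator(masks, D_DEFAULT)
    g = fc.uniform_shell_init(masks)
    return grid, masks, op, g


@pytest.fixture(scope="session")
def sphere_fpt(sphere_fixture):
    """Hybrid first-passage density on the sphere fixture (with eigen tail)."""
    _, _, op, g = sphere_fixture
    traj = fc.hybrid_trajectory(
        op, g, t_end=2.0, switch_window=(0.25, 2.0), cutoff=200.0
    )
    assert traj.t_switch is not None
    return fc.fpt_density(traj, op)


@pytest.fixture(scope="session")
def corridor3_fpt(corridor3):
    """Integrator-only first-passage density on corridor(3)."""
    _, _, op, g = corridor3
    traj = fc.evolve_density(op, g, t_end=0.2)
    return fc.fpt_density(traj, op)


@pytest.fixture(scope="session")
def random_cell_pair():
    """Seeded random cell: physiological and no-organelles masks/operators."""
    grid = fc.random_cell(fc.SyntheticCellParams())
    phys = fc.build_masks(grid, "physiological")
    empty = fc.build_masks(grid, "no_organelles")
    return {
        "grid": grid,
        "phys": (phys, fc.assemble_operator(phys, D_DEFAULT)),
        "empty": (empty, fc.assemble_operator(empty, D_DEFAULT)),
    }


def shell_support_mask(masks):
    """Full-grid boolean support of the uniform shell release."""
    return masks.shell


def support_of(masks, g):
    return masks.to_volume(g.support.astype(float)) > 0


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
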