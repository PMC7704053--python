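"""Synthetic segmented cell volumes with the structure of SXT reconstructions.

Soft X-ray tomography of lymphocytes yields a cubic-voxel label field with a
closed nucleus, a connected cytosol, organelle occlusions filling a sizeable
fraction of the cytosolic space, and a thin shell of cytosol against the cell
membrane.  The generators here emulate exactly that structure, so every
downstream stage (operator assembly, first-passage statistics, asymptotics)
is testable without any imaging data:

* :func:`concentric_spheres_grid` — the idealized nucleus-in-cell geometry
  used for continuum comparisons;
* :func:`corridor_grid` — a minimal 1D channel with a known graph distance to
  the nucleus, for exact hand-checkable oracles;
* :func:`random_cell` — a seeded ellipsoidal cell with random ellipsoidal
  organelle blobs at a target volume fraction, rejecting any blob that would
  disconnect the cytosol from the nucleus.

Default scale: the generator emulates a shrunken lymphocyte at roughly 64^3
voxels (h = 0.05 um), coarser than real SXT voxels (0.03515625 um); h is
always a parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import LabelGrid, _face_neighbor_count, _flood_fill

__all__ = [
    "SyntheticCellParams",
    "concentric_spheres_grid",
    "corridor_grid",
    "random_cell",
]

#: label values shared by all generators
LABELS = {0: "exterior", 1: "cytosol", 2: "nucleus"}


def concentric_spheres_grid(r_nuc: float, r_cell: float, h: float) -> LabelGrid:
    """Concentric-spheres cell: nucleus of radius ``r_nuc`` inside a cell of
    radius ``r_cell``, no organelles.

    Every voxel is classified by its centre's distance from the common
    centre: nucleus within ``r_nuc``, cytosol within ``r_cell``, exterior
    beyond.  Requires ``h < (r_cell - r_nuc)/2`` so the cytosol shell is at
    least two voxels thick.
    """
    if not 0 < r_nuc < r_cell:
        raise ValueError(f"need 0 < r_nuc < r_cell, got {r_nuc}, {r_cell}")
    if not h < (r_cell - r_nuc) / 2:
        raise ValueError(
            f"h={h} too coarse for the shell thickness {(r_cell - r_nuc)}"
        )
    n = 2 * math.ceil(r_cell / h) + 3
    c = n * h / 2.0
    x = (np.arange(n) + 0.5) * h - c
    r = np.sqrt(
        x[:, None, None] ** 2 + x[None, :, None] ** 2 + x[None, None, :] ** 2
    )
    labels = np.zeros((n, n, n), np.int32)
    labels[r < r_cell] = 1
    labels[r < r_nuc] = 2
    return LabelGrid(labels=labels, h=h, label_map=dict(LABELS))


def corridor_grid(length: int, h: float = 0.1) -> LabelGrid:
    """A straight corridor of ``length`` cytosol voxels capped by a nucleus.

    Voxel ``(0,1,1)`` is the nucleus; ``(1..L,1,1)`` are cytosol; the plane
    past the far end is exterior (so the far voxel is the whole membrane
    shell); everything else is a reflecting organelle wall.  By construction
    the graph distance from the far-end voxel to the nucleus is exactly L,
    and the diffusion operator is tridiagonal of size L.
    """
    if length < 1:
        raise ValueError("corridor length must be >= 1")
    nx = length + 2
    labels = np.full((nx, 3, 3), 3, np.int32)  # wall
    labels[-1, :, :] = 0  # exterior cap past the far end
    labels[0, 1, 1] = 2  # nucleus
    labels[1 : length + 1, 1, 1] = 1  # cytosol line
    label_map = dict(LABELS)
    label_map[3] = "wall"
    return LabelGrid(labels=labels, h=h, label_map=label_map)


@dataclass
class SyntheticCellParams:
    """Parameters of :func:`random_cell` (lengths in micrometres).

    Defaults give a shrunken-lymphocyte test cell on a ~64^3 grid: an
    ellipsoidal cell of semi-axes ~1.5 um with an offset ellipsoidal nucleus,
    organelle blobs occluding 30% of the cytosolic candidate space (the ER is
    the dominant barrier in real reconstructions), and h = 0.05 um.
    """

    cell_semi_axes: tuple[float, float, float] = (1.5, 1.3, 1.2)
    nucleus_semi_axes: tuple[float, float, float] = (0.75, 0.65, 0.6)
    nucleus_offset: tuple[float, float, float] = (0.25, 0.1, 0.0)
    organelle_fraction: float = 0.3
    blob_semi_axis_range: tuple[float, float] = (0.08, 0.3)
    max_blob_attempts: int = 2000
    h: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.organelle_fraction < 1:
            raise ValueError("organelle_fraction must be in [0, 1)")
        if self.h <= 0:
            raise ValueError("h must be positive")
        for ax, (c, n, o) in enumerate(
            zip(self.cell_semi_axes, self.nucleus_semi_axes, self.nucleus_offset)
        ):
            if n + abs(o) >= c:
                raise ValueError(
                    f"nucleus not strictly inside the cell along axis {ax}"
                )


def _ellipsoid_mask(
    x: np.ndarray, center: np.ndarray, semi: np.ndarray
) -> np.ndarray:
    """Voxels whose centres lie inside an axis-aligned ellipsoid."""
    q = np.zeros((len(x[0]), len(x[1]), len(x[2])))
    for axis in range(3):
        shape = [1, 1, 1]
        shape[axis] = -1
        q = q + (((x[axis] - center[axis]) / semi[axis]) ** 2).reshape(shape)
    return q < 1.0


def random_cell(params: SyntheticCellParams) -> LabelGrid:
    """Seeded random cell: ellipsoidal membrane + nucleus + organelle blobs.

    Blobs (random axis-aligned ellipsoids) are placed by rejection sampling:
    a blob is discarded if it overlaps the nucleus or if, after carving it
    out, any remaining cytosol voxel would no longer be 6-connected to a
    nucleus-adjacent voxel.  Placement stops once the achieved organelle
    volume fraction (organelle voxels / cytosol-candidate voxels) is within
    ±20% relative of the target; running out of attempts first is an error.
    Identical parameters (including seed) give bit-identical volumes.
    """
    rng = np.random.default_rng(params.seed)
    h = params.h
    semi_c = np.asarray(params.cell_semi_axes)
    semi_n = np.asarray(params.nucleus_semi_axes)
    off = np.asarray(params.nucleus_offset)

    dims = tuple(2 * math.ceil(a / h) + 3 for a in semi_c)
    center = np.array([d * h / 2.0 for d in dims])
    x = tuple((np.arange(d) + 0.5) * h for d in dims)

    cell = _ellipsoid_mask(x, center, semi_c)
    nucleus = _ellipsoid_mask(x, center + off, semi_n)
    candidates = cell & ~nucleus  # cytosolic candidate space
    n_candidates = int(candidates.sum())

    labels = np.zeros(dims, np.int32)
    labels[candidates] = 1
    labels[nucleus] = 2

    target = params.organelle_fraction
    organelle = np.zeros(dims, bool)
    if target > 0:
        cytosol = candidates.copy()
        lo, hi = params.blob_semi_axis_range
        achieved = 0.0
        for _ in range(params.max_blob_attempts):
            if achieved >= 0.95 * target:
                break
            # sample a blob centre on a cytosol voxel and random semi-axes
            flat = np.flatnonzero(cytosol.ravel())
            pick = flat[rng.integers(len(flat))]
            cijk = np.unravel_index(pick, dims)
            bc = (np.asarray(cijk) + 0.5) * h
            semi_b = rng.uniform(lo, hi, size=3)
            blob = _ellipsoid_mask(x, bc, semi_b) & cytosol
            if not blob.any() or (blob & nucleus).any():
                continue
            if achieved + blob.sum() / n_candidates > 1.15 * target:
                continue  # would overshoot the tolerance band
            trial = cytosol & ~blob
            adj = _face_neighbor_count(trial, nucleus) > 0
            if not adj.any():
                continue
            if _flood_fill(trial, adj).sum() != trial.sum():
                continue  # blob would strand part of the cytosol
            cytosol = trial
            organelle |= blob
            achieved = organelle.sum() / n_candidates
        achieved = organelle.sum() / n_candidates
        if abs(achieved - target) > 0.2 * target:
            raise RuntimeError(
                f"could not reach organelle fraction {target}: achieved "
                f"{achieved:.3f} after {params.max_blob_attempts} attempts"
            )
        labels[organelle] = 3

    label_map = dict(LABELS)
    label_map[3] = "organelle"
    return LabelGrid(labels=labels, h=h, label_map=label_map)
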