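"""Segmented label volumes and the voxel sets the diffusion model lives on.

A single cell is represented as a 3D Cartesian grid of cubic voxels of edge
``h`` (micrometres), each carrying an integer label that maps to a named
class: the exterior of the cell, free cytosol, components of the nucleus
(e.g. heterochromatin / euchromatin), or a cytosolic organelle (ER,
mitochondria, Golgi, ...).  The diffusion model is posed on the cytosol
voxels ``C_h``; nucleus voxels ``N_h`` absorb, and organelle voxels ``O_h``
and the exterior reflect (they simply carry no coupling).

Conventions
-----------
* voxel ``(i, j, k)`` (0-based) has its centre at ``((i+1/2)h, (j+1/2)h,
  (k+1/2)h)``;
* adjacency is 6-neighbor (shared faces) everywhere — the same stencil the
  discrete Laplacian uses;
* flat voxel ordering is x-fastest (Fortran order of the ``(nx, ny, nz)``
  label array); all file I/O documents this ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LabelGrid",
    "GeometryMasks",
    "InitialDensity",
    "VARIANTS",
    "load_label_volume",
    "save_label_volume",
    "build_masks",
    "membrane_shell",
    "uniform_shell_init",
    "patch_init",
    "point_init",
]

#: geometry variants: physiological keeps every organelle as a barrier,
#: no_ER opens the endoplasmic reticulum to diffusion, no_organelles opens all
#: organelles (empty cytosol between the two membranes).
VARIANTS = ("physiological", "no_ER", "no_organelles")

#: class names recognized as components of the nucleus.  The model's nucleus
#: N_h is the union of all of them.
NUCLEUS_CLASSES = frozenset(
    {"nucleus", "heterochromatin", "euchromatin", "nucleolus"}
)

#: class names recognized as the endoplasmic reticulum (for the no_ER variant).
ER_CLASSES = frozenset({"ER", "er", "endoplasmic reticulum"})

_KINDS = ("exterior", "cytosol", "nucleus", "organelle")


def class_kind(name: str) -> str:
    """Map a class name to one of exterior / cytosol / nucleus / organelle."""
    if name == "exterior":
        return "exterior"
    if name == "cytosol":
        return "cytosol"
    if name in NUCLEUS_CLASSES:
        return "nucleus"
    return "organelle"


@dataclass
class LabelGrid:
    """A raw segmented volume: integer label per voxel + voxel edge length.

    Parameters
    ----------
    labels : ndarray of int, shape (nx, ny, nz)
        Integer label per voxel, indexed ``labels[i, j, k]``.
    h : float
        Voxel edge length in micrometres (cubic voxels only).
    label_map : dict[int, str]
        Maps every integer occurring in ``labels`` to a class name.
    """

    labels: np.ndarray
    h: float
    label_map: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not self.h > 0:
            raise ValueError(f"voxel edge length must be positive, got {self.h}")
        present = set(np.unique(self.labels).tolist())
        missing = sorted(present - set(self.label_map))
        if missing:
            raise ValueError(
                f"labels absent from label_map: {missing}"
            )

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    def kind_masks(self) -> dict[str, np.ndarray]:
        """Boolean mask per kind (exterior / cytosol / nucleus / organelle)."""
        masks = {k: np.zeros(self.labels.shape, bool) for k in _KINDS}
        for value, name in self.label_map.items():
            masks[class_kind(name)] |= self.labels == value
        return masks

    def centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinate arrays (x, y, z), each 1D, in um."""
        return tuple(
            (np.arange(n) + 0.5) * self.h for n in self.labels.shape
        )  # type: ignore[return-value]


def _face_neighbor_count(of: np.ndarray, among: np.ndarray) -> np.ndarray:
    """Per-voxel count of 6-neighbors of ``of`` voxels that lie in ``among``.

    Returns an int array over the whole grid (zero outside ``of``).
    """
    cnt = np.zeros(of.shape, np.int64)
    for axis in range(3):
        for dirn in (1, -1):
            shifted = np.zeros_like(among)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if dirn == 1:
                src[axis] = slice(1, None)
                dst[axis] = slice(None, -1)
            else:
                src[axis] = slice(None, -1)
                dst[axis] = slice(1, None)
            shifted[tuple(dst)] = among[tuple(src)]
            cnt += shifted
    cnt[~of] = 0
    return cnt


def _flood_fill(allowed: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """6-connected flood fill of ``allowed`` starting from ``seeds``."""
    reached = seeds & allowed
    while True:
        grown = reached | (
            (_face_neighbor_count(allowed, reached) > 0) & allowed
        )
        if grown.sum() == reached.sum():
            return reached
        reached = grown


@dataclass
class GeometryMasks:
    """Classified voxel sets for one geometry variant.

    ``cytosol``, ``nucleus``, ``organelle`` and ``exterior`` partition the
    grid.  ``shell`` is the membrane shell: cytosol voxels with at least one
    exterior 6-neighbor (the model's stand-in for the inner surface of the
    cell membrane).  ``connected`` flags the cytosol voxels 6-connected to a
    nucleus-adjacent voxel — MFPTs are finite exactly there.
    """

    grid: LabelGrid
    variant: str
    cytosol: np.ndarray
    nucleus: np.ndarray
    organelle: np.ndarray
    exterior: np.ndarray
    shell: np.ndarray = field(default=None)  # type: ignore[assignment]
    connected: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def h(self) -> float:
        return self.grid.h

    @property
    def n_cytosol(self) -> int:
        return int(self.cytosol.sum())

    # -- canonical cytosol vector ordering (x-fastest) ---------------------
    def cytosol_order(self) -> np.ndarray:
        """Flat (Fortran-order) indices of cytosol voxels, x-fastest."""
        return np.flatnonzero(self.cytosol.ravel(order="F"))

    def to_vector(self, vol: np.ndarray) -> np.ndarray:
        """Restrict a full-grid array to the cytosol vector ordering."""
        return vol.ravel(order="F")[self.cytosol_order()]

    def to_volume(self, vec: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a cytosol vector back onto the full grid."""
        flat = np.full(self.cytosol.size, fill, dtype=float)
        flat[self.cytosol_order()] = vec
        return flat.reshape(self.cytosol.shape, order="F")

    def summary(self) -> dict:
        return {
            "variant": self.variant,
            "h_um": self.h,
            "dims": list(self.grid.dims),
            "counts": {
                "cytosol": int(self.cytosol.sum()),
                "nucleus": int(self.nucleus.sum()),
                "organelle": int(self.organelle.sum()),
                "exterior": int(self.exterior.sum()),
                "shell": int(self.shell.sum()) if self.shell is not None else None,
            },
        }


@dataclass
class InitialDensity:
    """Initial probability density g_h over cytosol voxels, in um^-3.

    ``values`` follows the masks' cytosol vector ordering; ``support`` is the
    boolean mask (same ordering) of voxels where g_h != 0.  The density
    integrates to one: sum(values) * h^3 = 1.
    """

    values: np.ndarray
    support: np.ndarray
    h: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if np.any(self.values < 0):
            raise ValueError("initial density must be nonnegative")
        if np.any(self.values[~self.support] != 0):
            raise ValueError("initial density must vanish outside its support")
        total = self.values.sum() * self.h**3
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"initial density integrates to {total}, not 1")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_SIDECAR_SUFFIX = ".labels.json"


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + _SIDECAR_SUFFIX)


def save_label_volume(grid: LabelGrid, path: str | Path) -> None:
    """Write a label volume (NRRD/MetaImage via SimpleITK, or .raw + JSON).

    The label map (and, for raw output, dims/h/dtype/ordering) goes to a JSON
    sidecar next to the volume.  Raw output is x-fastest.
    """
    path = Path(path)
    meta = {
        "dims": list(grid.dims),
        "h_um": grid.h,
        "order": "x-fastest",
        "label_map": {str(k): v for k, v in grid.label_map.items()},
    }
    if path.suffix == ".raw":
        arr = np.ascontiguousarray(grid.labels.astype(np.int32))
        meta["dtype"] = "int32"
        path.write_bytes(arr.ravel(order="F").tobytes())
    else:
        import SimpleITK as sitk

        # SimpleITK array axis order is (z, y, x); transpose so that the
        # image's x axis is our first index.
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(grid.labels.astype(np.int32).transpose(2, 1, 0))
        )
        img.SetSpacing((grid.h, grid.h, grid.h))
        sitk.WriteImage(img, str(path))
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def load_label_volume(
    path: str | Path, label_map: dict[int, str] | None = None
) -> LabelGrid:
    """Read a label volume written by :func:`save_label_volume`.

    ``label_map`` overrides the sidecar's map when given.  Anisotropic voxel
    spacing is rejected: the model is defined on cubic voxels only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if label_map is None:
        if "label_map" not in meta:
            raise ValueError(f"no label map given and no sidecar at {sidecar}")
        label_map = {int(k): v for k, v in meta["label_map"].items()}

    if path.suffix == ".raw":
        dims = tuple(meta["dims"])
        labels = np.frombuffer(
            path.read_bytes(), dtype=meta.get("dtype", "int32")
        ).reshape(dims, order="F")
        h = float(meta["h_um"])
    else:
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        sx, sy, sz = img.GetSpacing()
        if not (abs(sx - sy) < 1e-9 * sx and abs(sx - sz) < 1e-9 * sx):
            raise ValueError(
                f"anisotropic voxels {(sx, sy, sz)}: cubic voxels required"
            )
        h = float(sx)
        labels = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return LabelGrid(labels=np.asarray(labels), h=h, label_map=label_map)


# ---------------------------------------------------------------------------
# mask construction
# ---------------------------------------------------------------------------


def build_masks(grid: LabelGrid, variant: str = "physiological") -> GeometryMasks:
    """Classify a label grid into the voxel sets of one geometry variant.

    ``no_ER`` moves ER-labeled voxels into the cytosol; ``no_organelles``
    moves every organelle voxel into the cytosol.  The membrane shell and the
    nucleus-connected component are computed as part of the result.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; one of {VARIANTS}")
    kinds = grid.kind_masks()
    cytosol = kinds["cytosol"].copy()
    organelle = kinds["organelle"].copy()
    nucleus = kinds["nucleus"]
    exterior = kinds["exterior"]

    if variant == "no_ER":
        er = np.zeros(grid.labels.shape, bool)
        for value, name in grid.label_map.items():
            if name in ER_CLASSES:
                er |= grid.labels == value
        cytosol |= er
        organelle &= ~er
    elif variant == "no_organelles":
        cytosol |= organelle
        organelle = np.zeros_like(organelle)

    if not nucleus.any():
        raise ValueError("empty nucleus")
    if not cytosol.any():
        raise ValueError("empty cytosol")
    if (_face_neighbor_count(nucleus, exterior) > 0).any():
        raise ValueError(
            "nucleus voxels touch the exterior; segmentation is inconsistent"
        )

    nucleus_adjacent = _face_neighbor_count(cytosol, nucleus) > 0
    if not nucleus_adjacent.any():
        raise ValueError("nucleus unreachable: no cytosol voxel borders it")
    connected = _flood_fill(cytosol, nucleus_adjacent)

    masks = GeometryMasks(
        grid=grid,
        variant=variant,
        cytosol=cytosol,
        nucleus=nucleus,
        organelle=organelle,
        exterior=exterior,
        connected=connected,
    )
    masks.shell = membrane_shell(masks)
    return masks


def membrane_shell(masks: GeometryMasks) -> np.ndarray:
    """Cytosol voxels bordering the exterior of the cell (boolean mask)."""
    shell = _face_neighbor_count(masks.cytosol, masks.exterior) > 0
    if not shell.any():
        raise ValueError("empty membrane shell: the cell touches no exterior")
    return shell


# ---------------------------------------------------------------------------
# initial conditions (membrane release)
# ---------------------------------------------------------------------------


def uniform_shell_init(masks: GeometryMasks) -> InitialDensity:
    """Uniform density over the membrane shell: g = 1/|shell volume| on it.

    This is the model of a molecule activated at a uniformly random point of
    the inner cell membrane.
    """
    shell_vec = masks.to_vector(masks.shell).astype(bool)
    k = int(shell_vec.sum())
    if k == 0:
        raise ValueError("empty membrane shell")
    values = np.where(shell_vec, 1.0 / (k * masks.h**3), 0.0)
    return InitialDensity(values=values, support=shell_vec, h=masks.h)


def patch_init(
    masks: GeometryMasks, center: tuple[int, int, int], radius: float
) -> InitialDensity:
    """Uniform density over the shell voxels within ``radius`` um of ``center``.

    Models activation localized to a small patch of the cell membrane;
    ``center`` must itself be a shell voxel.
    """
    if not masks.shell[center]:
        raise ValueError(f"patch center {center} is not a membrane-shell voxel")
    h = masks.h
    idx = np.argwhere(masks.shell)
    dist = np.sqrt((((idx - np.asarray(center)) * h) ** 2).sum(axis=1))
    chosen = idx[dist <= radius]
    if len(chosen) == 0:
        raise ValueError(f"no shell voxel within {radius} um of {center}")
    support_vol = np.zeros(masks.cytosol.shape, bool)
    support_vol[tuple(chosen.T)] = True
    support = masks.to_vector(support_vol).astype(bool)
    values = np.where(support, 1.0 / (support.sum() * h**3), 0.0)
    return InitialDensity(values=values, support=support, h=h)


def point_init(masks: GeometryMasks, voxel: tuple[int, int, int]) -> InitialDensity:
    """Point source: all mass in one cytosol voxel (density 1/h^3)."""
    if not masks.cytosol[voxel]:
        raise ValueError(f"{voxel} is not a cytosol voxel")
    vol = np.zeros(masks.cytosol.shape, bool)
    vol[voxel] = True
    support = masks.to_vector(vol).astype(bool)
    values = np.where(support, 1.0 / masks.h**3, 0.0)
    return InitialDensity(values=values, support=support, h=masks.h)
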