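"""Geometry layer: classification, variants, shells, initial densities."""

import numpy as np
import pytest

import fptcell as fc
from fptcell.geometry import class_kind


def cube_grid(n=3, h=0.1, fill="cytosol"):
    label_map = {0: "exterior", 1: "cytosol", 2: "nucleus", 3: "ER",
                 4: "mitochondria"}
    labels = np.zeros((n, n, n), np.int32)
    if fill == "cytosol":
        labels[:] = 1
    return fc.LabelGrid(labels=labels, h=h, label_map=label_map)


class TestLabelGrid:
    def test_unknown_labels_rejected_by_name(self):
        with pytest.raises(ValueError, match=r"\[7\]"):
            fc.LabelGrid(
                labels=np.full((2, 2, 2), 7, np.int32),
                h=0.1,
                label_map={0: "exterior"},
            )

    def test_nonpositive_voxel_edge_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cube_grid(h=0.0)

    def test_class_kinds(self):
        assert class_kind("heterochromatin") == "nucleus"
        assert class_kind("euchromatin") == "nucleus"
        assert class_kind("Golgi") == "organelle"
        assert class_kind("cytosol") == "cytosol"


class TestBuildMasks:
    def test_all_exterior_has_empty_nucleus(self):
        grid = fc.LabelGrid(
            labels=np.zeros((3, 3, 3), np.int32), h=0.1,
            label_map={0: "exterior"},
        )
        with pytest.raises(ValueError, match="empty nucleus"):
            fc.build_masks(grid)

    def test_partition_covers_grid_for_every_variant(self, random_cell_pair):
        grid = random_cell_pair["grid"]
        for variant in fc.geometry.VARIANTS:
            m = fc.build_masks(grid, variant)
            total = (
                m.cytosol.sum() + m.nucleus.sum() + m.organelle.sum()
                + m.exterior.sum()
            )
            assert total == np.prod(grid.dims)
            overlap = (
                m.cytosol.astype(int) + m.nucleus + m.organelle + m.exterior
            )
            assert overlap.max() == 1

    def test_variant_monotonicity(self, random_cell_pair):
        grid = random_cell_pair["grid"]
        phys = fc.build_masks(grid, "physiological")
        no_er = fc.build_masks(grid, "no_ER")
        empty = fc.build_masks(grid, "no_organelles")
        assert np.all(phys.cytosol <= no_er.cytosol)
        assert np.all(no_er.cytosol <= empty.cytosol)
        assert not empty.organelle.any()
        # opened voxels are exactly the physiological organelles
        assert np.array_equal(
            empty.cytosol, phys.cytosol | phys.organelle
        )

    def test_no_er_opens_blocked_corridor(self):
        # corridor whose third cytosol slot is ER: physiological strands the
        # far voxel; no_ER reconnects it
        labels = np.full((6, 3, 3), 5, np.int32)  # wall
        labels[-1, :, :] = 0
        labels[0, 1, 1] = 2
        labels[1, 1, 1] = labels[2, 1, 1] = labels[4, 1, 1] = 1
        labels[3, 1, 1] = 3  # ER plug
        grid = fc.LabelGrid(labels=labels, h=0.1, label_map={
            0: "exterior", 1: "cytosol", 2: "nucleus", 3: "ER", 5: "wall"})
        phys = fc.build_masks(grid, "physiological")
        assert not phys.connected[4, 1, 1]
        no_er = fc.build_masks(grid, "no_ER")
        assert no_er.cytosol[3, 1, 1]
        assert no_er.connected[4, 1, 1]
        assert no_er.organelle[1, 0, 1]  # walls stay closed

    def test_corridor_masks_counts(self, corridor3):
        _, masks, _, _ = corridor3
        assert masks.n_cytosol == 3
        assert int(masks.nucleus.sum()) == 1
        assert np.array_equal(masks.connected, masks.cytosol)

    def test_idempotent_on_variant_applied_grid(self, random_cell_pair):
        # relabel the no-organelles masks as a plain grid; rebuilding with
        # the same variant must change nothing
        grid = random_cell_pair["grid"]
        empty = fc.build_masks(grid, "no_organelles")
        relabeled = fc.LabelGrid(
            labels=np.where(empty.cytosol, 1, grid.labels), h=grid.h,
            label_map=grid.label_map,
        )
        again = fc.build_masks(relabeled, "no_organelles")
        assert np.array_equal(again.cytosol, empty.cytosol)
        assert np.array_equal(again.shell, empty.shell)


class TestMembraneShell:
    def test_corridor_shell_is_far_voxel(self, corridor3):
        _, masks, _, _ = corridor3
        assert int(masks.shell.sum()) == 1
        assert masks.shell[3, 1, 1]

    def test_solid_cube_shell_is_all_26_surface_voxels(self):
        # 3x3x3 cube (nucleus at the centre, cytosol around it) floating in
        # exterior: the shell is all 26 surface voxels
        labels = np.zeros((5, 5, 5), np.int32)
        labels[1:4, 1:4, 1:4] = 1
        labels[2, 2, 2] = 2
        grid = fc.LabelGrid(labels=labels, h=0.1, label_map={
            0: "exterior", 1: "cytosol", 2: "nucleus"})
        masks = fc.build_masks(grid)
        assert int(masks.shell.sum()) == 26
        # brute-force adjacency enumeration agrees voxel by voxel
        expected = np.zeros_like(masks.cytosol)
        for i, j, k in np.argwhere(masks.cytosol):
            for d in ((1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)):
                if masks.exterior[i + d[0], j + d[1], k + d[2]]:
                    expected[i, j, k] = True
        assert np.array_equal(masks.shell, expected)

    def test_sphere_shell_definition(self, sphere_fixture):
        _, masks, _, _ = sphere_fixture
        from fptcell.geometry import _face_neighbor_count

        has_ext = _face_neighbor_count(masks.cytosol, masks.exterior) > 0
        assert np.array_equal(masks.shell, has_ext)


class TestInitialDensities:
    def test_uniform_shell_value_and_mass(self, sphere_fixture):
        _, masks, _, _ = sphere_fixture
        g = fc.uniform_shell_init(masks)
        k = int(masks.shell.sum())
        h3 = masks.h**3
        assert np.allclose(g.values[g.support], 1.0 / (k * h3))
        assert abs(g.values.sum() * h3 - 1.0) < 1e-12

    def test_single_voxel_shell_density(self, corridor3):
        _, masks, _, _ = corridor3
        g = fc.uniform_shell_init(masks)
        assert g.values.max() == pytest.approx(1.0 / 0.1**3)

    def test_patch_point_limit_and_full_limit(self, sphere_fixture):
        _, masks, _, _ = sphere_fixture
        center = tuple(np.argwhere(masks.shell)[0])
        tiny = fc.patch_init(masks, center, radius=0.01)
        assert int(tiny.support.sum()) == 1
        assert tiny.values.max() == pytest.approx(1.0 / masks.h**3)
        big = fc.patch_init(masks, center, radius=1e6)
        full = fc.uniform_shell_init(masks)
        assert np.allclose(big.values, full.values)

    def test_patch_support_matches_bruteforce_distance_filter(
        self, sphere_fixture
    ):
        _, masks, _, _ = sphere_fixture
        idx = np.argwhere(masks.shell)
        center = tuple(idx[len(idx) // 2])
        radius = 0.35
        g = fc.patch_init(masks, center, radius)
        support_vol = masks.to_volume(g.support.astype(float)) > 0
        expect = np.zeros_like(masks.shell)
        for v in idx:
            if np.linalg.norm((v - np.asarray(center)) * masks.h) <= radius:
                expect[tuple(v)] = True
        assert np.array_equal(support_vol, expect)

    def test_patch_center_must_be_on_shell(self, sphere_fixture):
        _, masks, _, _ = sphere_fixture
        interior = tuple(np.argwhere(masks.cytosol & ~masks.shell)[0])
        with pytest.raises(ValueError, match="shell"):
            fc.patch_init(masks, interior, 0.5)


class TestVolumeIO:
    @pytest.mark.parametrize("suffix", [".nrrd", ".mha", ".raw"])
    def test_round_trip(self, tmp_path, suffix, corridor3):
        grid, _, _, _ = corridor3
        path = tmp_path / f"vol{suffix}"
        fc.save_label_volume(grid, path)
        back = fc.load_label_volume(path)
        assert back.h == pytest.approx(grid.h)
        assert np.array_equal(back.labels, grid.labels)
        assert back.label_map == grid.label_map

    def test_sxt_scale_voxel_edge_preserved(self, tmp_path):
        grid = fc.corridor_grid(2, h=0.03515625)
        path = tmp_path / "sxt.nrrd"
        fc.save_label_volume(grid, path)
        assert fc.load_label_volume(path).h == 0.03515625

    def test_anisotropic_rejected(self, tmp_path):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.zeros((3, 3, 3), np.int32))
        img.SetSpacing((0.1, 0.1, 0.2))
        sitk.WriteImage(img, str(tmp_path / "aniso.nrrd"))
        with pytest.raises(ValueError, match="cubic"):
            fc.load_label_volume(
                tmp_path / "aniso.nrrd", label_map={0: "exterior"}
            )

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            fc.load_label_volume("no/such/file.nrrd")
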