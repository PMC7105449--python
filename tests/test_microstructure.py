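"""Lamella stacks, bundle layouts, and voxelization contracts."""

import numpy as np
import pytest

from afcomp.microstructure import (LamellaSpec, SpecimenSpec, build_ply_stack,
                                   build_specimen, build_voxel_model,
                                   fiber_volume_fraction, inplane_fiber_dir,
                                   write_vtk)


class TestFiberVolumeFraction:
    def test_hand_value(self):
        vf = fiber_volume_fraction(LamellaSpec())
        assert vf == pytest.approx(np.pi * 0.06**2 / (0.22 * 0.2), rel=1e-12)
        assert vf == pytest.approx(0.257, abs=5e-4)

    def test_zero_radius(self):
        assert fiber_volume_fraction(LamellaSpec(bundle_radius=0.0)) == 0.0

    def test_doubling_spacing_halves_fraction(self):
        a = fiber_volume_fraction(LamellaSpec(spacing=0.22))
        b = fiber_volume_fraction(LamellaSpec(spacing=0.44))
        assert a == pytest.approx(2 * b, rel=1e-12)

    def test_edge_spacing_convention(self):
        lam = LamellaSpec(spacing=0.22, spacing_convention="edge")
        assert lam.center_spacing == pytest.approx(0.34)
        assert fiber_volume_fraction(lam) < fiber_volume_fraction(LamellaSpec())


class TestSpecValidation:
    def test_overlapping_bundles_rejected(self):
        with pytest.raises(ValueError):
            LamellaSpec(bundle_radius=0.15, spacing=0.22)

    def test_bad_specimen_rejected(self):
        with pytest.raises(ValueError):
            SpecimenSpec(length=-1.0)
        with pytest.raises(ValueError):
            SpecimenSpec(n_lamellae=0)
        with pytest.raises(ValueError):
            SpecimenSpec(model_family="OTHER")


class TestPlyStack:
    def test_alternating_signs(self):
        stack = build_ply_stack(SpecimenSpec(n_lamellae=5), LamellaSpec())
        signs = [np.sign(p.angle_to_transverse) for p in stack.plies]
        assert signs == [1, -1, 1, -1, 1]

    def test_hom_single_lamella_has_two_families(self):
        spec = SpecimenSpec(n_lamellae=1, model_family="HOM")
        stack = build_specimen(spec, LamellaSpec())   # resolution=None path
        assert len(stack.plies) == 1
        assert len(stack.plies[0].fiber_dirs) == 2

    def test_axial_orientation_uses_complementary_angle(self):
        d_circ = inplane_fiber_dir(30.0, "circumferential")
        d_ax = inplane_fiber_dir(30.0, "axial")
        # 30 deg from x when loading circumferentially; 60 deg when axial
        assert np.degrees(np.arccos(d_circ[0])) == pytest.approx(30.0)
        assert np.degrees(np.arccos(d_ax[0])) == pytest.approx(60.0)


class TestVoxelization:
    def test_fine_voxelization_fraction_within_ten_percent(self):
        # separate-volume map of a 10 x 2.5 x 0.6 mm specimen at 0.05 mm
        spec = SpecimenSpec(length=10.0, width=2.5, n_lamellae=3)
        vm = build_voxel_model(spec, LamellaSpec(), 0.05)
        target = fiber_volume_fraction(LamellaSpec())
        assert abs(vm.labeled_fiber_fraction() - target) / target < 0.10
        # partial-volume weights are exact up to sub-sampling error
        assert abs(vm.weighted_fiber_fraction() - target) / target < 0.03

    def test_weighted_fraction_accurate_even_at_coarse_resolution(self):
        spec = SpecimenSpec(length=4.0, width=2.0, n_lamellae=3)
        target = fiber_volume_fraction(LamellaSpec())
        for res in (0.2, 0.1):
            vm = build_voxel_model(spec, LamellaSpec(), res)
            assert abs(vm.weighted_fiber_fraction() - target) / target < 0.05

    def test_consecutive_lamellae_have_opposite_angles(self):
        vm = build_voxel_model(SpecimenSpec(length=1, width=1, n_lamellae=4),
                               LamellaSpec(), 0.2)
        xs = vm.fiber_dirs[:, 0, 1]   # y-component alternates with the angle
        assert np.all(np.sign(xs[:-1]) == -np.sign(xs[1:]))

    def test_hom_model_carries_no_bundle_weights(self):
        vm = build_voxel_model(
            SpecimenSpec(length=1, width=1, model_family="HOM"),
            LamellaSpec(), 0.2)
        assert vm.bundle_weight.max() == 0.0
        assert vm.fiber_dirs.shape[1] == 2

    def test_anisotropic_voxels_preserve_fraction(self):
        spec = SpecimenSpec(length=2, width=1, n_lamellae=2)
        target = fiber_volume_fraction(LamellaSpec())
        vm = build_voxel_model(spec, LamellaSpec(), (0.2, 0.2, 0.1))
        assert vm.shape[2] == 4
        assert abs(vm.weighted_fiber_fraction() - target) / target < 0.05

    def test_resolution_coarser_than_lamella_rejected(self):
        with pytest.raises(ValueError):
            build_voxel_model(SpecimenSpec(), LamellaSpec(), 0.3)

    def test_vtk_export(self, tmp_path):
        vm = build_voxel_model(SpecimenSpec(length=1, width=1), LamellaSpec(),
                               0.2)
        path = tmp_path / "model.vtk"
        write_vtk(vm, path)
        text = path.read_text().splitlines()
        assert text[0].startswith("# vtk DataFile")
        assert any(line.startswith("DIMENSIONS") for line in text)
        n_vals = sum(1 for line in text if line and line[0].isdigit()
                     or line.startswith("0."))
        assert f"CELL_DATA {vm.n_voxels}" in "\n".join(text)
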