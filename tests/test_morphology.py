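"""Morphometry against analytic solids, scaling laws, and density arithmetic."""

import numpy as np
import pytest

from mito3d.morphology import (
    MorphRecord,
    instance_axes,
    instance_surface_area,
    instance_volume,
    measure_instances,
    summarize,
)
from mito3d.volume import VoxelSpacing


def _ball(radius_um: float, spacing: VoxelSpacing) -> np.ndarray:
    scale = np.array(spacing.as_tuple()) * 1e-3
    half = np.ceil(radius_um / scale).astype(int) + 2
    zz, yy, xx = np.meshgrid(
        *(((np.arange(2 * h + 1) - h + 0.0) * s) for h, s in zip(half, scale)),
        indexing="ij",
    )
    return zz**2 + yy**2 + xx**2 <= radius_um**2


def _cylinder(length_um, radius_um, spacing):
    scale = np.array(spacing.as_tuple()) * 1e-3
    nz = int(np.ceil(length_um / scale[0])) + 4
    nr = int(np.ceil(radius_um / scale[1])) + 4
    zz, yy, xx = np.meshgrid(
        (np.arange(nz) - nz / 2) * scale[0],
        (np.arange(2 * nr + 1) - nr) * scale[1],
        (np.arange(2 * nr + 1) - nr) * scale[2],
        indexing="ij",
    )
    return (np.abs(zz) <= length_um / 2) & (yy**2 + xx**2 <= radius_um**2)


class TestInstanceVolume:
    def test_single_voxel_unit_conversion(self, iso10):
        mask = np.zeros((1, 1, 1), dtype=bool)
        mask[0, 0, 0] = True
        v = instance_volume(mask, VoxelSpacing(5, 5, 5))
        assert v == pytest.approx(1.25e-7, rel=1e-12)

    def test_cuboid_anisotropic_arithmetic(self):
        mask = np.ones((10, 10, 10), dtype=bool)  # 1,000 voxels at 2x2x50 nm
        v = instance_volume(mask, VoxelSpacing(50, 2, 2))
        assert v == pytest.approx(1000 * 200 * 1e-9, rel=1e-12)  # 2e-4 um^3

    def test_digitized_sphere_within_two_percent(self, iso10):
        mask = _ball(0.5, iso10)
        v = instance_volume(mask, iso10)
        assert v == pytest.approx(4 / 3 * np.pi * 0.5**3, rel=0.02)

    def test_empty_instance_rejected(self, iso10):
        with pytest.raises(ValueError):
            instance_volume(np.zeros((2, 2, 2), dtype=bool), iso10)


class TestSurfaceArea:
    @pytest.mark.parametrize("radius", [0.1, 0.25, 0.5])
    def test_digitized_spheres_within_five_percent(self, radius, iso10):
        area = instance_surface_area(_ball(radius, iso10), iso10)
        assert area == pytest.approx(4 * np.pi * radius**2, rel=0.05)

    def test_cube_within_five_percent(self, iso10):
        mask = np.zeros((24, 24, 24), dtype=bool)
        mask[2:22, 2:22, 2:22] = True  # 0.2 um cube at 10 nm
        area = instance_surface_area(mask, iso10)
        assert area == pytest.approx(0.24, rel=0.05)

    def test_spacing_scaling_law(self, iso10):
        mask = _ball(0.3, iso10)
        a1 = instance_surface_area(mask, iso10)
        a2 = instance_surface_area(mask, VoxelSpacing(20, 20, 20))
        assert a2 == pytest.approx(4 * a1, rel=1e-6)

    def test_single_voxel_fallback_is_box_surface(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        area = instance_surface_area(mask, VoxelSpacing(50, 2, 2))
        expected = 2 * (50 * 2 + 50 * 2 + 2 * 2) * 1e-6
        assert area == pytest.approx(expected, rel=1e-9)


class TestPrincipalAxes:
    def test_sphere_axes_and_flatness(self, iso10):
        length, width, flat, degenerate = instance_axes(_ball(0.5, iso10), iso10)
        assert not degenerate
        assert length == pytest.approx(1.0, rel=0.05)
        assert width == pytest.approx(1.0, rel=0.05)
        assert flat == pytest.approx(1.0, abs=0.05)

    def test_flat_plate_has_small_flatness(self, iso10):
        mask = np.zeros((5, 22, 22), dtype=bool)
        mask[2, 1:21, 1:21] = True  # one voxel thick
        *_, flat, _ = instance_axes(mask, iso10)
        assert flat <= 0.2

    def test_cylinder_length_width_ratio(self, iso10):
        mask = _cylinder(1.0, 0.1, iso10)  # length 1 um, diameter 0.2 um
        length, width, flat, _ = instance_axes(mask, iso10)
        assert length == pytest.approx(1.0, rel=0.10)
        assert width == pytest.approx(0.2, rel=0.10)
        assert length / width == pytest.approx(5.0, rel=0.10)
        assert flat == pytest.approx(1.0, abs=0.1)  # circular cross-section

    def test_isotropic_rescaling_laws(self, iso10):
        # distinct extents per axis so the principal directions are unique
        mask = np.zeros((46, 20, 12), dtype=bool)
        mask[3:43, 3:17, 3:9] = True
        l1, w1, f1, _ = instance_axes(mask, iso10)
        l2, w2, f2, _ = instance_axes(mask, VoxelSpacing(30, 30, 30))
        assert l2 == pytest.approx(3 * l1, rel=1e-9)
        assert w2 == pytest.approx(3 * w1, rel=1e-9)
        assert f2 == pytest.approx(f1, rel=1e-9)
        v1 = instance_volume(mask, iso10)
        v2 = instance_volume(mask, VoxelSpacing(30, 30, 30))
        assert v2 == pytest.approx(27 * v1, rel=1e-12)

    def test_volume_additivity_on_split(self, default_scene):
        _, labels, _ = default_scene
        inst_id = 1
        mask = labels.data == inst_id
        spacing = labels.spacing
        half = mask.copy()
        zs = np.argwhere(mask)[:, 0]
        mid = int(np.median(zs))
        half[: mid + 1] = False
        other = mask & ~half
        if half.any() and other.any():
            assert instance_volume(mask, spacing) == pytest.approx(
                instance_volume(half, spacing) + instance_volume(other, spacing),
                rel=1e-12,
            )


class TestSummaries:
    @pytest.mark.parametrize(
        "count,extent,expected",
        [
            (1478, (15.2, 17.2, 8.9), 0.6352),  # cortex-stack worked example
            (319, (10.2, 7.6, 5.3), 0.7764),  # hippocampus-stack worked example
        ],
    )
    def test_density_worked_examples_to_4dp(self, count, extent, expected):
        records = [
            MorphRecord(
                instance_id=i + 1, volume_um3=0.1, surface_um2=1.0,
                surface_to_volume=10.0, length_um=1.0, width_um=0.4,
                length_width_ratio=2.5, flatness=0.5,
            )
            for i in range(count)
        ]
        total = float(np.prod(extent))
        s = summarize(records, total)
        assert round(s.density_per_um3, 4) == expected

    def test_single_record_mean_is_value_sd_zero(self):
        rec = MorphRecord(1, 0.2, 1.5, 7.5, 1.0, 0.5, 2.0, 0.6)
        s = summarize([rec], 10.0)
        assert s.means["volume_um3"] == pytest.approx(0.2)
        assert s.stds["volume_um3"] == 0.0
        assert s.density_per_um3 == pytest.approx(0.1)

    def test_measure_instances_full_table(self, default_scene):
        vol, labels, manifest = default_scene
        records = measure_instances(labels)
        assert len(records) == len(manifest)
        for rec, obj in zip(records, manifest):
            assert rec.volume_um3 == pytest.approx(obj.analytic_volume_um3, rel=0.05)
            assert rec.length_um >= rec.width_um > 0
            assert 0 < rec.flatness <= 1
            assert rec.surface_to_volume == pytest.approx(
                rec.surface_um2 / rec.volume_um3, rel=1e-12
            )

    def test_mesh_export_writes_valid_obj(self, tmp_path, default_scene):
        from mito3d.morphology import export_instance_meshes

        _, labels, manifest = default_scene
        paths = export_instance_meshes(labels, tmp_path / "meshes")
        assert len(paths) == len(manifest)
        text = open(paths[0]).read().splitlines()
        n_verts = sum(1 for line in text if line.startswith("v "))
        n_faces = sum(1 for line in text if line.startswith("f "))
        assert n_verts > 0 and n_faces > 0
        # face indices are 1-based and reference existing vertices
        idx = [int(t) for line in text if line.startswith("f ") for t in line.split()[1:]]
        assert min(idx) >= 1 and max(idx) <= n_verts

    def test_zero_volume_rejected(self):
        rec = MorphRecord(1, 0.2, 1.5, 7.5, 1.0, 0.5, 2.0, 0.6)
        with pytest.raises(ValueError):
            summarize([rec], 0.0)
        with pytest.raises(ValueError):
            summarize([], 1.0)
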