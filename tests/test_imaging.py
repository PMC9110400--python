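"""Phantom generation and micro-CT damage quantification round-trips."""

import numpy as np
import pytest

from coralmech.imaging import (
    VoxelImage,
    affected_layer,
    make_phantom,
    measure_porosity,
    pore_components,
    pore_mask,
    thin_outer_wall,
)


def digitise_ellipsoid(shape, center, semi_axes, axis=2):
    """Voxelised axis-aligned ellipsoid in an otherwise solid block."""
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d = np.stack([zz - center[0], yy - center[1], xx - center[2]])
    a = np.ones(3)
    a[:] = semi_axes
    inside = (d[0] / a[0]) ** 2 + (d[1] / a[1]) ** 2 + (d[2] / a[2]) ** 2 <= 1.0
    return inside


@pytest.fixture(scope="module")
def hollow_cylinder():
    solid = np.zeros((20, 80, 80), bool)
    yy, xx = np.meshgrid(np.arange(80), np.arange(80), indexing="ij")
    rr = np.hypot(yy - 39.5, xx - 39.5)
    solid[:] = (rr >= 15) & (rr <= 35)
    return VoxelImage(solid, 10.0), rr


class TestPhantomGenerator:
    def test_zero_porosity_gives_solid_wall(self):
        img, truth = make_phantom(porosity=0.0, seed=1)
        assert truth.n_pores == 0
        assert measure_porosity(img) == 0.0

    def test_fixed_seed_is_bit_identical(self):
        a, _ = make_phantom(porosity=0.15, seed=42, height=100)
        b, _ = make_phantom(porosity=0.15, seed=42, height=100)
        assert np.array_equal(a.data, b.data)

    def test_different_seeds_differ(self):
        a, _ = make_phantom(porosity=0.15, seed=1, height=100)
        b, _ = make_phantom(porosity=0.15, seed=2, height=100)
        assert not np.array_equal(a.data, b.data)

    def test_block_preset_emulates_28_percent_voi(self):
        """28% porosity in a 120 um volume of interest."""
        img, truth = make_phantom(porosity=0.28, geometry="block",
                                  voxel_size=4.0, pore_minor_radius=8.0, seed=3)
        assert 0.27 <= measure_porosity(img) <= 0.29

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError):
            make_phantom(porosity=0.6, seed=1)


class TestPorosityMeasurement:
    def test_porosity_recovery_over_seeded_phantoms(self):
        """Fill-based porosity matches the generator ground truth to < 1%
        absolute across targets spanning 5-33%."""
        targets = np.linspace(0.05, 0.33, 10)
        for i, t in enumerate(targets):
            for seed in (2 * i, 2 * i + 1):
                img, truth = make_phantom(
                    porosity=float(t), geometry="block", voxel_size=8.0,
                    pore_minor_radius=12.0, block_size=160.0, seed=seed,
                )
                measured = measure_porosity(img)
                assert abs(measured - truth.achieved_porosity) < 0.01

    def test_analytic_sphere_volumes(self):
        """Digitised non-overlapping spheres: measured porosity within 1%
        absolute of the analytic value (voxel <= r/5)."""
        shape = (60, 60, 60)
        solid = np.ones(shape, bool)
        centers = [(15, 15, 15), (15, 40, 40), (40, 20, 40), (42, 42, 16)]
        r = 8.0
        for c in centers:
            solid &= ~digitise_ellipsoid(shape, c, (r, r, r))
        img = VoxelImage(solid, 1.0)
        analytic = len(centers) * 4.0 / 3.0 * np.pi * r ** 3
        expected = analytic / np.prod(shape)
        assert abs(measure_porosity(img) - expected) < 0.01

    def test_exterior_space_is_not_counted(self, hollow_cylinder):
        img, _ = hollow_cylinder
        assert measure_porosity(img) == 0.0
        assert not pore_mask(img).any()

    def test_empty_voi_rejected(self, hollow_cylinder):
        img, _ = hollow_cylinder
        with pytest.raises(ValueError):
            measure_porosity(img, (slice(0, 5), slice(0, 5), slice(0, 5)))


class TestAffectedLayer:
    def test_uniform_layer_thickness_recovery(self):
        """A ~150 um porous layer is recovered to within 2 voxels, and
        within 5% of the realised band depth."""
        img, truth = make_phantom(
            porosity=0.33, layer_depth=150.0, voxel_size=10.0,
            pore_minor_radius=10.0, outer_radius=450.0,
            wall_thickness=200.0, height=150.0, seed=7,
        )
        lm = affected_layer(img, alpha=0.05)
        err = abs(lm.median_thickness - truth.layer_depth_achieved)
        assert err <= 2.0 * img.voxel_size
        assert err / truth.layer_depth_achieved < 0.05

    def test_solid_image_yields_empty_map(self, hollow_cylinder):
        img, _ = hollow_cylinder
        lm = affected_layer(img)
        assert not lm.mask.any()
        assert lm.median_thickness == 0.0
        assert len(lm.skipped_slices) == img.data.shape[0]

    def test_measured_range_inside_generator_envelope(self):
        img, truth = make_phantom(
            porosity=0.30, layer_depth=200.0, voxel_size=10.0,
            pore_minor_radius=10.0, height=120.0, seed=11,
        )
        lm = affected_layer(img)
        lo, hi = lm.thickness_range
        assert hi <= truth.layer_depth_achieved + 3 * img.voxel_size
        assert lm.median_thickness > 0.5 * truth.layer_depth_achieved


class TestPoreComponents:
    def test_single_sphere_is_isotropic(self):
        shape = (40, 40, 40)
        solid = np.ones(shape, bool) & ~digitise_ellipsoid(shape, (20, 20, 20),
                                                           (10, 10, 10))
        stats = pore_components(VoxelImage(solid, 2.0))
        assert stats.count == 1
        assert stats.degree_of_anisotropy[0] == pytest.approx(1.0, abs=0.05)
        assert stats.volumes[0] == pytest.approx(4 / 3 * np.pi * 10 ** 3 * 8,
                                                 rel=0.02)

    def test_two_to_one_spheroid_anisotropy(self):
        """A 2:1 prolate pore with >= 20 voxels across the minor axis reads
        a degree of anisotropy of 2 within 5%."""
        shape = (100, 50, 50)
        solid = np.ones(shape, bool) & ~digitise_ellipsoid(
            shape, (50, 25, 25), (40, 20, 20)
        )
        stats = pore_components(VoxelImage(solid, 1.0))
        assert stats.count == 1
        assert stats.degree_of_anisotropy[0] == pytest.approx(2.0, rel=0.05)

    def test_touching_spheres_merge_under_26_connectivity(self):
        shape = (40, 80, 40)
        solid = np.ones(shape, bool)
        solid &= ~digitise_ellipsoid(shape, (20, 30, 20), (8, 8, 8))
        solid &= ~digitise_ellipsoid(shape, (20, 46, 20), (8, 8, 8))
        stats = pore_components(VoxelImage(solid, 1.0))
        assert stats.count == 1

    def test_empty_image_reports_zero_pores(self, hollow_cylinder):
        img, _ = hollow_cylinder
        stats = pore_components(img)
        assert stats.count == 0


class TestOuterWallThinning:
    def test_zero_depth_is_identity(self, hollow_cylinder):
        img, _ = hollow_cylinder
        out = thin_outer_wall(img, 0.0)
        assert np.array_equal(out.data, img.data)

    def test_annulus_thins_from_outside_only(self, hollow_cylinder):
        img, rr = hollow_cylinder
        out = thin_outer_wall(img, 50.0)  # 5 voxels at 10 um
        mid = out.data[10]
        assert rr[mid].max() == pytest.approx(30.0, abs=1.0)
        assert rr[mid].min() == pytest.approx(rr[img.data[10]].min(), abs=1.0)

    def test_internal_pores_untouched(self):
        shape = (30, 60, 60)
        solid = np.zeros(shape, bool)
        solid[2:-2, 5:-5, 5:-5] = True  # block with free outer surface
        solid &= ~digitise_ellipsoid(shape, (15, 30, 30), (6, 6, 6))
        img = VoxelImage(solid, 1.0)
        out = thin_outer_wall(img, 3.0)
        before = pore_components(img).volumes[0]
        after = pore_components(out).volumes[0]
        assert after == before
        assert out.data.sum() < img.data.sum()

    def test_erosion_ladder_preset_is_monotone(self):
        """Stepwise erosion in thirds of a 0.35 mm step mirrors progressive
        outer-layer loss."""
        solid = np.zeros((20, 120, 120), bool)
        yy, xx = np.meshgrid(np.arange(120), np.arange(120), indexing="ij")
        rr = np.hypot(yy - 59.5, xx - 59.5)
        solid[:] = (rr >= 10) & (rr <= 50)  # 400 um wall at 10 um voxels
        img = VoxelImage(solid, 10.0)
        vols = [thin_outer_wall(img, d).data.sum()
                for d in (0.0, 350.0 / 3, 2 * 350.0 / 3, 350.0)]
        assert all(a > b for a, b in zip(vols, vols[1:]))

    def test_excessive_depth_warns_and_perforates(self, hollow_cylinder):
        img, _ = hollow_cylinder
        with pytest.warns(UserWarning, match="wall"):
            out = thin_outer_wall(img, 1000.0)
        assert not out.data.any()


class TestVoxelImageIO:
    def test_tiff_roundtrip_preserves_data_and_spacing(self, tmp_path):
        img, _ = make_phantom(porosity=0.15, seed=9, height=80.0)
        p = tmp_path / "phantom.tiff"
        img.to_tiff(p)
        back = VoxelImage.from_tiff(p)
        assert np.array_equal(back.data, img.data)
        assert back.voxel_size == pytest.approx(img.voxel_size)

    def test_nrrd_roundtrip(self, tmp_path):
        img, _ = make_phantom(porosity=0.1, seed=9, height=60.0)
        p = tmp_path / "phantom.nrrd"
        img.to_nrrd(p)
        back = VoxelImage.from_nrrd(p)
        assert np.array_equal(back.data, img.data)
        assert back.voxel_size == pytest.approx(img.voxel_size)
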