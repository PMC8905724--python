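"""Implant geometry: cylinder/box rasterization, comparators, derating."""

import numpy as np
import pytest

from sonoquant import (
    EmptyRegionError,
    GeometryError,
    ImplantGeometry,
    ParameterError,
    box_mask,
    comparator_masks,
    cylinder_mask,
    derate_pressure,
    implant_box_mask,
    mask_mean,
)
from tests.conftest import make_grid
from tests.oracles import brute_force_box, brute_force_cylinder


def geom_z(entry=(0.0, 0.0, -30.0), axis=(0.0, 0.0, 1.0)):
    return ImplantGeometry(np.asarray(entry, float), np.asarray(axis, float))


class TestImplantGeometry:
    def test_axis_must_be_unit(self):
        with pytest.raises(ParameterError, match="unit"):
            ImplantGeometry(np.zeros(3), np.array([0.0, 0.0, 2.0]))

    def test_json_round_trip(self, tmp_path):
        g = ImplantGeometry(np.array([1.0, 2.0, 3.0]), np.array([1.0, 0.0, 0.0]),
                            pressure_mpa=0.9, freq_mhz=1.0)
        g.to_json(tmp_path / "g.json")
        back = ImplantGeometry.from_json(tmp_path / "g.json")
        assert np.allclose(back.entry_mm, g.entry_mm)
        assert back.pressure_mpa == 0.9


class TestCylinder:
    def test_voxel_count_matches_continuum_volume(self):
        # pi * 7.5^2 * 55 = 9719 mm^3; 1-mm voxel-center count within 2%
        # (odd transverse extents put voxel centers on the axis)
        grid = make_grid((41, 41, 70))
        roi = cylinder_mask(geom_z(), grid, diameter_mm=15.0, length_mm=55.0)
        expected = np.pi * 7.5**2 * 55
        assert abs(roi.n_voxels - expected) / expected < 0.02

    def test_agrees_with_brute_force_oracle_for_random_geometries(self):
        rng = np.random.default_rng(12)
        grid = make_grid((40, 40, 40))
        for _ in range(8):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            geom = ImplantGeometry(rng.uniform(-12, 12, 3), axis)
            d, ln = rng.uniform(4, 20), rng.uniform(5, 35)
            roi = cylinder_mask(geom, grid, diameter_mm=d, length_mm=ln)
            assert np.array_equal(roi.mask, brute_force_cylinder(geom, grid, d, ln))

    def test_rotation_preserves_count_within_discretization(self):
        grid = make_grid((60, 60, 60))
        along_z = cylinder_mask(geom_z((0, 0, -27.5)), grid, 15.0, 55.0)
        along_x = cylinder_mask(
            ImplantGeometry(np.array([-27.5, 0.0, 0.0]), np.array([1.0, 0.0, 0.0])),
            grid, 15.0, 55.0,
        )
        assert abs(along_x.n_voxels - along_z.n_voxels) / along_z.n_voxels < 0.02

    def test_degenerate_and_out_of_grid_inputs(self):
        grid = make_grid((20, 20, 20))
        with pytest.raises(GeometryError):
            cylinder_mask(geom_z(), grid, diameter_mm=15.0, length_mm=0.0)
        with pytest.raises(GeometryError):
            cylinder_mask(geom_z(entry=(500.0, 0.0, 0.0)), grid)


class TestImplantBox:
    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        grid = make_grid((30, 30, 30))
        for _ in range(5):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            geom = ImplantGeometry(rng.uniform(-10, 10, 3), axis)
            dims = tuple(rng.uniform(4, 14, 3))
            roi = box_mask(geom, grid, dims_mm=dims)
            assert np.array_equal(roi.mask, brute_force_box(geom, grid, dims))

    def test_tissue_restrictions(self, small_labels):
        grid = small_labels.labels
        geom = ImplantGeometry(np.array([0.0, 0.0, -25.0]), np.array([0.0, 0.0, 1.0]))
        full = implant_box_mask(geom, grid, small_labels, restrict="none")
        gm_only = implant_box_mask(geom, grid, small_labels, restrict="GM-only")
        no_csf = implant_box_mask(geom, grid, small_labels, restrict="exclude-CSF")
        gm = small_labels.tissue_mask("GM")
        csf = small_labels.tissue_mask("CSF")
        assert np.array_equal(gm_only.mask, full.mask & gm)
        assert np.array_equal(no_csf.mask, full.mask & ~csf)
        assert gm_only.n_voxels < no_csf.n_voxels <= full.n_voxels

    def test_restriction_emptying_box_is_an_error(self, small_labels):
        # a box wholly inside white matter has no CSF or GM voxels
        geom = ImplantGeometry(np.array([0.0, 0.0, -8.0]), np.array([0.0, 0.0, 1.0]))
        with pytest.raises(EmptyRegionError):
            implant_box_mask(geom, small_labels.labels, small_labels,
                             dims_mm=(6.0, 6.0, 10.0), restrict="GM-only")


@pytest.fixture(scope="module")
def roiset(clean_phantom):
    return comparator_masks(
        clean_phantom.geometry,
        clean_phantom.pre,
        clean_phantom.labels,
        restrict="GM-only",
        brain_mask=clean_phantom.brain_mask,
    )


class TestComparators:
    def test_opposite_roi_mirrors_the_implant_box(self, roiset):
        # the phantom is mid-sagittally symmetric, so counts must agree
        assert roiset.opposite_hemisphere.n_voxels == roiset.implant_box.n_voxels
        assert roiset.implant_box.side == "left"
        assert roiset.opposite_hemisphere.side == "right"

    def test_rois_are_disjoint(self, roiset):
        trio = [roiset.implant_box, roiset.same_hemisphere, roiset.opposite_hemisphere]
        for i, a in enumerate(trio):
            for b in trio[i + 1:]:
                assert not (a.mask & b.mask).any()
        assert not (roiset.beam.mask & roiset.control.mask).any()

    def test_uniform_volume_has_equal_means_everywhere(self, roiset, clean_phantom):
        vol = clean_phantom.pre.like(np.full(clean_phantom.pre.shape, 3.0))
        means = [
            mask_mean(vol, r)
            for r in (roiset.implant_box, roiset.same_hemisphere, roiset.opposite_hemisphere)
        ]
        assert np.allclose(means, 3.0)

    def test_planted_hot_implant_region_gives_exact_ratio(self, roiset, clean_phantom):
        data = np.ones(clean_phantom.pre.shape)
        data[roiset.implant_box.mask] *= 1.10
        vol = clean_phantom.pre.like(data)
        ratio = mask_mean(vol, roiset.implant_box) / mask_mean(vol, roiset.opposite_hemisphere)
        assert ratio == pytest.approx(1.10, abs=1e-12)

    def test_distal_box_must_stay_in_brain(self, clean_phantom):
        with pytest.raises((GeometryError, EmptyRegionError)):
            comparator_masks(
                clean_phantom.geometry,
                clean_phantom.pre,
                clean_phantom.labels,
                distal_offset_mm=120.0,
                brain_mask=clean_phantom.brain_mask,
            )

    def test_distal_shift_must_be_coronal_in_plane(self, clean_phantom):
        with pytest.raises(ParameterError, match="coronal"):
            comparator_masks(
                clean_phantom.geometry,
                clean_phantom.pre,
                clean_phantom.labels,
                distal_direction=np.array([0.0, -1.0, 0.0]),
            )


class TestDerating:
    def test_reference_values(self):
        g = geom_z()  # 1.03 MPa, 1 MHz defaults
        assert derate_pressure(g, 0.0) == pytest.approx(1.03)
        # 0.6 dB/cm/MHz * 1 MHz * 5 cm = 3 dB -> 10^(-0.15)
        assert derate_pressure(g, 5.0) == pytest.approx(1.03 * 10 ** (-0.15), abs=1e-6)
        assert derate_pressure(g, 5.0, attenuation_db_cm_mhz=0.0) == pytest.approx(1.03)

    def test_strictly_decreasing_and_multiplicative_over_path_segments(self):
        g = geom_z()
        depths = np.linspace(0, 8, 30)
        p = derate_pressure(g, depths)
        assert np.all(np.diff(p) < 0)
        p0 = g.pressure_mpa
        for d1, d2 in [(1.0, 2.5), (0.3, 4.2)]:
            lhs = derate_pressure(g, d1 + d2) / p0
            rhs = (derate_pressure(g, d1) / p0) * (derate_pressure(g, d2) / p0)
            assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_negative_depth_rejected(self):
        with pytest.raises(ParameterError):
            derate_pressure(geom_z(), -1.0)
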