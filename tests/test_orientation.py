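import numpy as np
import pytest

import cardioem as ce
from cardioem.orientation import planar_angles_xz

GEOM = ce.VolumeGeometry(spacing=(10.0, 10.0, 40.0))
ISO = ce.VolumeGeometry(spacing=(1.0, 1.0, 1.0))


def _mask_from(voxels, shape):
    m = np.zeros(shape, dtype=bool)
    m[tuple(np.asarray(voxels).T)] = True
    return m


class TestSplitObjects:
    def test_two_disjoint_cylinders(self):
        a = ce.rasterize_cylinder((1, 0, 0), (200, 100, 120), 25, 300, GEOM, (64, 64, 8))
        b = ce.rasterize_cylinder((1, 0, 0), (200, 400, 120), 25, 300, GEOM, (64, 64, 8))
        mask = _mask_from(np.vstack([a, b]), (64, 64, 8))
        objs = ce.split_objects(mask, GEOM, min_object_voxels=1)
        assert len(objs) == 2

    def test_corner_touching_connectivity_semantics(self):
        mask = np.zeros((6, 6, 2), dtype=bool)
        mask[0:2, 0:2, 0] = True
        mask[2:4, 2:4, 0] = True   # touches only at a corner voxel
        assert len(ce.split_objects(mask, ISO, connectivity=26,
                                    min_object_voxels=1)) == 1
        assert len(ce.split_objects(mask, ISO, connectivity=6,
                                    min_object_voxels=1)) == 2

    def test_single_voxel_below_min_size_empty(self):
        mask = np.zeros((5, 5, 2), dtype=bool)
        mask[1, 1, 0] = True
        assert ce.split_objects(mask, ISO, min_object_voxels=10) == []

    def test_empty_mask_empty_list(self):
        assert ce.split_objects(np.zeros((4, 4, 2), dtype=bool), ISO) == []


class TestObjectOrientation:
    def test_voxel_row_along_x(self):
        idx = np.array([[3, j, 1] for j in range(10)])
        axis, _ = ce.object_orientation(idx, GEOM)
        assert np.allclose(axis, [1, 0, 0])

    def test_perfect_cube_indeterminate(self):
        idx = np.argwhere(np.ones((5, 5, 5), dtype=bool))
        axis, _ = ce.object_orientation(idx, ISO)
        assert axis is None

    def test_anisotropy_corrected(self):
        # 4 voxels along z at 40 nm spacing = 160 nm; 8 voxels along x = 80 nm:
        # physical axis is z even though the voxel extent is larger in x.
        idx = [[0, j, k] for j in range(2) for k in range(8)]
        axis, _ = ce.object_orientation(np.array(idx), GEOM)
        assert abs(axis[2]) > 0.99

    def test_rasterized_cylinder_axis_within_2_degrees(self):
        d = ce.direction_from_angles(30.0, 0.0)
        vox = ce.rasterize_cylinder(d, (1000, 1500, 200), 30, 1000, GEOM,
                                    (300, 300, 10))
        axis, _ = ce.object_orientation(vox, GEOM)
        dev = np.degrees(np.arccos(abs(float(np.dot(axis, d)))))
        assert dev < 2.0
        assert ce.transmural_angle(axis) == pytest.approx(30.0, abs=2.0)

    def test_sign_normalized_x_nonnegative(self, rng):
        for _ in range(10):
            idx = rng.integers(0, 20, (50, 3))
            axis, _ = ce.object_orientation(idx, GEOM)
            if axis is not None:
                assert axis[0] >= 0


class TestAngles:
    @pytest.mark.parametrize("axis,expected", [
        ((1, 0, 0), 0.0), ((0, 1, 0), 90.0),
        ((1 / np.sqrt(2), 1 / np.sqrt(2), 0), 45.0),
        ((-1 / np.sqrt(2), 1 / np.sqrt(2), 0), 135.0),
    ])
    def test_transmural_examples(self, axis, expected):
        assert ce.transmural_angle(np.array(axis)) == pytest.approx(expected)

    @pytest.mark.parametrize("axis,expected", [
        ((1, 0, 0), 0.0), ((0, 0, 1), 90.0),
        ((1 / np.sqrt(2), 0, 1 / np.sqrt(2)), 45.0),
    ])
    def test_elliptical_examples(self, axis, expected):
        assert ce.elliptical_angle(np.array(axis)) == pytest.approx(expected)

    def test_axis_parallel_to_z_theta_undefined(self):
        with pytest.raises(ValueError):
            ce.transmural_angle(np.array([0.0, 0.0, 1.0]))

    def test_axis_parallel_to_y_phi_undefined(self):
        with pytest.raises(ValueError):
            ce.elliptical_angle(np.array([0.0, 1.0, 0.0]))


class TestResampleToXz:
    def test_z_axis_upsampled_by_spacing_ratio(self, small_phantom):
        out = ce.resample_to_xz(small_phantom.labels)
        ny, nx, nz = small_phantom.labels.shape
        assert out.shape == (nz * 4, nx, ny)
        assert out.geometry.spacing == (10.0, 10.0, 10.0)

    def test_label_set_preserved(self, small_phantom):
        out = ce.resample_to_xz(small_phantom.labels)
        assert set(np.unique(out.data)) == set(np.unique(small_phantom.labels.data))

    def test_fibril_along_z_appears_at_phi_90_in_plane(self):
        # a rod along z in the original frame
        vox = ce.rasterize_cylinder((0, 0, 1), (320, 320, 600), 25, 1200,
                                    GEOM, (64, 64, 40))
        labels = np.zeros((64, 64, 40), dtype=np.uint8)
        labels[tuple(vox.T)] = ce.CLASS_MYOFIBRIL
        lv = ce.LabelVolume(labels, dict(ce.EM_CLASS_MAP), GEOM)
        table = planar_angles_xz(ce.resample_to_xz(lv), ce.CLASS_MYOFIBRIL,
                                 min_object_voxels=10)
        assert len(table) == 1
        assert table.phi_deg.iloc[0] == pytest.approx(90.0, abs=2.0)


class TestHistogram:
    def test_example_binning(self):
        counts = ce.angle_histogram([0, 5, 15, 175])
        assert counts[0] == 2 and counts[1] == 1 and counts[17] == 1
        assert counts.sum() == 4

    def test_empty_input_all_zero(self):
        counts = ce.angle_histogram([])
        assert counts.shape == (18,) and counts.sum() == 0

    def test_180_folds_into_first_bin(self):
        assert ce.angle_histogram([180.0])[0] == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ce.angle_histogram([-1.0])
        with pytest.raises(ValueError):
            ce.angle_histogram([360.0])

    def test_counts_sum_to_n(self, rng):
        angles = rng.uniform(0, 180, 500)
        assert ce.angle_histogram(angles).sum() == 500


class TestAngleSummary:
    def test_constant_sample_zero_sd_both_modes(self):
        for mode in ("linear", "circular-axial"):
            s = ce.angle_summary([45.0] * 5, mode=mode)
            assert s.mean_deg == pytest.approx(45.0, abs=1e-9)
            assert s.sd_deg == pytest.approx(0.0, abs=1e-6)

    def test_linear_two_values(self):
        s = ce.angle_summary([10.0, 20.0], mode="linear")
        assert s.mean_deg == pytest.approx(15.0)
        assert s.sd_deg == pytest.approx(7.0711, abs=1e-3)

    def test_wrap_divergence_between_modes(self):
        """{5°, 175°} straddles the axial wrap: the linear mean is 90° but the
        axial mean direction is 0°."""
        lin = ce.angle_summary([5.0, 175.0], mode="linear")
        axi = ce.angle_summary([5.0, 175.0], mode="circular-axial")
        assert lin.mean_deg == pytest.approx(90.0)
        assert axi.mean_deg == pytest.approx(0.0, abs=1e-9)
        assert lin.wrap_warning

    def test_histogram_counts_sum_to_n_objects(self, rng):
        s = ce.angle_summary(rng.uniform(0, 180, 77))
        assert s.histogram.sum() == s.n_objects == 77

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ce.angle_summary([])


class TestRotationEquivariance:
    def test_rotating_axes_about_z_shifts_theta(self, rng):
        """Rotating fibril axes by +Δ about z shifts recovered θ by Δ mod 180."""
        delta = 25.0
        for _ in range(5):
            theta = rng.uniform(0, 180)
            d = ce.direction_from_angles(theta, rng.uniform(0, 180))
            c, s = np.cos(np.radians(delta)), np.sin(np.radians(delta))
            rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]]) @ d
            got = ce.transmural_angle(rot)
            assert got == pytest.approx((theta + delta) % 180.0, abs=1e-6)


def test_angle_table_marks_indeterminate(small_phantom):
    objs = ce.split_objects(small_phantom.labels.mask(ce.CLASS_MYOFIBRIL),
                            small_phantom.labels.geometry, min_object_voxels=50)
    table = ce.angle_table(objs)
    assert set(table.columns) == {"object_id", "theta_deg", "phi_deg", "n_voxels"}
    assert len(table) == len(objs)
    assert (table.n_voxels >= 50).all()
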