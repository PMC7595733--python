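import numpy as np
import pytest

import cardioem as ce
from cardioem.phantom import PackingError


GEOM = ce.VolumeGeometry(spacing=(10.0, 10.0, 40.0))


class TestRasterizeCylinder:
    def test_thin_cylinder_along_x_is_one_voxel_row(self):
        vox = ce.rasterize_cylinder((1, 0, 0), (200, 200, 40), 10.0, 300.0,
                                    GEOM, (64, 64, 4))
        assert np.unique(vox[:, 0]).size == 1      # single row
        assert np.unique(vox[:, 2]).size == 1      # single slice
        assert np.unique(vox[:, 1]).size == 30     # 300 nm / 10 nm

    def test_axial_length_spans_length_over_spacing_slices(self):
        # 400 nm along z at 40 nm sections -> exactly 10 slice centers
        vox = ce.rasterize_cylinder((0, 0, 1), (200, 200, 200), 30.0, 400.0,
                                    GEOM, (40, 40, 30))
        assert np.unique(vox[:, 2]).size == 10

    def test_diagonal_axis_symmetric_under_xy_swap(self):
        d = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        vox = ce.rasterize_cylinder(d, (200, 200, 40), 35.0, 250.0,
                                    GEOM, (64, 64, 2))
        voxset = {tuple(v) for v in vox}
        swapped = {(j, i, k) for i, j, k in voxset}
        assert voxset == swapped

    def test_outside_grid_returns_empty(self):
        vox = ce.rasterize_cylinder((1, 0, 0), (1e6, 1e6, 1e6), 30.0, 300.0,
                                    GEOM, (32, 32, 8))
        assert vox.shape == (0, 3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ce.rasterize_cylinder((0, 0, 0), (0, 0, 0), 10, 100, GEOM, (8, 8, 8))
        with pytest.raises(ValueError):
            ce.rasterize_cylinder((1, 0, 0), (0, 0, 0), -1, 100, GEOM, (8, 8, 8))

    def test_all_voxels_within_radius_in_physical_coords(self, rng):
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        center = np.array([300.0, 320.0, 200.0])
        radius, length = 45.0, 400.0
        vox = ce.rasterize_cylinder(d, center, radius, length, GEOM, (64, 64, 12))
        pts = GEOM.physical_coords(vox)
        w = pts - (center - 0.5 * length * d)
        t = w @ d
        perp = np.sqrt(np.maximum(0, (w ** 2).sum(1) - t ** 2))
        assert (perp < radius).all()
        assert ((t >= 0) & (t < length)).all()


class TestEmPhantom:
    def test_empty_phantom_is_all_ec_or_other(self):
        p = ce.EmPhantomParams(seed=3, grid_shape=(48, 48, 8), n_myofibrils=0,
                               n_nuclei=0, n_mitochondria=0)
        ph = ce.generate_em_volume(p)
        counts = ph.labels.class_counts()
        assert counts[ce.CLASS_MYOFIBRIL] == 0
        assert counts[ce.CLASS_NUCLEUS] == 0
        assert counts[ce.CLASS_MITOCHONDRION] == 0
        total = ph.labels.data.size
        assert counts[ce.CLASS_EXTRACELLULAR] + counts[ce.CLASS_OTHER_CYTOPLASM] == total

    def test_same_seed_bit_identical(self):
        p = ce.EmPhantomParams(seed=9, grid_shape=(64, 64, 12), n_myofibrils=3,
                               fibril_radius=30, fibril_length=300,
                               n_nuclei=0, n_mitochondria=3,
                               mito_semiaxes=(90.0, 70.0, 70.0))
        a, b = ce.generate_em_volume(p), ce.generate_em_volume(p)
        assert np.array_equal(a.intensity.data, b.intensity.data)
        assert np.array_equal(a.labels.data, b.labels.data)
        assert np.array_equal(a.fibril_ids, b.fibril_ids)
        assert a.angles.equals(b.angles)

    def test_class_counts_sum_to_grid(self, small_phantom):
        counts = small_phantom.labels.class_counts()
        assert sum(counts.values()) == small_phantom.labels.data.size

    def test_ec_fraction_control(self, small_phantom):
        rep = ce.compute_fractions(small_phantom.labels)
        assert rep.ec_fraction == pytest.approx(0.2, abs=0.05)

    def test_each_myofibril_voxel_has_one_fibril_id(self, small_phantom):
        myo = small_phantom.labels.data == ce.CLASS_MYOFIBRIL
        assert (small_phantom.fibril_ids[myo] > 0).all()
        assert (small_phantom.fibril_ids[~myo] == 0).all()

    def test_zero_sd_angles_recovered_within_2_degrees(self):
        """theta_sd = phi_sd = 0: every rasterized fibril's principal axis in
        physical coordinates lies within 2 degrees of the requested direction."""
        p = ce.EmPhantomParams(seed=21, grid_shape=(160, 160, 50),
                               n_myofibrils=12, fibril_radius=40,
                               fibril_length=700, theta_mean=45.0,
                               theta_sd=0.0, phi_mean=20.0, phi_sd=0.0,
                               n_nuclei=0, n_mitochondria=0,
                               ec_fraction_target=0.0)
        ph = ce.generate_em_volume(p)
        true_d = ce.direction_from_angles(45.0, 20.0)
        for fid in ph.angles.fibril_id:
            idx = np.argwhere(ph.fibril_ids == fid)
            axis, _ = ce.object_orientation(idx, ph.labels.geometry)
            dev = np.degrees(np.arccos(min(1.0, abs(float(np.dot(axis, true_d))))))
            assert dev < 2.0

    def test_infeasible_packing_names_class(self):
        p = ce.EmPhantomParams(seed=4, grid_shape=(48, 48, 8),
                               n_myofibrils=500, fibril_radius=40,
                               fibril_length=400, n_nuclei=0,
                               n_mitochondria=0, max_retries=5)
        with pytest.raises(PackingError, match="myofibril"):
            ce.generate_em_volume(p)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ce.EmPhantomParams(seed=1, ec_fraction_target=1.0)
        with pytest.raises(ValueError):
            ce.EmPhantomParams(seed=1, fibril_radius=2.0)
        with pytest.raises(ValueError):
            ce.EmPhantomParams(seed=1, intensity_means={0: 10.0, 1: 10.0, 2: 20.0})

    def test_slice_jitter_recorded_and_reference_fixed(self):
        p = ce.EmPhantomParams(seed=6, grid_shape=(64, 64, 10), n_myofibrils=2,
                               fibril_radius=30, fibril_length=300,
                               n_nuclei=0, n_mitochondria=0,
                               slice_jitter_sd=2.0)
        ph = ce.generate_em_volume(p)
        assert ph.true_slice_shifts.shape == (10, 2)
        assert tuple(ph.true_slice_shifts[0]) == (0, 0)
        assert np.abs(ph.true_slice_shifts).max() > 0


class TestHeartPhantom:
    def test_ratio_13_recovered(self):
        p = ce.HeartPhantomParams(
            seed=1, rv_semiaxes=ce.rv_semiaxes_for_ratio((600.0, 500.0, 800.0), 1.3))
        ratio = ce.ventricle_volume_ratio(ce.generate_heart_phantom(p))["rv_over_lv"]
        assert 1.26 <= ratio <= 1.34

    def test_identical_lumens_ratio_one(self):
        p = ce.HeartPhantomParams(seed=1, lv_semiaxes=(500.0, 450.0, 600.0),
                                  rv_semiaxes=(500.0, 450.0, 600.0))
        ratio = ce.ventricle_volume_ratio(ce.generate_heart_phantom(p))["rv_over_lv"]
        assert ratio == pytest.approx(1.0, abs=0.03)

    def test_rasterized_lumen_volume_matches_analytic(self, heart_phantom):
        counts = heart_phantom.class_counts()
        vv = heart_phantom.geometry.voxel_volume
        analytic = 4.0 / 3.0 * np.pi * 600.0 * 500.0 * 800.0
        measured = counts[ce.HEART_LV_LUMEN] * vv
        assert measured == pytest.approx(analytic, rel=0.03)

    def test_zero_wall_thickness_rejected(self):
        with pytest.raises(ValueError):
            ce.HeartPhantomParams(seed=1, wall_thickness=0.0)

    def test_overlapping_lumens_rejected(self):
        p = ce.HeartPhantomParams(seed=1, lv_center_frac=(0.5, 0.5, 0.5),
                                  rv_center_frac=(0.52, 0.5, 0.5))
        with pytest.raises(ValueError, match="overlap"):
            ce.generate_heart_phantom(p)


def test_direction_from_angles_roundtrip():
    for theta, phi in [(0, 0), (30, 60), (135, 20), (90, 90), (179, 91)]:
        d = ce.direction_from_angles(theta, phi)
        assert np.linalg.norm(d) == pytest.approx(1.0)
        if theta not in (90,):
            assert ce.transmural_angle(d) == pytest.approx(theta, abs=1e-6)
            assert ce.elliptical_angle(d) == pytest.approx(phi, abs=1e-6)
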