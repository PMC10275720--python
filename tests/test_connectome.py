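"""Connectome assembly: FD/QC, regressions, smoothing, filtering, matrix."""

import numpy as np
import pytest

from dbsmap import synthetic as syn
from dbsmap.connectome import (ConnectomeSubject, build_matrix, compute_fd,
                               measure_filter_cutoff, measure_smoothing_fwhm,
                               nuisance_regress, preprocess_subject, qc_filter,
                               regress_motion, smooth_spatial, temporal_filter)
from dbsmap.images import ImageVolume, TimeSeriesImage, centered_grid


def _subject_with_motion(motion, n_xyz=(3, 3, 3)):
    t = motion.shape[0]
    bold = TimeSeriesImage(np.random.default_rng(0).normal(size=n_xyz + (t,)),
                           np.eye(4), tr=2.0)
    mask = ImageVolume(np.ones(n_xyz, np.uint8), np.eye(4))
    return ConnectomeSubject("s", bold, motion, {"brain": mask})


class TestFramewiseDisplacement:
    def test_translation_jump(self):
        motion = np.zeros((5, 6))
        motion[2:, 0] = 0.6  # single 0.6 mm jump in x
        fd = compute_fd(motion)
        np.testing.assert_allclose(fd, [0, 0, 0.6, 0, 0])

    def test_zero_motion(self):
        assert np.all(compute_fd(np.zeros((10, 6))) == 0)

    def test_rotation_arc_length(self):
        motion = np.zeros((3, 6))
        motion[1:, 4] = 0.01  # 0.01 rad step about y
        fd = compute_fd(motion)
        assert fd[1] == pytest.approx(0.5)  # 50 mm x 0.01 rad

    def test_first_volume_is_zero(self, rng):
        fd = compute_fd(rng.normal(size=(8, 6)))
        assert fd[0] == 0.0


class TestQcFilter:
    def test_synthetic_violators_excluded(self):
        """107 subjects with 7 constructed violators -> 100 retained."""
        spec = syn.ConnectomeSpec(n_subjects=107, n_violators=7, n_volumes=60,
                                  seed=3)
        subjects = []
        for i in range(spec.n_subjects):
            motion = syn.simulate_motion_trace(spec, i)
            bold = TimeSeriesImage(np.zeros((2, 2, 2, spec.n_volumes)),
                                   np.eye(4), tr=2.0)
            mask = ImageVolume(np.ones((2, 2, 2), np.uint8), np.eye(4))
            subjects.append(ConnectomeSubject(f"s{i}", bold, motion,
                                              {"brain": mask}))
        retained, excluded = qc_filter(subjects)
        assert len(retained) == 100
        assert len(excluded) == 7
        assert {s.subject_id for s in excluded} == {f"s{i}" for i in range(7)}

    def test_boundaries_are_strict(self):
        t = 40
        # exactly 50 % of volumes above threshold -> retained
        m = np.zeros((t, 6))
        m[:, 0] = np.concatenate([np.arange(21), np.full(19, 20.0)]) * 0.6
        fd = compute_fd(m)
        assert (fd > 0.5).mean() == 0.5
        retained, _ = qc_filter([_subject_with_motion(m)])
        assert retained
        # FD exactly at 0.5 mm everywhere -> retained
        m2 = np.zeros((t, 6))
        m2[:, 0] = np.arange(t) * 0.5
        fd2 = compute_fd(m2)
        assert np.all(fd2[1:] == 0.5)
        retained2, _ = qc_filter([_subject_with_motion(m2)])
        assert retained2


class TestRegressions:
    def _bold(self, data):
        return TimeSeriesImage(data, np.eye(4), tr=2.0)

    def test_motion_combination_removed(self, rng):
        t = 60
        motion = rng.normal(size=(t, 6))
        coef = rng.normal(size=6)
        course = motion @ coef + 5.0
        data = np.tile(course, (2, 2, 2, 1))
        out = regress_motion(self._bold(data), motion)
        assert out.data[0, 0, 0].var() < 1e-10 * course.var()
        assert out.data[0, 0, 0].mean() == pytest.approx(course.mean())

    def test_orthogonal_course_untouched(self, rng):
        t = 120
        motion = rng.normal(size=(t, 6))
        design = np.column_stack([np.ones(t), np.linspace(-1, 1, t), motion])
        x = rng.normal(size=t)
        x -= design @ np.linalg.lstsq(design, x, rcond=None)[0]  # orthogonalize
        data = np.tile(x, (1, 1, 1, 1))
        out = regress_motion(self._bold(data), motion)
        r = np.corrcoef(out.data[0, 0, 0], x)[0, 1]
        assert r > 0.999

    def test_zero_motion_warns_rank_deficient_design(self, rng):
        t = 30
        data = rng.normal(size=(2, 2, 2, t))
        with pytest.warns(UserWarning, match="rank-deficient"):
            regress_motion(self._bold(data), np.zeros((t, 6)))

    def test_nuisance_exact_fit_and_global(self, rng):
        t = 50
        shape = (4, 4, 4)
        data = rng.normal(size=shape + (t,))
        csf = np.zeros(shape, np.uint8); csf[0, 0, 0] = 1
        wm = np.zeros(shape, np.uint8); wm[1, 0, 0] = 1
        csf_vol = ImageVolume(csf, np.eye(4))
        wm_vol = ImageVolume(wm, np.eye(4))
        # plant a voxel identical to the CSF course
        data[3, 3, 3] = data[0, 0, 0]
        out = nuisance_regress(self._bold(data), csf_vol, wm_vol,
                               global_signal=False)
        assert out.data[3, 3, 3].var() < 1e-10 * data[3, 3, 3].var()
        # with GSR on, a voxel equal to the global mean vanishes too
        # (fixed point: set the voxel to the mean of the *other* voxels)
        data2 = data.copy()
        flat = data2.reshape(-1, t)
        others_mean = (flat.sum(axis=0) - data2[2, 2, 2]) / (flat.shape[0] - 1)
        data2[2, 2, 2] = others_mean
        out2 = nuisance_regress(self._bold(data2), csf_vol, wm_vol,
                                global_signal=True)
        assert out2.data[2, 2, 2].var() < 1e-8 * others_mean.var()

    def test_nuisance_empty_mask_rejected(self, rng):
        data = rng.normal(size=(2, 2, 2, 30))
        empty = ImageVolume(np.zeros((2, 2, 2), np.uint8), np.eye(4))
        full = ImageVolume(np.ones((2, 2, 2), np.uint8), np.eye(4))
        with pytest.raises(ValueError, match="empty"):
            nuisance_regress(self._bold(data), empty, full)


class TestSmoothing:
    def test_impulse_response_fwhm_is_6mm(self):
        assert measure_smoothing_fwhm(6.0, n=61, spacing=1.0) == \
            pytest.approx(6.0, abs=0.2)

    def test_constant_volume_unchanged(self):
        vol = ImageVolume(np.full((40, 40, 40), 2.0), np.eye(4))
        out = smooth_spatial(vol, 6.0)
        inner = out.data[16:24, 16:24, 16:24]  # away from the zero boundary
        np.testing.assert_allclose(inner, 2.0, rtol=1e-6)

    def test_mass_preserved_away_from_boundary(self, rng):
        data = np.zeros((40, 40, 40))
        data[18:22, 18:22, 18:22] = rng.random((4, 4, 4))
        vol = ImageVolume(data, np.eye(4))
        out = smooth_spatial(vol, 6.0)
        assert out.data.sum() == pytest.approx(data.sum(), rel=1e-3)

    def test_anisotropic_spacing_per_axis(self):
        aff = np.diag([1.0, 2.0, 1.0, 1.0])
        data = np.zeros((41, 41, 41)); data[20, 20, 20] = 1.0
        out = smooth_spatial(ImageVolume(data, aff), 6.0)
        # the y axis has 2 mm voxels: the voxel-space profile is narrower
        px = out.data[:, 20, 20]
        py = out.data[20, :, 20]
        assert (px > px.max() / 2).sum() > (py > py.max() / 2).sum()


class TestTemporalFilter:
    def _sine_bold(self, freq, t=600, tr=2.0):
        x = np.sin(2 * np.pi * freq * np.arange(t) * tr)
        return TimeSeriesImage(np.tile(x, (1, 1, 1, 1)), np.eye(4), tr=tr), x

    def test_dc_removed(self):
        bold = TimeSeriesImage(np.full((2, 2, 2, 100), 7.0), np.eye(4), tr=2.0)
        out = temporal_filter(bold)
        assert np.var(out.data[0, 0, 0]) < 1e-10
        assert out.data[0, 0, 0].mean() == pytest.approx(7.0)

    def test_passband_preserved(self):
        bold, x = self._sine_bold(0.04)
        out = temporal_filter(bold)
        core = slice(100, 500)  # avoid filtfilt edge transients
        amp = out.data[0, 0, 0][core].std() / x[core].std()
        assert amp >= 0.9

    def test_single_pass_minus3db_at_high_cutoff(self):
        f = measure_filter_cutoff(tr=2.0, n_volumes=1200)
        assert f == pytest.approx(0.08, abs=0.005)

    def test_bad_cutoffs_rejected(self):
        bold, _ = self._sine_bold(0.04, t=50)
        with pytest.raises(ValueError):
            temporal_filter(bold, 0.08, 0.01)
        with pytest.raises(ValueError):
            temporal_filter(bold, 0.01, 0.3)  # above Nyquist at tr = 2


class TestMatrix:
    def test_shape_round_trip_and_masking(self, rng):
        shape = (5, 6, 4)
        t = 30
        data = rng.normal(size=shape + (t,))
        mask = (rng.random(shape) > 0.5).astype(np.uint8)
        bold = TimeSeriesImage(data, np.eye(4), tr=2.0)
        mat = build_matrix(bold, ImageVolume(mask, np.eye(4)), "s1")
        assert mat.values.shape == (mask.sum(), t)
        # matrix -> volume -> matrix round trip is exact
        vol = mat.to_volume(mat.values[:, 3])
        np.testing.assert_array_equal(vol.data[mask > 0], data[mask > 0, 3])
        assert np.all(vol.data[mask == 0] == 0)
        # masked-out voxels never appear
        i, j, k = mat.voxel_index.T
        assert np.all(mask[i, j, k] == 1)

    def test_x_fastest_ordering(self):
        mask = np.ones((2, 2, 2), np.uint8)
        bold = TimeSeriesImage(np.zeros((2, 2, 2, 2)), np.eye(4), tr=1.0)
        mat = build_matrix(bold, ImageVolume(mask, np.eye(4)))
        np.testing.assert_array_equal(
            mat.voxel_index,
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
             [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1]])

    def test_save_load_round_trip(self, rng, tmp_path):
        data = rng.normal(size=(3, 3, 3, 10))
        mask = np.ones((3, 3, 3), np.uint8)
        bold = TimeSeriesImage(data, np.eye(4), tr=2.5)
        mat = build_matrix(bold, ImageVolume(mask, np.eye(4)), "sx")
        from dbsmap.connectome import ConnectomeMatrix
        mat.save(tmp_path / "m.npz")
        back = ConnectomeMatrix.load(tmp_path / "m.npz")
        np.testing.assert_array_equal(back.values, mat.values)
        assert back.tr == 2.5 and back.subject_id == "sx"


class TestFullPipeline:
    def test_planted_network_recovery(self):
        """After full preprocessing, within-network voxel pairs correlate
        more strongly than between-network pairs (planted-truth check)."""
        spec = syn.ConnectomeSpec(n_subjects=6, n_violators=0, n_volumes=80,
                                  grid=(centered_grid((16, 20, 16), 5.0), (16, 20, 16)),
                                  network_amplitude=2.0, seed=12)
        maps = syn.network_spatial_maps(spec)
        within_all, between_all = [], []
        for i in range(spec.n_subjects):
            subj = syn.simulate_connectome_subject(spec, i)
            mat = preprocess_subject(subj)
            vals = {}
            for k, m in enumerate(maps[:2]):
                vi, vj, vk = mat.voxel_index.T
                weights = m.data[vi, vj, vk]
                top = np.argsort(weights)[-4:]  # 4 strongest voxels
                vals[k] = mat.values[top]
            def corr(a, b):
                return np.corrcoef(a, b)[0, 1]
            w = [corr(vals[0][p], vals[0][q]) for p in range(4) for q in range(p + 1, 4)]
            b = [corr(vals[0][p], vals[1][q]) for p in range(4) for q in range(4)]
            within_all.append(np.mean(w))
            between_all.append(np.mean(b))
        assert np.mean(within_all) - np.mean(between_all) > 0.2
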