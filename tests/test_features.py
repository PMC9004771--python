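"""CorrTF spectral ratios, Fisher z, frequency averaging, feature vectors."""

import numpy as np
import pytest

import corrtf
from corrtf.features import (
    EPS_CLIP,
    flatten_features,
    offdiag_edge_index,
)


@pytest.fixture()
def x130(rng):
    return rng.normal(size=130)


class TestCorrTFPair:
    def test_identity_ratio_is_one(self, x130):
        spec, guarded = corrtf.corrtf_pair(x130, x130)
        np.testing.assert_allclose(spec[~guarded], 1.0, atol=1e-9)

    def test_gain_two_gives_half(self, x130):
        spec, guarded = corrtf.corrtf_pair(x130, 2 * x130)
        np.testing.assert_allclose(spec[~guarded], 0.5, atol=1e-9)

    def test_circular_shift_matches_dft_shift_theorem(self, x130):
        d = 7
        T = x130.size
        y = np.roll(x130, d)  # y(t) = x(t - d) circularly
        spec, guarded = corrtf.corrtf_pair(x130, y)
        k = np.arange(T)
        expected = np.exp(2j * np.pi * k * d / T)
        np.testing.assert_allclose(spec[~guarded], expected[~guarded], atol=1e-9)
        np.testing.assert_allclose(np.abs(spec[~guarded]), 1.0, atol=1e-9)

    def test_length_mismatch_rejected(self, x130):
        with pytest.raises(ValueError, match="shapes"):
            corrtf.corrtf_pair(x130, x130[:-1])

    def test_all_zero_denominator_without_guard_errors(self, x130):
        with pytest.raises(ValueError, match="all-zero"):
            corrtf.corrtf_pair(x130, np.zeros_like(x130), guard=False)

    def test_guard_zeroes_negligible_denominator_bins(self):
        t = np.arange(64)
        y = np.sin(2 * np.pi * 4 * t / 64)  # single-bin spectrum
        x = np.sin(2 * np.pi * 5 * t / 64)
        spec, guarded = corrtf.corrtf_pair(x, y)
        assert guarded.sum() == 62  # all bins except +/- the tone
        np.testing.assert_array_equal(spec[guarded], 0.0)


class TestCorrTFTensor:
    def test_full_scale_tensor_shape(self):
        cfg = corrtf.SimConfig(
            groups=(corrtf.GroupSpec("NC", 1),), n_rois=116, n_timepoints=130, seed=2
        )
        ts = corrtf.generate_cohort(cfg).subjects[0][2]
        tensor = corrtf.corrtf_tensor(ts)
        assert tensor.values.shape == (116, 116, 130)

    def test_reciprocal_identity_at_unguarded_bins(self, band_signal):
        tensor = corrtf.corrtf_tensor(band_signal)
        v, g = tensor.values, tensor.guarded
        for i in range(tensor.n_rois):
            for j in range(tensor.n_rois):
                ok = ~(g[i, j] | g[j, i])
                np.testing.assert_allclose(
                    v[i, j, ok] * v[j, i, ok], 1.0, atol=1e-9
                )

    def test_diagonal_is_one_where_unguarded(self, band_signal):
        tensor = corrtf.corrtf_tensor(band_signal)
        for i in range(tensor.n_rois):
            ok = ~tensor.guarded[i, i]
            np.testing.assert_allclose(tensor.values[i, i, ok], 1.0, atol=1e-12)

    def test_gain_equivariance_under_row_scaling(self, band_signal):
        alpha = 2.5
        scaled = corrtf.ROITimeSeries(
            band_signal.values * np.where(np.arange(band_signal.n_rois) == 1, alpha, 1.0)[:, None],
            roi_ids=band_signal.roi_ids,
            tr_seconds=band_signal.tr_seconds,
        )
        t0 = corrtf.corrtf_tensor(band_signal)
        t1 = corrtf.corrtf_tensor(scaled)
        ok = ~(t0.guarded | t1.guarded)
        # numerator row 1 scales by alpha, denominator column 1 by 1/alpha
        np.testing.assert_allclose(
            np.abs(t1.values[1, 0, ok[1, 0]]),
            alpha * np.abs(t0.values[1, 0, ok[1, 0]]), atol=1e-9,
        )
        np.testing.assert_allclose(
            np.abs(t1.values[0, 1, ok[0, 1]]),
            np.abs(t0.values[0, 1, ok[0, 1]]) / alpha, atol=1e-9,
        )


class TestKernelRecovery:
    ZERO_SUM_KERNEL = (0.5, -0.2, -0.3)  # H(0) = 0, matching the guarded DC bin

    def _recovered_error(self, noise_sd, seed=21):
        ks = corrtf.KernelSpec(1, 2, self.ZERO_SUM_KERNEL, noise_sd=noise_sd)
        cfg = corrtf.SimConfig(
            groups=(corrtf.GroupSpec("NC", 1, (ks,)),),
            n_rois=4, n_timepoints=130, seed=seed,
        )
        ts = corrtf.generate_cohort(cfg).subjects[0][2]
        tensor = corrtf.corrtf_tensor(ts)
        hpad = np.zeros(130)
        hpad[:3] = self.ZERO_SUM_KERNEL
        H = np.abs(np.fft.fft(hpad))
        return np.abs(np.abs(tensor.values[1, 0]) - H)

    def test_noise_free_recovery_at_every_bin(self):
        assert self._recovered_error(0.0).max() < 1e-6

    def test_error_decreases_along_noise_ladder(self):
        maes = [self._recovered_error(sd).mean() for sd in (0.3, 0.1, 0.0)]
        assert maes[0] > maes[1] > maes[2]


class TestFisherZ:
    def test_arctanh_closed_forms(self):
        z = corrtf.fisher_z(np.array([0.0, 0.5], dtype=complex))
        assert z[0] == 0.0
        assert abs(z[1] - 0.5 * np.log(3.0)) < 1e-12

    def test_unit_magnitude_is_clipped_finite(self):
        z, n_clipped = corrtf.fisher_z(np.array([1.0 + 0j]), return_clip_count=True)
        assert np.isfinite(z[0])
        assert z[0] == pytest.approx(np.arctanh(1 - EPS_CLIP))
        assert n_clipped == 1

    def test_real_part_mode(self):
        z = corrtf.fisher_z(np.array([-0.5 + 0.2j]), mode="real")
        assert z[0] == pytest.approx(np.arctanh(-0.5))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            corrtf.fisher_z(np.zeros(2, dtype=complex), mode="imaginary")


class TestAverageOverFreq:
    def test_constant_tensor(self):
        z = np.full((3, 3, 8), 0.7)
        mat = corrtf.average_over_freq(z)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(mat.values[off], 0.7)
        np.testing.assert_array_equal(np.diag(mat.values), 0.0)
        assert mat.diagonal_excluded

    def test_two_bin_mean(self):
        z = np.zeros((2, 2, 2))
        z[0, 1] = [0.2, 0.6]
        assert corrtf.average_over_freq(z).values[0, 1] == pytest.approx(0.4)

    def test_band_limited_averaging_uses_inband_bins_only(self, band_signal):
        tensor = corrtf.corrtf_tensor(band_signal)
        z = corrtf.fisher_z(tensor)
        keep = (np.abs(tensor.freq_hz) >= 0.01) & (np.abs(tensor.freq_hz) <= 0.08)
        expected = z[:, :, keep].mean(axis=2)
        np.fill_diagonal(expected, 0.0)
        got = corrtf.average_over_freq(
            z, freq_hz=tensor.freq_hz, band=(0.01, 0.08)
        )
        np.testing.assert_allclose(got.values, expected, atol=1e-12)


class TestSubjectFeatures:
    def test_full_pipeline_matches_one_shot_oracle(self, band_signal):
        """Composed stages equal the single-expression brute-force computation."""
        F = np.fft.fft(band_signal.values, axis=1)
        R, T = F.shape
        oracle = np.zeros((R, R))
        for i in range(R):
            for j in range(R):
                if i == j:
                    continue
                mag = np.abs(F[j])
                dead = mag < 1e-8 * mag.max()
                ratio = np.where(dead, 0.0, np.abs(F[i]) / np.where(dead, 1.0, mag))
                oracle[i, j] = np.arctanh(np.clip(ratio, 0, 1 - 1e-6)).mean()
        fv = corrtf.subject_features(band_signal)
        off = ~np.eye(R, dtype=bool)
        np.testing.assert_allclose(fv.values, oracle[off], atol=1e-10)

    def test_feature_length_is_r_times_r_minus_one(self):
        cfg = corrtf.SimConfig(
            groups=(corrtf.GroupSpec("NC", 1),), n_rois=116, n_timepoints=130, seed=1
        )
        ts = corrtf.generate_cohort(cfg).subjects[0][2]
        fv = corrtf.subject_features(ts)
        assert len(fv.values) == 116 * 115 == 13340

    def test_identical_subjects_give_identical_vectors(self, band_signal):
        a = corrtf.subject_features(band_signal)
        b = corrtf.subject_features(band_signal)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.edge_index == b.edge_index

    def test_permuting_rois_permutes_edges_consistently(self, band_signal):
        perm = np.array([2, 0, 3, 1])
        permuted = corrtf.ROITimeSeries(
            band_signal.values[perm],
            roi_ids=[band_signal.roi_ids[p] for p in perm],
            tr_seconds=band_signal.tr_seconds,
        )
        fa = corrtf.subject_features(band_signal)
        fb = corrtf.subject_features(permuted)
        lookup = dict(zip(fb.edge_index, fb.values))
        for (a, b), v in zip(fa.edge_index, fa.values):
            assert lookup[(a, b)] == pytest.approx(v, abs=1e-12)


class TestTransformer:
    def test_transformer_matches_function_api(self, small_cohort):
        ts_list = [ts for _, _, ts in small_cohort.subjects][:4]
        tf = corrtf.CorrTFTransformer().fit(ts_list)
        X = tf.transform(ts_list)
        assert X.shape == (4, 16 * 15)
        np.testing.assert_allclose(X[0], corrtf.subject_features(ts_list[0]).values)

    def test_transformer_accepts_raw_arrays(self, band_signal):
        X3 = np.stack([band_signal.values, band_signal.values])
        tf = corrtf.CorrTFTransformer(tr_seconds=3.0).fit(X3)
        out = tf.transform(X3)
        np.testing.assert_allclose(out[0], out[1])

    def test_sklearn_param_round_trip(self):
        tf = corrtf.CorrTFTransformer(band_limited=True)
        assert corrtf.CorrTFTransformer(**tf.get_params()).band_limited


def test_edge_index_is_row_major_offdiagonal():
    assert offdiag_edge_index([1, 2, 3]) == [
        (1, 2), (1, 3), (2, 1), (2, 3), (3, 1), (3, 2)
    ]


def test_flatten_rejects_nothing_but_preserves_order():
    mat = corrtf.ConnectivityFeatureMatrix(
        np.array([[0.0, 1.0], [2.0, 0.0]]), roi_ids=[1, 2]
    )
    fv = flatten_features(mat)
    assert list(fv.values) == [1.0, 2.0]
    assert fv.edge_index == [(1, 2), (2, 1)]
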