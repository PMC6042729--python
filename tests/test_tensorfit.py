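import numpy as np
import pytest

from dtihist.core_io import DWIDataset, GradientScheme
from dtihist.phantom import MS, add_rician_noise, make_gradient_scheme, simulate_signal
from dtihist.tensorfit import (
    BMatrix,
    METHOD_CODES,
    build_bmatrix,
    estimate_noise_sigma,
    fit_tensor_lls,
    fit_tensor_restore,
    fit_tensor_wlls,
    rotate_bmatrix,
)

from conftest import random_psd_tensors


def _dataset_from_signals(signals, scheme):
    """Stack per-voxel measurement vectors (V, N) into a (V,1,1,N) dataset."""
    signals = np.atleast_2d(signals)
    return DWIDataset(signal=signals[:, None, None, :], affine=np.eye(4),
                      scheme=scheme)


def _tensor6_of(field, v):
    return field.tensor[v, 0, 0]


# ---------------------------------------------------------------------------
# b-matrix construction


class TestBuildBMatrix:
    def test_axis_gradient_row(self):
        scheme = GradientScheme(bvals=[0, 1000], bvecs=[[0, 0, 0], [1, 0, 0]])
        bm = BMatrix(bvals=scheme.bvals, bvecs=scheme.bvecs)
        np.testing.assert_allclose(bm.design[1], [1000, 0, 0, 0, 0, 0, 1])

    def test_diagonal_gradient_row(self):
        # direct evaluation of the convention: b*(gx^2, gy^2, gz^2, 2gxgy, ...)
        g = np.array([1, 1, 0]) / np.sqrt(2)
        scheme = GradientScheme(bvals=[0, 1000], bvecs=[[0, 0, 0], g])
        bm = BMatrix(bvals=scheme.bvals, bvecs=scheme.bvecs)
        np.testing.assert_allclose(bm.design[1], [500, 500, 0, 1000, 0, 0, 1],
                                   atol=1e-9)

    def test_b0_row_zero_except_intercept(self, bmatrix15):
        np.testing.assert_allclose(bmatrix15.design[0], [0, 0, 0, 0, 0, 0, 1])

    def test_full_rank_for_valid_scheme(self, bmatrix15):
        assert np.linalg.matrix_rank(bmatrix15.design) == 7

    def test_coplanar_scheme_rejected(self):
        # 8 in-plane directions: rank-deficient design
        angles = np.linspace(0, np.pi * 0.9, 8)
        bvecs = np.vstack([np.zeros(3),
                           np.stack([np.cos(angles), np.sin(angles),
                                     np.zeros(8)], axis=1)])
        scheme = GradientScheme(bvals=[0] + [1000] * 8, bvecs=bvecs)
        with pytest.raises(ValueError, match="rank"):
            build_bmatrix(scheme)


class TestRotateBMatrix:
    def test_identity_affine_is_noop(self, bmatrix15):
        rotated = rotate_bmatrix(bmatrix15, np.eye(4))
        np.testing.assert_allclose(rotated.design, bmatrix15.design, atol=1e-12)

    def test_pure_scaling_has_no_rotation(self, bmatrix15):
        affine = np.diag([1.1, 0.9, 1.0, 1.0])
        rotated = rotate_bmatrix(bmatrix15, affine)
        np.testing.assert_allclose(rotated.design, bmatrix15.design, atol=1e-12)

    def test_90deg_z_rotation_maps_x_to_y(self):
        scheme_x = GradientScheme(bvals=[0, 1000], bvecs=[[0, 0, 0], [1, 0, 0]])
        scheme_y = GradientScheme(bvals=[0, 1000], bvecs=[[0, 0, 0], [0, 1, 0]])
        affine = np.eye(4)
        affine[:3, :3] = [[0, -1, 0], [1, 0, 0], [0, 0, 1]]
        rotated = rotate_bmatrix(BMatrix(scheme_x.bvals, scheme_x.bvecs), affine)
        expected = BMatrix(scheme_y.bvals, scheme_y.bvecs)
        np.testing.assert_allclose(rotated.design, expected.design, atol=1e-12)

    def test_bvalues_unchanged(self, bmatrix15, rng):
        affine = np.eye(4)
        affine[:3, :3] = 1.3 * np.linalg.qr(rng.standard_normal((3, 3)))[0]
        rotated = rotate_bmatrix(bmatrix15, affine)
        np.testing.assert_array_equal(rotated.bvals, bmatrix15.bvals)

    def test_singular_affine_rejected(self, bmatrix15):
        affine = np.zeros((4, 4))
        with pytest.raises(ValueError, match="singular"):
            rotate_bmatrix(bmatrix15, affine)


# ---------------------------------------------------------------------------
# plain fits


class TestFitLLS:
    def test_isotropic_exact_recovery(self, scheme15, bmatrix15):
        d = 0.8 * MS
        s = simulate_signal(np.diag([d, d, d]), scheme15, s0=100.0)
        tf = fit_tensor_lls(_dataset_from_signals(s, scheme15), bmatrix15)
        np.testing.assert_allclose(_tensor6_of(tf, 0), [d, d, d, 0, 0, 0],
                                   atol=1e-10)
        assert tf.s0[0, 0, 0] == pytest.approx(100.0, rel=1e-10)

    def test_anisotropic_exact_recovery(self, scheme15, bmatrix15):
        truth = np.array([1.7, 0.3, 0.3, 0, 0, 0]) * MS
        s = simulate_signal(np.diag(truth[:3]), scheme15, s0=80.0)
        tf = fit_tensor_lls(_dataset_from_signals(s, scheme15), bmatrix15)
        np.testing.assert_allclose(_tensor6_of(tf, 0), truth, atol=1e-13)

    def test_six_measurement_scheme_rejected(self):
        scheme = GradientScheme(
            bvals=[0] + [1000] * 5,
            bvecs=np.vstack([np.zeros(3),
                             make_gradient_scheme(5 + 6, 1000, 1).bvecs[1:6]]))
        bm = BMatrix(scheme.bvals, scheme.bvecs)
        ds = _dataset_from_signals(np.ones(6) * 10, scheme)
        with pytest.raises(ValueError, match="at least 7"):
            fit_tensor_lls(ds, bm)

    def test_nonpositive_signals_clamped_and_flagged(self, scheme15, bmatrix15):
        s = simulate_signal(np.diag([1, 0.5, 0.5]) * MS, scheme15, 50.0)
        s[3] = 0.0
        tf = fit_tensor_lls(_dataset_from_signals(s, scheme15), bmatrix15)
        assert tf.clamped[0, 0, 0]
        assert tf.valid[0, 0, 0]


class TestFitWLLS:
    def test_noise_free_equals_lls(self, scheme15, bmatrix15, rng):
        t6, _ = random_psd_tensors(20, rng)
        signals = np.stack([
            simulate_signal(t, scheme15, 100.0) for t in t6])
        ds = _dataset_from_signals(signals, scheme15)
        a = fit_tensor_lls(ds, bmatrix15)
        b = fit_tensor_wlls(ds, bmatrix15)
        np.testing.assert_allclose(a.tensor, b.tensor, atol=1e-10)

    def test_all_equal_signals_zero_diffusivity(self, scheme15, bmatrix15):
        ds = _dataset_from_signals(np.full(16, 30.0), scheme15)
        tf = fit_tensor_wlls(ds, bmatrix15)
        np.testing.assert_allclose(_tensor6_of(tf, 0), np.zeros(6), atol=1e-12)
        assert tf.s0[0, 0, 0] == pytest.approx(30.0)

    def test_beats_lls_under_rician_noise(self, scheme15, bmatrix15):
        rng = np.random.default_rng(77)
        truth = np.array([1.0, 0.6, 0.6, 0, 0, 0]) * MS
        clean = simulate_signal(np.diag(truth[:3]), scheme15, 100.0)
        signals = add_rician_noise(np.tile(clean, (500, 1)), 5.0, rng)
        ds = _dataset_from_signals(signals, scheme15)
        lls = fit_tensor_lls(ds, bmatrix15)
        wlls = fit_tensor_wlls(ds, bmatrix15)
        err_lls = np.mean(np.sum((lls.tensor[:, 0, 0] - truth) ** 2, axis=1))
        err_wlls = np.mean(np.sum((wlls.tensor[:, 0, 0] - truth) ** 2, axis=1))
        assert err_wlls <= err_lls


# ---------------------------------------------------------------------------
# robust fit


class TestRestore:
    def test_noise_free_equals_wlls_no_outliers(self, scheme15, bmatrix15, rng):
        t6, _ = random_psd_tensors(10, rng)
        signals = np.stack([simulate_signal(t, scheme15, 100.0) for t in t6])
        ds = _dataset_from_signals(signals, scheme15)
        wlls = fit_tensor_wlls(ds, bmatrix15)
        restore = fit_tensor_restore(ds, bmatrix15, noise_sigma=1.0)
        np.testing.assert_allclose(restore.tensor, wlls.tensor, atol=1e-12)
        assert np.all(restore.outlier_count == 0)
        assert np.all(restore.method[restore.valid] == METHOD_CODES["restore"])

    def test_single_corrupted_measurement_recovered(self, scheme15, bmatrix15):
        truth = np.array([1.0, 0.6, 0.6, 0, 0, 0]) * MS
        clean = simulate_signal(np.diag(truth[:3]), scheme15, 100.0)
        corrupted = clean.copy()
        corrupted[5] *= 1.5
        ds = _dataset_from_signals(corrupted, scheme15)
        restore = fit_tensor_restore(ds, bmatrix15, noise_sigma=1.0)
        lls = fit_tensor_lls(ds, bmatrix15)
        assert restore.outlier_count[0, 0, 0] == 1
        rel = np.linalg.norm(_tensor6_of(restore, 0) - truth) / np.linalg.norm(truth)
        assert rel <= 1e-8
        rel_lls = np.linalg.norm(_tensor6_of(lls, 0) - truth) / np.linalg.norm(truth)
        assert rel_lls > 1e-3  # the plain fit is visibly biased

    def test_majority_corruption_falls_back(self, scheme15, bmatrix15):
        rng = np.random.default_rng(3)
        truth = np.diag([1.0, 0.6, 0.6]) * MS
        clean = simulate_signal(truth, scheme15, 100.0)
        corrupted = clean.copy()
        corrupted[1:11] *= rng.uniform(3.0, 20.0, 10)  # 10 of 16, inconsistent
        ds = _dataset_from_signals(corrupted, scheme15)
        restore = fit_tensor_restore(ds, bmatrix15, noise_sigma=1.0)
        assert restore.method[0, 0, 0] == METHOD_CODES["restore_fallback"]
        # fallback keeps the full-data WLLS tensor
        wlls = fit_tensor_wlls(ds, bmatrix15)
        np.testing.assert_allclose(restore.tensor, wlls.tensor, atol=1e-12)

    def test_requires_positive_sigma(self, scheme15, bmatrix15):
        ds = _dataset_from_signals(np.full(16, 10.0), scheme15)
        with pytest.raises(ValueError, match="noise_sigma"):
            fit_tensor_restore(ds, bmatrix15, noise_sigma=0.0)


class TestNoiseSigmaEstimator:
    def test_monte_carlo_accuracy(self):
        rng = np.random.default_rng(8)
        background = add_rician_noise(np.zeros((10 ** 4, 16)), 5.0, rng)
        mask = np.ones(10 ** 4, dtype=bool)
        sigma = estimate_noise_sigma(background, mask)
        assert sigma == pytest.approx(5.0, rel=0.02)

    def test_all_zero_background(self):
        sigma = estimate_noise_sigma(np.zeros((200, 16)), np.ones(200, dtype=bool))
        assert sigma == 0.0

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError, match="100"):
            estimate_noise_sigma(np.zeros((50, 16)), np.ones(50, dtype=bool))


# ---------------------------------------------------------------------------
# properties


class TestFitProperties:
    @pytest.mark.parametrize("fitter", ["lls", "wlls", "restore"])
    def test_exact_recovery_random_psd(self, scheme15, bmatrix15, fitter):
        rng = np.random.default_rng(99)
        t6, _ = random_psd_tensors(100, rng)
        signals = np.stack([simulate_signal(t, scheme15, 100.0) for t in t6])
        ds = _dataset_from_signals(signals, scheme15)
        if fitter == "lls":
            tf = fit_tensor_lls(ds, bmatrix15)
        elif fitter == "wlls":
            tf = fit_tensor_wlls(ds, bmatrix15)
        else:
            tf = fit_tensor_restore(ds, bmatrix15, noise_sigma=1.0)
        fitted = tf.tensor[:, 0, 0]
        norm = np.maximum(np.linalg.norm(t6, axis=1), 1e-30)
        rel = np.linalg.norm(fitted - t6, axis=1) / norm
        assert np.max(rel) <= 1e-8

    def test_rotation_consistency(self, scheme15, rng):
        # data measured with rotated gradients + rotated b-matrix recover
        # the tensor expressed in the unrotated frame
        angle = 0.7
        r = np.array([[np.cos(angle), -np.sin(angle), 0],
                      [np.sin(angle), np.cos(angle), 0],
                      [0, 0, 1]])
        affine = np.eye(4)
        affine[:3, :3] = r @ np.diag([1.05, 0.95, 1.0])  # rotation + scaling
        truth6, _ = random_psd_tensors(5, rng)
        bm = build_bmatrix(scheme15)
        bm_rot = rotate_bmatrix(bm, affine)
        rotated_scheme = GradientScheme(bvals=scheme15.bvals,
                                        bvecs=scheme15.bvecs @ r.T)
        signals = np.stack([simulate_signal(t, rotated_scheme, 100.0)
                            for t in truth6])
        ds = _dataset_from_signals(signals, scheme15)  # scheme only sets N
        tf = fit_tensor_lls(ds, bm_rot)
        np.testing.assert_allclose(tf.tensor[:, 0, 0], truth6, atol=1e-12)
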