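"""GLM fitting, contrasts, motion screening and VOI eigenvariate extraction."""

import numpy as np
import pandas as pd
import pytest

from valdcm.design import DesignMatrix, build_design_matrix
from valdcm.extraction import (
    DesignError,
    VoiExclusionError,
    contrast_vector,
    extract_voi,
    fit_glm,
    framewise_displacement,
    t_contrast,
)


def _design(mat, names=None):
    names = names or tuple(f"col_{i}" for i in range(mat.shape[1]))
    return DesignMatrix(matrix=mat, column_names=tuple(names))


class TestFitGlm:
    def test_exact_recovery_of_column_combination(self, rng):
        X = _design(rng.normal(size=(50, 3)))
        y = 2.0 * X.matrix[:, 0] + 3.0 * X.matrix[:, 1]
        fit = fit_glm(y, X)
        np.testing.assert_allclose(fit.betas, [2.0, 3.0, 0.0], atol=1e-10)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-18)

    def test_matches_pseudoinverse_oracle(self, rng):
        X = _design(rng.normal(size=(60, 4)))
        y = rng.normal(size=(60, 5))
        fit = fit_glm(y, X)
        expected = np.linalg.pinv(X.matrix) @ y
        np.testing.assert_allclose(fit.betas, expected, atol=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        base = rng.normal(size=(30, 2))
        X = _design(np.column_stack([base, base[:, 0]]), ("a", "b", "dup"))
        with pytest.raises(DesignError, match="collinear"):
            fit_glm(rng.normal(size=30), X)

    def test_row_mismatch_rejected(self, rng):
        X = _design(rng.normal(size=(30, 2)))
        with pytest.raises(DesignError, match="rows"):
            fit_glm(rng.normal(size=29), X)

    def test_intercept_absorbs_constant_offset(self, rng):
        X = _design(
            np.column_stack([rng.normal(size=(80, 3)), np.ones(80)]),
            ("a", "b", "c", "constant"),
        )
        y = rng.normal(size=80)
        f1 = fit_glm(y, X)
        f2 = fit_glm(y + 7.5, X)
        np.testing.assert_allclose(f1.betas[:3], f2.betas[:3], atol=1e-9)
        assert f2.betas[3] - f1.betas[3] == pytest.approx(7.5, abs=1e-9)


class TestTContrast:
    def test_noise_free_unit_contrast_is_infinite(self, rng):
        X = _design(rng.normal(size=(40, 2)))
        y = X.matrix[:, 0]
        fit = fit_glm(y, X)
        t, p = t_contrast(fit, np.array([1.0, 0.0]))
        assert np.isinf(t) and t > 0
        assert p == 0.0

    def test_zero_estimate_with_zero_variance_errors(self, rng):
        X = _design(rng.normal(size=(40, 2)))
        fit = fit_glm(X.matrix[:, 0], X)
        with pytest.raises(FloatingPointError):
            t_contrast(fit, np.array([0.0, 1.0]))

    def test_zero_contrast_rejected(self, rng):
        X = _design(rng.normal(size=(40, 2)))
        fit = fit_glm(rng.normal(size=40), X)
        with pytest.raises(ValueError, match="zero"):
            t_contrast(fit, np.zeros(2))

    def test_type_one_error_calibration(self, rng):
        """Null simulation: rejection rate at alpha = 0.05 stays near 0.05."""
        X = _design(rng.normal(size=(40, 3)))
        c = np.array([1.0, 0.0, 0.0])
        Y = rng.normal(size=(40, 1000))
        fit = fit_glm(Y, X)
        t, p = t_contrast(fit, c)
        rate = np.mean(p < 0.05)
        assert 0.03 <= rate <= 0.07

    def test_matches_scipy_regression_t(self, rng):
        import scipy.stats as sps

        x = rng.normal(size=30)
        y = 0.3 * x + rng.normal(size=30)
        X = _design(np.column_stack([x, np.ones(30)]), ("x", "const"))
        fit = fit_glm(y, X)
        t, p = t_contrast(fit, np.array([1.0, 0.0]))
        res = sps.linregress(x, y)
        # dof differ by conventions? both n-2 here
        assert t == pytest.approx(res.slope / res.stderr, rel=1e-10)


class TestFramewiseDisplacement:
    def test_constant_motion_gives_zero(self):
        fd = framewise_displacement(np.tile([1, 2, 3, 0.1, 0.2, 0.3], (20, 1)))
        assert np.all(fd.fd == 0)
        assert not fd.flagged

    def test_single_translation_step(self):
        motion = np.zeros((10, 6))
        motion[5:, 0] = 0.1
        fd = framewise_displacement(motion)
        assert fd.fd[5] == pytest.approx(0.1)
        assert np.sum(fd.fd) == pytest.approx(0.1)

    def test_rotation_converted_at_50mm(self):
        motion = np.zeros((10, 6))
        motion[3:, 4] = 0.002
        fd = framewise_displacement(motion)
        assert fd.fd[3] == pytest.approx(0.002 * 50)

    def test_offset_invariance(self, rng):
        motion = rng.normal(size=(50, 6)) * 0.01
        fd1 = framewise_displacement(motion)
        fd2 = framewise_displacement(motion + np.array([1, -2, 3, 0.1, 0.2, -0.1]))
        np.testing.assert_allclose(fd1.fd, fd2.fd, atol=1e-12)

    def test_high_motion_flagged(self, rng):
        steps = rng.normal(0, 0.3, size=(100, 6))
        fd = framewise_displacement(np.cumsum(steps, axis=0))
        assert fd.flagged

    def test_wrong_column_count_rejected(self, rng):
        with pytest.raises(ValueError, match="6"):
            framewise_displacement(rng.normal(size=(10, 5)))


def _voxel_table(offsets, series):
    frame = pd.DataFrame(series, columns=[f"vol_{t}" for t in range(series.shape[1])])
    frame.insert(0, "dz_mm", offsets[:, 2])
    frame.insert(0, "dy_mm", offsets[:, 1])
    frame.insert(0, "dx_mm", offsets[:, 0])
    return frame


@pytest.fixture(scope="module")
def glm_setup():
    from valdcm.design import build_block_schedule

    design = build_block_schedule()
    X = build_design_matrix(design)
    c = contrast_vector(X, {"all_faces": 1.0, "shapes": -1.0})
    signal = X.column("all_faces") - X.column("shapes")
    return X, c, signal


class TestExtractVoi:

    def test_rank_one_voi_recovers_series(self, glm_setup, rng):
        X, c, signal = glm_setup
        offsets = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2]], float)
        series = np.tile(signal, (4, 1)) + rng.normal(0, 1e-4, (4, signal.size))
        voi = extract_voi(_voxel_table(offsets, series), X, c)
        assert voi.explained_variance_fraction > 0.99
        cen = signal - signal.mean()
        cos = abs(cen @ voi.eigenvariate) / (
            np.linalg.norm(cen) * np.linalg.norm(voi.eigenvariate)
        )
        assert cos > 0.999

    def test_no_active_voxels_raises_exclusion(self, glm_setup, rng):
        X, c, _ = glm_setup
        offsets = np.zeros((3, 3))
        series = rng.normal(size=(3, X.n_volumes))
        with pytest.raises(VoiExclusionError) as err:
            extract_voi(
                _voxel_table(offsets, series), X, c, subject_id="sub-07",
                region="LPFC", threshold_p=1e-6,
            )
        assert err.value.subject_id == "sub-07"
        assert err.value.region == "LPFC"

    def test_sign_aligned_with_voi_mean(self, glm_setup, rng):
        """Anticorrelated voxel groups: the eigenvariate follows the majority
        mean, deterministically."""
        X, c, signal = glm_setup
        offsets = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0]], float)
        noise = rng.normal(0, 0.01, (3, signal.size))
        series = np.vstack([signal, signal, -0.5 * signal]) + noise
        voi = extract_voi(_voxel_table(offsets, series), X, c)
        mean_series = series.mean(axis=0) - series.mean()
        assert np.corrcoef(voi.eigenvariate, series.mean(axis=0))[0, 1] > 0

    def test_center_constrained_to_search_radius(self, glm_setup, rng):
        X, c, signal = glm_setup
        # best voxel outside the 12-mm search sphere must be ignored
        offsets = np.array([[0, 0, 0], [20, 0, 0]], float)
        weak = 0.3 * signal + rng.normal(0, 0.5, signal.size)
        strong = signal
        series = np.vstack([weak, strong])
        voi = extract_voi(_voxel_table(offsets, series), X, c, voi_radius=6.0)
        assert np.linalg.norm(voi.center_offset) <= 12.0
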