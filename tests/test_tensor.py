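"""Tensor fit: exactness on noise-free data, rotation sanity, clamping,
noise behaviour, and ROI diffusivity extraction."""

import numpy as np
import pytest

import dtialps as da
from dtialps.errors import ExtractionError, ValidationError
from dtialps.tensor import design_matrix

from conftest import uniform_field


def signals_from_tensor(scheme, d6, s0=1000.0):
    """Closed-form monoexponential signal for one tensor, all volumes."""
    B = design_matrix(scheme)
    return s0 * np.exp(-(B @ np.asarray(d6)))


def dwi_from_tensors(grid, scheme, d6_array, s0=1000.0):
    B = design_matrix(scheme)
    data = s0 * np.exp(-(d6_array.reshape(-1, 6) @ B.T))
    return da.DWIVolume(
        data=data.reshape(grid.shape + (scheme.n_volumes,)), grid=grid, gradients=scheme
    )


class TestNoiseFreeExactness:
    @pytest.mark.parametrize(
        "d6",
        [
            (1.2e-3, 0.8e-3, 0.7e-3, 0, 0, 0),
            (0.8e-3, 0.8e-3, 0.8e-3, 0, 0, 0),
            (1.1e-3, 0.9e-3, 0.6e-3, 1e-4, -5e-5, 8e-5),
        ],
    )
    def test_recovery_to_1e9(self, tiny_grid, scheme, d6):
        truth = np.tile(np.asarray(d6), tiny_grid.shape + (1,))
        dwi = dwi_from_tensors(tiny_grid, scheme, truth)
        field = da.fit_dti(dwi)
        assert np.max(np.abs(field.components - truth)) < 1e-9

    def test_isotropic_offdiagonals_vanish(self, tiny_grid, scheme):
        truth = np.zeros(tiny_grid.shape + (6,))
        truth[..., :3] = 0.8e-3
        field = da.fit_dti(dwi_from_tensors(tiny_grid, scheme, truth))
        assert np.max(np.abs(field.components[..., 3:])) < 1e-12
        assert np.allclose(field.components[..., :3], 0.8e-3, atol=1e-12)

    def test_residual_norm_tiny(self, tiny_grid, scheme):
        rng = np.random.default_rng(0)
        diag = rng.uniform(0.4e-3, 1.5e-3, tiny_grid.shape + (3,))
        truth = np.concatenate([diag, np.zeros(tiny_grid.shape + (3,))], axis=-1)
        dwi = dwi_from_tensors(tiny_grid, scheme, truth)
        field = da.fit_dti(dwi)
        B = design_matrix(scheme)
        y = np.log(1000.0 / dwi.data.reshape(-1, 36))
        resid = y - field.components.reshape(-1, 6) @ B.T
        assert np.max(np.linalg.norm(resid, axis=1)) < 1e-10


def test_rotation_leaves_eigenvalues_unchanged(tiny_grid, scheme):
    """Rotating gradients and tensor by the same rotation is a no-op on the
    eigenvalue spectrum."""
    from scipy.spatial.transform import Rotation

    R = Rotation.from_euler("xyz", [31, -17, 55], degrees=True).as_matrix()
    D = np.diag([1.4e-3, 0.7e-3, 0.5e-3])
    Drot = R @ D @ R.T

    def as6(M):
        return np.array([M[0, 0], M[1, 1], M[2, 2], M[0, 1], M[0, 2], M[1, 2]])

    rot_scheme = da.GradientScheme(bvals=scheme.bvals, bvecs=scheme.bvecs @ R.T)
    fit_a = da.fit_dti(dwi_from_tensors(tiny_grid, scheme, np.tile(as6(D), tiny_grid.shape + (1,))))
    fit_b = da.fit_dti(dwi_from_tensors(tiny_grid, rot_scheme, np.tile(as6(Drot), tiny_grid.shape + (1,))))

    def eigs(field):
        c = field.components[0, 0, 0]
        M = np.array([[c[0], c[3], c[4]], [c[3], c[1], c[5]], [c[4], c[5], c[2]]])
        return np.sort(np.linalg.eigvalsh(M))

    assert np.allclose(eigs(fit_a), eigs(fit_b), atol=1e-9)


class TestRobustness:
    def test_all_zero_voxel_masked_not_fatal(self, tiny_grid, scheme):
        truth = np.zeros(tiny_grid.shape + (6,))
        truth[..., :3] = 0.8e-3
        dwi = dwi_from_tensors(tiny_grid, scheme, truth)
        data = dwi.data.copy()
        data[0, 0, 0, :] = 0.0
        dwi = da.DWIVolume(data=data, grid=tiny_grid, gradients=scheme)
        field = da.fit_dti(dwi)
        assert not field.mask[0, 0, 0]
        assert field.mask.sum() == np.prod(tiny_grid.shape) - 1

    def test_collinear_scheme_rejected_at_entry(self, tiny_grid):
        base = np.array([1.0, 2.0, 3.0])
        base /= np.linalg.norm(base)
        with pytest.raises(ValidationError):
            scheme = da.GradientScheme(
                bvals=np.array([0] + [1000] * 6, dtype=float),
                bvecs=np.vstack([[0, 0, 0]] + [base] * 6),
            )
            da.fit_dti(dwi_from_tensors(tiny_grid, scheme, np.zeros(tiny_grid.shape + (6,))))

    def test_clamp_count_equals_negative_diagonal_fits(self, tiny_grid, scheme):
        rng = np.random.default_rng(7)
        truth = np.zeros(tiny_grid.shape + (6,))
        truth[..., :3] = 5e-5  # near-zero diffusivity: noise drives fits negative
        B = design_matrix(scheme)
        data = 1000.0 * np.exp(-(truth.reshape(-1, 6) @ B.T))
        data += rng.normal(0, 30.0, data.shape)
        data = np.clip(data, 0, None)
        dwi = da.DWIVolume(
            data=data.reshape(tiny_grid.shape + (36,)), grid=tiny_grid, gradients=scheme
        )
        field = da.fit_dti(dwi)
        # independent recount: unclamped OLS fit per voxel
        pinv = np.linalg.pinv(B)
        s0 = data[:, :6].mean(axis=1)
        y = np.log(s0[:, None] / np.maximum(data, 1e-6 * s0[:, None]))
        raw = y @ pinv.T
        expected = int((raw[:, :3] < 0).any(axis=1).sum())
        assert field.n_clamped == expected > 0
        assert np.all(field.components[..., :3] >= 0)

    def test_rician_noise_component_error_bounded(self, scheme):
        """Monte-Carlo: at SNR 50 the median absolute diagonal-component
        error over 1000 voxels stays below 5e-5 mm^2/s."""
        grid = da.VolumeGrid((10, 10, 10), (2, 2, 2), np.diag([2, 2, 2, 1.0]))
        truth = np.zeros(grid.shape + (6,))
        truth[..., 0], truth[..., 1], truth[..., 2] = 1.2e-3, 0.8e-3, 0.7e-3
        B = design_matrix(scheme)
        clean = 1000.0 * np.exp(-(truth.reshape(-1, 6) @ B.T))
        rng = np.random.default_rng(11)
        sigma = 1000.0 / 50.0
        noisy = np.sqrt(
            (clean + rng.normal(0, sigma, clean.shape)) ** 2
            + rng.normal(0, sigma, clean.shape) ** 2
        )
        dwi = da.DWIVolume(
            data=noisy.reshape(grid.shape + (36,)), grid=grid, gradients=scheme
        )
        field = da.fit_dti(dwi)
        err = np.abs(field.components[..., :3] - truth[..., :3])
        assert np.median(err) < 5e-5


class TestAxisDiffusivities:
    def test_uniform_field(self, tiny_grid):
        field = uniform_field(tiny_grid, 0.8e-3, 0.8e-3, 0.8e-3)
        mask = np.zeros(tiny_grid.shape, dtype=bool)
        mask[2:4, 2:4, 2:4] = True
        assert da.axis_diffusivities(field, mask) == pytest.approx(
            (0.8e-3, 0.8e-3, 0.8e-3), rel=1e-14
        )

    def test_single_voxel(self, tiny_grid):
        field = uniform_field(tiny_grid, 1e-3, 2e-3, 3e-3)
        field.components[1, 2, 3, :3] = (4e-3, 5e-3, 6e-3)
        mask = np.zeros(tiny_grid.shape, dtype=bool)
        mask[1, 2, 3] = True
        assert da.axis_diffusivities(field, mask) == (4e-3, 5e-3, 6e-3)

    def test_half_and_half_averages(self, tiny_grid):
        field = uniform_field(tiny_grid, 1.0e-3, 1.0e-3, 1.0e-3)
        field.components[3:, :, :, :3] = 2.0e-3
        mask = np.zeros(tiny_grid.shape, dtype=bool)
        mask[2, 1, 1] = True  # one voxel at 1.0e-3
        mask[4, 1, 1] = True  # one voxel at 2.0e-3
        assert da.axis_diffusivities(field, mask) == pytest.approx(
            (1.5e-3, 1.5e-3, 1.5e-3), rel=1e-12
        )

    def test_empty_intersection_raises(self, tiny_grid):
        field = uniform_field(tiny_grid, 1e-3, 1e-3, 1e-3)
        with pytest.raises(ExtractionError):
            da.axis_diffusivities(field, np.zeros(tiny_grid.shape, dtype=bool))
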