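"""LCMV beamformer: covariance estimation, unit-gain constraint, closed-form
identity-covariance limit, localization of a simulated dipole, and virtual
electrodes."""

import numpy as np
import pytest

from iedmap.beamformer import data_covariance, lcmv_weights, virtual_electrode
from iedmap.containers import Recording
from iedmap.exceptions import DomainError, ParameterError
from iedmap.forward import dipole_field


class TestDataCovariance:
    def test_white_channels_near_identity(self, rng):
        x = rng.standard_normal((8, 18000))
        cov = data_covariance(Recording(data=x, fs=150.0))
        C = cov.matrix
        np.testing.assert_allclose(np.diag(C), 1.0, atol=0.05)
        off = C - np.diag(np.diag(C))
        assert np.max(np.abs(off)) < 0.05

    def test_single_active_channel_rank_one(self, rng):
        x = np.zeros((6, 3000))
        x[2] = rng.standard_normal(3000)
        cov = data_covariance(Recording(data=x, fs=150.0))
        assert cov.rank == 1

    def test_band_against_nyquist(self, rng):
        rec = Recording(data=rng.standard_normal((4, 1500)), fs=150.0)
        data_covariance(rec, band=(20.0, 70.0))  # valid
        with pytest.raises(ParameterError):
            data_covariance(rec, band=(20.0, 100.0))

    def test_short_window_warns_empty_errors(self, rng):
        rec = Recording(data=rng.standard_normal((4, 1500)), fs=150.0)
        with pytest.warns(UserWarning):
            data_covariance(rec, window=(0.0, 0.5))
        with pytest.raises(ParameterError):
            data_covariance(rec, window=(1.0, 1.0))


class TestLcmvWeights:
    def test_unit_gain_constraint(self, leadfield10, rng):
        C = np.cov(rng.standard_normal((32, 4000)))
        cov = data_covariance(Recording(data=rng.standard_normal((32, 4000)), fs=150.0))
        w = lcmv_weights(leadfield10, cov)
        L = leadfield10.values[w.valid]
        basis = leadfield10.basis[w.valid]
        # gain of each weight vector on its own oriented leadfield
        theta = np.einsum("vdj,vd->vj", basis, w.orientations[w.valid])
        gains = np.einsum("vc,vcj,vj->v", w.weights[w.valid], L, theta)
        np.testing.assert_allclose(gains, 1.0, atol=1e-8)

    def test_identity_covariance_closed_form(self, leadfield10):
        """At C = I the beamformer reduces to the matched filter L th/|L th|^2."""
        from iedmap.beamformer import CovarianceSpec
        n = 32
        cov = CovarianceSpec(matrix=np.eye(n), band=None, window=None, rank=n)
        w = lcmv_weights(leadfield10, cov)
        v = leadfield10.n_voxels // 2
        L = leadfield10.values[v]
        theta = np.einsum("dj,d->j", leadfield10.basis[v], w.orientations[v])
        l_vec = L @ theta
        np.testing.assert_allclose(w.weights[v], l_vec / (l_vec @ l_vec), atol=1e-10)

    def test_localizes_simulated_dipole(self, grid10, leadfield10, conductor, sensors32, rng):
        """Peak projected variance falls on the true source voxel (within one
        10 mm grid step) for a strong simulated dipole in white sensor noise.

        The noise floor is kept well below the source power so the
        depth-dependent noise amplification of the unregularized beamformer
        does not dominate the (unnormalized) power map.
        """
        masked = grid10.positions[grid10.inside_mask]
        v_true = int(np.argmin(np.linalg.norm(masked - np.array([0.02, 0.03, 0.05]), axis=1)))
        pos = masked[v_true]
        field = dipole_field(pos, 40.0 * leadfield10.basis[v_true, :, 0], conductor, sensors32)
        src = rng.standard_normal(3000)
        noise_rms = 0.02 * np.max(np.abs(field))
        data = np.outer(field, src) + noise_rms * rng.standard_normal((32, 3000))
        cov = data_covariance(Recording(data=data, fs=150.0))
        w = lcmv_weights(leadfield10, cov)
        var = np.einsum("vc,cd,vd->v", w.weights, cov.matrix, w.weights)
        var[~w.valid] = -np.inf
        best = masked[np.argmax(var)]
        assert np.linalg.norm(best - pos) <= 0.010 + 1e-9

    def test_rank_deficient_covariance_rejected(self, leadfield10):
        from iedmap.beamformer import CovarianceSpec
        cov = CovarianceSpec(matrix=np.zeros((32, 32)), band=None, window=None, rank=0)
        with pytest.raises(DomainError):
            lcmv_weights(leadfield10, cov)


class TestVirtualElectrode:
    def test_one_hot_weights_return_channel(self, leadfield10, rng):
        from iedmap.beamformer import BeamformerWeights, CovarianceSpec
        n = 32
        W = np.zeros((leadfield10.n_voxels, n))
        W[:, 5] = 1.0
        bw = BeamformerWeights(
            weights=W, orientations=np.zeros((leadfield10.n_voxels, 3)),
            valid=np.ones(leadfield10.n_voxels, bool), leadfield=leadfield10,
            cov=CovarianceSpec(matrix=np.eye(n), band=None, window=None, rank=n),
            voxel_indices=np.arange(leadfield10.n_voxels))
        rec = Recording(data=rng.standard_normal((n, 500)), fs=150.0)
        trace = virtual_electrode(bw, rec, voxel=3)
        np.testing.assert_array_equal(trace, rec.data[5])

    def test_zero_data_zero_trace(self, leadfield10):
        from iedmap.beamformer import CovarianceSpec
        cov = CovarianceSpec(matrix=np.eye(32), band=None, window=None, rank=32)
        w = lcmv_weights(leadfield10, cov)
        rec = Recording(data=np.zeros((32, 100)), fs=150.0)
        assert np.all(virtual_electrode(w, rec, voxel=0) == 0)

    def test_scale_equivariance(self, leadfield10, rng):
        x = rng.standard_normal((32, 2000))
        cov = data_covariance(Recording(data=x, fs=150.0))
        w = lcmv_weights(leadfield10, cov)
        t1 = virtual_electrode(w, Recording(data=x, fs=150.0), voxel=10)
        t2 = virtual_electrode(w, Recording(data=3.0 * x, fs=150.0), voxel=10)
        np.testing.assert_allclose(t2, 3.0 * t1, rtol=1e-12)

    def test_invalid_voxel_rejected(self, leadfield10, rng):
        x = rng.standard_normal((32, 2000))
        cov = data_covariance(Recording(data=x, fs=150.0))
        w = lcmv_weights(leadfield10, cov)
        with pytest.raises(ParameterError):
            virtual_electrode(w, Recording(data=x, fs=150.0), voxel=10**6)
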