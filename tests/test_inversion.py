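"""EBB inversion: covariance, beamformer prior, ReML fit, source estimates."""

import numpy as np
import pytest
from scipy import linalg

from opmarray.forward import leadfield_sphere, SourceSpace
from opmarray.inversion import (DataMatrix, EmpiricalBayesBeamformer,
                                ebb_prior, estimate_sources,
                                sample_covariance)


@pytest.fixture(scope="module")
def toy_leadfield(cap_array, tangential_sources, sphere_head):
    return leadfield_sphere(cap_array, tangential_sources, sphere_head)


class TestSampleCovariance:
    def test_unit_spike_per_channel(self):
        nc = 5
        Y = np.eye(nc)  # one unit spike per channel, Nt = Nc
        C = sample_covariance(Y)
        assert np.allclose(C, np.eye(nc) / nc)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(4, 100))
        C = sample_covariance(Y)
        ref = sum(np.outer(y, y) for y in Y.T) / 100
        assert np.allclose(C, ref, atol=1e-15)

    def test_symmetric_psd(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(6, 30))
        C = sample_covariance(Y)
        assert np.allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() >= -1e-18

    def test_channel_normalizer(self):
        Y = np.random.default_rng(2).normal(size=(4, 50))
        assert np.allclose(sample_covariance(Y, "Nc") * 4,
                           sample_covariance(Y, "Nt") * 50)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sample_covariance(np.empty((3, 0)))


class TestEBBPrior:
    def test_symmetric_case_constant(self):
        # orthogonal equal-norm columns, white covariance -> flat prior
        L = np.eye(6) * 3.0
        gamma = ebb_prior(L, 2.0 * np.eye(6))
        assert np.allclose(gamma, 1.0)

    def test_scale_invariance(self, toy_leadfield):
        C = sample_covariance(
            np.random.default_rng(3).normal(size=(13, 200)) * 1e-13)
        g1 = ebb_prior(toy_leadfield, C)
        g2 = ebb_prior(toy_leadfield, 7.3 * C)
        assert np.allclose(g1, g2, rtol=1e-12)

    def test_per_source_beamformer_oracle(self):
        rng = np.random.default_rng(4)
        L = rng.normal(size=(3, 5))
        C = sample_covariance(rng.normal(size=(3, 50)))
        gamma = ebb_prior(L, C, normalize="none")
        Ci = np.linalg.inv(C)
        for d in range(5):
            power = 1.0 / (L[:, d] @ Ci @ L[:, d])
            assert gamma[d] == pytest.approx(power, rel=1e-12)

    def test_singular_covariance_guidance(self):
        L = np.random.default_rng(5).normal(size=(4, 6))
        C = np.outer([1, 2, 3, 4.0], [1, 2, 3, 4.0])  # rank one
        with pytest.raises(np.linalg.LinAlgError):
            ebb_prior(L, C, regularization=0.0)
        gamma = ebb_prior(L, C, regularization=0.05)
        assert np.all(np.isfinite(gamma))


class TestHyperparameterFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(6)
        nc, nd, nt = 13, 40, 10_000
        L = rng.normal(size=(nc, nd)) * 1e-13
        gamma = rng.uniform(0.5, 2.0, nd)
        gamma /= gamma.mean()
        a, b = (2e-13) ** 2, 3.0
        C_true = a * np.eye(nc) + b * (L * gamma) @ L.T
        Y = np.linalg.cholesky(C_true) @ rng.normal(size=(nc, nt))
        res = EmpiricalBayesBeamformer(Y, L, gamma=gamma, n_eff=None).fit()
        assert res.converged
        assert res.params[0] == pytest.approx(a, rel=0.10)
        assert res.params[1] == pytest.approx(b, rel=0.10)

    def test_pure_noise_shrinks_source_term(self, toy_leadfield):
        rng = np.random.default_rng(7)
        Y = 2e-13 * rng.normal(size=(13, 2000))
        full = EmpiricalBayesBeamformer(Y, toy_leadfield, n_eff=None).fit()
        noise = EmpiricalBayesBeamformer(Y, toy_leadfield, n_eff=None,
                                         noise_only=True).fit()
        # source variance collapses and the extra component earns < 3 nats
        assert full.params[1] < 1e-3 * full.params[0] / np.trace(
            full.model.components[1]) * 13 or full.params[1] < full.params[0]
        assert full.free_energy - noise.free_energy < 3.0

    def test_scale_equivariance(self, toy_leadfield):
        rng = np.random.default_rng(8)
        v = toy_leadfield.matrix[:, 3]
        Y = np.outer(v, np.sin(np.linspace(0, 20, 300))) * 1e-9 \
            + 1e-13 * rng.normal(size=(13, 300))
        r1 = EmpiricalBayesBeamformer(Y, toy_leadfield, n_eff=None).fit()
        r2 = EmpiricalBayesBeamformer(2 * Y, toy_leadfield, n_eff=None).fit()
        assert np.allclose(r2.params, 4.0 * r1.params, rtol=0.02)
        j1 = r1.source_estimate().J
        j2 = r2.source_estimate().J
        assert np.allclose(j2, 2.0 * j1, rtol=0.02, atol=1e-18)

    def test_summary_mentions_hyperparameters(self, toy_leadfield):
        Y = np.random.default_rng(9).normal(size=(13, 100)) * 1e-13
        res = EmpiricalBayesBeamformer(Y, toy_leadfield).fit()
        text = res.summary()
        assert "free energy" in text and "lambda_1" in text


class TestSourceEstimate:
    def test_zero_data_zero_sources(self, toy_leadfield):
        rng = np.random.default_rng(10)
        Y = rng.normal(size=(13, 50)) * 1e-13
        res = EmpiricalBayesBeamformer(Y, toy_leadfield).fit()
        est = estimate_sources(np.zeros((13, 20)), res.cov_model,
                               toy_leadfield)
        assert np.all(est.J == 0)

    def test_noiseless_single_source_peaks_at_truth(self, toy_leadfield,
                                                    tangential_sources):
        true_d = 17
        s = np.sin(2 * np.pi * 10 * np.arange(300) / 1000.0) * 1e-8
        Y = np.outer(toy_leadfield.matrix[:, true_d], s)
        Y = Y + 1e-17 * np.random.default_rng(11).normal(size=Y.shape)
        res = EmpiricalBayesBeamformer(Y, toy_leadfield,
                                       regularization=1e-10).fit()
        est = res.source_estimate()
        # peak within the immediate neighbourhood of the true source
        pos = tangential_sources.positions
        dist = np.linalg.norm(pos[est.peak_index] - pos[true_d])
        neighbourhood = np.sort(
            np.linalg.norm(pos - pos[true_d], axis=1))[5]
        assert dist <= neighbourhood

    def test_solve_equals_explicit_inverse(self, toy_leadfield):
        rng = np.random.default_rng(12)
        Y = rng.normal(size=(13, 60)) * 1e-13
        res = EmpiricalBayesBeamformer(Y, toy_leadfield).fit()
        est = res.source_estimate()
        cov = res.cov_model
        Q = cov.lambda_[1] * np.diag(cov.gamma)
        J_ref = Q @ toy_leadfield.matrix.T @ np.linalg.inv(cov.C_model) @ Y
        assert np.allclose(est.J, J_ref, rtol=1e-10, atol=1e-30)

    def test_linearity_in_data(self, toy_leadfield):
        rng = np.random.default_rng(13)
        Y1 = rng.normal(size=(13, 40)) * 1e-13
        Y2 = rng.normal(size=(13, 40)) * 1e-13
        res = EmpiricalBayesBeamformer(Y1, toy_leadfield).fit()
        j = lambda Y: estimate_sources(Y, res.cov_model, toy_leadfield).J
        combined = j(Y1 + 2 * Y2)
        assert np.allclose(combined, j(Y1) + 2 * j(Y2), rtol=1e-10,
                           atol=1e-12 * np.abs(combined).max())

    def test_large_noise_prior_shrinks_estimate(self, toy_leadfield):
        from opmarray.inversion import CovarianceModel

        rng = np.random.default_rng(14)
        Y = rng.normal(size=(13, 40)) * 1e-13
        gamma = np.ones(toy_leadfield.n_sources)
        M = (toy_leadfield.matrix * gamma) @ toy_leadfield.matrix.T
        lam2 = 1.0
        norms = []
        for lam1 in (1e-26, 1e-22, 1e-18):
            cov = CovarianceModel(
                np.array([lam1, lam2]), gamma,
                lam1 * np.eye(13) + lam2 * M, np.eye(2), np.zeros(2),
                np.eye(2) * 1e-6)
            norms.append(np.linalg.norm(
                estimate_sources(Y, cov, toy_leadfield).J))
        assert norms[0] > norms[1] > norms[2]

    def test_channel_reordering_invariance(self, toy_leadfield):
        rng = np.random.default_rng(15)
        Y = rng.normal(size=(13, 80)) * 1e-13
        perm = rng.permutation(13)
        r1 = EmpiricalBayesBeamformer(Y, toy_leadfield.matrix).fit()
        r2 = EmpiricalBayesBeamformer(Y[perm],
                                      toy_leadfield.matrix[perm]).fit()
        assert r2.free_energy == pytest.approx(r1.free_energy, abs=1e-6)
        assert np.allclose(r1.source_estimate().J, r2.source_estimate().J,
                           rtol=1e-6, atol=1e-30)

    def test_dimension_mismatch(self, toy_leadfield):
        rng = np.random.default_rng(16)
        Y = rng.normal(size=(13, 50)) * 1e-13
        res = EmpiricalBayesBeamformer(Y, toy_leadfield).fit()
        with pytest.raises(ValueError):
            estimate_sources(np.zeros((12, 20)), res.cov_model,
                             toy_leadfield)


def test_short_data_warns():
    with pytest.warns(UserWarning, match="rank deficient"):
        DataMatrix(np.zeros((10, 4)), 1000.0)
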