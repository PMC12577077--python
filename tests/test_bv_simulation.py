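"""Breeding-value and phenotype simulation: covariance structure checks."""

import numpy as np
import pytest

from ssgreml import bv_simulation as bv
from ssgreml.exact_oracle import dense_h, tabular_a
from ssgreml.io_model import ResidualOps
from ssgreml.mc_traces import run_mc_round
from ssgreml.mme_solver import MMEOperator
from ssgreml.params import VarianceState
from ssgreml.relationships import HInverseOperator, apy_decompose

from conftest import TH2, R2, cov_z_stats, full_state

B = 30000  # draws for empirical covariance checks


class TestGeneDrop:
    def test_zero_theta_gives_zero(self, small_h_bundle):
        study, _, engine = small_h_bundle
        L = np.zeros((1, 1))
        a = bv.gene_drop(study.pedigree, engine.ped_kin.phi, L,
                         np.random.default_rng(0), shape=(10,))
        assert np.abs(a).max() == 0.0

    def test_founder_variance_is_theta(self, small_h_bundle):
        study, _, engine = small_h_bundle
        L = np.eye(1)
        a = bv.gene_drop(study.pedigree, engine.ped_kin.phi, L,
                         np.random.default_rng(1), shape=(B,))
        founders = np.where(study.pedigree.sire == -1)[0]
        var = a[:, founders, 0].var(axis=0)
        se = np.sqrt(2.0 / B)
        assert np.abs(var - 1.0).max() < 3.5 * se

    def test_empirical_covariance_matches_tabular_a(self, small_h_bundle):
        study, _, engine = small_h_bundle
        theta = np.array([[2.0]])
        L = np.linalg.cholesky(theta)
        a = bv.gene_drop(study.pedigree, engine.ped_kin.phi, L,
                         np.random.default_rng(2), shape=(B,))
        A = tabular_a(study.pedigree)
        emp = np.einsum("bit,bjt->ij", a, a) / B
        maxz, frac = cov_z_stats(emp, 2.0 * A, B)
        assert frac < 0.01 and maxz < 5.0


class TestGenomicTerms:
    def test_zero_jvar_gives_zero_mu(self, small_h_bundle):
        study, _, _ = small_h_bundle
        g, mu = bv.sample_genomic_terms(study.genotypes, 0.0, np.eye(1),
                                        np.random.default_rng(0), shape=(5,))
        assert np.abs(mu).max() == 0.0

    def test_negative_jvar_rejected(self, small_h_bundle):
        study, _, _ = small_h_bundle
        with pytest.raises(ValueError, match="J-factor"):
            bv.sample_genomic_terms(study.genotypes, -0.1, np.eye(1),
                                    np.random.default_rng(0))

    def test_marker_part_realizes_g_raw(self, small_h_bundle):
        study, _, engine = small_h_bundle
        g, _ = bv.sample_genomic_terms(study.genotypes, engine.genomic.j_var,
                                       np.eye(1), np.random.default_rng(3),
                                       shape=(B,))
        mg = study.genotypes.M @ g  # (B, n_g, 1)
        emp = np.einsum("bit,bjt->ij", mg, mg) / B
        maxz, frac = cov_z_stats(emp, engine.genomic.g_raw, B)
        assert frac < 0.01 and maxz < 5.0

    def test_independent_columns_uncorrelated(self, small_h_bundle):
        study, _, _ = small_h_bundle
        g, _ = bv.sample_genomic_terms(study.genotypes, 0.1, np.eye(2),
                                       np.random.default_rng(4), shape=(2000,))
        corr = np.corrcoef(g[..., 0].ravel(), g[..., 1].ravel())[0, 1]
        assert abs(corr) < 3.0 / np.sqrt(g[..., 0].size)


class TestCombine:
    def test_alpha_one_is_pure_pedigree_sample(self, small_h_bundle):
        study, _, engine = small_h_bundle
        rng = np.random.default_rng(5)
        L = np.eye(1)
        a = bv.gene_drop(study.pedigree, engine.ped_kin.phi, L, rng, shape=(4,))
        g, mu = bv.sample_genomic_terms(study.genotypes, engine.genomic.j_var, L,
                                        rng, shape=(4,))
        u, delta = bv.combine_ssgblup(a, g, mu, 1.0, study.genotypes, engine.h_op)
        np.testing.assert_allclose(u, a, atol=1e-12)
        assert np.abs(delta).max() < 1e-12

    def test_ssgblup_covariance_matches_dense_h(self, small_h_bundle):
        """Empirical Cov(u) over many draws equals theta (x) H with H built
        densely from the identical blended G."""
        study, _, engine = small_h_bundle
        theta = np.array([[2.0]])
        L = np.linalg.cholesky(theta)
        rng = np.random.default_rng(6)
        a = bv.gene_drop(study.pedigree, engine.ped_kin.phi, L, rng, shape=(B,))
        g, mu = bv.sample_genomic_terms(study.genotypes, engine.genomic.j_var, L,
                                        rng, shape=(B,))
        u, _ = bv.combine_ssgblup(a, g, mu, study.spec.alpha, study.genotypes,
                                  engine.h_op)
        H = dense_h(engine)
        emp = np.einsum("bit,bjt->ij", u, u) / B
        maxz, frac = cov_z_stats(emp, 2.0 * H, B)
        assert frac < 0.01 and maxz < 5.0


class TestApySampler:
    def test_all_core_identical_to_ssgblup_stream(self, small_h_bundle):
        study, _, engine = small_h_bundle
        gk = engine.genomic
        parts = apy_decompose(gk, np.arange(gk.g_blend.shape[0]))
        hop_apy = HInverseOperator(engine.ped_kin, gk, parts)
        L = np.linalg.cholesky(np.array([[25.0]]))
        r1, r2 = np.random.default_rng(9), np.random.default_rng(9)
        a1 = bv.gene_drop(study.pedigree, engine.ped_kin.phi, L, r1, shape=(5,))
        a2 = bv.gene_drop(study.pedigree, engine.ped_kin.phi, L, r2, shape=(5,))
        g1, m1 = bv.sample_genomic_terms(study.genotypes, gk.j_var, L, r1, shape=(5,))
        g2, m2 = bv.sample_genomic_terms(study.genotypes, gk.j_var, L, r2, shape=(5,))
        u_ref, _ = bv.combine_ssgblup(a1, g1, m1, 0.05, study.genotypes, engine.h_op)
        u_apy, _ = bv.combine_apy(a2, g2, m2, 0.05, parts, study.genotypes,
                                  hop_apy, np.random.default_rng(1), L, shape=(5,))
        np.testing.assert_allclose(u_apy, u_ref, atol=1e-10)

    def test_strict_core_covariance_matches_implied_g(self, small_h_bundle):
        study, _, engine = small_h_bundle
        gk = engine.genomic
        n_g = gk.g_blend.shape[0]
        core = np.arange(0, n_g, 2)
        parts = apy_decompose(gk, core)
        hop = HInverseOperator(engine.ped_kin, gk, parts)
        L = np.linalg.cholesky(np.array([[2.0]]))
        rng = np.random.default_rng(12)
        a = bv.gene_drop(study.pedigree, engine.ped_kin.phi, L, rng, shape=(B,))
        g, mu = bv.sample_genomic_terms(study.genotypes, gk.j_var, L, rng, shape=(B,))
        u, _ = bv.combine_apy(a, g, mu, 0.05, parts, study.genotypes, hop,
                              rng, L, shape=(B,))
        u2 = u[:, gk.ids, 0]
        emp = (u2.T @ u2) / B
        order = np.concatenate([parts.core, parts.noncore])
        rank = np.empty_like(order)
        rank[order] = np.arange(len(order))
        G_implied = parts.implied_g()[np.ix_(rank, rank)]
        maxz, frac = cov_z_stats(emp, 2.0 * G_implied, B)
        assert frac < 0.01 and maxz < 5.0

    def test_noncore_deterministic_when_psi_zero(self, small_h_bundle):
        study, _, engine = small_h_bundle
        gk = engine.genomic
        core = np.arange(0, gk.g_blend.shape[0], 2)
        parts = apy_decompose(gk, core)
        parts.psi[:] = 0.0
        hop = HInverseOperator(engine.ped_kin, gk, apy_decompose(gk, core))
        L = np.eye(1)
        rng = np.random.default_rng(3)
        a = bv.gene_drop(study.pedigree, engine.ped_kin.phi, L, rng, shape=(2,))
        g, mu = bv.sample_genomic_terms(study.genotypes, gk.j_var, L, rng, shape=(2,))
        u, _ = bv.combine_apy(a, g, mu, 0.05, parts, study.genotypes, hop,
                              rng, L, shape=(2,))
        u2 = u[:, gk.ids, :]
        u_c = u2[:, parts.core, 0]
        np.testing.assert_allclose(u2[:, parts.noncore, 0], u_c @ parts.p_nc.T,
                                   atol=1e-10)


class TestPhenotypes:
    def test_residual_pattern_respected(self, two_trait_bundle):
        study, design, engine = two_trait_bundle
        state = full_state(design, [TH2], R2)
        resid = ResidualOps(design, state.r0)
        sampler = bv.EffectSampler(design, engine, study.genotypes, design.spec)
        smp = sampler.draw_sample(state, resid, sample_index=0)
        assert (smp.y_tilde[~design.mask] == 0.0).all()
        assert (smp.e_tilde[~design.mask] == 0.0).all()

    def test_residual_covariance_realized(self, two_trait_complete_bundle):
        _, design, _ = two_trait_complete_bundle
        resid = ResidualOps(design, R2)
        e = resid.sample(np.random.default_rng(0), shape=(400,))
        E = e.reshape(-1, 2)
        emp = (E.T @ E) / len(E)
        maxz, frac = cov_z_stats(emp, R2, len(E))
        assert maxz < 4.0

    def test_signal_plus_noise_composition(self, two_trait_bundle):
        study, design, engine = two_trait_bundle
        state = full_state(design, [TH2], R2)
        resid = ResidualOps(design, state.r0)
        sampler = bv.EffectSampler(design, engine, study.genotypes, design.spec)
        smp = sampler.draw_sample(state, resid, sample_index=1)
        recon = design.signal(smp.u) + smp.e_tilde
        recon[~design.mask] = 0.0
        np.testing.assert_allclose(smp.y_tilde, recon, atol=1e-12)


class TestStreams:
    def test_draws_reproducible_bitwise(self, two_trait_bundle):
        study, design, engine = two_trait_bundle
        state = full_state(design, [TH2], R2)
        resid = ResidualOps(design, state.r0)
        sampler = bv.EffectSampler(design, engine, study.genotypes, design.spec)
        s1 = sampler.draw_sample(state, resid, sample_index=3, round_index=1)
        s2 = sampler.draw_sample(state, resid, sample_index=3, round_index=8)
        # reuse_sequence on: different rounds consume identical streams
        assert (s1.y_tilde == s2.y_tilde).all()
        assert all((s1.u[g] == s2.u[g]).all() for g in s1.u)
        s3 = sampler.draw_sample(state, resid, sample_index=4, round_index=1)
        assert not (s1.y_tilde == s3.y_tilde).all()

    def test_round_key_active_without_reuse(self, two_trait_bundle):
        import copy

        study, design, engine = two_trait_bundle
        spec = copy.deepcopy(design.spec)
        spec.mc.reuse_sequence = False
        state = full_state(design, [TH2], R2)
        resid = ResidualOps(design, state.r0)
        sampler = bv.EffectSampler(design, engine, study.genotypes, spec)
        s1 = sampler.draw_sample(state, resid, sample_index=3, round_index=1)
        s2 = sampler.draw_sample(state, resid, sample_index=3, round_index=2)
        assert not (s1.y_tilde == s2.y_tilde).all()
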