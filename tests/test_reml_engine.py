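"""EM/AI-REML updates, gradient, AI matrix, likelihood, convergence."""

import copy

import numpy as np
import pytest

from ssgreml.exact_oracle import DenseReference, finite_difference_gradient
from ssgreml.io_model import (
    FixedSpec,
    ModelSpec,
    PhenotypeTable,
    RandomGroupSpec,
    ResidualOps,
    TraitSpec,
    build_design,
    renumber_pedigree,
)
from ssgreml.mme_solver import MMEOperator, compute_quadforms, pcg_solve
from ssgreml.params import VarianceState
from ssgreml.relationships import build_engine
from ssgreml.reml_engine import (
    REMLState,
    ai_matrix,
    ai_step,
    check_convergence,
    em_information,
    em_update,
    gradient,
    restricted_loglik,
    run_reml,
    standard_errors,
)

from conftest import TH2, R2, full_state, one_way_fixture


def _round_pieces(bundle, state, exact=True):
    _, design, engine = bundle
    resid = ResidualOps(design, state.r0)
    op = MMEOperator(design, state, engine, resid)
    sol = pcg_solve(op, op.rhs(), tol=1e-11, max_iter=5000)
    quads = compute_quadforms(sol, state, engine, resid)
    ref = DenseReference(design, state, engine)
    traces = ref.exact_traces()
    return design, engine, resid, sol, quads, traces, ref


class TestEmUpdate:
    def test_stationary_point_unchanged(self, two_trait_complete_bundle):
        """When T_k + S_k = q_k theta_k and the residual terms balance, the EM
        update leaves theta in place and the analytic gradient is zero."""
        from ssgreml.mc_traces import TraceSet
        from ssgreml.mme_solver import QuadForms

        _, design, engine = two_trait_complete_bundle
        state = full_state(design, [TH2], R2)
        q = design.groups[0].q
        S = np.array([[3.0, 1.0], [1.0, 2.0]])
        T = q * TH2 - S
        n_ij = design.n_ij
        ee = np.array([[5.0, 2.0], [2.0, 4.0]])
        trw = [n_ij * R2 - ee]  # single complete-record pattern
        assert len(design.patterns) == 1
        traces = TraceSet(T=[T], trw_pattern=trw, n_ij=n_ij, s_used=0)
        resid = ResidualOps(design, state.r0)
        quads = QuadForms(S=[S], ee=ee, ree=resid.rinv_emb[0] @ ee @ resid.rinv_emb[0],
                          n_ij=n_ij)
        new = em_update(traces, quads, state, design)
        np.testing.assert_allclose(new.free_values(), state.free_values(),
                                   rtol=1e-12)
        g = gradient(traces, quads, state, design, resid)
        assert np.abs(g).max() < 1e-8

    def test_masked_entries_stay_zero(self):
        from ssgreml import synthetic_data as sd

        study = sd.simulate_study(sd.SimConfig(seed=13, n_founders=14,
                                               n_generations=3, n_matings=7,
                                               m_loci=40))
        design = build_design(study.pedigree, study.phenotypes, study.spec)
        engine = build_engine(study.pedigree, study.genotypes, study.spec)
        spec = copy.deepcopy(study.spec)
        spec.convergence.max_rounds = 4
        res = run_reml(design, engine, spec, method="ai", traces="exact",
                       compute_se=False)
        th = res.varstate.theta[0]
        mask = res.varstate.masks[0]
        assert (th[~mask] == 0.0).all()
        assert (res.varstate.r0[~res.varstate.r_mask] == 0.0).all()
        # masked parameters do not appear among the free parameters
        assert res.varstate.n_free == 14


class TestGradient:
    def test_matches_finite_differences(self, two_trait_bundle):
        state = full_state(two_trait_bundle[1], [TH2], R2)
        design, engine, resid, sol, quads, traces, _ = _round_pieces(
            two_trait_bundle, state
        )
        g = gradient(traces, quads, state, design, resid)
        fd = finite_difference_gradient(
            lambda s: restricted_loglik(design, s, engine), state, step=1e-5
        )
        np.testing.assert_allclose(g, fd, rtol=1e-4, atol=1e-6 * np.abs(fd).max())

    def test_residual_gradient_sign_flips_far_from_optimum(self, two_trait_bundle):
        """Inflating a residual variance far above its optimum flips the sign
        of that gradient entry."""
        _, design, engine = two_trait_bundle
        lo = full_state(design, [TH2], 0.2 * R2)
        hi = full_state(design, [TH2], 20.0 * R2)
        out = []
        for st in (lo, hi):
            _, _, resid, _, quads, traces, _ = _round_pieces(
                (None, design, engine), st
            )
            g = gradient(traces, quads, st, design, resid)
            out.append(g[-1])  # last residual variance entry
        assert out[0] < 0 < out[1]


class TestAiMatrix:
    def test_symmetric_and_positive(self, two_trait_bundle):
        state = full_state(two_trait_bundle[1], [TH2], R2)
        design, engine, resid, sol, quads, traces, ref = _round_pieces(
            two_trait_bundle, state
        )
        ai = ai_matrix(sol, state, design, resid, ref.solve)
        np.testing.assert_allclose(ai, ai.T, atol=1e-8)
        assert np.linalg.eigvalsh(ai).min() > 0

    def test_single_parameter_matches_dense_p(self):
        """One free parameter: AI equals y'P (dV/dt) P (dV/dt) P y computed
        from the dense projection matrix."""
        ped = renumber_pedigree(
            [(str(i + 1), "0", "0") for i in range(8)]
            + [(str(i + 9), str(1 + i % 4), str(5 + i % 4)) for i in range(8)]
        )
        rng = np.random.default_rng(0)
        pheno = PhenotypeTable(
            animal=np.arange(8, 16),
            fixed_codes={"mu": np.array(["1"] * 8)},
            y=rng.standard_normal((8, 1)) * 3 + 10,
            mask=np.ones((8, 1), dtype=bool),
        )
        spec = ModelSpec(
            traits=[TraitSpec("y", 3)],
            animal_col=1,
            fixed=[FixedSpec("mu", 2, ["y"])],
            random_groups=[
                RandomGroupSpec(name="u", kind="a", columns=[("direct", "y")])
            ],
        )
        design = build_design(ped, pheno, spec)
        engine = build_engine(ped, None, spec)
        state = full_state(design, [np.array([[2.0]])], np.array([[1.5]]))
        resid = ResidualOps(design, state.r0)
        op = MMEOperator(design, state, engine, resid)
        sol = pcg_solve(op, op.rhs(), tol=1e-12)
        ref = DenseReference(design, state, engine)
        ai = ai_matrix(sol, state, design, resid, ref.solve)
        # dense evaluation over observed cells
        P = ref.dense_p()
        y = design.y[ref.cell_rec, ref.cell_trait]
        from ssgreml.exact_oracle import tabular_a

        A = tabular_a(ped)
        Z = np.zeros((8, 16))
        Z[np.arange(8), np.arange(8, 16)] = 1.0
        dV_u = Z @ A @ Z.T
        dV_e = np.eye(8)
        Py = P @ y
        expected = np.array(
            [
                [Py @ dV_u @ P @ dV_u @ Py, Py @ dV_u @ P @ dV_e @ Py],
                [Py @ dV_e @ P @ dV_u @ Py, Py @ dV_e @ P @ dV_e @ Py],
            ]
        )
        np.testing.assert_allclose(ai, expected, atol=1e-8)


class TestAiStep:
    def test_zero_gradient_leaves_theta_unchanged(self, two_trait_bundle):
        state = full_state(two_trait_bundle[1], [TH2], R2)
        design = two_trait_bundle[1]
        resid = ResidualOps(design, state.r0)
        info = em_information(state, design, resid)
        new, kind = ai_step(state, np.zeros(state.n_free), np.eye(state.n_free),
                            info)
        np.testing.assert_allclose(new.free_values(), state.free_values())
        assert kind == "ai"

    def test_newton_property_on_quadratic_surrogate(self, two_trait_bundle):
        """With AI equal to the true Hessian of a quadratic -2logL surrogate,
        one step lands exactly on the optimum."""
        state = full_state(two_trait_bundle[1], [TH2], R2)
        design = two_trait_bundle[1]
        resid = ResidualOps(design, state.r0)
        rng = np.random.default_rng(1)
        n = state.n_free
        Hs = rng.standard_normal((n, n))
        H = Hs @ Hs.T + n * np.eye(n)
        opt = state.free_values() * 0.9
        grad = H @ (state.free_values() - opt)
        info = em_information(state, design, resid)
        new, _ = ai_step(state, grad, H, info)
        np.testing.assert_allclose(new.free_values(), opt, rtol=1e-10)

    def test_overshooting_step_is_blended_back_into_parameter_space(
        self, two_trait_bundle
    ):
        """A raw AI step engineered to drive a variance negative triggers the
        AI-EM blending and returns an SPD state."""
        state = full_state(two_trait_bundle[1], [TH2], R2)
        design = two_trait_bundle[1]
        resid = ResidualOps(design, state.r0)
        info = em_information(state, design, resid)
        grad = np.zeros(state.n_free)
        grad[0] = 2.5
        ai = np.eye(state.n_free) * 0.1  # raw step: -25 on the first variance
        new, kind = ai_step(state, grad, ai, info)
        assert new.all_spd()
        assert kind != "ai"
        assert new.theta[0][0, 0] > 0


class TestLoglik:
    def test_no_random_effects_reduces_to_ols(self):
        """With no random effects and R = I: -2logL = log|X'X| + RSS."""
        ped = renumber_pedigree([(str(i + 1), "0", "0") for i in range(6)])
        rng = np.random.default_rng(3)
        codes = np.array(["a", "a", "b", "b", "c", "c"])
        y = rng.standard_normal((6, 1))
        pheno = PhenotypeTable(animal=np.arange(6), fixed_codes={"g": codes},
                               y=y, mask=np.ones((6, 1), dtype=bool))
        spec = ModelSpec(
            traits=[TraitSpec("y", 3)], animal_col=1,
            fixed=[FixedSpec("g", 2, ["y"])], random_groups=[],
        )
        design = build_design(ped, pheno, spec)
        engine = build_engine(ped, None, spec)
        state = VarianceState([], np.array([[1.0]]), [],
                              np.ones((1, 1), dtype=bool), [])
        m2ll = restricted_loglik(design, state, engine)
        X = np.zeros((6, 3))
        X[np.arange(6), [0, 0, 1, 1, 2, 2]] = 1.0
        beta = np.linalg.lstsq(X, y[:, 0], rcond=None)[0]
        rss = float(np.sum((y[:, 0] - X @ beta) ** 2))
        expected = np.linalg.slogdet(X.T @ X)[1] + rss
        assert m2ll == pytest.approx(expected, abs=1e-8)

    def test_matches_dense_v_evaluation(self, two_trait_bundle):
        state = full_state(two_trait_bundle[1], [TH2], R2)
        _, design, engine = two_trait_bundle
        ref = DenseReference(design, state, engine)
        assert restricted_loglik(design, state, engine, dense_ref=ref) == (
            pytest.approx(ref.loglik_via_v(), abs=1e-6)
        )

    def test_invariant_to_record_order(self, two_trait_bundle):
        study, design, engine = two_trait_bundle
        state = full_state(design, [TH2], R2)
        base = restricted_loglik(design, state, engine)
        perm = np.random.default_rng(0).permutation(study.phenotypes.n_records)
        pheno = PhenotypeTable(
            animal=study.phenotypes.animal[perm],
            fixed_codes={k: v[perm] for k, v in study.phenotypes.fixed_codes.items()},
            y=study.phenotypes.y[perm],
            mask=study.phenotypes.mask[perm],
        )
        design2 = build_design(study.pedigree, pheno, design.spec)
        assert restricted_loglik(design2, state, engine) == pytest.approx(
            base, abs=1e-8
        )


class TestConvergence:
    def test_identical_theta_two_rounds_converges(self):
        st = REMLState()
        st.delta_theta = 0.0
        done, reason = check_convergence(st, 1e-12, 1e-4)
        assert done and "delta_theta" in reason

    def test_constant_loglik_five_rounds_converges(self):
        st = REMLState()
        st.delta_theta = 1.0
        st.logl_history = [100.0] * 5
        done, reason = check_convergence(st, 1e-12, 1e-4)
        assert done and "cv_logl" in reason

    def test_defaults(self, two_trait_bundle):
        spec = two_trait_bundle[1].spec
        assert spec.convergence.t1 == 1e-12
        assert spec.convergence.t2 == 1e-4
        assert spec.start_variance == 1.0 and spec.start_covariance == 0.1


class TestRunReml:
    def test_em_monotone_decrease_of_minus2ll(self):
        design, engine, spec, _ = one_way_fixture()
        sp = copy.deepcopy(spec)
        sp.convergence.max_rounds = 30
        res = run_reml(design, engine, sp, method="em", traces="exact",
                       compute_se=False)
        hist = np.array(res.state.logl_history)
        assert (np.diff(hist) <= 1e-8).all()

    def test_em_and_ai_reach_same_likelihood(self):
        design, engine, spec, _ = one_way_fixture()
        sp = copy.deepcopy(spec)
        sp.convergence.t2 = 0.0
        sp.convergence.max_rounds = 500
        em = run_reml(design, engine, sp, method="em", traces="exact",
                      compute_se=False)
        ai = run_reml(design, engine, sp, method="ai", traces="exact",
                      compute_se=False)
        assert abs(em.state.logl_history[-1] - ai.state.logl_history[-1]) < 1e-3

    def test_gradient_near_zero_at_ai_optimum(self, two_trait_bundle):
        _, design, engine = two_trait_bundle
        sp = copy.deepcopy(design.spec)
        sp.convergence.t2 = 0.0
        sp.convergence.max_rounds = 200
        res = run_reml(design, engine, sp, method="ai", traces="exact",
                       compute_se=False)
        state = res.varstate
        _, _, resid, _, quads, traces, _ = _round_pieces(
            (None, design, engine), state
        )
        g = gradient(traces, quads, state, design, resid)
        assert np.abs(g).max() < 1e-6 * np.abs(state.free_values()).max()


class TestStandardErrors:
    def test_positive_at_spd_optimum(self, two_trait_bundle):
        _, design, engine = two_trait_bundle
        sp = copy.deepcopy(design.spec)
        sp.convergence.max_rounds = 60
        res = run_reml(design, engine, sp, method="ai", traces="exact")
        assert res.se is not None and (res.se > 0).all()

    def test_balanced_one_way_matches_closed_form_information(self):
        """SE from 2*AI^-1 agrees with the closed-form asymptotic variances of
        balanced one-way REML within 10%."""
        design, engine, spec, cf = one_way_fixture(n_groups=40, n_per=8)
        sp = copy.deepcopy(spec)
        sp.convergence.max_rounds = 200
        res = run_reml(design, engine, sp, method="ai", traces="exact")
        sa2, se2 = res.varstate.free_values()
        a, n = 40, 8
        lam = se2 + n * sa2
        var_se2 = 2 * se2**2 / (a * (n - 1))
        var_sa2 = (2 / n**2) * (lam**2 / (a - 1) + se2**2 / (a * (n - 1)))
        np.testing.assert_allclose(
            res.se, np.sqrt([var_sa2, var_se2]), rtol=0.10
        )

    def test_singular_ai_reported_missing(self, two_trait_bundle):
        state = full_state(two_trait_bundle[1], [TH2], R2)
        se = standard_errors(np.zeros((state.n_free, state.n_free)), state)
        assert np.isnan(se).all()
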