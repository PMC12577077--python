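"""EM and Average-Information REML over masked (co)variance components.

One round of the estimation loop: solve the data MME, compute solution
quadratic forms, obtain the PEV traces (exactly from a dense inverse, or by
Monte Carlo simulation), form the gradient of -2 logL, take an EM or a
safeguarded AI step, evaluate the restricted log-likelihood, and test the
dual convergence criterion (max relative parameter change Delta-theta < t1,
or coefficient of variation of the last five log-likelihoods < t2).

Free parameters are the unmasked lower-triangle entries of each group
covariance matrix and of R0; masked entries are structural zeros and never
move.  Standard errors come from the inverse AI matrix at the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import exact_oracle
from .bv_simulation import EffectSampler
from .io_model import DesignSet, ResidualOps
from .mc_traces import TraceSet, run_mc_round
from .mme_solver import MMEOperator, MMESolution, QuadForms, compute_quadforms, pcg_solve
from .params import VarianceState, duplication_matrix, is_spd, nearest_spd, start_state
from .relationships import RelationshipEngine

log = logging.getLogger("ssgreml")

AI_BLEND_SCHEDULE = (0.1, 0.3, 0.5, 0.9, 1.0)


# ---------------------------------------------------------------------------
# updates and derivatives
# ---------------------------------------------------------------------------


def em_update(
    traces: TraceSet, quads: QuadForms, varstate: VarianceState, design: DesignSet
) -> VarianceState:
    """EM-REML update: theta_k <- (T_k + S_k)/q_k on unmasked entries, and the
    per-pair residual rule R0_ij <- (e_i'e_j + TRW_ij)/n_ij."""
    new = varstate.copy()
    for k, (T, S) in enumerate(zip(traces.T, quads.S)):
        q_k = design.groups[k].q
        cand = (T + S) / q_k
        cand[~varstate.masks[k]] = 0.0
        if not is_spd(cand):
            log.warning("EM update for group %d left the parameter space; projecting", k)
            cand = nearest_spd(cand)
            cand[~varstate.masks[k]] = 0.0
        new.theta[k] = cand
    trw = traces.trw
    n_ij = traces.n_ij
    r_new = varstate.r0.copy()
    t = r_new.shape[0]
    for i in range(t):
        for j in range(i + 1):
            if not varstate.r_mask[i, j]:
                continue
            if n_ij[i, j] == 0:
                raise ValueError(f"no shared records for residual pair ({i},{j})")
            val = (quads.ee[i, j] + trw[i, j]) / n_ij[i, j]
            r_new[i, j] = r_new[j, i] = val
    r_new[~varstate.r_mask] = 0.0
    if not is_spd(r_new):
        log.warning("EM residual update left the parameter space; projecting")
        r_new = nearest_spd(r_new)
        r_new[~varstate.r_mask] = 0.0
    new.r0 = r_new
    new.enforce_masks()
    return new


def gradient(
    traces: TraceSet,
    quads: QuadForms,
    varstate: VarianceState,
    design: DesignSet,
    resid_ops: ResidualOps,
) -> np.ndarray:
    """Gradient of -2 logL over the free parameters.

    Group blocks: D = q theta^-1 - theta^-1 (T + S) theta^-1, entry (i,j)
    doubled off-diagonal (symmetric-perturbation convention).  Residual
    entries combine the pattern counts, the pattern-weighted PEV sums and the
    R^-1-weighted residual cross-products.
    """
    vals = []
    Dk = {}
    for k, (T, S) in enumerate(zip(traces.T, quads.S)):
        th_inv = np.linalg.inv(varstate.theta[k])
        q_k = design.groups[k].q
        Dk[k] = q_k * th_inv - th_inv @ (T + S) @ th_inv
    t = design.n_traits
    term1 = np.zeros((t, t))
    term2 = np.zeros((t, t))
    for p, rows in enumerate(design.pattern_rows):
        rinv = resid_ops.rinv_emb[p]
        term1 += len(rows) * rinv
        term2 += rinv @ traces.trw_pattern[p] @ rinv
    Dres = term1 - term2 - quads.ree
    for kind, k, i, j in varstate.free_entries():
        c = 1.0 if i == j else 2.0
        mat = Dk[k] if kind == "group" else Dres
        vals.append(c * mat[i, j])
    return np.array(vals)


def em_information(varstate: VarianceState, design: DesignSet, resid_ops: ResidualOps) -> np.ndarray:
    """Complete-data (EM) information matrix of -2 logL over free parameters:
    q_k D'(theta^-1 (x) theta^-1)D per group and the pattern-weighted residual
    analogue.  Used to safeguard AI steps and as the EM scoring matrix."""
    entries = varstate.free_entries()
    n = len(entries)
    info = np.zeros((n, n))
    # group blocks
    for k, th in enumerate(varstate.theta):
        t_k = th.shape[0]
        D = duplication_matrix(t_k)
        th_inv = np.linalg.inv(th)
        full = design.groups[k].q * D.T @ np.kron(th_inv, th_inv) @ D
        pairs = [(i, j) for i in range(t_k) for j in range(i + 1)]
        keep = [p for p, (i, j) in enumerate(pairs) if varstate.masks[k][i, j]]
        pos = [pi for pi, (kind, kk, _, _) in enumerate(entries) if kind == "group" and kk == k]
        info[np.ix_(pos, pos)] = full[np.ix_(keep, keep)]
    # residual block
    t = design.n_traits
    D = duplication_matrix(t)
    full = np.zeros((D.shape[1], D.shape[1]))
    for p, rows in enumerate(design.pattern_rows):
        rinv = resid_ops.rinv_emb[p]
        full += len(rows) * D.T @ np.kron(rinv, rinv) @ D
    pairs = [(i, j) for i in range(t) for j in range(i + 1)]
    keep = [p for p, (i, j) in enumerate(pairs) if varstate.r_mask[i, j]]
    pos = [pi for pi, (kind, _, _, _) in enumerate(entries) if kind == "residual"]
    info[np.ix_(pos, pos)] = full[np.ix_(keep, keep)]
    return info


def ai_matrix(
    sol: MMESolution,
    varstate: VarianceState,
    design: DesignSet,
    resid_ops: ResidualOps,
    solver: Callable[[np.ndarray], np.ndarray],
) -> np.ndarray:
    """Average-information matrix AI[p,q] = f_p' P f_q with one linear solve
    per free parameter: f_p' P f_q = f_p'R^-1 f_q - (Q'R^-1 f_p)' C^-1 (Q'R^-1 f_q)."""
    e = sol.e_hat()
    re = resid_ops.apply_rinv(e)
    mask = design.mask
    entries = varstate.free_entries()
    fgrids = []
    UKth = {}
    for kind, k, i, j in entries:
        F = np.zeros((design.n_records, design.n_traits))
        if kind == "group":
            if k not in UKth:
                UKth[k] = sol.u_hat(k) @ np.linalg.inv(varstate.theta[k])
            layout = design.groups[k]
            combos = [(i, j)] if i == j else [(i, j), (j, i)]
            for ci, cj in combos:
                ti = layout.terms[ci]
                tm = design.terms[ti]
                rows = design._term_rows[ti]
                lev = (design._term_eq[ti] - layout.offset - ci) // layout.t
                F[rows, tm.trait] += UKth[k][lev, cj]
        else:
            F[:, i] += re[:, j] * mask[:, i]
            if i != j:
                F[:, j] += re[:, i] * mask[:, j]
        fgrids.append(F)
    n = len(entries)
    rfs = [resid_ops.apply_rinv(F) for F in fgrids]
    rhss = [design.adjoint(rf) for rf in rfs]
    xs = [solver(r) for r in rhss]
    AI = np.zeros((n, n))
    for p in range(n):
        for q in range(p, n):
            val = float(np.sum(fgrids[p] * rfs[q])) - float(rhss[p] @ xs[q])
            AI[p, q] = AI[q, p] = val
    return AI


def ai_step(
    varstate: VarianceState,
    grad: np.ndarray,
    ai: np.ndarray,
    em_info: np.ndarray,
    em_state: Optional[VarianceState] = None,
) -> tuple[VarianceState, str]:
    """Newton-type update vech(theta)+ = vech(theta) - M^-1 grad, with M the
    AI matrix blended toward the EM information whenever the raw step leaves
    the parameter space; final fallback is the pure EM update."""

    def attempt(M: np.ndarray) -> Optional[VarianceState]:
        try:
            delta = np.linalg.solve(M, grad)
        except np.linalg.LinAlgError:
            return None
        cand = varstate.with_free(varstate.free_values() - delta)
        return cand if cand.all_spd() else None

    cand = attempt(ai)
    if cand is not None:
        return cand, "ai"
    for w in AI_BLEND_SCHEDULE:
        cand = attempt((1.0 - w) * ai + w * em_info)
        if cand is not None:
            return cand, f"ai-em(w={w})"
    if em_state is not None and em_state.all_spd():
        return em_state, "em-fallback"
    raise RuntimeError(
        "AI step and all AI-EM blends left the parameter space; "
        f"gradient={grad}, theta={varstate.free_values()}"
    )


# ---------------------------------------------------------------------------
# restricted log-likelihood (exact, via factorized C)
# ---------------------------------------------------------------------------


def restricted_loglik(
    design: DesignSet,
    varstate: VarianceState,
    engine: RelationshipEngine,
    dense_ref: Optional[exact_oracle.DenseReference] = None,
) -> float:
    """-2 restricted logL = log|C| + log|R| + sum_k (q_k log|theta_k|
    + t_k log|K_k|) + y'Py, evaluated with exact factorizations.

    Requires a full-rank fixed-effect parameterization (class effects with
    levels taken from the observed records satisfy this).
    """
    ref = dense_ref or exact_oracle.DenseReference(design, varstate, engine)
    resid = ref.resid
    val = ref.logdet_c + resid.logdet
    for k, layout in enumerate(design.groups):
        sign, ld = np.linalg.slogdet(varstate.theta[k])
        if sign <= 0:
            raise ValueError("non-PD group covariance in logL")
        op = engine.operator_for(layout.kind)
        ld_k = op.logdet_h if op is not None else 0.0
        val += layout.q * ld + layout.t * ld_k
    W = resid.apply_rinv(design.y)
    rhs = design.adjoint(W)
    sol = ref.solve(rhs)
    ypy = float(np.sum(design.y * W)) - float(rhs @ sol)
    return val + ypy


# ---------------------------------------------------------------------------
# state, convergence, main loop
# ---------------------------------------------------------------------------


@dataclass
class REMLState:
    round: int = 0
    theta_history: list[np.ndarray] = field(default_factory=list)
    logl_history: list[float] = field(default_factory=list)  # -2 logL values
    delta_theta: float = np.inf
    cv_logl: float = np.inf
    converged: bool = False
    reason: str = ""
    gradient: Optional[np.ndarray] = None
    ai: Optional[np.ndarray] = None
    step_kinds: list[str] = field(default_factory=list)


def check_convergence(state: REMLState, t1: float, t2: float) -> tuple[bool, str]:
    """Converged iff Delta-theta < t1 OR CV(logL over last 5 rounds) < t2."""
    if state.delta_theta < t1:
        return True, f"delta_theta {state.delta_theta:.3g} < {t1:.3g}"
    if len(state.logl_history) >= 5:
        last = np.array(state.logl_history[-5:])
        cv = float(np.std(last) / max(abs(float(np.mean(last))), 1e-300))
        state.cv_logl = cv
        if cv < t2:
            return True, f"cv_logl {cv:.3g} < {t2:.3g}"
    return False, ""


@dataclass
class REMLResult:
    varstate: VarianceState
    state: REMLState
    se: Optional[np.ndarray]
    ai: Optional[np.ndarray]
    solution: MMESolution
    labels: list[str]


def standard_errors(ai: np.ndarray, varstate: VarianceState) -> np.ndarray:
    """SE_p = sqrt(diag(2 AI^-1)): the AI matrix tracks -2 logL curvature, so
    the asymptotic covariance of the estimates is 2 AI^-1."""
    try:
        cov = 2.0 * np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        log.warning("singular AI matrix; standard errors unavailable")
        return np.full(varstate.n_free, np.nan)
    d = np.diag(cov).copy()
    bad = d < 0
    if bad.any():
        log.warning("negative AI variance estimates for %d parameters", int(bad.sum()))
        d[bad] = np.nan
    return np.sqrt(d)


def run_reml(
    design: DesignSet,
    engine: RelationshipEngine,
    spec=None,
    method: str = "ai",
    traces: str = "mc",
    start: Optional[VarianceState] = None,
    genotypes=None,
    compute_se: bool = True,
) -> REMLResult:
    """Full EM- or AI-REML estimation loop with MC or exact traces."""
    spec = spec or design.spec
    if method not in ("em", "ai"):
        raise ValueError("method must be 'em' or 'ai'")
    if traces not in ("mc", "exact"):
        raise ValueError("traces must be 'mc' or 'exact'")
    varstate = start.copy() if start is not None else start_state(spec, design)
    state = REMLState()
    sampler = EffectSampler(design, engine, genotypes, spec) if traces == "mc" else None
    conv = spec.convergence
    warm = None
    sol = None
    dense_ref = None  # factorized C for the *current* varstate, reused per round
    for rnd in range(1, conv.max_rounds + 1):
        state.round = rnd
        resid_ops = ResidualOps(design, varstate.r0)
        op = MMEOperator(design, varstate, engine, resid_ops)
        if dense_ref is None:
            dense_ref = exact_oracle.DenseReference(design, varstate, engine)
        rhs = op.rhs()
        sol = pcg_solve(op, rhs, tol=spec.solver.tol_data,
                        max_iter=spec.solver.max_iter, warm_start=warm)
        warm = sol.x
        quads = compute_quadforms(sol, varstate, engine, resid_ops)
        if traces == "exact":
            ts = dense_ref.exact_traces()
        else:
            ts = run_mc_round(design, varstate, engine, sampler, op, rnd)
        grad = gradient(ts, quads, varstate, design, resid_ops)
        state.gradient = grad
        em_state = em_update(ts, quads, varstate, design)
        if method == "em":
            new_state, kind = em_state, "em"
        else:
            ai = ai_matrix(sol=sol, varstate=varstate, design=design,
                           resid_ops=resid_ops, solver=dense_ref.solve)
            state.ai = ai
            em_info = em_information(varstate, design, resid_ops)
            new_state, kind = ai_step(varstate, grad, ai, em_info, em_state)
        state.step_kinds.append(kind)
        state.delta_theta = new_state.delta_rel(varstate)
        varstate = new_state
        dense_ref = exact_oracle.DenseReference(design, varstate, engine)
        m2ll = restricted_loglik(design, varstate, engine, dense_ref=dense_ref)
        state.logl_history.append(m2ll)
        state.theta_history.append(varstate.free_values())
        log.info(
            "round %d [%s/%s %s]: -2logL=%.6f dtheta=%.3g",
            rnd, method, traces, kind, m2ll, state.delta_theta,
        )
        done, reason = check_convergence(state, conv.t1, conv.t2)
        if done:
            state.converged = True
            state.reason = reason
            break
    if not state.converged:
        state.reason = f"max_rounds={conv.max_rounds} reached"
        log.warning("REML did not converge: %s", state.reason)
    # final AI matrix and standard errors at the optimum
    se = ai_final = None
    if compute_se:
        resid_ops = ResidualOps(design, varstate.r0)
        op = MMEOperator(design, varstate, engine, resid_ops)
        sol = pcg_solve(op, op.rhs(), tol=spec.solver.tol_data,
                        max_iter=spec.solver.max_iter, warm_start=warm)
        ai_final = ai_matrix(sol=sol, varstate=varstate, design=design,
                             resid_ops=resid_ops, solver=dense_ref.solve)
        se = standard_errors(ai_final, varstate)
    labels = varstate.labels(
        group_columns=[[g.column_label(c) for c in range(len(g.columns))]
                       for g in spec.random_groups],
        trait_names=spec.trait_names,
    )
    return REMLResult(varstate, state, se, ai_final, sol, labels)


def report(result: REMLResult) -> str:
    """Plain-text parameter / estimate / SE table."""
    lines = ["parameter estimate se"]
    se = result.se if result.se is not None else np.full(result.varstate.n_free, np.nan)
    for lab, val, s in zip(result.labels, result.varstate.free_values(), se):
        lines.append(f"{lab} {val:.6g} {s:.4g}")
    lines.append(
        f"# rounds={result.state.round} converged={result.state.converged} "
        f"reason='{result.state.reason}'"
    )
    return "\n".join(lines)
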