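"""Hutchinson-type Monte Carlo approximation of the PEV traces for REML.

For each of s samples, random effects / residuals / phenotypes are simulated
with the current covariance structure, the mixed model equations are solved
with the simulated right-hand side, and the trace terms required by the EM and
AI updates are accumulated:

    T_k[i,j]  ~=  q_k theta_k[i,j] - s^-1 sum_l  u~_i' K^-1 u~_j      (primary)
              ~=  s^-1 sum_l (u_i - u~_i)' K^-1 (u_j - u~_j)          (centered)

and for the residual side the per-record sum of prediction (co)variances
TRW[i,j] = sum_r [Q C^-1 Q']_r(i,j) over records observing both traits:

    TRW[i,j]  ~=  n_ij R0[i,j] - s^-1 sum_m  e~_i' e~_j               (primary)
              ~=  sum over patterns of centered residual products      (centered)

The residual accumulation is stratified by missingness pattern so that the
analytic gradient can weight each pattern by its own R sub-block inverse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bv_simulation import EffectSampler, MCSample
from .io_model import DesignSet, ResidualOps
from .mme_solver import MMEOperator, pcg_solve
from .params import VarianceState
from .relationships import RelationshipEngine

log = logging.getLogger("ssgreml")


@dataclass
class TraceSet:
    """MC (or exact) trace estimates for one REML round."""

    T: list[np.ndarray]  # per group: estimate of tr(K^-1 C^{k_i k_j})
    trw_pattern: list[np.ndarray]  # per pattern p: sum_r-in-p [QC^-1Q']_r (t,t) embedded
    n_ij: np.ndarray
    s_used: int
    variant: str = "primary"

    @property
    def trw(self) -> np.ndarray:
        """Pattern-combined TRW matrix (t,t)."""
        return np.sum(self.trw_pattern, axis=0)


def _group_quad(sample: MCSample, gi: int, design: DesignSet, engine) -> np.ndarray:
    layout = design.groups[gi]
    U = sample.solution.u_hat(gi)
    op = engine.operator_for(layout.kind)
    KU = op.apply(U) if op is not None else U
    return U.T @ KU


def _group_quad_centered(sample: MCSample, gi: int, design: DesignSet, engine) -> np.ndarray:
    layout = design.groups[gi]
    D = sample.u[gi] - sample.solution.u_hat(gi)
    op = engine.operator_for(layout.kind)
    KD = op.apply(D) if op is not None else D
    return D.T @ KD


def estimate_trace_Tk(
    samples: Sequence[MCSample],
    theta_k: np.ndarray,
    q_k: int,
    gi: int,
    design: DesignSet,
    engine: RelationshipEngine,
    variant: str = "primary",
) -> np.ndarray:
    if len(samples) == 0:
        raise ValueError("need at least one MC sample")
    acc = np.zeros_like(theta_k)
    for smp in samples:
        if variant == "primary":
            acc += _group_quad(smp, gi, design, engine)
        else:
            acc += _group_quad_centered(smp, gi, design, engine)
    acc /= len(samples)
    if variant == "primary":
        T = q_k * theta_k - acc
    else:
        T = acc
    return 0.5 * (T + T.T)


def estimate_trace_residual(
    samples: Sequence[MCSample],
    r0: np.ndarray,
    design: DesignSet,
    variant: str = "primary",
) -> list[np.ndarray]:
    """Per-pattern TRW estimates (embedded t x t matrices)."""
    if len(samples) == 0:
        raise ValueError("need at least one MC sample")
    t = design.n_traits
    out = []
    for p, rows in enumerate(design.pattern_rows):
        obs = np.array(design.patterns[p])
        acc = np.zeros((t, t))
        for smp in samples:
            eh = smp.solution.e_hat(smp.y_tilde)[rows]
            if variant == "primary":
                acc += eh.T @ eh
            else:
                dv = smp.e_tilde[rows] - eh
                acc += dv.T @ dv
        acc /= len(samples)
        if variant == "primary":
            n_p = len(rows)
            est = n_p * (r0 * np.outer(obs, obs)) - acc
        else:
            est = acc
        out.append(0.5 * (est + est.T))
    return out


def run_mc_round(
    design: DesignSet,
    varstate: VarianceState,
    engine: RelationshipEngine,
    sampler: EffectSampler,
    op: MMEOperator,
    round_index: int,
) -> TraceSet:
    """Simulate s samples, solve each simulated MME, accumulate estimators.

    Sample solves reuse the round's operator and preconditioner and are
    cold-started at the relaxed MC tolerance.  Deterministic given
    (base_seed, round, reuse_sequence).  MC settings come from the sampler's
    model spec.
    """
    spec = sampler.spec
    s = spec.mc.samples
    if s < 1:
        raise ValueError("mc.samples must be >= 1")
    variant = spec.mc.variant
    resid_ops = op.resid
    t = design.n_traits
    acc_T = [np.zeros((g.t, g.t)) for g in design.groups]
    acc_R = [np.zeros((t, t)) for _ in design.patterns]
    for l in range(s):
        smp = sampler.draw_sample(varstate, resid_ops, l, round_index)
        rhs = op.rhs(smp.y_tilde)
        smp.solution = pcg_solve(
            op, rhs, tol=spec.solver.tol_mc, max_iter=spec.solver.max_iter
        )
        for gi in range(len(design.groups)):
            if variant == "primary":
                acc_T[gi] += _group_quad(smp, gi, design, engine)
            else:
                acc_T[gi] += _group_quad_centered(smp, gi, design, engine)
        eh = smp.solution.e_hat(smp.y_tilde)
        for p, rows in enumerate(design.pattern_rows):
            if variant == "primary":
                E = eh[rows]
                acc_R[p] += E.T @ E
            else:
                D = smp.e_tilde[rows] - eh[rows]
                acc_R[p] += D.T @ D
    T = []
    for gi, layout in enumerate(design.groups):
        mean_q = acc_T[gi] / s
        if variant == "primary":
            Tg = layout.q * varstate.theta[gi] - mean_q
        else:
            Tg = mean_q
        T.append(0.5 * (Tg + Tg.T))
    trw = []
    for p, rows in enumerate(design.pattern_rows):
        obs = np.array(design.patterns[p])
        if variant == "primary":
            est = len(rows) * (varstate.r0 * np.outer(obs, obs)) - acc_R[p] / s
        else:
            est = acc_R[p] / s
        trw.append(0.5 * (est + est.T))
    ts = TraceSet(T=T, trw_pattern=trw, n_ij=design.n_ij.copy(), s_used=s, variant=variant)
    log.info(
        "MC round %d: s=%d, T diag %s",
        round_index,
        s,
        [np.round(np.diag(x), 4).tolist() for x in ts.T],
    )
    return ts
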