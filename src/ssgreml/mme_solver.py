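"""Mixed-model-equations operator, preconditioned conjugate gradients, and
solution-side quadratic forms.

The coefficient matrix C = Q' R^-1 Q + sum_k theta_k^-1 (x) K_k^-1 is applied
without materializing H^-1: the data part routes through the per-record
residual-pattern inverses, the random part through the implicit relationship
operators.  The preconditioner is the block diagonal of C over (level x trait)
blocks, with zero fixed-effect pivots pseudo-inverted so rank-deficient fixed
effects are handled in a least-squares sense.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io_model import DesignSet, ResidualOps
from .params import VarianceState
from .relationships import RelationshipEngine

log = logging.getLogger("ssgreml")


class MMEOperator:
    """Matrix-free v -> C v with a block-diagonal preconditioner."""

    def __init__(
        self,
        design: DesignSet,
        varstate: VarianceState,
        engine: RelationshipEngine,
        resid_ops: Optional[ResidualOps] = None,
    ):
        self.design = design
        self.varstate = varstate
        self.engine = engine
        self.resid = resid_ops or ResidualOps(design, varstate.r0)
        self.theta_inv = []
        for th in varstate.theta:
            try:
                self.theta_inv.append(np.linalg.inv(th))
            except np.linalg.LinAlgError as err:
                raise ValueError("singular group covariance matrix") from err
        self._kinv_diag = {}
        for gi, layout in enumerate(design.groups):
            op = engine.operator_for(layout.kind)
            self._kinv_diag[gi] = op.diagonal() if op is not None else np.ones(layout.q)
        self._build_preconditioner()

    # --- matvec --------------------------------------------------------------

    def matvec(self, v: np.ndarray) -> np.ndarray:
        d = self.design
        F = d.fitted(v)
        W = self.resid.apply_rinv(F)
        out = d.adjoint(W)
        for gi, layout in enumerate(d.groups):
            blk = d.group_block(v, gi)
            op = self.engine.operator_for(layout.kind)
            kinv_blk = op.apply(blk) if op is not None else blk
            out[layout.offset : layout.offset + layout.q * layout.t] += (
                kinv_blk @ self.theta_inv[gi]
            ).ravel()
        return out

    def rhs(self, y: Optional[np.ndarray] = None) -> np.ndarray:
        W = self.resid.apply_rinv(self.design.y if y is None else y)
        return self.design.adjoint(W)

    # --- preconditioner -------------------------------------------------------

    def _build_preconditioner(self):
        d = self.design
        diag = np.zeros(d.n_eq)
        rinv_dd = np.stack([self.resid.rinv_emb[p] for p in d.pattern_of])
        for tm, rows, eq in zip(d.terms, d._term_rows, d._term_eq):
            np.add.at(diag, eq, rinv_dd[rows, tm.trait, tm.trait])
        self._fixed_inv = np.zeros(d.n_eq)
        self._group_blocks = []
        for tm in d.terms:
            if tm.kind == "fixed":
                sl = slice(tm.offset, tm.offset + tm.n_levels)
                dv = diag[sl]
                inv = np.zeros_like(dv)
                nz = dv > 0
                inv[nz] = 1.0 / dv[nz]  # zero pivots pseudo-inverted
                self._fixed_inv[sl] = inv
        for gi, layout in enumerate(d.groups):
            q, t = layout.q, layout.t
            blocks = (
                self.theta_inv[gi][None, :, :] * self._kinv_diag[gi][:, None, None]
            ).copy()
            data_diag = diag[layout.offset : layout.offset + q * t].reshape(q, t)
            ii = np.arange(t)
            blocks[:, ii, ii] += data_diag
            self._group_blocks.append(np.linalg.inv(blocks))

    def precond(self, r: np.ndarray) -> np.ndarray:
        d = self.design
        z = r * self._fixed_inv
        for gi, layout in enumerate(d.groups):
            q, t = layout.q, layout.t
            blk = r[layout.offset : layout.offset + q * t].reshape(q, t)
            z[layout.offset : layout.offset + q * t] = np.einsum(
                "qij,qj->qi", self._group_blocks[gi], blk
            ).ravel()
        return z


@dataclass
class MMESolution:
    x: np.ndarray
    design: DesignSet
    iterations: int
    rel_residual: float
    converged: bool
    flagged: bool = False

    def u_hat(self, gi: int) -> np.ndarray:
        """Group-k solutions as a (levels, trait-columns) array."""
        return self.design.group_block(self.x, gi)

    def y_hat(self) -> np.ndarray:
        return self.design.fitted(self.x)

    def e_hat(self, y: Optional[np.ndarray] = None) -> np.ndarray:
        """Residuals y - Q sol on observed cells, zeros elsewhere."""
        y = self.design.y if y is None else y
        e = y - self.y_hat()
        e[~self.design.mask] = 0.0
        return e


def pcg_solve(
    op: MMEOperator,
    rhs: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 5000,
    warm_start: Optional[np.ndarray] = None,
) -> MMESolution:
    """Preconditioned conjugate gradients on C x = rhs.

    Deterministic given (operator, rhs, tol, warm_start).  Reaching max_iter
    flags the solution with a warning; NaNs abort.
    """
    rhs_norm = float(np.linalg.norm(rhs))
    if rhs_norm == 0.0:
        return MMESolution(np.zeros_like(rhs), op.design, 0, 0.0, True)
    x = np.zeros_like(rhs) if warm_start is None else warm_start.copy()
    r = rhs - op.matvec(x) if warm_start is not None else rhs.copy()
    z = op.precond(r)
    p = z.copy()
    rz = float(r @ z)
    it = 0
    rel = float(np.linalg.norm(r)) / rhs_norm
    while rel > tol and it < max_iter:
        Ap = op.matvec(p)
        pAp = float(p @ Ap)
        if not np.isfinite(pAp) or pAp <= 0.0:
            raise FloatingPointError("PCG breakdown: operator not positive definite")
        alpha = rz / pAp
        x += alpha * p
        r -= alpha * Ap
        if not np.all(np.isfinite(r)):
            raise FloatingPointError("NaN in PCG iterates")
        z = op.precond(r)
        rz_new = float(r @ z)
        p = z + (rz_new / rz) * p
        rz = rz_new
        it += 1
        rel = float(np.linalg.norm(r)) / rhs_norm
    converged = rel <= tol
    if not converged:
        log.warning("PCG hit max_iter=%d (rel residual %.3g)", max_iter, rel)
    return MMESolution(x, op.design, it, rel, converged, flagged=not converged)


@dataclass
class QuadForms:
    """Solution quadratic forms S_k = u_i' K^-1 u_j and residual products."""

    S: list[np.ndarray]  # per group, (t_k, t_k)
    ee: np.ndarray  # (t,t) residual cross products over shared records
    ree: np.ndarray  # (t,t) cross products of R^-1-weighted residuals
    n_ij: np.ndarray
    e_hat: np.ndarray = field(repr=False, default=None)


def compute_quadforms(
    sol: MMESolution,
    varstate: VarianceState,
    engine: RelationshipEngine,
    resid_ops: ResidualOps,
) -> QuadForms:
    d = sol.design
    S = []
    for gi, layout in enumerate(d.groups):
        U = sol.u_hat(gi)
        op = engine.operator_for(layout.kind)
        KU = op.apply(U) if op is not None else U
        Sg = U.T @ KU
        S.append(0.5 * (Sg + Sg.T))
    e = sol.e_hat()
    re = resid_ops.apply_rinv(e)
    return QuadForms(S=S, ee=e.T @ e, ree=re.T @ re, n_ij=d.n_ij.copy(), e_hat=e)
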