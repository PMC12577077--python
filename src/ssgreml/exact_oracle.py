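"""Brute-force dense reference computations on small instances.

Everything here trades memory for transparency: the coefficient matrix C is
materialized and inverted, the phenotypic covariance V is formed explicitly on
tiny fixtures, and traces are read off dense inverse blocks.  This module is
the exact ss-GREML benchmark that the Monte Carlo machinery is validated
against, and it also provides the deterministic restricted log-likelihood
pieces used for convergence monitoring.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .io_model import UNKNOWN, DesignSet, Pedigree, ResidualOps
from .mc_traces import TraceSet
from .params import VarianceState
from .relationships import RelationshipEngine

MEMORY_GUARD_EQ = 5000  # dense paths refuse beyond this many equations


def tabular_a(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method."""
    n = ped.n_animals
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(n)
        if s != UNKNOWN:
            row += 0.5 * A[s]
        if d != UNKNOWN:
            row += 0.5 * A[d]
        A[i, :i] = row[:i]
        A[:i, i] = row[:i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if s != UNKNOWN and d != UNKNOWN else 0.0)
    return A


def dense_h(engine: RelationshipEngine) -> np.ndarray:
    """Dense single-step H from the blended G and the pedigree A."""
    A = tabular_a(engine.ped_kin.ped)
    gk = engine.genomic
    if gk is None:
        return A
    geno = gk.ids
    non = np.setdiff1d(np.arange(A.shape[0]), geno)
    G = engine.apy.implied_g() if engine.apy is not None else gk.g_blend
    if engine.apy is not None:
        order = np.concatenate([engine.apy.core, engine.apy.noncore])
        rank = np.empty_like(order)
        rank[order] = np.arange(len(order))
        G = G[np.ix_(rank, rank)]  # back to natural genotyped order
    a22 = gk.a22
    a22_inv = np.linalg.inv(a22)
    a12 = A[np.ix_(non, geno)]
    W = a12 @ a22_inv
    H = A.copy()
    H[np.ix_(geno, geno)] = G
    H[np.ix_(non, geno)] = W @ G
    H[np.ix_(geno, non)] = (W @ G).T
    H[np.ix_(non, non)] = A[np.ix_(non, non)] + W @ (G - a22) @ W.T
    return H


class DenseReference:
    """Dense C, its inverse, and trace/AI building blocks for one theta."""

    def __init__(self, design: DesignSet, varstate: VarianceState, engine: RelationshipEngine):
        if design.n_eq > MEMORY_GUARD_EQ:
            raise MemoryError(
                f"dense reference limited to {MEMORY_GUARD_EQ} equations "
                f"(got {design.n_eq})"
            )
        self.design = design
        self.varstate = varstate
        self.engine = engine
        self.resid = ResidualOps(design, varstate.r0)
        Q, rec, trait = design.qobs_sparse()
        self.Q, self.cell_rec, self.cell_trait = Q, rec, trait
        # residual inverse over stacked observed cells
        rinv_cells = np.zeros((len(rec), len(rec)))
        t = design.n_traits
        cell_of = -np.ones((design.n_records, t), dtype=np.int64)
        cell_of[rec, trait] = np.arange(len(rec))
        for p, rows in enumerate(design.pattern_rows):
            obs = np.where(np.array(design.patterns[p]))[0]
            inv = np.linalg.inv(varstate.r0[np.ix_(obs, obs)])
            for r in rows:
                cells = cell_of[r, obs]
                rinv_cells[np.ix_(cells, cells)] = inv
        self.rinv_cells = rinv_cells
        self.kinv: dict[int, np.ndarray | None] = {}
        for gi, layout in enumerate(design.groups):
            op = engine.operator_for(layout.kind)
            self.kinv[gi] = op.dense() if op is not None else None
        C = (Q.T @ rinv_cells @ Q.toarray()) if sp.issparse(Q) else None
        C = np.asarray(C)
        for gi, layout in enumerate(design.groups):
            theta_inv = np.linalg.inv(varstate.theta[gi])
            kin = self.kinv[gi] if self.kinv[gi] is not None else np.eye(layout.q)
            block = np.kron(kin, theta_inv)  # level-major equation layout
            sl = slice(layout.offset, layout.offset + layout.q * layout.t)
            C[sl, sl] += block
        self.C = 0.5 * (C + C.T)
        self.chol = sla.cho_factor(self.C, lower=True)
        self.logdet_c = float(2.0 * np.sum(np.log(np.diag(self.chol[0]))))
        self.Cinv = sla.cho_solve(self.chol, np.eye(design.n_eq))

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return sla.cho_solve(self.chol, rhs)

    # --- traces ---------------------------------------------------------------

    def exact_traces(self) -> TraceSet:
        d = self.design
        T = []
        for gi, layout in enumerate(d.groups):
            q, t = layout.q, layout.t
            sl = slice(layout.offset, layout.offset + q * t)
            B4 = self.Cinv[sl, sl].reshape(q, t, q, t)
            if self.kinv[gi] is None:
                Tg = np.einsum("lilj->ij", B4)
            else:
                Tg = np.einsum("lm,milj->ij", self.kinv[gi], B4)
            T.append(0.5 * (Tg + Tg.T))
        trw = self._per_pattern_w_sums()
        return TraceSet(T=T, trw_pattern=trw, n_ij=d.n_ij.copy(), s_used=0, variant="exact")

    def _per_pattern_w_sums(self) -> list[np.ndarray]:
        """sum over records of [Q C^-1 Q']_r(i,j), stratified by pattern."""
        d = self.design
        t = d.n_traits
        n_rec = d.n_records
        # per-trait full-record incidence (zero rows where trait missing)
        cell_of = -np.ones((n_rec, t), dtype=np.int64)
        cell_of[self.cell_rec, self.cell_trait] = np.arange(len(self.cell_rec))
        Zt = []
        Qcsr = self.Q.tocsr()
        for j in range(t):
            rows_obs = np.where(cell_of[:, j] >= 0)[0]
            sub = Qcsr[cell_of[rows_obs, j]].tocoo()
            Z = sp.csr_matrix(
                (sub.data, (rows_obs[sub.row], sub.col)), shape=(n_rec, d.n_eq)
            )
            Zt.append(Z)
        out = [np.zeros((t, t)) for _ in d.patterns]
        for j in range(t):
            Yj = np.asarray(Zt[j] @ self.Cinv)  # (n_rec, n_eq)
            for i in range(t):
                diag = np.asarray(Zt[i].multiply(Yj).sum(axis=1)).ravel()
                for p, rows in enumerate(d.pattern_rows):
                    out[p][i, j] = diag[rows].sum()
        return [0.5 * (m + m.T) for m in out]

    # --- dense V path (tiny fixtures) -----------------------------------------

    def dense_v(self) -> np.ndarray:
        d = self.design
        n_cells = len(self.cell_rec)
        V = np.linalg.inv(self.rinv_cells)  # residual part over observed cells
        for gi, layout in enumerate(d.groups):
            kin = (
                np.linalg.inv(self.kinv[gi])
                if self.kinv[gi] is not None
                else np.eye(layout.q)
            )
            sl = slice(layout.offset, layout.offset + layout.q * layout.t)
            Zg = self.Q[:, sl].toarray().reshape(n_cells, layout.q, layout.t)
            th = self.varstate.theta[gi]
            V += np.einsum("alt,ts,lm,bms->ab", Zg, th, kin, Zg, optimize=True)
        return 0.5 * (V + V.T)

    def x_dense(self) -> np.ndarray:
        d = self.design
        cols = []
        for tm in d.terms:
            if tm.kind == "fixed":
                cols.append(self.Q[:, tm.offset : tm.offset + tm.n_levels].toarray())
        if not cols:
            return np.zeros((len(self.cell_rec), 0))
        return np.hstack(cols)

    def loglik_via_v(self) -> float:
        """-2 restricted logL via the explicit V decomposition."""
        V = self.dense_v()
        X = self.x_dense()
        y = self.design.y[self.cell_rec, self.cell_trait]
        Vinv = np.linalg.inv(V)
        sign, logdet_v = np.linalg.slogdet(V)
        XVX = X.T @ Vinv @ X
        P = Vinv
        if X.shape[1]:
            XVXi = np.linalg.inv(XVX)
            P = Vinv - Vinv @ X @ XVXi @ X.T @ Vinv
            sign_x, logdet_x = np.linalg.slogdet(XVX)
        else:
            logdet_x = 0.0
        return float(logdet_v + logdet_x + y @ P @ y)

    def dense_p(self) -> np.ndarray:
        V = self.dense_v()
        X = self.x_dense()
        Vinv = np.linalg.inv(V)
        if not X.shape[1]:
            return Vinv
        return Vinv - Vinv @ X @ np.linalg.inv(X.T @ Vinv @ X) @ X.T @ Vinv


def finite_difference_gradient(
    minus2ll, varstate: VarianceState, step: float = 1e-5
) -> np.ndarray:
    """Central differences of -2 logL over the free parameters.

    ``minus2ll`` is a callable VarianceState -> float.
    """
    if step <= 0 or step < 1e-12:
        raise ValueError("step underflow")
    base = varstate.free_values()
    grad = np.zeros(len(base))
    for p in range(len(base)):
        h = step * max(1.0, abs(base[p]))
        up = base.copy()
        up[p] += h
        dn = base.copy()
        dn[p] -= h
        grad[p] = (minus2ll(varstate.with_free(up)) - minus2ll(varstate.with_free(dn))) / (
            2.0 * h
        )
    return grad


def exact_reml_reference(design, engine, spec, start=None, method="ai"):
    """Run the REML loop with exact traces substituted; the benchmark that
    MC runs are compared against."""
    from .reml_engine import run_reml

    return run_reml(design, engine, spec, method=method, traces="exact", start=start)
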