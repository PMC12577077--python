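"""Pedigree and genomic relationship structures for single-step models.

Provides the inverse numerator relationship matrix A^-1 (Henderson's rules
with inbreeding from the Meuwissen-Luo recursion), indirect products with A
(Colleau's method), the A22 sub-block machinery, the VanRaden method-1 genomic
matrix with J-factor adjustment and residual-polygenic blending, the APY
core/non-core decomposition, and the implicit H^-1 operator

    x' H^-1 y = x' A^-1 y + x2' G^-1 y2 - x2' A22^-1 y2

which never forms H explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .io_model import UNKNOWN, GenotypeSet, Pedigree

log = logging.getLogger("ssgreml")


# ---------------------------------------------------------------------------
# pedigree side
# ---------------------------------------------------------------------------


def compute_inbreeding_phi(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Inbreeding coefficients F and Mendelian-sampling variance fractions phi.

    F follows the Meuwissen-Luo recursion: A_ii = sum_j L_ij^2 d_j over the
    ancestors j of i, accumulated by walking the L row of each animal down the
    (topologically ordered) pedigree.  phi is the within-family variance of a
    breeding value given the parents:

        both parents known:  0.5 - 0.25 (F_s + F_d)
        one parent known:    0.75 - 0.25 F_known
        founders:            1
    """
    n = ped.n_animals
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    phi = np.ones(n)
    Lrow = np.zeros(n + 1)
    for i in range(n):
        s, d = sire[i], dam[i]
        # phi depends only on the parents' (already computed) inbreeding
        if s != UNKNOWN and d != UNKNOWN:
            phi[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s != UNKNOWN or d != UNKNOWN:
            known = s if s != UNKNOWN else d
            phi[i] = 0.75 - 0.25 * F[known]
        else:
            phi[i] = 1.0
        if s == UNKNOWN and d == UNKNOWN:
            F[i] = 0.0
        else:
            Lrow[: i + 1] = 0.0
            Lrow[i] = 1.0
            aii = 0.0
            for cur in range(i, -1, -1):
                l = Lrow[cur]
                if l == 0.0:
                    continue
                aii += l * l * phi[cur]
                cs, cd = sire[cur], dam[cur]
                if cs != UNKNOWN:
                    Lrow[cs] += 0.5 * l
                if cd != UNKNOWN:
                    Lrow[cd] += 0.5 * l
            F[i] = aii - 1.0
        # phi enters the diagonal of D in A = T D T'; correct by construction,
        # but guard against corrupt pedigrees
        if phi[i] <= 0.0:
            raise ValueError(f"non-positive Mendelian variance for animal {i}")
    return F, phi


def build_a_inverse(ped: Pedigree, phi: np.ndarray) -> sp.csc_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding (d_i = phi_i)."""
    if np.any(phi <= 0.0):
        raise ValueError("non-positive Mendelian variance (corrupt F)")
    n = ped.n_animals
    rows, cols, vals = [], [], []
    for i in range(n):
        dinv = 1.0 / phi[i]
        idx = [i]
        coef = [1.0]
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN:
                idx.append(p)
                coef.append(-0.5)
        for a, ca in zip(idx, coef):
            for b, cb in zip(idx, coef):
                rows.append(a)
                cols.append(b)
                vals.append(dinv * ca * cb)
    return sp.csc_matrix((vals, (rows, cols)), shape=(n, n))


def colleau_matmat(ped: Pedigree, phi: np.ndarray, V: np.ndarray) -> np.ndarray:
    """A @ V without forming A, via A = (I-P)^-1 D (I-P)^-T (Colleau's
    indirect method); V is (n, k)."""
    n = ped.n_animals
    V = np.atleast_2d(V.T).T
    Z = V.copy().astype(np.float64)
    # (I-P)^T z = v  -> reverse order
    for i in range(n - 1, -1, -1):
        zi = Z[i]
        if ped.sire[i] != UNKNOWN:
            Z[ped.sire[i]] += 0.5 * zi
        if ped.dam[i] != UNKNOWN:
            Z[ped.dam[i]] += 0.5 * zi
    Z *= phi[:, None]
    # (I-P) w = D z -> forward order
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s != UNKNOWN:
            Z[i] += 0.5 * Z[s]
        if d != UNKNOWN:
            Z[i] += 0.5 * Z[d]
    return Z


@dataclass
class PedigreeKinship:
    ped: Pedigree
    F: np.ndarray
    phi: np.ndarray
    a_inv: sp.csc_matrix

    @property
    def logdet_a(self) -> float:
        # |A| = prod d_i for A = T D T' with unit-triangular T
        return float(np.sum(np.log(self.phi)))


def build_pedigree_kinship(ped: Pedigree) -> PedigreeKinship:
    F, phi = compute_inbreeding_phi(ped)
    return PedigreeKinship(ped, F, phi, build_a_inverse(ped, phi))


# ---------------------------------------------------------------------------
# genomic side
# ---------------------------------------------------------------------------


@dataclass
class GenomicKinship:
    ids: np.ndarray  # pedigree codes of genotyped animals
    g_raw: np.ndarray  # M M' / (2 sum p q)
    a22: np.ndarray  # pedigree relationships among genotyped animals
    j_var: float  # v = n^-2 1'(A22 - G_raw)1
    g_blend: np.ndarray
    a_cols_geno: np.ndarray  # full A columns at genotyped animals (n x n_g)


def build_genomic(
    genotypes: GenotypeSet,
    ped_kin: PedigreeKinship,
    alpha: float,
    blend: str = "variance",
) -> GenomicKinship:
    """VanRaden method-1 G with J-factor mean alignment and residual-polygenic
    blending with A22.

    The J-factor variance v = n^-2 1'(A22 - G_raw)1 aligns the genomic base
    with the pedigree base.  The default 'variance' convention blends as
    (1-alpha)(G_raw + v 11') + alpha A22, which is the covariance the breeding
    value sampler realizes; the 'sqrt' convention uses sqrt(1-alpha)/sqrt(alpha)
    weights instead.
    """
    ids = genotypes.ids
    n = len(ids)
    ecol = np.zeros((ped_kin.ped.n_animals, n))
    ecol[ids, np.arange(n)] = 1.0
    a_cols = colleau_matmat(ped_kin.ped, ped_kin.phi, ecol)
    a22 = a_cols[ids]
    a22 = 0.5 * (a22 + a22.T)
    M = genotypes.M
    g_raw = (M @ M.T) / genotypes.center_scale
    j_var = float(np.mean(a22 - g_raw))
    if j_var < 0.0:
        log.warning("negative J-factor variance %.3g clipped to 0", j_var)
        j_var = 0.0
    if blend == "variance":
        g_blend = (1.0 - alpha) * (g_raw + j_var) + alpha * a22
    else:
        g_blend = np.sqrt(1.0 - alpha) * (g_raw + j_var) + np.sqrt(alpha) * a22
    g_blend = 0.5 * (g_blend + g_blend.T)
    try:
        np.linalg.cholesky(g_blend)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "blended genomic matrix not positive definite; increase alpha"
        ) from err
    return GenomicKinship(ids, g_raw, a22, j_var, g_blend, a_cols)


@dataclass
class ApyParts:
    core: np.ndarray  # positions (within the genotyped set) of core animals
    noncore: np.ndarray
    p_nc: np.ndarray  # G_nc G_cc^-1
    psi: np.ndarray  # diag(G_nn - G_nc G_cc^-1 G_cn)
    g_cc: np.ndarray
    g_cc_chol: np.ndarray

    @property
    def logdet_g(self) -> float:
        return float(
            2.0 * np.sum(np.log(np.diag(self.g_cc_chol))) + np.sum(np.log(self.psi))
        )

    def implied_g(self) -> np.ndarray:
        """Dense APY-implied genomic matrix in (core, noncore) order."""
        top = np.hstack([self.g_cc, self.g_cc @ self.p_nc.T])
        gnn = self.p_nc @ self.g_cc @ self.p_nc.T + np.diag(self.psi)
        bottom = np.hstack([self.p_nc @ self.g_cc, gnn])
        return np.vstack([top, bottom])

    def inverse_dense(self) -> np.ndarray:
        """Dense evaluation of the sparse APY inverse (core, noncore order)."""
        gcc_inv = sla.cho_solve((self.g_cc_chol, True), np.eye(len(self.core)))
        psi_inv = 1.0 / self.psi
        tl = gcc_inv + self.p_nc.T @ (psi_inv[:, None] * self.p_nc)
        tr = -self.p_nc.T * psi_inv
        return np.block([[tl, tr], [tr.T, np.diag(psi_inv)]])


def apy_decompose(gk: GenomicKinship, core_positions: np.ndarray) -> ApyParts:
    """Split the blended G into APY core/non-core parts."""
    n = gk.g_blend.shape[0]
    core = np.asarray(sorted(core_positions), dtype=np.int64)
    if len(core) == 0:
        raise ValueError("core set must be non-empty")
    noncore = np.setdiff1d(np.arange(n), core)
    g_cc = gk.g_blend[np.ix_(core, core)]
    try:
        chol = np.linalg.cholesky(g_cc)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular core block G_cc") from err
    g_nc = gk.g_blend[np.ix_(noncore, core)]
    p_nc = sla.cho_solve((chol, True), g_nc.T).T
    g_nn_diag = np.diag(gk.g_blend)[noncore]
    psi = g_nn_diag - np.einsum("ij,ij->i", p_nc, g_nc)
    if len(noncore) and np.any(psi <= 0.0):
        raise ValueError("non-positive APY conditional variance Psi")
    return ApyParts(core, noncore, p_nc, psi, g_cc, chol)


def select_core(n_genotyped: int, n_core: int, seed: int) -> np.ndarray:
    """Uniform random core selection without replacement, seeded."""
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_genotyped, size=n_core, replace=False))


# ---------------------------------------------------------------------------
# H^-1 operator
# ---------------------------------------------------------------------------


class HInverseOperator:
    """Implicit symmetric positive-definite H^-1 for ssGBLUP models.

    matvec(x) = A^-1 x + scatter(G^-1 x2 - A22^-1 x2); with an empty genotyped
    set this reduces to A^-1.  The genomic backend is either the dense inverse
    of the blended G or the sparse APY representation; A22^-1 has two
    cross-checked backends (direct dense factorization of A22, and the
    identity A22^-1 x2 = B22 x2 - B21 B11^-1 B12 x2 on the blocks B of A^-1).
    """

    def __init__(
        self,
        ped_kin: PedigreeKinship,
        genomic: Optional[GenomicKinship] = None,
        apy: Optional[ApyParts] = None,
        a22_backend: str = "direct",
    ):
        self.ped_kin = ped_kin
        self.genomic = genomic
        self.apy = apy
        self.a22_backend = a22_backend
        n = ped_kin.ped.n_animals
        self.n = n
        if genomic is None:
            self.geno = np.array([], dtype=np.int64)
            return
        self.geno = genomic.ids
        self.nongeno = np.setdiff1d(np.arange(n), self.geno)
        self._a22_chol = sla.cho_factor(genomic.a22, lower=True)
        self.logdet_a22 = float(2.0 * np.sum(np.log(np.diag(self._a22_chol[0]))))
        ainv = ped_kin.a_inv.tocsr()
        self._B11 = ainv[self.nongeno][:, self.nongeno].tocsc()
        self._B12 = ainv[self.nongeno][:, self.geno].tocsc()
        self._B22 = ainv[self.geno][:, self.geno].tocsc()
        self._B11_lu = spla.splu(self._B11) if len(self.nongeno) else None
        if apy is not None:
            self._ginv = apy.inverse_dense()  # desk scale; (core, noncore) order
            self._apy_order = np.concatenate([apy.core, apy.noncore])
            self._apy_rank = np.empty_like(self._apy_order)
            self._apy_rank[self._apy_order] = np.arange(len(self._apy_order))
            self.logdet_g = apy.logdet_g
        else:
            gch = np.linalg.cholesky(genomic.g_blend)
            self._ginv = sla.cho_solve((gch, True), np.eye(len(self.geno)))
            self._apy_rank = None
            self.logdet_g = float(2.0 * np.sum(np.log(np.diag(gch))))

    # --- component applications --------------------------------------------

    def g_inv_apply(self, x2: np.ndarray) -> np.ndarray:
        if self._apy_rank is not None:
            return (self._ginv @ x2[self._apy_order])[self._apy_rank]
        return self._ginv @ x2

    def a22_apply(self, x2: np.ndarray, mode: str = "solve", backend: Optional[str] = None):
        """A22^-1 x2 ('solve') or x2' A22^-1 x2 ('quad')."""
        backend = backend or self.a22_backend
        if backend == "direct":
            w = sla.cho_solve(self._a22_chol, x2)
        elif backend == "identity":
            w = self._B22 @ x2
            if self._B11_lu is not None:
                w -= self._B12.T @ self._B11_lu.solve(np.asarray(self._B12 @ x2))
        else:
            raise ValueError(f"unknown A22 backend {backend!r}")
        if mode == "solve":
            return w
        if mode == "quad":
            return float(np.sum(x2 * w))
        raise ValueError(f"unknown mode {mode!r}")

    def a12_a22inv(self, delta: np.ndarray, backend: str = "sparse") -> np.ndarray:
        """A12 A22^-1 delta over the non-genotyped animals.

        Default 'sparse' backend uses A12 A22^-1 = -(B11)^-1 B12 on the blocks
        of A^-1; 'direct' solves A22 w = delta and multiplies by dense A12.
        """
        if len(self.nongeno) == 0:
            return np.zeros((0,) + delta.shape[1:])
        if backend == "sparse":
            return -self._B11_lu.solve(np.asarray(self._B12 @ delta))
        if backend == "direct":
            w = sla.cho_solve(self._a22_chol, delta)
            a12 = self.genomic.a_cols_geno[self.nongeno]
            return a12 @ w
        raise ValueError(f"unknown backend {backend!r}")

    # --- operator interface --------------------------------------------------

    def apply(self, x: np.ndarray) -> np.ndarray:
        """H^-1 x for x of shape (n,) or (n, k)."""
        out = np.asarray(self.ped_kin.a_inv @ x)
        if len(self.geno):
            x2 = x[self.geno]
            out[self.geno] += self.g_inv_apply(x2) - self.a22_apply(x2, "solve")
        return out

    def bilinear(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """x' H^-1 y via the three-term decomposition; accepts (n,k) blocks,
        returning the (k,k) Gram matrix."""
        x = x if x.ndim == 2 else x[:, None]
        y2 = y if y.ndim == 2 else y[:, None]
        out = x.T @ self.apply(y2)
        return out

    def diagonal(self) -> np.ndarray:
        d = np.asarray(self.ped_kin.a_inv.diagonal()).copy()
        if len(self.geno):
            a22inv_diag = np.diag(
                sla.cho_solve(self._a22_chol, np.eye(len(self.geno)))
            )
            if self._apy_rank is not None:
                gdiag = np.diag(self._ginv)[self._apy_rank]
            else:
                gdiag = np.diag(self._ginv)
            d[self.geno] += gdiag - a22inv_diag
        return d

    @property
    def logdet_h(self) -> float:
        """log|H| = log|A| - log|A22| + log|G|."""
        ld = self.ped_kin.logdet_a
        if len(self.geno):
            ld += self.logdet_g - self.logdet_a22
        return ld

    def dense(self) -> np.ndarray:
        """Dense H^-1 (desk scale only)."""
        out = self.ped_kin.a_inv.toarray()
        if len(self.geno):
            x2 = np.eye(len(self.geno))
            blk = self.g_inv_apply(x2) - self.a22_apply(x2, "solve")
            out[np.ix_(self.geno, self.geno)] += blk
        return out

    def self_test(self, rng=None, tol: float = 1e-6) -> None:
        """Cross-check the two A22 backends on a random probe."""
        if not len(self.geno):
            return
        rng = rng or np.random.default_rng(0)
        x = rng.standard_normal(len(self.geno))
        wa = self.a22_apply(x, "solve", backend="direct")
        wb = self.a22_apply(x, "solve", backend="identity")
        if np.max(np.abs(wa - wb)) > tol:
            raise RuntimeError("A22 backend disagreement beyond tolerance")


@dataclass
class RelationshipEngine:
    """All relationship operators needed by one model."""

    ped_kin: PedigreeKinship
    genomic: Optional[GenomicKinship]
    apy: Optional[ApyParts]
    h_op: Optional[HInverseOperator]  # for 'h' groups
    a_op: HInverseOperator  # pedigree-only operator (empty genotyped set)

    def operator_for(self, kind: str) -> Optional[HInverseOperator]:
        if kind == "h":
            return self.h_op
        if kind == "a":
            return self.a_op
        return None  # identity


def build_engine(ped, genotypes, spec) -> RelationshipEngine:
    ped_kin = build_pedigree_kinship(ped)
    a_op = HInverseOperator(ped_kin, None)
    genomic = apy = h_op = None
    if genotypes is not None and any(g.kind == "h" for g in spec.random_groups):
        genomic = build_genomic(genotypes, ped_kin, spec.alpha, spec.blend)
        if spec.apy.enabled:
            n_core = spec.apy.n_core or genotypes.n_genotyped
            core = select_core(genotypes.n_genotyped, n_core, spec.apy.seed)
            apy = apy_decompose(genomic, core)
        h_op = HInverseOperator(ped_kin, genomic, apy)
    return RelationshipEngine(ped_kin, genomic, apy, h_op, a_op)


def write_matrix_market(path, matrix) -> None:
    """Debug writer for A^-1 / G in Matrix Market format."""
    from scipy.io import mmwrite

    mmwrite(str(path), sp.coo_matrix(matrix))
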