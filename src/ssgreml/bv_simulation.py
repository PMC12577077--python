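"""Simulation of random effects with the exact model covariance structure.

The centerpiece samples breeding values u ~ N(0, G0 (x) H) without ever
forming H: pedigree gene dropping gives a ~ N(0, G0 (x) A); marker effects,
a J-factor mean term and the polygenic fraction are combined on the genotyped
animals; and the non-genotyped animals receive the imputation-consistent
correction A12 A22^-1 delta.  An APY variant restricts the genomic part to the
core animals and adds conditional noise psi for the non-core.  All draws are
made through counter-keyed streams so a round can reuse the identical random
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._streams import stream
from .io_model import UNKNOWN, DesignSet, GenotypeSet, Pedigree, ResidualOps
from .params import VarianceState
from .relationships import ApyParts, HInverseOperator, RelationshipEngine


def _blend_weights(alpha: float, convention: str) -> tuple[float, float]:
    """Sampler weights (w_genomic, w_polygenic); their squares are the blending
    coefficients applied to (G_raw + v 11') and A22 respectively."""
    if convention == "variance":
        return float(np.sqrt(1.0 - alpha)), float(np.sqrt(alpha))
    return float((1.0 - alpha) ** 0.25), float(alpha**0.25)


def _pedigree_levels(ped: Pedigree) -> list[np.ndarray]:
    depth = ped.depth_levels()
    return [np.where(depth == l)[0] for l in range(depth.max() + 1)]


def gene_drop(
    ped: Pedigree,
    phi: np.ndarray,
    chol_theta: np.ndarray,
    rng,
    shape: tuple = (),
    levels: Optional[list[np.ndarray]] = None,
) -> np.ndarray:
    """Pedigree-only breeding values a ~ N(0, theta (x) A).

    a_i = 0.5 (a_s + a_d) + L x sqrt(phi_i); unknown parents contribute 0.
    Vectorized over pedigree depth levels and over an arbitrary batch shape.
    """
    n = ped.n_animals
    t = chol_theta.shape[0]
    x = rng.standard_normal(shape + (n, t))
    noise = (x @ chol_theta.T) * np.sqrt(phi)[:, None]
    a = np.zeros(shape + (n, t))
    for idx in levels if levels is not None else _pedigree_levels(ped):
        s, d = ped.sire[idx], ped.dam[idx]
        ps = a[..., s, :] * (s != UNKNOWN)[:, None]
        pd = a[..., d, :] * (d != UNKNOWN)[:, None]
        a[..., idx, :] = 0.5 * (ps + pd) + noise[..., idx, :]
    return a


def sample_genomic_terms(
    genotypes: GenotypeSet, j_var: float, chol_theta: np.ndarray, rng, shape: tuple = ()
) -> tuple[np.ndarray, np.ndarray]:
    """Marker effects g (per-locus variance (2 sum pq)^-1 theta) and the
    J-factor mean draw mu (variance v theta)."""
    if j_var < 0.0:
        raise ValueError("negative J-factor variance: relationship matrices inconsistent")
    t = chol_theta.shape[0]
    m = genotypes.n_loci
    xg = rng.standard_normal(shape + (m, t))
    g = (xg @ chol_theta.T) / np.sqrt(genotypes.center_scale)
    xm = rng.standard_normal(shape + (1, t))
    mu = (xm @ chol_theta.T) * np.sqrt(j_var)
    return g, mu


def _apply_a12_a22inv(hop: HInverseOperator, delta: np.ndarray) -> np.ndarray:
    """Batched A12 A22^-1 delta for delta of shape (..., n_g, t)."""
    lead = delta.shape[:-2]
    n_g, t = delta.shape[-2:]
    flat = np.moveaxis(delta.reshape(-1, n_g, t), 0, -1).reshape(n_g, -1)
    out = hop.a12_a22inv(flat)
    n1 = out.shape[0]
    out = np.moveaxis(out.reshape(n1, t, -1)[..., :], -1, 0).reshape(lead + (n1, t))
    return out


def combine_ssgblup(
    a: np.ndarray,
    g: np.ndarray,
    mu: np.ndarray,
    alpha: float,
    genotypes: GenotypeSet,
    hop: HInverseOperator,
    convention: str = "variance",
) -> tuple[np.ndarray, np.ndarray]:
    """Turn pedigree-sampled a into u ~ N(0, theta (x) H).

    u2 = w_g (1 mu + M g) + w_a a2 on the genotyped animals,
    delta = w_g (1 mu + M g) + (w_a - 1) a2,
    u1 = A12 A22^-1 delta + a1 on the rest.
    """
    wg, wa = _blend_weights(alpha, convention)
    return _combine(a, g, mu, wg, wa, genotypes.M, hop.geno, hop)


def _combine(a, g, mu, wg, wa, M, geno, hop):
    mg = M @ g  # (..., n_g, t)
    genomic_part = wg * (mu + mg)
    a2 = a[..., geno, :]
    u = a.copy()
    u[..., geno, :] = genomic_part + wa * a2
    delta = genomic_part + (wa - 1.0) * a2
    if len(hop.nongeno):
        u[..., hop.nongeno, :] += _apply_a12_a22inv(hop, delta)
    return u, delta


def combine_apy(
    a: np.ndarray,
    g: np.ndarray,
    mu: np.ndarray,
    alpha: float,
    apy: ApyParts,
    genotypes: GenotypeSet,
    hop: HInverseOperator,
    rng,
    chol_theta: np.ndarray,
    shape: tuple = (),
    convention: str = "variance",
) -> tuple[np.ndarray, np.ndarray]:
    """APY variant: the genomic part uses only the core animals; non-core
    values are the conditional mean P_nc u_c plus diagonal noise psi."""
    wg, wa = _blend_weights(alpha, convention)
    geno = hop.geno
    core, noncore = apy.core, apy.noncore
    Mc = genotypes.M[core]
    mg_c = Mc @ g
    genomic_c = wg * (mu + mg_c)
    a2 = a[..., geno, :]
    a_c = a2[..., core, :]
    u_c = genomic_c + wa * a_c
    delta_c = genomic_c + (wa - 1.0) * a_c
    t = chol_theta.shape[0]
    xpsi = rng.standard_normal(shape + (len(noncore), t))
    psi = (xpsi @ chol_theta.T) * np.sqrt(apy.psi)[:, None]
    u_n = apy.p_nc @ u_c + psi
    delta_n = u_n - a2[..., noncore, :]
    u2 = np.zeros_like(a2)
    u2[..., core, :] = u_c
    u2[..., noncore, :] = u_n
    delta = np.zeros_like(a2)
    delta[..., core, :] = delta_c
    delta[..., noncore, :] = delta_n
    u = a.copy()
    u[..., geno, :] = u2
    if len(hop.nongeno):
        u[..., hop.nongeno, :] += _apply_a12_a22inv(hop, delta)
    return u, delta


def sample_identity(q: int, chol_theta: np.ndarray, rng, shape: tuple = ()) -> np.ndarray:
    """Draws for identity-structured groups: N(0, theta (x) I_q)."""
    t = chol_theta.shape[0]
    x = rng.standard_normal(shape + (q, t))
    return x @ chol_theta.T


@dataclass
class MCSample:
    """One simulated realization and (later) its MME solution."""

    u: dict[int, np.ndarray]  # per group: (q, t) draws
    e_tilde: np.ndarray
    y_tilde: np.ndarray
    solution: object = None
    delta: Optional[np.ndarray] = field(default=None, repr=False)


class EffectSampler:
    """Draws all random effects of a model with the current theta.

    Stream keys are (base_seed, sample_index, site, round_key); with
    reuse_sequence the round key is pinned to 0 so every round consumes the
    identical standard-normal sequence.
    """

    def __init__(
        self,
        design: DesignSet,
        engine: RelationshipEngine,
        genotypes: Optional[GenotypeSet],
        spec,
    ):
        self.design = design
        self.engine = engine
        self.genotypes = genotypes
        self.spec = spec
        self.levels = _pedigree_levels(design.pedigree)

    def _round_key(self, round_index: int) -> int:
        return 0 if self.spec.mc.reuse_sequence else round_index

    def draw_group(
        self, gi: int, varstate: VarianceState, sample_index: int, round_index: int = 0,
        shape: tuple = ()
    ) -> np.ndarray:
        layout = self.design.groups[gi]
        L = np.linalg.cholesky(varstate.theta[gi])
        seed = self.spec.mc.seed
        rkey = self._round_key(round_index)
        name = layout.name
        if layout.kind == "identity":
            rng = stream(seed, sample_index, f"ident:{name}", rkey)
            return sample_identity(layout.q, L, rng, shape)
        ped_kin = self.engine.ped_kin
        rng_a = stream(seed, sample_index, f"gene_drop:{name}", rkey)
        a = gene_drop(self.design.pedigree, ped_kin.phi, L, rng_a, shape, self.levels)
        if layout.kind == "a":
            return a
        hop = self.engine.h_op
        gk = self.engine.genomic
        rng_g = stream(seed, sample_index, f"markers:{name}", rkey)
        g, _ = sample_genomic_terms(self.genotypes, max(gk.j_var, 0.0), L, rng_g, shape)
        rng_m = stream(seed, sample_index, f"jfactor:{name}", rkey)
        xm = rng_m.standard_normal(shape + (1, L.shape[0]))
        mu = (xm @ L.T) * np.sqrt(max(gk.j_var, 0.0))
        wg, wa = _blend_weights(self.spec.alpha, self.spec.blend)
        if self.engine.apy is not None:
            rng_p = stream(seed, sample_index, f"psi:{name}", rkey)
            u, _ = combine_apy(
                a, g, mu, self.spec.alpha, self.engine.apy, self.genotypes, hop,
                rng_p, L, shape, self.spec.blend,
            )
        else:
            u, _ = _combine(a, g, mu, wg, wa, self.genotypes.M, hop.geno, hop)
        return u

    def draw_sample(
        self,
        varstate: VarianceState,
        resid_ops: ResidualOps,
        sample_index: int,
        round_index: int = 0,
    ) -> MCSample:
        """Draw all effects, residuals, and phenotypes for one MC sample."""
        d = self.design
        u = {
            gi: self.draw_group(gi, varstate, sample_index, round_index)
            for gi in range(len(d.groups))
        }
        rkey = self._round_key(round_index)
        rng_e = stream(self.spec.mc.seed, sample_index, "residual", rkey)
        e = resid_ops.sample(rng_e)
        y = d.signal(u) + e
        y[~d.mask] = 0.0
        return MCSample(u=u, e_tilde=e, y_tilde=y)
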