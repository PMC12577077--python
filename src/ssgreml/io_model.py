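"""Data files, model configuration, and mixed-model design structures.

The file dialects follow the conventions dominant in animal breeding software:
a whitespace-delimited pedigree (``animal sire dam``, ``0`` = unknown parent),
a SNP file with one line per individual (``ID 01202...``, one digit per locus),
and a whitespace-delimited phenotype table whose column roles are declared in a
TOML configuration.  Animal identifiers may be arbitrary strings; they are
renumbered internally to consecutive codes with parents preceding offspring.

The design side turns a :class:`ModelSpec` into equation layout and incidence
structures for the mixed model equations: a set of *terms* (one equation block
per fixed effect x trait, or per column of a correlated random-effect group)
plus per-record residual missingness patterns.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

log = logging.getLogger("ssgreml")

UNKNOWN = -1  # internal code for an unknown parent


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Pedigree:
    """Topologically ordered pedigree with internal 0-based codes."""

    labels: list[str]
    sire: np.ndarray  # int64, UNKNOWN where missing
    dam: np.ndarray

    @property
    def n_animals(self) -> int:
        return len(self.labels)

    @property
    def code_of(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def validate(self) -> None:
        n = self.n_animals
        for arr in (self.sire, self.dam):
            if arr.shape != (n,):
                raise ValueError("parent arrays must match animal count")
            bad = (arr >= np.arange(n)) & (arr != UNKNOWN)
            if bad.any():
                raise ValueError("pedigree is not topologically ordered")
            if ((arr < UNKNOWN) | (arr >= n)).any():
                raise ValueError("parent code out of range")

    def depth_levels(self) -> np.ndarray:
        """Generation depth (founders = 0); animals in one level have all
        parents in strictly earlier levels, enabling vectorized gene dropping."""
        n = self.n_animals
        lev = np.zeros(n, dtype=np.int64)
        for i in range(n):
            ds = lev[self.sire[i]] + 1 if self.sire[i] != UNKNOWN else 0
            dd = lev[self.dam[i]] + 1 if self.dam[i] != UNKNOWN else 0
            lev[i] = max(ds, dd)
        return lev


@dataclass
class GenotypeSet:
    """Centered SNP dosages for the genotyped subset of the pedigree."""

    ids: np.ndarray  # pedigree codes of genotyped animals (0-based)
    dosages: np.ndarray  # n_g x m, values in {0,1,2}
    p: np.ndarray  # observed allele frequency per retained locus

    @property
    def n_genotyped(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def center_scale(self) -> float:
        """VanRaden method-1 denominator 2*sum(p_i q_i)."""
        return float(2.0 * np.sum(self.p * (1.0 - self.p)))

    @property
    def M(self) -> np.ndarray:
        """Dosages centered by twice the allele frequency."""
        return self.dosages - 2.0 * self.p


@dataclass
class PhenotypeTable:
    animal: np.ndarray  # pedigree code per record
    fixed_codes: dict[str, np.ndarray]  # raw class codes, per fixed effect
    y: np.ndarray  # n_rec x n_traits, 0.0 where missing
    mask: np.ndarray  # bool, True = observed

    @property
    def n_records(self) -> int:
        return len(self.animal)

    def n_ij(self) -> np.ndarray:
        """Counts of records where trait pairs are jointly observed."""
        m = self.mask.astype(np.float64)
        return m.T @ m


# --- configuration -----------------------------------------------------------


@dataclass
class TraitSpec:
    name: str
    column: int  # 1-based column in the phenotype file
    missing: Optional[float] = None  # sentinel value treated as missing


@dataclass
class FixedSpec:
    name: str
    column: int
    traits: list[str]


@dataclass
class RandomGroupSpec:
    name: str
    kind: str  # 'h' (ssGBLUP), 'a' (pedigree only), 'identity'
    columns: list[tuple[str, str]]  # (role, trait); roles: direct/maternal (a,h)
    #                                 or animal/dam (identity)
    zeros: list[tuple[str, str]] = field(default_factory=list)  # pairs "role:trait"

    def column_label(self, i: int) -> str:
        role, trait = self.columns[i]
        return f"{role}:{trait}"

    def zero_mask(self) -> np.ndarray:
        """Boolean (t,t) matrix, True where the (co)variance is free."""
        t = len(self.columns)
        labels = [self.column_label(i) for i in range(t)]
        mask = np.ones((t, t), dtype=bool)
        for a, b in self.zeros:
            i, j = labels.index(a), labels.index(b)
            if i == j:
                raise ValueError("cannot mask a diagonal variance to zero")
            mask[i, j] = mask[j, i] = False
        return mask


@dataclass
class McSettings:
    samples: int = 30
    seed: int = 1234
    reuse_sequence: bool = True
    variant: str = "primary"  # or 'centered'


@dataclass
class ApySettings:
    enabled: bool = False
    n_core: int = 0
    seed: int = 0
    rule: str = "random"


@dataclass
class SolverSettings:
    tol_data: float = 1e-10
    tol_mc: float = 1e-6
    max_iter: int = 5000


@dataclass
class ConvergenceSettings:
    t1: float = 1e-12  # round-to-round relative change in theta
    t2: float = 1e-4  # CV of the restricted logL over the last five rounds
    max_rounds: int = 100


@dataclass
class ModelSpec:
    traits: list[TraitSpec]
    animal_col: int
    fixed: list[FixedSpec]
    random_groups: list[RandomGroupSpec]
    residual_zeros: list[tuple[str, str]] = field(default_factory=list)
    alpha: float = 0.05
    unknown_dam: str = "drop"  # or 'phantom' (identity maternal groups only)
    blend: str = "variance"  # or 'sqrt': convention for G blending weights
    apy: ApySettings = field(default_factory=ApySettings)
    mc: McSettings = field(default_factory=McSettings)
    solver: SolverSettings = field(default_factory=SolverSettings)
    convergence: ConvergenceSettings = field(default_factory=ConvergenceSettings)
    start_variance: float = 1.0
    start_covariance: float = 0.1

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.mc.samples < 1:
            raise ValueError("mc.samples must be >= 1")
        names = set(self.trait_names)
        for f in self.fixed:
            unknown = set(f.traits) - names
            if unknown:
                raise ValueError(f"fixed effect {f.name} references unknown traits {unknown}")
        for g in self.random_groups:
            if g.kind not in ("h", "a", "identity"):
                raise ValueError(f"unknown covariance kind {g.kind!r}")
            for role, trait in g.columns:
                if trait not in names:
                    raise ValueError(f"group {g.name} references unknown trait {trait}")
                valid = ("direct", "maternal") if g.kind in ("a", "h") else ("animal", "dam")
                if role not in valid:
                    raise ValueError(f"role {role!r} invalid for kind {g.kind!r}")
            g.zero_mask()  # raises on malformed zero pairs
        for a, b in self.residual_zeros:
            if a not in names or b not in names:
                raise ValueError(f"residual zero pair ({a},{b}) references unknown trait")
        if self.blend not in ("variance", "sqrt"):
            raise ValueError("blend must be 'variance' or 'sqrt'")

    def residual_mask(self) -> np.ndarray:
        t = len(self.traits)
        mask = np.ones((t, t), dtype=bool)
        idx = {n: i for i, n in enumerate(self.trait_names)}
        for a, b in self.residual_zeros:
            i, j = idx[a], idx[b]
            if i == j:
                raise ValueError("cannot mask a residual variance to zero")
            mask[i, j] = mask[j, i] = False
        return mask


# ---------------------------------------------------------------------------
# file readers / writers
# ---------------------------------------------------------------------------


def load_pedigree(path: str | Path) -> Pedigree:
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise ValueError(f"pedigree line needs 3 fields: {line!r}")
            rows.append(tuple(parts[:3]))
    return renumber_pedigree(rows)


def renumber_pedigree(records: Sequence[tuple[str, str, str]]) -> Pedigree:
    """Renumber arbitrary string ids to topological 0-based codes."""
    parents: dict[str, tuple[str, str]] = {}
    for a, s, d in records:
        if a == "0":
            raise ValueError("animal id '0' is reserved for unknown parents")
        if a in parents:
            raise ValueError(f"duplicate pedigree entry for {a!r}")
        parents[a] = (s, d)
    for a, (s, d) in parents.items():
        for p in (s, d):
            if p != "0" and p not in parents:
                raise ValueError(f"parent {p!r} of {a!r} not in pedigree file")
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(a: str) -> None:
        stack = [a]
        while stack:
            cur = stack[-1]
            st = state.get(cur, 0)
            if st == 2:
                stack.pop()
                continue
            if st == 1:
                state[cur] = 2
                order.append(cur)
                stack.pop()
                continue
            state[cur] = 1
            for p in parents[cur]:
                if p != "0":
                    if state.get(p, 0) == 1:
                        raise ValueError(f"pedigree cycle involving {p!r}")
                    if state.get(p, 0) == 0:
                        stack.append(p)

    for a in parents:
        visit(a)
    code = {lab: i for i, lab in enumerate(order)}
    sire = np.array([code[parents[a][0]] if parents[a][0] != "0" else UNKNOWN for a in order])
    dam = np.array([code[parents[a][1]] if parents[a][1] != "0" else UNKNOWN for a in order])
    ped = Pedigree(labels=order, sire=sire, dam=dam)
    ped.validate()
    return ped


def load_genotypes(path: str | Path, pedigree: Pedigree) -> GenotypeSet:
    ids, rows = [], []
    code = pedigree.code_of
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise ValueError(f"genotype line needs 'ID digits': {line!r}")
            lab, digits = parts
            if lab not in code:
                raise ValueError(f"genotyped animal {lab!r} absent from pedigree")
            ids.append(code[lab])
            rows.append(np.frombuffer(digits.encode(), dtype=np.uint8) - ord("0"))
    if not rows:
        raise ValueError("empty genotype file")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("genotype string length mismatch across individuals")
    dos = np.vstack(rows).astype(np.float64)
    if dos.max() > 2:
        raise ValueError("allele dosages must be in {0,1,2}")
    return build_genotype_set(np.asarray(ids), dos)


def build_genotype_set(ids: np.ndarray, dosages: np.ndarray) -> GenotypeSet:
    """Drop monomorphic loci and compute observed allele frequencies."""
    p = dosages.mean(axis=0) / 2.0
    keep = (p > 0.0) & (p < 1.0)
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropped %d monomorphic loci (%d retained)", dropped, int(keep.sum()))
    if not keep.any():
        raise ValueError("all loci monomorphic")
    order = np.argsort(ids, kind="stable")
    return GenotypeSet(ids=np.asarray(ids)[order], dosages=dosages[order][:, keep], p=p[keep])


def load_phenotypes(path: str | Path, spec: ModelSpec, pedigree: Pedigree) -> PhenotypeTable:
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    code = pedigree.code_of
    animals = df.iloc[:, spec.animal_col - 1]
    missing_ped = [a for a in animals if a not in code]
    if missing_ped:
        raise ValueError(f"animals with records absent from pedigree: {missing_ped[:5]}")
    animal = np.array([code[a] for a in animals])
    fixed_codes = {f.name: df.iloc[:, f.column - 1].to_numpy() for f in spec.fixed}
    t = len(spec.traits)
    y = np.zeros((len(df), t))
    mask = np.zeros((len(df), t), dtype=bool)
    for j, tr in enumerate(spec.traits):
        col = pd.to_numeric(df.iloc[:, tr.column - 1], errors="coerce")
        vals = col.to_numpy(dtype=np.float64)
        obs = ~np.isnan(vals)
        if tr.missing is not None:
            obs &= vals != tr.missing
        y[:, j] = np.where(obs, vals, 0.0)
        mask[:, j] = obs
    keep = mask.any(axis=1)
    if not keep.all():
        log.info("dropped %d records with no observed trait", int((~keep).sum()))
    return PhenotypeTable(
        animal=animal[keep],
        fixed_codes={k: v[keep] for k, v in fixed_codes.items()},
        y=y[keep],
        mask=mask[keep],
    )


def parse_config(source: str | Path | dict) -> ModelSpec:
    """Parse the TOML model configuration (sections [model], [solver], [mc],
    [apy], [convergence]) into a validated :class:`ModelSpec`."""
    if isinstance(source, dict):
        cfg = source
    else:
        with open(source, "rb") as fh:
            cfg = tomllib.load(fh)
    m = cfg.get("model", {})
    traits = [
        TraitSpec(d["name"], int(d["column"]), d.get("missing"))
        for d in m.get("traits", [])
    ]
    fixed = [
        FixedSpec(d["name"], int(d["column"]), list(d.get("traits", [t.name for t in traits])))
        for d in m.get("fixed", [])
    ]
    groups = [
        RandomGroupSpec(
            name=d["name"],
            kind=d.get("kind", "a"),
            columns=[(r, t) for r, t in d["columns"]],
            zeros=[(a, b) for a, b in d.get("zeros", [])],
        )
        for d in m.get("random", [])
    ]
    resid = [(a, b) for a, b in m.get("residual", {}).get("zeros", [])]

    def build(cls, key):
        return cls(**cfg.get(key, {}))

    spec = ModelSpec(
        traits=traits,
        animal_col=int(m.get("animal_col", 1)),
        fixed=fixed,
        random_groups=groups,
        residual_zeros=resid,
        alpha=float(m.get("alpha", 0.05)),
        unknown_dam=m.get("unknown_dam", "drop"),
        blend=m.get("blend", "variance"),
        apy=build(ApySettings, "apy"),
        mc=build(McSettings, "mc"),
        solver=build(SolverSettings, "solver"),
        convergence=build(ConvergenceSettings, "convergence"),
        start_variance=float(cfg.get("start", {}).get("variance", 1.0)),
        start_covariance=float(cfg.get("start", {}).get("covariance", 0.1)),
    )
    spec.validate()
    return spec


def load_dataset(pedigree_path, genotype_path, phenotype_path, config):
    """Load all inputs; ``genotype_path`` may be None for pedigree-only models."""
    spec = config if isinstance(config, ModelSpec) else parse_config(config)
    ped = load_pedigree(pedigree_path)
    geno = load_genotypes(genotype_path, ped) if genotype_path is not None else None
    if geno is None and any(g.kind == "h" for g in spec.random_groups):
        raise ValueError("model uses an H-structured group but no genotype file given")
    pheno = load_phenotypes(phenotype_path, spec, ped)
    return ped, geno, pheno, spec


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclass
class Term:
    """One equation block: a fixed effect x trait, or one column of a group."""

    name: str
    kind: str  # 'fixed' | 'random'
    trait: int
    n_levels: int
    offset: int
    eq_index: np.ndarray  # per record: equation index, or -1 when absent
    group: Optional[int] = None
    col: Optional[int] = None


@dataclass
class GroupLayout:
    name: str
    kind: str
    t: int  # number of trait-columns
    q: int  # levels (animals for a/h, distinct entities for identity)
    offset: int  # first equation of the block; layout is level-major
    mask: np.ndarray  # (t,t) bool, True = free parameter
    terms: list[int]  # indices into DesignSet.terms, one per column
    entity_of_level: Optional[np.ndarray] = None  # identity groups only


class DesignSet:
    """Equation layout, incidence structures, and residual patterns."""

    def __init__(self, pedigree: Pedigree, pheno: PhenotypeTable, spec: ModelSpec):
        self.spec = spec
        self.pedigree = pedigree
        self.n_traits = len(spec.traits)
        t = self.n_traits

        # --- record filtering under maternal models ------------------------
        needs_dam = any(
            role in ("maternal", "dam")
            for g in spec.random_groups
            for role, _ in g.columns
        )
        keep = np.ones(pheno.n_records, dtype=bool)
        dam_of_rec = pedigree.dam[pheno.animal]
        if needs_dam and spec.unknown_dam == "drop":
            keep = dam_of_rec != UNKNOWN
            if not keep.all():
                log.info("dropped %d records with unknown dam (maternal model)", int((~keep).sum()))
        elif needs_dam and spec.unknown_dam == "phantom":
            if any(
                g.kind in ("a", "h") and any(r == "maternal" for r, _ in g.columns)
                for g in spec.random_groups
            ):
                raise ValueError("phantom dams are only supported for identity groups")
        self.animal = pheno.animal[keep]
        self.y = pheno.y[keep]
        self.mask = pheno.mask[keep]
        self.fixed_codes = {k: v[keep] for k, v in pheno.fixed_codes.items()}
        self.dam_of_rec = pedigree.dam[self.animal]
        self.n_records = len(self.animal)
        if self.n_records == 0:
            raise ValueError("no usable records")

        # --- residual patterns ---------------------------------------------
        pat_keys, pat_inv = np.unique(self.mask, axis=0, return_inverse=True)
        self.patterns = [tuple(bool(b) for b in row) for row in pat_keys]
        self.pattern_of = pat_inv.astype(np.int64)
        self.pattern_rows = [np.where(self.pattern_of == p)[0] for p in range(len(self.patterns))]
        m = self.mask.astype(np.float64)
        self.n_ij = m.T @ m

        # --- terms ----------------------------------------------------------
        self.terms: list[Term] = []
        self.groups: list[GroupLayout] = []
        offset = 0
        trait_idx = {n: i for i, n in enumerate(spec.trait_names)}
        for f in spec.fixed:
            codes = self.fixed_codes[f.name]
            for trn in f.traits:
                j = trait_idx[trn]
                obs = self.mask[:, j]
                levels = sorted(set(codes[obs]))
                lvl = {c: i for i, c in enumerate(levels)}
                rec_level = np.array([lvl.get(c, -1) for c in codes])
                rec_level[~obs] = -1
                eq = np.where(rec_level >= 0, offset + rec_level, -1)
                self.terms.append(
                    Term(f"{f.name}:{trn}", "fixed", j, len(levels), offset, eq)
                )
                offset += len(levels)

        for gi, g in enumerate(spec.random_groups):
            tg = len(g.columns)
            entity_cols = []
            for role, trn in g.columns:
                ent = self.animal if role in ("direct", "animal") else self.dam_of_rec
                entity_cols.append(ent)
            if g.kind in ("a", "h"):
                q = pedigree.n_animals
                ent_of_level = None
                level_of = None
            else:
                usable = []
                for c, (role, trn) in enumerate(g.columns):
                    j = trait_idx[trn]
                    e = entity_cols[c]
                    usable.append(e[self.mask[:, j] & (e != UNKNOWN)])
                entities = np.unique(np.concatenate(usable)) if usable else np.array([], int)
                if spec.unknown_dam == "phantom" and any(r == "dam" for r, _ in g.columns):
                    entities = np.append(entities, UNKNOWN)
                q = len(entities)
                ent_of_level = entities
                level_of = {int(e): i for i, e in enumerate(entities)}
            layout = GroupLayout(g.name, g.kind, tg, q, offset, g.zero_mask(), [], ent_of_level)
            for c, (role, trn) in enumerate(g.columns):
                j = trait_idx[trn]
                e = entity_cols[c]
                if g.kind in ("a", "h"):
                    lev = e.copy()
                else:
                    lev = np.array([level_of.get(int(x), -1) for x in e])
                lev = np.where(self.mask[:, j] & (lev >= 0) if g.kind == "identity" else self.mask[:, j] & (e != UNKNOWN), lev, -1)
                eq = np.where(lev >= 0, offset + lev * tg + c, -1)
                layout.terms.append(len(self.terms))
                self.terms.append(
                    Term(f"{g.name}:{g.column_label(c)}", "random", j, q, offset, eq, gi, c)
                )
            self.groups.append(layout)
            offset += q * tg
        self.n_eq = offset

        # fast paths for matvecs
        self._term_rows = [np.where(tm.eq_index >= 0)[0] for tm in self.terms]
        self._term_eq = [tm.eq_index[r] for tm, r in zip(self.terms, self._term_rows)]

    # --- incidence application ---------------------------------------------

    def fitted(self, v: np.ndarray) -> np.ndarray:
        """Q v mapped to the (record, trait) grid (zeros where no incidence)."""
        F = np.zeros((self.n_records, self.n_traits))
        for tm, rows, eq in zip(self.terms, self._term_rows, self._term_eq):
            F[rows, tm.trait] += v[eq]
        return F

    def adjoint(self, W: np.ndarray, out: Optional[np.ndarray] = None) -> np.ndarray:
        """Q' W for a (record, trait) grid W."""
        if out is None:
            out = np.zeros(self.n_eq)
        for tm, rows, eq in zip(self.terms, self._term_rows, self._term_eq):
            np.add.at(out, eq, W[rows, tm.trait])
        return out

    def group_block(self, v: np.ndarray, gi: int) -> np.ndarray:
        g = self.groups[gi]
        return v[g.offset : g.offset + g.q * g.t].reshape(g.q, g.t)

    def signal(self, group_values: dict[int, np.ndarray]) -> np.ndarray:
        """Sum of Z_k k for given per-group (q,t) value arrays (batch leading
        dims allowed), on the (record, trait) grid."""
        shapes = next(iter(group_values.values())).shape[:-2]
        F = np.zeros(shapes + (self.n_records, self.n_traits))
        for gi, vals in group_values.items():
            g = self.groups[gi]
            for c, ti in enumerate(g.terms):
                tm = self.terms[ti]
                rows = self._term_rows[ti]
                lev = (self._term_eq[ti] - g.offset - c) // g.t
                F[..., rows, tm.trait] += vals[..., lev, c]
        return F

    def qobs_sparse(self) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
        """Incidence over stacked observed cells (record-major): returns
        (Q, rec_of_cell, trait_of_cell)."""
        rec, trait = np.nonzero(self.mask)
        cell_of = -np.ones((self.n_records, self.n_traits), dtype=np.int64)
        cell_of[rec, trait] = np.arange(len(rec))
        rows, cols = [], []
        for tm, r, eq in zip(self.terms, self._term_rows, self._term_eq):
            cells = cell_of[r, tm.trait]
            ok = cells >= 0
            rows.append(cells[ok])
            cols.append(eq[ok])
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        Q = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(rec), self.n_eq)
        )
        return Q, rec, trait


def build_design(pedigree: Pedigree, pheno: PhenotypeTable, spec: ModelSpec) -> DesignSet:
    spec.validate()
    return DesignSet(pedigree, pheno, spec)


class ResidualOps:
    """Per-pattern residual covariance blocks under a given R0.

    Each missingness pattern gets the observed sub-block of R0, its inverse
    embedded back into a t x t matrix (zero rows/cols at missing traits), a
    Cholesky factor for sampling, and its log-determinant contribution.
    """

    def __init__(self, design: DesignSet, R0: np.ndarray):
        self.design = design
        self.R0 = np.asarray(R0, dtype=np.float64)
        t = design.n_traits
        self.rinv_emb: list[np.ndarray] = []
        self.chol_emb: list[np.ndarray] = []
        self.logdet = 0.0
        for p, obs in enumerate(design.patterns):
            idx = np.where(np.array(obs))[0]
            sub = self.R0[np.ix_(idx, idx)]
            try:
                c = np.linalg.cholesky(sub)
            except np.linalg.LinAlgError as err:
                raise ValueError(f"residual block for pattern {obs} not SPD") from err
            inv = np.linalg.inv(sub)
            emb = np.zeros((t, t))
            emb[np.ix_(idx, idx)] = inv
            ch = np.zeros((t, t))
            ch[np.ix_(idx, idx)] = c
            self.rinv_emb.append(emb)
            self.chol_emb.append(ch)
            self.logdet += len(design.pattern_rows[p]) * 2.0 * np.sum(np.log(np.diag(c)))

    def apply_rinv(self, F: np.ndarray) -> np.ndarray:
        """Per-record R^-1 F on the (record, trait) grid (batch dims allowed)."""
        W = np.zeros_like(F)
        for p, rows in enumerate(self.design.pattern_rows):
            W[..., rows, :] = F[..., rows, :] @ self.rinv_emb[p]
        return W

    def sample(self, rng, shape=()) -> np.ndarray:
        """Residual draws with the pattern-restricted covariance."""
        d = self.design
        x = rng.standard_normal(shape + (d.n_records, d.n_traits))
        e = np.zeros_like(x)
        for p, rows in enumerate(self.design.pattern_rows):
            e[..., rows, :] = x[..., rows, :] @ self.chol_emb[p].T
        return e

    def cross_products(self, E: np.ndarray) -> np.ndarray:
        """(t,t) matrix of e_i'e_j over records where both traits observed."""
        return E.T @ E

    def pattern_cross_products(self, E: np.ndarray) -> list[np.ndarray]:
        return [E[rows].T @ E[rows] for rows in self.design.pattern_rows]


def write_solutions(path, design: DesignSet, x: np.ndarray) -> None:
    """Whitespace-delimited 'effect trait level solution' writer."""
    names = design.spec.trait_names
    with open(path, "w") as fh:
        for tm in design.terms:
            if tm.kind == "fixed":
                block = x[tm.offset : tm.offset + tm.n_levels]
            else:
                g = design.groups[tm.group]
                block = x[g.offset + tm.col : g.offset + g.q * g.t : g.t]
            for lev, val in enumerate(block):
                fh.write(f"{tm.name} {names[tm.trait]} {lev + 1} {val:.10g}\n")
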