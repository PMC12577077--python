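"""Synthetic pedigree / genotype / phenotype studies with known truth.

The generator emulates the structure of a national beef-cattle growth
evaluation at desk scale: a multi-generation pedigree with discrete
generations and random mating, a genotyped subset (by default the youngest
animals, as in routine evaluations), and a three-trait growth model — birth
weight (bw), weaning weight (ww), post-weaning gain (pwg) — with direct and
maternal genetic effects sharing one relationship structure, a maternal
permanent-environment effect for ww, contemporary-group fixed effects, and
trait-specific record missingness.  The default true parameters are realistic
(co)variances for such a model, including the structural zeros conventionally
assumed between the residuals of pwg and the weaning traits and between most
direct-maternal pairs.

True breeding values are gene-dropped from the PEDIGREE covariance by default,
keeping truth generation independent of the single-step machinery under test;
``truth_structure='h'`` routes through the ssGBLUP sampler instead for
end-to-end recovery experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import bv_simulation as bv
from .io_model import (
    FixedSpec,
    GenotypeSet,
    ModelSpec,
    Pedigree,
    PhenotypeTable,
    RandomGroupSpec,
    ResidualOps,
    TraitSpec,
    build_design,
    build_genotype_set,
)
from .params import VarianceState
from .relationships import build_engine


def beef_growth_template() -> tuple[ModelSpec, list[np.ndarray], np.ndarray]:
    """Three-trait maternal growth model with realistic true parameters.

    Genetic columns: direct bw / ww / pwg, maternal bw / ww (one shared K);
    maternal permanent environment for ww; residual covariances involving pwg
    masked to zero.
    """
    spec = ModelSpec(
        traits=[
            TraitSpec("bw", 3, missing=0.0),
            TraitSpec("ww", 4, missing=0.0),
            TraitSpec("pwg", 5, missing=0.0),
        ],
        animal_col=1,
        fixed=[FixedSpec("cg", 2, ["bw", "ww", "pwg"])],
        random_groups=[
            RandomGroupSpec(
                name="genetic",
                kind="h",
                columns=[
                    ("direct", "bw"),
                    ("direct", "ww"),
                    ("direct", "pwg"),
                    ("maternal", "bw"),
                    ("maternal", "ww"),
                ],
                zeros=[
                    ("direct:bw", "maternal:ww"),
                    ("direct:ww", "maternal:bw"),
                    ("direct:ww", "maternal:ww"),
                    ("direct:pwg", "maternal:bw"),
                    ("direct:pwg", "maternal:ww"),
                    ("maternal:bw", "maternal:ww"),
                ],
            ),
            RandomGroupSpec(name="mpe", kind="identity", columns=[("dam", "ww")]),
        ],
        residual_zeros=[("bw", "pwg"), ("ww", "pwg")],
        alpha=0.05,
    )
    genetic = np.array(
        [
            [24.90, 38.29, 52.51, -0.82, 0.0],
            [38.29, 380.19, 34.94, 0.0, 0.0],
            [52.51, 34.94, 560.17, 0.0, 0.0],
            [-0.82, 0.0, 0.0, 4.20, 0.0],
            [0.0, 0.0, 0.0, 0.0, 184.51],
        ]
    )
    mpe = np.array([[262.26]])
    r0 = np.array(
        [
            [30.91, 57.58, 0.0],
            [57.58, 1443.60, 0.0],
            [0.0, 0.0, 1627.00],
        ]
    )
    return spec, [genetic, mpe], r0


@dataclass
class SimConfig:
    """Study-generation settings; defaults emulate the growth evaluation at
    desk scale."""

    n_founders: int = 60
    n_generations: int = 4  # breeding cycles after the founders
    n_matings: int = 30
    offspring_per_mating: int = 4
    male_fraction: float = 0.5
    m_loci: int = 400
    freq_low: float = 0.05
    freq_high: float = 0.95
    genotyped_fraction: float = 0.25
    genotyped_rule: str = "youngest"  # or 'random'
    record_prob: dict = field(
        default_factory=lambda: {"bw": 0.95, "ww": 0.85, "pwg": 0.85}
    )
    cg_size: int = 20
    trait_means: dict = field(
        default_factory=lambda: {"bw": 35.0, "ww": 230.0, "pwg": 340.0}
    )
    seed: int = 20240901
    truth_structure: str = "pedigree"  # or 'h'
    spec: Optional[ModelSpec] = None
    true_theta: Optional[list[np.ndarray]] = None
    true_r0: Optional[np.ndarray] = None

    def resolve_model(self):
        if self.spec is None or self.true_theta is None or self.true_r0 is None:
            spec, theta, r0 = beef_growth_template()
            return (
                self.spec or spec,
                self.true_theta or theta,
                self.true_r0 if self.true_r0 is not None else r0,
            )
        return self.spec, self.true_theta, self.true_r0


def simulate_pedigree(cfg: SimConfig, rng) -> tuple[Pedigree, np.ndarray]:
    """Discrete-generation pedigree with random mating; returns the pedigree
    and the generation number of each animal."""
    if cfg.n_founders < 2:
        raise ValueError("need at least two founders")
    sire, dam, gen = [], [], []
    for _ in range(cfg.n_founders):
        sire.append(-1)
        dam.append(-1)
        gen.append(0)
    pool = np.arange(cfg.n_founders)
    for g in range(1, cfg.n_generations):
        sex = rng.random(len(pool)) < cfg.male_fraction
        males, females = pool[sex], pool[~sex]
        if len(males) == 0 or len(females) == 0:
            males = females = pool
        start = len(sire)
        for _ in range(cfg.n_matings):
            s = int(rng.choice(males))
            d = int(rng.choice(females))
            for _ in range(cfg.offspring_per_mating):
                sire.append(s)
                dam.append(d)
                gen.append(g)
        pool = np.arange(start, len(sire))
    labels = [str(i + 1) for i in range(len(sire))]
    ped = Pedigree(labels, np.array(sire), np.array(dam))
    ped.validate()
    return ped, np.array(gen)


def simulate_genotypes(ped: Pedigree, cfg: SimConfig, rng) -> GenotypeSet:
    """Gene-drop biallelic loci through the pedigree and genotype a subset."""
    n, m = ped.n_animals, cfg.m_loci
    freq = rng.uniform(cfg.freq_low, cfg.freq_high, size=m)
    hap = np.zeros((n, 2, m), dtype=np.int8)
    for i in range(n):
        for h, parent in enumerate((ped.sire[i], ped.dam[i])):
            if parent < 0:
                hap[i, h] = rng.random(m) < freq
            else:
                pick = rng.integers(0, 2, size=m)
                hap[i, h] = hap[parent, pick, np.arange(m)]
    dosages = hap.sum(axis=1).astype(np.float64)
    n_geno = max(2, int(round(cfg.genotyped_fraction * n)))
    if cfg.genotyped_rule == "youngest":
        ids = np.arange(n - n_geno, n)
    elif cfg.genotyped_rule == "random":
        ids = np.sort(rng.choice(n, size=n_geno, replace=False))
    else:
        raise ValueError(f"unknown genotyped_rule {cfg.genotyped_rule!r}")
    return build_genotype_set(ids, dosages[ids])


@dataclass
class StudyData:
    pedigree: Pedigree
    genotypes: Optional[GenotypeSet]
    phenotypes: PhenotypeTable
    spec: ModelSpec
    truth: dict
    true_state: VarianceState
    generation: np.ndarray


def simulate_study(cfg: SimConfig, out_dir: Optional[str | Path] = None) -> StudyData:
    """Generate a complete study with known true parameters.

    Records are assigned to all non-founder animals (their dams are known, so
    maternal terms are always defined), with per-trait Bernoulli missingness;
    contemporary groups are generation x random block with at least
    ``cg_size // 2`` members.  Outputs are byte-identical given the seed.
    """
    spec, true_theta, true_r0 = cfg.resolve_model()
    rng = np.random.default_rng(cfg.seed)
    ped, gen = simulate_pedigree(cfg, rng)
    uses_h = any(g.kind == "h" for g in spec.random_groups)
    genotypes = simulate_genotypes(ped, cfg, rng) if uses_h else None

    # records: non-founders, per-trait missingness
    rec_animals = np.where(gen > 0)[0]
    t = len(spec.traits)
    probs = np.array([cfg.record_prob.get(tr.name, 1.0) for tr in spec.traits])
    mask = rng.random((len(rec_animals), t)) < probs
    keep = mask.any(axis=1)
    rec_animals, mask = rec_animals[keep], mask[keep]

    # contemporary groups: generation x random block
    cg_codes = np.empty(len(rec_animals), dtype=object)
    for g in np.unique(gen[rec_animals]):
        rows = np.where(gen[rec_animals] == g)[0]
        perm = rng.permutation(rows)
        n_blocks = max(1, len(rows) // cfg.cg_size)
        for b, chunk in enumerate(np.array_split(perm, n_blocks)):
            for r in chunk:
                cg_codes[r] = f"{g}_{b + 1}"

    pheno = PhenotypeTable(
        animal=rec_animals,
        fixed_codes={spec.fixed[0].name: cg_codes.astype(str)},
        y=np.zeros((len(rec_animals), t)),
        mask=mask,
    )
    design = build_design(ped, pheno, spec)

    masks = [g.zero_mask() for g in spec.random_groups]
    true_state = VarianceState(
        [th.copy() for th in true_theta],
        true_r0.copy(),
        masks,
        spec.residual_mask(),
        [g.name for g in spec.random_groups],
    )
    if not true_state.all_spd():
        raise ValueError("true theta not positive definite under the masks")

    engine = build_engine(ped, genotypes, spec)
    draws = {}
    for gi, layout in enumerate(design.groups):
        L = np.linalg.cholesky(true_state.theta[gi])
        sub = np.random.default_rng(rng.integers(2**31))
        if layout.kind == "identity":
            draws[gi] = bv.sample_identity(layout.q, L, sub)
        elif layout.kind == "a" or cfg.truth_structure == "pedigree":
            # pedigree-true breeding values: gene dropping only
            draws[gi] = bv.gene_drop(ped, engine.ped_kin.phi, L, sub)
        else:  # H-structured truth via the ssGBLUP sampler
            a = bv.gene_drop(ped, engine.ped_kin.phi, L, sub)
            g, mu = bv.sample_genomic_terms(
                genotypes, max(engine.genomic.j_var, 0.0), L, sub
            )
            draws[gi], _ = bv.combine_ssgblup(
                a, g, mu, spec.alpha, genotypes, engine.h_op, spec.blend
            )
    resid_ops = ResidualOps(design, true_r0)
    rng_e = np.random.default_rng(rng.integers(2**31))
    e = resid_ops.sample(rng_e)

    # fixed contemporary-group effects: trait mean plus an environment-sized shift
    cg_sd = np.sqrt(np.diag(true_r0)) * 0.5
    means = np.array([cfg.trait_means.get(tr.name, 0.0) for tr in spec.traits])
    cg_values = {}
    rng_cg = np.random.default_rng(rng.integers(2**31))
    for code in sorted(set(cg_codes)):
        cg_values[code] = means + rng_cg.standard_normal(t) * cg_sd

    y = design.signal(draws) + e
    for r, code in enumerate(cg_codes):
        y[r] += cg_values[code]
    y[~mask] = 0.0
    design.y = y
    pheno.y = y

    truth = {
        "theta": {
            g.name: true_state.theta[gi].tolist()
            for gi, g in enumerate(spec.random_groups)
        },
        "r0": true_state.r0.tolist(),
        "seed": cfg.seed,
        "n_animals": ped.n_animals,
        "n_records": len(rec_animals),
        "n_genotyped": genotypes.n_genotyped if genotypes is not None else 0,
        "truth_structure": cfg.truth_structure,
    }
    study = StudyData(ped, genotypes, pheno, spec, truth, true_state, gen)
    if out_dir is not None:
        write_study(study, out_dir)
    return study


# ---------------------------------------------------------------------------
# file output in the dialects io_model reads
# ---------------------------------------------------------------------------


def write_study(study: StudyData, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped = study.pedigree
    paths = {}

    p = out / "pedigree.txt"
    with open(p, "w") as fh:
        for i, lab in enumerate(ped.labels):
            s = ped.labels[ped.sire[i]] if ped.sire[i] >= 0 else "0"
            d = ped.labels[ped.dam[i]] if ped.dam[i] >= 0 else "0"
            fh.write(f"{lab} {s} {d}\n")
    paths["pedigree"] = p

    if study.genotypes is not None:
        p = out / "genotypes.txt"
        with open(p, "w") as fh:
            for row, code in zip(study.genotypes.dosages, study.genotypes.ids):
                digits = "".join(str(int(v)) for v in row)
                fh.write(f"{ped.labels[code]} {digits}\n")
        paths["genotypes"] = p

    p = out / "phenotypes.txt"
    ph = study.phenotypes
    cg = ph.fixed_codes[study.spec.fixed[0].name]
    with open(p, "w") as fh:
        for r in range(ph.n_records):
            vals = " ".join(
                f"{ph.y[r, j]:.6f}" if ph.mask[r, j] else "0"
                for j in range(ph.y.shape[1])
            )
            fh.write(f"{ped.labels[ph.animal[r]]} {cg[r]} {vals}\n")
    paths["phenotypes"] = p

    p = out / "truth.json"
    with open(p, "w") as fh:
        json.dump(study.truth, fh, indent=2)
    paths["truth"] = p

    p = out / "config.toml"
    with open(p, "w") as fh:
        fh.write(render_config(study.spec))
    paths["config"] = p
    return paths


def render_config(spec: ModelSpec) -> str:
    """Render a ModelSpec back to the TOML dialect parse_config reads."""
    lines = ["[model]", f"animal_col = {spec.animal_col}", f"alpha = {spec.alpha}"]
    lines.append(f'unknown_dam = "{spec.unknown_dam}"')
    lines.append(f'blend = "{spec.blend}"')
    trait_items = []
    for tr in spec.traits:
        miss = f", missing = {tr.missing}" if tr.missing is not None else ""
        trait_items.append(f'{{ name = "{tr.name}", column = {tr.column}{miss} }}')
    lines.append("traits = [" + ", ".join(trait_items) + "]")
    fx = [
        f'{{ name = "{f.name}", column = {f.column}, traits = {json.dumps(f.traits)} }}'
        for f in spec.fixed
    ]
    lines.append("fixed = [" + ", ".join(fx) + "]")
    for g in spec.random_groups:
        lines.append("")
        lines.append("[[model.random]]")
        lines.append(f'name = "{g.name}"')
        lines.append(f'kind = "{g.kind}"')
        cols = ", ".join(f'["{r}", "{t}"]' for r, t in g.columns)
        lines.append(f"columns = [{cols}]")
        if g.zeros:
            zz = ", ".join(f'["{a}", "{b}"]' for a, b in g.zeros)
            lines.append(f"zeros = [{zz}]")
    if spec.residual_zeros:
        lines.append("")
        lines.append("[model.residual]")
        zz = ", ".join(f'["{a}", "{b}"]' for a, b in spec.residual_zeros)
        lines.append(f"zeros = [{zz}]")
    lines.append("")
    lines.append("[mc]")
    lines.append(f"samples = {spec.mc.samples}")
    lines.append(f"seed = {spec.mc.seed}")
    lines.append(f"reuse_sequence = {'true' if spec.mc.reuse_sequence else 'false'}")
    lines.append("")
    lines.append("[apy]")
    lines.append(f"enabled = {'true' if spec.apy.enabled else 'false'}")
    if spec.apy.n_core:
        lines.append(f"n_core = {spec.apy.n_core}")
    lines.append(f"seed = {spec.apy.seed}")
    lines.append("")
    lines.append("[solver]")
    lines.append(f"tol_data = {spec.solver.tol_data}")
    lines.append(f"tol_mc = {spec.solver.tol_mc}")
    lines.append(f"max_iter = {spec.solver.max_iter}")
    lines.append("")
    lines.append("[convergence]")
    lines.append(f"t1 = {spec.convergence.t1}")
    lines.append(f"t2 = {spec.convergence.t2}")
    lines.append(f"max_rounds = {spec.convergence.max_rounds}")
    lines.append("")
    return "\n".join(lines)
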