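"""Shared fixtures: small synthetic studies with known truth."""

from __future__ import annotations

import copy

import numpy as np
import pytest

from ssgreml import synthetic_data as sd
from ssgreml.io_model import (
    FixedSpec,
    ModelSpec,
    Pedigree,
    PhenotypeTable,
    RandomGroupSpec,
    TraitSpec,
    build_design,
)
from ssgreml.params import VarianceState
from ssgreml.relationships import build_engine


def single_trait_spec(kind: str = "h") -> ModelSpec:
    return ModelSpec(
        traits=[TraitSpec("bw", 3, missing=0.0)],
        animal_col=1,
        fixed=[FixedSpec("cg", 2, ["bw"])],
        random_groups=[
            RandomGroupSpec(name="genetic", kind=kind, columns=[("direct", "bw")])
        ],
    )


def two_trait_spec(kind: str = "h") -> ModelSpec:
    return ModelSpec(
        traits=[TraitSpec("bw", 3, missing=0.0), TraitSpec("ww", 4, missing=0.0)],
        animal_col=1,
        fixed=[FixedSpec("cg", 2, ["bw", "ww"])],
        random_groups=[
            RandomGroupSpec(
                name="genetic", kind=kind, columns=[("direct", "bw"), ("direct", "ww")]
            )
        ],
    )


TH2 = np.array([[25.0, 15.0], [15.0, 40.0]])
R2 = np.array([[30.0, 10.0], [10.0, 60.0]])


def make_bundle(spec, true_theta, true_r0, seed=31, record_prob=None, **sim_kw):
    defaults = dict(
        n_founders=16,
        n_generations=3,
        n_matings=9,
        offspring_per_mating=3,
        m_loci=40,
        genotyped_fraction=0.3,
    )
    defaults.update(sim_kw)
    cfg = sd.SimConfig(
        seed=seed,
        spec=copy.deepcopy(spec),
        true_theta=[t.copy() for t in true_theta],
        true_r0=true_r0.copy(),
        record_prob=record_prob or {t.name: 1.0 for t in spec.traits},
        **defaults,
    )
    study = sd.simulate_study(cfg)
    design = build_design(study.pedigree, study.phenotypes, study.spec)
    engine = build_engine(study.pedigree, study.genotypes, study.spec)
    return study, design, engine


@pytest.fixture(scope="session")
def small_h_bundle():
    """~70-animal single-trait ssGBLUP study, complete records."""
    return make_bundle(single_trait_spec(), [np.array([[25.0]])], np.array([[30.0]]))


@pytest.fixture(scope="session")
def two_trait_bundle():
    """~180-animal two-trait ssGBLUP study with per-trait missingness."""
    return make_bundle(
        two_trait_spec(),
        [TH2],
        R2,
        seed=42,
        record_prob={"bw": 0.9, "ww": 0.8},
        n_founders=20,
        n_matings=12,
        m_loci=50,
    )


@pytest.fixture(scope="session")
def two_trait_complete_bundle():
    """Two-trait study with complete records (EM fixed-point checks)."""
    return make_bundle(
        two_trait_spec(), [TH2], R2, seed=77, n_founders=18, n_matings=10, m_loci=50
    )


def full_state(design, theta_list, r0) -> VarianceState:
    """VarianceState with all-free masks matching the design layout."""
    masks = [np.ones((g.t, g.t), dtype=bool) for g in design.groups]
    t = design.n_traits
    return VarianceState(
        [th.copy() for th in theta_list],
        r0.copy(),
        masks,
        np.ones((t, t), dtype=bool),
        [g.name for g in design.groups],
    )


def one_way_fixture(n_groups=40, n_per=8, seed=123, mean=10.0, sa=2.0, se=3.0):
    """Balanced one-way random-effects design with its closed-form ANOVA-REML
    estimates (the random 'animals' are unrelated, K = I)."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sa, n_groups)
    y = mean + a[:, None] + rng.normal(0.0, se, (n_groups, n_per))
    ped = Pedigree(
        [str(i + 1) for i in range(n_groups)],
        np.full(n_groups, -1),
        np.full(n_groups, -1),
    )
    animal = np.repeat(np.arange(n_groups), n_per)
    pheno = PhenotypeTable(
        animal=animal,
        fixed_codes={"mu": np.array(["1"] * len(animal))},
        y=y.reshape(-1, 1),
        mask=np.ones((len(animal), 1), dtype=bool),
    )
    spec = ModelSpec(
        traits=[TraitSpec("y", 3)],
        animal_col=1,
        fixed=[FixedSpec("mu", 2, ["y"])],
        random_groups=[
            RandomGroupSpec(name="grp", kind="identity", columns=[("animal", "y")])
        ],
    )
    design = build_design(ped, pheno, spec)
    engine = build_engine(ped, None, spec)
    ybar_i = y.mean(axis=1)
    msb = n_per * np.sum((ybar_i - y.mean()) ** 2) / (n_groups - 1)
    msw = np.sum((y - ybar_i[:, None]) ** 2) / (n_groups * (n_per - 1))
    closed_form = np.array([(msb - msw) / n_per, msw])
    return design, engine, spec, closed_form


def cov_z_stats(emp: np.ndarray, target: np.ndarray, n_draws: int):
    """Elementwise z-scores of an empirical covariance against its target,
    using the asymptotic SE (v_ii v_jj + v_ij^2)/B of covariance estimates."""
    se = np.sqrt(
        (np.outer(np.diag(target), np.diag(target)) + target**2) / n_draws
    )
    z = np.abs(emp - target) / se
    return float(z.max()), float(np.mean(z > 3.0))
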