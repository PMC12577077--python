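"""Variance-component parameter state with structural-zero masks.

The parameter set theta is one symmetric matrix per correlated random-effect
group plus the residual covariance R0.  Structural zeros (entries assumed zero
by the model, e.g. residual covariances involving a sparsely recorded trait)
are masked: they stay exactly zero through every update and are excluded from
the free-parameter vector (vech over unmasked lower-triangle entries).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def duplication_matrix(t: int) -> np.ndarray:
    """Maps vech (lower triangle, row-major) to vec of a symmetric t x t."""
    pairs = [(i, j) for i in range(t) for j in range(i + 1)]
    D = np.zeros((t * t, len(pairs)))
    for k, (i, j) in enumerate(pairs):
        D[i * t + j, k] = 1.0
        D[j * t + i, k] = 1.0
    return D


def is_spd(mat: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(mat)
        return True
    except np.linalg.LinAlgError:
        return False


def nearest_spd(mat: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue projection to the SPD cone (used as an EM safeguard)."""
    w, v = np.linalg.eigh(0.5 * (mat + mat.T))
    w = np.maximum(w, floor * max(1.0, w.max()))
    return (v * w) @ v.T


@dataclass
class VarianceState:
    """theta_k per random group plus R0, with boolean free-parameter masks."""

    theta: list[np.ndarray]
    r0: np.ndarray
    masks: list[np.ndarray]  # True = free
    r_mask: np.ndarray
    group_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.theta = [np.array(t, dtype=np.float64) for t in self.theta]
        self.r0 = np.array(self.r0, dtype=np.float64)
        self.enforce_masks()

    # --- vech bookkeeping ---------------------------------------------------

    def free_entries(self) -> list[tuple[str, int, int, int]]:
        """Ordered free parameters: ('group', k, i, j) then ('residual',-1,i,j),
        lower triangle (i >= j), masked entries skipped."""
        out = []
        for k, (th, mask) in enumerate(zip(self.theta, self.masks)):
            t = th.shape[0]
            for i in range(t):
                for j in range(i + 1):
                    if mask[i, j]:
                        out.append(("group", k, i, j))
        t = self.r0.shape[0]
        for i in range(t):
            for j in range(i + 1):
                if self.r_mask[i, j]:
                    out.append(("residual", -1, i, j))
        return out

    @property
    def n_free(self) -> int:
        return len(self.free_entries())

    def free_values(self) -> np.ndarray:
        vals = []
        for kind, k, i, j in self.free_entries():
            mat = self.theta[k] if kind == "group" else self.r0
            vals.append(mat[i, j])
        return np.array(vals)

    def labels(self, group_columns: list[list[str]] | None = None,
               trait_names: list[str] | None = None) -> list[str]:
        out = []
        for kind, k, i, j in self.free_entries():
            if kind == "group":
                name = self.group_names[k] if self.group_names else f"g{k}"
                if group_columns is not None:
                    ci, cj = group_columns[k][i], group_columns[k][j]
                else:
                    ci, cj = str(i), str(j)
                out.append(f"{name}({ci},{cj})" if i != j else f"{name}({ci})")
            else:
                ti = trait_names[i] if trait_names else str(i)
                tj = trait_names[j] if trait_names else str(j)
                out.append(f"residual({ti},{tj})" if i != j else f"residual({ti})")
        return out

    def with_free(self, values: np.ndarray) -> "VarianceState":
        new = self.copy()
        for val, (kind, k, i, j) in zip(values, self.free_entries()):
            mat = new.theta[k] if kind == "group" else new.r0
            mat[i, j] = mat[j, i] = val
        return new

    # --- utilities ----------------------------------------------------------

    def copy(self) -> "VarianceState":
        return VarianceState(
            [t.copy() for t in self.theta],
            self.r0.copy(),
            [m.copy() for m in self.masks],
            self.r_mask.copy(),
            list(self.group_names),
        )

    def enforce_masks(self) -> None:
        for th, mask in zip(self.theta, self.masks):
            th[~mask] = 0.0
        self.r0[~self.r_mask] = 0.0

    def all_spd(self) -> bool:
        return all(is_spd(t) for t in self.theta) and is_spd(self.r0)

    def delta_rel(self, prev: "VarianceState", eps: float = 1e-10) -> float:
        """Max relative round-to-round parameter change (the Delta-theta
        convergence statistic)."""
        a, b = self.free_values(), prev.free_values()
        return float(np.max(np.abs(a - b) / (np.abs(b) + eps)))


def start_state(spec, design) -> VarianceState:
    """Default starting values: 1.0 for variances, 0.1 for covariances."""
    theta, masks, names = [], [], []
    for g, layout in zip(spec.random_groups, design.groups):
        t = layout.t
        th = np.full((t, t), spec.start_covariance)
        np.fill_diagonal(th, spec.start_variance)
        theta.append(th)
        masks.append(layout.mask)
        names.append(g.name)
    t = design.n_traits
    r0 = np.full((t, t), spec.start_covariance)
    np.fill_diagonal(r0, spec.start_variance)
    st = VarianceState(theta, r0, masks, spec.residual_mask(), names)
    if not st.all_spd():
        raise ValueError("starting values not positive definite under the masks")
    return st
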