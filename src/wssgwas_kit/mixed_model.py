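"""Single-trait animal-model mixed-model equations with H^-1.

The model is y = Xb + Za + e with a ~ N(0, H sigma_a^2) over ALL pedigree
animals (genotyped or not) and e ~ N(0, I sigma_e^2).  Variance components
are treated as known inputs.  Solving

    [X'X      X'Z            ] [b]   [X'y]
    [Z'X      Z'Z + lambda H^-1] [a] = [Z'y],   lambda = sigma_e^2 / sigma_a^2

yields fixed-effect solutions and GEBV; the genomic-only DGV for a
genotyped animal i is -(sum_{j != i} g^{ij} GEBV_j) / g^{ii} with g^{ij}
elements of the (blended) G inverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .relationships import HInverse


class StructuralError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Trait, fixed-effect structure, and known variance components."""

    trait: str
    fixed_factors: list[str]
    covariates: list[str]
    sigma_a2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        if self.sigma_a2 <= 0 or self.sigma_e2 <= 0:
            raise ValueError("variance components must be positive")

    @property
    def lam(self) -> float:
        return self.sigma_e2 / self.sigma_a2


@dataclass
class DesignMatrices:
    X: np.ndarray
    Z: sp.csr_matrix
    y: np.ndarray
    x_columns: list[str]
    record_animals: list[str]


def build_incidence(
    phenotypes: pd.DataFrame,
    spec: ModelSpec,
    pedigree_ids: list[str],
    reference_coding: bool = True,
) -> DesignMatrices:
    """Incidence matrices for records with a non-missing trait value.

    The first factor enters with a full set of level dummies (absorbing
    the intercept); each later factor drops its first level (reference
    coding) so X has full column rank for crossed designs.  With
    ``reference_coding=False`` all levels of all factors are kept (rank
    deficient; the solver then falls back to a least-squares solution) —
    predicted values are invariant to this choice.
    Z maps records to positions in ``pedigree_ids``; animals without
    records simply get empty Z columns but still receive a GEBV.
    """
    table = phenotypes.loc[phenotypes[spec.trait].notna()].reset_index(drop=True)
    idx = {str(a): i for i, a in enumerate(pedigree_ids)}
    animals = table["animal"].astype(str).tolist()
    missing = [a for a in animals if a not in idx]
    if missing:
        raise StructuralError(
            f"record for animal {missing[0]!r} absent from pedigree"
        )
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for j, factor in enumerate(spec.fixed_factors):
        dummies = pd.get_dummies(
            table[factor].astype(str),
            prefix=factor,
            drop_first=reference_coding and j > 0,
        )
        blocks.append(dummies.to_numpy(dtype=np.float64))
        names.extend(dummies.columns)
    if not spec.fixed_factors:
        blocks.append(np.ones((len(table), 1)))
        names.append("intercept")
    for cov in spec.covariates:
        blocks.append(table[cov].to_numpy(dtype=np.float64)[:, None])
        names.append(cov)
    X = np.hstack(blocks)
    rows = np.arange(len(table))
    cols = np.array([idx[a] for a in animals])
    Z = sp.csr_matrix(
        (np.ones(len(table)), (rows, cols)), shape=(len(table), len(pedigree_ids))
    )
    y = table[spec.trait].to_numpy(dtype=np.float64)
    return DesignMatrices(X, Z, y, names, animals)


@dataclass
class MmeSolution:
    b_hat: np.ndarray
    gebv: pd.Series  # indexed by pedigree animal id
    x_columns: list[str]
    method: str
    residual_norm: float

    def fitted(self, design: DesignMatrices) -> np.ndarray:
        return design.X @ self.b_hat + design.Z @ self.gebv.to_numpy()


def solve_mme(
    design: DesignMatrices,
    h_inv: HInverse,
    spec: ModelSpec,
    rtol: float = 1e-8,
) -> MmeSolution:
    """Solve the mixed-model equations by sparse symmetric factorization.

    A rank-deficient left-hand side (e.g. full dummy coding) falls back to
    a dense minimum-norm least-squares solution, which leaves estimable
    functions (fitted values, GEBV contrasts) unchanged.
    """
    X = sp.csr_matrix(design.X)
    Z, y = design.Z, design.y
    lam = spec.lam
    lhs = sp.bmat(
        [
            [X.T @ X, X.T @ Z],
            [Z.T @ X, Z.T @ Z + lam * h_inv.values],
        ],
        format="csc",
    )
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    method = "sparse_lu"
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", spla.MatrixRankWarning)
        try:
            sol = spla.spsolve(lhs, rhs)
        except RuntimeError:
            sol = np.full(lhs.shape[0], np.nan)
    resid = _relative_residual(lhs, sol, rhs)
    if not np.all(np.isfinite(sol)) or resid > rtol:
        sol, *_ = np.linalg.lstsq(lhs.toarray(), rhs, rcond=None)
        method = "dense_lstsq"
        resid = _relative_residual(lhs, sol, rhs)
    n_fixed = design.X.shape[1]
    gebv = pd.Series(sol[n_fixed:], index=list(h_inv.ids), name="gebv")
    return MmeSolution(sol[:n_fixed], gebv, design.x_columns, method, resid)


def _relative_residual(lhs, sol, rhs) -> float:
    denom = np.linalg.norm(rhs)
    if denom == 0:
        return float(np.linalg.norm(lhs @ sol))
    return float(np.linalg.norm(lhs @ sol - rhs) / denom)


def compute_dgv(
    g_blend_inverse: np.ndarray, gebv_genotyped: np.ndarray
) -> np.ndarray:
    """DGV_i = -(sum_{j != i} g^{ij} GEBV_j) / g^{ii}.

    The conditional-expectation form of the genomic-only prediction for
    animal i given the breeding values of its genotyped relatives.
    """
    Ginv = np.asarray(g_blend_inverse, dtype=np.float64)
    g = np.asarray(gebv_genotyped, dtype=np.float64)
    diag = np.diag(Ginv)
    if np.any(diag == 0):
        raise ValueError("zero diagonal element in G inverse")
    off = Ginv @ g - diag * g
    return -off / diag
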