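"""Pedigree and genomic relationship matrices for single-step evaluation.

Builds the numerator relationship matrix A (tabular method), its sparse
inverse (Henderson rules with inbreeding), the genomic relationship matrix
G from centered SNP dosages (VanRaden scaling, optionally SNP-weighted),
the G/A22 blend that guards against singular G, and the combined H inverse

    H^-1 = A^-1 + [0 0; 0 (w_g G + w_a A22)^-1 - A22^-1]

which carries genomic information into the genotyped block of the
mixed-model equations while leaving ungenotyped animals on pure pedigree
expectations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .panel import GenotypePanel
from .pedigree import Pedigree

SYMMETRY_TOL = 1e-10


class DegenerateInputError(ValueError):
    """Input admits no valid relationship matrix (monomorphic panel, ...)."""


@dataclass
class KinshipMatrix:
    """Symmetric relationship matrix over an ordered set of animals."""

    ids: list[str]
    values: np.ndarray
    kind: str  # A | A22 | G_raw | G_blend

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("kinship matrix shape does not match id count")
        asym = np.max(np.abs(self.values - self.values.T), initial=0.0)
        if asym > 1e-8:
            raise ValueError(f"kinship matrix asymmetric (max dev {asym:.2e})")
        self.values = 0.5 * (self.values + self.values.T)

    def submatrix(self, ids: list[str]) -> "KinshipMatrix":
        idx = {a: i for i, a in enumerate(self.ids)}
        rows = np.array([idx[str(a)] for a in ids])
        return KinshipMatrix(
            list(ids), self.values[np.ix_(rows, rows)], self.kind
        )


@dataclass
class SnpWeights:
    """Per-SNP positive weights; trace is kept equal to the SNP count."""

    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("SNP weights must be finite and non-negative")

    @classmethod
    def identity(cls, m: int) -> "SnpWeights":
        return cls(np.ones(m))

    @property
    def trace(self) -> float:
        return float(self.d.sum())


@dataclass
class CenteringStats:
    """Allele frequencies and the VanRaden scale 2*sum p(1-p)."""

    p: np.ndarray
    scale_c: float


@dataclass
class HInverse:
    """Sparse H^-1 over all pedigree animals."""

    ids: list[str]
    values: sp.csr_matrix
    genotyped_ids: list[str]


# ---------------------------------------------------------------------------
# Pedigree side


def compute_A(
    pedigree: Pedigree, subset: list[str] | None = None
) -> KinshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Diagonal entries are 1 + F (F = inbreeding coefficient); off-diagonals
    are parent-average recursions in topological order.  ``subset``
    extracts the block for the given animals (A22 when these are the
    genotyped ones).
    """
    n = len(pedigree)
    s, d = pedigree.parent_indices()
    A = np.zeros((n, n))
    for i in pedigree.topological_order():
        si, di = s[i], d[i]
        row = np.zeros(n)
        if si >= 0:
            row += 0.5 * A[si]
        if di >= 0:
            row += 0.5 * A[di]
        A[i, :] = row
        A[:, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
    mat = KinshipMatrix(pedigree.ids, A, "A")
    if subset is not None:
        mat = mat.submatrix(subset)
        mat.kind = "A22"
    return mat


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """F per animal, in record order (diag(A) - 1)."""
    return np.diag(compute_A(pedigree).values) - 1.0


def compute_A_inverse(pedigree: Pedigree) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    Mendelian-sampling variances use parental inbreeding coefficients
    (d_i = 0.5 - 0.25(F_s + F_d) with both parents known, etc.), so the
    product with :func:`compute_A` is the identity also on inbred
    pedigrees.
    """
    n = len(pedigree)
    s, d = pedigree.parent_indices()
    F = inbreeding_coefficients(pedigree)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            dm = 0.5 - 0.25 * (F[si] + F[di])
        elif si >= 0 or di >= 0:
            dm = 0.75 - 0.25 * F[si if si >= 0 else di]
        else:
            dm = 1.0
        alpha = 1.0 / dm
        add(i, i, alpha)
        for p in (si, di):
            if p >= 0:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
                add(p, p, 0.25 * alpha)
        if si >= 0 and di >= 0:
            add(si, di, 0.25 * alpha)
            add(di, si, 0.25 * alpha)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


# ---------------------------------------------------------------------------
# Genomic side


def compute_G(
    panel: GenotypePanel, weights: SnpWeights | None = None
) -> tuple[KinshipMatrix, CenteringStats]:
    """Genomic relationship matrix G = M D M' / (2 sum p(1-p)).

    M is the column-centered dosage matrix (dosage - 2p with p observed in
    the panel); with D = I this is VanRaden's method 1.  Missing dosages
    are mean-imputed before centering.
    """
    if panel.n_snps == 0 or panel.n_animals == 0:
        raise DegenerateInputError("empty genotype panel")
    if weights is None:
        weights = SnpWeights.identity(panel.n_snps)
    if len(weights.d) != panel.n_snps:
        raise ValueError("weight vector length does not match SNP count")
    p = panel.allele_frequencies()
    c = float(2.0 * np.sum(p * (1.0 - p)))
    if c <= 0:
        raise DegenerateInputError("all SNPs monomorphic: scale 2*sum p(1-p) = 0")
    M = panel.imputed_dosages() - 2.0 * p
    G = (M * weights.d) @ M.T / c
    return KinshipMatrix(panel.animal_ids, G, "G_raw"), CenteringStats(p, c)


def centered_dosages(panel: GenotypePanel) -> tuple[np.ndarray, CenteringStats]:
    """Mean-imputed, column-centered dosage matrix M with its stats."""
    p = panel.allele_frequencies()
    c = float(2.0 * np.sum(p * (1.0 - p)))
    if c <= 0:
        raise DegenerateInputError("all SNPs monomorphic")
    return panel.imputed_dosages() - 2.0 * p, CenteringStats(p, c)


def blend_G(
    G: KinshipMatrix,
    A22: KinshipMatrix,
    g_coef: float = 0.95,
    a_coef: float = 0.05,
) -> KinshipMatrix:
    """Convex blend w_g*G + w_a*A22 that restores invertibility of G."""
    if G.ids != A22.ids:
        raise ValueError("G and A22 must be over the same animals in order")
    if abs(g_coef + a_coef - 1.0) > 1e-12:
        raise ValueError("blend coefficients must sum to 1")
    return KinshipMatrix(
        G.ids, g_coef * G.values + a_coef * A22.values, "G_blend"
    )


def invert_spd(mat: KinshipMatrix) -> np.ndarray:
    """Inverse via Cholesky; raises with a condition report if not SPD."""
    try:
        L = np.linalg.cholesky(mat.values)
        pivots = np.diag(L)
        if pivots.min() < 1e-7 * pivots.max():
            raise np.linalg.LinAlgError("numerically singular")
    except np.linalg.LinAlgError as exc:
        eig = np.linalg.eigvalsh(mat.values)
        raise DegenerateInputError(
            f"{mat.kind} not positive definite "
            f"(eigenvalue range [{eig[0]:.3e}, {eig[-1]:.3e}])"
        ) from exc
    ident = np.eye(len(mat.ids))
    Linv = np.linalg.solve(L, ident)
    return Linv.T @ Linv


def compute_H_inverse(
    A_inv: sp.spmatrix,
    A22: KinshipMatrix,
    G_blend: KinshipMatrix,
    genotyped_ids: list[str],
    pedigree_ids: list[str],
) -> HInverse:
    """A^-1 plus the genotyped-block correction (G_blend^-1 - A22^-1)."""
    H = sp.lil_matrix(A_inv.shape)
    H[:, :] = A_inv
    if genotyped_ids:
        if G_blend.ids != list(genotyped_ids) or A22.ids != list(genotyped_ids):
            raise ValueError("G_blend / A22 id order must match genotyped_ids")
        idx = {a: i for i, a in enumerate(pedigree_ids)}
        pos = np.array([idx[str(a)] for a in genotyped_ids])
        corr = invert_spd(G_blend) - invert_spd(A22)
        H[np.ix_(pos, pos)] = H[np.ix_(pos, pos)].toarray() + corr
    return HInverse(list(pedigree_ids), H.tocsr(), list(genotyped_ids))
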