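"""Pedigree (A) and genomic (G) additive relationship matrices.

A is built with the recursive tabular method; its sparse inverse comes
from Henderson's rules with inbreeding accounted for.  G follows VanRaden:
G = Z Z' / k with Z the column-centred SNP matrix and
k = 2 sum_l q_l (1 - q_l), allele frequencies taken from the supplied
animals (training and prediction jointly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class RelationshipMatrix:
    kind: str                 # "pedigree_A" | "genomic_G"
    ids: np.ndarray           # animal ids in matrix order
    matrix: np.ndarray        # dense symmetric PSD

    def index_of(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([lookup[a] for a in np.asarray(ids)], dtype=np.intp)
        except KeyError as err:
            raise KeyError(f"animal {err.args[0]} not in relationship matrix") from None

    def submatrix(self, ids) -> "RelationshipMatrix":
        idx = self.index_of(ids)
        return RelationshipMatrix(kind=self.kind, ids=np.asarray(ids),
                                  matrix=self.matrix[np.ix_(idx, idx)])


def _pedigree_arrays(pedigree: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ids plus 0-based sire/dam indices (-1 unknown), parents-before-offspring."""
    ids = pedigree["id"].to_numpy()
    if np.unique(ids).size != ids.size:
        raise ValueError("duplicate animal ids in pedigree")
    pos = {a: i for i, a in enumerate(ids)}
    sire = np.array([pos.get(s, -1) for s in pedigree["sire"]], dtype=np.intp)
    dam = np.array([pos.get(d, -1) for d in pedigree["dam"]], dtype=np.intp)
    order = np.arange(ids.size)
    if np.any(sire >= order) or np.any(dam >= order):
        raise ValueError("pedigree not sorted parents-before-offspring "
                         "(or contains a cycle)")
    return ids, sire, dam


def pedigree_A(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Dense numerator relationship matrix by the tabular method.

    A_ii = 1 + 0.5 A(sire, dam); A_ij = 0.5 (A(j, sire_i) + A(j, dam_i)).
    Memory is O(n²); intended for study-scale pedigrees (a few thousand
    animals), not national ones.
    """
    ids, sire, dam = _pedigree_arrays(pedigree)
    n = ids.size
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return RelationshipMatrix(kind="pedigree_A", ids=ids, matrix=A)


def pedigree_A_inverse(pedigree: pd.DataFrame) -> sp.csr_matrix:
    """Sparse A⁻¹ by Henderson's rules, with inbreeding.

    Mendelian sampling variances use the parental inbreeding coefficients
    (taken from the tabular A diagonal), so the product with the dense A
    is the identity for any valid pedigree.
    """
    ids, sire, dam = _pedigree_arrays(pedigree)
    F = pedigree_A(pedigree).matrix.diagonal() - 1.0
    n = ids.size
    rows, cols, vals = [], [], []
    for i in range(n):
        s, d = sire[i], dam[i]
        a_ss = 1.0 + F[s] if s >= 0 else 0.0
        a_dd = 1.0 + F[d] if d >= 0 else 0.0
        known = (s >= 0) + (d >= 0)
        dii = 1.0 - 0.25 * (a_ss + a_dd) if known else 1.0
        w = 1.0 / dii
        entries = [(i, i, w)]
        for p in (s, d):
            if p >= 0:
                entries += [(p, i, -0.5 * w), (i, p, -0.5 * w)]
        if s >= 0 and d >= 0:
            entries += [(s, d, 0.25 * w), (d, s, 0.25 * w)]
        for p in (s, d):
            if p >= 0:
                entries.append((p, p, 0.25 * w))
        for r, c, v in entries:
            rows.append(r), cols.append(c), vals.append(v)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def genomic_G(dosages: np.ndarray, ids: np.ndarray | None = None,
              ridge: float = 0.0) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix from {0,1,2} dosages.

    Allele frequencies come from the supplied animals; monomorphic markers
    contribute nothing to k and are dropped with a warning.  An optional
    ridge can be added to the diagonal for factorisation of rank-deficient
    G (markers < animals).
    """
    dosages = np.asarray(dosages, dtype=float)
    if not np.isin(dosages, (0.0, 1.0, 2.0)).all():
        raise ValueError("dosages must be 0, 1 or 2")
    q = dosages.mean(axis=0) / 2.0
    poly = (q > 0) & (q < 1)
    if not poly.all():
        warnings.warn(f"dropping {int((~poly).sum())} monomorphic markers from G")
        dosages, q = dosages[:, poly], q[poly]
    if q.size == 0:
        raise ValueError("no polymorphic markers")
    Z = dosages - 2.0 * q
    k = 2.0 * np.sum(q * (1.0 - q))
    G = Z @ Z.T / k
    if ridge:
        G[np.diag_indices_from(G)] += ridge
    if ids is None:
        ids = np.arange(1, dosages.shape[0] + 1)
    return RelationshipMatrix(kind="genomic_G", ids=np.asarray(ids), matrix=G)


def write_sparse_triplets(mat, path) -> None:
    """3-column (i, j, value) text export of a sparse or dense matrix."""
    coo = sp.coo_matrix(mat)
    pd.DataFrame({"i": coo.row + 1, "j": coo.col + 1, "value": coo.data}).to_csv(
        path, index=False)
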