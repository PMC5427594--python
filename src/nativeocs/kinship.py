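"""Classical and origin-aware pedigree kinships.

All matrices are probabilities for a pair of alleles, one drawn at random from
each of two individuals (with replacement when the two individuals coincide,
so the diagonal is f(i,i) = (1 + F_i)/2):

* ``fA``   — the classical kinship: P(the two alleles are IBD).
* ``fN``   — P(both alleles descend from native founders).
* ``fM``   — P(both alleles descend from migrant founders).
* ``Knat`` — P(the alleles are IBD *and* native).  IBD alleles are copies of a
  single founder allele and therefore share one origin, which makes the
  decompositions below disjoint unions.
* ``fB = Knat + (1 - fN)`` — P(IBD or at least one allele migrant).
* ``fC = Knat + fM``       — P(IBD or both alleles migrant).

The kinship at native alleles for a contribution vector ``c`` is the
conditional IBD probability given both alleles are native,

    fD(c) = 1 - (1 - c'fB c) / (c'fN c) = c'Knat c / c'fN c.

Everything is computed by one pass over the topologically ordered pedigree
(the tabular method); origin-aware variants only change the founder base cases
and the diagonal term, replacing the constant 1 by the native (or migrant)
fraction of the individual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import OriginAnnotation, Pedigree

__all__ = [
    "KinshipMatrix", "KinshipSet", "kinship_classical", "native_pair_prob",
    "migrant_pair_prob", "native_ibd_kinship", "assemble_fB", "assemble_fC",
    "compute_kinship_set", "mean_kinship", "fD_of_contributions",
    "mean_candidate_kinship",
]


@dataclass
class KinshipMatrix:
    ids: list[str]
    values: np.ndarray
    role: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id list")

    def loc(self, i: str, j: str) -> float:
        idx = {v: k for k, v in enumerate(self.ids)}
        return float(self.values[idx[i], idx[j]])


@dataclass
class KinshipSet:
    fA: KinshipMatrix
    fN: KinshipMatrix
    fM: KinshipMatrix
    Knat: KinshipMatrix
    fB: KinshipMatrix
    fC: KinshipMatrix

    @property
    def ids(self) -> list[str]:
        return self.fA.ids


def _recurse(ped: Pedigree, founder_row, founder_diag, diag_weight) -> np.ndarray:
    """Shared tabular recursion.

    ``founder_row(i, done)`` fills entries against all earlier individuals for
    a founder row, ``founder_diag(i)`` its diagonal, and ``diag_weight(i)`` the
    same-allele-draw weight w_i in f(i,i) = (w_i + f(s_i, d_i)) / 2.
    """
    n = len(ped)
    F = np.zeros((n, n))
    s, d = ped.sire_idx, ped.dam_idx
    for i in range(n):
        if s[i] < 0:  # founder (phantoms included)
            if i:
                row = founder_row(i, i)
                F[i, :i] = row
                F[:i, i] = row
            F[i, i] = founder_diag(i)
        else:
            si, di = s[i], d[i]
            row = 0.5 * (F[si, :i] + F[di, :i])
            F[i, :i] = row
            F[:i, i] = row
            F[i, i] = 0.5 * (diag_weight(i) + F[si, di])
    return F


def _subset_block(ped: Pedigree, F: np.ndarray, subset) -> np.ndarray:
    idx = [ped.index[i] for i in subset]
    return F[np.ix_(idx, idx)]


def kinship_classical(ped: Pedigree, subset: list[str] | None = None) -> KinshipMatrix:
    """Classical kinship by the tabular method over the full pedigree."""
    subset = list(subset) if subset is not None else ped.ids
    F = _recurse(
        ped,
        founder_row=lambda i, k: np.zeros(k),
        founder_diag=lambda i: 0.5,
        diag_weight=lambda i: 1.0,
    )
    return KinshipMatrix(subset, _subset_block(ped, F, subset), "fA")


def _origin_vectors(ped: Pedigree, origin: OriginAnnotation) -> np.ndarray:
    return np.array([origin.mc[r.id] for r in ped])


def native_pair_prob(ped: Pedigree, origin: OriginAnnotation,
                     subset: list[str] | None = None) -> KinshipMatrix:
    """P(both sampled alleles descend from native founders).

    A founder's allele origin is fixed by its classification and independent of
    every non-descendant, so founder rows factorize into
    n_i * (1 - mc[j]).
    """
    subset = list(subset) if subset is not None else ped.ids
    mc = _origin_vectors(ped, origin)
    nat = 1.0 - mc
    F = _recurse(
        ped,
        founder_row=lambda i, k: nat[i] * nat[:k],
        founder_diag=lambda i: nat[i],
        diag_weight=lambda i: nat[i],
    )
    return KinshipMatrix(subset, _subset_block(ped, F, subset), "fN")


def migrant_pair_prob(ped: Pedigree, origin: OriginAnnotation,
                      subset: list[str] | None = None) -> KinshipMatrix:
    """P(both sampled alleles descend from migrant founders); mirror of fN."""
    subset = list(subset) if subset is not None else ped.ids
    mc = _origin_vectors(ped, origin)
    F = _recurse(
        ped,
        founder_row=lambda i, k: mc[i] * mc[:k],
        founder_diag=lambda i: mc[i],
        diag_weight=lambda i: mc[i],
    )
    return KinshipMatrix(subset, _subset_block(ped, F, subset), "fM")


def native_ibd_kinship(ped: Pedigree, origin: OriginAnnotation,
                       subset: list[str] | None = None) -> KinshipMatrix:
    """P(alleles IBD and native): classical recursion with native-weighted diagonal."""
    subset = list(subset) if subset is not None else ped.ids
    mc = _origin_vectors(ped, origin)
    nat = 1.0 - mc
    F = _recurse(
        ped,
        founder_row=lambda i, k: np.zeros(k),
        founder_diag=lambda i: 0.5 * nat[i],
        diag_weight=lambda i: nat[i],
    )
    return KinshipMatrix(subset, _subset_block(ped, F, subset), "Knat")


def _check_range(values: np.ndarray, role: str, tol: float = 1e-9) -> None:
    if values.min() < -tol or values.max() > 1 + tol:
        raise ValueError(f"{role} entries outside [0, 1]: internal inconsistency")


def assemble_fB(Knat: KinshipMatrix, fN: KinshipMatrix) -> KinshipMatrix:
    """fB = Knat + (1 - fN): IBD (necessarily same-origin) or >=1 migrant allele."""
    if Knat.ids != fN.ids:
        raise ValueError("id order mismatch")
    vals = Knat.values + (1.0 - fN.values)
    _check_range(vals, "fB")
    return KinshipMatrix(list(Knat.ids), vals, "fB")


def assemble_fC(Knat: KinshipMatrix, fM: KinshipMatrix) -> KinshipMatrix:
    """fC = Knat + fM: IBD-and-native is disjoint from both-migrant."""
    if Knat.ids != fM.ids:
        raise ValueError("id order mismatch")
    vals = Knat.values + fM.values
    _check_range(vals, "fC")
    return KinshipMatrix(list(Knat.ids), vals, "fC")


def compute_kinship_set(ped: Pedigree, origin: OriginAnnotation,
                        subset: list[str] | None = None,
                        prune: bool = True) -> KinshipSet:
    """All six matrices over ``subset``, pruning to the ancestor closure first."""
    subset = list(subset) if subset is not None else ped.ids
    if prune:
        ped = ped.ancestor_closure(subset)
    fA = kinship_classical(ped, subset)
    fN = native_pair_prob(ped, origin, subset)
    fM = migrant_pair_prob(ped, origin, subset)
    Knat = native_ibd_kinship(ped, origin, subset)
    return KinshipSet(fA=fA, fN=fN, fM=fM, Knat=Knat,
                      fB=assemble_fB(Knat, fN), fC=assemble_fC(Knat, fM))


def mean_kinship(c: np.ndarray, M: KinshipMatrix) -> float:
    """Offspring-generation mean kinship, the quadratic form c'Mc."""
    c = np.asarray(c, dtype=float)
    if c.shape != (len(M.ids),):
        raise ValueError("contribution vector does not match matrix dimension")
    return float(c @ M.values @ c)


def fD_of_contributions(c: np.ndarray, fB: KinshipMatrix, fN: KinshipMatrix,
                        eps: float = 1e-8) -> float:
    """Kinship at native alleles, fD(c) = 1 - (1 - c'fB c)/(c'fN c)."""
    denom = mean_kinship(c, fN)
    if denom <= eps:
        raise ValueError("no native ancestry in offspring generation")
    return 1.0 - (1.0 - mean_kinship(c, fB)) / denom


def mean_candidate_kinship(fA: KinshipMatrix, include_diagonal: bool = False) -> float:
    """Average kinship of the candidates (distinct pairs by default)."""
    v = fA.values
    n = v.shape[0]
    if include_diagonal:
        return float(v.mean())
    if n < 2:
        raise ValueError("need at least two candidates")
    return float((v.sum() - np.trace(v)) / (n * (n - 1)))
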