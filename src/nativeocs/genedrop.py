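"""Gene-dropping simulation and exhaustive transmission enumeration.

Both routines estimate the same pairwise probabilities the kinship recursions
compute — IBD, both-native, both-migrant, IBD-and-native — plus per-individual
migrant contributions, but from first principles: every founder receives two
uniquely labeled alleles tagged with the founder's origin, and alleles are
transmitted down the pedigree by Mendelian sampling.

``gene_drop`` is a seeded Monte-Carlo dropper (vectorized over replicates,
processed in chunks to bound memory).  ``enumerate_transmissions`` sums over
all 2^T equiprobable inheritance patterns (T = number of meioses) in exact
rational arithmetic and is the correctness arbiter for the recursions on
small pedigrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .pedigree import OriginAnnotation, Pedigree

__all__ = ["DropResult", "gene_drop", "enumerate_transmissions"]

_KEYS = ("fA", "fN", "fM", "Knat")


@dataclass
class DropResult:
    ids: list[str]
    fA: np.ndarray
    fN: np.ndarray
    fM: np.ndarray
    Knat: np.ndarray
    mc: dict[str, float]
    replicates: int | None = None
    seed: int | None = None
    exact: dict[str, list[list[Fraction]]] | None = None

    def matrix(self, role: str) -> np.ndarray:
        return getattr(self, role)


def _founder_origins(ped: Pedigree, origin: OriginAnnotation) -> np.ndarray:
    """Per-allele migrant flag, alleles of individual i are 2i and 2i+1."""
    n = len(ped)
    migrant = np.zeros(2 * n, dtype=bool)
    for i, r in enumerate(ped):
        if r.is_founder and origin.is_migrant_founder[r.id]:
            migrant[2 * i] = migrant[2 * i + 1] = True
    return migrant


def gene_drop(ped: Pedigree, origin: OriginAnnotation, subset: list[str],
              replicates: int, seed: int, chunk: int = 100_000) -> DropResult:
    """Monte-Carlo estimates of fA, fN, fM, Knat over ``subset`` and MC for all.

    Per replicate every non-founder inherits one uniformly chosen allele from
    each parent; per pair one allele is drawn from each individual (with
    replacement on the diagonal) and the event indicators are averaged.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    n = len(ped)
    k = len(subset)
    sidx = np.array([ped.index[i] for i in subset])
    migrant = _founder_origins(ped, origin)
    rng = np.random.default_rng(seed)

    sums = {key: np.zeros((k, k)) for key in _KEYS}
    mc_sum = np.zeros(n)
    done = 0
    while done < replicates:
        r = min(chunk, replicates - done)
        pat = np.empty((n, r), dtype=np.int32)
        mat = np.empty((n, r), dtype=np.int32)
        for i in range(n):
            si, di = ped.sire_idx[i], ped.dam_idx[i]
            if si < 0:
                pat[i] = 2 * i
                mat[i] = 2 * i + 1
            else:
                pick = rng.integers(0, 2, size=r, dtype=np.int8)
                pat[i] = np.where(pick == 0, pat[si], mat[si])
                pick = rng.integers(0, 2, size=r, dtype=np.int8)
                mat[i] = np.where(pick == 0, pat[di], mat[di])
        mc_sum += 0.5 * (migrant[pat].sum(axis=1) + migrant[mat].sum(axis=1))

        # one random allele per (pair slot, individual); independent draws so
        # the diagonal is sampled with replacement
        pick_a = rng.integers(0, 2, size=(k, r), dtype=np.int8)
        pick_b = rng.integers(0, 2, size=(k, r), dtype=np.int8)
        al_a = np.where(pick_a == 0, pat[sidx], mat[sidx])
        al_b = np.where(pick_b == 0, pat[sidx], mat[sidx])
        for a in range(k):
            ibd = al_a[a][None, :] == al_b
            both_nat = ~migrant[al_a[a]][None, :] & ~migrant[al_b]
            sums["fA"][a] += ibd.sum(axis=1)
            sums["fN"][a] += both_nat.sum(axis=1)
            sums["fM"][a] += (migrant[al_a[a]][None, :] & migrant[al_b]).sum(axis=1)
            sums["Knat"][a] += (ibd & both_nat).sum(axis=1)
        done += r

    est = {key: sums[key] / replicates for key in _KEYS}
    # symmetrize: (i,j) and (j,i) are estimates of the same probability
    est = {key: 0.5 * (m + m.T) for key, m in est.items()}
    mc = {r_.id: float(mc_sum[i] / replicates) for i, r_ in enumerate(ped)}
    return DropResult(ids=list(subset), mc=mc, replicates=replicates, seed=seed,
                      **est)


def enumerate_transmissions(ped: Pedigree, origin: OriginAnnotation,
                            subset: list[str], max_meioses: int = 24) -> DropResult:
    """Exact probabilities by enumerating all inheritance patterns.

    Each non-founder contributes two meioses; with T meioses there are 2^T
    equiprobable patterns, and within each the four equiprobable allele draws
    per pair are enumerated too, so results are exact rationals with
    denominator 4 * 2^T.
    """
    n = len(ped)
    nonfounders = [i for i in range(n) if ped.sire_idx[i] >= 0]
    T = 2 * len(nonfounders)
    if T > max_meioses:
        raise ValueError(
            f"{T} meioses exceed the enumeration bound {max_meioses}; "
            "use gene_drop instead")
    migrant = _founder_origins(ped, origin)
    k = len(subset)
    sidx = [ped.index[i] for i in subset]

    counts = {key: [[0] * k for _ in range(k)] for key in _KEYS}
    mc_counts = [0] * n
    pat = np.empty(n, dtype=np.int64)
    mat = np.empty(n, dtype=np.int64)
    for i in range(n):
        if ped.sire_idx[i] < 0:
            pat[i] = 2 * i
            mat[i] = 2 * i + 1

    npat = 1 << T
    for pattern in range(npat):
        bits = pattern
        for idx, i in enumerate(nonfounders):
            si, di = ped.sire_idx[i], ped.dam_idx[i]
            pat[i] = pat[si] if (bits >> (2 * idx)) & 1 else mat[si]
            mat[i] = pat[di] if (bits >> (2 * idx + 1)) & 1 else mat[di]
        for i in range(n):
            mc_counts[i] += int(migrant[pat[i]]) + int(migrant[mat[i]])
        for a in range(k):
            for b in range(a, k):
                ia, ib = sidx[a], sidx[b]
                for al_a in (pat[ia], mat[ia]):
                    for al_b in (pat[ib], mat[ib]):
                        ibd = al_a == al_b
                        nat = not migrant[al_a] and not migrant[al_b]
                        mig = migrant[al_a] and migrant[al_b]
                        if ibd:
                            counts["fA"][a][b] += 1
                        if nat:
                            counts["fN"][a][b] += 1
                        if mig:
                            counts["fM"][a][b] += 1
                        if ibd and nat:
                            counts["Knat"][a][b] += 1

    denom = 4 * npat
    exact: dict[str, list[list[Fraction]]] = {}
    mats: dict[str, np.ndarray] = {}
    for key in _KEYS:
        frac = [[Fraction(0)] * k for _ in range(k)]
        arr = np.zeros((k, k))
        for a in range(k):
            for b in range(a, k):
                f = Fraction(counts[key][a][b], denom)
                frac[a][b] = frac[b][a] = f
                arr[a, b] = arr[b, a] = float(f)
        exact[key] = frac
        mats[key] = arr
    mc = {r.id: float(Fraction(mc_counts[i], 2 * npat))
          for i, r in enumerate(ped)}
    return DropResult(ids=list(subset), mc=mc, exact=exact, **mats)
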