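"""Pedigree I/O, validation, origin classification and migrant contributions.

A pedigree is a list of records (id, sire, dam, sex, birth year, breed, EBV)
kept in topological order (parents before offspring).  Founders are parentless
records; unknown-parent slots of non-founders are filled with *phantom*
founders so that downstream recursions never branch on missing parents.

Origin classification follows the herdbook convention for local breeds with
historical introgression: a founder is *native* when its breed code belongs to
the native breed, or when its breed is unknown but it was born before a cutoff
year (default 1970); every other founder is a *migrant*.  The migrant
contribution MC of a non-founder is the average of its parents' MC, so MC is
the expected fraction of the genome descending from migrant founders.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

MISSING = None

MALE = "male"
FEMALE = "female"

#: accepted spellings of sex codes in input files
_SEX_CODES = {
    "m": MALE, "male": MALE, "1": MALE, "s": MALE,
    "f": FEMALE, "female": FEMALE, "2": FEMALE, "d": FEMALE,
}

DEFAULT_SENTINELS = ("", "0", "NA", ".")


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles, sex conflicts)."""


@dataclass(frozen=True)
class PedigreeRecord:
    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str | None = None
    birth_year: int | None = None
    breed: str | None = None
    ebv: float | None = None
    phantom: bool = False

    @property
    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None


class Pedigree:
    """Topologically ordered pedigree with index-based parent lookup."""

    def __init__(self, records: list[PedigreeRecord]):
        self.records = records
        self.index = {r.id: i for i, r in enumerate(records)}
        if len(self.index) != len(records):
            seen: set[str] = set()
            for r in records:
                if r.id in seen:
                    raise PedigreeError(f"duplicate id: {r.id!r}")
                seen.add(r.id)
        n = len(records)
        self.sire_idx = np.full(n, -1, dtype=np.int64)
        self.dam_idx = np.full(n, -1, dtype=np.int64)
        for i, r in enumerate(records):
            if r.sire is not None:
                j = self.index[r.sire]
                if j >= i:
                    raise PedigreeError(f"record {r.id!r} precedes its sire {r.sire!r}")
                self.sire_idx[i] = j
            if r.dam is not None:
                j = self.index[r.dam]
                if j >= i:
                    raise PedigreeError(f"record {r.id!r} precedes its dam {r.dam!r}")
                self.dam_idx[i] = j

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, id_: str) -> PedigreeRecord:
        return self.records[self.index[id_]]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def founders(self) -> list[PedigreeRecord]:
        return [r for r in self.records if r.is_founder]

    def ancestor_closure(self, subset: list[str]) -> "Pedigree":
        """Prune to ``subset`` and all their ancestors, preserving order."""
        keep = np.zeros(len(self), dtype=bool)
        for id_ in subset:
            keep[self.index[id_]] = True
        for i in range(len(self) - 1, -1, -1):
            if keep[i]:
                if self.sire_idx[i] >= 0:
                    keep[self.sire_idx[i]] = True
                if self.dam_idx[i] >= 0:
                    keep[self.dam_idx[i]] = True
        return Pedigree([r for i, r in enumerate(self.records) if keep[i]])


@dataclass
class OriginAnnotation:
    """Founder origin flags and per-individual migrant contributions.

    ``mc[i]`` is the expected fraction of migrant-founder alleles in ``i``;
    ``native_fraction[i] = 1 - mc[i]``.
    """

    is_migrant_founder: dict[str, bool] = field(default_factory=dict)
    mc: dict[str, float] = field(default_factory=dict)

    @property
    def native_fraction(self) -> dict[str, float]:
        return {k: 1.0 - v for k, v in self.mc.items()}


@dataclass
class CandidateSet:
    males: list[str]
    females: list[str]
    ebv: dict[str, float]
    mc: dict[str, float]
    ebv_normalized: dict[str, float] = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return self.males + self.females

    def sex_of(self, id_: str) -> str:
        return MALE if id_ in set(self.males) else FEMALE


def _clean(value: str | None, sentinels) -> str | None:
    if value is None:
        return None
    value = value.strip()
    return None if value in sentinels else value


DEFAULT_COLUMNS = {
    "id": "id", "sire": "sire", "dam": "dam", "sex": "sex",
    "born": "born", "breed": "breed", "ebv": "ebv",
}


def build_pedigree(records: list[PedigreeRecord]) -> Pedigree:
    """Validate and topologically sort raw records; insert phantom founders.

    Raises :class:`PedigreeError` on duplicate ids, cycles, or an id used as
    both sire and dam.
    """
    by_id: dict[str, PedigreeRecord] = {}
    for r in records:
        if not r.id:
            raise PedigreeError("empty individual id")
        if r.id in by_id:
            raise PedigreeError(f"duplicate id: {r.id!r}")
        by_id[r.id] = r

    used_as_sire = {r.sire for r in records if r.sire is not None}
    used_as_dam = {r.dam for r in records if r.dam is not None}
    conflict = used_as_sire & used_as_dam
    if conflict:
        raise PedigreeError(f"id used as both sire and dam: {sorted(conflict)[0]!r}")

    # infer sex from parentage role; check against declared sex
    full: list[PedigreeRecord] = []
    phantom_n = 0
    for r in records:
        sex = r.sex
        if r.id in used_as_sire:
            if sex == FEMALE:
                raise PedigreeError(f"female {r.id!r} used as sire")
            sex = MALE
        elif r.id in used_as_dam:
            if sex == MALE:
                raise PedigreeError(f"male {r.id!r} used as dam")
            sex = FEMALE
        full.append(replace(r, sex=sex))

    # parents referenced but absent from the file become phantom founders;
    # a non-founder with exactly one known parent gets a phantom for the
    # missing slot so every non-founder has two parents
    known = set(by_id)
    extra: list[PedigreeRecord] = []
    patched: list[PedigreeRecord] = []
    for r in full:
        sire, dam = r.sire, r.dam
        if sire is not None and sire not in known:
            extra.append(PedigreeRecord(sire, sex=MALE, phantom=True))
            known.add(sire)
        if dam is not None and dam not in known:
            extra.append(PedigreeRecord(dam, sex=FEMALE, phantom=True))
            known.add(dam)
        if (sire is None) != (dam is None):
            phantom_n += 1
            pid = f"__phantom{phantom_n}"
            psex = MALE if sire is None else FEMALE
            extra.append(PedigreeRecord(pid, sex=psex, birth_year=r.birth_year,
                                        phantom=True))
            known.add(pid)
            if sire is None:
                sire = pid
            else:
                dam = pid
        patched.append(replace(r, sire=sire, dam=dam))

    allrec = {r.id: r for r in extra}
    allrec.update({r.id: r for r in patched})

    g = nx.DiGraph()
    g.add_nodes_from(allrec)
    for r in allrec.values():
        if r.sire is not None:
            g.add_edge(r.sire, r.id)
        if r.dam is not None:
            g.add_edge(r.dam, r.id)
    try:
        # lexicographical tie-break makes the order canonical under row shuffles
        order = list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        raise PedigreeError(f"pedigree cycle involving {cycle[0][0]!r}") from None
    return Pedigree([allrec[i] for i in order])


def read_pedigree(path, columns: dict[str, str] | None = None,
                  sentinels=DEFAULT_SENTINELS, delimiter: str | None = None) -> Pedigree:
    """Read a delimited pedigree table and return a validated :class:`Pedigree`.

    ``columns`` maps the logical names {id, sire, dam, sex, born, breed, ebv}
    to the header names in the file; only id/sire/dam are required.  Missing
    values are encoded by any of ``sentinels``.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    with open(path, newline="", encoding="utf-8") as fh:
        if delimiter is None:
            sniff = fh.readline()
            delimiter = "\t" if sniff.count("\t") >= sniff.count(",") else ","
            fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None or cols["id"] not in reader.fieldnames:
            raise PedigreeError(f"missing id column {cols['id']!r}")
        records = []
        for row in reader:
            sex_raw = _clean(row.get(cols["sex"]), sentinels)
            sex = _SEX_CODES.get(sex_raw.lower()) if sex_raw else None
            born = _clean(row.get(cols["born"]), sentinels)
            ebv = _clean(row.get(cols["ebv"]), sentinels)
            records.append(PedigreeRecord(
                id=_clean(row.get(cols["id"]), sentinels) or "",
                sire=_clean(row.get(cols["sire"]), sentinels),
                dam=_clean(row.get(cols["dam"]), sentinels),
                sex=sex,
                birth_year=int(born) if born is not None else None,
                breed=_clean(row.get(cols["breed"]), sentinels),
                ebv=float(ebv) if ebv is not None else None,
            ))
    return build_pedigree(records)


def write_pedigree(ped: Pedigree, path, delimiter: str = ",") -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["id", "sire", "dam", "sex", "born", "breed", "ebv"])
        for r in ped:
            if r.phantom:
                continue
            w.writerow([
                r.id, r.sire or "0", r.dam or "0",
                {MALE: "M", FEMALE: "F"}.get(r.sex, "0"),
                r.birth_year if r.birth_year is not None else "0",
                r.breed or "0",
                repr(r.ebv) if r.ebv is not None else "0",
            ])


def classify_origin(ped: Pedigree, native_breeds: set[str],
                    cutoff_year: int = 1970,
                    generation_interval: int = 0,
                    unknown_policy: str = "error") -> OriginAnnotation:
    """Flag every founder as native or migrant.

    A founder is native iff its breed is one of ``native_breeds``, or its breed
    is unknown and it was born before ``cutoff_year``.  A phantom founder with
    no own birth year borrows its offspring's year minus ``generation_interval``
    (the year was stored at phantom creation; the interval shifts it back).
    ``unknown_policy`` controls founders with neither breed nor birth year:
    ``"error"`` (default) or ``"migrant"``.
    """
    if not native_breeds:
        raise ValueError("native_breeds must be non-empty")
    flags: dict[str, bool] = {}
    for r in ped.founders():
        if r.breed is not None:
            flags[r.id] = r.breed not in native_breeds
            continue
        year = r.birth_year
        if year is not None and r.phantom:
            year -= generation_interval
        if year is None:
            if unknown_policy == "migrant":
                flags[r.id] = True
                continue
            raise PedigreeError(
                f"founder {r.id!r} has neither breed nor birth year")
        flags[r.id] = year >= cutoff_year
    return OriginAnnotation(is_migrant_founder=flags)


def compute_mc(ped: Pedigree, origin: OriginAnnotation) -> OriginAnnotation:
    """Fill migrant contributions for every individual.

    Founders get MC 0 (native) or 1 (migrant); any other individual gets the
    parental average, so MC is the expected proportion of migrant alleles.
    """
    n = len(ped)
    mc = np.empty(n)
    for i, r in enumerate(ped):
        if r.is_founder:
            mc[i] = 1.0 if origin.is_migrant_founder[r.id] else 0.0
        else:
            mc[i] = 0.5 * (mc[ped.sire_idx[i]] + mc[ped.dam_idx[i]])
    return OriginAnnotation(
        is_migrant_founder=dict(origin.is_migrant_founder),
        mc={r.id: float(mc[i]) for i, r in enumerate(ped)},
    )


def select_candidates(ped: Pedigree, native_breeds: set[str],
                      progeny_window: tuple[int, int],
                      n_dams: int, seed: int,
                      origin: OriginAnnotation | None = None,
                      dam_birth_window: tuple[int, int] | None = None) -> CandidateSet:
    """Pick male and female selection candidates.

    Males: herdbook-purebred sires with at least one progeny born inside
    ``progeny_window`` (inclusive).  Females: ``n_dams`` herdbook-purebred
    females sampled without replacement with ``seed``.  Purebred status comes
    from the breed code, not from MC.
    """
    lo, hi = progeny_window
    if lo > hi:
        raise ValueError("empty progeny window")
    purebred = {r.id for r in ped if not r.phantom and r.breed in native_breeds}
    sires_in_window: set[str] = set()
    for r in ped:
        if r.sire is not None and r.birth_year is not None and lo <= r.birth_year <= hi:
            sires_in_window.add(r.sire)
    males = sorted(s for s in sires_in_window if s in purebred)
    if not males:
        raise ValueError("no eligible male candidates in the progeny window")

    male_set = set(males)
    females = [r.id for r in ped
               if r.sex == FEMALE and r.id in purebred and r.id not in male_set]
    if dam_birth_window is not None:
        flo, fhi = dam_birth_window
        females = [f for f in females
                   if ped[f].birth_year is not None and flo <= ped[f].birth_year <= fhi]
    if n_dams > len(females):
        raise ValueError(f"n_dams={n_dams} exceeds {len(females)} eligible females")
    rng = np.random.default_rng(seed)
    females_sorted = sorted(females)
    picked = sorted(rng.choice(len(females_sorted), size=n_dams, replace=False))
    females = [females_sorted[i] for i in picked]

    ebv = {i: ped[i].ebv for i in males + females}
    if origin is not None and origin.mc:
        mc = {i: origin.mc[i] for i in males + females}
    else:
        mc = {}
    return CandidateSet(males=males, females=females, ebv=ebv, mc=mc)


def normalize_ebv(cands: CandidateSet, ddof: int = 0) -> CandidateSet:
    """Normalize EBVs to mean 0 and standard deviation 1 across all candidates.

    Males and females are pooled, as in routine cross-breed comparison.  The
    population-SD convention (``ddof=0``) is the default.
    """
    ids = cands.ids
    vals = np.array([cands.ebv[i] for i in ids], dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least two candidates to normalize EBVs")
    if np.any(np.isnan(vals)):
        raise ValueError("missing EBV among selection candidates")
    sd = vals.std(ddof=ddof)
    if sd == 0:
        raise ValueError("all EBVs identical; standard deviation undefined")
    z = (vals - vals.mean()) / sd
    return CandidateSet(
        males=list(cands.males), females=list(cands.females),
        ebv=dict(cands.ebv), mc=dict(cands.mc),
        ebv_normalized={i: float(v) for i, v in zip(ids, z)},
    )
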