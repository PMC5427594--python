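import numpy as np
import pytest

from nativeocs import (compute_kinship_set, mean_candidate_kinship,
                       normalize_ebv, select_candidates, run_scenario_suite,
                       ub_fA_from_deltaF, deltaF_from_Ne)
from nativeocs.pedigree import (FEMALE, MALE, CandidateSet, PedigreeRecord,
                                build_pedigree, compute_mc, OriginAnnotation)
from nativeocs.synthped import (NATIVE_BREED, MIGRANT_BREED, SynthConfig,
                                fixture_suite, generate)

TINY_NAMES = ("parent_offspring", "full_sibs", "migrant_native_f1", "mixed_3gen")


@pytest.fixture(scope="session")
def fixtures():
    return fixture_suite()


@pytest.fixture(scope="session")
def population():
    """Default synthetic herdbook population: 200 sires x 1000 dams + kinships."""
    ped, origin = generate(SynthConfig())
    cands = normalize_ebv(select_candidates(
        ped, {NATIVE_BREED}, (2005, 2006), 1000, seed=7, origin=origin,
        dam_birth_window=(1995, 1995)))
    kin = compute_kinship_set(ped, origin, cands.males + cands.females)
    ub_fA = ub_fA_from_deltaF(mean_candidate_kinship(kin.fA), deltaF_from_Ne(50))
    return {"ped": ped, "origin": origin, "cands": cands, "kin": kin,
            "ub_fA": ub_fA}


SUITE_NAMES = ["maxEBV.A.MC", "maxEBV.A.D.MC", "minfB.A.MC", "minMC.A.EBV"]


@pytest.fixture(scope="session")
def scenario_results(population):
    """REF, TS, the five single-constraint scenarios and four bounded ones."""
    return run_scenario_suite(
        population["kin"], population["cands"], SUITE_NAMES,
        ub_fA=population["ub_fA"], lam=0.3, Ne_target=50.0, n_dams=1000, seed=1)


def toy_candidates(n_males=3, migrant_sire=True):
    """Tiny half-sib family: 3 candidate sires, 3 candidate dams, mixed origin."""
    N, M = NATIVE_BREED, MIGRANT_BREED
    recs = [
        PedigreeRecord("S1", sex=MALE, birth_year=1950, breed=N),
        PedigreeRecord("S2", sex=MALE, birth_year=1975,
                       breed=(M if migrant_sire else N)),
        PedigreeRecord("D1", sex=FEMALE, birth_year=1950, breed=N),
        PedigreeRecord("D2", sex=FEMALE, birth_year=1950, breed=N),
        PedigreeRecord("D3", sex=FEMALE, birth_year=1950, breed=N),
        PedigreeRecord("M1", "S1", "D1", MALE, 1985, N),
        PedigreeRecord("M2", "S1", "D2", MALE, 1985, N),
        PedigreeRecord("M3", "S2", "D3", MALE, 1985, N),
    ]
    ped = build_pedigree(recs)
    flags = {"S1": False, "S2": migrant_sire, "D1": False, "D2": False,
             "D3": False}
    origin = compute_mc(ped, OriginAnnotation(is_migrant_founder=flags))
    males = ["M1", "M2", "M3"][:n_males]
    females = ["D1", "D2", "D3"]
    ebv = {"M1": 1.0, "M2": 0.0, "M3": 2.0, "D1": -1.0, "D2": 0.5, "D3": -0.5}
    cands = CandidateSet(males=males, females=females,
                         ebv={i: ebv[i] for i in males + females},
                         mc={i: origin.mc[i] for i in males + females})
    cands = normalize_ebv(cands)
    kin = compute_kinship_set(ped, origin, males + females)
    return ped, origin, cands, kin


@pytest.fixture(scope="session")
def toy3():
    return toy_candidates()


def simplex_grid_search(kin, cands, objective, bounds, resolution=1e-3):
    """Dense-grid oracle over 3 male contributions summing to 0.5.

    Returns (best objective value, best c_male).  Independent of the solver
    path: evaluates raw quadratic/linear forms on every feasible grid point.
    """
    ids = cands.males + cands.females
    n_f = len(cands.females)
    steps = int(round(0.5 / resolution))
    pts = []
    for i in range(steps + 1):
        for j in range(steps + 1 - i):
            pts.append((i, j, steps - i - j))
    c_m = np.array(pts, dtype=float) * resolution
    cf = np.full((len(c_m), n_f), 0.5 / n_f)
    C = np.hstack([c_m, cf])

    def quad(M):
        return np.einsum("ni,ij,nj->n", C, M, C)

    vals = {
        "fA": quad(kin.fA.values), "fB": quad(kin.fB.values),
        "fC": quad(kin.fC.values), "fN": quad(kin.fN.values),
        "Knat": quad(kin.Knat.values),
        "MC": C @ np.array([cands.mc[i] for i in ids]),
        "EBV": C @ np.array([cands.ebv_normalized[i] for i in ids]),
    }
    vals["fD"] = vals["Knat"] / vals["fN"]

    feas = np.ones(len(C), dtype=bool)
    for key, level in bounds.active().items():
        if key == "lb_EBV":
            feas &= vals["EBV"] >= level - 1e-9
        else:
            feas &= vals[key.replace("ub_", "")] <= level + 1e-9
    if not feas.any():
        return None, None
    obj_key = {"min_fA": "fA", "min_fB": "fB", "min_fC": "fC", "min_fD": "fD",
               "min_MC": "MC", "max_EBV": "EBV"}[objective]
    obj = vals[obj_key][feas]
    sign = -1.0 if objective == "max_EBV" else 1.0
    k = np.argmin(sign * obj)
    return float(obj[k]), c_m[feas][k]
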