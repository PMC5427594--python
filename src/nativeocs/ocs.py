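"""Constrained optimization of genetic contributions.

Scenarios minimize an origin-aware kinship (fB, fC, fD), minimize migrant
contribution, or maximize genetic gain, subject to an upper bound on the
classical kinship (controlling the rate of inbreeding) and optional bounds on
the other criteria.  Structural constraints on the contribution vector c:

    (a) c_i >= 0
    (b) the contributions of each sex sum to 0.5
    (c) all dams contribute equally (so only sire contributions are free)
        and every sire contribution is at most 0.5

Scenario names follow the ``prefix.suffix`` grammar, e.g. ``maxEBV.A.D.MC``
maximizes mean EBV under bounds on fA, fD and MC.  Bound levels other than
ub.fA are set by λ-interpolation between the equal-contribution reference
(REF) and the single-constraint optimum of the bounded criterion.

Convex problems (quadratic objectives/constraints with PSD matrices, linear
MC/EBV terms) are solved by sequential quadratic programming; the kinship at
native alleles fD — a ratio of quadratic forms, hence non-convex — is
minimized by Dinkelbach's fractional-programming iteration with a
convex–concave linearization of the concave part and multiple starts, and its
solutions are reported as local optima.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .kinship import KinshipMatrix, KinshipSet
from .pedigree import CandidateSet

__all__ = [
    "BoundSet", "ScenarioSpec", "ScenarioResult", "MeanKinshipReport",
    "deltaF_from_Ne", "ub_fA_from_deltaF", "ts_sire_count", "derive_bounds",
    "parse_scenario_name", "ref_scenario", "ts_scenario", "build_problem",
    "solve_scenario", "minimize_fD", "count_selected", "run_scenario_suite",
    "NONZERO_THRESHOLD", "OBJECTIVES",
]

#: a sire contribution below this is treated as zero when counting selected sires
NONZERO_THRESHOLD = 0.00025

OBJECTIVES = ("min_fA", "min_fB", "min_fC", "min_fD", "min_MC", "max_EBV")

_PREFIX = {"minfA": "min_fA", "minfB": "min_fB", "minfC": "min_fC",
           "minfD": "min_fD", "minMC": "min_MC", "maxEBV": "max_EBV"}
_SUFFIX = {"A": "ub_fA", "B": "ub_fB", "C": "ub_fC", "D": "ub_fD",
           "MC": "ub_MC", "EBV": "lb_EBV"}


# ---------------------------------------------------------------- arithmetic

def deltaF_from_Ne(Ne: float) -> float:
    """Per-generation rate of inbreeding, ΔF = 1/(2 Ne)."""
    if Ne <= 0:
        raise ValueError("Ne must be positive")
    return 1.0 / (2.0 * Ne)


def ub_fA_from_deltaF(mean_fA: float, deltaF: float) -> float:
    """Kinship ceiling f̄A + (1 - f̄A) ΔF keeping inbreeding at rate ΔF."""
    if not 0 <= mean_fA < 1:
        raise ValueError("mean kinship must be in [0, 1)")
    return mean_fA + (1.0 - mean_fA) * deltaF


def ts_sire_count(Ne_target: float, n_dams: int) -> int:
    """Smallest sire number reaching Ne_target, from 1/Ne = 1/(4 Ns) + 1/(4 Nd)."""
    rest = 1.0 / Ne_target - 1.0 / (4.0 * n_dams)
    if rest <= 0:
        raise ValueError("dam number too small for target Ne")
    return math.ceil(1.0 / (4.0 * rest))


# ------------------------------------------------------------------- types

@dataclass
class BoundSet:
    ub_fA: float | None = None
    ub_fB: float | None = None
    ub_fC: float | None = None
    ub_fD: float | None = None
    ub_MC: float | None = None
    lb_EBV: float | None = None

    def active(self) -> dict[str, float]:
        return {k: v for k, v in self.__dict__.items() if v is not None}


@dataclass
class ScenarioSpec:
    objective: str
    bounds: BoundSet = field(default_factory=BoundSet)
    name: str = ""
    optimize_both_sexes: bool = False

    def __post_init__(self):
        if self.objective not in OBJECTIVES:
            raise ValueError(f"unknown objective {self.objective!r}")


@dataclass
class MeanKinshipReport:
    fA_bar: float
    fB_bar: float
    fC_bar: float
    fD_val: float
    mc_bar: float
    ebv_bar: float


@dataclass
class ScenarioResult:
    name: str
    c: dict[str, float]
    achieved: MeanKinshipReport
    selected_fraction: float
    sd_male_contributions: float
    solver_status: str
    bounds: BoundSet = field(default_factory=BoundSet)
    violated: list[str] = field(default_factory=list)


def parse_scenario_name(name: str) -> ScenarioSpec:
    """Parse ``prefix.suffix`` names like ``minfB.A.MC`` into a spec skeleton.

    The bound letters only mark which constraints are active; their numeric
    levels are filled in later (ub.fA from ΔF, the rest by λ-interpolation).
    """
    parts = name.split(".")
    if parts[0] not in _PREFIX:
        raise ValueError(f"unknown scenario prefix {parts[0]!r}")
    bounds = BoundSet()
    for letter in parts[1:]:
        if letter not in _SUFFIX:
            raise ValueError(f"unknown constraint letter {letter!r} in {name!r}")
        setattr(bounds, _SUFFIX[letter], math.nan)  # placeholder: active, level TBD
    return ScenarioSpec(objective=_PREFIX[parts[0]], bounds=bounds, name=name)


def derive_bounds(lam: float, optima: dict[str, float],
                  ref_values: dict[str, float],
                  active: list[str]) -> BoundSet:
    """λ-interpolated bound levels: λ·(single-constraint optimum) + (1-λ)·REF.

    ``optima`` and ``ref_values`` are keyed by bound name (``ub_fB`` ...
    ``lb_EBV``); ``active`` lists the bounds to fill.  ``ub_fA`` is not
    interpolated (it comes from ΔF) and must be supplied separately.
    """
    if not 0 <= lam <= 1:
        raise ValueError("lambda must be in [0, 1]")
    bs = BoundSet()
    for key in active:
        if key == "ub_fA":
            continue
        if key not in optima or key not in ref_values:
            raise ValueError(f"missing single-constraint optimum for {key}")
        setattr(bs, key, lam * optima[key] + (1.0 - lam) * ref_values[key])
    return bs


# ------------------------------------------------------- problem formulation

class _Quad:
    """c'Mc restated in the free variables x, with c = P x + t."""

    def __init__(self, M: np.ndarray, P: np.ndarray, t: np.ndarray):
        self.Q = P.T @ M @ P
        self.Q = 0.5 * (self.Q + self.Q.T)
        self.b = 2.0 * (P.T @ (M @ t))
        self.a0 = float(t @ M @ t)

    def value(self, x: np.ndarray) -> float:
        return float(x @ self.Q @ x + self.b @ x + self.a0)

    def grad(self, x: np.ndarray) -> np.ndarray:
        return 2.0 * (self.Q @ x) + self.b


class _Lin:
    def __init__(self, v: np.ndarray, P: np.ndarray, t: np.ndarray):
        self.w = P.T @ v
        self.a0 = float(v @ t)

    def value(self, x: np.ndarray) -> float:
        return float(self.w @ x + self.a0)

    def grad(self, x: np.ndarray) -> np.ndarray:
        return self.w


@dataclass
class Problem:
    """Scenario restated in the free contribution variables."""

    spec: ScenarioSpec
    ids: list[str]            # candidate order: males then females
    n_males: int
    P: np.ndarray
    t: np.ndarray
    quads: dict[str, _Quad]   # fA, fB, fC, fN, Knat
    lins: dict[str, _Lin]     # MC, EBV
    eq: list[tuple[np.ndarray, float]]        # a'x = rhs
    box: list[tuple[float, float]]
    ineq: list[tuple[str, object, float, int]]  # (label, form, level, sign)
    nonconvex_flags: list[str] = field(default_factory=list)

    @property
    def n_vars(self) -> int:
        return self.P.shape[1]

    def contributions(self, x: np.ndarray) -> np.ndarray:
        return self.P @ x + self.t


def _fd_value(quads: dict[str, _Quad], x: np.ndarray, eps: float = 1e-8) -> float:
    d = quads["fN"].value(x)
    if d <= eps:
        return math.nan
    return quads["Knat"].value(x) / d


def build_problem(spec: ScenarioSpec, kin: KinshipSet, cands: CandidateSet) -> Problem:
    """Expand every quadratic form into the free male variables.

    With fixed equal dam contributions, c = P x + t where x are the sire
    contributions; all constants are absorbed into the restated forms.  The fD
    bound is rewritten as the quadratic c'fB c + (1 - ub_fD) c'fN c <= 1,
    algebraically equivalent for contribution vectors summing to one; since
    fB and fN are PSD and ub_fD <= 1 the combination is PSD (an indefinite
    instance would be flagged non-convex and routed through the CCP path).
    """
    ids = cands.males + cands.females
    if kin.ids != ids:
        raise ValueError("kinship matrices must be indexed males-then-females")
    n_m, n_f = len(cands.males), len(cands.females)
    n = n_m + n_f
    if spec.optimize_both_sexes:
        P = np.eye(n)
        t = np.zeros(n)
        s_ind = np.concatenate([np.ones(n_m), np.zeros(n_f)])
        d_ind = 1.0 - s_ind
        eq = [(s_ind, 0.5), (d_ind, 0.5)]
    else:
        P = np.vstack([np.eye(n_m), np.zeros((n_f, n_m))])
        t = np.concatenate([np.zeros(n_m), np.full(n_f, 0.5 / n_f)])
        eq = [(np.ones(n_m), 0.5)]
    box = [(0.0, 0.5)] * P.shape[1]

    ebv = np.array([cands.ebv_normalized[i] for i in ids])
    mc = np.array([cands.mc[i] for i in ids])
    quads = {role: _Quad(getattr(kin, role).values, P, t)
             for role in ("fA", "fB", "fC", "fN", "Knat")}
    lins = {"MC": _Lin(mc, P, t), "EBV": _Lin(ebv, P, t)}

    ineq: list[tuple[str, object, float, int]] = []
    nonconvex: list[str] = []
    b = spec.bounds
    for label, form, level, sign in (
            ("ub_fA", quads["fA"], b.ub_fA, -1),
            ("ub_fB", quads["fB"], b.ub_fB, -1),
            ("ub_fC", quads["fC"], b.ub_fC, -1),
            ("ub_MC", lins["MC"], b.ub_MC, -1),
            ("lb_EBV", lins["EBV"], b.lb_EBV, +1)):
        if level is not None and not math.isnan(level):
            ineq.append((label, form, float(level), sign))
    if b.ub_fD is not None and not math.isnan(b.ub_fD):
        M = kin.fB.values + (1.0 - b.ub_fD) * kin.fN.values
        q = _Quad(M, P, t)
        if np.linalg.eigvalsh(q.Q).min() < -1e-8:
            nonconvex.append("ub_fD")
        ineq.append(("ub_fD", q, 1.0, -1))

    return Problem(spec=spec, ids=ids, n_males=n_m, P=P, t=t, quads=quads,
                   lins=lins, eq=eq, box=box, ineq=ineq,
                   nonconvex_flags=nonconvex)


# ------------------------------------------------------------------ solving

def _slsqp_constraints(prob: Problem):
    cons = []
    for a, rhs in prob.eq:
        cons.append({"type": "eq",
                     "fun": (lambda x, a=a, r=rhs: float(a @ x) - r),
                     "jac": (lambda x, a=a: a)})
    for label, form, level, sign in prob.ineq:
        if sign < 0:  # form(x) <= level
            cons.append({"type": "ineq",
                         "fun": (lambda x, f=form, l=level: l - f.value(x)),
                         "jac": (lambda x, f=form: -f.grad(x))})
        else:         # form(x) >= level
            cons.append({"type": "ineq",
                         "fun": (lambda x, f=form, l=level: f.value(x) - l),
                         "jac": (lambda x, f=form: f.grad(x))})
    return cons


def _violations(prob: Problem, x: np.ndarray, tol_eq: float, tol_ineq: float):
    out = []
    for a, rhs in prob.eq:
        if abs(float(a @ x) - rhs) > tol_eq:
            out.append("sex_sum")
    if x.min() < -tol_ineq or x.max() > 0.5 + tol_ineq:
        out.append("box")
    for label, form, level, sign in prob.ineq:
        v = form.value(x)
        if sign < 0 and v > level + tol_ineq:
            out.append(label)
        elif sign > 0 and v < level - tol_ineq:
            out.append(label)
    return out


def _starts(prob: Problem, n_random: int = 3, seed: int = 0) -> list[np.ndarray]:
    n = prob.n_vars
    if prob.spec.optimize_both_sexes:
        n_m = prob.n_males
        n_f = len(prob.ids) - n_m
        xs = [np.concatenate([np.full(n_m, 0.5 / n_m), np.full(n_f, 0.5 / n_f)])]
    else:
        xs = [np.full(n, 0.5 / n)]
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        w = rng.dirichlet(np.ones(n))
        if prob.spec.optimize_both_sexes:
            n_m = prob.n_males
            w = w.copy()
            w[:n_m] *= 0.5 / max(w[:n_m].sum(), 1e-12)
            w[n_m:] *= 0.5 / max(w[n_m:].sum(), 1e-12)
            xs.append(np.minimum(w, 0.5))
        else:
            xs.append(np.minimum(0.5 * w, 0.5))
    return xs


def _solve_smooth(prob: Problem, objective, x0s: list[np.ndarray],
                  tol: float, maxiter: int = 400):
    """SLSQP multi-start with a trust-constr fallback; returns best feasible x."""
    fun, jac = objective
    cons = _slsqp_constraints(prob)
    best = None
    for x0 in x0s:
        res = minimize(fun, x0, jac=jac, method="SLSQP", bounds=prob.box,
                       constraints=cons,
                       options={"maxiter": maxiter, "ftol": 1e-12})
        x = np.clip(res.x, 0.0, 0.5)
        if not _violations(prob, x, 1e-6, 10 * tol):
            if best is None or fun(x) < fun(best) - 0.0:
                best = x
    if best is None:
        from scipy.optimize import NonlinearConstraint
        nlcs = []
        for a, rhs in prob.eq:
            nlcs.append(NonlinearConstraint(
                lambda x, a=a: float(a @ x), rhs, rhs, jac=lambda x, a=a: a[None, :]))
        for label, form, level, sign in prob.ineq:
            lo, hi = (-np.inf, level) if sign < 0 else (level, np.inf)
            nlcs.append(NonlinearConstraint(
                lambda x, f=form: f.value(x), lo, hi,
                jac=lambda x, f=form: f.grad(x)[None, :]))
        res = minimize(fun, x0s[0], jac=jac, method="trust-constr",
                       bounds=prob.box, constraints=nlcs,
                       options={"maxiter": 2000, "gtol": 1e-10, "xtol": 1e-12})
        x = np.clip(res.x, 0.0, 0.5)
        if not _violations(prob, x, 1e-6, 10 * tol):
            best = x
    return best


def _report(kin: KinshipSet, cands: CandidateSet, c: np.ndarray) -> MeanKinshipReport:
    ids = cands.males + cands.females
    ebv = np.array([cands.ebv_normalized[i] for i in ids])
    mc = np.array([cands.mc[i] for i in ids])
    fn = float(c @ kin.fN.values @ c)
    fb = float(c @ kin.fB.values @ c)
    fd = math.nan if fn <= 1e-8 else 1.0 - (1.0 - fb) / fn
    return MeanKinshipReport(
        fA_bar=float(c @ kin.fA.values @ c), fB_bar=fb,
        fC_bar=float(c @ kin.fC.values @ c), fD_val=fd,
        mc_bar=float(mc @ c), ebv_bar=float(ebv @ c))


def count_selected(c_males: np.ndarray,
                   threshold: float = NONZERO_THRESHOLD) -> tuple[float, float]:
    """Fraction of sires with non-negligible contributions, and the SD of all
    male contributions (zeros included, population convention)."""
    c_males = np.asarray(c_males, dtype=float)
    frac = float(np.mean(c_males >= threshold))
    return frac, float(c_males.std(ddof=0))


def _result(name: str, prob: Problem, kin: KinshipSet, cands: CandidateSet,
            x: np.ndarray, status: str, bounds: BoundSet) -> ScenarioResult:
    c = prob.contributions(x)
    frac, sd = count_selected(c[:prob.n_males])
    return ScenarioResult(
        name=name, c=dict(zip(prob.ids, map(float, c))),
        achieved=_report(kin, cands, c), selected_fraction=frac,
        sd_male_contributions=sd, solver_status=status, bounds=bounds)


def _infeasible(name: str, prob: Problem, bounds: BoundSet,
                tol: float) -> ScenarioResult:
    # certificate: bounds still violated at the least-infeasible point
    def total_viol(x):
        v = 0.0
        g = np.zeros_like(x)
        for label, form, level, sign in prob.ineq:
            gap = (form.value(x) - level) * (1 if sign < 0 else -1)
            if gap > 0:
                v += gap * gap
                g += 2 * gap * form.grad(x) * (1 if sign < 0 else -1)
        return v, g
    cons = [{"type": "eq", "fun": (lambda x, a=a, r=r: float(a @ x) - r),
             "jac": (lambda x, a=a: a)} for a, r in prob.eq]
    res = minimize(lambda x: total_viol(x), np.full(prob.n_vars, 0.5 / prob.n_vars),
                   jac=True, method="SLSQP", bounds=prob.box, constraints=cons,
                   options={"maxiter": 300, "ftol": 1e-14})
    x = np.clip(res.x, 0.0, 0.5)
    violated = _violations(prob, x, 1e-6, 10 * tol) or ["unknown"]
    return ScenarioResult(
        name=name, c={}, achieved=MeanKinshipReport(*([math.nan] * 6)),
        selected_fraction=math.nan, sd_male_contributions=math.nan,
        solver_status="infeasible", bounds=bounds,
        violated=[v for v in violated if v not in ("sex_sum", "box")])


def ref_scenario(kin: KinshipSet, cands: CandidateSet) -> ScenarioResult:
    """Equal contributions for every candidate of each sex."""
    n_m, n_f = len(cands.males), len(cands.females)
    if n_m == 0 or n_f == 0:
        raise ValueError("both sexes need candidates")
    c = np.concatenate([np.full(n_m, 0.5 / n_m), np.full(n_f, 0.5 / n_f)])
    frac, sd = count_selected(c[:n_m])
    return ScenarioResult(
        name="REF", c=dict(zip(cands.males + cands.females, map(float, c))),
        achieved=_report(kin, cands, c), selected_fraction=frac,
        sd_male_contributions=sd, solver_status="optimal")


def ts_scenario(kin: KinshipSet, cands: CandidateSet, Ne_target: float = 50.0,
                n_dams: int | None = None) -> ScenarioResult:
    """Truncation selection: the top sires by EBV, all parents contributing equally.

    The sire number is the smallest reaching the target effective size when
    mated to the dam candidates.  EBV ties at the cutoff break by ascending id.
    """
    n_m, n_f = len(cands.males), len(cands.females)
    n_sires = ts_sire_count(Ne_target, n_dams if n_dams is not None else n_f)
    order = sorted(cands.males,
                   key=lambda i: (-cands.ebv_normalized[i], i))[:n_sires]
    chosen = set(order)
    c_m = np.array([0.5 / n_sires if i in chosen else 0.0 for i in cands.males])
    c = np.concatenate([c_m, np.full(n_f, 0.5 / n_f)])
    frac, sd = count_selected(c_m)
    return ScenarioResult(
        name="TS", c=dict(zip(cands.males + cands.females, map(float, c))),
        achieved=_report(kin, cands, c), selected_fraction=frac,
        sd_male_contributions=sd, solver_status="optimal")


def solve_scenario(spec: ScenarioSpec, kin: KinshipSet, cands: CandidateSet,
                   tol: float = 1e-6, seed: int = 0) -> ScenarioResult:
    """Solve one scenario; dispatches the fD objective to :func:`minimize_fD`."""
    if spec.objective == "min_fD":
        return minimize_fD(kin, cands, spec.bounds, tol=tol, seed=seed,
                           spec=spec)
    prob = build_problem(spec, kin, cands)
    sign = -1.0 if spec.objective == "max_EBV" else 1.0
    if spec.objective in ("min_fA", "min_fB", "min_fC"):
        form = prob.quads[spec.objective.split("_")[1]]
    elif spec.objective == "min_MC":
        form = prob.lins["MC"]
    else:
        form = prob.lins["EBV"]
    objective = ((lambda x: sign * form.value(x)),
                 (lambda x: sign * form.grad(x)))
    x = _solve_smooth(prob, objective, _starts(prob, seed=seed), tol)
    if x is None:
        return _infeasible(spec.name or spec.objective, prob, spec.bounds, tol)
    return _result(spec.name or spec.objective, prob, kin, cands, x,
                   "optimal", spec.bounds)


def minimize_fD(kin: KinshipSet, cands: CandidateSet, bounds: BoundSet,
                tol: float = 1e-6, seed: int = 0, n_starts: int = 5,
                max_outer: int = 60,
                spec: ScenarioSpec | None = None) -> ScenarioResult:
    """Minimize fD(c) = c'Knat c / c'fN c by Dinkelbach iteration.

    Each outer step solves min c'Knat c - q * [linearized c'fN c] under the
    scenario constraints (the concave -q c'fN c term is linearized around the
    current iterate, making the subproblem convex), then updates
    q = fD(current).  Multi-start over the uniform solution, the minimum-fA
    solution and seeded random points; the best fixed point is reported with
    status ``local``.
    """
    if spec is None:
        spec = ScenarioSpec(objective="min_fD", bounds=bounds, name="minfD")
    prob = build_problem(spec, kin, cands)
    N, D = prob.quads["Knat"], prob.quads["fN"]
    cons = _slsqp_constraints(prob)

    starts = _starts(prob, n_random=max(0, n_starts - 2), seed=seed)
    fa_res = solve_scenario(replace(spec, objective="min_fA", name="minfA.start"),
                            kin, cands, tol=tol, seed=seed)
    if fa_res.solver_status == "infeasible":
        return _infeasible(spec.name or "minfD", prob, bounds, tol)
    ids = cands.males + cands.females
    if prob.spec.optimize_both_sexes:
        starts.insert(1, np.array([fa_res.c[i] for i in ids]))
    else:
        starts.insert(1, np.array([fa_res.c[i] for i in cands.males]))

    best_x, best_q = None, np.inf
    for x0 in starts:
        x = x0
        # restore feasibility of the start via one constrained solve
        res = minimize(lambda z: N.value(z), x, jac=N.grad, method="SLSQP",
                       bounds=prob.box, constraints=cons,
                       options={"maxiter": 200, "ftol": 1e-12})
        x = np.clip(res.x, 0.0, 0.5)
        if _violations(prob, x, 1e-6, 10 * tol):
            continue
        d = D.value(x)
        if d <= 1e-8:
            continue
        q = N.value(x) / d
        for _ in range(max_outer):
            g = D.grad(x)
            fun = (lambda z, q=q, g=g: N.value(z) - q * float(g @ z))
            jac = (lambda z, q=q, g=g: N.grad(z) - q * g)
            res = minimize(fun, x, jac=jac, method="SLSQP", bounds=prob.box,
                           constraints=cons,
                           options={"maxiter": 300, "ftol": 1e-14})
            x_new = np.clip(res.x, 0.0, 0.5)
            if _violations(prob, x_new, 1e-6, 10 * tol):
                break
            d = D.value(x_new)
            if d <= 1e-8:
                break
            q_new = N.value(x_new) / d
            if abs(q_new - q) < tol and np.linalg.norm(x_new - x) < 1e2 * tol:
                x, q = x_new, q_new
                break
            x, q = x_new, q_new
        if not _violations(prob, x, 1e-6, 10 * tol) and q < best_q:
            best_x, best_q = x, q
    if best_x is None:
        return _infeasible(spec.name or "minfD", prob, bounds, tol)
    return _result(spec.name or "minfD", prob, kin, cands, best_x, "local",
                   spec.bounds)


# ---------------------------------------------------------------- pipelines

_CRITERION_OF = {"ub_fB": ("min_fB", "fB_bar"), "ub_fC": ("min_fC", "fC_bar"),
                 "ub_fD": ("min_fD", "fD_val"), "ub_MC": ("min_MC", "mc_bar"),
                 "lb_EBV": ("max_EBV", "ebv_bar")}


def run_scenario_suite(kin: KinshipSet, cands: CandidateSet, names: list[str],
                       ub_fA: float, lam: float = 0.3,
                       Ne_target: float = 50.0, n_dams: int | None = None,
                       tol: float = 1e-6, seed: int = 0,
                       ) -> dict[str, ScenarioResult]:
    """REF, TS, the five single-constraint scenarios, and the requested ones.

    Single-constraint optima (objective under the fA bound only) and REF
    achievements feed the λ-interpolation that sets every other bound level.
    """
    results: dict[str, ScenarioResult] = {}
    results["REF"] = ref_scenario(kin, cands)
    results["TS"] = ts_scenario(kin, cands, Ne_target, n_dams)

    ref_vals = {key: getattr(results["REF"].achieved, attr)
                for key, (_, attr) in _CRITERION_OF.items()}
    optima: dict[str, float] = {}
    for key, (obj, attr) in _CRITERION_OF.items():
        name = {"min_fB": "minfB.A", "min_fC": "minfC.A", "min_fD": "minfD.A",
                "min_MC": "minMC.A", "max_EBV": "maxEBV.A"}[obj]
        spec = ScenarioSpec(objective=obj, bounds=BoundSet(ub_fA=ub_fA),
                            name=name)
        res = solve_scenario(spec, kin, cands, tol=tol, seed=seed)
        results[name] = res
        optima[key] = getattr(res.achieved, attr)

    for name in names:
        if name in results:
            continue
        spec = parse_scenario_name(name)
        active = [k for k, v in spec.bounds.__dict__.items()
                  if v is not None and math.isnan(v)]
        levels = derive_bounds(lam, optima, ref_vals, active)
        if "ub_fA" in active:
            levels.ub_fA = ub_fA
        spec.bounds = levels
        results[name] = solve_scenario(spec, kin, cands, tol=tol, seed=seed)
    return results
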