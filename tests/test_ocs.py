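import math

import numpy as np
import pytest

from nativeocs.ocs import (BoundSet, ScenarioSpec, count_selected,
                           deltaF_from_Ne, derive_bounds, minimize_fD,
                           parse_scenario_name, ref_scenario, solve_scenario,
                           ts_scenario, ts_sire_count, ub_fA_from_deltaF)

from conftest import simplex_grid_search, toy_candidates


class TestThresholdArithmetic:
    def test_deltaF(self):
        assert deltaF_from_Ne(50) == 0.01
        assert deltaF_from_Ne(100) == 0.005
        assert deltaF_from_Ne(1e12) == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            deltaF_from_Ne(0)

    def test_ub_fA(self):
        assert ub_fA_from_deltaF(0.020, 0.01) == pytest.approx(0.0298)
        assert ub_fA_from_deltaF(0.025, 0.01) == pytest.approx(0.03475)
        assert ub_fA_from_deltaF(0.0, 0.0) == 0.0

    def test_ts_sire_count(self):
        assert ts_sire_count(50, 1000) == 13
        assert ts_sire_count(50, 10**9) == 13   # limit: ceil(12.5)
        assert ts_sire_count(50, 50) == 17
        with pytest.raises(ValueError, match="dam number too small"):
            ts_sire_count(50, 10)

    def test_derive_bounds_interpolation(self):
        optima = {"ub_fB": 0.1, "ub_MC": 0.3, "lb_EBV": 1.0}
        ref = {"ub_fB": 0.2, "ub_MC": 0.6, "lb_EBV": 0.0}
        lam0 = derive_bounds(0.0, optima, ref, ["ub_fB", "ub_MC", "lb_EBV"])
        assert (lam0.ub_fB, lam0.ub_MC, lam0.lb_EBV) == (0.2, 0.6, 0.0)
        lam1 = derive_bounds(1.0, optima, ref, ["ub_fB", "ub_MC", "lb_EBV"])
        assert (lam1.ub_fB, lam1.ub_MC, lam1.lb_EBV) == (0.1, 0.3, 1.0)
        mid = derive_bounds(0.3, optima, ref, ["ub_fB"])
        assert mid.ub_fB == pytest.approx(0.17)

    def test_derive_bounds_missing_optimum(self):
        with pytest.raises(ValueError, match="missing"):
            derive_bounds(0.5, {}, {}, ["ub_fB"])


class TestScenarioNames:
    def test_grammar(self):
        spec = parse_scenario_name("maxEBV.A.B.MC")
        assert spec.objective == "max_EBV"
        assert math.isnan(spec.bounds.ub_fA)
        assert math.isnan(spec.bounds.ub_fB)
        assert math.isnan(spec.bounds.ub_MC)
        assert spec.bounds.ub_fC is None and spec.bounds.lb_EBV is None

    @pytest.mark.parametrize("bad", ["maxGain.A", "minfB.Z", "minfB.A.XY"])
    def test_rejects_unknown_tokens(self, bad):
        with pytest.raises(ValueError):
            parse_scenario_name(bad)


class TestBaselines:
    def test_ref_equal_contributions(self, toy3):
        _, _, cands, kin = toy3
        res = ref_scenario(kin, cands)
        assert all(res.c[m] == pytest.approx(0.5 / 3) for m in cands.males)
        assert all(res.c[f] == pytest.approx(0.5 / 3) for f in cands.females)
        assert res.sd_male_contributions == pytest.approx(0.0)

    def test_ref_ebv_nonzero_when_sexes_differ(self, scenario_results):
        # normalized EBVs average 0 over all candidates, but the sexes differ
        # in mean EBV and REF weights them 0.5/0.5, not by head count
        assert (scenario_results["REF"].achieved.ebv_bar
                != pytest.approx(0.0, abs=1e-6))

    def test_ref_mean_kinships_match_double_sum(self, toy3):
        _, _, cands, kin = toy3
        res = ref_scenario(kin, cands)
        ids = cands.males + cands.females
        c = np.array([res.c[i] for i in ids])
        brute = sum(c[i] * c[j] * kin.fA.values[i, j]
                    for i in range(6) for j in range(6))
        assert res.achieved.fA_bar == pytest.approx(brute, abs=1e-12)

    def test_ts_top_sires_equal_contributions(self, population, scenario_results):
        cands = population["cands"]
        res = scenario_results["TS"]
        c_m = np.array([res.c[m] for m in cands.males])
        assert (c_m > 0).sum() == 13
        assert res.selected_fraction == pytest.approx(13 / 200)
        nz = c_m[c_m > 0]
        assert nz == pytest.approx(np.full(13, 0.5 / 13))

    def test_ts_single_sire_is_top_ebv(self, toy3):
        _, _, cands, kin = toy3
        res = ts_scenario(kin, cands, Ne_target=2.9, n_dams=1000)
        # Ne 2.9 with many dams needs ceil(1/(4*(1/2.9-0.00025))) = 1 sire;
        # highest-EBV male is M3
        nz = [m for m in cands.males if res.c[m] > 0]
        assert nz == ["M3"]

    def test_ts_tie_break_by_ascending_id(self, toy3):
        _, _, cands, kin = toy3
        from nativeocs.pedigree import CandidateSet, normalize_ebv
        tied = normalize_ebv(CandidateSet(
            males=list(cands.males), females=list(cands.females),
            ebv={"M1": 1.0, "M2": 1.0, "M3": 1.0,
                 "D1": 0.0, "D2": 2.0, "D3": 1.0},
            mc=dict(cands.mc)))
        res = ts_scenario(kin, tied, Ne_target=7.9, n_dams=10**6)  # 2 sires
        nz = [m for m in tied.males if res.c[m] > 0]
        assert nz == ["M1", "M2"]

    def test_ts_ebv_at_least_ref(self, scenario_results):
        assert (scenario_results["TS"].achieved.ebv_bar
                >= scenario_results["REF"].achieved.ebv_bar - 1e-9)


class TestToySolver:
    @pytest.mark.parametrize("objective", ["min_fA", "min_fB", "min_fC",
                                           "min_MC", "max_EBV"])
    def test_convex_objectives_match_grid_search(self, toy3, objective):
        _, _, cands, kin = toy3
        bounds = BoundSet(ub_fA=0.14)
        spec = ScenarioSpec(objective=objective, bounds=bounds, name="toy")
        res = solve_scenario(spec, kin, cands, seed=3)
        assert res.solver_status == "optimal"
        grid_obj, _ = simplex_grid_search(kin, cands, objective, bounds)
        attr = {"min_fA": "fA_bar", "min_fB": "fB_bar", "min_fC": "fC_bar",
                "min_MC": "mc_bar", "max_EBV": "ebv_bar"}[objective]
        assert getattr(res.achieved, attr) == pytest.approx(grid_obj, abs=2e-3)

    def test_min_fd_matches_grid_search(self, toy3):
        _, _, cands, kin = toy3
        bounds = BoundSet(ub_fA=0.14)
        res = minimize_fD(kin, cands, bounds, seed=3)
        assert res.solver_status == "local"
        grid_obj, _ = simplex_grid_search(kin, cands, "min_fD", bounds)
        assert res.achieved.fD_val == pytest.approx(grid_obj, abs=2e-3)

    def test_dinkelbach_fixed_point(self, toy3):
        """At the solution, c'Knat c - fD * c'fN c vanishes."""
        _, _, cands, kin = toy3
        res = minimize_fD(kin, cands, BoundSet(ub_fA=0.14), seed=3)
        ids = cands.males + cands.females
        c = np.array([res.c[i] for i in ids])
        num = float(c @ kin.Knat.values @ c)
        den = float(c @ kin.fN.values @ c)
        assert abs(num - res.achieved.fD_val * den) < 1e-6

    def test_max_ebv_unbounded_is_lp_corner(self, toy3):
        _, _, cands, kin = toy3
        spec = ScenarioSpec(objective="max_EBV", bounds=BoundSet(), name="corner")
        res = solve_scenario(spec, kin, cands, seed=0)
        # M3 has the highest EBV: all male mass lands on it
        assert res.c["M3"] == pytest.approx(0.5, abs=1e-6)
        assert res.c["M1"] == pytest.approx(0.0, abs=1e-6)

    def test_min_fa_over_unrelated_males_is_uniform(self):
        from nativeocs.pedigree import (CandidateSet, MALE, FEMALE,
                                        PedigreeRecord, build_pedigree,
                                        compute_mc, OriginAnnotation,
                                        normalize_ebv)
        from nativeocs.kinship import compute_kinship_set
        recs = [PedigreeRecord(f"M{i}", sex=MALE, birth_year=1950, breed="NAT")
                for i in range(3)]
        recs += [PedigreeRecord(f"F{i}", sex=FEMALE, birth_year=1950,
                                breed="NAT") for i in range(2)]
        ped = build_pedigree(recs)
        origin = compute_mc(ped, OriginAnnotation(
            {r.id: False for r in recs}))
        cands = CandidateSet(males=["M0", "M1", "M2"], females=["F0", "F1"],
                             ebv={"M0": 1.0, "M1": 2.0, "M2": 3.0,
                                  "F0": 0.0, "F1": 1.0},
                             mc={r.id: 0.0 for r in recs})
        cands = normalize_ebv(cands)
        kin = compute_kinship_set(ped, origin, cands.ids)
        res = solve_scenario(ScenarioSpec("min_fA"), kin, cands, seed=0)
        for m in cands.males:
            assert res.c[m] == pytest.approx(0.5 / 3, abs=1e-5)

    def test_infeasible_bound_reported(self, toy3):
        _, _, cands, kin = toy3
        # MC cannot go below the fixed female floor: demand the impossible
        spec = ScenarioSpec(objective="max_EBV",
                            bounds=BoundSet(ub_MC=-0.1), name="impossible")
        res = solve_scenario(spec, kin, cands, seed=0)
        assert res.solver_status == "infeasible"
        assert "ub_MC" in res.violated

    def test_constraint_evaluation_consistency(self, toy3):
        """Post-hoc quadratic forms agree with the solver's constraint values."""
        _, _, cands, kin = toy3
        spec = ScenarioSpec(objective="max_EBV",
                            bounds=BoundSet(ub_fA=0.14), name="chk")
        res = solve_scenario(spec, kin, cands, seed=0)
        ids = cands.males + cands.females
        c = np.array([res.c[i] for i in ids])
        assert float(c @ kin.fA.values @ c) == pytest.approx(
            res.achieved.fA_bar, abs=1e-8)
        assert res.achieved.fA_bar <= 0.14 + 1e-6


class TestCountSelected:
    def test_threshold_rule(self):
        frac, _ = count_selected(np.array([0.4999, 0.0001]))
        assert frac == 0.5

    def test_equal_contributions_zero_sd(self):
        frac, sd = count_selected(np.full(10, 0.05))
        assert frac == 1.0 and sd == 0.0

    def test_ts_like_fraction(self):
        c = np.zeros(200)
        c[:13] = 0.5 / 13
        frac, sd = count_selected(c)
        assert frac == pytest.approx(0.065)
        assert sd == pytest.approx(np.std(c))
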