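import numpy as np
import pytest

from aerotype import fba, network
from aerotype.fba import (
    FluxSolution, PhenotypeConstraints, compute_proteome_allocation,
    knockout, solve_growth, uniform_expression,
)
from aerotype.network import ValidationError

from lp_oracle import enumerate_lp_max


def stoichiometric_matrix(model):
    mets = sorted(model.metabolites)
    rxns = sorted(model.reactions)
    S = np.zeros((len(mets), len(rxns)))
    for j, rid in enumerate(rxns):
        for met, coef in model.reactions[rid].stoichiometry.items():
            S[mets.index(met), j] = coef
    return S, rxns


class TestSolveGrowth:
    def test_reference_model_is_feasible_and_grows(self, model):
        ph = PhenotypeConstraints(glucose_uptake=10, fix_acetate=False)
        sol = solve_growth(model, ph)
        assert sol.optimal
        assert sol.growth_rate > 0.5

    def test_steady_state_holds_componentwise(self, model):
        ph = PhenotypeConstraints(glucose_uptake=10, fix_acetate=False)
        sol = solve_growth(model, ph)
        S, rxns = stoichiometric_matrix(model)
        v = np.array([sol.fluxes[r] for r in rxns])
        assert np.max(np.abs(S @ v)) < 1e-6

    def test_no_carbon_no_growth(self, model):
        ph = PhenotypeConstraints(glucose_uptake=0, fix_acetate=False)
        sol = solve_growth(model, ph)
        assert sol.optimal
        assert sol.growth_rate == pytest.approx(0.0, abs=1e-9)

    def test_growth_monotone_in_glucose(self, model):
        mus = []
        for glc in (1.0, 2.5, 4.0, 6.0, 8.0):
            ph = PhenotypeConstraints(glucose_uptake=glc, fix_acetate=False)
            mus.append(solve_growth(model, ph).growth_rate)
        assert all(b >= a - 1e-9 for a, b in zip(mus, mus[1:]))

    def test_infeasible_returns_status_not_exception(self, model):
        # demand acetate secretion without any carbon source
        ph = PhenotypeConstraints(glucose_uptake=0, acetate_secretion=5.0)
        sol = solve_growth(model, ph)
        assert sol.status == "infeasible"

    def test_unbounded_model_raises(self, toy_model):
        m = toy_model.copy()
        # uncapped influx: growth has no finite optimum
        inf = float("inf")
        m.reactions["EX_a"].lower_bound = -inf
        for rid in ("T_a", "R1", "R2", "GROW"):
            m.reactions[rid].upper_bound = inf
        with pytest.raises(ValidationError, match="unbounded|cap"):
            solve_growth(m)

    def test_matches_vertex_enumeration_on_toys(self, toy_model):
        sol = solve_growth(toy_model)
        S, rxns = stoichiometric_matrix(toy_model)
        c = np.array([1.0 if r == "GROW" else 0.0 for r in rxns])
        lower = np.array([toy_model.reactions[r].lower_bound for r in rxns])
        upper = np.array([toy_model.reactions[r].upper_bound for r in rxns])
        best, _ = enumerate_lp_max(c, S, lower, upper)
        assert sol.growth_rate == pytest.approx(best, abs=1e-7)

    def test_matches_vertex_enumeration_with_branch_competition(self, toy_model):
        # tighten the efficient route so the lossy bypass must carry flux
        m = toy_model.copy()
        m.reactions["R1"].upper_bound = 1.0
        sol = solve_growth(m)
        S, rxns = stoichiometric_matrix(m)
        c = np.array([1.0 if r == "GROW" else 0.0 for r in rxns])
        lower = np.array([m.reactions[r].lower_bound for r in rxns])
        upper = np.array([m.reactions[r].upper_bound for r in rxns])
        best, _ = enumerate_lp_max(c, S, lower, upper)
        assert best == pytest.approx(1.0 + (5.0 - 1.0) / 2.0)   # 3: R1 + bypass
        assert sol.growth_rate == pytest.approx(best, abs=1e-7)


class TestCapacityConstraints:
    def test_expression_cap_limits_flux(self, model):
        # give the PTS gene a vanishing share: uptake must collapse
        expr = uniform_expression(model)
        bleed = expr["ptsG"] - 1e-6
        expr["ptsG"] = 1e-6
        expr["pgi"] += bleed
        ph = PhenotypeConstraints(glucose_uptake=10, fix_acetate=False)
        capped = solve_growth(model, ph, expr)
        free = solve_growth(model, ph)
        assert capped.optimal
        assert capped.growth_rate < 0.05 * free.growth_rate

    def test_shares_must_be_normalized(self, model):
        ph = PhenotypeConstraints(glucose_uptake=10, fix_acetate=False)
        with pytest.raises(ValueError, match="sum"):
            solve_growth(model, ph, {"pgi": 0.4})

    def test_uniform_expression_sums_to_one(self, model):
        shares = uniform_expression(model)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in shares.values())

    def test_shared_budget_binds(self, model):
        ph = PhenotypeConstraints(glucose_uptake=50, fix_acetate=False,
                                  o2_uptake_max=40)
        small = solve_growth(model, ph, None, 0.25)
        large = solve_growth(model, ph, None, 0.55)
        assert 0 < small.growth_rate < large.growth_rate


class TestProteomeAllocation:
    def test_hand_computed_single_enzyme_mass(self):
        sol = FluxSolution("optimal", 0.5, {}, {"g": 0.01})
        m = network.MetabolicModel(
            metabolites={}, reactions={"BIOMASS": network.Reaction(
                "BIOMASS", {}, 0, 1, [], "biomass")},
            enzymes={"g": network.EnzymeSpec("g", 100.0, 1.0)},
            ets_components={}, ats_gene_set={"g"},
            atps_reaction_id="BIOMASS", h_per_atp=10 / 3)
        alloc = compute_proteome_allocation(sol, m)
        assert alloc.per_protein_mass["g"] == pytest.approx(100 * 0.5 * 0.01)
        assert alloc.ats_fraction == pytest.approx(1.0)

    def test_total_equals_sum_of_parts(self, model):
        ph = PhenotypeConstraints(glucose_uptake=10, fix_acetate=False)
        sol = solve_growth(model, ph, None, fba.PROTEOME_BUDGET)
        alloc = compute_proteome_allocation(sol, model)
        assert alloc.total == pytest.approx(sum(alloc.per_protein_mass.values()),
                                            abs=1e-9)
        assert 0 <= alloc.ats_fraction <= 1
        assert alloc.ats_total <= alloc.total + 1e-12

    def test_zero_flux_solution_reports_zero_with_warning(self, caplog):
        sol = FluxSolution("optimal", 0.0, {}, {})
        m = network.MetabolicModel(
            metabolites={}, reactions={}, enzymes={}, ets_components={},
            ats_gene_set=set(), atps_reaction_id="x", h_per_atp=10 / 3)
        import logging
        with caplog.at_level(logging.WARNING, logger="aerotype"):
            alloc = compute_proteome_allocation(sol, m)
        assert alloc.total == 0.0
        assert alloc.ats_fraction == 0.0
        assert any("zero" in r.message for r in caplog.records)

    def test_infeasible_solution_rejected(self, model):
        sol = FluxSolution("infeasible", 0.0, {}, {})
        with pytest.raises(ValidationError):
            compute_proteome_allocation(sol, model)


class TestKnockout:
    def test_knockout_closes_reaction_bounds(self, model):
        out = knockout(model, ["ndh"])
        rxn = out.reactions["NDH2pp"]
        assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 0.0)

    def test_unknown_gene_is_reported(self, model):
        with pytest.raises(ValidationError, match="nosuchgene"):
            knockout(model, ["nosuchgene"])

    def test_solver_respects_knockout(self, model):
        out = knockout(model, ["ndh", "cyoB"])    # leaves NDH-I + CBD
        ph = PhenotypeConstraints(glucose_uptake=10, fix_acetate=False)
        sol = solve_growth(out, ph)
        assert sol.optimal
        assert sol.fluxes["NDH2pp"] == pytest.approx(0.0, abs=1e-9)
        assert sol.fluxes["CYOpp"] == pytest.approx(0.0, abs=1e-9)

    def test_knockout_leaves_input_untouched(self, model):
        bounds_before = model.reactions["NDH2pp"].upper_bound
        knockout(model, ["ndh"])
        assert model.reactions["NDH2pp"].upper_bound == bounds_before


class TestPhenotypeValidation:
    @pytest.mark.parametrize("kwargs", [
        {"glucose_uptake": -1.0},
        {"glucose_uptake": float("nan")},
        {"glucose_uptake": 5.0, "acetate_secretion": -2.0},
    ])
    def test_invalid_rates_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhenotypeConstraints(**kwargs)

    def test_phenotype_tsv_round_trip(self, model, tmp_path):
        import pandas as pd
        df = pd.DataFrame([{"strain": "s1", "glucose_uptake": 8.0,
                            "acetate_secretion": 1.0, "o2_max": 20.0,
                            "growth_rate": 0.7}])
        path = tmp_path / "p.tsv"
        df.to_csv(path, sep="\t", index=False)
        table = fba.read_phenotypes(path)
        assert table["s1"].glucose_uptake == 8.0
        assert table["s1"].growth_rate_observed == 0.7
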