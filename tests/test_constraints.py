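"""LP assembly and solution: constraint families, closure, monotonicity."""

from dataclasses import replace

import pytest

from pcforge.constraints import (
    ConditionParameters,
    assemble_lp,
    solve_min_uptake,
)
from pcforge.reconstruction import build_pc_model
from pcforge.toy import ToyOrganismSpec, generate_toy_organism


@pytest.fixture(scope="module")
def solved(pc, bundle):
    params = bundle.condition.at_mu(0.05)
    lp = assemble_lp(pc, params)
    return params, lp, solve_min_uptake(lp)


class TestParameterValidation:
    def test_mu_zero_rejected(self):
        with pytest.raises(ValueError):
            ConditionParameters(mu=0.0)

    def test_minimum_supported_mu(self):
        assert ConditionParameters(mu=1e-4).mu == 1e-4

    def test_up_ratio_range(self):
        with pytest.raises(ValueError):
            ConditionParameters(up_ratio_c=1.0)


class TestRowStructure:
    def test_every_row_tag_is_a_known_family(self, solved):
        _, lp, _ = solved
        families = {"mass_balance", "enzyme_capacity", "ribosome_capacity",
                    "up_floor", "mrna_coupling", "trna_coupling",
                    "total_proteome", "rna_mass", "glycogen_mass", "closure"}
        assert {row.tag for row in lp.rows} <= families

    def test_one_capacity_row_per_linked_reaction(self, solved, pc):
        _, lp, _ = solved
        n = sum(r.tag == "enzyme_capacity" for r in lp.rows)
        assert n == len(pc.enzyme_links)

    def test_enzyme_capacity_rearrangement(self, solved, pc):
        # v_e = v_i * mu / kcat_h: with kcat 18000/h and mu 0.1, a flux of
        # 10 forces a formation flux of 10*0.1/18000
        params, _, _ = solved
        row = next(r for r in assemble_lp(pc, params.at_mu(0.1)).rows
                   if r.name == "cap_R_upt")
        kcat_h = pc.enzyme_links["R_upt"][1] * 3600.0
        form = pc.complex_formation_rxn["CPLX_upt"]
        assert row.coefs[form] == pytest.approx(-kcat_h / 0.1)
        # rearranged: v_e = 10 / (kcat_h/mu)
        assert 10.0 / (kcat_h / 0.1) == pytest.approx(10 * 0.1 / kcat_h)

    def test_ribosome_summation_row(self, solved, pc):
        _, lp, sol = solved
        # sum eR_i equals v_syn,ribo / mu at the optimum
        er_total = sum(v for k, v in sol.values.items()
                       if k.startswith("eR_"))
        assert er_total == pytest.approx(
            sol.values[pc.ribosome_synthesis_rxn] / 0.05, rel=1e-9)


class TestSolution:
    def test_optimal_and_all_fluxes_nonnegative(self, solved):
        _, _, sol = solved
        assert sol.optimal
        assert min(sol.values.values()) >= -1e-9

    def test_equality_residuals_tiny(self, solved):
        _, _, sol = solved
        assert sol.max_residual <= 1e-8

    def test_closure_exact(self, solved):
        _, _, sol = solved
        total = sol.values["TotalProtein"] + sol.values["RNA"] \
            + sol.values["Glycogen"]
        assert total == pytest.approx(0.93, abs=1e-8)

    def test_up_floor_met(self, solved, pc):
        params, _, sol = solved
        up_mass = sol.values[pc.up_translation_rxn] / params.mu \
            * pc.weights["up"] / 1000.0
        assert up_mass >= params.up_ratio_c * sol.values["TotalProtein"] - 1e-9

    def test_ngam_enforced(self, solved, pc):
        params, _, sol = solved
        assert sol.values[pc.ngam_rxn] >= params.ngam - 1e-9

    def test_infeasible_above_mu_max(self, pc, bundle):
        sol = solve_min_uptake(assemble_lp(pc, bundle.condition.at_mu(0.2)))
        assert sol.status == "infeasible"


class TestMonotonicity:
    def test_feasibility_monotone_in_mu(self, pc, bundle):
        statuses = [
            solve_min_uptake(assemble_lp(pc, bundle.condition.at_mu(mu))).status
            for mu in (0.01, 0.04, 0.07, 0.12, 0.2)]
        seen_infeasible = False
        for s in statuses:
            if s == "infeasible":
                seen_infeasible = True
            else:
                assert not seen_infeasible, "feasible after infeasible"

    def test_raising_kcat_weakly_decreases_uptake(self, bundle):
        spec_fast = ToyOrganismSpec(seed=1, kcat_cat_fast=0.10)
        b2 = generate_toy_organism(spec_fast)
        pc2 = build_pc_model(b2.gem, b2.records, b2.kcat_entries,
                             b2.complex_defs, b2.expr_config)
        from pcforge.reconstruction import build_pc_model as bpm
        pc1 = bpm(bundle.gem, bundle.records, bundle.kcat_entries,
                  bundle.complex_defs, bundle.expr_config)
        u1 = solve_min_uptake(assemble_lp(pc1, bundle.condition.at_mu(0.05)))
        u2 = solve_min_uptake(assemble_lp(pc2, b2.condition.at_mu(0.05)))
        assert u2.objective <= u1.objective + 1e-9

    def test_raising_up_ratio_weakly_increases_uptake(self, pc, bundle):
        lo = replace(bundle.condition.at_mu(0.05), up_ratio_c=0.2)
        hi = replace(bundle.condition.at_mu(0.05), up_ratio_c=0.6)
        u_lo = solve_min_uptake(assemble_lp(pc, lo)).objective
        u_hi = solve_min_uptake(assemble_lp(pc, hi)).objective
        assert u_hi >= u_lo - 1e-9

    def test_solution_invariant_to_reaction_order(self, pc, bundle):
        params = bundle.condition.at_mu(0.05)
        base = solve_min_uptake(assemble_lp(pc, params))
        shuffled = pc.model.copy()
        shuffled.reactions.sort(key=lambda r: r.id, reverse=True)
        from dataclasses import replace as drep
        pc2 = drep(pc, model=shuffled)
        other = solve_min_uptake(assemble_lp(pc2, params))
        assert other.objective == pytest.approx(base.objective, rel=1e-9)
        for key in ("TotalProtein", "RNA", "Glycogen"):
            assert other.values[key] == pytest.approx(
                base.values[key], rel=1e-7, abs=1e-10)


class TestClosureVariants:
    def test_glycogen_capped(self, pc, bundle):
        p = replace(bundle.condition.at_mu(0.05),
                    closure_mode="glycogen_capped")
        sol = solve_min_uptake(assemble_lp(pc, p))
        assert sol.optimal
        assert sol.values["Glycogen"] == pytest.approx(0.02, abs=1e-8)
        total = sol.values["TotalProtein"] + sol.values["RNA"] \
            + sol.values["Glycogen"]
        assert total == pytest.approx(0.93, abs=1e-8)

    def test_free_amino_acid_closure(self, pc, bundle):
        p = replace(bundle.condition.at_mu(0.05),
                    closure_mode="free_amino_acids")
        sol = solve_min_uptake(assemble_lp(pc, p))
        assert sol.optimal
        total = sol.values["TotalProtein"] + sol.values["RNA"] \
            + sol.values["FreeAA"]
        assert total == pytest.approx(0.93, abs=1e-8)
        assert sol.values["Glycogen"] == pytest.approx(0.0, abs=1e-9)


class TestExport:
    def test_lp_format_written(self, solved, tmp_path):
        _, lp, _ = solved
        path = tmp_path / "toy.lp"
        lp.to_lp_format(path)
        text = path.read_text()
        assert text.startswith("Minimize")
        assert "Subject To" in text and "Bounds" in text
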