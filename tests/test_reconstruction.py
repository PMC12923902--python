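"""Network reconstruction: splitting, isozyme expansion, templates, biomass."""

import cobra
import pytest
from cobra import Metabolite, Reaction

from pcforge.annotation_io import InputError, peptide_mw
from pcforge.reconstruction import (
    ROLES,
    build_pc_model,
    expand_isozymes,
    gpr_to_isozymes,
    load_pc_model,
    save_pc_model,
    split_reversible,
)


def _tiny_model():
    m = cobra.Model("tiny")
    a, b = Metabolite("a", compartment="c"), Metabolite("b", compartment="c")
    m.add_metabolites([a, b])
    rev = Reaction("REV", lower_bound=-10, upper_bound=10)
    rev.add_metabolites({a: -1, b: 1})
    irr = Reaction("IRR", lower_bound=0, upper_bound=5)
    irr.add_metabolites({a: -1, b: 1})
    m.add_reactions([rev, irr])
    return m


class TestSplitReversible:
    def test_reversible_becomes_fwd_rev_pair(self):
        m = split_reversible(_tiny_model())
        fwd = m.reactions.get_by_id("REV_fwd")
        rev = m.reactions.get_by_id("REV_rev")
        assert (fwd.lower_bound, fwd.upper_bound) == (0, 10)
        assert (rev.lower_bound, rev.upper_bound) == (0, 10)
        # net flux space preserved: reversed stoichiometry negated
        a = m.metabolites.get_by_id("a")
        assert fwd.metabolites[a] == -1 and rev.metabolites[a] == 1

    def test_irreversible_untouched(self):
        m = split_reversible(_tiny_model())
        assert m.reactions.get_by_id("IRR").upper_bound == 5

    def test_count_is_n_plus_r(self, bundle):
        gem = bundle.gem.copy()
        n = len(gem.reactions)
        r = sum(rxn.lower_bound < 0 < rxn.upper_bound for rxn in gem.reactions)
        assert len(split_reversible(gem).reactions) == n + r

    def test_all_lower_bounds_nonnegative(self, pc):
        assert all(rxn.lower_bound >= 0 for rxn in pc.model.reactions)


class TestIsozymeExpansion:
    def test_or_of_and_normal_form(self):
        assert gpr_to_isozymes("(g1 and g2) or g3") == \
            [("g1", "g2"), ("g3",)]

    def test_single_gene_is_monomer(self):
        assert gpr_to_isozymes("g1") == [("g1",)]

    def test_malformed_gpr_names_reaction(self):
        with pytest.raises(InputError, match="RX"):
            gpr_to_isozymes("g1 and (or g2", "RX")

    def test_copies_count_equals_isozyme_count(self):
        m = _tiny_model()
        m.reactions.get_by_id("IRR").gene_reaction_rule = \
            "(g1 and g2) or g3 or g4"
        links = expand_isozymes(m)
        copies = [rid for rid in links if rid.startswith("IRR_iso")]
        assert len(copies) == 3
        assert not m.reactions.has_id("IRR")

    def test_every_linked_reaction_has_one_complex(self, pc):
        assert set(pc.enzyme_links) == {"R_upt", "R_cat_iso1", "R_cat_iso2"}
        assert pc.enzyme_links["R_cat_iso1"][0] != \
            pc.enzyme_links["R_cat_iso2"][0]


class TestExpressionReactions:
    def test_reaction_census_from_gene_counts(self, bundle, pc):
        # 4 mRNA-side reactions per translated peptide (incl. the UP
        # pseudo-gene), 3 per tRNA gene, 1 per rRNA gene
        c = sum(r.feature_type == "CDS" for r in bundle.records) + 1
        t = sum(r.feature_type == "tRNA" for r in bundle.records)
        r_ = sum(r.feature_type == "rRNA" for r in bundle.records)
        roles = pc.roles
        n_trsc = sum(v == "transcription" for v in roles.values())
        n_trans = sum(v in ("translation", "up_synthesis")
                      for v in roles.values())
        n_deg = sum(v == "mrna_degradation" for v in roles.values())
        n_charge = sum(v == "trna_charging" for v in roles.values())
        assert n_trans == c
        assert n_deg == c
        assert n_trsc == c + t + r_
        assert n_charge == t  # one tRNA gene per class in the toy

    def test_translation_consumes_n_charged_trnas(self, bundle, pc):
        rec = next(r for r in bundle.records if r.locus_tag == "catA")
        rxn = pc.model.reactions.get_by_id(pc.translation_rxn["catA"])
        consumed = -sum(
            coef for met, coef in rxn.metabolites.items()
            if met.id.startswith("trna_charged_"))
        assert consumed == len(rec.peptide_seq)

    def test_degradation_returns_transcript_nucleotides(self, bundle, pc):
        rec = next(r for r in bundle.records if r.locus_tag == "catA")
        rxn = pc.model.reactions.get_by_id(pc.mrna_degradation_rxn["catA"])
        released = sum(coef for met, coef in rxn.metabolites.items()
                       if met.id == "nmp_c")
        assert released == len(rec.nucleotide_seq)

    def test_formation_conserves_mass(self, bundle, pc):
        # complex MW equals copies x subunit peptide MW for the dimer
        mw = pc.weights["complex"]["CPLX_upt"]
        peps = {r.locus_tag: r.peptide_seq for r in bundle.records
                if r.feature_type == "CDS"}
        assert mw == pytest.approx(
            2 * peptide_mw(peps["uptA"]) + peptide_mw(peps["uptB"]))

    def test_up_is_pooled_composition(self, pc):
        # UP length is the mean CDS length and its composition is a
        # convex combination of the modeled residues
        assert pc.up.length == pytest.approx(
            round(sum(len(r.peptide_seq) for r in pc.genes.values()
                      if r.feature_type == "CDS") / 6))
        assert sum(pc.up.aa_composition.values()) == pytest.approx(
            pc.up.length)


class TestBiomassAdjustment:
    def test_residual_mass_is_007(self, bundle, pc):
        rxn = pc.model.reactions.get_by_id(pc.biomass_residual_rxn)
        mass = -sum(coef * bundle.expr_config.metabolite_mw[m.id] / 1000.0
                    for m, coef in rxn.metabolites.items() if coef < 0)
        assert mass == pytest.approx(0.07)

    def test_protein_and_rna_components_removed(self, pc):
        rxn = pc.model.reactions.get_by_id(pc.biomass_residual_rxn)
        ids = {m.id for m in rxn.metabolites}
        assert "protein_b_c" not in ids and "rna_b_c" not in ids

    def test_gam_reaction_hydrolyzes_gam_atp(self, pc):
        rxn = pc.model.reactions.get_by_id(pc.gam_rxn)
        atp = pc.model.metabolites.get_by_id("atp_c")
        assert rxn.metabolites[atp] == -25.0

    def test_missing_biomass_is_fatal(self, bundle):
        from dataclasses import replace
        cfg = replace(bundle.expr_config, biomass_rxn_id="NOPE")
        with pytest.raises(InputError):
            build_pc_model(bundle.gem, bundle.records, bundle.kcat_entries,
                           bundle.complex_defs, cfg)


class TestModelContracts:
    def test_roles_partition_all_reactions(self, pc):
        assert set(pc.roles) == {r.id for r in pc.model.reactions}
        assert set(pc.roles.values()) <= set(ROLES)

    def test_one_dilution_per_diluted_species(self, pc):
        # every complex, mRNA, tRNA class, ribosome and UP has exactly one
        # dilution reaction
        dilutions = [rid for rid, role in pc.roles.items()
                     if role == "dilution"]
        # 3 complexes + 7 mRNAs + 2 tRNAs + ribosome + UP + glycogen + freeAA
        assert len(dilutions) == 16

    def test_reconstruction_deterministic(self, bundle, tmp_path):
        from pcforge.toy import ToyOrganismSpec, generate_toy_organism
        b2 = generate_toy_organism(ToyOrganismSpec(seed=1))
        pc1 = build_pc_model(bundle.gem, bundle.records,
                             bundle.kcat_entries, bundle.complex_defs,
                             bundle.expr_config)
        pc2 = build_pc_model(b2.gem, b2.records, b2.kcat_entries,
                             b2.complex_defs, b2.expr_config)
        p1, p2 = tmp_path / "a.xml", tmp_path / "b.xml"
        save_pc_model(pc1, p1, tmp_path / "a.json")
        save_pc_model(pc2, p2, tmp_path / "b.json")
        assert p1.read_bytes() == p2.read_bytes()
        assert (tmp_path / "a.json").read_bytes() == \
            (tmp_path / "b.json").read_bytes()

    def test_round_trip_preserves_couplings(self, pc, tmp_path):
        save_pc_model(pc, tmp_path / "m.xml", tmp_path / "m.json")
        pc2 = load_pc_model(tmp_path / "m.xml", tmp_path / "m.json")
        assert {r.id for r in pc2.model.reactions} == \
            {r.id for r in pc.model.reactions}
        assert pc2.enzyme_links == pc.enzyme_links
        assert pc2.weights == pc.weights
        assert pc2.trna_class == pc.trna_class
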