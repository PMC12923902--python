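"""Network reconstruction: from a GEM to a proteome-constrained model.

The transformation runs in the order the pipeline executes it:

1. every reversible reaction is divided into two irreversible copies
   (``_fwd``/``_rev``), so all fluxes are non-negative;
2. reactions whose gene-protein-reaction rule contains ``or`` are expanded
   into one copy per isozyme (``_isoN``), so each flux-carrying reaction
   maps to exactly one enzyme complex;
3. the biomass reaction is stripped of its protein and RNA components (the
   expression machinery now pays for those explicitly) and rescaled so the
   residual composition (lipids, vitamins, ...) amounts to 0.07 gDW per
   gDW of biomass; separate growth-associated (GAM) and non-growth
   (NGAM) ATP-maintenance reactions are provided;
4. template reactions for gene expression are generated per gene:
   transcription, mRNA degradation, translation and mRNA dilution for each
   CDS; transcription, charging and dilution for each tRNA; transcription
   for each rRNA;
5. formation and dilution reactions are added for every enzyme complex,
   the ribosome, and the unspecific protein (UP) — a pseudo-peptide whose
   residue composition is the pooled composition of all modeled peptides.

Dilution reactions are sinks (species -> nothing); growth dilution enters
the linear program through 1/mu coupling terms, not through biomass
stoichiometry.  Template energy costs (GTP per elongation step,
transcription initiation ATP, ...) are configuration values, not code.
"""

from __future__ import annotations

import itertools
import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

import cobra
from cobra import Metabolite, Reaction

from .annotation_io import (
    AA_RESIDUE_MASS,
    NMP_MASS,
    WATER_MASS,
    ComplexDefinition,
    GeneRecord,
    InputError,
    apply_kcat_policy,
    peptide_mw,
    rna_mw,
)

__all__ = [
    "ExpressionConfig",
    "RibosomeDefinition",
    "UPDefinition",
    "PcModel",
    "split_reversible",
    "expand_isozymes",
    "gpr_to_isozymes",
    "adjust_biomass",
    "build_expression_reactions",
    "build_assembly_and_dilution",
    "build_pc_model",
    "save_pc_model",
    "load_pc_model",
    "ROLES",
]

#: Role vocabulary; every reaction of a pc-model carries exactly one.
ROLES = (
    "metabolic", "translation", "transcription", "mrna_degradation",
    "trna_charging", "ribosome_assembly", "complex_formation", "dilution",
    "up_synthesis", "gam", "exchange", "biomass_residual",
    "glycogen_synthesis", "free_aa_synthesis",
)

#: Anhydroglucose unit of glycogen, g/mmol.
GLYCOGEN_UNIT_MW = 162.1406


@dataclass
class ExpressionConfig:
    """Template stoichiometries and species wiring for expression reactions.

    ``species`` maps logical names (atp, adp, amp, gtp, gdp, ntp, nmp and
    optionally h2o/pi/ppi/h) to metabolite ids of the host GEM;
    ``aa_species`` maps one-letter amino-acid codes to metabolite ids.
    Logical species missing from the maps are simply left out of the
    templates, which lets miniature models run without tracking, e.g.,
    inorganic phosphate.
    """

    species: dict = field(default_factory=dict)
    aa_species: dict = field(default_factory=dict)
    #: r-protein content of one ribosome: list of (locus_tag, copies).
    r_proteins: list = field(default_factory=list)
    # --- template energy costs (ATP/GTP equivalents) ------------------
    gtp_per_elongation: float = 2.0     # GTP per peptide bond
    gtp_initiation: float = 1.0         # GTP per translation initiation
    atp_per_charging: float = 1.0       # ATP -> AMP per charged tRNA
    ntp_per_nt: float = 1.0             # NTP per transcribed nucleotide
    atp_transcription_init: float = 2.0
    ribosome_assembly_gtp: float = 2.0
    # --- biomass adjustment -------------------------------------------
    biomass_rxn_id: str | None = None   # autodetected when None
    protein_components: list = field(default_factory=list)
    rna_components: list = field(default_factory=list)
    energy_components: list = field(default_factory=list)  # atp/adp/pi/... in biomass
    residual_mass: float = 0.07         # gDW residual biomass per gDW
    gam: float = 25.0                   # mmol ATP per gDW built into the GAM reaction
    ngam_rxn_id: str | None = None      # created when absent
    # --- misc ----------------------------------------------------------
    glycogen_rxn_id: str | None = None  # synthesis reaction in the GEM
    glycogen_mw: float = GLYCOGEN_UNIT_MW
    metabolite_mw: dict = field(default_factory=dict)  # id -> g/mmol overrides
    compartment: str = "c"
    up_length: int | None = None        # residues; pooled mean when None


@dataclass
class RibosomeDefinition:
    """Composition of one ribosome: r-protein genes (with copies) and rRNAs."""

    r_protein_genes: list  # [(locus_tag, copies)]
    rrna_genes: list       # [locus_tag]
    mw_r_proteins: float = 0.0  # g/mmol, protein part only
    mw_rRNA: float = 0.0        # g/mmol, rRNA part only


@dataclass
class UPDefinition:
    """Unspecific protein: pooled-composition pseudo-peptide.

    ``aa_composition`` holds (possibly fractional) residue counts per
    one-letter code; ``nt_composition`` the composition of its notional
    transcript.  Fractional stoichiometry is legitimate inside an LP.
    """

    aa_composition: dict
    nt_composition: dict
    length: float
    mw: float        # g/mmol peptide
    mrna_mw: float   # g/mmol transcript


@dataclass
class PcModel:
    """A proteome-constrained model: network plus coupling metadata."""

    model: cobra.Model
    roles: dict                      # reaction id -> role
    enzyme_links: dict               # metabolic rxn id -> (complex_id, kcat s^-1)
    weights: dict                    # see build_pc_model
    genes: dict                      # locus_tag -> GeneRecord
    ribosome: RibosomeDefinition | None = None
    up: UPDefinition | None = None
    # reaction-id maps, keyed by locus tag / class / complex id
    translation_rxn: dict = field(default_factory=dict)
    transcription_rxn: dict = field(default_factory=dict)
    mrna_degradation_rxn: dict = field(default_factory=dict)
    mrna_dilution_rxn: dict = field(default_factory=dict)
    trna_transcription_rxn: dict = field(default_factory=dict)
    trna_charging_rxn: dict = field(default_factory=dict)
    trna_class: dict = field(default_factory=dict)  # tRNA locus -> aa class
    complex_formation_rxn: dict = field(default_factory=dict)
    peptide_length: dict = field(default_factory=dict)
    ribosome_synthesis_rxn: str = ""
    up_translation_rxn: str = ""
    glycogen_rxn: str = ""
    free_aa_rxn: str = ""
    biomass_residual_rxn: str = ""
    gam_rxn: str = ""
    ngam_rxn: str = ""
    built_gam: float = 25.0

    def exchange_pair(self, base_id: str) -> tuple[str | None, str | None]:
        """(secretion, uptake) reaction ids for an exchange, after the
        reversibility split."""
        ids = {r.id for r in self.model.reactions}
        fwd = base_id if base_id in ids else (
            f"{base_id}_fwd" if f"{base_id}_fwd" in ids else None)
        rev = f"{base_id}_rev" if f"{base_id}_rev" in ids else None
        return fwd, rev


# ---------------------------------------------------------------------------
# 1. Reversibility split
# ---------------------------------------------------------------------------

def split_reversible(model: cobra.Model) -> cobra.Model:
    """Divide every reversible reaction into irreversible ``_fwd``/``_rev``
    copies with lower bound 0; the net flux space is preserved."""
    for rxn in list(model.reactions):
        if rxn.lower_bound >= 0:
            continue
        if rxn.upper_bound <= 0:  # runs backwards only: flip in place
            rev = Reaction(rxn.id + "_rev", name=rxn.name,
                           lower_bound=0.0, upper_bound=-rxn.lower_bound)
            rev.add_metabolites({m: -c for m, c in rxn.metabolites.items()})
            rev.gene_reaction_rule = rxn.gene_reaction_rule
            model.add_reactions([rev])
            model.remove_reactions([rxn])
            continue
        fwd = Reaction(rxn.id + "_fwd", name=rxn.name,
                       lower_bound=0.0, upper_bound=rxn.upper_bound)
        fwd.add_metabolites(dict(rxn.metabolites))
        rev = Reaction(rxn.id + "_rev", name=rxn.name,
                       lower_bound=0.0, upper_bound=-rxn.lower_bound)
        rev.add_metabolites({m: -c for m, c in rxn.metabolites.items()})
        rule = rxn.gene_reaction_rule
        model.add_reactions([fwd, rev])
        fwd.gene_reaction_rule = rule
        rev.gene_reaction_rule = rule
        model.remove_reactions([rxn])
    return model


# ---------------------------------------------------------------------------
# 2. Isozyme expansion
# ---------------------------------------------------------------------------

def gpr_to_isozymes(rule: str, reaction_id: str = "?") -> list[tuple[str, ...]]:
    """Normalize a GPR string to a list of isozymes, each a sorted tuple of
    subunit genes (OR-of-AND normal form)."""
    from ast import And, BoolOp, Expression, Name, Or

    if not rule.strip():
        return []
    try:
        gpr = cobra.core.gene.GPR.from_string(rule)
    except Exception as exc:
        raise InputError(f"reaction {reaction_id}: malformed GPR {rule!r}") from exc

    def walk(node) -> list[frozenset]:
        if isinstance(node, (cobra.core.gene.GPR, Expression)):
            return walk(node.body)
        if isinstance(node, Name):
            return [frozenset([node.id])]
        if isinstance(node, BoolOp):
            parts = [walk(v) for v in node.values]
            if isinstance(node.op, Or):
                return [s for p in parts for s in p]
            if isinstance(node.op, And):
                combos = []
                for combo in itertools.product(*parts):
                    combos.append(frozenset().union(*combo))
                return combos
        raise InputError(
            f"reaction {reaction_id}: unsupported GPR node {node!r}")

    seen, out = set(), []
    for iso in walk(gpr):
        key = tuple(sorted(iso))
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out


def expand_isozymes(model: cobra.Model) -> dict[str, tuple[str, ...]]:
    """Split each multi-isozyme reaction into one copy per isozyme.

    Returns reaction id -> subunit gene tuple for every reaction with a
    GPR after expansion.
    """
    links: dict[str, tuple[str, ...]] = {}
    for rxn in list(model.reactions):
        isozymes = gpr_to_isozymes(rxn.gene_reaction_rule, rxn.id)
        if not isozymes:
            continue
        if len(isozymes) == 1:
            rxn.gene_reaction_rule = " and ".join(isozymes[0])
            links[rxn.id] = isozymes[0]
            continue
        for k, iso in enumerate(isozymes, start=1):
            copy = Reaction(f"{rxn.id}_iso{k}", name=rxn.name,
                            lower_bound=rxn.lower_bound,
                            upper_bound=rxn.upper_bound)
            copy.add_metabolites(dict(rxn.metabolites))
            model.add_reactions([copy])
            copy.gene_reaction_rule = " and ".join(iso)
            links[copy.id] = iso
        model.remove_reactions([rxn])
    return links


# ---------------------------------------------------------------------------
# 3. Biomass adjustment, GAM and NGAM
# ---------------------------------------------------------------------------

def _metabolite_mw(met: Metabolite, config: ExpressionConfig) -> float:
    if met.id in config.metabolite_mw:
        return config.metabolite_mw[met.id]
    if met.formula:
        return met.formula_weight
    raise InputError(
        f"no molecular weight available for biomass component {met.id}")


def adjust_biomass(
    model: cobra.Model, config: ExpressionConfig, roles: dict
) -> tuple[str, str, str]:
    """Strip protein/RNA from the biomass reaction and rescale the residual.

    The protein, RNA and energy (GAM) components are removed; the
    remaining reactants are rescaled so one unit of flux drains
    ``residual_mass`` (default 0.07) grams of residual biomass — the
    assembled LP later fixes this flux to mu, making the residual
    composition growth-rate independent.  A dedicated GAM reaction
    hydrolysing ``config.gam`` mmol ATP per unit flux and an
    ATP-maintenance (NGAM) reaction are ensured.

    Returns (residual_rxn_id, gam_rxn_id, ngam_rxn_id).
    """
    # locate the biomass reaction
    if config.biomass_rxn_id is not None:
        try:
            biomass = model.reactions.get_by_id(config.biomass_rxn_id)
        except KeyError:
            raise InputError(
                f"biomass reaction {config.biomass_rxn_id!r} not found")
    else:
        cands = [r for r in model.reactions if "biomass" in r.id.lower()]
        if not cands:
            raise InputError("no biomass reaction found (id containing "
                             "'biomass'); set biomass_rxn_id")
        biomass = cands[0]

    drop = set(config.protein_components) | set(config.rna_components) \
        | set(config.energy_components)
    removed = {m: c for m, c in biomass.metabolites.items() if m.id in drop}
    biomass.subtract_metabolites(removed)

    residual_reactants = {
        m: c for m, c in biomass.metabolites.items() if c < 0}
    if not residual_reactants:
        raise InputError(
            "biomass reaction has no residual components after removing "
            "protein/RNA; cannot carry the 0.07 gDW residual")
    mass_per_flux = sum(
        -c * _metabolite_mw(m, config) / 1000.0
        for m, c in residual_reactants.items())
    scale = config.residual_mass / mass_per_flux
    biomass.subtract_metabolites(
        {m: c * (1.0 - scale) for m, c in biomass.metabolites.items()})
    biomass.lower_bound, biomass.upper_bound = 0.0, 1000.0
    roles[biomass.id] = "biomass_residual"

    sp = config.species

    def _met(logical: str) -> Metabolite | None:
        mid = sp.get(logical)
        return model.metabolites.get_by_id(mid) if mid else None

    atp, adp = _met("atp"), _met("adp")
    if atp is None or adp is None:
        raise InputError("species map must define 'atp' and 'adp'")
    hydrolysis = {atp: -1.0, adp: 1.0}
    for logical, coef in (("h2o", -1.0), ("pi", 1.0), ("h", 1.0)):
        met = _met(logical)
        if met is not None:
            hydrolysis[met] = coef

    gam = Reaction("GAM_PC", name="growth-associated maintenance",
                   lower_bound=0.0, upper_bound=1000.0)
    gam.add_metabolites({m: c * config.gam for m, c in hydrolysis.items()})
    model.add_reactions([gam])
    roles[gam.id] = "gam"

    if config.ngam_rxn_id is not None:
        ngam_id = config.ngam_rxn_id
        model.reactions.get_by_id(ngam_id)  # must exist
    else:
        ngam = Reaction("NGAM_PC", name="non-growth maintenance",
                        lower_bound=0.0, upper_bound=1000.0)
        ngam.add_metabolites(dict(hydrolysis))
        model.add_reactions([ngam])
        ngam_id = ngam.id
    roles.setdefault(ngam_id, "metabolic")  # ATP-maintenance reaction
    return biomass.id, gam.id, ngam_id


# ---------------------------------------------------------------------------
# 4. Expression template reactions
# ---------------------------------------------------------------------------

def _expr_met(model: cobra.Model, mid: str, name: str, compartment: str
              ) -> Metabolite:
    if model.metabolites.has_id(mid):
        return model.metabolites.get_by_id(mid)
    met = Metabolite(mid, name=name, compartment=compartment)
    model.add_metabolites([met])
    return met


def _mapped(model: cobra.Model, config: ExpressionConfig, logical: str
            ) -> Metabolite | None:
    mid = config.species.get(logical)
    return model.metabolites.get_by_id(mid) if mid else None


def _add(stoich: dict, met: Metabolite | None, coef: float) -> None:
    if met is not None and coef != 0:
        stoich[met] = stoich.get(met, 0.0) + coef


def _nt_composition(seq: str) -> dict[str, int]:
    return dict(Counter(seq.upper().replace("T", "U")))


def build_expression_reactions(
    model: cobra.Model,
    records: list[GeneRecord],
    config: ExpressionConfig,
    roles: dict,
    pc: "PcModel",
    up: UPDefinition | None = None,
) -> None:
    """Generate the per-gene expression machinery.

    Per CDS: transcription (NTPs -> mRNA), mRNA degradation (mRNA -> NMPs),
    translation (charged tRNAs + GTP -> peptide + uncharged tRNAs) and mRNA
    dilution.  Per tRNA gene: transcription; per amino-acid class: one
    charging reaction and one tRNA dilution.  Per rRNA gene: transcription.
    When an UP definition is given it receives the same four mRNA-side
    reactions, with fractional composition-based stoichiometry.
    """
    comp = config.compartment
    ntp = _mapped(model, config, "ntp")
    nmp = _mapped(model, config, "nmp")
    atp = _mapped(model, config, "atp")
    adp = _mapped(model, config, "adp")
    amp = _mapped(model, config, "amp")
    gtp = _mapped(model, config, "gtp")
    gdp = _mapped(model, config, "gdp")
    ppi = _mapped(model, config, "ppi")
    h2o = _mapped(model, config, "h2o")
    if ntp is None:
        raise InputError("species map must define 'ntp'")

    trna_classes: dict[str, list[GeneRecord]] = {}
    for rec in records:
        if rec.feature_type == "tRNA":
            if not rec.aa_class:
                raise InputError(f"{rec.locus_tag}: tRNA record without aa_class")
            trna_classes.setdefault(rec.aa_class, []).append(rec)

    def transcription(tag: str, nt_comp: dict, product: Metabolite,
                      role: str = "transcription") -> Reaction:
        n = sum(nt_comp.values())
        rxn = Reaction(f"TRSC_{tag}", name=f"transcription {tag}",
                       lower_bound=0.0, upper_bound=1000.0)
        stoich: dict = {}
        _add(stoich, ntp, -config.ntp_per_nt * n)
        _add(stoich, atp, -config.atp_transcription_init)
        _add(stoich, adp, config.atp_transcription_init)
        _add(stoich, ppi, n)  # pyrophosphate per incorporated NTP, if tracked
        stoich[product] = 1.0
        rxn.add_metabolites(stoich)
        model.add_reactions([rxn])
        roles[rxn.id] = role
        return rxn

    # --- protein-coding genes (and UP pseudo-gene) --------------------
    def expression_for_peptide(tag: str, aa_comp: dict, nt_comp: dict,
                               length: float, is_up: bool) -> None:
        mrna = _expr_met(model, f"mrna_{tag}", f"mRNA {tag}", comp)
        pep = _expr_met(
            model, "up_protein" if is_up else f"pep_{tag}",
            "unspecific protein" if is_up else f"peptide {tag}", comp)

        trsc = transcription(tag, nt_comp, mrna)
        pc.transcription_rxn[tag] = trsc.id

        n_nt = sum(nt_comp.values())
        deg = Reaction(f"DEG_{tag}", name=f"mRNA degradation {tag}",
                       lower_bound=0.0, upper_bound=1000.0)
        dstoich: dict = {mrna: -1.0}
        _add(dstoich, nmp, n_nt)
        _add(dstoich, h2o, -(n_nt - 1))
        deg.add_metabolites(dstoich)
        model.add_reactions([deg])
        roles[deg.id] = "mrna_degradation"
        pc.mrna_degradation_rxn[tag] = deg.id

        dil = Reaction(f"DIL_mrna_{tag}", name=f"mRNA dilution {tag}",
                       lower_bound=0.0, upper_bound=1000.0)
        dil.add_metabolites({mrna: -1.0})
        model.add_reactions([dil])
        roles[dil.id] = "dilution"
        pc.mrna_dilution_rxn[tag] = dil.id

        trans = Reaction(f"TRANS_{tag}", name=f"translation {tag}",
                         lower_bound=0.0, upper_bound=1000.0)
        tstoich: dict = {pep: 1.0}
        gtp_cost = config.gtp_per_elongation * length + config.gtp_initiation
        _add(tstoich, gtp, -gtp_cost)
        _add(tstoich, gdp, gtp_cost)
        for aa, count in sorted(aa_comp.items()):
            if aa not in trna_classes:
                raise InputError(
                    f"{tag}: no tRNA gene for amino-acid class {aa!r}")
            charged = _expr_met(model, f"trna_charged_{aa}",
                                f"charged tRNA {aa}", comp)
            uncharged = _expr_met(model, f"trna_{aa}", f"tRNA {aa}", comp)
            tstoich[charged] = -float(count)
            tstoich[uncharged] = float(count)
        trans.add_metabolites(tstoich)
        model.add_reactions([trans])
        roles[trans.id] = "up_synthesis" if is_up else "translation"
        pc.translation_rxn[tag] = trans.id
        pc.peptide_length[tag] = length
        if is_up:
            pc.up_translation_rxn = trans.id

    for rec in records:
        if rec.feature_type == "CDS":
            expression_for_peptide(
                rec.locus_tag, dict(Counter(rec.peptide_seq)),
                _nt_composition(rec.nucleotide_seq),
                len(rec.peptide_seq), rec.is_up)

    if up is not None:
        expression_for_peptide("UP", up.aa_composition, up.nt_composition,
                               up.length, True)

    # --- tRNA genes ----------------------------------------------------
    for aa, recs in sorted(trna_classes.items()):
        uncharged = _expr_met(model, f"trna_{aa}", f"tRNA {aa}", comp)
        charged = _expr_met(model, f"trna_charged_{aa}",
                            f"charged tRNA {aa}", comp)
        for rec in recs:
            trsc = transcription(rec.locus_tag,
                                 _nt_composition(rec.nucleotide_seq),
                                 uncharged)
            pc.trna_transcription_rxn[rec.locus_tag] = trsc.id
            pc.trna_class[rec.locus_tag] = aa
        chg = Reaction(f"CHARGE_{aa}", name=f"tRNA charging {aa}",
                       lower_bound=0.0, upper_bound=1000.0)
        cstoich: dict = {uncharged: -1.0, charged: 1.0}
        aa_met = config.aa_species.get(aa)
        if aa_met:
            cstoich[model.metabolites.get_by_id(aa_met)] = -1.0
        _add(cstoich, atp, -config.atp_per_charging)
        _add(cstoich, amp, config.atp_per_charging)
        _add(cstoich, ppi, config.atp_per_charging)
        chg.add_metabolites(cstoich)
        model.add_reactions([chg])
        roles[chg.id] = "trna_charging"
        pc.trna_charging_rxn[aa] = chg.id

        dil = Reaction(f"DIL_trna_{aa}", name=f"tRNA dilution {aa}",
                       lower_bound=0.0, upper_bound=1000.0)
        dil.add_metabolites({uncharged: -1.0})
        model.add_reactions([dil])
        roles[dil.id] = "dilution"

    # --- rRNA genes ----------------------------------------------------
    for rec in records:
        if rec.feature_type == "rRNA":
            rrna = _expr_met(model, f"rrna_{rec.locus_tag}",
                             f"rRNA {rec.locus_tag}", comp)
            trsc = transcription(rec.locus_tag,
                                 _nt_composition(rec.nucleotide_seq), rrna)
            pc.transcription_rxn[rec.locus_tag] = trsc.id


# ---------------------------------------------------------------------------
# 5. Assembly and dilution
# ---------------------------------------------------------------------------

def build_assembly_and_dilution(
    model: cobra.Model,
    complexes: list[ComplexDefinition],
    ribosome: RibosomeDefinition,
    config: ExpressionConfig,
    roles: dict,
    pc: "PcModel",
) -> None:
    """Formation + dilution per complex; ribosome assembly + dilution; UP
    dilution.  Formation reactions conserve mass by construction (complex
    MW = sum of copies x subunit MW)."""
    comp = config.compartment
    gtp = _mapped(model, config, "gtp")
    gdp = _mapped(model, config, "gdp")

    for cdef in complexes:
        cplx = _expr_met(model, f"cplx_{cdef.complex_id}",
                         f"complex {cdef.complex_id}", comp)
        form = Reaction(f"FORM_{cdef.complex_id}",
                        name=f"formation {cdef.complex_id}",
                        lower_bound=0.0, upper_bound=1000.0)
        stoich: dict = {cplx: 1.0}
        for tag, copies in cdef.subunits:
            pid = f"pep_{tag}"
            if not model.metabolites.has_id(pid):
                raise InputError(
                    f"complex {cdef.complex_id}: unknown subunit {tag}")
            stoich[model.metabolites.get_by_id(pid)] = -float(copies)
        form.add_metabolites(stoich)
        model.add_reactions([form])
        roles[form.id] = "complex_formation"
        pc.complex_formation_rxn[cdef.complex_id] = form.id

        dil = Reaction(f"DIL_cplx_{cdef.complex_id}",
                       name=f"dilution {cdef.complex_id}",
                       lower_bound=0.0, upper_bound=1000.0)
        dil.add_metabolites({cplx: -1.0})
        model.add_reactions([dil])
        roles[dil.id] = "dilution"

    # ribosome
    ribo = _expr_met(model, "ribosome", "ribosome", comp)
    asm = Reaction("FORM_ribosome", name="ribosome assembly",
                   lower_bound=0.0, upper_bound=1000.0)
    stoich = {ribo: 1.0}
    for tag, copies in ribosome.r_protein_genes:
        stoich[model.metabolites.get_by_id(f"pep_{tag}")] = -float(copies)
    for tag in ribosome.rrna_genes:
        stoich[model.metabolites.get_by_id(f"rrna_{tag}")] = -1.0
    _add(stoich, gtp, -config.ribosome_assembly_gtp)
    _add(stoich, gdp, config.ribosome_assembly_gtp)
    asm.add_metabolites(stoich)
    model.add_reactions([asm])
    roles[asm.id] = "ribosome_assembly"
    pc.ribosome_synthesis_rxn = asm.id

    rdil = Reaction("DIL_ribosome", name="ribosome dilution",
                    lower_bound=0.0, upper_bound=1000.0)
    rdil.add_metabolites({ribo: -1.0})
    model.add_reactions([rdil])
    roles[rdil.id] = "dilution"

    # UP dilution
    if model.metabolites.has_id("up_protein"):
        updil = Reaction("DIL_up", name="UP dilution",
                         lower_bound=0.0, upper_bound=1000.0)
        updil.add_metabolites(
            {model.metabolites.get_by_id("up_protein"): -1.0})
        model.add_reactions([updil])
        roles[updil.id] = "dilution"


# ---------------------------------------------------------------------------
# UP pseudo-peptide from the modeled-peptide pool
# ---------------------------------------------------------------------------

def derive_up_definition(records: list[GeneRecord],
                         config: ExpressionConfig) -> UPDefinition:
    """Pooled-composition unspecific protein.

    Residue and transcript-nucleotide frequencies are pooled over all CDS
    records (weighting each gene by its length, i.e., uniform abundance per
    residue); the UP length defaults to the mean CDS length.
    """
    aa_pool: Counter = Counter()
    nt_pool: Counter = Counter()
    lengths = []
    for rec in records:
        if rec.feature_type != "CDS" or rec.is_up:
            continue
        aa_pool.update(rec.peptide_seq)
        nt_pool.update(rec.nucleotide_seq.upper().replace("T", "U"))
        lengths.append(len(rec.peptide_seq))
    if not lengths:
        raise InputError("cannot derive UP composition: no CDS records")
    length = config.up_length if config.up_length is not None \
        else round(sum(lengths) / len(lengths))
    total_aa = sum(aa_pool.values())
    aa_comp = {aa: length * n / total_aa for aa, n in sorted(aa_pool.items())}
    nt_len = 3 * length
    total_nt = sum(nt_pool.values())
    nt_comp = {nt: nt_len * n / total_nt for nt, n in sorted(nt_pool.items())}
    mw = sum(c * AA_RESIDUE_MASS[aa] for aa, c in aa_comp.items()) + WATER_MASS
    mrna_mw = sum(c * NMP_MASS[nt] for nt, c in nt_comp.items()) \
        - (nt_len - 1) * WATER_MASS
    return UPDefinition(aa_composition=aa_comp, nt_composition=nt_comp,
                        length=float(length), mw=mw, mrna_mw=mrna_mw)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def build_pc_model(
    gem: cobra.Model,
    records: list[GeneRecord],
    kcat_entries: list,
    complex_defs: list[ComplexDefinition],
    config: ExpressionConfig,
) -> PcModel:
    """Full reconstruction pipeline: GEM -> proteome-constrained model."""
    model = gem.copy()
    roles: dict[str, str] = {}

    split_reversible(model)
    links = expand_isozymes(model)

    # default role assignment for the metabolic part
    for rxn in model.reactions:
        roles[rxn.id] = "exchange" if rxn.boundary else "metabolic"

    pc = PcModel(model=model, roles=roles, enzyme_links={}, weights={},
                 genes={r.locus_tag: r for r in records})
    pc.built_gam = config.gam

    residual_id, gam_id, ngam_id = adjust_biomass(model, config, roles)
    pc.biomass_residual_rxn, pc.gam_rxn, pc.ngam_rxn = \
        residual_id, gam_id, ngam_id

    # peptide weights
    pep_mws = {r.locus_tag: peptide_mw(r.peptide_seq)
               for r in records if r.feature_type == "CDS" and not r.is_up}

    # match expanded GPR gene sets to declared complexes; undeclared sets
    # become implicit 1-copy complexes (monomer assumption and its
    # multi-subunit analogue)
    declared = {tuple(sorted(t for t, _ in c.subunits)): c
                for c in complex_defs}
    complexes_used: dict[str, ComplexDefinition] = {}
    rxn_complex: dict[str, str] = {}
    for rxn_id, genes in sorted(links.items()):
        key = tuple(sorted(genes))
        if key in declared:
            cdef = declared[key]
        else:
            cid = "CPLX_" + "_".join(key)
            cdef = complexes_used.get(cid) or ComplexDefinition(
                cid, subunits=[(g, 1) for g in key])
        complexes_used[cdef.complex_id] = cdef
        rxn_complex[rxn_id] = cdef.complex_id
    for cdef in complexes_used.values():
        cdef.compute_mw(pep_mws)

    # kcat policy over the complexes the network actually uses
    kcats = apply_kcat_policy(kcat_entries, sorted(complexes_used))
    pc.enzyme_links = {
        rxn_id: (cid, kcats[cid]) for rxn_id, cid in rxn_complex.items()}

    # ribosome definition
    if not config.r_proteins:
        raise InputError("config.r_proteins must list the r-protein genes")
    rrna_genes = [r.locus_tag for r in records if r.feature_type == "rRNA"]
    if not rrna_genes:
        raise InputError("no rRNA genes in the annotation")
    ribosome = RibosomeDefinition(
        r_protein_genes=list(config.r_proteins),
        rrna_genes=rrna_genes,
        mw_r_proteins=sum(n * pep_mws[t] for t, n in config.r_proteins),
        mw_rRNA=sum(rna_mw(r.nucleotide_seq) for r in records
                    if r.feature_type == "rRNA"),
    )
    pc.ribosome = ribosome

    pc.up = derive_up_definition(records, config)

    build_expression_reactions(model, records, config, roles, pc, up=pc.up)
    build_assembly_and_dilution(model, list(complexes_used.values()),
                                ribosome, config, roles, pc)

    # glycogen synthesis: locate in GEM, add the storage-pool dilution
    if config.glycogen_rxn_id is not None:
        gly = model.reactions.get_by_id(config.glycogen_rxn_id)
        roles[gly.id] = "glycogen_synthesis"
        pc.glycogen_rxn = gly.id
        # the storage species is the product this reaction alone produces
        orphans = [m for m, c in gly.metabolites.items()
                   if c > 0 and len(m.reactions) == 1]
        if len(orphans) != 1:
            raise InputError(
                f"cannot identify the glycogen storage species of "
                f"{gly.id}; expected exactly one dead-end product")
        dil = Reaction("DIL_glycogen", name="glycogen dilution",
                       lower_bound=0.0, upper_bound=1000.0)
        dil.add_metabolites({orphans[0]: -1.0})
        model.add_reactions([dil])
        roles[dil.id] = "dilution"

    # free-amino-acid pool (used by the free-AA closure variant)
    if config.aa_species:
        faa = _expr_met(model, "free_aa_pool", "free amino-acid pool",
                        config.compartment)
        rxn = Reaction("FREEAA_SYN", name="free amino-acid accumulation",
                       lower_bound=0.0, upper_bound=1000.0)
        up_comp = pc.up.aa_composition
        total = sum(up_comp.values())
        stoich: dict = {faa: 1.0}
        for aa, count in sorted(up_comp.items()):
            met_id = config.aa_species.get(aa)
            if met_id:
                stoich[model.metabolites.get_by_id(met_id)] = -count / total
        rxn.add_metabolites(stoich)
        model.add_reactions([rxn])
        roles[rxn.id] = "free_aa_synthesis"
        pc.free_aa_rxn = rxn.id
        dil = Reaction("DIL_freeaa", name="free amino-acid dilution",
                       lower_bound=0.0, upper_bound=1000.0)
        dil.add_metabolites({faa: -1.0})
        model.add_reactions([dil])
        roles[dil.id] = "dilution"

    # weights table
    up_comp = pc.up.aa_composition
    total = sum(up_comp.values())
    free_aa_mw = sum((AA_RESIDUE_MASS[aa] + WATER_MASS) * c / total
                     for aa, c in up_comp.items())
    pc.weights = {
        "peptide": pep_mws,
        "complex": {cid: c.mw for cid, c in complexes_used.items()},
        "mrna": {r.locus_tag: rna_mw(r.nucleotide_seq) for r in records
                 if r.feature_type == "CDS" and not r.is_up},
        "trna": {r.locus_tag: rna_mw(r.nucleotide_seq) for r in records
                 if r.feature_type == "tRNA"},
        "r_proteins": ribosome.mw_r_proteins,
        "rrna": ribosome.mw_rRNA,
        "up": pc.up.mw,
        "up_mrna": pc.up.mrna_mw,
        "glycogen": config.glycogen_mw,
        "free_aa": free_aa_mw,
    }
    pc.weights["mrna"]["UP"] = pc.up.mrna_mw

    # record roles on the reactions for SBML round-tripping
    for rxn in model.reactions:
        rxn.notes["pcforge_role"] = roles[rxn.id]
    return pc


# ---------------------------------------------------------------------------
# Persistence: SBML + sidecar JSON
# ---------------------------------------------------------------------------

def save_pc_model(pc: PcModel, sbml_path: str | Path,
                  sidecar_path: str | Path) -> None:
    """Write the network as SBML L3/fbc plus a JSON sidecar holding the
    coupling metadata and weights."""
    cobra.io.write_sbml_model(pc.model, str(sbml_path))
    payload = {
        "roles": pc.roles,
        "enzyme_links": pc.enzyme_links,
        "weights": pc.weights,
        "translation_rxn": pc.translation_rxn,
        "transcription_rxn": pc.transcription_rxn,
        "mrna_degradation_rxn": pc.mrna_degradation_rxn,
        "mrna_dilution_rxn": pc.mrna_dilution_rxn,
        "trna_transcription_rxn": pc.trna_transcription_rxn,
        "trna_charging_rxn": pc.trna_charging_rxn,
        "trna_class": pc.trna_class,
        "complex_formation_rxn": pc.complex_formation_rxn,
        "peptide_length": pc.peptide_length,
        "ribosome_synthesis_rxn": pc.ribosome_synthesis_rxn,
        "up_translation_rxn": pc.up_translation_rxn,
        "glycogen_rxn": pc.glycogen_rxn,
        "free_aa_rxn": pc.free_aa_rxn,
        "biomass_residual_rxn": pc.biomass_residual_rxn,
        "gam_rxn": pc.gam_rxn,
        "ngam_rxn": pc.ngam_rxn,
        "built_gam": pc.built_gam,
        "ribosome": asdict(pc.ribosome) if pc.ribosome else None,
        "up": asdict(pc.up) if pc.up else None,
    }
    with open(sidecar_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_pc_model(sbml_path: str | Path, sidecar_path: str | Path) -> PcModel:
    model = cobra.io.read_sbml_model(str(sbml_path))
    with open(sidecar_path) as fh:
        payload = json.load(fh)
    pc = PcModel(model=model, roles=payload["roles"],
                 enzyme_links={k: tuple(v) for k, v in
                               payload["enzyme_links"].items()},
                 weights=payload["weights"], genes={})
    for key in ("translation_rxn", "transcription_rxn",
                "mrna_degradation_rxn", "mrna_dilution_rxn",
                "trna_transcription_rxn", "trna_charging_rxn", "trna_class",
                "complex_formation_rxn", "peptide_length",
                "ribosome_synthesis_rxn", "up_translation_rxn",
                "glycogen_rxn", "free_aa_rxn", "biomass_residual_rxn",
                "gam_rxn", "ngam_rxn", "built_gam"):
        setattr(pc, key, payload[key])
    if payload["ribosome"]:
        rb = payload["ribosome"]
        pc.ribosome = RibosomeDefinition(
            r_protein_genes=[tuple(x) for x in rb["r_protein_genes"]],
            rrna_genes=rb["rrna_genes"],
            mw_r_proteins=rb["mw_r_proteins"], mw_rRNA=rb["mw_rRNA"])
    if payload["up"]:
        pc.up = UPDefinition(**payload["up"])
    return pc
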