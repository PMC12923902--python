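"""Miniature test organism and its exact-arithmetic analytic oracle.

The generator emits a self-consistent fixture bundle — a small GEM (SBML),
a gene-annotation table, a turnover-number table, a complex-stoichiometry
table and a condition file — in exactly the formats real inputs use, so
the whole pipeline is exercisable without any download.  The chemistry is
schematic (a substrate S is converted to ATP, amino acids, nucleotides,
glycogen and a residual-biomass precursor; a waste product W is excreted):
it tests the formulation, not the biology.

The organism (fixed topology, tunable rates/lengths):

* six protein-coding genes over the two-letter amino-acid alphabet {G, A}:
  two ribosomal proteins (``rps1``, ``rpl2``), a two-subunit uptake complex
  (``uptA`` x2 + ``uptB``, an "and" GPR), and an isozyme pair for the
  catabolic reaction (``catA`` or ``catB``, strictly ordered kcats so the
  uptake-minimizing vertex is unique);
* one tRNA gene per amino-acid class and two rRNA genes;
* one reversible metabolic reaction (nucleoside-diphosphate kinase).

``analytic_oracle`` solves the complete steady state at one growth rate by
writing out every species balance, capacity/coupling constraint and mass
equation in exact rational arithmetic and eliminating — a code path fully
independent of the reconstruction builder and the LP solver.  The active
set at the uptake-minimizing vertex (UP floor tight, losing isozyme idle,
substrate never secreted) is fixed by construction of the toy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import cobra
import numpy as np
import sympy
import yaml
from cobra import Metabolite, Reaction

from .annotation_io import (
    AA_RESIDUE_MASS,
    NMP_MASS,
    WATER_MASS,
    ComplexDefinition,
    GeneRecord,
    KcatEntry,
)
from .constraints import ConditionParameters
from .reconstruction import ExpressionConfig

__all__ = [
    "ToyOrganismSpec",
    "ToyBundle",
    "generate_toy_organism",
    "toy_condition",
    "analytic_oracle",
    "oracle_mu_max",
]


@dataclass
class ToyOrganismSpec:
    """Tunable parameters of the fixture organism."""

    seed: int = 1
    peptide_lengths: dict = field(default_factory=lambda: {
        "rps1": 40, "rpl2": 60, "uptA": 40, "uptB": 60,
        "catA": 100, "catB": 100})
    kcat_uptake: float = 0.05     # s^-1, uptake complex (curated-low, keep_raw)
    kcat_cat_fast: float = 0.05   # s^-1, isozyme A
    kcat_cat_slow: float = 0.02   # s^-1, isozyme B
    trna_length: int = 75         # nt
    rrna_lengths: dict = field(default_factory=lambda: {"rrs": 120, "rrl": 230})
    closure_total: float = 0.93
    residual_mw: float = 350.0    # g/mmol of the residual-biomass precursor
    substrate_uptake_max: float = 10.0  # mmol/gDW/h


@dataclass
class ToyBundle:
    """Everything the pipeline needs, in memory and/or on disk."""

    spec: ToyOrganismSpec
    gem: cobra.Model
    records: list
    kcat_entries: list
    complex_defs: list
    expr_config: ExpressionConfig
    condition: ConditionParameters


def _random_seq(rng, alphabet: str, n: int) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def toy_condition(spec: ToyOrganismSpec, mu: float = 0.05,
                  **overrides) -> ConditionParameters:
    base = dict(
        mu=mu, gam=25.0, ngam=1.0, up_ratio_c=0.44,
        kcat_ribo_condition="formate",
        medium={"EX_S": (0.0, spec.substrate_uptake_max)},
        limiting_exchange="EX_S",
        closure_total=spec.closure_total,
    )
    base.update(overrides)
    return ConditionParameters(**base)


def generate_toy_organism(
    spec: ToyOrganismSpec | None = None,
    outdir: str | Path | None = None,
) -> ToyBundle:
    """Build the fixture bundle; deterministic for a given seed.

    When ``outdir`` is given the bundle is also written as
    ``toy_gem.xml``, ``toy_annotation.tsv``, ``toy_kcats.tsv``,
    ``toy_complexes.tsv`` and ``toy_condition.yaml``.
    """
    spec = spec or ToyOrganismSpec()
    rng = np.random.default_rng(spec.seed)

    # --- annotation -----------------------------------------------------
    records: list[GeneRecord] = []
    pos = 1
    for tag in sorted(spec.peptide_lengths):
        length = spec.peptide_lengths[tag]
        nt = _random_seq(rng, "ACGT", 3 * length + 3)
        pep = _random_seq(rng, "GA", length)
        records.append(GeneRecord(
            locus_tag=tag, feature_type="CDS", start=pos,
            end=pos + len(nt) - 1, strand="+",
            nucleotide_seq=nt, peptide_seq=pep))
        pos += len(nt) + 10
    for aa in ("G", "A"):
        nt = _random_seq(rng, "ACGT", spec.trna_length)
        records.append(GeneRecord(
            locus_tag=f"trn{aa}", feature_type="tRNA", start=pos,
            end=pos + len(nt) - 1, strand="-", nucleotide_seq=nt,
            aa_class=aa))
        pos += len(nt) + 10
    for tag in sorted(spec.rrna_lengths):
        nt = _random_seq(rng, "ACGT", spec.rrna_lengths[tag])
        records.append(GeneRecord(
            locus_tag=tag, feature_type="rRNA", start=pos,
            end=pos + len(nt) - 1, strand="+", nucleotide_seq=nt))
        pos += len(nt) + 10

    # --- metabolic network ---------------------------------------------
    gem = cobra.Model("toygem")
    mets = {}
    for mid, compartment in [
        ("S_e", "e"), ("W_e", "e"), ("S_c", "c"), ("atp_c", "c"),
        ("adp_c", "c"), ("amp_c", "c"), ("gtp_c", "c"), ("gdp_c", "c"),
        ("ntp_c", "c"), ("nmp_c", "c"), ("aaG_c", "c"), ("aaA_c", "c"),
        ("glyc_c", "c"), ("res_c", "c"), ("protein_b_c", "c"),
        ("rna_b_c", "c"),
    ]:
        mets[mid] = Metabolite(mid, compartment=compartment)
    gem.add_metabolites(list(mets.values()))

    def rxn(rid, stoich, lb=0.0, ub=1000.0, gpr=""):
        r = Reaction(rid, lower_bound=lb, upper_bound=ub)
        r.add_metabolites({mets[m]: c for m, c in stoich.items()})
        gem.add_reactions([r])
        if gpr:
            r.gene_reaction_rule = gpr
        return r

    rxn("EX_S", {"S_e": -1}, lb=-spec.substrate_uptake_max)
    rxn("EX_W", {"W_e": -1})
    rxn("R_upt", {"S_e": -1, "S_c": 1}, gpr="uptA and uptB")
    rxn("R_cat", {"S_c": -1, "adp_c": -2, "atp_c": 2, "W_e": 1},
        gpr="catA or catB")
    rxn("R_ndk", {"atp_c": -1, "gdp_c": -1, "adp_c": 1, "gtp_c": 1},
        lb=-1000.0)  # the reversible reaction
    rxn("R_ak", {"atp_c": -1, "amp_c": -1, "adp_c": 2})
    rxn("R_aaG", {"S_c": -1, "atp_c": -1, "aaG_c": 1, "adp_c": 1})
    rxn("R_aaA", {"S_c": -1, "atp_c": -1, "aaA_c": 1, "adp_c": 1})
    rxn("R_ntp", {"S_c": -1, "atp_c": -2, "ntp_c": 1, "adp_c": 2})
    rxn("R_nmp", {"nmp_c": -1, "atp_c": -1, "ntp_c": 1, "adp_c": 1})
    rxn("R_glyc", {"S_c": -1, "atp_c": -1, "glyc_c": 1, "adp_c": 1})
    rxn("R_res", {"S_c": -1, "atp_c": -1, "res_c": 1, "adp_c": 1})
    rxn("BIOMASS_toy",
        {"res_c": -0.2, "protein_b_c": -0.4, "rna_b_c": -0.1,
         "atp_c": -30.0, "adp_c": 30.0})

    # --- tables ---------------------------------------------------------
    kcat_entries = [
        KcatEntry("R_upt", "CPLX_upt", spec.kcat_uptake,
                  tier="target_species", keep_raw=True),
        KcatEntry("R_cat", "CPLX_catA", spec.kcat_cat_fast,
                  tier="target_species", keep_raw=True),
        KcatEntry("R_cat", "CPLX_catB", spec.kcat_cat_slow,
                  tier="related_methanogen", keep_raw=True),
    ]
    complex_defs = [
        ComplexDefinition("CPLX_upt", subunits=[("uptA", 2), ("uptB", 1)]),
    ]
    expr_config = ExpressionConfig(
        species={"atp": "atp_c", "adp": "adp_c", "amp": "amp_c",
                 "gtp": "gtp_c", "gdp": "gdp_c", "ntp": "ntp_c",
                 "nmp": "nmp_c"},
        aa_species={"G": "aaG_c", "A": "aaA_c"},
        r_proteins=[("rps1", 1), ("rpl2", 1)],
        biomass_rxn_id="BIOMASS_toy",
        protein_components=["protein_b_c"],
        rna_components=["rna_b_c"],
        energy_components=["atp_c", "adp_c"],
        glycogen_rxn_id="R_glyc",
        metabolite_mw={"res_c": spec.residual_mw},
    )
    condition = toy_condition(spec)

    bundle = ToyBundle(spec=spec, gem=gem, records=records,
                       kcat_entries=kcat_entries, complex_defs=complex_defs,
                       expr_config=expr_config, condition=condition)
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: ToyBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cobra.io.write_sbml_model(bundle.gem, str(outdir / "toy_gem.xml"))
    lines = ["locus_tag\ttype\tstart\tend\tstrand\tseq\tpeptide_seq"
             "\taa_class\tis_up"]
    for r in bundle.records:
        lines.append("\t".join([
            r.locus_tag, r.feature_type, str(r.start), str(r.end), r.strand,
            r.nucleotide_seq, r.peptide_seq, r.aa_class,
            "true" if r.is_up else "false"]))
    (outdir / "toy_annotation.tsv").write_text("\n".join(lines) + "\n")
    lines = ["reaction_id\tenzyme_id\tkcat_per_s\ttier\tkeep_raw"]
    for e in bundle.kcat_entries:
        lines.append(f"{e.reaction_id}\t{e.enzyme_id}\t{e.kcat}\t{e.tier}"
                     f"\t{str(e.keep_raw).lower()}")
    (outdir / "toy_kcats.tsv").write_text("\n".join(lines) + "\n")
    lines = ["complex_id\tlocus_tag\tcopies"]
    for c in bundle.complex_defs:
        for tag, n in c.subunits:
            lines.append(f"{c.complex_id}\t{tag}\t{n}")
    (outdir / "toy_complexes.tsv").write_text("\n".join(lines) + "\n")
    from dataclasses import asdict

    cfg = asdict(bundle.expr_config)
    cfg["r_proteins"] = [list(x) for x in cfg["r_proteins"]]
    (outdir / "toy_build.yaml").write_text(yaml.safe_dump(cfg))
    cond = bundle.condition
    (outdir / "toy_condition.yaml").write_text(yaml.safe_dump({
        "mu": cond.mu, "gam": cond.gam, "ngam": cond.ngam,
        "up_ratio_c": cond.up_ratio_c,
        "kcat_ribo_condition": cond.kcat_ribo_condition,
        "medium": {k: list(v) for k, v in cond.medium.items()},
        "limiting_exchange": cond.limiting_exchange,
        "closure_total": cond.closure_total,
        "closure_mode": cond.closure_mode,
    }))


# ===========================================================================
# Analytic oracle
# ===========================================================================

def _Q(x) -> sympy.Rational:
    """Exact rational of a binary float (no decimal re-rounding)."""
    return sympy.Rational(Fraction(float(x)))


def analytic_oracle(
    bundle: ToyBundle,
    mu: float,
    params: ConditionParameters | None = None,
) -> dict[str, Fraction]:
    """Exact steady-state solution of the toy model at growth rate ``mu``.

    Restates every species balance, capacity/coupling constraint and mass
    equation of the toy in rational arithmetic, fixes the active set of the
    uptake-minimizing vertex, and solves the resulting linear system by
    elimination.  Returns variable name -> exact value for every flux,
    ribosome-allocation and mass variable of the corresponding LP.

    Raises if the system is singular or not uniquely determined.
    """
    params = params or bundle.condition.at_mu(mu)
    if abs(params.mu - mu) > 0:
        params = params.at_mu(mu)
    spec = bundle.spec
    mode = params.closure_mode

    MU = _Q(mu)
    kdeg, kmrna, ktrna = _Q(params.k_deg), _Q(params.k_mrna), _Q(params.k_trna)
    kribo = _Q(params.resolved_kcat_ribo())
    c_up = _Q(params.up_ratio_c)
    closure = _Q(params.closure_total)

    # --- gene data, restated from the records ---------------------------
    cds = {r.locus_tag: r for r in bundle.records if r.feature_type == "CDS"}
    trnas = {r.aa_class: r for r in bundle.records if r.feature_type == "tRNA"}
    rrnas = [r for r in bundle.records if r.feature_type == "rRNA"]

    def aa_counts(seq: str) -> dict[str, int]:
        return {a: seq.count(a) for a in sorted(set(seq))}

    # pooled-composition unspecific protein (same pooling rule, re-derived)
    pool_aa: dict[str, int] = {}
    pool_nt: dict[str, int] = {}
    lengths = []
    for r in cds.values():
        for a in r.peptide_seq:
            pool_aa[a] = pool_aa.get(a, 0) + 1
        for n in r.nucleotide_seq.upper().replace("T", "U"):
            pool_nt[n] = pool_nt.get(n, 0) + 1
        lengths.append(len(r.peptide_seq))
    up_len = sympy.Integer(round(sum(lengths) / len(lengths)))
    tot_aa = sum(pool_aa.values())
    up_aa = {a: up_len * n / sympy.Integer(tot_aa)
             for a, n in sorted(pool_aa.items())}
    tot_nt = sum(pool_nt.values())
    up_nt_len = 3 * up_len
    up_nt = {n: up_nt_len * k / sympy.Integer(tot_nt)
             for n, k in sorted(pool_nt.items())}

    W = _Q(WATER_MASS)
    aa_mass = {a: _Q(m) for a, m in AA_RESIDUE_MASS.items()}
    nmp_mass = {n: _Q(m) for n, m in NMP_MASS.items()}

    def pep_mw(seq: str):
        return sum(aa_mass[a] for a in seq) + W

    def rna_mw_(seq: str):
        s = seq.upper().replace("T", "U")
        return sum(nmp_mass[n] for n in s) - (len(s) - 1) * W

    mw_pep = {t: pep_mw(r.peptide_seq) for t, r in cds.items()}
    mw_mrna = {t: rna_mw_(r.nucleotide_seq) for t, r in cds.items()}
    mw_trna = {a: rna_mw_(r.nucleotide_seq) for a, r in trnas.items()}
    mw_rrna_total = sum(rna_mw_(r.nucleotide_seq) for r in rrnas)
    mw_up = sum(k * aa_mass[a] for a, k in up_aa.items()) + W
    mw_up_mrna = sum(k * nmp_mass[n] for n, k in up_nt.items()) \
        - (up_nt_len - 1) * W
    mw_rproteins = mw_pep["rps1"] + mw_pep["rpl2"]
    mw_gly = _Q(bundle.expr_config.glycogen_mw)
    tot = sum(up_aa.values())
    mw_free_aa = sum((aa_mass[a] + W) * k / tot for a, k in up_aa.items())

    # --- symbols and equation accumulators ------------------------------
    cds_tags = sorted(cds)            # catA, catB, rps1, rpl2, uptA, uptB
    pep_tags = cds_tags + ["UP"]
    var_names = (
        ["EX_S_fwd", "EX_S_rev", "EX_W", "R_upt", "R_cat_iso1", "R_cat_iso2",
         "R_ndk_fwd", "R_ndk_rev", "R_ak", "R_aaG", "R_aaA", "R_ntp",
         "R_nmp", "R_glyc", "R_res", "BIOMASS_toy", "GAM_PC", "NGAM_PC",
         "FORM_ribosome", "DIL_ribosome", "DIL_up", "DIL_glycogen",
         "FREEAA_SYN", "DIL_freeaa"]
        + [f"TRSC_{t}" for t in pep_tags]
        + [f"DEG_{t}" for t in pep_tags]
        + [f"DIL_mrna_{t}" for t in pep_tags]
        + [f"TRANS_{t}" for t in pep_tags]
        + [f"eR_{t}" for t in pep_tags]
        + [f"TRSC_trn{a}" for a in sorted(trnas)]
        + [f"CHARGE_{a}" for a in sorted(trnas)]
        + [f"DIL_trna_{a}" for a in sorted(trnas)]
        + [f"TRSC_{r.locus_tag}" for r in rrnas]
        + ["FORM_CPLX_upt", "DIL_cplx_CPLX_upt", "FORM_CPLX_catA",
           "DIL_cplx_CPLX_catA", "FORM_CPLX_catB", "DIL_cplx_CPLX_catB"]
        + ["TotalProtein", "rRNA", "mRNA", "tRNA", "RNA", "Glycogen",
           "FreeAA"]
    )
    sym = {n: sympy.Symbol(n) for n in var_names}
    balances: dict[str, sympy.Expr] = {}
    equations: list[sympy.Expr] = []

    def add(species: str, var: str, coef) -> None:
        balances[species] = balances.get(species, sympy.Integer(0)) \
            + coef * sym[var]

    cfg = bundle.expr_config  # template energy costs

    # metabolic network (restated)
    add("S_e", "EX_S_rev", 1); add("S_e", "EX_S_fwd", -1)
    add("S_e", "R_upt", -1); add("S_c", "R_upt", 1)
    for iso in ("R_cat_iso1", "R_cat_iso2"):
        add("S_c", iso, -1); add("adp", iso, -2)
        add("atp", iso, 2); add("W_e", iso, 1)
    add("W_e", "EX_W", -1)
    add("atp", "R_ndk_fwd", -1); add("gdp", "R_ndk_fwd", -1)
    add("adp", "R_ndk_fwd", 1); add("gtp", "R_ndk_fwd", 1)
    add("atp", "R_ndk_rev", 1); add("gdp", "R_ndk_rev", 1)
    add("adp", "R_ndk_rev", -1); add("gtp", "R_ndk_rev", -1)
    add("atp", "R_ak", -1); add("amp", "R_ak", -1); add("adp", "R_ak", 2)
    for r, product in (("R_aaG", "aaG"), ("R_aaA", "aaA")):
        add("S_c", r, -1); add("atp", r, -1)
        add(product, r, 1); add("adp", r, 1)
    add("S_c", "R_ntp", -1); add("atp", "R_ntp", -2)
    add("ntp", "R_ntp", 1); add("adp", "R_ntp", 2)
    add("nmp", "R_nmp", -1); add("atp", "R_nmp", -1)
    add("ntp", "R_nmp", 1); add("adp", "R_nmp", 1)
    add("S_c", "R_glyc", -1); add("atp", "R_glyc", -1)
    add("glyc", "R_glyc", 1); add("adp", "R_glyc", 1)
    add("S_c", "R_res", -1); add("atp", "R_res", -1)
    add("res", "R_res", 1); add("adp", "R_res", 1)
    add("res", "BIOMASS_toy", _Q(-0.2))
    gam_coef = _Q(bundle.expr_config.gam)
    add("atp", "GAM_PC", -gam_coef); add("adp", "GAM_PC", gam_coef)
    add("atp", "NGAM_PC", -1); add("adp", "NGAM_PC", 1)

    # expression machinery (independently templated)
    init_atp = _Q(cfg.atp_transcription_init)
    gtp_el, gtp_init = _Q(cfg.gtp_per_elongation), _Q(cfg.gtp_initiation)
    chg_atp = _Q(cfg.atp_per_charging)

    def transcription(var: str, n_nt, product: str) -> None:
        add("ntp", var, -_Q(cfg.ntp_per_nt) * n_nt)
        add("atp", var, -init_atp); add("adp", var, init_atp)
        add(product, var, 1)

    for tag in pep_tags:
        if tag == "UP":
            comps = {a: k for a, k in up_aa.items()}
            n_nt, length = up_nt_len, up_len
            pep_species = "up_protein"
        else:
            comps = aa_counts(cds[tag].peptide_seq)
            n_nt = len(cds[tag].nucleotide_seq)
            length = len(cds[tag].peptide_seq)
            pep_species = f"pep_{tag}"
        transcription(f"TRSC_{tag}", n_nt, f"mrna_{tag}")
        add(f"mrna_{tag}", f"DEG_{tag}", -1); add("nmp", f"DEG_{tag}", n_nt)
        add(f"mrna_{tag}", f"DIL_mrna_{tag}", -1)
        tr = f"TRANS_{tag}"
        gtp_cost = gtp_el * length + gtp_init
        add("gtp", tr, -gtp_cost); add("gdp", tr, gtp_cost)
        for a, k in sorted(comps.items()):
            add(f"trna_charged_{a}", tr, -k); add(f"trna_{a}", tr, k)
        add(pep_species, tr, 1)
        # capacity and coupling rows
        equations.append(sym[tr] - kribo / length * sym[f"eR_{tag}"])
        equations.append(sym[tr] - kmrna / (kdeg + MU) * sym[f"TRSC_{tag}"])
        equations.append(sym[f"DEG_{tag}"]
                         - kdeg / (kdeg + MU) * sym[f"TRSC_{tag}"])

    for a in sorted(trnas):
        transcription(f"TRSC_trn{a}", len(trnas[a].nucleotide_seq),
                      f"trna_{a}")
        chg = f"CHARGE_{a}"
        add(f"trna_{a}", chg, -1); add(f"aa{a}", chg, -1)
        add("atp", chg, -chg_atp); add("amp", chg, chg_atp)
        add(f"trna_charged_{a}", chg, 1)
        add(f"trna_{a}", f"DIL_trna_{a}", -1)
        equations.append(sym[chg] - ktrna / MU * sym[f"TRSC_trn{a}"])

    for r in rrnas:
        transcription(f"TRSC_{r.locus_tag}", len(r.nucleotide_seq),
                      f"rrna_{r.locus_tag}")

    # ribosome assembly and dilution
    asm_gtp = _Q(cfg.ribosome_assembly_gtp)
    add("pep_rps1", "FORM_ribosome", -1)
    add("pep_rpl2", "FORM_ribosome", -1)
    for r in rrnas:
        add(f"rrna_{r.locus_tag}", "FORM_ribosome", -1)
    add("gtp", "FORM_ribosome", -asm_gtp); add("gdp", "FORM_ribosome", asm_gtp)
    add("ribosome", "FORM_ribosome", 1)
    add("ribosome", "DIL_ribosome", -1)
    add("up_protein", "DIL_up", -1)
    equations.append(
        sum(sym[f"eR_{t}"] for t in pep_tags)
        - sym["FORM_ribosome"] / MU)

    # complexes
    add("pep_uptA", "FORM_CPLX_upt", -2); add("pep_uptB", "FORM_CPLX_upt", -1)
    add("cplx_upt", "FORM_CPLX_upt", 1); add("cplx_upt", "DIL_cplx_CPLX_upt", -1)
    add("pep_catA", "FORM_CPLX_catA", -1)
    add("cplx_catA", "FORM_CPLX_catA", 1)
    add("cplx_catA", "DIL_cplx_CPLX_catA", -1)
    add("pep_catB", "FORM_CPLX_catB", -1)
    add("cplx_catB", "FORM_CPLX_catB", 1)
    add("cplx_catB", "DIL_cplx_CPLX_catB", -1)
    equations.append(sym["R_upt"]
                     - _Q(spec.kcat_uptake) * 3600 / MU * sym["FORM_CPLX_upt"])
    equations.append(sym["R_cat_iso1"]
                     - _Q(spec.kcat_cat_fast) * 3600 / MU
                     * sym["FORM_CPLX_catA"])
    equations.append(sym["R_cat_iso2"]
                     - _Q(spec.kcat_cat_slow) * 3600 / MU
                     * sym["FORM_CPLX_catB"])

    # glycogen dilution and free-AA pool
    add("glyc", "DIL_glycogen", -1)
    tot = sum(up_aa.values())
    for a, k in sorted(up_aa.items()):
        add(f"aa{a}", "FREEAA_SYN", -k / tot)
    add("faa", "FREEAA_SYN", 1)
    add("faa", "DIL_freeaa", -1)

    # mass-accounting equations
    equations.append(
        sym["FORM_CPLX_upt"] / MU * (2 * mw_pep["uptA"] + mw_pep["uptB"]) / 1000
        + sym["FORM_CPLX_catA"] / MU * mw_pep["catA"] / 1000
        + sym["FORM_CPLX_catB"] / MU * mw_pep["catB"] / 1000
        + sym["FORM_ribosome"] / MU * mw_rproteins / 1000
        + sym["TRANS_UP"] / MU * mw_up / 1000
        - sym["TotalProtein"])
    equations.append(sym["FORM_ribosome"] / MU * mw_rrna_total / 1000
                     - sym["rRNA"])
    equations.append(
        sum(sym[f"TRSC_{t}"] * (mw_up_mrna if t == "UP" else mw_mrna[t])
            / 1000 / (MU + kdeg) for t in pep_tags)
        - sym["mRNA"])
    equations.append(
        sum(sym[f"TRSC_trn{a}"] * mw_trna[a] / 1000 / MU
            for a in sorted(trnas))
        - sym["tRNA"])
    equations.append(sym["rRNA"] + sym["mRNA"] + sym["tRNA"] - sym["RNA"])
    equations.append(sym["R_glyc"] / MU * mw_gly / 1000 - sym["Glycogen"])
    equations.append(sym["FREEAA_SYN"] / MU * mw_free_aa / 1000
                     - sym["FreeAA"])

    # fixed/active constraints at the uptake-minimizing vertex
    equations.append(sym["BIOMASS_toy"] - MU)
    equations.append(sym["GAM_PC"] - MU * _Q(params.gam) / gam_coef)
    equations.append(sym["NGAM_PC"] - _Q(params.ngam))
    equations.append(sym["EX_S_fwd"])     # no substrate secretion
    equations.append(sym["R_ndk_rev"])    # net GTP demand is positive
    equations.append(sym["R_cat_iso2"])   # strictly costlier isozyme idle
    up_mass = sym["TRANS_UP"] / MU * mw_up / 1000

    if mode == "glycogen":
        equations.append(up_mass - c_up * sym["TotalProtein"])  # floor tight
        equations.append(sym["FREEAA_SYN"])
        equations.append(sym["TotalProtein"] + sym["RNA"] + sym["Glycogen"]
                         - closure)
    elif mode == "glycogen_capped":
        equations.append(sym["Glycogen"] - _Q(params.glycogen_cap))
        equations.append(sym["FREEAA_SYN"])
        equations.append(sym["TotalProtein"] + sym["RNA"] + sym["Glycogen"]
                         - closure)
    elif mode == "free_amino_acids":
        equations.append(up_mass - c_up * sym["TotalProtein"])
        equations.append(sym["R_glyc"])
        equations.append(sym["TotalProtein"] + sym["RNA"] + sym["FreeAA"]
                         - closure)
    else:
        raise ValueError(f"unknown closure mode {mode!r}")

    equations.extend(balances.values())

    symbols = [sym[n] for n in var_names]
    solset = sympy.linsolve(equations, symbols)
    if not solset:
        raise ValueError("toy steady-state system is infeasible/singular")
    (solution,) = solset
    free = set().union(*(v.free_symbols for v in solution)) if solution else set()
    if free:
        raise ValueError(
            f"toy steady-state system underdetermined; free: {free}")
    out = {}
    for name, value in zip(var_names, solution):
        q = sympy.Rational(value)
        out[name] = Fraction(int(q.p), int(q.q))
    return out


def oracle_mu_max(bundle: ToyBundle,
                  params: ConditionParameters | None = None,
                  lo: float = 1e-3, hi: float = 0.5,
                  tol: float = 1e-3) -> float:
    """Closure-saturation growth rate of the toy.

    The toy's steady state is a unique vertex, so the LP is feasible at mu
    exactly when the oracle's solution vector is non-negative; as mu grows
    the glycogen mass is the first variable to cross zero (the closure
    saturates).  Bisection on that sign gives the analytic µmax."""
    params = params or bundle.condition

    def feasible(mu: float) -> bool:
        sol = analytic_oracle(bundle, mu, params)
        return min(sol.values()) >= 0

    if not feasible(lo):
        return 0.0
    if feasible(hi):
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    return lo
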