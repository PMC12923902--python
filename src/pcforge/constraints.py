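"""Assembly and solution of the growth-rate-parameterized linear program.

At a fixed specific growth rate mu the proteome-constrained model is a
sparse LP over non-negative fluxes v, ribosome-allocation variables eR_i
and macromolecular mass variables, with the constraint families:

* mass balance            S.v = 0
* enzyme capacity         v_i - (kcat/mu) v_e = 0 per enzyme-linked reaction
* ribosome capacity       v_trans,i - (kcat_ribo/len_i) eR_i = 0 and
                          sum_i eR_i - (1/mu) v_syn,ribo = 0
* UP floor                UP mass >= c (relative to TotalProtein by default)
* mRNA coupling           v_trans,i - (k_mRNA/(k_deg+mu)) v_transcription,i = 0
* tRNA coupling           v_charging,i - (k_tRNA/mu) v_transcription,tRNA,i = 0
* total proteome          sum (v_e/mu)(mw_e/1000) + ribosomal + UP terms
                          = TotalProtein
* RNA mass                rRNA, mRNA (with mu+k_deg denominator), tRNA rows
                          and their sum
* glycogen mass           (v_glycogen/mu)(mw/1000) = Glycogen
* closure                 TotalProtein + RNA + Glycogen = 0.93 (or the
                          capped-glycogen / free-amino-acid variants)

The objective is minimal uptake of the limiting nutrient, matching
chemostat physiology.  Units: fluxes mmol gDW^-1 h^-1, masses g gDW^-1,
molecular weights g/mmol (hence the /1000 factors); kcats are stored in
s^-1 and converted to h^-1 (x3600) exactly once, here.

Rows are equilibrated (max-abs scaling) before the solve because the
coefficients span many orders of magnitude; the solver is HiGHS via
scipy.optimize.linprog with tightened feasibility tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix

from .calibration import kcat_ribo_schedule
from .reconstruction import PcModel

__all__ = [
    "ConditionParameters",
    "PcLinearProgram",
    "LPSolution",
    "assemble_lp",
    "add_capacity_constraints",
    "add_expression_couplings",
    "add_mass_accounting",
    "cap_protein_fraction",
    "solve_min_uptake",
]

MIN_MU = 1e-4  # constraints divide by mu; below this the LP is ill-posed

MASS_VARS = ("TotalProtein", "rRNA", "mRNA", "tRNA", "RNA", "Glycogen",
             "FreeAA")


@dataclass
class ConditionParameters:
    """Everything condition-specific the LP needs at one growth rate."""

    mu: float = 0.1                 # h^-1
    gam: float = 25.0               # mmol ATP / gDW
    ngam: float = 1.0               # mmol ATP / gDW / h
    up_ratio_c: float = 0.44        # UP floor, fraction of total protein
    kcat_ribo: float | None = None  # aa/h; overrides the schedule if set
    kcat_ribo_condition: str = "formate"  # schedule used when kcat_ribo is None
    k_deg: float = 6.93             # mRNA degradation, h^-1 (10-min half-life)
    k_mrna: float = 2700.0          # mRNA catalytic rate, h^-1
    k_trna: float = 3600.0          # tRNA catalytic rate, h^-1
    medium: dict = field(default_factory=dict)  # exchange -> (uptake lb, ub)
    limiting_exchange: str = ""
    closure_total: float = 0.93     # gDW
    closure_mode: str = "glycogen"  # | glycogen_capped | free_amino_acids
    glycogen_cap: float = 0.02      # g/gDW, capped variant
    up_floor_mode: str = "relative"  # | absolute

    def __post_init__(self) -> None:
        if self.mu < MIN_MU:
            raise ValueError(f"mu must be >= {MIN_MU} h^-1, got {self.mu}")
        if not (0 < self.closure_total <= 1):
            raise ValueError("closure_total must lie in (0, 1]")
        if not (0 <= self.up_ratio_c < 1):
            raise ValueError("up_ratio_c must lie in [0, 1)")

    def resolved_kcat_ribo(self) -> float:
        if self.kcat_ribo is not None:
            return self.kcat_ribo
        return kcat_ribo_schedule(self.mu, self.kcat_ribo_condition)

    def at_mu(self, mu: float) -> "ConditionParameters":
        return replace(self, mu=mu)


@dataclass
class LPRow:
    name: str
    tag: str            # constraint family
    coefs: dict         # variable name -> coefficient
    sense: str          # '=', '<=', '>='
    rhs: float


@dataclass
class PcLinearProgram:
    """Sparse LP: named non-negative variables, tagged rows, linear
    objective (minimization)."""

    var_names: list = field(default_factory=list)
    var_index: dict = field(default_factory=dict)
    lb: list = field(default_factory=list)
    ub: list = field(default_factory=list)
    objective: dict = field(default_factory=dict)  # var -> coefficient
    rows: list = field(default_factory=list)

    def add_var(self, name: str, lb: float = 0.0, ub: float = np.inf) -> None:
        if name in self.var_index:
            raise ValueError(f"duplicate variable {name}")
        self.var_index[name] = len(self.var_names)
        self.var_names.append(name)
        self.lb.append(lb)
        self.ub.append(ub)

    def set_bounds(self, name: str, lb: float, ub: float) -> None:
        i = self.var_index[name]
        self.lb[i], self.ub[i] = lb, ub

    def add_row(self, name: str, tag: str, coefs: dict, sense: str,
                rhs: float = 0.0) -> None:
        self.rows.append(LPRow(name, tag, dict(coefs), sense, rhs))

    # ---- export for cross-solver debugging ---------------------------
    def to_lp_format(self, path: str | Path) -> None:
        """Write the program in CPLEX LP text format."""
        def term(coefs):
            parts = []
            for var, c in coefs.items():
                parts.append(f"{'+' if c >= 0 else '-'} {abs(c):.17g} {var}")
            return " ".join(parts) or "0 x0"

        lines = ["Minimize", " obj: " + term(self.objective), "Subject To"]
        for i, row in enumerate(self.rows):
            op = {"=": "=", "<=": "<=", ">=": ">="}[row.sense]
            lines.append(f" r{i}_{row.name}: {term(row.coefs)} {op} {row.rhs:.17g}")
        lines.append("Bounds")
        for name, lo, hi in zip(self.var_names, self.lb, self.ub):
            hi_s = "+inf" if np.isinf(hi) else f"{hi:.17g}"
            lines.append(f" {lo:.17g} <= {name} <= {hi_s}")
        lines.append("End")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class LPSolution:
    status: str                      # optimal | infeasible | error
    objective: float = float("nan")
    values: dict = field(default_factory=dict)
    max_residual: float = float("nan")  # worst |Ax-b| over equality rows

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _base_lp(pc: PcModel, params: ConditionParameters) -> PcLinearProgram:
    """Flux variables with bounds, mass variables, and the S.v = 0 rows."""
    lp = PcLinearProgram()
    mu = params.mu

    for rxn in pc.model.reactions:
        lp.add_var(rxn.id, max(rxn.lower_bound, 0.0), rxn.upper_bound)

    # condition-dependent fixed fluxes
    if pc.biomass_residual_rxn:
        lp.set_bounds(pc.biomass_residual_rxn, mu, mu)
    if pc.gam_rxn:
        gam_flux = mu * params.gam / pc.built_gam
        lp.set_bounds(pc.gam_rxn, gam_flux, gam_flux)
    if pc.ngam_rxn:
        lp.set_bounds(pc.ngam_rxn, params.ngam, np.inf)

    # medium: bounds act on the uptake-direction variable of each exchange
    for base_id, (lo, hi) in params.medium.items():
        fwd, rev = pc.exchange_pair(base_id)
        if rev is None:
            raise ValueError(
                f"exchange {base_id} has no uptake direction in the model")
        lp.set_bounds(rev, lo, np.inf if hi is None else hi)

    for name in MASS_VARS:
        lp.add_var(name, 0.0, np.inf)

    # mass balance (constraint family 1)
    by_met: dict[str, dict] = {}
    for rxn in pc.model.reactions:
        for met, coef in rxn.metabolites.items():
            by_met.setdefault(met.id, {})[rxn.id] = coef
    for met_id in sorted(by_met):
        lp.add_row(f"mb_{met_id}", "mass_balance", by_met[met_id], "=", 0.0)
    return lp


def add_capacity_constraints(lp: PcLinearProgram, pc: PcModel,
                             params: ConditionParameters) -> PcLinearProgram:
    """Enzyme capacity (one row per enzyme-linked reaction) and ribosome
    capacity (one row per translation reaction plus the summation row)."""
    mu = params.mu
    for rxn_id, (complex_id, kcat_s) in sorted(pc.enzyme_links.items()):
        if kcat_s is None:
            raise ValueError(f"missing kcat for {rxn_id} ({complex_id})")
        form = pc.complex_formation_rxn[complex_id]
        lp.add_row(f"cap_{rxn_id}", "enzyme_capacity",
                   {rxn_id: 1.0, form: -(kcat_s * 3600.0) / mu}, "=", 0.0)

    kribo = params.resolved_kcat_ribo()
    er_sum: dict[str, float] = {}
    for tag, trans_id in sorted(pc.translation_rxn.items()):
        er = f"eR_{tag}"
        lp.add_var(er, 0.0, np.inf)
        length = pc.peptide_length[tag]
        lp.add_row(f"ribocap_{tag}", "ribosome_capacity",
                   {trans_id: 1.0, er: -kribo / length}, "=", 0.0)
        er_sum[er] = 1.0
    er_sum[pc.ribosome_synthesis_rxn] = -1.0 / mu
    lp.add_row("ribosome_sum", "ribosome_capacity", er_sum, "=", 0.0)
    return lp


def add_expression_couplings(lp: PcLinearProgram, pc: PcModel,
                             params: ConditionParameters) -> PcLinearProgram:
    """mRNA coupling per translated gene and tRNA coupling per class.

    The mRNA family carries two rows per gene: the translation-transcription
    coupling, and the tie that fixes the degradation flux to its
    steady-state share k_deg/(k_deg+mu) of transcription (dilution takes
    the rest through mass balance).
    """
    mu, kdeg, kmrna, ktrna = params.mu, params.k_deg, params.k_mrna, params.k_trna
    for tag, trans_id in sorted(pc.translation_rxn.items()):
        trsc = pc.transcription_rxn[tag]
        lp.add_row(f"mrna_{tag}", "mrna_coupling",
                   {trans_id: 1.0, trsc: -kmrna / (kdeg + mu)}, "=", 0.0)
        deg = pc.mrna_degradation_rxn[tag]
        lp.add_row(f"mrnadeg_{tag}", "mrna_coupling",
                   {deg: 1.0, trsc: -kdeg / (kdeg + mu)}, "=", 0.0)

    by_class: dict[str, list] = {}
    for locus, trsc_id in pc.trna_transcription_rxn.items():
        by_class.setdefault(pc.trna_class[locus], []).append(trsc_id)
    for aa, charge_id in sorted(pc.trna_charging_rxn.items()):
        coefs = {charge_id: 1.0}
        for trsc_id in by_class.get(aa, []):
            coefs[trsc_id] = -ktrna / mu
        lp.add_row(f"trna_{aa}", "trna_coupling", coefs, "=", 0.0)
    return lp


def add_mass_accounting(lp: PcLinearProgram, pc: PcModel,
                        params: ConditionParameters) -> PcLinearProgram:
    """Mass variables, the UP floor, and the closure row."""
    mu = params.mu
    w = pc.weights

    # total proteome
    coefs: dict[str, float] = {}
    for complex_id, form in sorted(pc.complex_formation_rxn.items()):
        coefs[form] = coefs.get(form, 0.0) + w["complex"][complex_id] / 1000.0 / mu
    coefs[pc.ribosome_synthesis_rxn] = w["r_proteins"] / 1000.0 / mu
    coefs[pc.up_translation_rxn] = \
        coefs.get(pc.up_translation_rxn, 0.0) + w["up"] / 1000.0 / mu
    coefs["TotalProtein"] = -1.0
    lp.add_row("total_protein", "total_proteome", coefs, "=", 0.0)

    # RNA masses
    lp.add_row("rrna_mass", "rna_mass",
               {pc.ribosome_synthesis_rxn: w["rrna"] / 1000.0 / mu,
                "rRNA": -1.0}, "=", 0.0)
    mcoefs: dict[str, float] = {"mRNA": -1.0}
    for tag, trsc in sorted(pc.transcription_rxn.items()):
        if tag in w["mrna"]:
            mcoefs[trsc] = w["mrna"][tag] / 1000.0 / (mu + params.k_deg)
    lp.add_row("mrna_mass", "rna_mass", mcoefs, "=", 0.0)
    tcoefs: dict[str, float] = {"tRNA": -1.0}
    for locus, trsc in sorted(pc.trna_transcription_rxn.items()):
        tcoefs[trsc] = w["trna"][locus] / 1000.0 / mu
    lp.add_row("trna_mass", "rna_mass", tcoefs, "=", 0.0)
    lp.add_row("rna_sum", "rna_mass",
               {"rRNA": 1.0, "mRNA": 1.0, "tRNA": 1.0, "RNA": -1.0}, "=", 0.0)

    # glycogen and free amino acids
    if pc.glycogen_rxn:
        lp.add_row("glycogen_mass", "glycogen_mass",
                   {pc.glycogen_rxn: w["glycogen"] / 1000.0 / mu,
                    "Glycogen": -1.0}, "=", 0.0)
    else:
        lp.set_bounds("Glycogen", 0.0, 0.0)
    if pc.free_aa_rxn:
        lp.add_row("free_aa_mass", "glycogen_mass",
                   {pc.free_aa_rxn: w["free_aa"] / 1000.0 / mu,
                    "FreeAA": -1.0}, "=", 0.0)
    else:
        lp.set_bounds("FreeAA", 0.0, 0.0)

    # UP floor (constraint family 4)
    up_mass_coef = w["up"] / 1000.0 / mu
    if params.up_floor_mode == "relative":
        lp.add_row("up_floor", "up_floor",
                   {pc.up_translation_rxn: up_mass_coef,
                    "TotalProtein": -params.up_ratio_c}, ">=", 0.0)
    else:
        lp.add_row("up_floor", "up_floor",
                   {pc.up_translation_rxn: up_mass_coef}, ">=",
                   params.up_ratio_c)

    # closure (constraint family 10)
    if params.closure_mode in ("glycogen", "glycogen_capped"):
        lp.add_row("closure", "closure",
                   {"TotalProtein": 1.0, "RNA": 1.0, "Glycogen": 1.0},
                   "=", params.closure_total)
        if params.closure_mode == "glycogen_capped":
            lp.add_row("glycogen_cap", "closure",
                       {"Glycogen": 1.0}, "=", params.glycogen_cap)
    elif params.closure_mode == "free_amino_acids":
        if not pc.free_aa_rxn:
            raise ValueError(
                "free_amino_acids closure requires a free-AA pool reaction")
        lp.add_row("closure", "closure",
                   {"TotalProtein": 1.0, "RNA": 1.0, "FreeAA": 1.0},
                   "=", params.closure_total)
    else:
        raise ValueError(f"unknown closure mode {params.closure_mode!r}")
    return lp


def cap_protein_fraction(lp: PcLinearProgram, pc: PcModel,
                         params: ConditionParameters, complex_id: str,
                         max_fraction: float) -> PcLinearProgram:
    """Bound one complex's proteome share:
    (v_e/mu) mw_e/1000 <= max_fraction * TotalProtein."""
    if not (0 < max_fraction <= 1):
        raise ValueError("max_fraction must lie in (0, 1]")
    form = pc.complex_formation_rxn[complex_id]
    mw = pc.weights["complex"][complex_id]
    lp.add_row(f"capfrac_{complex_id}", "enzyme_capacity",
               {form: mw / 1000.0 / params.mu,
                "TotalProtein": -max_fraction}, "<=", 0.0)
    return lp


def assemble_lp(
    pc: PcModel,
    params: ConditionParameters,
    zero_fluxes: frozenset | set = frozenset(),
    protein_caps: dict | None = None,
) -> PcLinearProgram:
    """Build the complete LP for one growth rate.

    ``zero_fluxes`` fixes named reactions to zero (knockouts);
    ``protein_caps`` maps complex ids to maximal proteome fractions.
    """
    lp = _base_lp(pc, params)
    add_capacity_constraints(lp, pc, params)
    add_expression_couplings(lp, pc, params)
    add_mass_accounting(lp, pc, params)
    for rxn_id in zero_fluxes:
        lp.set_bounds(rxn_id, 0.0, 0.0)
    for complex_id, frac in (protein_caps or {}).items():
        cap_protein_fraction(lp, pc, params, complex_id, frac)
    if params.limiting_exchange:
        _, rev = pc.exchange_pair(params.limiting_exchange)
        if rev is None:
            raise ValueError(
                f"limiting exchange {params.limiting_exchange} has no "
                "uptake direction")
        lp.objective = {rev: 1.0}
    return lp


# ---------------------------------------------------------------------------
# Solution
# ---------------------------------------------------------------------------

_HIGHS_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-9,
}


def _matrices(lp: PcLinearProgram, equilibrate: bool):
    n = len(lp.var_names)
    c = np.zeros(n)
    for var, coef in lp.objective.items():
        c[lp.var_index[var]] = coef

    eq_rows, eq_rhs, ub_rows, ub_rhs = [], [], [], []
    for row in lp.rows:
        idx = np.array([lp.var_index[v] for v in row.coefs], dtype=int)
        val = np.array(list(row.coefs.values()), dtype=float)
        rhs = row.rhs
        if row.sense == ">=":
            val, rhs = -val, -rhs
        if equilibrate:
            scale = np.max(np.abs(val))
            if scale > 0:
                val = val / scale
                rhs = rhs / scale
        if row.sense == "=":
            eq_rows.append((idx, val)); eq_rhs.append(rhs)
        else:
            ub_rows.append((idx, val)); ub_rhs.append(rhs)

    def sparse(rows):
        data, ri, ci = [], [], []
        for i, (idx, val) in enumerate(rows):
            ri.extend([i] * len(idx)); ci.extend(idx); data.extend(val)
        return csr_matrix((data, (ri, ci)), shape=(len(rows), n))

    A_eq = sparse(eq_rows) if eq_rows else None
    A_ub = sparse(ub_rows) if ub_rows else None
    return (c, A_eq, np.array(eq_rhs), A_ub, np.array(ub_rhs))


def solve_min_uptake(lp: PcLinearProgram,
                     limiting_exchange: str | None = None) -> LPSolution:
    """Minimize the limiting uptake over the assembled LP.

    Returns status, objective and the full variable vector; on numerical
    failure the solve is retried without row equilibration, then without
    presolve, before giving up.
    """
    if limiting_exchange is not None:
        lp.objective = {limiting_exchange: 1.0}
    if not lp.objective:
        raise ValueError("no objective set; name a limiting exchange")

    bounds = list(zip(lp.lb, lp.ub))
    attempts = (
        {"equilibrate": True, "presolve": True},
        {"equilibrate": False, "presolve": True},
        {"equilibrate": False, "presolve": False},
    )
    res = None
    for attempt in attempts:
        c, A_eq, b_eq, A_ub, b_ub = _matrices(lp, attempt["equilibrate"])
        options = dict(_HIGHS_OPTIONS, presolve=attempt["presolve"])
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                      bounds=bounds, method="highs", options=options)
        if res.status in (0, 2):  # optimal or proven infeasible
            break
    if res is None or res.status not in (0, 2):
        return LPSolution(status="error")
    if res.status == 2:
        return LPSolution(status="infeasible")

    values = dict(zip(lp.var_names, res.x))
    # equality residuals in unscaled row space
    max_resid = 0.0
    for row in lp.rows:
        if row.sense != "=":
            continue
        lhs = sum(coef * values[v] for v, coef in row.coefs.items())
        scale = max(1.0, max(abs(c_) for c_ in row.coefs.values()))
        max_resid = max(max_resid, abs(lhs - row.rhs) / scale)
    return LPSolution(status="optimal", objective=float(res.fun),
                      values=values, max_residual=max_resid)
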