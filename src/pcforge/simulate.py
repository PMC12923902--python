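"""Simulation protocols: chemostat sweeps, batch µmax search, knockouts.

Chemostats impose the growth rate (dilution rate) and the cell minimizes
uptake of the limiting nutrient; batch growth is the largest µ at which
the LP stays feasible, found by bisection on [0, 0.5] h⁻¹ starting from
0.25; a knockout's fitness is the ratio of its µmax to the wild type's.
Gene deletions are applied by forcing the translation fluxes of the
deleted genes to zero — their complexes then carry no flux through the
enzyme-capacity coupling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

import yaml

from .constraints import (
    ConditionParameters,
    LPSolution,
    assemble_lp,
    solve_min_uptake,
)
from .reconstruction import PcModel

__all__ = [
    "ChemostatResult",
    "KnockoutSpec",
    "MuMaxResult",
    "simulate_chemostat",
    "find_mu_max",
    "model_mu_max",
    "simulate_knockout_fitness",
    "load_mutant_library",
]

MU_SEARCH_LO = 0.0
MU_SEARCH_HI = 0.5
MU_SEARCH_START = 0.25
DEFAULT_MU_TOL = 1e-4


@dataclass
class ChemostatResult:
    """Solved physiology at one dilution rate."""

    mu: float
    status: str
    uptake_flux: float = float("nan")       # mmol gDW^-1 h^-1
    product_fluxes: dict = field(default_factory=dict)
    masses: dict = field(default_factory=dict)        # g/gDW
    proteome_fractions: dict = field(default_factory=dict)
    yield_gdw_per_mol: float = float("nan")
    solution: LPSolution | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class KnockoutSpec:
    """One mutant: deleted genes, hard-zeroed reactions, medium changes."""

    name: str
    deleted_genes: list = field(default_factory=list)
    forced_zero_reactions: list = field(default_factory=list)
    medium_overrides: dict = field(default_factory=dict)
    protein_caps: dict = field(default_factory=dict)


@dataclass
class MuMaxResult:
    mu_max: float
    no_growth: bool
    iterations: int
    probes: list = field(default_factory=list)


def _postprocess(pc: PcModel, params: ConditionParameters,
                 sol: LPSolution, mu: float,
                 product_exchanges: tuple = ()) -> ChemostatResult:
    v = sol.values
    uptake = sol.objective
    masses = {
        "protein": v["TotalProtein"],
        "rRNA": v["rRNA"], "mRNA": v["mRNA"], "tRNA": v["tRNA"],
        "RNA": v["RNA"], "glycogen": v["Glycogen"], "free_aa": v["FreeAA"],
    }
    w = pc.weights
    total_protein = v["TotalProtein"]
    ribo_mass = v[pc.ribosome_synthesis_rxn] / mu * w["r_proteins"] / 1000.0
    up_mass = v[pc.up_translation_rxn] / mu * w["up"] / 1000.0
    metab_mass = sum(
        v[form] / mu * w["complex"][cid] / 1000.0
        for cid, form in pc.complex_formation_rxn.items())
    fractions = {}
    if total_protein > 0:
        fractions = {
            "ribosomal": ribo_mass / total_protein,
            "metabolic": metab_mass / total_protein,
            "UP": up_mass / total_protein,
        }
    products = {}
    for ex in product_exchanges:
        fwd, rev = pc.exchange_pair(ex)
        products[ex] = (v.get(fwd, 0.0) if fwd else 0.0) - \
            (v.get(rev, 0.0) if rev else 0.0)
    yld = mu / uptake * 1000.0 if uptake > 0 else float("inf")
    return ChemostatResult(
        mu=mu, status="optimal", uptake_flux=uptake,
        product_fluxes=products, masses=masses,
        proteome_fractions=fractions, yield_gdw_per_mol=yld, solution=sol)


def simulate_chemostat(
    pc: PcModel,
    params: ConditionParameters,
    mu_grid,
    product_exchanges: tuple = (),
    zero_fluxes: frozenset = frozenset(),
    protein_caps: dict | None = None,
) -> list[ChemostatResult]:
    """Minimize limiting uptake at each dilution rate of ``mu_grid``.

    Infeasible grid points are reported with their status, not raised.
    """
    results = []
    for mu in mu_grid:
        p = params.at_mu(float(mu))
        lp = assemble_lp(pc, p, zero_fluxes=zero_fluxes,
                         protein_caps=protein_caps)
        sol = solve_min_uptake(lp)
        if sol.optimal:
            results.append(_postprocess(pc, p, sol, float(mu),
                                        product_exchanges))
        else:
            results.append(ChemostatResult(mu=float(mu), status=sol.status))
    return results


def find_mu_max(
    feasible: Callable[[float], bool],
    lo: float = MU_SEARCH_LO,
    hi: float = MU_SEARCH_HI,
    tol: float = DEFAULT_MU_TOL,
    start: float = MU_SEARCH_START,
) -> MuMaxResult:
    """Bisection for the largest feasible growth rate.

    Probes ``start`` (the interval midpoint, 0.25 h⁻¹ by default) first,
    then halves the bracket until it is narrower than ``tol``.  Returns the
    last feasible µ; "no growth" is flagged when the result is below
    2·tol, acknowledging bisection resolution.  Iteration count is at most
    ceil(log2((hi-lo)/tol)).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    probes: list[float] = []

    def probe(mu: float) -> bool:
        probes.append(mu)
        return feasible(mu)

    lo_feas, hi_infeas = lo, hi
    mid = start
    iterations = 0
    while hi_infeas - lo_feas > tol:
        iterations += 1
        if probe(mid):
            lo_feas = mid
        else:
            hi_infeas = mid
        mid = 0.5 * (lo_feas + hi_infeas)
    mu_max = lo_feas
    if mu_max <= lo + tol and not probe(lo + tol):
        return MuMaxResult(mu_max=0.0, no_growth=True,
                           iterations=iterations, probes=probes)
    return MuMaxResult(mu_max=mu_max, no_growth=mu_max < 2 * tol,
                       iterations=iterations, probes=probes)


def model_mu_max(
    pc: PcModel,
    params: ConditionParameters,
    tol: float = DEFAULT_MU_TOL,
    zero_fluxes: frozenset = frozenset(),
    protein_caps: dict | None = None,
    lo: float = MU_SEARCH_LO,
    hi: float = MU_SEARCH_HI,
) -> MuMaxResult:
    """Maximum growth rate of the model: feasibility bisection over µ."""

    def feasible(mu: float) -> bool:
        try:
            p = params.at_mu(mu)
        except ValueError:  # below the minimum supported µ
            return False
        lp = assemble_lp(pc, p, zero_fluxes=zero_fluxes,
                         protein_caps=protein_caps)
        return solve_min_uptake(lp).optimal

    return find_mu_max(feasible, lo=lo, hi=hi, tol=tol)


def simulate_knockout_fitness(
    pc: PcModel,
    spec: KnockoutSpec,
    wildtype_mu_max: float,
    params: ConditionParameters,
    tol: float = DEFAULT_MU_TOL,
) -> float:
    """Fitness = µmax(mutant)/µmax(wild type).

    Deleted genes have their translation fluxes fixed to zero;
    ``forced_zero_reactions`` (e.g. GAPOR) are bounded to zero directly;
    medium overrides and proteome-fraction caps apply on top of ``params``.
    """
    if wildtype_mu_max <= 0:
        raise ValueError("wildtype_mu_max must be positive")
    zero = set(spec.forced_zero_reactions)
    for gene in spec.deleted_genes:
        if gene not in pc.translation_rxn:
            raise KeyError(f"unknown gene {gene!r} in knockout {spec.name}")
        zero.add(pc.translation_rxn[gene])
    p = params
    if spec.medium_overrides:
        medium = dict(params.medium)
        medium.update({k: tuple(v) for k, v in spec.medium_overrides.items()})
        from dataclasses import replace
        p = replace(params, medium=medium)
    result = model_mu_max(pc, p, tol=tol, zero_fluxes=frozenset(zero),
                          protein_caps=spec.protein_caps or None)
    return result.mu_max / wildtype_mu_max


def load_mutant_library(path=None) -> dict[str, KnockoutSpec]:
    """Load the built-in hydrogenase-mutant library (or one from ``path``).

    The built-in file mirrors the published knockout experiments on
    M. maripaludis (Δ3H₂ase, Δ5H₂ase, Δ6H₂ase, Δ6H₂ase-Δcdh and the
    GAPOR-reactivated suppressor strains); gene names are locus-tag
    placeholders to be mapped onto the host model's annotation.
    """
    if path is None:
        text = resources.files("pcforge").joinpath(
            "data/mutants.yaml").read_text()
    else:
        text = open(path).read()
    raw = yaml.safe_load(text)
    library = {}
    for name, entry in raw.items():
        library[name] = KnockoutSpec(
            name=name,
            deleted_genes=entry.get("deleted_genes", []),
            forced_zero_reactions=entry.get("forced_zero_reactions", []),
            medium_overrides=entry.get("medium_overrides", {}),
            protein_caps=entry.get("protein_caps", {}),
        )
    return library
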