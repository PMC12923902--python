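# Methods

## Model

`pcforge` turns a genome-scale metabolic model (GEM) into a
proteome-constrained (pc) model: the stoichiometric network is extended
with explicit gene-expression machinery, and fluxes are coupled to the
enzyme and ribosome abundances that have to be synthesized to carry them.
At a fixed specific growth rate µ (h⁻¹) the model is a linear program (LP)
over non-negative fluxes `v` (mmol gDW⁻¹ h⁻¹), ribosome-allocation
variables `eR_i` and macromolecular mass variables (g gDW⁻¹):

```
minimize    v_uptake                         (limiting-nutrient uptake)
subject to  S·v = 0                          (steady state)
            v_i − (kcat_i/µ)·v_e(i) = 0      (enzyme capacity)
            v_trans,i − (kcat_ribo/len_i)·eR_i = 0
            Σ_i eR_i − (1/µ)·v_syn,ribo = 0  (ribosome capacity)
            UP ≥ c·TotalProtein              (unspecific-protein floor)
            v_trans,i − (k_mRNA/(k_deg+µ))·v_transcription,i = 0
            v_charging,a − (k_tRNA/µ)·v_transcription,tRNA,a = 0
            Σ (v_e/µ)(mw_e/1000) + (v_syn,ribo/µ)(mw_rp/1000)
              + (v_UP/µ)(mw_UP/1000) = TotalProtein
            rRNA, mRNA, tRNA mass rows and RNA = rRNA+mRNA+tRNA
            (v_glycogen/µ)(mw_gly/1000) = Glycogen
            TotalProtein + RNA + Glycogen = 0.93
```

The key physical idea: a species with a dilution sink reaches steady-state
abundance `flux/µ`, so each `v/µ` term is an abundance and each
`(v/µ)(mw/1000)` term is a mass in g/gDW.  The mRNA rows use `µ + k_deg`
because transcripts are lost to both dilution and degradation.  The
closure row forces protein + RNA + glycogen to 0.93 gDW per gDW (the
remaining 0.07 gDW — lipids, vitamins — is a growth-rate-independent
residual drained by a fixed-flux biomass reaction).  Glycogen acts as the
closure's flexible store: at low µ the proteome is cheap and glycogen is
large; it shrinks as µ grows, and the µ at which it would go negative is
the maximum growth rate.

Two closure variants are supported: pinning glycogen at a measured value
(0.02 g/gDW), which forces extra protein/RNA production through the UP
inequality, and replacing glycogen by a free-amino-acid pool (for
phosphate-limited physiology, where storage of P-containing compounds is
implausible).

## Reconstruction

1. **Reversibility split.** Every reversible reaction becomes `_fwd`/`_rev`
   copies with lower bound 0 (the capacity coupling needs one enzyme
   demand per direction).
2. **Isozyme expansion.** GPR rules are normalized to OR-of-AND form;
   a reaction with k isozymes becomes k copies (`_isoN`), each linked to
   exactly one complex.  Gene sets not present in the complex table become
   implicit 1-copy complexes (monomer assumption).
3. **Expression templates.** Per protein-coding gene: transcription
   (NTPs → mRNA), degradation (mRNA → NMPs), translation (charged tRNAs +
   GTP → peptide) and mRNA dilution.  Per tRNA gene: transcription; per
   amino-acid class: one charging reaction and a dilution.  Per rRNA gene:
   transcription (rRNA is consumed by ribosome assembly, so it needs no
   dilution).  Template energy costs are configuration, not code; the
   defaults are 2 GTP per elongation step + 1 GTP initiation, ATP → AMP
   per tRNA charging, 1 NTP per transcribed nucleotide + 2 ATP initiation,
   hydrolytic (energy-free) mRNA degradation, 2 GTP per ribosome
   assembled.  These are declared assumptions — reasonable textbook costs
   — and can be swapped per organism without code changes.
4. **Assembly/dilution.** One formation + one dilution reaction per
   complex, ribosome assembly + dilution, UP dilution.  Formation
   conserves mass by construction (complex MW = Σ copies × subunit MW).
5. **Unspecific protein (UP).** The proteome mass not attributable to
   modeled enzymes or ribosomes is a pseudo-peptide whose residue and
   transcript compositions are pooled over all modeled CDSs (uniform
   weight per residue, i.e. genes weighted by length) and whose length is
   the mean CDS length.  Fractional stoichiometric coefficients are used
   directly; an LP does not need integer stoichiometry.  UP is wired
   through the same transcription/translation templates, so its cost
   structure matches a real protein's.

Simplifications to note: NTP/NMP pools are lumped into single species
(per-base accounting would change transcript costs by <10% and none of
the coupling structure); anticodon classes default to one per amino acid
(a wobble table can be supplied); enzymes catalyzing several reactions
share one formation flux, which over-constrains flux ratios through
promiscuous enzymes — the bundled fixtures keep reaction↔complex 1:1.

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| kcat (absent) | 5 | s⁻¹ | median of curated turnover numbers |
| kcat floor | 0.75 | s⁻¹ | lifts implausibly low curated values; `keep_raw` exempts genuinely slow enzymes (e.g. CODH, 0.002 s⁻¹) |
| kcat_ribo (formate) | 22×3600·µ | aa h⁻¹ | constant AA-per-ribosome ⇒ growth-rate-invariant ribosomal proteome fraction |
| kcat_ribo (phosphate) | A(µ)×3600·µ | aa h⁻¹ | A linear through (0.002, 40), (0.1, 22), clamped outside |
| k_deg | 6.93 | h⁻¹ | mRNA decay (10-min half-life); not experimentally pinned for the target organism |
| k_mRNA | 2700 | h⁻¹ | mRNA catalytic (translation events per transcript per h) |
| k_tRNA | 3600 | h⁻¹ | tRNA catalytic rate |
| GAM / NGAM | per condition | mmol ATP gDW⁻¹ (h⁻¹) | growth/non-growth maintenance; see condition table |
| UP ratio c | per condition | — | UP floor as fraction of total protein |
| closure | 0.93 | gDW | protein+RNA+glycogen mass per gDW |

Condition presets (UP %, GAM, NGAM): formate chemostat (75, 25, 1),
phosphate chemostat (44, 70, 1), formate batch (44, 25, 1), CO₂/H₂
chemostat (44, 130, 5), CO₂/H₂ batch (20, 25, 5).

The UP floor is encoded relative (`UP ≥ c·TotalProtein`) because c is
stated as a percentage of total protein mass; an absolute variant is
available via `up_floor_mode`.

The bulk AA-per-ribosome estimate `(P/m_aa)/(R·f_rRNA/m_rr)` uses assumed
constants m_aa = 0.100 g/mmol, f_rRNA = 0.90, m_rr = 1.5 MDa; with
P = 0.6, R = 0.14 g/gDW it gives 19.8×3600 aa/ribosome.  These constants
are assumptions (labelled as such in CLI output); the simulation
schedules above do not depend on them.

## Numerics

* The LP is solved with HiGHS (scipy.optimize.linprog) at feasibility
  tolerances of 1e-10; rows are max-abs equilibrated first because
  coefficients span ~9 orders of magnitude (kcat/µ up to ~10⁷ against
  mw/1000 mass terms).  Failed solves retry without equilibration, then
  without presolve.
* µ = 0 is rejected (division by µ throughout); the minimum supported µ
  is 1e-4 h⁻¹.
* Maximum growth rate is pure LP feasibility, bisected on [0, 0.5] h⁻¹
  starting at the midpoint 0.25, default tolerance 1e-4 h⁻¹ (consistent
  with two-decimal reporting of growth rates); "no growth" is declared
  below 2·tol.
* Isozyme tie-breaking is left to the LP (the cheapest proteome wins);
  alternative optima are possible when isozymes tie exactly.
* The degradation flux is pinned to its steady-state share
  `k_deg/(k_deg+µ)` of transcription by an explicit row; dilution takes
  the remainder through mass balance.  Without this row the
  degradation/dilution split of each transcript would be undetermined.

## The toy organism and what passing tests mean

The bundled fixture organism has 6 CDSs over a two-letter amino-acid
alphabet, one tRNA per class, two rRNAs, an "and" complex, an isozyme
pair with strictly ordered costs, one reversible reaction, and a
schematic metabolism (substrate → ATP/amino acids/NTPs/glycogen, waste
excreted).  Its LP (~80 variables) has a unique uptake-minimizing vertex,
so an independent oracle can solve the complete steady state by writing
out all balances and couplings in exact rational arithmetic and
eliminating.  LP and oracle agree to ~1e-12 relative on every variable,
which validates the assembly and the solver configuration, not the
biology: the toy's kcats are deliberately small so that proteome cost is
a binding constraint at miniature scale, and its chemistry conserves
neither phosphorus nor carbon atoms.  Results on real GEMs additionally
depend on curation quality (kcats, complex stoichiometry, biomass
composition), which the toy cannot test.

Problem sizes used by the test suite and the acceptance script: the
~80-variable toy LP, five-point µ grids on [0.01, 0.09], and bisection
tolerances of 1e-3–1e-4 h⁻¹.

## Known limitations

* No thermodynamic constraints, no saturation factors beyond the UP
  ratio, no time-course simulation, no post-translational modification.
* Proteome fractions are reported from single LP solutions; degenerate
  optima (exact isozyme ties) could redistribute mass between complexes
  without changing the objective.
* The mutant library ships with annotation gene symbols; mapping to a
  host model's locus tags is the user's curation step.
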