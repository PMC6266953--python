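# Methods

## The constraint-based model

gemflux treats a metabolic reconstruction as metabolites plus reactions
with signed stoichiometric coefficients (reactants negative, products
positive).  The stoichiometric matrix S is m × n with metabolites as rows
and reactions as columns.  Reversibility is not a flag: a reaction is
reversible exactly when its bounds straddle zero.  Reactions without
recoverable bounds default to ±1000 mmol/gDW/hr (reversible) or
(0, 1000) — the constraint-based community convention for "practically
unbounded".

Every species is, by default, subject to the pseudo-steady-state balance
(S·v = 0 for its row).  Import and export happen only through explicit
single-metabolite exchange reactions, where uptake is a negative flux.
An input file that instead marks species as boundary/exchange species is
converted on read: the species becomes an ordinary balanced species and a
generated exchange reaction `EX_<species>` (bounds ±1000) carries the
boundary flux.  This keeps one uniform steady-state constraint and makes
the conversion reversible.  Callers who want the literal free-row
semantics can disable the conversion, in which case the species' row of S
is simply not constrained.

Reaction taxonomy is structural and total: the objective-designated
reaction is `biomass` (designation beats structure); a reaction touching
exactly one metabolite is `exchange`; one whose metabolites span two or
more compartments is `transport`; the rest are `internal`.  Compartment
labels are free strings compared only for inequality, since organelle
vocabularies differ between reconstructions.  A published model's own
transport/boundary counts were produced by an unstated rule, so the audit
helper reports per-reaction categories rather than silently absorbing any
disagreement with published counts.

## The linear programs

FBA maximises c·v subject to the steady rows of S·v = 0 and the box
bounds.  The solver backend is a minimal contract (S, c, bounds, steady
mask in; flux vector and status out); the default backend is HiGHS via
`scipy.optimize.linprog`, run with primal/dual feasibility tolerances of
1e-10 so that constraint violations stay well inside the 1e-9 relative
optimality contract.  Infeasible and unbounded statuses are reported as
data, never clamped — an unbounded growth LP always means a missing uptake
limit.

FBA optima are degenerate, so per-reaction numbers depend on which optimal
vertex a solver happens to return.  All per-reaction reporting therefore
uses parsimonious FBA: stage one finds the growth optimum z\*, stage two
minimises Σ|vⱼ| subject to the original constraints plus
c·v ≥ z\* − 1e-9·|z\*|, with |vⱼ| linearised through auxiliary variables
aⱼ ≥ ±vⱼ.  The growth floor is purely relative (and two-sided around
zero), so the parsimonious growth never drops more than one part in 10⁹
below the optimum.  Biomass-level quantities are degeneracy-invariant and
use plain FBA.  Stage two needs inequality rows beyond the backend
contract and is solved directly with HiGHS.  Fluxes below 1e-6 print as
zero in CLI tables; this is the LP noise floor, not a model statement.

Per-reaction percent changes between two conditions are **not** comparable
across solver implementations even with pFBA when alternative minimal
routings exist; gemflux therefore treats per-reaction differential values
as qualitative (which pathways respond) and never asserts them against
published per-reaction numbers.

## Media and starvation semantics

A medium lists exchange-reaction bounds.  Applying it replaces the listed
bounds and closes the uptake of every unlisted exchange reaction
(lower bound ← max(lower, 0)) while leaving secretion open; "absence of a
nutrient" is a property of the medium, not a ban on the metabolite, so a
starved nutrient can still be excreted.  The starvation experiment solves
the full medium and the medium with one uptake closed, and reports

    (G_without − G_with) / |G_with| · 100

Baselines with |G_with| ≤ 1e-6 are undefined rather than divided through.
The same rule applies per reaction, with one refinement: a reaction whose
baseline parsimonious flux is zero but whose starved flux is not has no
finite percent change, yet it is the strongest possible responder — it
*activated*.  Such reactions carry both an `undefined-baseline` and an
`activated` flag and head the top-increased ranking with an infinite
change; zero-baseline reactions that stay silent are listed separately and
excluded from the ranking.  This choice keeps the division-by-noise guard
without hiding pathway switches, which are precisely what starvation
analysis is looking for.

## The synthetic generators

The generators exist so the entire stack is testable offline against
closed forms; they emulate the *structure* of a curated genome-scale
reconstruction (compartments, transport and exchange steps, a unique
biomass objective, uptake as negative flux) and none of its biochemical
realism — no cofactor coupling, no shared enzymes, no mass imbalance to
detect.  Passing tests on them demonstrates the correctness of the LP
machinery and pipeline plumbing, not the biological fidelity of any real
reconstruction.

* **Chain**: one substrate, a linear 1:1 pathway, biomass.  The optimum is
  the uptake cap, independent of length.
* **Branched**: disjoint pathways convert each substrate i to a shared
  biomass precursor with stoichiometric yield yᵢ under uptake cap uᵢ, so
  full-medium growth is Σyᵢuᵢ and single-source growth is yᵢuᵢ; ranking
  carbon sources therefore follows the constructed yields exactly.  The
  default four substrates (glucose, pyruvate, glycerol, glutamate; yields
  1.0 / 0.49 / 0.07 / 0.016, caps 10) mirror the relative substrate
  utilisation measured in classic radiolabelled-carbon incorporation
  experiments on *Tetrahymena*, normalised to glucose — glucose is the
  preferred carbon source by construction, as it is in vivo.
* **Starvation toy**: a primary and an alternative substrate with equal
  pathway lengths and a biomass cap equal to what the primary alone
  sustains (y_primary·u).  The parsimonious full-medium optimum routes
  everything through the primary pathway; closing the primary uptake
  forces the alternative, so growth falls to y_alt·u and the reduction is
  exactly (1 − y_alt/y_primary)·100 %.  The defaults (yields 1.0 and
  0.679, uptake cap 10, i.e. a glucose bound of −10 mmol/gDW/hr) encode
  the study condition of a 32.1 % biomass reduction under glucose
  starvation with growth maintained by an amino-acid pool.
* **Random**: a seeded composition of 1–4 branches with random lengths,
  yields and caps, orderings shuffled; feasibility and the optimum Σyᵢuᵢ
  hold by construction (no rejection sampling), which is what makes
  ground-truth testing possible.  One integer seed fully determines the
  model; no global random state is touched.

The shipped `data/default_medium.tsv` uses −10 for glucose and −5 for each
secondary substrate; the secondary bounds are assumptions (no measured
uptake rates exist for them) and are marked as such in the file.

## Verification set-up and problem sizes

The test suite checks the solver three independent ways: closed-form
generator ground truths; a brute-force vertex-enumeration oracle that
solves small LPs exhaustively (50 seeded models of 8–15 reactions — small
because vertex enumeration is combinatorial, which is the point of an
independent oracle); and COBRApy with its own LP stack on a handful of
models.  SBML round-trip identity is property-checked on 100 randomized
models, and invariants (mass balance at 1e-6, uptake-tightening
monotonicity, bound scaling, column-order stability) run over seeded
hypothesis cases.  The acceptance script uses 50 random networks of 8–30
reactions; all sizes are chosen so the whole verification runs in well
under a minute while still exercising every code path.

## Known limitations

No gene–protein–reaction rules, flux variability analysis, knockouts,
thermodynamic/loopless constraints or dynamic time courses.  The SBML
writer emits only the modern fbc dialect.  The MATLAB twin format of
published reconstructions is not parsed — SBML is the single interchange
source of truth.  Percent-change reporting near zero baselines is
flag-based by design; consumers who need a number for activated reactions
should use the raw flux difference instead.
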