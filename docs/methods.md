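# Methods

## The knowledge network and its serialisation

A reconstruction is a permissive knowledge store: metabolites (with
compartment, elemental formula, integer charge, MIRIAM-style annotations,
SBO term), reactions (stoichiometry over positive coefficients, flux bounds
in mmol·gDW⁻¹·h⁻¹, a boolean GPR string, a category, and a non-empty set of
provenance tags), and genes (locus tags or artificial ids `t/d/u/p/s/sk/gf`
+ digits; the `artificial` flag is derived from the id shape). Two
compartments are modelled, intracellular (`c`) and extracellular (`e`);
exchange reactions are written one-sided, so the system boundary is
implicit (an uptake has only products, a production only reactants).
Curation never deletes: a rejected reaction is *blocked* by setting both
bounds to zero, keeping the knowledge inspectable.

Serialisation is SBML L3V1 with FBC v2 (formula/charge as FBC attributes,
bounds as constant parameters, GPRs as gene-product associations).
Provenance, category, gene localisation and the verbatim GPR string have no
FBC slot and are stored as `key: value` note lines; entities are emitted
sorted by id, making writes byte-stable and diffable, and
`read(write(R)) == R` field-by-field. Arbitrary identifiers are escaped to
SBML SIds invertibly (`__<codepoint>__`). When a foreign file lacks a
category note, the category is inferred from the SBO term; SBO:0000627
cannot distinguish uptake from production, so foreign exchange reactions
default to uptake — our own files always carry the note.

Formula parsing accepts Hill notation over IUPAC element symbols with
optional integer counts. Placeholder tokens (R-groups, `X`, polymer
`(...)n`) make a formula *unparseable*, an explicit status rather than an
exception, because downstream balance checking must distinguish "checked
and imbalanced" from "uncheckable".

## Reconciliation

Merging subnetworks is a union on entity ids. A reaction present in both
inputs keeps one entry: provenance union plus the incoming source tag, the
OR-join of the two GPRs (verbose GPRs are kept — gene evidence is
information, not noise), and bounds widened to the containing interval
(the reconstruction stage is permissive; restriction happens when deriving
a flux model). The same id with different stoichiometry is a hard conflict
listing both equations. This makes merge associative on entity sets, which
the tests check.

External reactions are admitted only when (a) their id is already in the
reference namespace (possibly via the identifier dictionary), or (b) every
reactant and product maps to the reference namespace, in which case the
original reaction id is retained for traceability; both routes additionally
require at least one supporting gene. Everything else is rejected with a
machine-readable reason.

Duplicate detection groups reactions by their canonical stoichiometric key
(sorted (metabolite, coefficient) pairs per side; coefficients rounded at
1e-9): identical keys are `same_direction`, swapped sides
`opposite_direction`. Compartments live inside metabolite ids, so
cross-compartment copies are not duplicates. Resolution blocks the lesser
member only when one GPR gene set contains the other (identical or
subset); the balance rule dominates (keep the mass-balanced member — this
branch can only trigger for externally supplied pairs, since pairs found
by stoichiometric identity always share balance status), then the
reference-identifier rule (block the "homemade" id), then the
lexicographically smaller id for determinism. Pairs with disjoint or
overlapping GPRs are flagged for manual review, never auto-blocked.

Model versions are compared on exact metabolite ids or on the first
InChIKey block (planar structure, stereochemistry disregarded). Key
collisions within one model collapse to a single comparison unit; unkeyed
metabolites are reported as incomparable, never as exclusive.

## Topological producibility (scope)

The scope of a seed set is the least fixed point of network expansion: a
reaction direction fires when all its substrates are producible, its
products become producible, until convergence. Stoichiometric coefficients
are ignored (pure hypergraph reachability) and the two directions of a
reversible reaction fire independently — the standard semantics of
topological producibility tooling, and a known over-approximation for
reversible chemistry. Blocked reactions never fire, so scope counts reflect
curation-stage blocking. The production implementation is an indexed
worklist (each direction tracks its count of missing substrates, O(edges));
a deliberately naive full-pass closure is kept as an independent oracle,
and the two are checked for exact agreement on random networks.

Boundary seeds are the metabolites produced by uptake reactions — the
compounds the environment offers. Connectivity classes (consumed-only,
produced-only, both, disconnected) partition the metabolite set, with both
directions of reversible reactions counting; the progress report stacks
per-stage rows (entity counts, scope sizes, per-target-set producible
fractions, with absent targets kept in the denominator and flagged).

## Gap-filling

`minimal_completion` finds a smallest subset of a repair database making
the still-unproducible targets producible. Targets unreachable even with
the whole database are split off as unsatisfiable first, never silently
dropped. Exact mode is a branch-and-bound: candidates are pre-pruned to
reactions that can ever fire in the fully augmented network and produce
something new; the search branches on one frontier reaction (include /
permanently exclude), seeded with the greedy solution as incumbent, and
prunes at the incumbent cardinality. Every reaction of a minimal completion
must fire in the final scope (otherwise it is removable), so an activation
order exists and frontier branching is complete. Ties among equal-size
minima break to the lexicographically smallest sorted id tuple, so results
are deterministic and comparable with the enumeration oracle
(`brute_force_completion`, increasing cardinality, ≤ 20 repair reactions).
Greedy mode adds the reaction with the largest producibility gain until
satisfied, then prunes to subset-minimality; it does not certify minimum
cardinality. A reversible repair reaction counts as one addition.

`iterative_gapfill` runs per target tier (highest confidence first),
querying repair tiers in tier order and accepting the first pool that
satisfies new targets — so a tier-1 route is preferred over a shorter
tier-2 route — then the union of the tiers already tried for anything
still missing. Accepted reactions gain `gapfill:<label>` provenance and,
when the database supplies no gene, a fresh artificial gene in the `gf`
series (the `s` series is reserved for spontaneous reactions). Re-running
on the output adds nothing.

Spontaneous (enzyme-free) reactions are admitted only when at least one
reactant or product is already in the draft, each receiving an `s###` gene
assigned in deterministic id order.

## Flux models and QC

`derive_model` produces the three bound parameterisations: *closed* (all
uptakes shut), *open* (all uptakes at 10 mmol·gDW⁻¹·h⁻¹), *default*
(exactly a stated medium's uptakes open at their rates, requires an
explicit medium). A medium is carbon source (15), nitrogen source (5),
fixed cofactor uptakes (10), unlimited oxygen, everything else closed;
"unlimited" is the numeric bound 1e6 for solver robustness, not infinity.
An ATP-maintenance reaction, when present, keeps its stored bounds in all
modes. The demand convention here is an irreversible external→intracellular
transfer (SBO:0000628), which inverts the more common community convention;
it is kept deliberately for fidelity to the curation style this package
models.

Balance QC computes coefficient-weighted element and charge residuals
(products minus reactants); any participant with an absent or unparseable
formula makes the reaction undetermined. Protons and water are *not*
auto-excluded — imbalance is reported raw and the blocking policy is the
caller's. Boundary and pseudo-reactions (exchanges, demand, sink, biomass,
ATPM) are evaluated but tagged exempt and excluded from the summary counts.
The reversibility policy closes one bound per curated direction label and
blocks `unknown`-direction reactions outright.

Leak/siphon detection runs on the closed model: metabolite *i* leaks when
some flux has strictly positive net production of *i* and zero net for
everything else — an LP per metabolite with a unit-production relaxation
variable (maximise y s.t. S·v − e_i·y = 0, 0 ≤ y ≤ 1, flag when the
optimum exceeds 1e-6); siphons are symmetric. One-sided columns (exchanges
and lumped pseudo-reactions) are closed for this test, since they are
boundary crossings by design, not mass defects.

The energy-cycle screen adds, per carrier, a canonical dissipation reaction
(hydrolysis or oxidation to the discharged form: ATP + H₂O → ADP + Pi + H⁺,
NADH → NAD⁺ + H⁺, …, transmembrane H⁺ influx for the proton-motive force),
maximises its flux in the closed model and flags any optimum above 1e-9.
Thirteen carriers are screened by default (ATP, CTP, GTP, UTP, ITP, NADH,
NADPH, FADH₂, FMNH₂, ubiquinol-8, acetyl-CoA, glutamate, proton). Species
are resolved by alias matching on id stems and names; water, phosphate and
protons are optional co-species, and carriers whose core species are
missing are skipped with a warning rather than guessed.

## Simulation

FBA and FVA are assembled as dense LPs and solved with HiGHS
(`scipy.optimize.linprog`): maximise c·v subject to S·v = 0 and the bound
box. FVA fixes the objective at a fraction of its optimum (the constraint
is skipped when the optimum is zero, where it would be vacuous or
infeasible) and minimises/maximises each reaction; a reaction is active
when either end of its range clears 1e-9. The media scan builds one medium
per condition — candidate carbon source with the reference nitrogen source,
candidate nitrogen source with the reference carbon source, or an amino
acid replacing both at 15 mmol·gDW⁻¹·h⁻¹ — and records the growth optimum;
the specialised-metabolite scan reports each production reaction's FVA
maximum at 80% biomass with the pathway-specific conditional uptakes opened
at 10. Objective values are printed to four decimals.

## Synthetic ground truth

The generator emulates, at toy scale, the structures the pipeline curates:
per pathway a boundary substrate with uptake (rate 10) and transport, a
linear chain of 1:1 conversions with optional side branches and a
configurable reversible fraction, provenance tags sampled over several
sources, and a biomass reaction consuming the terminal products with
integer stoichiometries 1–3. Formulas are assigned compositionally (every
designed conversion preserves the formula), so all non-injected reactions
balance by construction, and the FBA optimum has the closed form
`min_i(rate_i / coefficient_i)`. Defaults (5 pathways × length 4, branch
probability 0.3, 20% reversible, 3 sources, no defects) are the smallest
shape exercising every mechanism.

Injected defects come with a registry: imbalance doubles a branch-reaction
product coefficient (branches carry no biomass flux, so the optimum is
untouched); missing formulas blank branch metabolites not used by the
imbalance injection (keeping the two defect classes distinguishable);
duplicates copy chain reactions under a `_homemade` id (uptake bounds, not
chain capacity, limit growth, so the optimum is again untouched); leaks are
catalytic mass-from-nothing reactions (carrier → carrier + new species).
Ground-truth scope is computed during generation by an independent naive
closure, not by the package's scope code, so generator and implementation
cross-check each other. `degrade` removes bridge reactions — verified by
re-computing scope without each candidate — so the removed set is a known
minimal completion; decoy repair reactions connect off-pathway metabolites
and can never restore reachability.

What passing on these toys does **not** show: behaviour on genome-scale
degree distributions, hub currency metabolites, multi-compartment
chemistry, or noisy real-world formulas; the toys certify algorithmic
correctness, not biological accuracy of any particular reconstruction.

## Numerical and design choices

- LP feasibility tolerance 1e-6; zero-flux threshold 1e-9; both
  configurable. Stoichiometric keys round coefficients at 1e-9.
- Determinism throughout: sorted-id iteration, one RNG stream per
  generator seed, lexicographic tie-breaks in duplicate resolution and
  gap-filling, byte-stable SBML writes.
- The acceptance script scales the study down to property level: 100
  random networks (≤ 30 reactions) for the scope oracle, 100 random
  instances (≤ 12 repair reactions) for gap-filling minimality, 50
  randomised biomass specs, 6 defect fixtures, 3 closed-model fixtures
  and 2 FVA fixtures — sizes at which the exhaustive oracles are exact
  and the whole run takes seconds.
- Known limitations: scope over-approximates producibility for coupled
  reversible reactions; duplicate detection requires exact coefficient
  equality (scaled copies are not matched); the energy-cycle screen
  depends on alias resolution and silently skips exotic carrier
  namespaces (reported as `skipped`); leak detection solves two LPs per
  metabolite and is meant for curation-time use, not inner loops.
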