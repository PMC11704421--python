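# Methods

## Model and procedure

A genome-scale metabolic model is treated as a stoichiometric LP: fluxes
*v* (mmol·gDW⁻¹·h⁻¹), steady state *S·v = 0*, box bounds, biomass flux
maximized as the growth rate μ (h⁻¹). Exchange reactions are written in
the export direction (`met =>`), so uptake is negative flux and
"opening" an exchange means lowering its lower bound. Gene deletions act
through GPR boolean rules: a reaction with a non-empty rule is forced to
zero flux when the rule evaluates false with deleted genes set to false;
reactions with empty rules are never gene-controlled.

The two-step rescue procedure classifies a knockout → rescue-compound
record as:

* **TYPE_I** — the knockout stays viable (experiment says lethal);
* **CORRECT** — the knockout is inviable and at least one rescue
  conjunct (all its compounds opened simultaneously at the uptake bound)
  restores viability;
* **TYPE_II** — the knockout is inviable and no conjunct rescues it;
* **UNRESOLVABLE** — the record is explicitly marked as such in the
  dataset (its compound cannot be mapped to the model at all); these are
  skipped and excluded from the accuracy denominator.

A rescue compound that simply lacks an exchange reaction is *not* marked
unresolvable automatically: it contributes zero growth to its conjunct,
so such pairs surface as TYPE_II. This matches how a missing exchange is
itself a curatable model defect (the heme case), while dataset-level
exclusions (sphingoid-like compounds) remain a curatorial decision
recorded in the TSV.

Viability is μ ≥ *fraction* × μ_wt with the wild-type optimum recomputed
per input model rather than hard-coded; ties at the threshold are viable.
Infeasible LPs are zero growth, hence inviable under any policy.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| viability fraction | 0.01 | — | the standard 1%-of-wild-type cutoff for calling simulated growth |
| rescue uptake bound | −1000 | mmol·gDW⁻¹·h⁻¹ | the conventional "unconstrained" uptake bound of consensus yeast models |
| substrate-usage uptake | −10 | mmol·gDW⁻¹·h⁻¹ | a physiological single-substrate feed rate; configurable per run |
| LP feasibility/optimality tol | 1e-9 | — | HiGHS defaults tightened to the scale of the models used |
| objective comparisons in tests | 1e-6 | — | well above solver tolerance, well below any biological difference |

## Curation edits

Edits are a closed vocabulary (`block_reaction`, `block_reverse`,
`set_gpr`, `add_reaction`, `add_exchange`, `pseudo_add_rescale`,
`pseudo_append`), each serializable with provenance and replayed in list
order. Application is all-or-nothing: operators are pure, so a failing
edit leaves the input model untouched. Added exchanges are created closed
for uptake — opening them is a simulation decision, not a curation
decision. Curation sets are deliberately not idempotent: re-adding an
existing reaction id is an error, which catches double application.

Pseudoreaction rescaling converts reactant coefficients to masses
(per-unit molar masses from elemental formulas, or explicit overrides for
polymeric pseudo-species), computes *f = M₀/(M₀ + mₙ)*, and scales every
reactant — the new species included — by *f*, conserving total reactant
mass exactly and preserving all pre-existing coefficient ratios. When the
*final* coefficient of the new species is prescribed instead of a raw
one (the chitin case, −0.02361), the raw value is recovered analytically
via |raw| = |final|·M₀/(M₀ − |final|·mₙ) before applying the same
procedure, so the curated stoichiometry shows the prescribed value to the
last digit. Trace cofactor additions (`pseudo_append`, the glutathione
case at −1e-06) deliberately skip rescaling: at that magnitude the mass
perturbation is below any meaningful composition precision.

The packaged Yeast9 set encodes the published row set verbatim: blocks
{r_0217, r_0312, r_4703, r_0559, r_1026, r_2070, r_2071; r_0815
reverse-only}, twelve GPR rewrites {r_0172, r_2488–r_2495, r_0477,
r_0080, r_0250}, additions {r_temp1 heme a exchange, r_temp2 HET-P
synthase, r_temp3 adenylated thiazole synthase}, and the two
pseudoreaction adjustments. Polymeric carbohydrate species carry
anhydro-monomer masses (162.14 g/mol for the glucans, glycogen and
mannan; 203.19 for chitin; trehalose at its molecular 342.30) chosen as
the standard residue masses — the published set prescribes the final
chitin coefficient, so these masses only determine the proportional
shrinkage of the other reactants. The grouped heme/ergosterol rows share
the r_temp1 edit and the grouped GSH1 rows share r_4598; all grouped
gene–compound pairs ride along as provenance on the shared edit.

A synthetic skeleton model (`yeast9_skeleton`) carries exactly the
targeted reactions with their published equations, bounds and
pre-curation rules so the set can be replayed and audited offline. It is
a stand-in for auditing the edits, not the consensus model: it has a
token objective and cannot reproduce consensus growth predictions, which
require the external SBML release.

## The toy generator

`make_toy_gem` builds a substrate exchange plus energy loop feeding
linear, gene-labelled pathways into a unit-coefficient biomass reaction.
Feature flags plant the misprediction mechanisms: a gene-free bypass
(TYPE_I until blocked), a missing precursor exchange (TYPE_II until
added), isoenzyme and complex rules, and a vitamin co-demanded by biomass
whose synthesis shares a pathway gene (rescuable only with the vitamin in
the medium). Topology is a deterministic function of the configuration;
the seed only permutes gene labels, so every expected quantity is closed
form: with uptake *U*, *n* precursors, *k* conditional vitamins and two
ATP per substrate, μ_wt = U/(n + k + ½). Defaults (U = 10, three
precursors, single-step pathways) are the reference conditions used by
the test suite.

What the toy does **not** emulate: realistic yeast network size or
growth-rate magnitudes, compartmentalization beyond
cytosol/extracellular, cofactor coupling, redundant routes longer than
one bypass, and thermodynamic or capacity constraints. Passing the
planted-truth tests therefore demonstrates the correctness of the
procedure's logic (classification, repair, screening), not predictive
accuracy on a real reconstruction.

The synthetic dataset generator emits records straight from the planted
truth, optionally corrupting a seeded `round(noise·n)` subset with a
wrong rescue compound (ground-truth flags returned alongside) — an
analogue of database mis-annotations.

## Oracles and verification

Three independent oracles back the implementation: a compiled
truth-table evaluator for GPR rules (every deletion subset, ≤ 8 genes);
exhaustive vertex enumeration for tiny LPs (≤ 8 reactions, every basis
with n − rank(S) fluxes fixed at bounds); and a plain brute-force
re-enumeration of (gene, exchange) rescue pairs without the screen's
matrix reuse. cobrapy/GLPK serves as an additional independent solver
cross-check in the test suite. Test problem sizes — 1,000 random rules,
≥ 200 random tiny networks, six-precursor trap models — were chosen as
the smallest instances that exercise every branch and all trap types.

## Numerical choices and degenerate inputs

* Only the LP objective value is contract-stable; alternative optima make
  individual fluxes non-unique, which the flux-diff report flags
  explicitly (it ranks candidate bypasses, it does not prove them).
* Gene-deletion handling distinguishes "gene unknown to the model" (an
  error naming the gene) from "gene has no reactions" (valid, disables
  nothing, never essential).
* Rescaling with a raw coefficient of zero is the identity; a
  non-negative coefficient, a species already present, or a reactant
  with no resolvable mass are errors naming the offending entity.
* The screen's inner loop opens one exchange at a time; conjunctive
  rescues are only expressible through dataset records, and the
  medium-conditional toy gene is the planted example of a knockout no
  single compound can rescue.
* Exchange matching is exact on ids first, then case-insensitive on
  display names with extracellular compartments preferred; ambiguity is
  an error listing the candidates rather than a silent pick.

## Known limitations

No flux-variability, parsimonious-FBA, or metabolite-dilution variants:
growth-coupled dilution of intermediates is outside the steady-state LP,
so closed interconversion loops (the spermine/spermidine pattern) and
enzyme-cofactor dependencies (siroheme-class cases) remain mispredicted
by construction. Accuracy percentages computed on toy fixtures
characterize the pipeline, not any organism's reconstruction; consensus
model results additionally depend on the model release used.
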