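# auxogem

Auxotrophy-based simulation, evaluation, and curation for genome-scale
metabolic models (GEMs).

## The problem

An auxotroph is a mutant that cannot synthesize a compound it needs and
grows only when that compound is supplied. Collections of knockout →
rescue-compound observations (gene–compound pairs) are a demanding test
for a metabolic reconstruction: the model must predict *both* that the
deletion abolishes growth *and* that supplying the compound restores it.
Where it fails, the failure mode points directly at what to fix — a
spurious bypass reaction, a wrong gene–reaction rule, a missing synthesis
or exchange reaction, or an incomplete biomass composition. The same
machinery, run exhaustively, predicts which compound must be fed to every
engineered knockout — the design input for nutrient-dependent cell
factories and synthetic consortia.

`auxogem` implements this workflow end to end for anyone curating a GEM
(of yeast or otherwise): simulation, misprediction taxonomy, replayable
curation edits, the encoded curation set for the yeast consensus model
Yeast9, and a systematic gene × compound screen.

## The method

Growth is predicted by flux balance analysis: with stoichiometric matrix
*S*, flux vector *v* (mmol·gDW⁻¹·h⁻¹) and biomass indicator *c*,

```
max  cᵀv   subject to   S·v = 0,   lb ≤ v ≤ ub
```

The biomass flux is the growth rate μ (h⁻¹). A prediction is **viable**
iff μ ≥ 1% of the wild-type optimum (for Yeast9, 1% of 0.0859 h⁻¹);
infeasible problems count as μ = 0.

Each gene–compound pair is tested in two steps:

1. **Knockout.** Delete the gene set; a reaction is disabled when its
   gene–protein–reaction (GPR) boolean rule — OR for isoenzymes, AND for
   complexes — evaluates false. If the knockout is still viable the
   model contradicts the lethal experiment: a **type I** error.
2. **Rescue.** Otherwise open the rescue compounds' exchange reactions
   to unconstrained uptake (lower bound −1000 mmol·gDW⁻¹·h⁻¹) and
   re-solve. If no rescue conjunct restores viability: a **type II**
   error; otherwise the pair is **correct**. Rescue specifications are
   disjunctions of compound sets (e.g. homoserine OR methionine +
   threonine), and medium supplements (e.g. thiamine on YNB medium) stay
   open through both steps.

Curation edits repair the errors: blocking reactions (fully or
reverse-only), rewriting GPR rules, adding synthesis or exchange
reactions, and adjusting biomass pseudoreactions. Adding a species of
per-unit mass *mₙ* at coefficient *cₙ* to a pseudoreaction with original
reactant mass *M₀* rescales every reactant coefficient by

```
f = M₀ / (M₀ + |cₙ|·mₙ)
```

so the total reactant mass stays *M₀* and all pre-existing coefficient
ratios are preserved. The packaged Yeast9 curation set encodes 12 GPR
rewrites, 8 reaction blocks, two synthesis reactions, one exchange, and
two pseudoreaction adjustments (chitin into carbohydrate at a final
coefficient of −0.02361; glutathione into cofactor at −1 × 10⁻⁶).

## Worked example

Toy models with planted ground truth make every stage testable without
downloads. Here a four-precursor network plants one type-I trap (a
gene-free bypass keeps the knockout alive) and one type-II trap (the
rescue compound has no exchange reaction):

```python
from auxogem import (ViabilityPolicy, accuracy, apply_edits, run_dataset,
                     systematic_screen)
from auxogem.fixtures import PrecursorFlags, ToyGemConfig, make_toy_gem

config = ToyGemConfig(
    n_precursors=4,
    features=(
        PrecursorFlags(),
        PrecursorFlags(bypass=True),        # planted type-I trap
        PrecursorFlags(no_exchange=True),   # planted type-II trap
        PrecursorFlags(isoenzyme=True),
    ),
    seed=7,
)
model, truth = make_toy_gem(config)
policy = ViabilityPolicy.from_model(model)
results, summary = run_dataset(model, truth.records, policy)
print(f"accuracy before curation: {100 * accuracy(summary):.2f}%")

repaired, log = apply_edits(model, truth.repair_edits)
policy2 = ViabilityPolicy.from_model(repaired)
_, summary2 = run_dataset(repaired, truth.records, policy2)
print(f"accuracy after curation:  {100 * accuracy(summary2):.2f}%")
```

prints

```
accuracy before curation: 33.33%
accuracy after curation:  100.00%
```

Before curation one record is correct, one is type I (the bypass), one is
type II (the missing exchange); blocking the bypass and adding the
exchange — the two edits the truth declares — repairs both. The
systematic screen on the repaired model then recovers exactly the planted
rescue pairs:

```python
screen = systematic_screen(repaired, policy2)
for gene, hits in sorted(screen.rescues.items()):
    for ex, compound, growth in hits:
        print(f"  {gene} rescued by {compound} (growth {growth:.3f} /h)")
```

```
  YAA100W rescued by prec2 (growth 2.857 /h)
  YAD103C rescued by prec3 (growth 2.857 /h)
  YAE104W rescued by prec1 (growth 2.857 /h)
```

The same workflow is available from the shell (`auxogem fixture`,
`curate`, `simulate`, `evaluate`, `screen`, `compare`, `report`); see
`auxogem --help`.

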