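# pytarg

Transcriptome-constrained flux balance analysis for prioritizing metabolic
drug targets — in particular, for finding *personalized therapeutic
windows*: small sets of metabolic reactions whose simultaneous inhibition is
predicted to halve the growth of a target cell (e.g. a cancer cell line)
while sparing a reference cell (e.g. a healthy proliferating stem cell).

## Who this is for

Computational/systems biologists with (i) a genome-scale metabolic model
(GSMM) of a human cell in SBML L3+FBC (or this package's simple tabular
dialect) and (ii) RNA-seq expression tables in RPKM, who want flux
estimates, reaction-inhibition effect scores, differential-flux statistics,
and candidate selective target sets — without any omics beyond expression.

## The method

**Constraining.** For each reaction *r* with at least one associated gene,
take the RPKM of its highest-expressed gene, round it up to the next
multiple of 10, and cap the flux magnitude proportionally:

    |v_r| ≤ k · ceil₁₀( max_{g ∈ genes(r)} RPKM_g ),   k = 0.0027 mmol gDW⁻¹ h⁻¹ per RPKM

Irreversible reactions are capped in their allowed direction; reversible
reactions are capped symmetrically. Gene-associated but silent reactions
close (bound 0); reactions with no gene association keep their bounds. The
constant *k* can be re-fit to an observed growth rate by bisection
(`calibrate_k`).

**Flux estimation.** Fluxes solve the parsimonious FBA problem

    max v_biomass  s.t.  S·v = 0,  lb ≤ v ≤ ub,    then    min Σ_r |v_r|  at the fixed optimum,

and the optimal face can additionally be characterized by seeded
random-objective sampling (`sample_alternative_optima`), yielding
per-reaction means and standard deviations over alternative optima.

**Target scoring.** `block` throttles chosen reactions to 10 % of their
baseline parsimonious flux, re-solves, and reports the growth ratio
after/before: 0.1 means growth is fully coupled to a targeted reaction, 1.0
means other pathways fully compensate. `screen_targets` compares block
ratios between two groups of models with a Welch t-test per reaction.

**Target-set search.** `personal` ranks reactions by the difference in
baseline flux usage between target and reference cell, then greedily keeps a
candidate only if, cumulatively, target relative growth < 0.9 and exceeds
the reference's disadvantage by > 0.05; it stops when target relative growth
reaches 0.5.

**Differential statistics.** `differential_use` applies per-feature Welch
tests with Benjamini–Hochberg correction (FDR 0.01 by default);
`hallmarks` intersects differentially used reactions with differentially
expressed associated genes.

## Worked example

The bundled `SELECTIVE` toy scenario plants the mechanism behind a
therapeutic window: biomass needs two precursors, one of which the target
cell — lacking transporter gene `gT` — can only synthesize internally
(reaction `S`), while the reference cell can also import it (reaction `T`).

```bash
pytarg fixture --scenario SELECTIVE --out-dir sel
pytarg personal --model sel/model.tsv --target-expr sel/target.csv \
                --reference-expr sel/reference.csv --out targets.json
```

prints `{"accepted": ["S"], "converged": true}`, and `targets.json` records
the decision trace:

```json
{
  "accepted": ["S"],
  "trace": [
    {"reaction_id": "EX_A", "target_ratio_after": 0.0999999900,
     "reference_ratio_after": 0.0999999900, "accepted": false},
    {"reaction_id": "S", "target_ratio_after": 0.0999999900,
     "reference_ratio_after": 1.0, "accepted": true}
  ],
  "final_target_ratio": 0.0999999900,
  "final_reference_ratio": 1.0,
  "converged": true
}
```

Reading the trace: the shared uptake `EX_A` is ranked first (largest flux
difference) but rejected — throttling it hurts both cells equally (ratio
0.1 vs 0.1, no selectivity). The synthesis reaction `S` is then accepted:
the target drops to 10 % growth while the reference, which reroutes through
its transporter, stays at 100 %. The search converges with a one-reaction
target set.

Flux estimation and calibration on the linear `CHAIN3` scenario
(one gene-associated conversion at 37 RPKM, which rounds up to 40, so the
capacity is 0.0027 × 40 = 0.108):

```bash
pytarg fixture --scenario CHAIN3 --out-dir chain
pytarg flux --model chain/model.tsv --expr chain/target.csv --sample target --out flux.tsv
# objective 0.108
pytarg calibrate --model chain/model.tsv --expr chain/target.csv --sample target \
                 --observed-growth 0.108
# 0.002699999925
```

## Scope

The package does not align reads or compute RPKM, does not curate models,
and does not perform thermodynamic/loopless or quadratic flux fitting.
Exhaustive minimal-cut-set search is out of scope: the target-set search is
deliberately the greedy heuristic described above.
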