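# Methods

## Model and assumptions

The cell is modeled as a stoichiometric network at steady state: a matrix
`S` (metabolites × reactions) with flux bounds, and a biomass pseudo-reaction
whose flux is read as the growth rate (h⁻¹). All predictions are
constraint-based linear programs; no kinetics, no thermodynamics, no
regulation beyond what expression-derived bounds encode.

The central assumption is that mRNA abundance caps enzymatic capacity:
a reaction can carry at most a flux proportional to the RPKM of its
highest-expressed associated gene. This is a *ceiling*, not a demand —
constraining can only shrink bounds, never widen them. Treating the maximum
over a reaction's gene set as its capacity deliberately ignores AND/OR
structure in gene–protein–reaction associations (complex members vs
isoenzymes): associations are flattened to plain gene lists at parse time.
An AND-aware rule (min over complex members) would be strictly more
conservative and is not implemented; this is a known limitation.

## Parameters

| parameter | default | units / range | meaning |
|---|---|---|---|
| `k` | 0.0027 | mmol gDW⁻¹ h⁻¹ per RPKM | capacity per unit expression; re-fittable by `calibrate_k` |
| `granularity` | 10 | RPKM | expression rounds *up* to this grid before scaling |
| `block_fraction` | 0.1 | (0,1) | throttled reactions keep this fraction of baseline flux |
| `single_threshold` | 0.9 | ratio | keep a candidate only if target relative growth falls below this |
| `selectivity_margin` | 0.05 | ratio difference | required excess of reference over target relative growth |
| `stop_ratio` | 0.5 | ratio | search stops once target relative growth reaches this |
| `fdr_level` | 0.01 | — | Benjamini–Hochberg significance level |
| `solver_tolerance` | 1e-7 | — | LP feasibility/optimality slack |

Rounding expression up to a coarse grid keeps LP bounds away from clusters
of nearly-degenerate values; zero expression is deliberately *not* rounded
up (a silent gene closes its reaction rather than re-opening at one
granule). Genes absent from a profile count as 0 RPKM — absence is read as
non-expression, logged as a warning.

## Numerical choices

- **LP backend.** One contract, `solve_lp(c, S, lb, ub, A_ub, b_ub)`,
  backed by HiGHS through `scipy.optimize.linprog`. Infeasible/unbounded
  outcomes are reported as statuses, never exceptions, from `fba`.
- **Parsimonious stage.** The objective flux is fixed via
  `v_obj ≥ (1 − tol)·z*` (inequality rather than equality, robust across
  backends), then `Σ|v|` is minimized with the standard split `v = f − b`,
  `f, b ≥ 0`. Consequently reported objective values sit at `(1 − tol)·z*`;
  ratios of objectives inherit an O(tol) wobble, which is why block ratios
  print as 0.0999999900 rather than 0.1.
- **Alternative optima.** The sampler maximizes i.i.d. standard-normal
  random objectives at the pinned optimum, seeded via
  `numpy.random.default_rng(seed)`; identical seeds give bit-identical
  samples. Vertex sampling under random objectives was chosen over
  hit-and-run for its deterministic contract and because means/SDs over
  face vertices are what downstream summaries need; the scheme is isolated
  behind `sample_alternative_optima` and can be swapped. Default n = 100.
- **Throttling rule.** For baseline flux `v > 0` the upper bound becomes
  `fraction·v` (lower bound capped to stay consistent); for `v < 0` the
  mirror; for `v = 0` the reaction closes. Throttling always refers to the
  *initial* parsimonious flux of each model, so the greedy search is
  order-dependent but deterministic.
- **Ranking and ties.** Candidates are ranked by `|v_target| − |v_reference|`
  (magnitudes make reversible reactions rank by usage; a signed variant sits
  behind `signed_ranking`), ranked once up front, ties broken
  lexicographically by reaction id for cross-platform determinism. The
  biomass reaction itself and candidates idle in both baselines are skipped
  (throttling them cannot create selectivity or change either ratio).
- **Acceptance test for a candidate.** Strict inequalities
  (`target < 0.9`, `reference − target > 0.05`), reading the margin as
  selectivity *against the target*; cumulative relative growth is used
  throughout because the stopping rule only makes sense cumulatively.
- **Degenerate statistics.** Two constant equal groups give `t = 0, p = 1`;
  constant unequal groups give the degenerate `p = 0` and are logged. The
  Welch–Satterthwaite denominator is guarded against float underflow.
  Welch (not pooled Student) is the default because group variances across
  heterogeneous cell lines/tissues cannot be assumed equal.
- **Calibration.** `calibrate_k` bisects on `k ∈ [1e-6, 1]`, exploiting
  that optimal growth is non-decreasing in `k`; an observed growth of 0
  returns the lower search bound with a warning, an unreachable growth
  raises.

## What the toy scenarios emulate — and what they do not

The bundled fixtures reproduce, at 3–10 reactions, each coupling regime the
method distinguishes: full coupling (CHAIN3), full compensation and
alternative optima (PARALLEL, uptake-limited so the two routes trade flux),
a planted therapeutic window driven by a missing transporter gene
(SELECTIVE — the same mechanism as cholesterol-auxotrophic cells that lack
a functional sterol importer and become dependent on biosynthesis), a
futile cycle that parsimony must silence (CYCLE), and seeded sparse random
networks with a planted feasible chain (RANDOM). All fixture bounds bracket
zero, so a throttled model always retains the fraction-scaled baseline
solution and block ratios provably stay in `[fraction, 1]`.

What they do not emulate: compartments, cofactor coupling, biomass
stoichiometry with many precursors, thousands of reactions with correlated
expression, or measurement noise in RPKM. Passing tests therefore certify
the *algorithmic contracts* (LP correctness against exhaustive enumeration,
bound arithmetic, ratio algebra, greedy-search behavior, statistical
calibration) — not predictive accuracy on real cells, which additionally
depends on the quality of the genome-scale reconstruction and expression
data used.

## Problem sizes used in tests and the acceptance script

Exhaustive LP cross-checks enumerate basic feasible points on models of up
to 10 reactions (the sign-aware enumeration needed for the parsimonious
check is combinatorial and is run exactly up to 8 reactions, with a
face-vertex bound above that). The statistics calibration uses 20
replicates of 1000 features × 10 + 10 samples; the sampler contract uses
n = 100 draws. These sizes were chosen so the entire suite completes in
well under a minute while every regime is still exercised.

## Known limitations

- No AND-semantics in gene associations (see above).
- The block lower-bound guarantee (`ratio ≥ fraction`) requires all bounds
  to bracket zero; models with forced maintenance fluxes can fall below it.
- The greedy search returns *a* small selective set, not a provably minimal
  one; re-ranking after each acceptance is deliberately not done (single
  upfront ranking keeps the procedure cheap and reproducible).
- `screen_targets` treats each model's ratio as one observation; it does
  not propagate within-model alternative-optima uncertainty into the test.
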