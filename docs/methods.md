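# Methods

## Model and assumptions

`contextflux` works on the standard constraint-based abstraction of
metabolism: a stoichiometric matrix `S` (metabolites × reactions), flux
bounds `lb ≤ v ≤ ub` in consistent units (conventionally mmol/gDW/h),
and the steady-state assumption `S v = 0`. Flux balance analysis (FBA)
maximizes the declared objective (biomass) flux `Z` over this polytope.
The package assumes the input GENRE is already curated — it validates
structure (unique ids, bound ordering, a declared objective) but does
not gap-fill, balance-check formulas, or edit the medium: exchange
reactions keep exactly the bounds the model file declares.

Transcript integration assumes abundances are comparable across genes
within one sample (RPKM-like). No cross-sample renormalization is
applied; the weighting below is scale-free per sample by construction.

## Transcript-weighted parsimony

Per reaction, gene abundances are combined through the GPR rule with
AND → min (an enzyme complex is limited by its scarcest subunit) and
OR → max (isozymes contribute their most abundant member). Reactions
without genes receive the median of the gene-backed reaction scores — a
neutral cost for transport/exchange/biomass pseudo-reactions. Abundances
`a_r` map to weights `w_r = 1 − a_r / max_r(a_r)` in [0, 1]: the linear
antitone map is the simplest choice consistent with "expressed pathways
are cheap to use", and downstream results depend only on the ordering
and rough spacing of weights, not the exact functional form.

The contextualization LP minimizes `Σ_r w_r (v_r⁺ + v_r⁻)` (an exact
split-variable linearization of `Σ w_r |v_r|`) subject to
`v_obj ≥ fraction · Z`. `fraction` defaults to 1.0 — only exactly
optimal states count — with 0.8 available in the configuration for
comparison with common context-extraction defaults.

## Pruning

A single parsimony-optimal vertex is solver-dependent, so pruning never
inspects it. Instead, flux variability analysis (FVA) runs under two
constraints — the objective floor and a cap on the weighted total flux
at `(1 + parsimony_slack) ×` the minimized value — and a reaction is
pruned when its attainable range lies within ±1e−6 flux units of zero.
This is robust to alternate optima: a reaction survives iff *some*
near-parsimonious optimal state uses it.

Numerical choices here interact and were set together:

* pruning tolerance: 1e−6 absolute flux units;
* `parsimony_slack`: 1e−9 relative (plus the 1e−9 LP feasibility
  tolerance absolutely). The slack exists only to keep the cap feasible
  under solver round-off. It must stay well below
  `pruning_tolerance × w_r / parsimony_value`; a looser slack (e.g.
  1e−6 relative, i.e. ~1e−5 absolute on a typical parsimony value of
  ~15) would let every low-weight reaction carry flux above the pruning
  tolerance and make pruning vacuous.
* LP solver: scipy's HiGHS interface, single-threaded, fixed
  tolerances — deterministic across runs and platforms of the same
  library versions.

## Flux sampling

Sampling uses artificial-centering hit-and-run (ACHR) over the pruned
polytope intersected with the objective floor and the parsimony cap.
Warmup points are the FVA extreme vertices; directions are drawn as
(random warmup − running center), which keeps every step inside the
affine space `S v = 0`; chords are clipped against the box bounds, the
objective floor, and the convex piecewise-linear cap (by bisection, 60
iterations). Burn-in is 100 steps and thinning 10; all draws come from
a seeded NumPy generator, so sample matrices are reproducible bit for
bit. The per-patient sample count is
`clamp(round(mean FVA range width), 50, 500)` — wider permissible
ranges earn more samples. A zero-volume polytope (common at
fraction = 1.0 with strictly ordered weights, where the optimum is a
single vertex) yields n copies of the parsimonious optimum and a logged
warning rather than an error.

## Classification and aggregation

All of a patient's flux points share the patient's label and are highly
correlated, so every train/test split operates on patients: per group,
`floor(0.8 n)` patients train, the rest test, and metrics are row-level
on the held-out patients' points. Class imbalance is handled by
uniform random under-sampling of majority-group patients before each
split. The classifier is scikit-learn's random forest with 100 trees,
Gini impurity, unlimited depth and √p features per node, seeded per
split. F1 uses "case" as the positive class.

Splits with F1 strictly greater than 0.70 qualify; each contributes its
top-20 reactions by impurity importance. The consensus ranking orders
reactions by qualification frequency, then mean importance over the
qualifying splits in which they appeared, then id — frequency first
because it is the most conservative consensus across resampled splits.
All stage seeds (under-sampling, splitting, forests, samplers) derive
from one master seed through tagged `SeedSequence` streams.

## Group comparison

The Mann–Whitney U test is two-sided, computed exactly (permutation
null) when the pooled sample has ≤ 16 observations without ties, and by
the tie-corrected normal approximation with continuity correction
otherwise. The default pools all flux points of a group's patients —
matching how sampled flux distributions are plotted — and a
per-patient-mean mode (one observation per patient) is available for
sensitivity analysis, since pooled points overstate the effective
sample size. Raw p < 0.05 is the decision rule; Benjamini–Hochberg
adjusted p-values are reported in a supplementary column.

## Synthetic benchmark

The generator emulates the *statistical structure* the method assumes:
metabolically redundant alternative routes to biomass whose gene
expression differs between groups. The toy network is one bounded
uptake (0 → A, [0, 10]), `n_linear_pathways` (default 2) parallel
single-gene chains A → … → B of length 3, a biomass sink B → 0, and 10
gene-bearing background reactions (paired import/export loops) that are
flux-neutral with respect to biomass. Abundances are
`base (10) × multiplier × exp(N(0, 0.5))` with multiplier
`effect_fold (4)` on the group's favored pathway genes,
`1/effect_fold` on the opposing pathway's, and 1 elsewhere; cohorts are
20 + 20. `effect_fold = 1` yields an exchangeable null cohort.

What passing on this benchmark shows — and what it does not: it
validates the machinery end to end (overlay, weighted parsimony,
pruning, sampling, leakage-free repeated classification, aggregation,
testing) on a cohort where ground truth is known. It does not emulate
genome-scale model properties (thousands of reactions, complex GPRs,
loops, many alternate optima), library-size or batch effects, or
biological covariance between genes; effect sizes on real data are far
subtler than a 4-fold planted swap.

A structural consequence worth knowing: with fraction = 1.0, one gene
per reaction and strictly ordered weights, each toy patient's feasible
set collapses to a single vertex, so flux features are effectively
binary "which route did parsimony pick" indicators. On a *fixed* finite
null cohort, repeated splits can then persistently exploit the chance
association between route choice and group label, holding mean accuracy
near 0.65 and letting a substantial fraction of splits clear F1 > 0.70;
across *fresh* null cohorts this association averages out. Null
controls should therefore vary the generator seed, not only the
pipeline seed — the acceptance checks do.

## Problem sizes

Default test and acceptance runs use the 18-reaction toy network,
40-patient cohorts, 50 flux points per patient and 100 splits;
oracle-backed LP checks use random networks of 4–8 reactions with
feasible-set dimension ≤ 3 so that brute-force vertex enumeration stays
exact and fast.

## Known limitations

* COBRA-JSON is canonical I/O; SBML is read-only (via cobrapy) and
  round-trip fidelity is only guaranteed for the JSON dialect.
* The weight map and the gene-less-reaction median rule are pragmatic
  stand-ins for any particular published scaling; conclusions that
  depend on fine weight differences should be checked for robustness.
* Impurity-based importances are biased toward high-cardinality
  features; with flux features this mainly means correlated reactions
  in one pathway share credit, which the family grouping absorbs.
* Pooled Mann–Whitney p-values treat flux points as independent, which
  they are not within a patient; use the per-patient-mean mode when
  calibrated p-values matter.
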