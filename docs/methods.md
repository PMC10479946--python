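# Methods

This note records the modeling assumptions, parameter choices and numerical
conventions behind `fluxshift`, including the places where the method as
published leaves a choice open and what this implementation chose.

## Model container and GPR semantics

A model is a plain stoichiometric network: metabolites, reactions with flux
bounds (model flux units throughout), boolean gene–protein–reaction rules,
and a single linear objective (the biomass or demand reaction). The JSON
dialect mirrors COBRA JSON (with a `schema_version` field) so Recon3D-style
files load unchanged; SBML L3+fbc goes through cobrapy/libsbml.

GPR scores aggregate gene expression with AND → min and OR → max by default:
an enzyme complex is limited by its scarcest subunit, while isozymes provide
alternative capacity. OR → sum is available for users who prefer additive
isozyme capacity. Genes missing from the score map are *absent*: OR ignores
absent children, AND with an absent child is absent, and absent-scored
reactions are exempt from every expression-based decision — the alternative
(treating missing as zero) silently deletes unannotated reactions, which is
worse than doing nothing.

## Condition-specific construction

Order of operations: medium bounds → measurement bounds → global pruning →
per-drug pruning. The ordering is a choice (the published procedure does not
state whether pruning preceded the respiration constraints); applying the
bounds first makes the feasibility guard test exactly the model that will be
used downstream, which is the conservative reading.

* **Medium.** Exchanges not listed in the medium have their uptake direction
  closed; listed ones get the stated uptake/secretion caps, clipped to the
  template's own capacity (the medium can only restrict, never widen).
* **Measurements.** Respiration parameters map to reactions (oxygen uptake
  for OCR/basal respiration, the ATP demand for ATP production) with an
  explicit unit-conversion factor, and bounds are intersected with
  mean ± k·σ, default k = 2 — "achieving the measured rates" is read as
  compatibility with a 2σ interval since no tolerance is published. An empty
  intersection is an error naming the measurement, not a silent clamp.
* **Pruning.** Candidates (reaction-level scores below the FPKM threshold of
  1 in all conditions; strict `< 1`) are removed greedily one at a time in
  ascending order of their max-across-conditions score, ties broken by
  reaction id, re-checking after each removal that the biomass optimum stays
  ≥ 20 % of the pre-pruning optimum under all imposed bounds. Batch removal
  was rejected: the per-removal guard is what makes the construction
  order-independent of arbitrary dict ordering and gives a deterministic,
  auditable log (every accepted and rejected candidate with its reason).
* The biomass reaction is a configurable slot; the toy fleet uses its ATP
  demand as the stand-in. A published macrophage biomass equation can be
  dropped in unchanged when available.

## Reference flux distribution

* **Penalties.** `p_i = s_max − s_i` on `s_i = log2(FPKM_i + 1)`; the
  published description says only "weighted by gene expression", so the
  standard GIM3E functional form was adopted (a linear-FPKM variant is
  selectable). Unscored reactions get penalty 0.
* **Minimization.** `min Σ w_i |v_i|` with `w_i = p_i + fallback` over the
  irreversible split model, subject to biomass ≥ 20 % of optimum. The
  uniform fallback (default 1) keeps the LP bounded when all penalties are
  zero and makes the uniform-expression case coincide exactly with
  parsimonious FBA — a property the test suite checks against cobrapy's
  independent implementation.
* **Solution space.** "Within 99 % of the optimum" for a minimization is
  ambiguous; it is implemented as `Σ w_i |v_i| ≤ (1 + slack)·P*` with slack
  0.01, the standard fraction-of-optimum semantics.
* **Sampling.** ACHR with warmup points taken from the FVA vertex solutions
  (two per reaction, capped at `n_warmup`), the center initialized at the
  warmup mean, direction = stored point − running center, and a uniform step
  on the feasible chord. The walk runs in null-space coordinates
  (`x = N z`, N an orthonormal basis of null(S) of the split model), so
  every emitted sample satisfies mass balance to machine precision by
  construction; box bounds and the penalty-budget/biomass rows become
  inequality constraints on z and bound the chord. Sampling in the split
  space keeps the |v| budget linear; a sample with simultaneous
  forward/backward flux maps to a net flux whose weighted norm is only
  smaller, so the budget is respected after mapping. Defaults: 5,000
  samples, thinning 100 (none of these are published; tests and the
  acceptance script use 200–1,000 samples with thinning 10, which the toy
  polytopes mix through easily). Sampling is bitwise seed-deterministic.
* `v_ref` is the componentwise sample mean; magnitudes below 1e−9 are
  clamped to 0 so downstream reference-scaled divisions are stable.

## Quadratic transformation

The objective is separable per reaction — every term is
`w·(v_i − target)²` — so the QP has a diagonal Hessian with the
stoichiometric equalities and box bounds as constraints. OSQP solves it with
eps 1e−10 and polishing; an independent trust-constr (interior point) solve
of the same program serves as the oracle in tests, and the two agree to
~1e−8 in flux on the toy fleet.

Conventions where the published formula is ambiguous or silent:

* Denominator exponents: the DE term divides by `(v_ref·(FC−1))²` (squared,
  as typeset) and the unchanged term by `|v_ref|` (unsquared). The
  alternative reading (squared unchanged denominator) sits behind
  `QMTAConfig.squared_ru_denominator`.
* The measured term divides by σ (not σ²), following the formula as printed.
* `|v_ref|` in denominators is floored at `epsilon_ref = 1e−6`; `|FC − 1|`
  at `epsilon_fc = 1e−6` (a gene at FC ≈ 1 contributes nothing — its target
  equals the reference). A DE-targeted reaction with `v_ref = 0` falls back
  to an unscaled squared deviation, logged.
* Membership: a measured reaction is Rexp even if a DE gene maps to it
  (experimental data overrides, logged); otherwise DE-targeted if any
  significant gene maps to it; otherwise Ru. Each DE gene contributes its
  own term per mapped reaction (the literal double sum) — fold changes are
  never pre-aggregated per reaction.
* Targets scale the signed reference flux (`target = v_ref·FC`), so a fold
  change amplifies or damps flux along the reference direction.
* The strict `lb < v < ub` of the published constraint is implemented as
  closed bounds (QP solvers require closed sets).
* Gene weights use FDR-adjusted p-values with `p_th = 0.25`; the pruning
  stage keeps its own stricter FDR < 0.05 gate, each following its quoted
  context. Note the consequence checked in the test suite: on an unbranched
  chain where only one reaction carries a DE gene, mass balance plus the
  unchanged-flux term yield a *weighted compromise* between the expression
  target and the reference, not a full doubling — the flux-variation term
  is a genuine prior toward the reference state.

Per-reaction output is `log2((|v_MTA|+ε)/(|v_ref|+ε))` with a separate
direction-flip flag (a magnitude ratio cannot express sign reversal), plus
the raw predicted flux, grouped by subsystem in the pathway report.

## DEG overlap

The DEG gate is `|log2FC| ≥ 1 and p < 0.05` on the raw p column (FDR
optional). Venn summaries store counts and always recompute percentages from
them with half-up rounding to one decimal; published percentage values that
are not arithmetic-consistent with their own counts cannot be reproduced by
any set arithmetic and are not asserted.

## Synthetic data: what it emulates, and what it does not

The generator emulates the pipeline's full input surface: a toy metabolic
network with hand-derivable optima (the canonical 8-reaction cell has FBA
optimum 20), a feasible ground-truth perturbed flux state (requested
per-reaction multipliers projected onto the feasible set by a small QP, with
*achieved* fold changes reported as truth), an FPKM matrix whose gene fold
changes equal the achieved flux fold changes of their reactions at zero
noise (log-normal baseline, median 10 FPKM; 4 samples per condition,
matching typical donor counts), a DE table, and noisy measurements
(mean·(1+ε), ε ~ N(0, cv), σ floored at 1e−3).

The coupling between expression and flux is deliberately direct so that a
recovery failure implicates the pipeline, not the generator. Consequently,
passing the recovery tests shows the optimization faithfully inverts the
generative convention — it does *not* show that real enzymes' expression
fold changes translate into flux fold changes, which is precisely the
biological approximation the method rests on. The generator's FDR column is
likewise a labeling convention (two-sample t on logs at small n, floored at
1e−6 in the noiseless case) for exercising the significance weighting, not a
statistical claim. Realistic count-level RNA-seq noise (negative binomial,
library sizes) is out of scope.

## Problem sizes and tolerances

Feasibility checks use 1e−6; LP optimality is HiGHS defaults (~1e−9
relative); OSQP runs at 1e−10 with polishing. The test suite and acceptance
script run on the 8-reaction toy fleet (20 seeds for recovery and oracle
equivalence, 10,000 draws for the 1-D sampler check, 1,000 for the polytope
soundness check), sizes chosen so the full suite completes in well under a
minute while keeping every Monte-Carlo band at 3σ or tighter.

## Known limitations

* Headline fluxes from the original genome-scale study (Recon3D, deposited
  patient-derived expression, unpublished respiration values, a published
  macrophage biomass equation) are supported as a data mode but not
  reproduced here; the toy fleet exercises every code path instead.
* No thermodynamic/loopless constraints; flux cycles are discouraged only by
  the weighted-minimization objective and the penalty budget.
* Single linear objective; no multi-objective biomass trade-offs.
* ACHR convergence is monitored only through the mean-stability and
  soundness checks; no formal mixing diagnostics.
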