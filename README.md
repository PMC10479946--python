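# fluxshift

Predict how a drug treatment redistributes metabolic flux in a cell, starting
from nothing but transcriptomics, a handful of respiration measurements, and a
genome-scale metabolic model.

`fluxshift` is aimed at systems biologists who have differential-expression
results for a treated vs. control condition (e.g. macrophages exposed to a
DNA-binding antitumor drug) and want a constraint-based estimate of the
metabolic flux state the treatment induces — which pathways speed up, which
shut down, and by how much — without any isotope-tracing data.

## What it computes

The pipeline has three stages, all over a stoichiometric model
(S, lb, ub, gene–protein–reaction rules):

1. **Condition-specific model construction.** Reactions whose GPR-aggregated
   expression (mean FPKM; AND → min, OR → max) is below 1 in *every*
   condition are removed one at a time, each removal accepted only if the
   model still produces ≥ 20 % of the optimal biomass and still admits the
   measured respiration rates (oxygen uptake, ATP production; bounds
   mean ± 2σ). Significantly down-regulated reactions (FDR < 0.05) that are
   lowly expressed only under the drug are additionally removed from that
   drug's model.

2. **Reference flux distribution** `v_ref` for the control condition:
   an expression-weighted flux minimization (penalty `s_max − s_i` on
   `log2(FPKM+1)` scores, GIM3E-style) subject to the biomass and
   measurement constraints; flux variability analysis restricted to within
   1 % of that optimum; artificially-centered hit-and-run (ACHR) sampling of
   the restricted polytope; `v_ref` = per-reaction sample mean.

3. **Quadratic metabolic transformation (qMTA).** The treated state
   `v` solves the convex QP

   ```
   min   Σ_{m∈DExp} W_m Σ_{i∈R_m} ( (v_i^ref·FC_m − v_i) / (v_i^ref (FC_m − 1)) )²
       + Σ_{i∈Ru} (v_i^ref − v_i)² / |v_i^ref|
       + Σ_{j∈Rexp} (E_j − v_j)² / σ_j
   s.t.  S v = 0,   lb ≤ v ≤ ub
   ```

   with gene weights `W_m = log10(p_th) − log10(p_m)`, `p_th = 0.25` on
   FDR-adjusted p-values. DExp are the significantly changed genes, R_m the
   reactions carrying gene m, Ru the reactions mapped to no changed gene or
   measurement, Rexp the measured fluxes. Both fitted terms are scaled by
   the reference flux so high-flux reactions do not dominate. Results are
   reported per reaction as log2 fold change of flux, grouped by pathway.

A DEG-overlap module (|log2FC| ≥ 1, p < 0.05 gate; top-N ranking; exact
Venn arithmetic) and a synthetic-data generator (toy networks with known
optima, ground-truth flux perturbations, expression/DE tables consistent
with them, noisy measurements) complete the package, so the whole pipeline
runs and is tested end-to-end with no external data.

## Worked example

Generate a ground-truth scenario on the 8-reaction toy cell (glycolysis-like
upper branch, O2-limited oxidative branch, fermentative overflow), then fit
the treated state from its DE table and measurements:

```python
import fluxshift as fs

sc = fs.make_scenario(seed=0, noise_cv=0.0)      # truth: R_upper x3.1, R_ferm x3.2, R_ox x0.45
vref = fs.FluxDistribution(dict(sc.v_control), sc.model.id)
vref.check_feasibility(sc.model)
weights = fs.gene_weights(sc.de_table)
spec = fs.assemble_qp(sc.model, vref, sc.de_table, weights, sc.measurements)
result = fs.solve_qmta(spec)
print(fs.pathway_report(result, sc.model).to_string(index=False))
```

```
      subsystem reaction_id  v_ref  v_mta  log2FC  sign_flip direction
         Demand      DM_ATP 12.000 13.990   0.221      False        up
       Exchange        EX_A  6.000  9.818   0.710      False        up
       Exchange        EX_C  3.000  2.086  -0.524      False      down
       Exchange        EX_D  3.000  7.732   1.366      False        up
       Exchange       EX_O2  3.000  2.086  -0.524      False      down
Glycolysis-like      R_ferm  3.000  7.732   1.366      False        up
Glycolysis-like     R_upper  6.000  9.818   0.710      False        up
      Oxidative        R_ox  3.000  2.086  -0.524      False      down
```

The fitted shifts recover the generating perturbation: the fermentative
branch more than doubles (true log2FC 1.370, predicted 1.366), the oxidative
branch drops (true −0.528, predicted −0.524), and the stoichiometrically
coupled exchanges follow. The objective decomposes into its DE, unchanged
and measured terms (here 0.0008 + 10.17 + 0.043).

The same flow is available from the shell:

```bash
fluxshift synth --scenario glyc-ox-8 --seed 1 --out data/
fluxshift run --config cfg.json          # reference + qMTA + reports
fluxshift venn --a de_drugA.tsv --b de_drugB.tsv --direction up
```

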