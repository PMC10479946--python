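"""Synthetic inputs: toy networks, ground-truth flux perturbations, expression
and differential-expression tables consistent with them, and noisy flux
measurements.

The generator couples gene expression to flux deliberately directly (at zero
noise the expression fold change of a gene equals the achieved flux fold
change of its reaction), so that a failure of downstream recovery implicates
the pipeline rather than the generator.  The FDR column it emits is a
labeling convention for exercising significance weighting, not the output of
a real differential-expression fit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FluxDistribution, MetabolicModel, Metabolite, Reaction
from .lp import fba

__all__ = [
    "toy_network",
    "random_network",
    "perturb_fluxes",
    "synth_expression",
    "synth_measurements",
    "GroundTruthScenario",
    "make_scenario",
]


def toy_network(spec: str = "glyc-ox-8") -> MetabolicModel:
    """Named toy fixtures.

    ``glyc-ox-8`` is an 8-reaction cell with a glycolysis-like upper branch
    (substrate A -> B, 1 ATP), an oxygen-limited oxidative branch
    (B + O2 -> C, 2 ATP) and a fermentative overflow branch (B -> D), plus an
    ATP demand as the biomass stand-in.  Its FBA optimum is 20:
    10 ATP from the upper branch plus 2 x 5 from the O2-capped oxidative one.
    """
    if spec != "glyc-ox-8":
        raise ValueError(f"unknown toy network {spec!r}")
    m = MetabolicModel(id="glyc-ox-8", compartments={"c": "cytosol"})
    for mid in ["A", "B", "C", "D", "O2", "ATP"]:
        m.metabolites.append(Metabolite(mid, mid, "c"))
    m.reactions = [
        Reaction("EX_A", {"A": 1.0}, 0.0, 10.0, subsystem="Exchange", name="A uptake"),
        Reaction("EX_O2", {"O2": 1.0}, 0.0, 5.0, subsystem="Exchange", name="O2 uptake"),
        Reaction("R_upper", {"A": -1.0, "B": 1.0, "ATP": 1.0}, 0.0, 1000.0,
                 gpr="g1", subsystem="Glycolysis-like", name="upper pathway"),
        Reaction("R_ox", {"B": -1.0, "O2": -1.0, "C": 1.0, "ATP": 2.0}, 0.0, 1000.0,
                 gpr="g2 and g3", subsystem="Oxidative", name="oxidative branch"),
        Reaction("R_ferm", {"B": -1.0, "D": 1.0}, 0.0, 1000.0,
                 gpr="g4 or g5", subsystem="Glycolysis-like", name="fermentative branch"),
        Reaction("EX_C", {"C": -1.0}, 0.0, 1000.0, subsystem="Exchange", name="C secretion"),
        Reaction("EX_D", {"D": -1.0}, 0.0, 1000.0, subsystem="Exchange", name="D secretion"),
        Reaction("DM_ATP", {"ATP": -1.0}, 0.0, 1000.0, subsystem="Demand",
                 name="ATP demand (biomass stand-in)"),
    ]
    m.genes = ["g1", "g2", "g3", "g4", "g5"]
    m.objective = {"DM_ATP": 1.0}
    m.validate()
    return m


def random_network(n_chain: int = 4, n_branch: int = 2, seed: int = 0,
                   max_retries: int = 10) -> MetabolicModel:
    """A randomized linear pathway with secreting side branches.

    Guaranteed (with bounded retries) to pass model validation and to have a
    strictly positive demand optimum.
    """
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        m = MetabolicModel(id=f"chain-{n_chain}-{n_branch}-s{seed}",
                           compartments={"c": "cytosol"})
        mets = [f"M{i}" for i in range(n_chain + 1)]
        for mid in mets + ["P"]:
            m.metabolites.append(Metabolite(mid, mid, "c"))
        uptake = float(rng.uniform(2, 10))
        m.reactions.append(Reaction("EX_M0", {"M0": 1.0}, 0.0, uptake, subsystem="Exchange"))
        gene_i = 0
        for i in range(n_chain):
            gene = f"g{gene_i}"
            gene_i += 1
            m.reactions.append(
                Reaction(f"R{i}", {mets[i]: -1.0, mets[i + 1]: 1.0, "P": 1.0},
                         0.0, 1000.0, gpr=gene, subsystem="Chain"))
        for b in range(n_branch):
            src = mets[int(rng.integers(1, n_chain))]
            gene = f"g{gene_i}"
            gene_i += 1
            m.reactions.append(
                Reaction(f"B{b}", {src: -1.0}, 0.0, float(rng.uniform(1, 5)),
                         gpr=gene, subsystem="Branch"))
        m.reactions.append(Reaction(f"EX_{mets[-1]}", {mets[-1]: -1.0}, 0.0, 1000.0,
                                    subsystem="Exchange"))
        m.reactions.append(Reaction("DM_P", {"P": -1.0}, 0.0, 1000.0, subsystem="Demand"))
        m.genes = [f"g{i}" for i in range(gene_i)]
        m.objective = {"DM_P": 1.0}
        m.validate()
        res = fba(m)
        if res.ok and res.objective_value and res.objective_value > 1e-6:
            return m
    raise RuntimeError(f"could not generate a feasible random network from seed {seed}")


# ---------------------------------------------------------------------------
# Ground-truth perturbation
# ---------------------------------------------------------------------------

def perturb_fluxes(
    model: MetabolicModel,
    v_control: dict[str, float],
    plan: dict[str, float],
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Project requested per-reaction multipliers onto the feasible flux set.

    Solves min ||v - target||^2 s.t. S v = 0, lb <= v <= ub, where
    target_i = plan[i] * v_control_i for planned reactions and v_control_i
    otherwise.  Returns ``(v_treated, achieved_fc)`` where achieved fold
    changes are computed from the projection (not the request).
    """
    import osqp
    from scipy import sparse

    rids = model.reaction_ids()
    unknown = sorted(set(plan) - set(rids))
    if unknown:
        raise KeyError(f"perturbation plan names unknown reactions: {unknown}")
    v0 = np.array([v_control[rid] for rid in rids])
    target = v0.copy()
    for rid, mult in plan.items():
        target[rids.index(rid)] = mult * v_control[rid]
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = len(rids)
    P = sparse.csc_matrix(2.0 * sparse.eye(n))
    q = -2.0 * target
    A = sparse.vstack([sparse.csc_matrix(S), sparse.eye(n)], format="csc")
    l = np.concatenate([np.zeros(S.shape[0]), lb])
    u = np.concatenate([np.zeros(S.shape[0]), ub])
    prob = osqp.OSQP()
    prob.setup(P=P, q=q, A=A, l=l, u=u, eps_abs=1e-10, eps_rel=1e-10,
               max_iter=200_000, polishing=True, verbose=False)
    res = prob.solve()
    if "solved" not in res.info.status:
        raise RuntimeError(f"perturbation projection failed: {res.info.status}")
    v = np.clip(res.x, lb, ub)
    v_treated = dict(zip(rids, map(float, v)))
    eps = 1e-9
    achieved = {
        rid: float((abs(v_treated[rid]) + eps) / (abs(v_control[rid]) + eps))
        for rid in rids
    }
    return v_treated, achieved


# ---------------------------------------------------------------------------
# Expression + DE tables
# ---------------------------------------------------------------------------

def synth_expression(
    model: MetabolicModel,
    v_control: dict[str, float],
    v_treated: dict[str, float],
    noise_cv: float = 0.0,
    n_samples: int = 4,
    seed: int = 0,
    baseline_median: float = 10.0,
    conditions: tuple[str, str] = ("control", "treated"),
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """FPKM matrix (gene x sample), sample->condition map, and a DE table.

    Baseline FPKM is log-normal with median ``baseline_median``.  Each gene
    attached to a reaction whose flux changed gets its treated mean scaled by
    the achieved flux fold change of that reaction (geometric mean across
    reactions when a gene maps to several).  Per-sample noise is
    multiplicative log-normal with coefficient of variation ``noise_cv``.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(model.genes)
    eps = 1e-9
    gene_fc: dict[str, float] = {}
    for g in genes:
        logs = []
        for r in model.reactions:
            if g in r.genes():
                fc = (abs(v_treated[r.id]) + eps) / (abs(v_control[r.id]) + eps)
                logs.append(math.log(fc))
        gene_fc[g] = math.exp(float(np.mean(logs))) if logs else 1.0

    base = baseline_median * np.exp(rng.normal(0.0, 0.5, size=len(genes)))
    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0
    cols, names, cond_map = [], [], {}
    for ci, cond in enumerate(conditions):
        for s in range(n_samples):
            mean = base * np.array([gene_fc[g] if ci == 1 else 1.0 for g in genes])
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=len(genes))) if sigma else 1.0
            cols.append(mean * noise)
            name = f"{cond}_{s + 1}"
            names.append(name)
            cond_map[name] = cond
    fpkm = pd.DataFrame(np.column_stack(cols), index=genes, columns=names)
    fpkm.index.name = "gene"

    ctrl_cols = [n for n in names if cond_map[n] == conditions[0]]
    trt_cols = [n for n in names if cond_map[n] == conditions[1]]
    mc = fpkm[ctrl_cols].mean(axis=1)
    mt = fpkm[trt_cols].mean(axis=1)
    fc = (mt + eps) / (mc + eps)
    log2fc = np.log2(fc)

    from scipy import stats

    pvals = []
    for g in genes:
        a = np.log(fpkm.loc[g, ctrl_cols].to_numpy() + eps)
        b = np.log(fpkm.loc[g, trt_cols].to_numpy() + eps)
        if np.std(a) < 1e-12 and np.std(b) < 1e-12:
            # noiseless convention: changed genes are called with a floor FDR
            pvals.append(1e-6 if abs(math.log(fc[g])) > 1e-9 else 1.0)
        else:
            pvals.append(float(stats.ttest_ind(a, b, equal_var=False).pvalue))
    p = np.clip(np.array(pvals), 1e-300, 1.0)
    fdr = np.minimum(1.0, p * len(p) / stats.rankdata(p, method="max"))
    de = pd.DataFrame({
        "gene": genes,
        "log2FC": log2fc.to_numpy(),
        "FC": fc.to_numpy(),
        "pvalue": p,
        "FDR": fdr,
    })
    return fpkm, cond_map, de


def synth_measurements(
    v_treated: dict[str, float],
    reaction_ids: list[str],
    cv: float = 0.05,
    seed: int = 0,
) -> list[dict]:
    """Noisy flux measurements (mean, sd) for the named reactions.

    mean = v * (1 + eps), eps ~ Normal(0, cv); sd = cv * |mean| floored at
    1e-3 so a zero-flux measurement still has positive uncertainty.
    """
    rng = np.random.default_rng(seed)
    out = []
    names = {"EX_O2": "OCR", "DM_ATP": "ATP_production"}
    for rid in reaction_ids:
        true = v_treated[rid]
        mean = float(true * (1.0 + rng.normal(0.0, cv))) if cv > 0 else float(true)
        sd = max(cv * abs(mean), 1e-3)
        out.append({
            "parameter": names.get(rid, "basal_respiration"),
            "reaction_id": rid,
            "mean": mean,
            "sd": sd,
            "units": "model_flux",
            "conversion": 1.0,
        })
    return out


# ---------------------------------------------------------------------------
# Full scenario
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthScenario:
    """Everything a pipeline run needs plus the generating truth."""

    model: MetabolicModel
    v_control: dict[str, float]
    v_treated: dict[str, float]
    achieved_fc: dict[str, float]
    plan: dict[str, float]
    fpkm: pd.DataFrame
    condition_map: dict[str, str]
    de_table: pd.DataFrame
    measurements: list[dict]
    seed: int

    def true_log2fc(self, eps: float = 1e-9) -> dict[str, float]:
        return {
            rid: math.log2((abs(self.v_treated[rid]) + eps)
                           / (abs(self.v_control[rid]) + eps))
            for rid in self.model.reaction_ids()
        }

    def write(self, outdir: str | Path) -> None:
        from .core import save_model

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_model(self.model, outdir / "model.json")
        self.fpkm.to_csv(outdir / "expression.tsv", sep="\t")
        (outdir / "conditions.json").write_text(json.dumps(self.condition_map, indent=1))
        self.de_table.to_csv(outdir / "de_treated.tsv", sep="\t", index=False)
        (outdir / "measurements.json").write_text(json.dumps(self.measurements, indent=1))
        truth = {
            "seed": self.seed,
            "plan": self.plan,
            "v_control": self.v_control,
            "v_treated": self.v_treated,
            "achieved_fc": self.achieved_fc,
        }
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))


def make_scenario(
    seed: int = 0,
    noise_cv: float = 0.0,
    n_samples: int = 4,
    measurement_cv: float = 0.0,
    network: str = "glyc-ox-8",
    plan: dict[str, float] | None = None,
) -> GroundTruthScenario:
    """Build a complete ground-truth scenario on the toy cell.

    The control flux state is an interior point (uniform-penalty minimal-flux
    vertex averaged with a mild interiorization toward mid-bounds via the
    perturbation projector), so every pathway carries nonzero flux and fold
    changes are well defined.  The perturbation plan, when not given, draws
    multipliers from [0.25, 0.5] or [2, 4] for 1-3 internal reactions.
    """
    rng = np.random.default_rng(seed)
    model = toy_network(network)
    # interior-ish control state: fix demand at 60% of optimum, split branches
    res = fba(model)
    assert res.ok
    opt = res.objective_value
    demand = 0.6 * opt
    # hand-picked balanced split consistent with S v = 0 on the toy
    o2 = min(5.0, demand / 4.0)
    upper = demand - 2.0 * o2
    v_control = {
        "EX_A": upper, "EX_O2": o2, "R_upper": upper, "R_ox": o2,
        "R_ferm": upper - o2, "EX_C": o2, "EX_D": upper - o2, "DM_ATP": demand,
    }
    flux = FluxDistribution(v_control, model.id)
    if not flux.check_feasibility(model):
        raise RuntimeError("control state construction violated feasibility")
    if plan is None:
        internal = ["R_upper", "R_ox", "R_ferm"]
        k = int(rng.integers(1, len(internal) + 1))
        chosen = [str(x) for x in rng.choice(internal, size=k, replace=False)]
        plan = {}
        for rid in chosen:
            if rng.random() < 0.5:
                plan[rid] = float(rng.uniform(0.25, 0.5))
            else:
                plan[rid] = float(rng.uniform(2.0, 4.0))
    v_treated, achieved = perturb_fluxes(model, v_control, plan, seed=seed)
    fpkm, cond_map, de = synth_expression(
        model, v_control, v_treated, noise_cv=noise_cv,
        n_samples=n_samples, seed=seed)
    meas = synth_measurements(v_treated, ["EX_O2", "DM_ATP"],
                              cv=measurement_cv, seed=seed)
    return GroundTruthScenario(model, v_control, v_treated, achieved, plan,
                               fpkm, cond_map, de, meas, seed)
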