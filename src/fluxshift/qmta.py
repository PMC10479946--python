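"""Quadratic metabolic transformation: fit a perturbed flux state to
differential-expression fold changes.

Given a reference flux state v_ref, a differential-expression table and
optional measured fluxes, the algorithm solves the convex quadratic program

    min  sum_{m in DExp} W_m sum_{i in R_m} ((v_i^ref FC_m - v_i) / (v_i^ref (FC_m - 1)))^2
       + sum_{i in Ru} (v_i^ref - v_i)^2 / |v_i^ref|
       + sum_{j in Rexp} (E_j - v_j)^2 / sigma_j
    s.t. S v = 0,  lb <= v <= ub

where DExp are genes differentially expressed below an FDR threshold p_th
(weighted W_m = log10(p_th) - log10(p_m)), R_m the reactions carrying gene m
in their GPR, Ru the reactions mapped to no DE gene or measurement, and Rexp
the measured reactions.  Both fitted terms are scaled by the reference flux
so high-flux reactions do not dominate.  The target flux for reaction i under
gene m is v_i^ref * FC_m (fold change multiplies the signed reference flux).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import FluxDistribution, MetabolicModel

__all__ = [
    "GeneWeight",
    "QMTAConfig",
    "QPSpec",
    "QMTAResult",
    "gene_weights",
    "map_genes_to_reactions",
    "assemble_qp",
    "solve_qmta",
    "flux_log2fc",
    "pathway_report",
]


@dataclass
class GeneWeight:
    gene: str
    weight: float


@dataclass
class QMTAConfig:
    p_th: float = 0.25
    epsilon_ref: float = 1e-6   # floor for |v_ref| in denominators
    epsilon_fc: float = 1e-6    # floor for |FC - 1|; genes under it drop out
    log2fc_epsilon: float = 1e-6
    squared_ru_denominator: bool = False  # alternative exponent reading
    osqp_eps: float = 1e-10

    def __post_init__(self) -> None:
        if not (0.0 < self.p_th < 1.0):
            raise ValueError("p_th must be in (0, 1)")
        if self.epsilon_ref <= 0:
            raise ValueError("epsilon_ref must be > 0")


def gene_weights(de_table: pd.DataFrame, p_th: float = 0.25) -> list[GeneWeight]:
    """Significance weights W_m = log10(p_th) - log10(p_m) for p_m < p_th.

    p_m is the FDR-adjusted p-value; genes at or above the threshold are
    excluded from the differentially-expressed set (their weight would be
    <= 0).  A zero p-value is rejected: floor it upstream.
    """
    out = []
    for row in de_table.itertuples(index=False):
        p_m = float(row.FDR)
        if p_m == 0.0:
            raise ValueError(f"gene {row.gene}: FDR of exactly 0 (log undefined); "
                             "floor p-values upstream")
        if not (0.0 < p_m <= 1.0):
            raise ValueError(f"gene {row.gene}: FDR {p_m} outside (0, 1]")
        if p_m < p_th:
            out.append(GeneWeight(str(row.gene), math.log10(p_th) - math.log10(p_m)))
    return out


def map_genes_to_reactions(
    model: MetabolicModel, genes: Sequence[str]
) -> tuple[dict[str, set[str]], list[str]]:
    """R_m: reactions whose GPR contains gene m as a leaf.

    Returns (mapping, dropped) where dropped lists query genes absent from
    every GPR in the model.
    """
    leaf_map: dict[str, set[str]] = {}
    for r in model.reactions:
        for g in r.genes():
            leaf_map.setdefault(g, set()).add(r.id)
    mapping, dropped = {}, []
    for g in genes:
        hits = leaf_map.get(g)
        if hits:
            mapping[g] = set(hits)
        else:
            dropped.append(g)
    return mapping, dropped


@dataclass
class QPSpec:
    """Separable convex QP: sum_k w_k (v_{i_k} - t_k)^2 over categorized terms."""

    model: MetabolicModel
    reaction_ids: list[str]
    term_index: np.ndarray    # reaction column of each term
    term_weight: np.ndarray
    term_target: np.ndarray
    term_kind: list[str]      # "de" | "ru" | "measured"
    v_ref: np.ndarray
    categories: dict[str, str]  # reaction -> "de" | "ru" | "measured"
    log: list[str] = field(default_factory=list)


def assemble_qp(
    model: MetabolicModel,
    v_ref: FluxDistribution,
    de_table: pd.DataFrame,
    weights: list[GeneWeight],
    measurements: list[dict] | None = None,
    config: QMTAConfig | None = None,
) -> QPSpec:
    """Build the quadratic objective from the three reaction categories.

    Measured reactions override DE targeting (experimental data wins, logged);
    every reaction mapped to no DE gene and not measured contributes the
    flux-variation (Ru) term.  Each DE gene contributes its own quadratic
    term per mapped reaction — no pre-aggregation of fold changes.
    """
    config = config or QMTAConfig()
    rids = model.reaction_ids()
    col = {rid: j for j, rid in enumerate(rids)}
    vref = v_ref.as_array(rids)
    log: list[str] = []

    measured: dict[str, tuple[float, float]] = {}
    for m in measurements or []:
        rid = m["reaction_id"]
        if rid not in col:
            raise KeyError(f"measurement maps to unknown reaction {rid!r}")
        conv = float(m.get("conversion", 1.0))
        measured[rid] = (float(m["mean"]) * conv, float(m["sd"]) * abs(conv))

    wmap = {w.gene: w.weight for w in weights}
    fcmap = {str(r.gene): float(r.FC) for r in de_table.itertuples(index=False)}
    gene_rxns, dropped = map_genes_to_reactions(model, list(wmap))
    for g in dropped:
        log.append(f"DE gene {g} absent from model GPRs; dropped")

    de_targeted: set[str] = set()
    idx, wts, tgt, kind = [], [], [], []
    for g, rxns in sorted(gene_rxns.items()):
        W = wmap[g]
        fc = fcmap.get(g)
        if fc is None or W <= 0.0:
            continue
        if abs(fc - 1.0) < config.epsilon_fc:
            log.append(f"gene {g}: |FC-1| < epsilon_fc; contributes nothing")
            continue
        for rid in sorted(rxns):
            if rid in measured:
                log.append(f"reaction {rid}: measured, overrides DE gene {g}")
                continue
            j = col[rid]
            de_targeted.add(rid)
            vr = vref[j]
            target = vr * fc
            if abs(vr) < config.epsilon_ref:
                # zero-reference fallback: unscaled squared deviation
                log.append(f"reaction {rid}: |v_ref| below floor; unscaled DE term")
                denom2 = 1.0
            else:
                denom2 = (abs(vr) * abs(fc - 1.0)) ** 2
            idx.append(j)
            wts.append(W / denom2)
            tgt.append(target)
            kind.append("de")

    categories = {}
    for rid in rids:
        j = col[rid]
        if rid in measured:
            categories[rid] = "measured"
            E, sd = measured[rid]
            idx.append(j)
            wts.append(1.0 / max(sd, 1e-12))
            tgt.append(E)
            kind.append("measured")
        elif rid in de_targeted:
            categories[rid] = "de"
        else:
            categories[rid] = "ru"
            vr = vref[j]
            denom = max(abs(vr), config.epsilon_ref)
            if config.squared_ru_denominator:
                denom = denom ** 2
            idx.append(j)
            wts.append(1.0 / denom)
            tgt.append(vr)
            kind.append("ru")

    return QPSpec(model, rids, np.array(idx, int), np.array(wts), np.array(tgt),
                  kind, vref, categories, log)


@dataclass
class QMTAResult:
    v_ref: FluxDistribution
    v_mta: FluxDistribution
    log2fc: dict[str, tuple[float, bool, float]]
    objective: float
    decomposition: dict[str, float]  # de / ru / measured term values
    status: str

    @property
    def ok(self) -> bool:
        return self.status == "solved"


def _objective_terms(spec: QPSpec, v: np.ndarray) -> dict[str, float]:
    dev = (v[spec.term_index] - spec.term_target) ** 2 * spec.term_weight
    out = {"de": 0.0, "ru": 0.0, "measured": 0.0}
    for val, kind in zip(dev, spec.term_kind):
        out[kind] += float(val)
    return out


def solve_qmta(spec: QPSpec, config: QMTAConfig | None = None) -> QMTAResult:
    """Solve the assembled QP with OSQP (polished, tight tolerances)."""
    import osqp
    from scipy import sparse

    config = config or QMTAConfig()
    n = len(spec.reaction_ids)
    diag = np.zeros(n)
    q = np.zeros(n)
    np.add.at(diag, spec.term_index, 2.0 * spec.term_weight)
    np.add.at(q, spec.term_index, -2.0 * spec.term_weight * spec.term_target)
    S = spec.model.stoichiometric_matrix()
    lb, ub = spec.model.bounds_arrays()
    P = sparse.diags(np.maximum(diag, 1e-12), format="csc")
    A = sparse.vstack([sparse.csc_matrix(S), sparse.eye(n)], format="csc")
    l = np.concatenate([np.zeros(S.shape[0]), lb])
    u = np.concatenate([np.zeros(S.shape[0]), ub])
    prob = osqp.OSQP()
    prob.setup(P=P, q=q, A=A, l=l, u=u, eps_abs=config.osqp_eps,
               eps_rel=config.osqp_eps, max_iter=500_000, polishing=True,
               verbose=False)
    res = prob.solve()
    if "solved" not in res.info.status:
        raise RuntimeError(
            f"qMTA solver failed: {res.info.status} "
            f"(pri_res={res.info.pri_res:.2e}, dua_res={res.info.dua_res:.2e})")
    v = np.clip(res.x, lb, ub)
    v_mta = FluxDistribution(dict(zip(spec.reaction_ids, map(float, v))),
                             spec.model.id)
    v_mta.check_feasibility(spec.model)
    decomp = _objective_terms(spec, v)
    vref_flux = FluxDistribution(dict(zip(spec.reaction_ids, map(float, spec.v_ref))),
                                 spec.model.id)
    vref_flux.check_feasibility(spec.model)
    l2fc = flux_log2fc(vref_flux, v_mta, config.log2fc_epsilon)
    return QMTAResult(vref_flux, v_mta, l2fc, sum(decomp.values()), decomp, "solved")


def flux_log2fc(
    v_ref: FluxDistribution,
    v_mta: FluxDistribution,
    epsilon: float = 1e-6,
) -> dict[str, tuple[float, bool, float]]:
    """Per-reaction (log2FC of |flux|, direction-flip flag, predicted flux).

    log2FC = log2((|v_mta| + eps) / (|v_ref| + eps)); a sign flip (the
    predicted flux reversing direction relative to the reference) is flagged
    separately because the magnitude ratio alone cannot express it.
    """
    out = {}
    for rid, ref in v_ref.values.items():
        mta = v_mta.values[rid]
        l2 = math.log2((abs(mta) + epsilon) / (abs(ref) + epsilon))
        out[rid] = (l2, bool(mta * ref < 0), mta)
    return out


def pathway_report(result: QMTAResult, model: MetabolicModel) -> pd.DataFrame:
    """Subsystem-grouped table: reaction, log2FC, predicted flux, direction.

    Mirrors the flux-map annotation style (enzyme id, log2FC, predicted flux
    in parentheses); rows ordered by subsystem then reaction id; empty
    subsystems are simply absent.
    """
    rows = []
    for r in model.reactions:
        l2, flip, flux = result.log2fc[r.id]
        rows.append({
            "subsystem": r.subsystem or "(none)",
            "reaction_id": r.id,
            "v_ref": result.v_ref.values[r.id],
            "v_mta": flux,
            "log2FC": l2,
            "sign_flip": flip,
            "direction": "up" if l2 > 0 else ("down" if l2 < 0 else "unchanged"),
        })
    df = pd.DataFrame(rows).sort_values(["subsystem", "reaction_id"], kind="stable")
    return df.reset_index(drop=True)
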