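"""Condition-specific model construction from a template model plus
expression, medium and respiration data.

The builder applies, in order: medium exchange bounds, measured-rate bounds
(mean +/- k*sd intersected with the template bounds), removal of reactions
whose expression score is below threshold in every condition, and per-drug
removal of significantly down-regulated, lowly-expressed reactions.  Every
candidate removal is re-validated: the pruned model must still reach the
required biomass fraction under all imposed bounds, otherwise the candidate
is retained and logged as essential.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MetabolicModel, evaluate_gpr
from .lp import fba

__all__ = [
    "ExpressionProfile",
    "MediumSpec",
    "ContextConfig",
    "reaction_expression",
    "apply_medium",
    "apply_measurements",
    "prune_globally_silent",
    "prune_condition_specific",
    "build_context_model",
]


@dataclass
class ExpressionProfile:
    """Gene x sample FPKM matrix with a sample -> condition map."""

    fpkm: pd.DataFrame
    condition_map: dict[str, str]

    def __post_init__(self) -> None:
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if self.fpkm.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        missing = set(self.fpkm.columns) - set(self.condition_map)
        if missing:
            raise ValueError(f"samples without a condition label: {sorted(missing)}")

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.condition_map.values()))

    def condition_means(self, condition: str) -> pd.Series:
        cols = [s for s, c in self.condition_map.items()
                if c == condition and s in self.fpkm.columns]
        if not cols:
            raise KeyError(f"no samples for condition {condition!r}")
        return self.fpkm[cols].mean(axis=1)

    @classmethod
    def from_files(cls, fpkm_tsv: str | Path, conditions_json: str | Path
                   ) -> "ExpressionProfile":
        fpkm = pd.read_csv(fpkm_tsv, sep="\t", index_col=0)
        cond = json.loads(Path(conditions_json).read_text())
        return cls(fpkm, cond)


@dataclass
class MediumSpec:
    """exchange id -> (uptake upper bound, secretion upper bound), both >= 0."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for rid, (up, sec) in self.bounds.items():
            if up < 0 or sec < 0:
                raise ValueError(f"medium bounds for {rid} must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "MediumSpec":
        data = json.loads(Path(path).read_text())
        return cls({k: (float(v[0]), float(v[1])) for k, v in data.items()})


@dataclass
class ContextConfig:
    fpkm_threshold: float = 1.0
    biomass_fraction: float = 0.2
    de_fdr_threshold: float = 0.05
    biomass_reaction: str = "DM_ATP"
    k_sd: float = 2.0
    or_rule: str = "max"

    def __post_init__(self) -> None:
        if not (0.0 < self.biomass_fraction <= 1.0):
            raise ValueError("biomass_fraction must be in (0, 1]")
        if self.fpkm_threshold <= 0 or self.de_fdr_threshold <= 0:
            raise ValueError("thresholds must be > 0")


def reaction_expression(
    model: MetabolicModel,
    profile: ExpressionProfile,
    condition: str,
    or_rule: str = "max",
) -> dict[str, float | None]:
    """GPR-aggregated mean FPKM per reaction; None for empty/absent GPRs."""
    means = profile.condition_means(condition).to_dict()
    return {
        r.id: evaluate_gpr(r.gpr, means, or_rule=or_rule)
        for r in model.reactions
    }


def _exchange_orientation(rxn) -> float:
    """+1 if forward flux imports the metabolite, -1 if it exports it."""
    (coef,) = rxn.stoichiometry.values()
    return 1.0 if coef > 0 else -1.0


def apply_medium(
    model: MetabolicModel,
    medium: MediumSpec,
    log: list[dict] | None = None,
) -> MetabolicModel:
    """Close uptake for all exchanges not listed; set bounds for listed ones.

    A medium bound wider than the template's is clipped to the template bound
    (the template encodes hard capacity; the medium can only restrict).
    """
    model = model.copy()
    exchange_ids = {r.id for r in model.exchange_reactions()}
    unknown = sorted(set(medium.bounds) - exchange_ids)
    if unknown:
        raise ValueError(f"medium lists non-exchange reactions: {unknown}")
    for r in model.reactions:
        if not r.is_boundary:
            continue
        orient = _exchange_orientation(r)
        if r.id in medium.bounds:
            uptake, secretion = medium.bounds[r.id]
            if orient > 0:
                new_ub = min(r.upper_bound, uptake)
                new_lb = max(r.lower_bound, -secretion)
            else:
                new_ub = min(r.upper_bound, secretion)
                new_lb = max(r.lower_bound, -uptake)
            capacity = r.upper_bound if orient > 0 else -r.lower_bound
            if log is not None and uptake > capacity:
                log.append({"stage": "medium", "reaction": r.id,
                            "note": "medium uptake clipped to template capacity"})
            if log is not None:
                log.append({"stage": "medium", "reaction": r.id,
                            "action": "set", "lb": new_lb, "ub": new_ub})
            r.lower_bound, r.upper_bound = new_lb, new_ub
        else:
            # close the uptake direction only
            if orient > 0:
                r.upper_bound = min(r.upper_bound, 0.0)
            else:
                r.lower_bound = max(r.lower_bound, 0.0)
            if log is not None:
                log.append({"stage": "medium", "reaction": r.id,
                            "action": "uptake_closed"})
    return model


def apply_measurements(
    model: MetabolicModel,
    measurements: list[dict],
    k_sd: float = 2.0,
    log: list[dict] | None = None,
) -> MetabolicModel:
    """Intersect each mapped reaction's bounds with mean +/- k_sd * sd.

    Values are converted to model flux units with the measurement's
    ``conversion`` factor.  An empty intersection raises, naming the
    measurement; k_sd = 0 fixes the reaction to the (converted) mean.
    """
    model = model.copy()
    for m in measurements:
        rid = m["reaction_id"]
        rxn = model.get_reaction(rid)
        conv = float(m.get("conversion", 1.0))
        mean = float(m["mean"]) * conv
        sd = float(m["sd"]) * abs(conv)
        if sd <= 0 and k_sd > 0:
            raise ValueError(f"measurement {m.get('parameter', rid)}: sd must be > 0")
        lo, hi = mean - k_sd * sd, mean + k_sd * sd
        new_lb, new_ub = max(rxn.lower_bound, lo), min(rxn.upper_bound, hi)
        if new_lb > new_ub + 1e-12:
            raise ValueError(
                f"measurement {m.get('parameter', rid)} on {rid}: interval "
                f"[{lo:.4g}, {hi:.4g}] does not intersect bounds "
                f"[{rxn.lower_bound:.4g}, {rxn.upper_bound:.4g}]")
        rxn.lower_bound, rxn.upper_bound = new_lb, min(new_ub, rxn.upper_bound)
        if log is not None:
            log.append({"stage": "measurements", "reaction": rid,
                        "parameter": m.get("parameter", ""),
                        "lb": rxn.lower_bound, "ub": rxn.upper_bound})
    return model


def _biomass_guard(model: MetabolicModel, target: float) -> bool:
    res = fba(model, "max")
    return res.ok and res.objective_value >= target - 1e-9


def prune_globally_silent(
    model: MetabolicModel,
    profile: ExpressionProfile,
    config: ContextConfig,
    protected: set[str] | None = None,
) -> tuple[MetabolicModel, list[dict]]:
    """Remove reactions scoring under the FPKM threshold in *all* conditions,
    one at a time, keeping each removal only if the model still attains the
    required biomass fraction under its current (medium + measurement) bounds.

    Candidates are processed in ascending order of their max-across-conditions
    score, ties broken by reaction id, so the result is deterministic.
    """
    protected = protected or set()
    log: list[dict] = []
    base = fba(model, "max")
    if not base.ok:
        raise RuntimeError(f"template infeasible before pruning: {base.status}")
    target = config.biomass_fraction * base.objective_value

    scores = {c: reaction_expression(model, profile, c, config.or_rule)
              for c in profile.conditions}
    candidates = []
    for r in model.reactions:
        if r.id in protected or r.id == config.biomass_reaction:
            continue
        per_cond = [scores[c][r.id] for c in profile.conditions]
        if any(s is None for s in per_cond):
            continue  # unannotated/absent reactions are exempt
        if all(s < config.fpkm_threshold for s in per_cond):
            candidates.append((max(per_cond), r.id))
    candidates.sort()

    pruned = model.copy()
    for score, rid in candidates:
        trial = pruned.copy()
        trial.remove_reactions([rid])
        if _biomass_guard(trial, target):
            pruned = trial
            log.append({"stage": "global_prune", "reaction": rid,
                        "max_score": score, "action": "removed"})
        else:
            log.append({"stage": "global_prune", "reaction": rid,
                        "max_score": score, "action": "retained",
                        "reason": "essential"})
    return pruned, log


def prune_condition_specific(
    model: MetabolicModel,
    de_table: pd.DataFrame,
    profile: ExpressionProfile,
    condition: str,
    untreated_condition: str,
    config: ContextConfig,
    protected: set[str] | None = None,
) -> tuple[MetabolicModel, list[dict]]:
    """Remove reactions of significantly down-regulated genes that are lowly
    expressed in the drug condition but not untreated, with the same
    per-removal biomass guard as the global prune."""
    protected = protected or set()
    log: list[dict] = []
    base = fba(model, "max")
    if not base.ok:
        raise RuntimeError(f"model infeasible before condition pruning: {base.status}")
    target = config.biomass_fraction * base.objective_value

    sig_genes = {str(r.gene) for r in de_table.itertuples(index=False)
                 if 0.0 < float(r.FDR) < config.de_fdr_threshold}
    treated = reaction_expression(model, profile, condition, config.or_rule)
    untreated = reaction_expression(model, profile, untreated_condition, config.or_rule)

    candidates = []
    for r in model.reactions:
        if r.id in protected or r.id == config.biomass_reaction:
            continue
        if not (r.genes() & sig_genes):
            continue
        t, u = treated[r.id], untreated[r.id]
        if t is None or u is None:
            continue
        if t < config.fpkm_threshold and u >= config.fpkm_threshold:
            candidates.append((t, r.id))
    candidates.sort()

    pruned = model.copy()
    for score, rid in candidates:
        trial = pruned.copy()
        trial.remove_reactions([rid])
        if _biomass_guard(trial, target):
            pruned = trial
            log.append({"stage": "condition_prune", "condition": condition,
                        "reaction": rid, "score": score, "action": "removed"})
        else:
            log.append({"stage": "condition_prune", "condition": condition,
                        "reaction": rid, "score": score, "action": "retained",
                        "reason": "essential"})
    return pruned, log


def build_context_model(
    template: MetabolicModel,
    profile: ExpressionProfile,
    de_tables: dict[str, pd.DataFrame],
    medium: MediumSpec | None,
    measurements: list[dict] | None,
    config: ContextConfig,
    untreated_condition: str = "control",
) -> tuple[dict[str, MetabolicModel], list[dict]]:
    """Orchestrate medium -> measurements -> global prune -> per-drug prune.

    Returns one model per condition (the untreated condition gets the
    globally-pruned model) plus a machine-readable provenance log of every
    bound change and every accepted/rejected removal.
    """
    log: list[dict] = []
    model = template.copy()
    protected = set(medium.bounds) if medium else set()
    if medium is not None:
        model = apply_medium(model, medium, log)
    if measurements:
        model = apply_measurements(model, measurements, config.k_sd, log)
    base, plog = prune_globally_silent(model, profile, config, protected)
    log.extend(plog)
    models = {untreated_condition: base}
    for cond, de in de_tables.items():
        if cond == untreated_condition:
            continue
        cm, clog = prune_condition_specific(
            base, de, profile, cond, untreated_condition, config, protected)
        log.extend(clog)
        models[cond] = cm
    return models, log
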