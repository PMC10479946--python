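"""Metabolic-network data model, gene-reaction rule evaluation and standard-format I/O.

The model container is a plain stoichiometric network: metabolites, reactions
with flux bounds and boolean gene--protein--reaction (GPR) rules, and a single
linear objective.  It maps losslessly onto the COBRA JSON dialect (so that
Recon3D-style files load unchanged) and onto :class:`cobra.Model` for SBML
(L3 + fbc) round trips.
"""

from __future__ import annotations

import ast
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxDistribution",
    "ModelValidationError",
    "evaluate_gpr",
    "gpr_genes",
    "load_model",
    "save_model",
    "to_cobra",
    "from_cobra",
]

JSON_SCHEMA_VERSION = "1"

#: Default numeric tolerances (feasibility / relative LP optimality).
FEASIBILITY_TOL = 1e-6
OPTIMALITY_TOL = 1e-9


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant; lists offenders."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

def _parse_gpr(rule: str) -> ast.expr | None:
    """Parse a boolean gene rule ("g1 and (g2 or g3)") into a Python AST."""
    rule = rule.strip()
    if not rule:
        return None
    normalized = rule.replace(" AND ", " and ").replace(" OR ", " or ")
    normalized = normalized.replace(" And ", " and ").replace(" Or ", " or ")
    try:
        tree = ast.parse(normalized, mode="eval")
    except SyntaxError as exc:  # pragma: no cover - message path
        raise ModelValidationError(f"malformed GPR rule {rule!r}: {exc}") from exc
    _check_gpr_node(tree.body, rule)
    return tree.body


def _check_gpr_node(node: ast.expr, rule: str) -> None:
    if isinstance(node, ast.BoolOp):
        for child in node.values:
            _check_gpr_node(child, rule)
    elif not isinstance(node, ast.Name):
        raise ModelValidationError(
            f"malformed GPR rule {rule!r}: only gene names, AND and OR are allowed"
        )


def gpr_genes(rule: str) -> frozenset[str]:
    """Return the set of gene identifiers appearing as leaves of ``rule``."""
    node = _parse_gpr(rule)
    if node is None:
        return frozenset()
    out: set[str] = set()
    stack = [node]
    while stack:
        cur = stack.pop()
        if isinstance(cur, ast.Name):
            out.add(cur.id)
        else:
            stack.extend(cur.values)  # type: ignore[attr-defined]
    return frozenset(out)


def evaluate_gpr(
    rule: str,
    gene_scores: Mapping[str, float],
    and_rule: str = "min",
    or_rule: str = "max",
) -> float | None:
    """Fold gene scores through a GPR tree.

    AND nodes model enzyme complexes (limited by their scarcest subunit,
    ``and_rule="min"``); OR nodes model isozymes, aggregated with ``max``
    (alternative capacity) or ``sum``.  Genes missing from ``gene_scores``
    are *absent*: an OR ignores absent children, an AND with any absent
    child is absent, and a reaction whose whole tree is absent returns
    ``None`` (empty rules return ``None`` as well).
    """
    if and_rule != "min":
        raise ValueError(f"unsupported and_rule {and_rule!r}")
    if or_rule not in ("max", "sum"):
        raise ValueError(f"unsupported or_rule {or_rule!r}")
    node = _parse_gpr(rule)
    if node is None:
        return None
    return _fold_gpr(node, gene_scores, or_rule)


def _fold_gpr(node: ast.expr, scores: Mapping[str, float], or_rule: str) -> float | None:
    if isinstance(node, ast.Name):
        value = scores.get(node.id)
        return float(value) if value is not None else None
    assert isinstance(node, ast.BoolOp)
    children = [_fold_gpr(child, scores, or_rule) for child in node.values]
    if isinstance(node.op, ast.And):
        if any(c is None for c in children):
            return None
        return min(children)  # type: ignore[type-var]
    present = [c for c in children if c is not None]
    if not present:
        return None
    return max(present) if or_rule == "max" else sum(present)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class Reaction:
    """A stoichiometric reaction with bounds and an optional GPR rule.

    ``stoichiometry`` maps metabolite id to its signed coefficient
    (negative = consumed when flux is positive).
    """

    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: str = ""
    subsystem: str = ""
    name: str = ""

    @property
    def is_boundary(self) -> bool:
        """Exchange/demand/sink pseudo-reactions touch a single metabolite."""
        return len(self.stoichiometry) <= 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def genes(self) -> frozenset[str]:
        return gpr_genes(self.gpr)


@dataclass
class MetabolicModel:
    id: str = "model"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    objective: dict[str, float] = field(default_factory=dict)
    compartments: dict[str, str] = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_boundary]

    # -- matrix view -----------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (rows metabolites, columns reactions)."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for mid, coef in rxn.stoichiometry.items():
                S[met_index[mid], j] = coef
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], float)
        ub = np.array([r.upper_bound for r in self.reactions], float)
        return lb, ub

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(len(self.reactions))
        idx = {r.id: j for j, r in enumerate(self.reactions)}
        for rid, coef in self.objective.items():
            c[idx[rid]] = coef
        return c

    # -- editing ---------------------------------------------------------
    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[Metabolite(m.id, m.name, m.compartment) for m in self.metabolites],
            reactions=[
                Reaction(r.id, dict(r.stoichiometry), r.lower_bound, r.upper_bound,
                         r.gpr, r.subsystem, r.name)
                for r in self.reactions
            ],
            genes=list(self.genes),
            objective=dict(self.objective),
            compartments=dict(self.compartments),
        )

    def remove_reactions(self, rids: Iterable[str]) -> None:
        drop = set(rids)
        self.reactions = [r for r in self.reactions if r.id not in drop]
        self.objective = {k: v for k, v in self.objective.items() if k not in drop}

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        problems: list[str] = []
        met_ids = self.metabolite_ids()
        if len(set(met_ids)) != len(met_ids):
            problems.append("duplicate metabolite ids")
        rxn_ids = self.reaction_ids()
        if len(set(rxn_ids)) != len(rxn_ids):
            problems.append("duplicate reaction ids")
        known = set(met_ids)
        gene_leaves: set[str] = set()
        for r in self.reactions:
            missing = sorted(set(r.stoichiometry) - known)
            if missing:
                problems.append(f"reaction {r.id} references undeclared metabolites: {missing}")
            if r.lower_bound > r.upper_bound:
                problems.append(f"reaction {r.id} has lower_bound > upper_bound")
            gene_leaves |= r.genes()
        orphan = gene_leaves - set(self.genes)
        if orphan:
            problems.append(f"GPR genes missing from gene list: {sorted(orphan)}")
        bad_obj = sorted(set(self.objective) - set(rxn_ids))
        if bad_obj:
            problems.append(f"objective references unknown reactions: {bad_obj}")
        if problems:
            raise ModelValidationError("; ".join(problems))


@dataclass
class FluxDistribution:
    """A reaction-indexed flux vector with a feasibility certificate."""

    values: dict[str, float]
    model_id: str = ""
    feasible: bool = False
    tolerance: float = FEASIBILITY_TOL

    def as_array(self, reaction_ids: Iterable[str]) -> np.ndarray:
        return np.array([self.values[rid] for rid in reaction_ids], float)

    def check_feasibility(self, model: MetabolicModel, tol: float = FEASIBILITY_TOL) -> bool:
        """Re-check mass balance and bounds; updates and returns ``feasible``."""
        v = self.as_array(model.reaction_ids())
        S = model.stoichiometric_matrix()
        lb, ub = model.bounds_arrays()
        ok = (
            float(np.max(np.abs(S @ v), initial=0.0)) <= tol
            and bool(np.all(v >= lb - tol))
            and bool(np.all(v <= ub + tol))
        )
        self.feasible = ok
        self.tolerance = tol
        return ok

    def to_tsv(self, model: MetabolicModel, path: str | Path) -> None:
        lines = ["reaction_id\tflux\tlb\tub\tsubsystem"]
        for r in model.reactions:
            lines.append(
                f"{r.id}\t{self.values[r.id]:.10g}\t{r.lower_bound:.10g}"
                f"\t{r.upper_bound:.10g}\t{r.subsystem}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# JSON dialect (mirrors COBRA JSON; schema_version field added)
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "schema_version": JSON_SCHEMA_VERSION,
        "id": model.id,
        "compartments": model.compartments,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr,
                "subsystem": r.subsystem,
                "objective_coefficient": model.objective.get(r.id, 0.0),
            }
            for r in model.reactions
        ],
        "genes": [{"id": g, "name": g} for g in model.genes],
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    model = MetabolicModel(
        id=data.get("id", "model"),
        compartments=dict(data.get("compartments", {})),
    )
    for m in data.get("metabolites", []):
        model.metabolites.append(
            Metabolite(m["id"], m.get("name", ""), m.get("compartment", ""))
        )
    for r in data.get("reactions", []):
        rxn = Reaction(
            id=r["id"],
            stoichiometry={k: float(v) for k, v in r.get("metabolites", {}).items()},
            lower_bound=float(r.get("lower_bound", 0.0)),
            upper_bound=float(r.get("upper_bound", 1000.0)),
            gpr=r.get("gene_reaction_rule", ""),
            subsystem=r.get("subsystem", "") or "",
            name=r.get("name", ""),
        )
        model.reactions.append(rxn)
        coef = float(r.get("objective_coefficient", 0.0))
        if coef != 0.0:
            model.objective[rxn.id] = coef
    model.genes = [g["id"] for g in data.get("genes", [])]
    declared = set(model.genes)
    for r in model.reactions:
        declared |= r.genes()
    model.genes = sorted(declared)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# cobra interop (SBML path, test oracles)
# ---------------------------------------------------------------------------

def to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        for m in model.metabolites
    }
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name, subsystem=r.subsystem,
                            lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r, cr in zip(model.reactions, rxns):
        cr.add_metabolites({mets[mid]: coef for mid, coef in r.stoichiometry.items()})
        if r.gpr:
            cr.gene_reaction_rule = r.gpr.replace(" AND ", " and ").replace(" OR ", " or ")
    cm.objective = {cm.reactions.get_by_id(rid): coef for rid, coef in model.objective.items()}
    return cm


def from_cobra(cm) -> MetabolicModel:
    model = MetabolicModel(id=cm.id or "model",
                           compartments=dict(cm.compartments))
    for m in cm.metabolites:
        model.metabolites.append(Metabolite(m.id, m.name or "", m.compartment or ""))
    from cobra.util.solver import linear_reaction_coefficients

    obj = {r.id: float(c) for r, c in linear_reaction_coefficients(cm).items()}
    for r in cm.reactions:
        model.reactions.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=r.gene_reaction_rule or "",
                subsystem=r.subsystem or "",
                name=r.name or "",
            )
        )
    model.objective = obj
    model.genes = sorted({g.id for g in cm.genes} | {g for r in model.reactions for g in r.genes()})
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Load / save
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    raise ValueError(f"cannot infer model format from {path.name!r}; pass format=")


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a model from COBRA-dialect JSON or SBML (L3 + fbc)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelValidationError(
                f"malformed JSON in {path.name} at line {exc.lineno}: {exc.msg}"
            ) from exc
        return _model_from_dict(data)
    if fmt == "sbml":
        import cobra

        cm = cobra.io.read_sbml_model(str(path))
        return from_cobra(cm)
    raise ValueError(f"unknown model format {fmt!r}")


def save_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1, sort_keys=True) + "\n")
    elif fmt == "sbml":
        import cobra

        cobra.io.write_sbml_model(to_cobra(model), str(path))
    else:
        raise ValueError(f"unknown model format {fmt!r}")
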