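"""LP primitives: flux balance analysis, flux variability analysis and
reversible-reaction splitting.

All LPs are solved with HiGHS through :func:`scipy.optimize.linprog` over the
model's stoichiometric arrays.  Infeasibility and unboundedness are reported
as statuses, never as partially-filled results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linprog

from .core import FEASIBILITY_TOL, FluxDistribution, MetabolicModel, Reaction

__all__ = ["LPStatus", "FBAResult", "fba", "fva", "split_reversible", "SplitModel"]


class LPStatus:
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"
    ERROR = "error"


_SCIPY_STATUS = {0: LPStatus.OPTIMAL, 2: LPStatus.INFEASIBLE, 3: LPStatus.UNBOUNDED}


@dataclass
class FBAResult:
    status: str
    objective_value: float | None
    fluxes: FluxDistribution | None

    @property
    def ok(self) -> bool:
        return self.status == LPStatus.OPTIMAL


def solve_lp(
    c: np.ndarray,
    A_eq: np.ndarray | None,
    b_eq: np.ndarray | None,
    bounds: Sequence[tuple[float, float]],
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
) -> tuple[str, np.ndarray | None, float | None]:
    """Minimize ``c @ x``; returns (status, x, objective)."""
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    status = _SCIPY_STATUS.get(res.status, LPStatus.ERROR)
    if status != LPStatus.OPTIMAL:
        return status, None, None
    return status, res.x, float(res.fun)


def fba(model: MetabolicModel, sense: str = "max") -> FBAResult:
    """Optimize the model's linear objective at steady state (S v = 0)."""
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = model.objective_vector()
    sign = -1.0 if sense == "max" else 1.0
    status, x, fun = solve_lp(sign * c, S, np.zeros(S.shape[0]), list(zip(lb, ub)))
    if status != LPStatus.OPTIMAL:
        return FBAResult(status, None, None)
    flux = FluxDistribution(dict(zip(model.reaction_ids(), map(float, x))), model.id)
    flux.check_feasibility(model)
    return FBAResult(status, sign * fun, flux)


def fva(
    model: MetabolicModel,
    reactions: Iterable[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-reaction flux min/max under the model's current constraints.

    Any objective-value constraint must already be encoded in the bounds by
    the caller (e.g. by fixing the objective reaction's bounds).
    """
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    rids = model.reaction_ids()
    targets = list(reactions) if reactions is not None else rids
    index = {rid: j for j, rid in enumerate(rids)}
    out: dict[str, tuple[float, float]] = {}
    b_eq = np.zeros(S.shape[0])
    bounds = list(zip(lb, ub))
    for rid in targets:
        j = index[rid]
        c = np.zeros(len(rids))
        c[j] = 1.0
        status, _, lo = solve_lp(c, S, b_eq, bounds)
        if status != LPStatus.OPTIMAL:
            raise RuntimeError(f"FVA {status} while minimizing {rid}")
        status, _, hi = solve_lp(-c, S, b_eq, bounds)
        if status != LPStatus.OPTIMAL:
            raise RuntimeError(f"FVA {status} while maximizing {rid}")
        lo, hi = float(lo), float(-hi)
        if lo > hi:  # solver noise on a fixed reaction
            lo = hi = 0.5 * (lo + hi)
        out[rid] = (lo, hi)
    return out


@dataclass
class SplitModel:
    """An irreversible copy of a model plus the forward/backward mapping.

    ``mapping[rid] = (fwd_id, bwd_id | None)``; net flux is
    ``v[fwd] - v[bwd]`` (``v[fwd]`` when no backward copy exists).
    """

    model: MetabolicModel
    mapping: dict[str, tuple[str, str | None]] = field(default_factory=dict)

    def to_net(self, split_values: dict[str, float]) -> dict[str, float]:
        net = {}
        for rid, (f, b) in self.mapping.items():
            net[rid] = split_values[f] - (split_values[b] if b else 0.0)
        return net

    def net_matrix(self) -> np.ndarray:
        """Linear map M with v_net = M @ x_split (columns in split order)."""
        split_ids = self.model.reaction_ids()
        col = {rid: j for j, rid in enumerate(split_ids)}
        M = np.zeros((len(self.mapping), len(split_ids)))
        for i, (f, b) in enumerate(self.mapping.values()):
            M[i, col[f]] = 1.0
            if b:
                M[i, col[b]] = -1.0
        return M


def split_reversible(model: MetabolicModel) -> SplitModel:
    """Split every reversible reaction into forward/backward irreversible copies.

    Any feasible split flux maps back to a feasible original flux with
    ``v = v_fwd - v_bwd``; the LP objective value is preserved.
    """
    out = MetabolicModel(id=model.id + "_irrev",
                         metabolites=[m for m in model.copy().metabolites],
                         genes=list(model.genes),
                         compartments=dict(model.compartments))
    mapping: dict[str, tuple[str, str | None]] = {}
    for r in model.reactions:
        if r.lower_bound >= 0:
            out.reactions.append(Reaction(r.id, dict(r.stoichiometry), r.lower_bound,
                                          r.upper_bound, r.gpr, r.subsystem, r.name))
            mapping[r.id] = (r.id, None)
        else:
            fwd = Reaction(r.id + "__fwd", dict(r.stoichiometry), 0.0,
                           max(r.upper_bound, 0.0), r.gpr, r.subsystem, r.name)
            bwd = Reaction(r.id + "__bwd",
                           {m: -c for m, c in r.stoichiometry.items()}, 0.0,
                           -r.lower_bound, r.gpr, r.subsystem, r.name)
            out.reactions.extend([fwd, bwd])
            mapping[r.id] = (fwd.id, bwd.id)
    for rid, coef in model.objective.items():
        f, b = mapping[rid]
        out.objective[f] = coef
        # the backward copy carries the negated coefficient so the net
        # objective is preserved for any split representation
        if b:
            out.objective[b] = -coef
    out.validate()
    return SplitModel(out, mapping)
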