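"""Reference flux distribution for the control condition.

Pipeline: expression-weighted flux minimization (GIM3E-style) subject to a
minimum biomass yield and the measured-rate bounds already present on the
model; flux variability analysis restricted to within a small slack of the
weighted-minimization optimum; artificially-centered hit-and-run (ACHR)
sampling of that solution space; and the per-reaction sample mean as the
reference state v_ref.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import FEASIBILITY_TOL, FluxDistribution, MetabolicModel
from .lp import LPStatus, SplitModel, fba, solve_lp, split_reversible

__all__ = [
    "PenaltyWeights",
    "SamplingConfig",
    "ReferenceResult",
    "expression_penalties",
    "gim3e_minimize",
    "solution_space",
    "achr_sample",
    "reference_distribution",
    "compute_reference",
]


@dataclass
class PenaltyWeights:
    """Per-reaction penalties (>= 0) in original reaction space."""

    values: dict[str, float]

    def vector(self, reaction_ids: list[str]) -> np.ndarray:
        return np.array([self.values.get(rid, 0.0) for rid in reaction_ids])


@dataclass
class SamplingConfig:
    n_warmup: int = 100
    n_samples: int = 5000
    thinning: int = 100
    seed: int = 0
    tolerance: float = FEASIBILITY_TOL

    def __post_init__(self) -> None:
        if self.n_warmup < 2 or self.n_samples < 1 or self.thinning < 1:
            raise ValueError("invalid sampling configuration")


@dataclass
class SolutionSpace:
    """Flux polytope in split (irreversible) coordinates.

    x satisfies S x = 0, l <= x <= u and A_ub x <= b_ub (penalty budget and
    biomass-yield rows).  ``split`` maps x back to net reaction fluxes.
    """

    split: SplitModel
    A_ub: np.ndarray
    b_ub: np.ndarray
    fva_bounds: dict[str, tuple[float, float]]


@dataclass
class ReferenceResult:
    penalty_optimum: float
    fva_bounds: dict[str, tuple[float, float]]
    samples: np.ndarray  # n_samples x n_reactions (net fluxes)
    reaction_ids: list[str]
    v_ref: FluxDistribution
    config: SamplingConfig
    slack: float

    def to_files(self, outdir: str | Path, model: MetabolicModel) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.v_ref.to_tsv(model, outdir / "v_ref.tsv")
        sidecar = {
            "penalty_optimum": self.penalty_optimum,
            "slack": self.slack,
            "seed": self.config.seed,
            "n_samples": self.config.n_samples,
            "thinning": self.config.thinning,
            "n_warmup": self.config.n_warmup,
            "config_hash": hashlib.sha256(
                json.dumps(vars(self.config), sort_keys=True).encode()
            ).hexdigest(),
        }
        (outdir / "reference.json").write_text(json.dumps(sidecar, indent=1))


# ---------------------------------------------------------------------------
# Penalties
# ---------------------------------------------------------------------------

def expression_penalties(
    model: MetabolicModel,
    reaction_scores: dict[str, float | None],
    log_transform: bool = True,
) -> PenaltyWeights:
    """GIM3E-style penalties: p_i = s_max - s_i on log2(score+1).

    Reactions without an expression score (empty GPR or absent genes) get
    penalty 0, so the minimization never biases unannotated reactions.
    With ``log_transform=False`` the penalty is computed on linear scores.
    """
    scored = {
        rid: (math.log2(s + 1.0) if log_transform else float(s))
        for rid, s in reaction_scores.items()
        if s is not None
    }
    if not scored:
        return PenaltyWeights({rid: 0.0 for rid in model.reaction_ids()})
    s_max = max(scored.values())
    out = {rid: 0.0 for rid in model.reaction_ids()}
    for rid, s in scored.items():
        out[rid] = max(0.0, s_max - s)
    return PenaltyWeights(out)


# ---------------------------------------------------------------------------
# Weighted minimization
# ---------------------------------------------------------------------------

def _split_weights(split: SplitModel, penalties: PenaltyWeights,
                   uniform_fallback: float) -> np.ndarray:
    w = np.zeros(len(split.model.reactions))
    col = {rid: j for j, rid in enumerate(split.model.reaction_ids())}
    for rid, (f, b) in split.mapping.items():
        wi = penalties.values.get(rid, 0.0) + uniform_fallback
        w[col[f]] = wi
        if b:
            w[col[b]] = wi
    return w


def _biomass_row(split: SplitModel, objective: dict[str, float]) -> np.ndarray:
    row = np.zeros(len(split.model.reactions))
    col = {rid: j for j, rid in enumerate(split.model.reaction_ids())}
    for rid, coef in objective.items():
        f, b = split.mapping[rid]
        row[col[f]] += coef
        if b:
            row[col[b]] -= coef
    return row


def gim3e_minimize(
    model: MetabolicModel,
    penalties: PenaltyWeights,
    biomass_fraction: float = 0.2,
    uniform_fallback: float = 1.0,
) -> tuple[float, FluxDistribution]:
    """Minimize sum_i w_i |v_i| subject to biomass >= fraction * optimum.

    w_i = penalty_i + uniform_fallback; the fallback keeps the LP bounded
    even when all penalties are zero (in which case the problem reduces to
    plain minimal-total-flux, pFBA-style).  Measurement bounds must already
    be on the model.  Returns the optimal penalty objective P* and one
    optimal flux vertex.
    """
    if uniform_fallback <= 0 and min(penalties.values.values(), default=0.0) <= 0:
        raise ValueError(
            "uniform_fallback must be > 0 when some penalties are zero, "
            "otherwise free cycles make the weighted minimization degenerate")
    res = fba(model, "max")
    if not res.ok:
        raise RuntimeError(f"biomass FBA failed: {res.status}")
    target = biomass_fraction * res.objective_value
    split = split_reversible(model)
    S = split.model.stoichiometric_matrix()
    lb, ub = split.model.bounds_arrays()
    w = _split_weights(split, penalties, uniform_fallback)
    bio = _biomass_row(split, model.objective)
    status, x, fun = solve_lp(
        w, S, np.zeros(S.shape[0]), list(zip(lb, ub)),
        A_ub=-bio[None, :], b_ub=np.array([-target]))
    if status != LPStatus.OPTIMAL:
        raise RuntimeError(f"weighted minimization {status}")
    net = split.to_net(dict(zip(split.model.reaction_ids(), x)))
    flux = FluxDistribution(net, model.id)
    flux.check_feasibility(model)
    # report P* in terms of the penalty weights actually used
    p_star = float(fun)
    return p_star, flux


def solution_space(
    model: MetabolicModel,
    penalties: PenaltyWeights,
    p_star: float,
    biomass_fraction: float = 0.2,
    uniform_fallback: float = 1.0,
    slack: float = 0.01,
) -> SolutionSpace:
    """Constrain the flux space to within ``slack`` of the weighted optimum.

    Adds sum_i w_i |v_i| <= (1 + slack) * P* on top of the model constraints
    and the biomass-yield row, then runs FVA in that space.
    """
    res = fba(model, "max")
    if not res.ok:
        raise RuntimeError(f"biomass FBA failed: {res.status}")
    target = biomass_fraction * res.objective_value
    split = split_reversible(model)
    S = split.model.stoichiometric_matrix()
    lb, ub = split.model.bounds_arrays()
    w = _split_weights(split, penalties, uniform_fallback)
    bio = _biomass_row(split, model.objective)
    A_ub = np.vstack([w[None, :], -bio[None, :]])
    b_ub = np.array([(1.0 + slack) * p_star, -target])

    fva_bounds: dict[str, tuple[float, float]] = {}
    bounds = list(zip(lb, ub))
    b_eq = np.zeros(S.shape[0])
    M = split.net_matrix()
    for i, rid in enumerate(split.mapping):
        c = M[i]
        st, _, lo = solve_lp(c, S, b_eq, bounds, A_ub=A_ub, b_ub=b_ub)
        if st != LPStatus.OPTIMAL:
            raise RuntimeError(f"solution-space FVA {st} on {rid} (min)")
        st, _, hi = solve_lp(-c, S, b_eq, bounds, A_ub=A_ub, b_ub=b_ub)
        if st != LPStatus.OPTIMAL:
            raise RuntimeError(f"solution-space FVA {st} on {rid} (max)")
        lo, hi = float(lo), float(-hi)
        if lo > hi:
            lo = hi = 0.5 * (lo + hi)
        fva_bounds[rid] = (lo, hi)
    return SolutionSpace(split, A_ub, b_ub, fva_bounds)


# ---------------------------------------------------------------------------
# ACHR sampling
# ---------------------------------------------------------------------------

def _warmup_points(space: SolutionSpace, n_warmup: int) -> np.ndarray:
    split = space.split
    S = split.model.stoichiometric_matrix()
    lb, ub = split.model.bounds_arrays()
    bounds = list(zip(lb, ub))
    b_eq = np.zeros(S.shape[0])
    M = split.net_matrix()
    pts = []
    for i in range(M.shape[0]):
        for sign in (1.0, -1.0):
            st, x, _ = solve_lp(sign * M[i], S, b_eq, bounds,
                                A_ub=space.A_ub, b_ub=space.b_ub)
            if st == LPStatus.OPTIMAL:
                pts.append(x)
            if len(pts) >= n_warmup:
                return np.array(pts)
    if len(pts) < 2:
        raise RuntimeError("could not obtain at least two warmup points")
    return np.array(pts)


def achr_sample(space: SolutionSpace, config: SamplingConfig) -> np.ndarray:
    """Artificially-centered hit-and-run over the constrained flux polytope.

    Each step picks a stored point (warmup or previously emitted sample),
    takes the direction from the running center to it, intersects the line
    with the box bounds and inequality rows, and steps uniformly inside the
    feasible chord.  Mass balance is preserved exactly because all stored
    points satisfy it and directions are differences of such points.
    Returns samples mapped to net reaction fluxes (n_samples x n_reactions).
    """
    from scipy.linalg import null_space

    rng = np.random.default_rng(config.seed)
    split = space.split
    lb, ub = split.model.bounds_arrays()
    warmup = _warmup_points(space, config.n_warmup)
    # walk in null-space coordinates x = N z: mass balance holds by
    # construction for every emitted point, so roundoff cannot drift off
    # the steady-state subspace
    S = split.model.stoichiometric_matrix()
    N = null_space(S)
    if N.shape[1] == 0:
        raise RuntimeError("stoichiometry admits only the zero flux subspace")
    # all remaining constraints become one-sided rows G z <= h
    G = np.vstack([N, -N, space.A_ub @ N])
    h = np.concatenate([ub, -lb, space.b_ub])
    Z = warmup @ N  # warmup points lie in range(N); z = N^T x recovers them
    store = [z for z in Z]
    center = Z.mean(axis=0)
    n_visited = len(store)
    z = center.copy()
    samples_z = []
    degenerate_warned = False
    while len(samples_z) < config.n_samples:
        moved = False
        for _ in range(config.thinning):
            pick = store[rng.integers(len(store))]
            d = pick - center
            norm = float(np.linalg.norm(d))
            if norm < 1e-9:
                continue
            d = d / norm
            Gd = G @ d
            resid = h - G @ z
            tmin, tmax = -np.inf, np.inf
            for k in range(len(h)):
                if Gd[k] > 1e-12:
                    tmax = min(tmax, resid[k] / Gd[k])
                elif Gd[k] < -1e-12:
                    tmin = max(tmin, resid[k] / Gd[k])
            if not (np.isfinite(tmin) and np.isfinite(tmax)) or tmax - tmin < 1e-12:
                continue
            t = rng.uniform(tmin, tmax)
            z = z + t * d
            moved = True
            n_visited += 1
            center = center + (z - center) / n_visited
        if not moved and not degenerate_warned:
            warnings.warn("sampling space is (near-)degenerate; "
                          "emitting the current feasible point")
            degenerate_warned = True
        samples_z.append(z.copy())
        store.append(z.copy())
    X = np.array(samples_z) @ N.T
    M = split.net_matrix()
    return X @ M.T


def reference_distribution(
    samples: np.ndarray,
    reaction_ids: list[str],
    model: MetabolicModel,
    zero_clamp: float = 1e-9,
) -> FluxDistribution:
    """Componentwise sample mean; fluxes below ``zero_clamp`` snap to 0."""
    if samples.ndim != 2 or samples.shape[0] < 1:
        raise ValueError("need at least one sample")
    mean = samples.mean(axis=0)
    mean[np.abs(mean) < zero_clamp] = 0.0
    flux = FluxDistribution(dict(zip(reaction_ids, map(float, mean))), model.id)
    flux.check_feasibility(model)
    return flux


def compute_reference(
    model: MetabolicModel,
    penalties: PenaltyWeights,
    biomass_fraction: float = 0.2,
    uniform_fallback: float = 1.0,
    slack: float = 0.01,
    config: SamplingConfig | None = None,
) -> ReferenceResult:
    """End-to-end: weighted minimization -> FVA space -> ACHR -> mean."""
    config = config or SamplingConfig()
    p_star, _ = gim3e_minimize(model, penalties, biomass_fraction, uniform_fallback)
    space = solution_space(model, penalties, p_star, biomass_fraction,
                           uniform_fallback, slack)
    samples = achr_sample(space, config)
    rids = list(space.split.mapping)
    v_ref = reference_distribution(samples, rids, model)
    return ReferenceResult(p_star, space.fva_bounds, samples, rids, v_ref,
                           config, slack)
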