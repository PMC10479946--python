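"""Reproducible end-to-end orchestration: context models -> reference flux ->
quadratic transformation -> reports, driven by a single JSON config."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .context import (ContextConfig, ExpressionProfile, MediumSpec,
                      build_context_model, reaction_expression)
from .core import MetabolicModel, load_model
from .degs import filter_degs, venn_overlap
from .qmta import QMTAConfig, assemble_qp, gene_weights, pathway_report, solve_qmta
from .reference import (PenaltyWeights, ReferenceResult, SamplingConfig,
                        compute_reference, expression_penalties)

__all__ = ["PipelineConfig", "run_reference", "run_qmta", "run_all"]


class PipelineValidationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    model_path: str
    expression_path: str
    conditions_path: str
    de_paths: dict[str, str]            # condition -> DE TSV
    output_dir: str
    medium_path: str | None = None
    measurements_path: str | None = None
    untreated_condition: str = "control"
    master_seed: int = 0
    context: dict = field(default_factory=dict)
    sampling: dict = field(default_factory=dict)
    qmta: dict = field(default_factory=dict)
    biomass_fraction: float = 0.2
    uniform_fallback: float = 1.0
    slack: float = 0.01

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        paths = [self.model_path, self.expression_path, self.conditions_path,
                 *self.de_paths.values()]
        if self.medium_path:
            paths.append(self.medium_path)
        if self.measurements_path:
            paths.append(self.measurements_path)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise PipelineValidationError(f"missing input files: {missing}")

    def resolved(self) -> dict:
        out = dict(vars(self))
        out["context"] = vars(ContextConfig(**self.context))
        out["sampling"] = vars(SamplingConfig(seed=self.master_seed, **self.sampling))
        out["qmta"] = vars(QMTAConfig(**self.qmta))
        return out

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True).encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    config.validate()
    model = load_model(config.model_path)
    profile = ExpressionProfile.from_files(config.expression_path,
                                           config.conditions_path)
    de_tables = {c: pd.read_csv(p, sep="\t") for c, p in config.de_paths.items()}
    medium = MediumSpec.from_file(config.medium_path) if config.medium_path else None
    measurements = (json.loads(Path(config.measurements_path).read_text())
                    if config.measurements_path else None)
    return model, profile, de_tables, medium, measurements


def run_reference(config: PipelineConfig) -> ReferenceResult:
    """Control context model -> weighted minimization -> FVA -> ACHR -> mean."""
    model, profile, de_tables, medium, measurements = _load_inputs(config)
    ctx = ContextConfig(**config.context)
    models, provenance = build_context_model(
        model, profile, de_tables, medium, measurements, ctx,
        config.untreated_condition)
    control = models[config.untreated_condition]
    scores = reaction_expression(control, profile, config.untreated_condition,
                                 ctx.or_rule)
    penalties = expression_penalties(control, scores)
    sampling = SamplingConfig(seed=config.master_seed, **config.sampling)
    result = compute_reference(control, penalties, config.biomass_fraction,
                               config.uniform_fallback, config.slack, sampling)
    outdir = Path(config.output_dir) / "reference"
    result.to_files(outdir, control)
    (outdir / "provenance.jsonl").write_text(
        "\n".join(json.dumps(e) for e in provenance) + "\n")
    (outdir / "config.json").write_text(
        json.dumps({"hash": config.hash(), **config.resolved()}, indent=1))
    return result


def run_qmta(config: PipelineConfig, reference: ReferenceResult) -> dict:
    """One qMTA fit + pathway report per treatment condition."""
    model, profile, de_tables, medium, measurements = _load_inputs(config)
    ctx = ContextConfig(**config.context)
    models, _ = build_context_model(model, profile, de_tables, medium,
                                    measurements, ctx, config.untreated_condition)
    qcfg = QMTAConfig(**config.qmta)
    results = {}
    outdir = Path(config.output_dir)
    for cond, de in de_tables.items():
        if cond == config.untreated_condition:
            continue
        m = models[cond]
        # restrict the reference to reactions surviving in this context
        weights = gene_weights(de, qcfg.p_th)
        spec = assemble_qp(m, _restrict(reference, m), de, weights,
                           measurements, qcfg)
        res = solve_qmta(spec, qcfg)
        results[cond] = res
        report = pathway_report(res, m)
        cdir = outdir / f"qmta_{cond}"
        cdir.mkdir(parents=True, exist_ok=True)
        report.to_csv(cdir / "result.tsv", sep="\t", index=False)
        (cdir / "summary.json").write_text(json.dumps({
            "objective": res.objective,
            "decomposition": res.decomposition,
            "status": res.status,
            "config_hash": config.hash(),
        }, indent=1))
    return results


def _restrict(reference: ReferenceResult, model: MetabolicModel):
    from .core import FluxDistribution

    values = {rid: reference.v_ref.values[rid] for rid in model.reaction_ids()}
    flux = FluxDistribution(values, model.id)
    flux.check_feasibility(model)
    return flux


def _load_cached_reference(config: PipelineConfig) -> ReferenceResult | None:
    """Reload a previously computed reference if its run config matches.

    Only v_ref and the scalar summary are persisted; the sample matrix is
    recomputable from the seed and is not needed downstream.  A corrupted or
    stale cache (hash mismatch, unreadable files) triggers recomputation.
    """
    import numpy as np

    from .core import FluxDistribution

    refdir = Path(config.output_dir) / "reference"
    sidecar, cfgfile = refdir / "reference.json", refdir / "config.json"
    if not (sidecar.exists() and cfgfile.exists()):
        return None
    try:
        cached_cfg = json.loads(cfgfile.read_text())
        meta = json.loads(sidecar.read_text())
        if cached_cfg.get("hash") != config.hash():
            return None
        df = pd.read_csv(refdir / "v_ref.tsv", sep="\t")
    except (OSError, ValueError, KeyError):
        return None
    values = dict(zip(df.reaction_id, df.flux))
    flux = FluxDistribution(values, feasible=True)
    sampling = SamplingConfig(seed=config.master_seed, **config.sampling)
    return ReferenceResult(
        penalty_optimum=float(meta["penalty_optimum"]),
        fva_bounds={}, samples=np.empty((0, len(values))),
        reaction_ids=list(values), v_ref=flux, config=sampling,
        slack=float(meta["slack"]))


def run_all(config: PipelineConfig) -> dict:
    """Full pipeline plus DEG overlap summaries and a run report."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = _load_cached_reference(config) or run_reference(config)
    t_ref = time.time()
    results = run_qmta(config, reference)
    t_qmta = time.time()

    venns = {}
    de_tables = {c: pd.read_csv(p, sep="\t") for c, p in config.de_paths.items()}
    conds = [c for c in de_tables if c != config.untreated_condition]
    for i, a in enumerate(conds):
        for b in conds[i + 1:]:
            da = filter_degs(de_tables[a])
            db = filter_degs(de_tables[b])
            for direction in ("up", "down"):
                sa = set(da.loc[da.direction == direction, "gene"])
                sb = set(db.loc[db.direction == direction, "gene"])
                venns[f"{a}_vs_{b}_{direction}"] = venn_overlap(sa, sb).as_dict()

    report = {
        "config_hash": config.hash(),
        "master_seed": config.master_seed,
        "timings_s": {"reference": t_ref - t0, "qmta": t_qmta - t_ref},
        "conditions": conds,
        "penalty_optimum": reference.penalty_optimum,
        "objectives": {c: r.objective for c, r in results.items()},
        "venn": venns,
    }
    (outdir / "run_report.json").write_text(json.dumps(report, indent=1))
    return report
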