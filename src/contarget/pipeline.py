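"""End-to-end orchestration of the four analysis stages.

Stage order: context extraction, then the objective-dependent screens (stage
1) and the network/controllability analyses (stages 2-3) — which are
independent of each other — and finally the intersection and ranking (stage
4).  Every run writes its configuration, per-stage tables, a structured log
of counts, and the ranked target table into the output directory; identical
configurations reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import synthetic_data
from .context_builder import (ContextModel, build_cohort_contexts,
                              cohort_manifest, load_expression_tsv)
from .controllability import (cancer_specific_from_maps, controlling_nodes,
                              gene_level_controlling)
from .errors import ValidationError
from .model_core import MetabolicModel, load_model, load_tasks
from .network_build import DirectedNetwork, build_mmn, build_rrn
from .prioritize import compute_centralities, intersect_targets, rank_targets
from .target_screen import (antimetabolite_screen, gene_silencing_screen,
                            screen_detail, screen_table, toxicity_filter)


@dataclass
class PipelineConfig:
    """Flat, fully serializable run configuration.

    ``toy_variant`` selects a generated reference model; alternatively
    ``model_path``/``model_format`` load one from disk.  Expression defaults
    to the generated planted cohort when paths are unset.
    """

    toy_variant: str | None = "cohort"
    model_path: str | None = None
    model_format: str = "json"
    expression_path: str | None = None
    groups_path: str | None = None
    tasks_path: str | None = None
    cancer_objective: str = synthetic_data.CANCER_OBJECTIVE
    noncancer_objective: str = synthetic_data.NONCANCER_OBJECTIVE
    eps: float = 1e-6
    cancer_fraction: float = 1.0
    min_cancer: int = 1
    aggregation: str = "mean"
    seed: int = 0
    n_cancer: int = 5
    n_noncancer: int = 5

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                         sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        doc = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)


@dataclass
class PipelineResult:
    contexts: list[ContextModel]
    screen_pass: list
    controlling: dict[str, dict]
    ranked: pd.DataFrame
    log: list[str] = field(default_factory=list)


def _load_inputs(config: PipelineConfig):
    if config.model_path:
        model = load_model(config.model_path, format=config.model_format)
    elif config.toy_variant:
        model = synthetic_data.generate_toy_gem(config.toy_variant,
                                                seed=config.seed)
    else:
        raise ValidationError("config must set model_path or toy_variant")
    if config.expression_path and config.groups_path:
        expr = load_expression_tsv(config.expression_path, config.groups_path)
    else:
        spec = synthetic_data.CohortSpec(n_cancer=config.n_cancer,
                                         n_noncancer=config.n_noncancer,
                                         seed=config.seed)
        expr = synthetic_data.generate_expression_cohort(spec, model)
    if config.tasks_path:
        tasks = load_tasks(config.tasks_path)
    else:
        tasks = synthetic_data.toy_tasks(model)
    return model, expr, tasks


def _base_level(controlling: Mapping[str, str],
                model: MetabolicModel) -> dict[str, str]:
    """Pool compartment-qualified MMN controlling nodes to base names."""
    tags: dict[str, set[str]] = {}
    for met, origin in controlling.items():
        base = model.base_metabolite_of.get(met, met)
        tags.setdefault(base, set()).add(origin)
    out = {}
    for base in sorted(tags):
        t = tags[base]
        if "both" in t or ("MDS" in t and "indispensable" in t):
            out[base] = "both"
        else:
            out[base] = next(iter(t))
    return out


def _base_centralities(net: DirectedNetwork,
                       model: MetabolicModel) -> dict[str, tuple[float, float]]:
    """MMN centralities pooled to base names (max over compartment instances)."""
    cents = compute_centralities(net)
    out: dict[str, tuple[float, float]] = {}
    for met, (deg, btw) in cents.items():
        base = model.base_metabolite_of.get(met, met)
        if base in out:
            out[base] = (max(out[base][0], deg), max(out[base][1], btw))
        else:
            out[base] = (deg, btw)
    return out


def _gene_centralities(net: DirectedNetwork,
                       model: MetabolicModel) -> dict[str, tuple[float, float]]:
    """RRN centralities lifted to genes (max over catalyzed reactions)."""
    cents = compute_centralities(net)
    out: dict[str, tuple[float, float]] = {}
    for gene in model.gene_ids:
        vals = [cents[rid] for rid in model.reactions_of_gene(gene)
                if rid in cents]
        if vals:
            out[gene] = (max(v[0] for v in vals), max(v[1] for v in vals))
    return out


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Execute all four stages; optionally write a full output directory."""
    log: list[str] = []
    model, expr, tasks = _load_inputs(config)
    tasks_by_group = {"cancer": tasks, "noncancer": tasks}
    log.append(f"reference model {model.name}: {model.n_metabolites} metabolites, "
               f"{model.n_reactions} reactions, {len(model.gene_ids)} genes")

    # contexts
    contexts = build_cohort_contexts(
        model, expr, config.cancer_objective, config.noncancer_objective,
        tasks_by_group["cancer"], tasks_by_group["noncancer"], eps=config.eps)
    bad = [c.sample_id for c in contexts if not c.functional]
    if bad:
        raise ValidationError(f"non-functional context(s): {bad}")
    cancer_ctx = [c for c in contexts if c.group == "cancer"]
    noncancer_ctx = [c for c in contexts if c.group == "noncancer"]
    log.append(f"contexts: {len(cancer_ctx)} cancer, {len(noncancer_ctx)} noncancer")

    # stage 1: objective-dependent screens + toxicity filter
    amet = antimetabolite_screen(contexts, tasks_by_group, eps=config.eps)
    genes = gene_silencing_screen(contexts, tasks_by_group, eps=config.eps)
    amet_pass = toxicity_filter(amet, len(cancer_ctx), config.cancer_fraction)
    genes_pass = toxicity_filter(genes, len(cancer_ctx), config.cancer_fraction)
    log.append(f"antimetabolites: {len(amet)} screened, {len(amet_pass)} pass "
               "toxicity filter")
    log.append(f"gene silencings: {len(genes)} screened, {len(genes_pass)} pass "
               "toxicity filter")

    # stages 2-3: networks and controllability
    cancer_mmn = [build_mmn(c) for c in cancer_ctx]
    noncancer_mmn = [build_mmn(c) for c in noncancer_ctx]
    cancer_rrn = [build_rrn(c) for c in cancer_ctx]
    noncancer_rrn = [build_rrn(c) for c in noncancer_ctx]

    mmn_maps_cancer = [_base_level(controlling_nodes(net), model)
                       for net in cancer_mmn]
    mmn_maps_noncancer = [_base_level(controlling_nodes(net), model)
                          for net in noncancer_mmn]
    met_controlling = cancer_specific_from_maps(
        mmn_maps_cancer, mmn_maps_noncancer, min_cancer=config.min_cancer)

    rrn_maps_cancer = [controlling_nodes(net) for net in cancer_rrn]
    rrn_maps_noncancer = [controlling_nodes(net) for net in noncancer_rrn]
    gene_maps_cancer = [
        {g: info["origin"]
         for g, info in gene_level_controlling(
             {r: {"count": 1, "origin": o} for r, o in m.items()}, model).items()}
        for m in rrn_maps_cancer]
    gene_maps_noncancer = [
        {g: info["origin"]
         for g, info in gene_level_controlling(
             {r: {"count": 1, "origin": o} for r, o in m.items()}, model).items()}
        for m in rrn_maps_noncancer]
    gene_controlling = cancer_specific_from_maps(
        gene_maps_cancer, gene_maps_noncancer, min_cancer=config.min_cancer)
    log.append(f"cancer-specific controlling: {len(met_controlling)} metabolites, "
               f"{len(gene_controlling)} genes")

    # stage 4: intersection, centralities, ranking
    candidates = (intersect_targets(amet_pass, met_controlling)
                  + intersect_targets(genes_pass, gene_controlling))
    met_cent = [_base_centralities(net, model) for net in cancer_mmn]
    gene_cent = [_gene_centralities(net, model) for net in cancer_rrn]
    ranked = rank_targets(candidates,
                          {"metabolite": met_cent, "gene": gene_cent},
                          aggregation=config.aggregation)
    log.append(f"final ranked targets: {len(ranked)}")

    result = PipelineResult(
        contexts=contexts,
        screen_pass=list(amet_pass) + list(genes_pass),
        controlling={**{f"metabolite:{k}": v for k, v in met_controlling.items()},
                     **{f"gene:{k}": v for k, v in gene_controlling.items()}},
        ranked=ranked, log=log)

    if out_dir is not None:
        _write_outputs(Path(out_dir), config, result, amet, genes,
                       amet_pass, genes_pass, contexts)
    return result


def _write_outputs(out: Path, config: PipelineConfig, result: PipelineResult,
                   amet, genes, amet_pass, genes_pass,
                   contexts: Sequence[ContextModel]) -> None:
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "config.json")
    cohort_manifest(contexts).to_csv(out / "manifest.tsv", sep="\t", index=False)
    screen_table(amet, amet_pass).to_csv(out / "antimetabolite_screen.tsv",
                                         sep="\t", index=False)
    screen_table(genes, genes_pass).to_csv(out / "gene_screen.tsv",
                                           sep="\t", index=False)
    screen_detail(list(amet) + list(genes)).to_csv(
        out / "screen_detail.tsv", sep="\t", index=False)
    pd.DataFrame([
        {"target": key, "count": info["count"], "origin": info["origin"]}
        for key, info in sorted(result.controlling.items())
    ]).to_csv(out / "controlling_nodes.tsv", sep="\t", index=False)
    result.ranked.to_csv(out / "ranked_targets.tsv", sep="\t", index=False)
    provenance = {
        "screen_passed": sorted(f"{r.target_type}:{r.target_id}"
                                for r in result.screen_pass),
        "controlling": result.controlling,
        "final_targets": list(result.ranked["target_id"]),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1,
                                                    sort_keys=True))
    (out / "run.log").write_text("\n".join(result.log) + "\n")
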