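"""Objective-dependent screens: antimetabolites, gene silencing, toxicity filter.

Both screens simulate a perturbation per context model and ask whether the
context stays viable (its group's objective above threshold and all of its
group's metabolic tasks feasible).  A perturbation that abolishes viability
in cancer contexts but leaves every non-cancer context viable is an
*anticancer non-toxic* candidate.

Antimetabolites: for each base metabolite name, pooled over compartments, the
screen removes every reaction in which any compartment instance of the
metabolite serves as substrate (reactant side for irreversible reactions,
either side for reversible ones).  Currency metabolites are screened like any
other; they are only excluded from the derived networks, not from this step.

Gene silencing: removes every reaction whose gene rule evaluates to
non-functional with the gene absent (an isozyme survives if any complex set
excluding the gene remains complete).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .context_builder import ContextModel
from .errors import ValidationError
from .model_core import MetabolicTask, delete_reactions, is_viable


@dataclass
class ScreenResult:
    """Per-target outcome of a cohort-wide perturbation screen."""

    target_id: str
    target_type: str  # metabolite | gene
    lethal_in: set[str] = field(default_factory=set)      # cancer samples
    toxic_in: set[str] = field(default_factory=set)       # non-cancer samples
    affected_reactions: dict[str, set[str]] = field(default_factory=dict)
    lethal_in_all: bool = False   # annotated by toxicity_filter
    lethal_in_any: bool = False


def _group_tasks(context: ContextModel,
                 tasks_by_group: Mapping[str, Sequence[MetabolicTask]],
                 ) -> Sequence[MetabolicTask]:
    return tasks_by_group.get(context.group, ())


def _perturbed_viable(context: ContextModel, removed: set[str],
                      tasks_by_group: Mapping[str, Sequence[MetabolicTask]],
                      eps: float) -> bool:
    model = delete_reactions(context.model, removed) if removed else context.model
    return is_viable(model, tasks=_group_tasks(context, tasks_by_group), eps=eps)


def _screen(contexts: Sequence[ContextModel], targets: Sequence[str],
            target_type: str, removal_of, tasks_by_group, eps: float,
            ) -> list[ScreenResult]:
    if not contexts:
        raise ValidationError("empty context list")
    results = []
    for target in targets:
        res = ScreenResult(target_id=target, target_type=target_type)
        for ctx in contexts:
            removed = removal_of(ctx, target)
            removed = {r for r in removed if r in ctx.kept_reactions}
            res.affected_reactions[ctx.sample_id] = removed
            if not removed:
                continue  # no-op perturbation cannot change viability
            if not _perturbed_viable(ctx, removed, tasks_by_group, eps):
                if ctx.group == "cancer":
                    res.lethal_in.add(ctx.sample_id)
                else:
                    res.toxic_in.add(ctx.sample_id)
        results.append(res)
    return results


def antimetabolite_screen(contexts: Sequence[ContextModel],
                          tasks_by_group: Mapping[str, Sequence[MetabolicTask]],
                          eps: float = 1e-6) -> list[ScreenResult]:
    """Screen every base metabolite name, regardless of compartmentalization."""
    if not contexts:
        raise ValidationError("empty context list")
    ref = contexts[0].model
    base_names = sorted(set(ref.base_metabolite_of.values()))

    def removal(ctx: ContextModel, base: str) -> set[str]:
        return ctx.model.substrate_reactions(base)

    return _screen(contexts, base_names, "metabolite", removal,
                   tasks_by_group, eps)


def reactions_lost_by_silencing(model, gene: str) -> set[str]:
    """Reactions whose gene rule fails with ``gene`` absent.

    A rule (list of isozyme complexes) survives if any complex not containing
    the gene remains complete; reactions without a rule are never lost.
    """
    lost = set()
    for rid, isozymes in model.gpr.items():
        if not isozymes:
            continue
        if all(gene in complex_ for complex_ in isozymes):
            lost.add(rid)
    return lost


def gene_silencing_screen(contexts: Sequence[ContextModel],
                          tasks_by_group: Mapping[str, Sequence[MetabolicTask]],
                          eps: float = 1e-6) -> list[ScreenResult]:
    """In-silico silencing of every gene of the reference model."""
    if not contexts:
        raise ValidationError("empty context list")
    genes = sorted(contexts[0].model.gene_ids)

    def removal(ctx: ContextModel, gene: str) -> set[str]:
        return reactions_lost_by_silencing(ctx.model, gene)

    return _screen(contexts, genes, "gene", removal, tasks_by_group, eps)


def toxicity_filter(results: Sequence[ScreenResult],
                    n_cancer: int, cancer_fraction: float = 1.0,
                    ) -> list[ScreenResult]:
    """Keep targets lethal in >= cancer_fraction of cancer contexts and toxic
    in none.

    The default fraction 1.0 demands lethality in every cancer context.  Each
    surviving result is annotated with the all-contexts and any-context tiers
    for reporting.
    """
    if not 0 < cancer_fraction <= 1:
        raise ValidationError("cancer_fraction must be in (0, 1]")
    kept = []
    threshold = cancer_fraction * n_cancer
    for res in results:
        res.lethal_in_all = len(res.lethal_in) == n_cancer
        res.lethal_in_any = len(res.lethal_in) >= 1
        if len(res.lethal_in) >= threshold and not res.toxic_in:
            kept.append(res)
    return kept


def screen_table(results: Sequence[ScreenResult],
                 passed: Sequence[ScreenResult]) -> pd.DataFrame:
    """Wide summary table of a screen (one row per target)."""
    passed_ids = {(r.target_type, r.target_id) for r in passed}
    rows = [{
        "target_id": r.target_id,
        "type": r.target_type,
        "n_lethal_cancer": len(r.lethal_in),
        "n_toxic_noncancer": len(r.toxic_in),
        "passes_filter": (r.target_type, r.target_id) in passed_ids,
    } for r in results]
    return pd.DataFrame(rows)


def screen_detail(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Long-format per-sample detail (removed reaction counts and outcomes)."""
    rows = []
    for r in results:
        for sample, removed in sorted(r.affected_reactions.items()):
            rows.append({
                "target_id": r.target_id,
                "type": r.target_type,
                "sample": sample,
                "n_reactions_removed": len(removed),
                "reactions_removed": ";".join(sorted(removed)),
                "lethal": sample in r.lethal_in,
                "toxic": sample in r.toxic_in,
            })
    return pd.DataFrame(rows)
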