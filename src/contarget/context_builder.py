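"""Build one functional context-specific model per expression sample.

Expression evidence (FPKM-like values) is discretized into four ordinal bins
(none < 1 <= low < 10 <= medium < 50 <= high), aggregated over each reaction's
gene rule, and used to subset the reference model.  The extractor keeps every
reaction with any expression evidence (bin >= 1), every boundary exchange and
every reaction without a gene rule, then greedily re-adds excluded reactions
(best evidence first) until the context passes its group's objective and
metabolic tasks.  This is a deterministic, evidence-threshold extraction in
the spirit of task-driven model extraction methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model_core import MetabolicModel, MetabolicTask, delete_reactions, is_viable

#: FPKM bin edges: [1, 10, 50) half-open boundaries, value >= edge enters the bin.
BIN_EDGES = (1.0, 10.0, 50.0)

#: Sentinel score for reactions with no gene rule (no evidence against them).
NEUTRAL = -1

GROUPS = ("cancer", "noncancer")


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression values with sample group labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("expression matrix shape does not match id lists")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in expression matrix")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise ValidationError(f"samples without a group label: {missing}")
        bad = {s: g for s, g in self.group_of.items() if g not in GROUPS}
        if bad:
            raise ValidationError(f"unknown group label(s): {bad}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]


@dataclass
class ContextModel:
    """A per-sample subset of the reference model (closed-bounds subset)."""

    sample_id: str
    group: str
    model: MetabolicModel
    kept_reactions: set[str]
    functional: bool = True
    gap_filled: list[str] = field(default_factory=list)


def bin_expression(expr: ExpressionMatrix) -> pd.DataFrame:
    """Discretize FPKM into ordinal bins 0..3 (genes x samples DataFrame).

    bin 0: FPKM < 1; bin 1: 1 <= FPKM < 10; bin 2: 10 <= FPKM < 50;
    bin 3: FPKM >= 50.
    """
    bins = np.zeros(expr.values.shape, dtype=int)
    for edge in BIN_EDGES:
        bins += (expr.values >= edge).astype(int)
    return pd.DataFrame(bins, index=expr.gene_ids, columns=expr.sample_ids)


def score_reactions(model: MetabolicModel, bins: pd.DataFrame,
                    sample: str) -> dict[str, int]:
    """Aggregate gene bins over each reaction's rule.

    Isozymes combine with max (any isoform suffices); complex members with min
    (all subunits needed).  Genes absent from the expression matrix count as
    unexpressed (bin 0).  Reactions without a rule get the NEUTRAL sentinel.
    """
    if sample not in bins.columns:
        raise ValidationError(f"sample {sample!r} not in binned expression")
    col = bins[sample]

    def gene_bin(g: str) -> int:
        return int(col[g]) if g in col.index else 0

    scores: dict[str, int] = {}
    for rid in model.reaction_ids:
        isozymes = model.gpr.get(rid, [])
        if not isozymes:
            scores[rid] = NEUTRAL
        else:
            scores[rid] = max(min(gene_bin(g) for g in complex_)
                              for complex_ in isozymes)
    return scores


def extract_context_model(model: MetabolicModel, scores: Mapping[str, int],
                          group: str, tasks: Sequence[MetabolicTask],
                          objective: str, sample_id: str = "",
                          eps: float = 1e-6) -> ContextModel:
    """Threshold-keep extraction with greedy task-driven gap-fill.

    Keeps reactions with score >= 1 plus all exchanges and all no-rule
    reactions.  If the subset fails the group's objective/tasks, excluded
    reactions are re-added greedily (highest score first, ties by reaction id)
    until viability is restored or candidates run out; irrecoverable contexts
    are flagged non-functional.
    """
    missing = set(model.reaction_ids) - set(scores)
    if missing:
        raise ValidationError(f"scores missing for reactions: {sorted(missing)}")
    if not is_viable(model, objective=objective, tasks=tasks, eps=eps):
        raise ValidationError(
            "reference model itself fails the group objective/tasks; "
            "check the configuration")

    kept = {rid for rid in model.reaction_ids
            if scores[rid] == NEUTRAL or scores[rid] >= 1 or model.is_exchange(rid)}
    excluded = [rid for rid in model.reaction_ids if rid not in kept]
    # highest evidence first, ties lexicographic
    excluded.sort(key=lambda rid: (-scores[rid], rid))

    def submodel(kept_now: set[str]) -> MetabolicModel:
        return delete_reactions(model, set(model.reaction_ids) - kept_now)

    gap_filled: list[str] = []
    current = submodel(kept)
    functional = is_viable(current, objective=objective, tasks=tasks, eps=eps)
    while not functional and excluded:
        rid = excluded.pop(0)
        kept.add(rid)
        gap_filled.append(rid)
        current = submodel(kept)
        functional = is_viable(current, objective=objective, tasks=tasks, eps=eps)
    return ContextModel(sample_id=sample_id, group=group, model=current,
                        kept_reactions=set(kept), functional=functional,
                        gap_filled=gap_filled)


def build_cohort_contexts(model: MetabolicModel, expr: ExpressionMatrix,
                          cancer_objective: str, noncancer_objective: str,
                          cancer_tasks: Sequence[MetabolicTask],
                          noncancer_tasks: Sequence[MetabolicTask],
                          eps: float = 1e-6) -> list[ContextModel]:
    """One context per sample; cancer contexts must additionally sustain growth.

    Cancer samples use the growth (biomass) reaction as objective, non-cancer
    samples the ATP-consumption reaction, each with its group's task list.
    """
    bins = bin_expression(expr)
    contexts = []
    for sample in expr.sample_ids:
        group = expr.group_of[sample]
        objective = cancer_objective if group == "cancer" else noncancer_objective
        tasks = cancer_tasks if group == "cancer" else noncancer_tasks
        scores = score_reactions(model, bins, sample)
        contexts.append(extract_context_model(
            model, scores, group, tasks, objective, sample_id=sample, eps=eps))
    return contexts


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def load_expression_tsv(values_path: str | Path,
                        groups_path: str | Path) -> ExpressionMatrix:
    """Read an expression table (first column gene id) and a two-column group map."""
    df = pd.read_csv(values_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", header=None,
                         names=["sample", "group"], comment="#")
    group_of = dict(zip(groups["sample"].astype(str), groups["group"].astype(str)))
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        group_of=group_of,
    )


def write_expression_tsv(expr: ExpressionMatrix, values_path: str | Path,
                         groups_path: str | Path) -> None:
    pd.DataFrame(expr.values, index=expr.gene_ids,
                 columns=expr.sample_ids).to_csv(values_path, sep="\t",
                                                index_label="gene")
    with open(groups_path, "w") as fh:
        for s in expr.sample_ids:
            fh.write(f"{s}\t{expr.group_of[s]}\n")


def cohort_manifest(contexts: Iterable[ContextModel]) -> pd.DataFrame:
    rows = [{"sample": c.sample_id, "group": c.group,
             "functional": c.functional, "n_reactions": len(c.kept_reactions),
             "n_gap_filled": len(c.gap_filled)} for c in contexts]
    return pd.DataFrame(rows)
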