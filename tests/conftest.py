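"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the package's own computation paths: flux
optima are recomputed by assembling the LP from a structurally rebuilt model,
lethality flags by from-scratch deletion, betweenness by explicit BFS path
counting, and driver counts by exact rational arithmetic.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linprog

from contarget.context_builder import ContextModel
from contarget.model_core import (MetabolicModel, model_from_dict,
                                  model_to_dict)
from contarget.synthetic_data import generate_toy_gem, toy_tasks


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

@pytest.fixture
def toy1() -> MetabolicModel:
    return generate_toy_gem("minimal")


@pytest.fixture
def toy1r() -> MetabolicModel:
    return generate_toy_gem("with_redundancy")


@pytest.fixture
def cohort_model() -> MetabolicModel:
    return generate_toy_gem("cohort")


@pytest.fixture(scope="session")
def pipeline_result():
    from contarget.pipeline import PipelineConfig, run_pipeline
    return run_pipeline(PipelineConfig(seed=1))


def as_context(model: MetabolicModel, group: str = "cancer",
               sample: str = "s1") -> ContextModel:
    """Wrap a bare model as a fully kept context."""
    return ContextModel(sample_id=sample, group=group, model=model,
                        kept_reactions=set(model.reaction_ids))


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def oracle_max_flux(model: MetabolicModel, objective: str,
                    removed: set[str] = frozenset()) -> float | None:
    """Maximal objective flux after *structurally* removing reactions.

    Rebuilds the stoichiometric system from the serialized document with the
    removed reactions dropped entirely (not bound-closed), then solves the LP
    directly.  Returns None if the objective reaction itself was removed or
    the system is infeasible.
    """
    doc = model_to_dict(model)
    doc["reactions"] = [r for r in doc["reactions"] if r["id"] not in removed]
    if not any(r["id"] == objective for r in doc["reactions"]):
        return None
    kept = [r["id"] for r in doc["reactions"]]
    met_index = {m: i for i, m in enumerate(doc["metabolites"])}
    S = np.zeros((len(met_index), len(kept)))
    bounds = []
    for j, r in enumerate(doc["reactions"]):
        for met, coef in r["stoichiometry"].items():
            S[met_index[met], j] = coef
        bounds.append((r["lb"], r["ub"]))
    c = np.zeros(len(kept))
    c[kept.index(objective)] = -1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                  method="highs")
    if res.status != 0:
        return None
    return float(-res.fun)


def oracle_task_feasible(model: MetabolicModel, task,
                         removed: set[str] = frozenset()) -> bool:
    """Task feasibility on a structurally rebuilt model (independent assembly)."""
    doc = model_to_dict(model)
    doc["reactions"] = [r for r in doc["reactions"] if r["id"] not in removed]
    met_index = {m: i for i, m in enumerate(doc["metabolites"])}
    n = len(doc["reactions"])
    S = np.zeros((len(met_index), n))
    bounds = []
    for j, r in enumerate(doc["reactions"]):
        stoich = r["stoichiometry"]
        for met, coef in stoich.items():
            S[met_index[met], j] = coef
        lb, ub = r["lb"], r["ub"]
        if len(stoich) == 1:  # boundary exchange: closed unless an allowed input
            lb, ub = 0.0, 0.0
            (met, coef), = stoich.items()
            if met in task.allowed_inputs:
                cap = task.allowed_inputs[met]
                lb, ub = (-cap, 0.0) if coef < 0 else (0.0, cap)
        bounds.append((lb, ub))
    cols = []
    for met, demand in sorted(task.required_outputs.items()):
        col = np.zeros((len(met_index), 1))
        col[met_index[met], 0] = -1.0
        cols.append(col)
        bounds.append((demand, 1e6))
    A = np.hstack([S] + cols) if cols else S
    res = linprog(np.zeros(A.shape[1]), A_eq=A, b_eq=np.zeros(A.shape[0]),
                  bounds=bounds, method="highs")
    return res.status == 0


def oracle_lethal(context: ContextModel, removed: set[str], tasks,
                  objective: str, eps: float = 1e-6) -> bool:
    """From-scratch viability loss check used against both screens."""
    closed = {rid for j, rid in enumerate(context.model.reaction_ids)
              if context.model.lb[j] == 0 and context.model.ub[j] == 0}
    gone = closed | set(removed)
    opt = oracle_max_flux(context.model, objective, gone)
    if opt is None or opt <= eps:
        return True
    return not all(oracle_task_feasible(context.model, t, gone) for t in tasks)


def oracle_substrate_reactions(model: MetabolicModel, base: str) -> set[str]:
    """Reactions consuming any compartment instance of a base metabolite."""
    hit = set()
    doc = model_to_dict(model)
    for r in doc["reactions"]:
        for met, coef in r["stoichiometry"].items():
            if model.base_metabolite_of[met] != base:
                continue
            if coef < 0 or r["rev"] == 1:
                hit.add(r["id"])
    return hit


def oracle_gene_removed(model: MetabolicModel, gene: str) -> set[str]:
    return {rid for rid, isozymes in model.gpr.items()
            if isozymes and all(gene in c for c in isozymes)}


def brute_force_screen_flags(model: MetabolicModel, eps: float = 1e-6):
    """Lethality of every base metabolite and gene on the bare model.

    Uses only oracle code paths; the model is treated as a single cancer
    context with its toy task list.
    """
    tasks = toy_tasks(model)
    ctx = as_context(model)
    met_flags = {}
    for base in sorted(set(model.base_metabolite_of.values())):
        removed = oracle_substrate_reactions(model, base)
        met_flags[base] = bool(removed) and oracle_lethal(
            ctx, removed, tasks, model.objective_id, eps)
    gene_flags = {}
    for gene in sorted(model.gene_ids):
        removed = oracle_gene_removed(model, gene)
        gene_flags[gene] = bool(removed) and oracle_lethal(
            ctx, removed, tasks, model.objective_id, eps)
    return met_flags, gene_flags


def oracle_betweenness(nodes, edges) -> dict[str, float]:
    """Directed shortest-path betweenness by explicit BFS enumeration."""
    from collections import deque

    adj = {n: [] for n in nodes}
    for u, v in edges:
        adj[u].append(v)
    score = {n: 0.0 for n in nodes}
    for s in nodes:
        # BFS shortest-path DAG from s
        dist = {s: 0}
        nsp = {s: 1.0}
        preds: dict[str, list[str]] = {n: [] for n in nodes}
        order = []
        q = deque([s])
        while q:
            u = q.popleft()
            order.append(u)
            for v in sorted(adj[u]):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nsp[v] = 0.0
                    q.append(v)
                if dist[v] == dist[u] + 1:
                    nsp[v] += nsp[u]
                    preds[v].append(u)
        dep = {n: 0.0 for n in nodes}
        for v in reversed(order):
            for u in preds[v]:
                dep[u] += nsp[u] / nsp[v] * (1.0 + dep[v])
            if v != s:
                score[v] += dep[v]
    n = len(nodes)
    norm = (n - 1) * (n - 2) if n > 2 else 1
    return {k: v / norm for k, v in score.items()}
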