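"""Deterministic generators: toy metabolic models, planted cohorts, random graphs.

Everything downstream is exercised on these generators, so each one is a pure
function of its arguments and seed.

Toy model TOY1 (variant ``minimal``) is a seven-reaction model with a carbon
uptake, a branched biosynthesis pathway to a biomass pseudo-metabolite, and a
currency pair (ATP/ADP) regenerated by the uptake transporter:

    EX_A:   A[e] <=>            (exchange, uptake capped at 10)
    T1:     A[e] + ADP -> A[c] + ATP        (g1)
    R2:     A[c] + ATP -> B[c] + ADP        (g2)
    R3:     A[c] -> C[c]                    (g3)
    R4:     B[c] + C[c] -> biomass[c]       (g4)
    GROWTH: biomass[c] ->                   (growth objective)
    ATPase: ATP -> ADP                      (ATP-consumption objective)

Maximum growth is 5.0 at the default uptake bound of 10 (two carbons per
biomass).  Variant ``with_redundancy`` adds the bypass R5: A[c] -> B[c] (g5),
making g2 non-essential.

Variant ``cohort`` is the planted-cohort reference: the conversion of A to B
runs through an intermediate X in two steps (R2A: A[c]+ATP -> X[c]+ADP by
g2a; R2B: X[c] -> B[c] by g2b), the pathway is serial (R3: B[c] -> C[c]),
and the bypass R5: A[c] -> B[c] (g5) short-circuits the X route.  Cancer
samples of the generated cohort do not express g5, making the X route (genes
g2a, g2b; metabolite X) essential in cancer contexts only.  By construction
the planted anticancer non-toxic targets are the genes g2a and g2b and the
metabolite X, with g2b carrying the highest degree among them in the cancer
reaction-reaction network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .context_builder import ExpressionMatrix
from .errors import ValidationError
from .model_core import BIG_BOUND, MetabolicModel, MetabolicTask, model_from_dict
from .network_build import DirectedNetwork, network_from_edges

#: Planted anticancer non-toxic targets of the default cohort (variant "cohort").
PLANTED_GENES = ("g2a", "g2b")
PLANTED_METABOLITES = ("X",)
PLANTED_TOP_TARGET = "g2b"

CANCER_OBJECTIVE = "GROWTH"
NONCANCER_OBJECTIVE = "ATPase"


def _toy_doc(reactions: list[dict], metabolites: list[str], name: str) -> dict:
    return {
        "name": name,
        "metabolites": metabolites,
        "reactions": reactions,
        "currency": ["ATP[c]", "ADP[c]"],
        "objective": "GROWTH",
    }


def _rxn(rid, stoich, gene=None, rev=0, lb=0.0, ub=BIG_BOUND):
    return {"id": rid, "stoichiometry": stoich, "rev": rev, "lb": lb, "ub": ub,
            "gpr": [[gene]] if gene else []}


def _toy1_reactions() -> list[dict]:
    return [
        _rxn("EX_A", {"A[e]": -1}, rev=1, lb=-10.0),
        _rxn("T1", {"A[e]": -1, "ADP[c]": -1, "A[c]": 1, "ATP[c]": 1}, gene="g1"),
        _rxn("R2", {"A[c]": -1, "ATP[c]": -1, "B[c]": 1, "ADP[c]": 1}, gene="g2"),
        _rxn("R3", {"A[c]": -1, "C[c]": 1}, gene="g3"),
        _rxn("R4", {"B[c]": -1, "C[c]": -1, "biomass[c]": 1}, gene="g4"),
        _rxn("GROWTH", {"biomass[c]": -1}),
        _rxn("ATPase", {"ATP[c]": -1, "ADP[c]": 1}),
    ]


def _cohort_reactions() -> list[dict]:
    return [
        _rxn("EX_A", {"A[e]": -1}, rev=1, lb=-10.0),
        _rxn("T1", {"A[e]": -1, "ADP[c]": -1, "A[c]": 1, "ATP[c]": 1}, gene="g1"),
        _rxn("R2A", {"A[c]": -1, "ATP[c]": -1, "X[c]": 1, "ADP[c]": 1}, gene="g2a"),
        _rxn("R2B", {"X[c]": -1, "B[c]": 1}, gene="g2b"),
        _rxn("R3", {"B[c]": -1, "C[c]": 1}, gene="g3"),
        _rxn("R4", {"B[c]": -1, "C[c]": -1, "biomass[c]": 1}, gene="g4"),
        _rxn("R5", {"A[c]": -1, "B[c]": 1}, gene="g5"),
        _rxn("GROWTH", {"biomass[c]": -1}),
        _rxn("ATPase", {"ATP[c]": -1, "ADP[c]": 1}),
    ]


def _random_gem(seed: int) -> MetabolicModel:
    """A seeded random viable toy model: a linear backbone with bypasses.

    The backbone (uptake -> chain -> biomass -> growth sink) is always intact,
    so the model is viable by construction; random bypass reactions, isozymes
    and complexes decorate it.
    """
    rng = np.random.default_rng(seed)
    length = int(rng.integers(4, 10))  # backbone intermediates M1..Mlength
    mets = ["M0[e]"] + [f"M{i}[c]" for i in range(1, length + 1)] + \
        ["biomass[c]", "ATP[c]", "ADP[c]"]
    reactions = [
        _rxn("EX_M0", {"M0[e]": -1}, rev=1, lb=-10.0),
        _rxn("T0", {"M0[e]": -1, "ADP[c]": -1, "M1[c]": 1, "ATP[c]": 1}, gene="gT0"),
    ]
    gene_counter = 0
    for i in range(1, length):
        gene_counter += 1
        reactions.append(_rxn(f"C{i}", {f"M{i}[c]": -1, f"M{i+1}[c]": 1},
                              gene=f"g{gene_counter}"))
    gene_counter += 1
    reactions.append(_rxn("RBIO", {f"M{length}[c]": -1, "biomass[c]": 1},
                          gene=f"g{gene_counter}"))
    reactions.append(_rxn("GROWTH", {"biomass[c]": -1}))
    reactions.append(_rxn("ATPase", {"ATP[c]": -1, "ADP[c]": 1}))
    n_bypass = int(rng.integers(0, min(6, length)))
    for k in range(n_bypass):
        i = int(rng.integers(1, length))
        j = int(rng.integers(i + 1, length + 1))
        gene_counter += 1
        rev = int(rng.random() < 0.3)
        reactions.append(_rxn(f"BY{k}", {f"M{i}[c]": -1, f"M{j}[c]": 1},
                              gene=f"g{gene_counter}", rev=rev,
                              lb=-BIG_BOUND if rev else 0.0))
    # decorate some reactions with isozymes or complex partners
    for r in reactions:
        if not r["gpr"]:
            continue
        u = rng.random()
        if u < 0.25:
            gene_counter += 1
            r["gpr"].append([f"g{gene_counter}"])          # isozyme (OR)
        elif u < 0.40:
            gene_counter += 1
            r["gpr"][0] = r["gpr"][0] + [f"g{gene_counter}"]  # complex (AND)
    doc = _toy_doc(reactions, mets, f"random-{seed}")
    model = model_from_dict(doc)
    model.name = f"random-{seed}"
    return model


def generate_toy_gem(variant: str = "minimal", seed: int = 0) -> MetabolicModel:
    """Build a toy model: ``minimal``, ``with_redundancy``, ``cohort``, or
    ``randomized`` (seeded)."""
    if variant == "minimal":
        return model_from_dict(_toy_doc(
            _toy1_reactions(),
            ["A[e]", "A[c]", "B[c]", "C[c]", "biomass[c]", "ATP[c]", "ADP[c]"],
            "TOY1"))
    if variant == "with_redundancy":
        reactions = _toy1_reactions()
        reactions.insert(5, _rxn("R5", {"A[c]": -1, "B[c]": 1}, gene="g5"))
        return model_from_dict(_toy_doc(
            reactions,
            ["A[e]", "A[c]", "B[c]", "C[c]", "biomass[c]", "ATP[c]", "ADP[c]"],
            "TOY1R"))
    if variant == "cohort":
        return model_from_dict(_toy_doc(
            _cohort_reactions(),
            ["A[e]", "A[c]", "X[c]", "B[c]", "C[c]", "biomass[c]",
             "ATP[c]", "ADP[c]"],
            "TOYC"))
    if variant == "randomized":
        return _random_gem(seed)
    raise ValidationError(f"unknown toy variant {variant!r}")


def toy_tasks(model: MetabolicModel) -> list[MetabolicTask]:
    """The toy functionality catalog: synthesize biomass from the carbon source."""
    source = next(m for m in model.metabolite_ids if m.endswith("[e]"))
    return [MetabolicTask(
        task_id="biomass_from_source",
        allowed_inputs={source: 10.0},
        required_outputs={"biomass[c]": 0.1},
        description=f"produce biomass from {source} alone")]


@dataclass
class CohortSpec:
    """Conditions for the planted synthetic cohort.

    Cancer samples silence the bypass gene(s) (median FPKM far below the
    no-expression threshold of 1), which makes the planted route essential in
    cancer contexts only.  All other genes are highly expressed in both
    groups, with medians two bins above the lowest expression threshold so
    log-normal noise cannot flip any bin that matters.
    """

    n_cancer: int = 5
    n_noncancer: int = 5
    seed: int = 0
    silenced_in_cancer: tuple[str, ...] = ("g5",)
    expressed_median: float = 100.0
    silenced_median: float = 0.05
    sigma: float = 0.3


def generate_expression_cohort(spec: CohortSpec,
                               model: MetabolicModel) -> ExpressionMatrix:
    """Seeded log-normal FPKM cohort with group-specific silencing."""
    missing = set(spec.silenced_in_cancer) - set(model.gene_ids)
    if missing:
        raise ValidationError(
            f"silenced gene(s) not in model: {sorted(missing)}")
    rng = np.random.default_rng(spec.seed)
    samples = [f"cancer_{i+1}" for i in range(spec.n_cancer)] + \
              [f"normal_{i+1}" for i in range(spec.n_noncancer)]
    group_of = {s: ("cancer" if s.startswith("cancer") else "noncancer")
                for s in samples}
    genes = list(model.gene_ids)
    values = np.empty((len(genes), len(samples)))
    for gi, gene in enumerate(genes):
        for si, sample in enumerate(samples):
            silenced = (group_of[sample] == "cancer"
                        and gene in spec.silenced_in_cancer)
            median = spec.silenced_median if silenced else spec.expressed_median
            values[gi, si] = median * np.exp(rng.normal(0.0, spec.sigma))
    return ExpressionMatrix(gene_ids=genes, sample_ids=samples,
                            values=values, group_of=group_of)


def generate_random_digraph(n: int, p: float, seed: int = 0) -> DirectedNetwork:
    """Erdos-Renyi G(n, p) digraph with string node ids, no self-loops."""
    if not 0 <= p <= 1:
        raise ValidationError("p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = [f"n{i:03d}" for i in range(n)]
    edges = [(nodes[i], nodes[j])
             for i in range(n) for j in range(n)
             if i != j and rng.random() < p]
    return network_from_edges(edges, nodes=nodes, kind="generic")
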