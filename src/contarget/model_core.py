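"""Constraint-based metabolic model core: data structures, I/O, FBA, task checks.

A :class:`MetabolicModel` is the stoichiometric substrate of every downstream
screen.  Conventions follow the constraint-based modeling field: the
stoichiometric matrix ``S`` is metabolites x reactions, a negative entry
``s_ij <= -1`` marks metabolite *i* as a reactant (substrate) of reaction *j*
and a positive entry marks it as a product; the binary ``rev`` vector flags
reversible reactions (1) vs irreversible (0).  Currency metabolites (ATP,
NADH, H2O, ...) are carried by the model and participate in flux balance, but
are excluded when association networks are derived from it.

Gene-protein-reaction (GPR) rules are stored as OR-of-ANDs: a list of
isozymes, each isozyme a set of genes that must all be present (a complex).
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .errors import ConsistencyError, FormatError, ValidationError

#: Base names treated as currency metabolites unless a model overrides them.
DEFAULT_CURRENCY = (
    "ATP", "ADP", "AMP", "NAD+", "NADH", "NADP+", "NADPH",
    "FAD", "FADH2", "H2O", "H+", "Pi", "PPi", "CO2", "O2", "CoA",
)

#: Finite cap used in place of an infinite flux bound so every LP is bounded.
BIG_BOUND = 1000.0

_COMPARTMENT_RE = re.compile(r"^(?P<base>.+?)\[(?P<comp>[^\[\]]+)\]$")


def split_compartment(metabolite_id: str) -> tuple[str, str | None]:
    """Split ``"glc[c]"`` into ``("glc", "c")``; ids without a suffix get ``None``."""
    m = _COMPARTMENT_RE.match(metabolite_id)
    if m is None:
        return metabolite_id, None
    return m.group("base"), m.group("comp")


@dataclass
class MetabolicModel:
    """A genome-scale (or toy-scale) metabolic model.

    Parameters mirror the standard stoichiometric formalism; see module
    docstring for sign conventions.  ``gpr`` maps reaction id to a list of
    gene sets (isozymes OR, complex members AND); reactions absent from the
    map (or mapped to an empty list) are spontaneous / non-enzymatic.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    rev: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    gpr: dict[str, list[frozenset[str]]]
    gene_ids: list[str]
    currency_ids: list[str]
    objective_id: str
    name: str = "model"
    base_metabolite_of: dict[str, str] = field(default_factory=dict)

    # ---- derived indices -------------------------------------------------
    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.rev = np.asarray(self.rev, dtype=int)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        if not self.base_metabolite_of:
            self.base_metabolite_of = {
                m: split_compartment(m)[0] for m in self.metabolite_ids
            }
        self._met_index = {m: i for i, m in enumerate(self.metabolite_ids)}
        self._rxn_index = {r: j for j, r in enumerate(self.reaction_ids)}
        self.validate()

    def validate(self) -> None:
        m, n = self.S.shape
        if len(self.metabolite_ids) != m or len(self.reaction_ids) != n:
            raise ValidationError(
                f"S is {m}x{n} but model lists {len(self.metabolite_ids)} "
                f"metabolites and {len(self.reaction_ids)} reactions"
            )
        for label, ids in (("metabolite", self.metabolite_ids),
                           ("reaction", self.reaction_ids),
                           ("gene", self.gene_ids)):
            dupes = {x for x in ids if ids.count(x) > 1} if len(set(ids)) != len(ids) else set()
            if dupes:
                raise ValidationError(f"duplicate {label} id(s): {sorted(dupes)}")
        if self.rev.shape != (n,) or self.lb.shape != (n,) or self.ub.shape != (n,):
            raise ValidationError("rev/lb/ub must each have one entry per reaction")
        if np.any(self.lb > self.ub):
            raise ValidationError("lb > ub for some reaction")
        irrev_neg = (self.rev == 0) & (self.lb < 0)
        if np.any(irrev_neg):
            bad = [self.reaction_ids[j] for j in np.where(irrev_neg)[0]]
            raise ValidationError(f"irreversible reaction(s) with lb < 0: {bad}")
        zero_cols = np.where(~np.any(self.S != 0, axis=0))[0]
        if zero_cols.size:
            bad = [self.reaction_ids[j] for j in zero_cols]
            raise ValidationError(f"reaction(s) touch no metabolite: {bad}")
        genes = set(self.gene_ids)
        for rid, isozymes in self.gpr.items():
            if rid not in self._rxn_index:
                raise ValidationError(f"GPR references unknown reaction {rid!r}")
            for complex_ in isozymes:
                unknown = set(complex_) - genes
                if unknown:
                    raise ValidationError(
                        f"GPR of {rid!r} references unknown gene(s) {sorted(unknown)}"
                    )
        mets = set(self.metabolite_ids)
        unknown_curr = set(self.currency_ids) - mets
        if unknown_curr:
            raise ValidationError(f"currency id(s) not in model: {sorted(unknown_curr)}")
        if self.objective_id not in self._rxn_index:
            raise ValidationError(f"objective {self.objective_id!r} not a reaction")

    # ---- convenience accessors ------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def metabolite_index(self, metabolite_id: str) -> int:
        try:
            return self._met_index[metabolite_id]
        except KeyError:
            raise ValidationError(f"unknown metabolite {metabolite_id!r}") from None

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self._rxn_index[reaction_id]
        except KeyError:
            raise ValidationError(f"unknown reaction {reaction_id!r}") from None

    def is_exchange(self, reaction_id: str) -> bool:
        """A reaction touching exactly one metabolite (system boundary)."""
        j = self.reaction_index(reaction_id)
        return int(np.count_nonzero(self.S[:, j])) == 1

    @property
    def exchange_ids(self) -> list[str]:
        return [r for r in self.reaction_ids if self.is_exchange(r)]

    def genes_of(self, reaction_id: str) -> set[str]:
        return set().union(*self.gpr.get(reaction_id, []), set())

    def reactions_of_gene(self, gene: str) -> list[str]:
        return [r for r in self.reaction_ids if gene in self.genes_of(r)]

    def substrate_reactions(self, base_name: str) -> set[str]:
        """Reactions in which any compartment instance of ``base_name`` is consumed.

        For irreversible reactions only the negative (reactant) side counts;
        a reversible reaction consumes on either side, so any nonzero entry
        counts.
        """
        rows = [i for i, m in enumerate(self.metabolite_ids)
                if self.base_metabolite_of[m] == base_name]
        hit: set[str] = set()
        for j, rid in enumerate(self.reaction_ids):
            for i in rows:
                s = self.S[i, j]
                if s < 0 or (s != 0 and self.rev[j] == 1):
                    hit.add(rid)
                    break
        return hit

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)


@dataclass(frozen=True)
class MetabolicTask:
    """One functionality check: can the model make the outputs from the inputs?

    Evaluated by LP feasibility with all boundary exchanges closed except the
    allowed inputs, and temporary sinks demanding each required output.
    """

    task_id: str
    allowed_inputs: Mapping[str, float]
    required_outputs: Mapping[str, float]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.required_outputs:
            raise ValidationError(f"task {self.task_id!r} has no required outputs")
        for met, v in self.allowed_inputs.items():
            if v < 0:
                raise ValidationError(f"task {self.task_id!r}: negative uptake for {met}")
        for met, v in self.required_outputs.items():
            if v <= 0:
                raise ValidationError(f"task {self.task_id!r}: non-positive demand for {met}")


@dataclass
class FluxResult:
    """Outcome of one flux balance LP."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: np.ndarray | None


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def _gpr_from_json(raw: object, rid: str) -> list[frozenset[str]]:
    if raw in (None, [], ""):
        return []
    if not isinstance(raw, list):
        raise FormatError(f"reaction {rid!r}: gpr must be a list of gene lists")
    out = []
    for iso in raw:
        if isinstance(iso, str):
            iso = [iso]
        if not isinstance(iso, list) or not all(isinstance(g, str) for g in iso):
            raise FormatError(f"reaction {rid!r}: malformed gpr entry {iso!r}")
        out.append(frozenset(iso))
    return out


def model_to_dict(model: MetabolicModel) -> dict:
    """Serialize to the native JSON document structure."""
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        stoich = {model.metabolite_ids[i]: float(model.S[i, j])
                  for i in np.where(model.S[:, j] != 0)[0]}
        reactions.append({
            "id": rid,
            "stoichiometry": stoich,
            "rev": int(model.rev[j]),
            "lb": float(model.lb[j]),
            "ub": float(model.ub[j]),
            "gpr": [sorted(c) for c in model.gpr.get(rid, [])],
        })
    return {
        "name": model.name,
        "metabolites": list(model.metabolite_ids),
        "reactions": reactions,
        "genes": list(model.gene_ids),
        "currency": list(model.currency_ids),
        "objective": model.objective_id,
    }


def model_from_dict(doc: Mapping) -> MetabolicModel:
    try:
        met_ids = list(doc["metabolites"])
        rxns = list(doc["reactions"])
        objective = doc["objective"]
    except KeyError as exc:
        raise FormatError(f"model document missing key {exc}") from exc
    rxn_ids = [r["id"] for r in rxns]
    met_index = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    rev = np.zeros(len(rxn_ids), dtype=int)
    lb = np.zeros(len(rxn_ids))
    ub = np.zeros(len(rxn_ids))
    gpr: dict[str, list[frozenset[str]]] = {}
    for j, r in enumerate(rxns):
        rid = r["id"]
        for met, coef in r.get("stoichiometry", {}).items():
            if met not in met_index:
                raise FormatError(f"reaction {rid!r} references unknown metabolite {met!r}")
            S[met_index[met], j] = float(coef)
        rev[j] = int(r.get("rev", 0))
        lb[j] = float(r.get("lb", -BIG_BOUND if rev[j] else 0.0))
        ub[j] = float(r.get("ub", BIG_BOUND))
        rules = _gpr_from_json(r.get("gpr"), rid)
        if rules:
            gpr[rid] = rules
    genes = doc.get("genes")
    if genes is None:
        genes = sorted(set().union(*[set().union(*v, set()) for v in gpr.values()], set()))
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S, rev=rev, lb=lb, ub=ub,
        gpr=gpr,
        gene_ids=list(genes),
        currency_ids=list(doc.get("currency", [])),
        objective_id=objective,
        name=doc.get("name", "model"),
    )


def write_model(model: MetabolicModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=True))


def _load_tsv_model(path: Path) -> MetabolicModel:
    """TSV dialect: a directory (or prefix) with metabolites/reactions/stoichiometry tables."""
    import pandas as pd

    base = Path(path)
    if base.is_dir():
        met_p, rxn_p, sto_p = (base / "metabolites.tsv", base / "reactions.tsv",
                               base / "stoichiometry.tsv")
    else:
        raise FormatError("TSV dialect expects a directory holding "
                          "metabolites.tsv, reactions.tsv, stoichiometry.tsv")
    try:
        mets = pd.read_csv(met_p, sep="\t")
        rxns = pd.read_csv(rxn_p, sep="\t")
        sto = pd.read_csv(sto_p, sep="\t")
    except Exception as exc:  # noqa: BLE001 - re-tag any parse failure
        raise FormatError(f"cannot parse TSV model under {base}: {exc}") from exc
    doc_rxns = []
    for _, row in rxns.iterrows():
        rid = str(row["id"])
        block = sto[sto["reaction"] == rid]
        gpr_raw = row.get("gpr", "")
        gpr = []
        if isinstance(gpr_raw, str) and gpr_raw.strip():
            gpr = [iso.split("&") for iso in gpr_raw.split("|")]
        doc_rxns.append({
            "id": rid,
            "stoichiometry": {str(m): float(c)
                              for m, c in zip(block["metabolite"], block["coefficient"])},
            "rev": int(row["rev"]), "lb": float(row["lb"]), "ub": float(row["ub"]),
            "gpr": gpr,
        })
    currency = list(mets.loc[mets.get("currency", 0) == 1, "id"].astype(str)) \
        if "currency" in mets.columns else []
    obj = rxns.loc[rxns.get("objective", 0) == 1, "id"]
    if len(obj) != 1:
        raise FormatError("TSV reactions table must flag exactly one objective reaction")
    return model_from_dict({
        "metabolites": list(mets["id"].astype(str)),
        "reactions": doc_rxns,
        "currency": currency,
        "objective": str(obj.iloc[0]),
    })


def load_model(path: str | Path, format: str = "json") -> MetabolicModel:
    """Load a model in the named dialect (``json`` or ``tsv``).

    The ``sbml`` dialect named in some configuration files is not available
    in this build; requesting it raises :class:`FormatError`.
    """
    path = Path(path)
    if format == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
        return model_from_dict(doc)
    if format == "tsv":
        return _load_tsv_model(path)
    if format == "sbml":
        raise FormatError("SBML import is not available in this build; "
                          "convert to the native JSON dialect instead")
    raise FormatError(f"unknown model format {format!r}")


def load_tasks(path: str | Path) -> list[MetabolicTask]:
    """Load a JSON list of metabolic task records."""
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON: {exc.msg}") from exc
    if not isinstance(raw, list):
        raise FormatError("task file must hold a JSON list")
    return [MetabolicTask(
        task_id=t["task_id"],
        allowed_inputs=dict(t.get("allowed_inputs", {})),
        required_outputs=dict(t["required_outputs"]),
        description=t.get("description", ""),
    ) for t in raw]


def write_tasks(tasks: Sequence[MetabolicTask], path: str | Path) -> None:
    Path(path).write_text(json.dumps([{
        "task_id": t.task_id,
        "allowed_inputs": dict(t.allowed_inputs),
        "required_outputs": dict(t.required_outputs),
        "description": t.description,
    } for t in tasks], indent=1))


# --------------------------------------------------------------------------
# Flux balance analysis
# --------------------------------------------------------------------------

def fba(model: MetabolicModel, objective: str | None = None,
        sense: str = "max") -> FluxResult:
    """Solve max/min c.v subject to S.v = 0, lb <= v <= ub (HiGHS).

    Only the optimum value is consumed downstream, so ties between alternate
    optimal flux distributions are irrelevant.
    """
    if sense not in ("max", "min"):
        raise ValidationError(f"sense must be 'max' or 'min', got {sense!r}")
    j = model.reaction_index(objective or model.objective_id)
    c = np.zeros(model.n_reactions)
    c[j] = -1.0 if sense == "max" else 1.0
    res = linprog(c, A_eq=model.S, b_eq=np.zeros(model.n_metabolites),
                  bounds=list(zip(model.lb, model.ub)), method="highs")
    if res.status == 2:
        return FluxResult("infeasible", None, None)
    if res.status == 3:
        return FluxResult("unbounded", None, None)
    if res.status != 0:
        raise ConsistencyError(f"LP solver failure: {res.message}")  # pragma: no cover
    value = float(-res.fun if sense == "max" else res.fun)
    return FluxResult("optimal", value, np.asarray(res.x))


def check_task(model: MetabolicModel, task: MetabolicTask) -> bool:
    """True iff the task's demands are feasible with only its inputs open.

    All boundary exchanges are closed, then each allowed input is opened as an
    uptake up to its cap; each required output is modeled as a temporary sink
    reaction with a lower bound at the minimum production.  The model is never
    mutated (a bounded copy is solved).
    """
    for met in list(task.allowed_inputs) + list(task.required_outputs):
        model.metabolite_index(met)  # raises ValidationError if unresolvable

    lb = model.lb.copy()
    ub = model.ub.copy()
    for rid in model.exchange_ids:
        j = model.reaction_index(rid)
        lb[j] = 0.0
        ub[j] = 0.0
    # Open uptakes: exchange written as "met ->" (coefficient -1) takes up the
    # metabolite at negative flux; "-> met" at positive flux.
    for met, cap in task.allowed_inputs.items():
        i = model.metabolite_index(met)
        for rid in model.exchange_ids:
            j = model.reaction_index(rid)
            s = model.S[i, j]
            if s == 0:
                continue
            if s < 0:
                lb[j] = -float(cap)
            else:
                ub[j] = float(cap)
    m, n = model.S.shape
    n_sinks = len(task.required_outputs)
    A = np.hstack([model.S, np.zeros((m, n_sinks))])
    sink_lb, sink_ub = [], []
    for k, (met, demand) in enumerate(sorted(task.required_outputs.items())):
        A[model.metabolite_index(met), n + k] = -1.0  # sink consumes the product
        sink_lb.append(float(demand))
        sink_ub.append(BIG_BOUND)
    bounds = list(zip(lb, ub)) + list(zip(sink_lb, sink_ub))
    res = linprog(np.zeros(n + n_sinks), A_eq=A, b_eq=np.zeros(m),
                  bounds=bounds, method="highs")
    return res.status == 0


def is_viable(model: MetabolicModel, objective: str | None = None,
              tasks: Iterable[MetabolicTask] = (), eps: float = 1e-6) -> bool:
    """Viability = objective optimum strictly above ``eps`` and all tasks pass."""
    if eps <= 0:
        raise ValidationError("eps must be positive")
    opt = fba(model, objective=objective, sense="max")
    if opt.status != "optimal" or opt.objective_value <= eps:
        return False
    return all(check_task(model, t) for t in tasks)


def delete_reactions(model: MetabolicModel, reaction_ids: Iterable[str]) -> MetabolicModel:
    """Return a copy with the listed reactions closed (bounds set to [0, 0]).

    Closure rather than structural removal keeps matrix indices, derived
    networks, and GPR maps aligned across modules.
    """
    out = model.copy()
    for rid in reaction_ids:
        j = out.reaction_index(rid)
        out.lb[j] = 0.0
        out.ub[j] = 0.0
    return out
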