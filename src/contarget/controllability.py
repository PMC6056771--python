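"""Exact network controllability: minimum driver sets, dispensability, filters.

For a directed network with adjacency A (A[target, source]) under linear
dynamics x' = Ax + Bu, the exact-controllability framework states that the
minimum number of driver nodes equals the maximum geometric multiplicity over
the eigenvalues of A:

    N_D = max_lambda mu(lambda),   mu(lambda) = N - rank(lambda I - A).

The eigenvalue attaining the maximum is written lambda_M.  A concrete minimum
driver set (MDS) is read off the row reduction of (lambda_M I - A): rows that
are linearly dependent on earlier rows (or zero) mark nodes that must receive
independent control signals.  Every returned driver set is certified against
the Popov-Belevitch-Hautus (PBH) rank condition,

    rank([lambda I - A | B]) = N  for every eigenvalue lambda,

where B's columns are the indicator vectors of the driver nodes.

Node dispensability is classified by recomputing N_D after removing each node
(row and column): removal that increases N_D marks the node indispensable,
a decrease marks it dispensable, no change neutral.  Driver-set members and
indispensable nodes together form the *controlling nodes* consumed by the
target-prioritization stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .errors import ConsistencyError, ValidationError
from .network_build import DirectedNetwork

#: Relative tolerance for grouping numerically coincident eigenvalues.
EIG_GROUP_RTOL = 1e-8

#: Factor for the SVD rank tolerance: tol = N * max_singular_value * RANK_RTOL.
RANK_RTOL = 1e-10


@dataclass
class ControllabilityResult:
    n_d: int
    lambda_m: complex
    mu: list[tuple[complex, int]]
    driver_set: list[str] | None = None
    #: one entry per input signal: the node(s) that signal attaches to.  The
    #: first node of signal j is driver_set[j]; extra nodes appear only when
    #: other degenerate eigenvalues need coverage by the same signals.
    input_attachments: list[list[str]] | None = None


@dataclass
class DispensabilityClass:
    n_d: int
    classes: dict[str, str]          # node -> indispensable | neutral | dispensable
    n_d_after: dict[str, int]


def _rank(M: np.ndarray) -> int:
    if M.size == 0:
        return 0
    sv = np.linalg.svd(M, compute_uv=False)
    if sv.size == 0 or sv[0] == 0:
        return 0
    tol = max(M.shape) * sv[0] * RANK_RTOL
    return int(np.sum(sv > tol))


def _candidate_eigenvalues(eigs: np.ndarray) -> list[complex]:
    """Candidate eigenvalues at which to probe the geometric multiplicity.

    Numerically computed eigenvalues of a defective matrix scatter around the
    true value at radius ~eps^(1/k) for a Jordan block of size k, which no
    fixed clustering tolerance can reunite reliably.  Instead of trusting the
    clusters alone, every cluster representative is complemented by its
    nearest Gaussian-integer snap, and 0 is always probed (unweighted
    adjacency spectra concentrate their degenerate eigenvalues on integers,
    most often 0 and -1).  Probing a value that is not an eigenvalue is
    harmless: the resolvent matrix has full rank there, so the measured
    multiplicity is zero.
    """
    scale = 1.0 + (np.abs(eigs).max() if eigs.size else 0.0)
    tol = EIG_GROUP_RTOL * scale
    clusters: list[list[complex]] = []
    for lam in sorted(eigs, key=lambda z: (z.real, z.imag)):
        for cluster in clusters:
            if any(abs(lam - member) <= tol for member in cluster):
                cluster.append(lam)
                break
        else:
            clusters.append([lam])
    candidates: list[complex] = [0j]
    for cluster in clusters:
        rep = complex(np.mean(cluster))
        candidates.append(rep)
        candidates.append(complex(round(rep.real), round(rep.imag)))
    deduped: list[complex] = []
    for lam in candidates:
        if not any(abs(lam - seen) <= tol for seen in deduped):
            deduped.append(lam)
    return deduped


def exact_controllability(net: DirectedNetwork) -> ControllabilityResult:
    """Compute N_D and lambda_M from the spectrum of the adjacency matrix.

    Ties between eigenvalue groups sharing the maximum multiplicity are broken
    deterministically: lambda = 0 is preferred, then smallest modulus, then
    smallest complex argument.
    """
    if net.n == 0:
        raise ValidationError("empty network")
    A = net.adjacency()
    eigs = np.linalg.eigvals(A)
    candidates = _candidate_eigenvalues(eigs)
    scale = 1.0 + float(np.abs(eigs).max())
    zero_tol = EIG_GROUP_RTOL * scale
    mu: list[tuple[complex, int]] = []
    for lam in candidates:
        M = lam * np.eye(net.n, dtype=complex) - A
        m = net.n - _rank(M)
        if m >= 1:  # spurious probes (non-eigenvalues) have full rank
            mu.append((lam, m))
    n_d = max(m for _, m in mu)

    def tie_key(item: tuple[complex, int]):
        lam, _ = item
        is_zero = abs(lam) <= zero_tol
        return (not is_zero, abs(lam), abs(np.angle(lam)), np.angle(lam))

    lambda_m = min((item for item in mu if item[1] == n_d), key=tie_key)[0]
    if abs(lambda_m) <= zero_tol:
        lambda_m = 0j
    return ControllabilityResult(n_d=n_d, lambda_m=lambda_m, mu=mu)


def _dependent_rows(A: np.ndarray, lam: complex,
                    node_ids: Sequence[str]) -> list[str]:
    """Nodes whose rows of (lam*I - A) depend on earlier independent rows."""
    n = len(node_ids)
    M = lam * np.eye(n, dtype=complex) - A
    sv = np.linalg.svd(M, compute_uv=False)
    sv_max = float(sv[0]) if sv.size else 0.0
    tol = max(n * sv_max * RANK_RTOL, 1e-12)
    basis: list[np.ndarray] = []
    dependent: list[str] = []
    for i, node in enumerate(node_ids):
        resid = M[i, :].astype(complex)
        for q in basis:
            resid -= np.vdot(q, resid) * q
        norm = float(np.linalg.norm(resid))
        if norm > tol:
            basis.append(resid / norm)
        else:
            dependent.append(node)
    return dependent


def _pbh_rank_ok(A: np.ndarray, lam: complex, B: np.ndarray) -> bool:
    n = A.shape[0]
    M = np.hstack([lam * np.eye(n, dtype=complex) - A, B.astype(complex)])
    return _rank(M) == n


def _build_input_matrix(net: DirectedNetwork, res: ControllabilityResult,
                        ) -> tuple[np.ndarray, list[list[str]]]:
    """Input matrix B with N_D signal columns satisfying PBH at every eigenvalue.

    Signal j first attaches to driver_set[j].  Where another eigenvalue group
    is left uncovered — e.g. degenerate eigenvalues living on disjoint
    components — its own canonical dependent-row nodes are attached to the
    existing signals round-robin, so the number of independent inputs stays
    N_D.  If plain unit attachment weights conspire to cancel, deterministic
    non-uniform weights are used for the supplementary attachments.
    """
    A = net.adjacency()
    index = {n: i for i, n in enumerate(net.node_ids)}
    drivers = list(res.driver_set or [])
    n_cols = max(len(drivers), 1)
    B = np.zeros((net.n, n_cols))
    attachments: list[list[str]] = [[] for _ in range(n_cols)]
    for k, d in enumerate(drivers):
        B[index[d], k] = 1.0
        attachments[k].append(d)
    eigenvalues = sorted((lam for lam, _ in res.mu),
                         key=lambda z: (z.real, z.imag))
    for lam in eigenvalues:
        if _pbh_rank_ok(A, lam, B):
            continue
        extra = _dependent_rows(A, lam, net.node_ids)
        for k, node in enumerate(extra):
            col = k % n_cols
            if node not in attachments[col]:
                attachments[col].append(node)
                B[index[node], col] = 1.0
        if _pbh_rank_ok(A, lam, B):
            continue
        # last resort: break accidental cancellations with fixed weights
        for col, nodes in enumerate(attachments):
            for node in nodes[1:]:
                i = index[node]
                B[i, col] = 1.0 + ((3 * i + 5 * col) % 11) / 13.0
        if not _pbh_rank_ok(A, lam, B):
            raise ConsistencyError(
                f"PBH certificate failed at eigenvalue {lam} with driver "
                f"set {drivers}; rank tolerance breakdown")
    # adding attachments for a later eigenvalue could in principle disturb an
    # earlier one; re-verify the full spectrum, with weighted attachments as
    # the final fallback
    if not all(_pbh_rank_ok(A, lam, B) for lam in eigenvalues):
        for col, nodes in enumerate(attachments):
            for node in nodes[1:]:
                i = index[node]
                B[i, col] = 1.0 + ((3 * i + 5 * col) % 11) / 13.0
        failed = [lam for lam in eigenvalues if not _pbh_rank_ok(A, lam, B)]
        if failed:
            raise ConsistencyError(
                f"PBH certificate failed at eigenvalue(s) {failed} with "
                f"driver set {drivers}")
    return B, attachments


def identify_mds(net: DirectedNetwork) -> ControllabilityResult:
    """Canonical minimum driver set from row reduction of (lambda_M I - A).

    Rows are processed in the recorded node order; a node whose row is
    linearly dependent on the independent rows seen so far (or zero) joins the
    driver set.  An input matrix built on the set is certified with the PBH
    condition at every eigenvalue before return.
    """
    res = exact_controllability(net)
    A = net.adjacency()
    drivers = _dependent_rows(A, res.lambda_m, net.node_ids)
    if len(drivers) != res.n_d:
        raise ConsistencyError(
            f"driver count {len(drivers)} != N_D {res.n_d}; "
            "rank tolerance breakdown")
    res.driver_set = drivers
    B, attachments = _build_input_matrix(net, res)
    res.input_attachments = attachments
    for lam, _ in res.mu:
        if not _pbh_rank_ok(A, lam, B):  # pragma: no cover - certified above
            raise ConsistencyError(f"PBH certificate failed at {lam}")
    return res


def verify_pbh(net: DirectedNetwork, drivers: Sequence[str],
               strict: bool = True) -> bool:
    """PBH check for a candidate driver set (True = controllable).

    With ``strict=True`` each input attaches only to its driver node
    (indicator columns); with ``strict=False`` supplementary attachments are
    allowed as in :func:`identify_mds`.
    """
    res = exact_controllability(net)
    A = net.adjacency()
    if strict:
        index = {n: i for i, n in enumerate(net.node_ids)}
        B = np.zeros((net.n, max(len(drivers), 1)))
        for k, d in enumerate(drivers):
            B[index[d], k] = 1.0
        return all(_pbh_rank_ok(A, lam, B) for lam, _ in res.mu)
    res.driver_set = list(drivers)
    try:
        _build_input_matrix(net, res)
    except ConsistencyError:
        return False
    return True


def classify_dispensability(net: DirectedNetwork) -> DispensabilityClass:
    """Per-node class from the change in N_D upon node removal.

    A removal leaving a single node uses the convention N_D = 1 (one driver
    controls one node).
    """
    if net.n < 2:
        raise ValidationError("dispensability needs at least 2 nodes")
    base = exact_controllability(net).n_d
    classes: dict[str, str] = {}
    after: dict[str, int] = {}
    for node in net.node_ids:
        sub = net.remove_node(node)
        nd = 1 if sub.n == 1 else exact_controllability(sub).n_d
        after[node] = nd
        if nd > base:
            classes[node] = "indispensable"
        elif nd < base:
            classes[node] = "dispensable"
        else:
            classes[node] = "neutral"
    return DispensabilityClass(n_d=base, classes=classes, n_d_after=after)


def controlling_nodes(net: DirectedNetwork) -> dict[str, str]:
    """Driver-set members and indispensable nodes, tagged by origin.

    Returns node -> origin in {"MDS", "indispensable", "both"}.
    """
    mds = set(identify_mds(net).driver_set or [])
    if net.n >= 2:
        indis = {n for n, c in classify_dispensability(net).classes.items()
                 if c == "indispensable"}
    else:
        indis = set()
    out: dict[str, str] = {}
    for node in sorted(mds | indis):
        if node in mds and node in indis:
            out[node] = "both"
        elif node in mds:
            out[node] = "MDS"
        else:
            out[node] = "indispensable"
    return out


def _merge_origins(tags: set[str]) -> str:
    if "both" in tags or ("MDS" in tags and "indispensable" in tags):
        return "both"
    return next(iter(tags))


def cancer_specific_from_maps(cancer_maps: Sequence[Mapping[str, str]],
                              noncancer_maps: Sequence[Mapping[str, str]],
                              min_cancer: int = 1) -> dict[str, dict]:
    """Cancer-specificity filter over precomputed per-network controlling maps.

    Each map is node -> origin tag for one network.  A node survives iff it is
    controlling in at least ``min_cancer`` cancer maps and in zero non-cancer
    maps; the result carries the per-node count of cancer networks (the
    "number of patients" annotation) and the merged origin tag.
    """
    if min_cancer < 1:
        raise ValidationError("min_cancer must be >= 1")
    counts: dict[str, int] = {}
    origins: dict[str, set[str]] = {}
    for cmap in cancer_maps:
        for node, origin in cmap.items():
            counts[node] = counts.get(node, 0) + 1
            origins.setdefault(node, set()).add(origin)
    excluded: set[str] = set()
    for nmap in noncancer_maps:
        excluded |= set(nmap)
    return {node: {"count": counts[node], "origin": _merge_origins(origins[node])}
            for node in sorted(counts)
            if counts[node] >= min_cancer and node not in excluded}


def cancer_specific_controlling(
        cancer_nets: Sequence[DirectedNetwork],
        noncancer_nets: Sequence[DirectedNetwork],
        min_cancer: int = 1,
        controlling_fn: Callable[[DirectedNetwork], Mapping[str, str]] = controlling_nodes,
) -> dict[str, dict]:
    """Nodes controlling in >= min_cancer cancer networks and in no non-cancer one.

    Returns node -> {"count": number of cancer networks where controlling,
    "origin": merged origin tag}.  Origins merge across networks: a node that
    is a driver somewhere and indispensable elsewhere is tagged "both".
    """
    return cancer_specific_from_maps(
        [controlling_fn(net) for net in cancer_nets],
        [controlling_fn(net) for net in noncancer_nets],
        min_cancer=min_cancer)


def gene_level_controlling(rrn_controlling: Mapping[str, dict] | Iterable[str],
                           model) -> dict[str, dict]:
    """Lift controlling reaction nodes to genes via the model's gene rules.

    A gene is controlling iff at least one reaction it catalyzes is a
    controlling RRN node; it inherits the maximum patient count over those
    reactions and their merged origin tag.
    """
    if not isinstance(rrn_controlling, Mapping):
        rrn_controlling = {rid: {"count": 1, "origin": "MDS"}
                           for rid in rrn_controlling}
    out: dict[str, dict] = {}
    for gene in model.gene_ids:
        hits = [rrn_controlling[rid] for rid in model.reactions_of_gene(gene)
                if rid in rrn_controlling]
        if not hits:
            continue
        tags = {h["origin"] for h in hits}
        if "both" in tags or ("MDS" in tags and "indispensable" in tags):
            origin = "both"
        else:
            origin = next(iter(tags))
        out[gene] = {"count": max(h["count"] for h in hits), "origin": origin}
    return out
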