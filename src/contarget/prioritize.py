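"""Intersect screen hits with controlling nodes and rank by centrality.

The final table contains only anticancer non-toxic *controlling* targets.
Indispensable-origin targets are ranked by (aggregated) total degree,
driver-set (MDS) targets by normalized directed betweenness; the
indispensable block precedes the MDS block, with "both"-origin targets
joining the indispensable block.  Centralities are aggregated (mean by
default) over the cancer networks in which the node exists.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .network_build import DirectedNetwork
from .target_screen import ScreenResult


def compute_centralities(net: DirectedNetwork) -> dict[str, tuple[int, float]]:
    """node -> (total degree, normalized directed betweenness).

    Betweenness uses the directed shortest-path definition normalized by
    (N-1)(N-2), so scores are comparable across networks of different sizes.
    """
    if net.n == 0:
        raise ValidationError("empty network")
    g = net.to_networkx()
    degree = net.total_degree()
    btw = nx.betweenness_centrality(g, normalized=True)
    return {n: (degree[n], float(btw[n])) for n in net.node_ids}


def intersect_targets(screen: Sequence[ScreenResult],
                      controlling: Mapping[str, dict]) -> list[dict]:
    """Targets that both passed the screen and are cancer-specific controlling.

    ``controlling`` maps target id -> {"count", "origin"} (metabolite ids are
    base names; gene ids are gene names).  Returns candidate records carrying
    both annotations.
    """
    out = []
    for res in screen:
        info = controlling.get(res.target_id)
        if info is None:
            continue
        out.append({
            "target_id": res.target_id,
            "target_type": res.target_type,
            "origin": info["origin"],
            "n_cancer_controlling": info["count"],
            "n_cancer_lethal": len(res.lethal_in),
        })
    return out


def aggregate_centrality(node_ids: Sequence[str],
                         centrality_maps: Sequence[Mapping[str, tuple[int, float]]],
                         aggregation: str = "mean") -> dict[str, tuple[float, float]]:
    """Aggregate (degree, betweenness) for each node over the maps containing it."""
    if aggregation not in ("mean", "median"):
        raise ValidationError("aggregation must be 'mean' or 'median'")
    agg = pd.Series.mean if aggregation == "mean" else pd.Series.median
    out = {}
    for node in node_ids:
        degs = pd.Series([m[node][0] for m in centrality_maps if node in m], dtype=float)
        btws = pd.Series([m[node][1] for m in centrality_maps if node in m], dtype=float)
        if len(degs):
            out[node] = (float(agg(degs)), float(agg(btws)))
    return out


def rank_targets(candidates: Sequence[Mapping],
                 centrality_maps: Mapping[str, Sequence[Mapping]],
                 aggregation: str = "mean") -> pd.DataFrame:
    """Build the ranked target table.

    ``centrality_maps`` maps target_type -> list of per-cancer-network
    centrality maps (metabolites are looked up in MMN maps by any compartment
    instance already resolved to base names by the caller; genes in RRN maps
    lifted to gene names by the caller).  Candidates absent from every map are
    dropped with a warning.  Ranking: indispensable/both block sorted by
    aggregated degree (desc), then MDS block by aggregated betweenness (desc);
    ties broken by n_cancer_controlling (desc), then id.
    """
    rows = []
    for cand in candidates:
        maps = centrality_maps.get(cand["target_type"], [])
        agg = aggregate_centrality([cand["target_id"]], maps, aggregation)
        if cand["target_id"] not in agg:
            warnings.warn(f"target {cand['target_id']!r} absent from all "
                          "cancer networks; dropped", stacklevel=2)
            continue
        degree, betweenness = agg[cand["target_id"]]
        rows.append({**cand, "degree": degree, "betweenness": betweenness})
    indis = [r for r in rows if r["origin"] in ("indispensable", "both")]
    mds = [r for r in rows if r["origin"] == "MDS"]
    indis.sort(key=lambda r: (-r["degree"], -r["n_cancer_controlling"],
                              r["target_id"]))
    mds.sort(key=lambda r: (-r["betweenness"], -r["n_cancer_controlling"],
                            r["target_id"]))
    ordered = indis + mds
    for rank, row in enumerate(ordered, start=1):
        row["rank"] = rank
    columns = ["rank", "target_id", "target_type", "origin", "degree",
               "betweenness", "n_cancer_lethal", "n_cancer_controlling"]
    return pd.DataFrame(ordered, columns=columns)
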