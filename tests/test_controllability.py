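"""Exact controllability: driver counts, canonical MDS, dispensability."""

import networkx as nx
import numpy as np
import pytest

from contarget.controllability import (cancer_specific_controlling,
                                       cancer_specific_from_maps,
                                       classify_dispensability,
                                       controlling_nodes,
                                       exact_controllability,
                                       gene_level_controlling, identify_mds,
                                       verify_pbh)
from contarget.errors import ValidationError
from contarget.exact_oracle import exact_nd, exact_nd_network
from contarget.network_build import DirectedNetwork, build_mmn, build_rrn, \
    network_from_edges
from contarget.synthetic_data import generate_random_digraph, generate_toy_gem


def edgeless(n):
    return DirectedNetwork(node_ids=[f"n{i}" for i in range(n)], edges=set())


def directed_path(n):
    return network_from_edges([(f"n{i:02d}", f"n{i+1:02d}")
                               for i in range(n - 1)])


def complete(n):
    ids = [f"n{i}" for i in range(n)]
    return network_from_edges([(a, b) for a in ids for b in ids if a != b])


def undirected_star(n):
    """1 center + n-1 leaves, both edge directions."""
    edges = [("center", f"l{i}") for i in range(1, n)]
    edges += [(v, u) for u, v in edges]
    return network_from_edges(edges)


class TestClosedForms:
    @pytest.mark.parametrize("n", range(2, 11))
    def test_edgeless_needs_all_drivers(self, n):
        res = exact_controllability(edgeless(n))
        assert res.n_d == n and res.lambda_m == 0

    @pytest.mark.parametrize("n", range(2, 11))
    def test_directed_path_needs_one_driver(self, n):
        assert exact_controllability(directed_path(n)).n_d == 1

    @pytest.mark.parametrize("n", range(2, 11))
    def test_complete_graph_needs_all_but_one(self, n):
        res = exact_controllability(complete(n))
        assert res.n_d == n - 1
        if n >= 3:  # at n=2 both simple eigenvalues tie; -1 is degenerate above
            assert res.lambda_m == pytest.approx(-1)

    @pytest.mark.parametrize("n", range(4, 11))
    def test_star_needs_all_but_two(self, n):
        res = exact_controllability(undirected_star(n))
        assert res.n_d == n - 2
        assert res.lambda_m == 0


class TestDriverSets:
    def test_isolated_nodes_all_drivers(self):
        res = identify_mds(edgeless(4))
        assert res.driver_set == [f"n{i}" for i in range(4)]

    def test_path_driver_is_head(self):
        res = identify_mds(directed_path(6))
        assert res.driver_set == ["n00"]

    def test_toy1_mmn_canonical_driver_set(self, toy1):
        net = build_mmn(toy1)
        res = identify_mds(net)
        assert res.n_d == 2
        assert set(res.driver_set) == {"A[e]", "C[c]"}

    @pytest.mark.parametrize("seed", range(12))
    def test_pbh_certificate_on_random_digraphs(self, seed):
        rng = np.random.default_rng(seed)
        net = generate_random_digraph(int(rng.integers(3, 12)),
                                      float(rng.uniform(0.1, 0.5)),
                                      seed=seed)
        res = identify_mds(net)  # raises ConsistencyError on PBH failure
        assert len(res.driver_set) == res.n_d
        assert verify_pbh(net, res.driver_set, strict=False)
        # each input signal is anchored at its driver node
        assert [a[0] for a in res.input_attachments] == res.driver_set

    def test_pbh_rejects_wrong_driver_set(self):
        net = directed_path(3)
        assert verify_pbh(net, ["n02"]) is False
        assert verify_pbh(net, ["n00"]) is True

    def test_empty_network_rejected(self):
        with pytest.raises(ValidationError):
            exact_controllability(DirectedNetwork(node_ids=[], edges=set()))


class TestOracleEquivalence:
    @pytest.mark.parametrize("batch", range(4))
    def test_floating_point_matches_exact_arithmetic(self, batch):
        """SVD-based N_D equals the exact rational-arithmetic value on seeded
        random digraphs spanning sparse to dense regimes."""
        rng = np.random.default_rng(100 + batch)
        for k in range(15):
            n = int(rng.integers(3, 13))
            p = float(rng.uniform(0.05, 0.6))
            net = generate_random_digraph(n, p, seed=batch * 1000 + k)
            assert exact_controllability(net).n_d == exact_nd_network(net)

    def test_oracle_on_known_spectra(self):
        assert exact_nd(np.zeros((4, 4), dtype=int)) == 4
        assert exact_nd_network(complete(5)) == 4
        assert exact_nd_network(undirected_star(6)) == 4


class TestDispensability:
    def test_star_center_indispensable_leaves_dispensable(self):
        disp = classify_dispensability(undirected_star(5))
        assert disp.classes["center"] == "indispensable"
        assert all(disp.classes[f"l{i}"] == "dispensable" for i in range(1, 5))
        assert disp.n_d_after["center"] == 4 and disp.n_d_after["l1"] == 2

    def test_path3_middle_indispensable_head_neutral(self):
        disp = classify_dispensability(directed_path(3))
        assert disp.classes == {"n00": "neutral", "n01": "indispensable",
                                "n02": "neutral"}

    def test_edgeless_all_dispensable(self):
        disp = classify_dispensability(edgeless(5))
        assert set(disp.classes.values()) == {"dispensable"}

    def test_two_node_removal_convention(self):
        # removing either node leaves a single node: one driver by convention
        disp = classify_dispensability(network_from_edges([("a", "b")]))
        assert disp.n_d_after == {"a": 1, "b": 1}

    @pytest.mark.parametrize("seed", range(6))
    def test_classes_partition_nodes(self, seed):
        net = generate_random_digraph(10, 0.25, seed=seed)
        disp = classify_dispensability(net)
        assert set(disp.classes) == set(net.node_ids)
        counts = {c: list(disp.classes.values()).count(c)
                  for c in ("indispensable", "neutral", "dispensable")}
        assert sum(counts.values()) == net.n

    def test_indispensable_nodes_have_higher_mean_degree(self):
        """On scale-free-like networks, hubs tend to be indispensable: the
        pooled mean degree of indispensable nodes exceeds that of dispensable
        ones across seeded replicates."""
        indis_degs, disp_degs = [], []
        for seed in range(8):
            g = nx.scale_free_graph(20, seed=seed)
            net = network_from_edges({(str(u), str(v))
                                      for u, v in g.edges() if u != v})
            deg = net.total_degree()
            classes = classify_dispensability(net).classes
            indis_degs += [deg[n] for n, c in classes.items()
                           if c == "indispensable"]
            disp_degs += [deg[n] for n, c in classes.items()
                          if c == "dispensable"]
        assert indis_degs and disp_degs
        assert np.mean(indis_degs) >= np.mean(disp_degs)


class TestControllingNodes:
    def test_star_union_of_mds_and_indispensable(self):
        tags = controlling_nodes(undirected_star(5))
        assert tags["center"] == "indispensable"
        assert sum(1 for t in tags.values() if t in ("MDS", "both")) == 3

    def test_isolated_all_mds_none_indispensable(self):
        tags = controlling_nodes(edgeless(3))
        assert set(tags.values()) == {"MDS"}
        assert len(tags) == 3

    def test_path3_head_and_middle(self):
        tags = controlling_nodes(directed_path(3))
        assert tags == {"n00": "MDS", "n01": "indispensable"}


class TestCancerSpecificity:
    def test_kept_with_patient_count(self):
        cancer = [{"x": "MDS"}, {"x": "indispensable"}, {"x": "MDS"}]
        noncancer = [{"y": "MDS"}]
        out = cancer_specific_from_maps(cancer, noncancer)
        assert out == {"x": {"count": 3, "origin": "both"}}

    def test_shared_nodes_excluded(self):
        out = cancer_specific_from_maps([{"x": "MDS"}], [{"x": "MDS"}])
        assert out == {}

    def test_empty_cancer_set(self):
        assert cancer_specific_from_maps([], [{"x": "MDS"}]) == {}

    def test_min_cancer_threshold(self):
        cancer = [{"x": "MDS"}, {"y": "MDS"}, {"y": "MDS"}]
        out = cancer_specific_from_maps(cancer, [], min_cancer=2)
        assert set(out) == {"y"}
        with pytest.raises(ValidationError):
            cancer_specific_from_maps(cancer, [], min_cancer=0)

    def test_network_level_wrapper(self):
        net_a = directed_path(3)
        noncancer = network_from_edges([("n00", "n02")])
        out = cancer_specific_controlling([net_a], [noncancer])
        # n00/n01 control the path; n00 also controls (MDS) the non-cancer
        # edge, so only the middle node survives
        assert set(out) == {"n01"}
        assert out["n01"] == {"count": 1, "origin": "indispensable"}


class TestGeneLevel:
    def test_gene_inherits_controlling_reaction(self, toy1):
        rrn_controlling = {"R4": {"count": 3, "origin": "indispensable"}}
        out = gene_level_controlling(rrn_controlling, toy1)
        assert out == {"g4": {"count": 3, "origin": "indispensable"}}

    def test_any_rule_and_max_count(self, toy1):
        model = toy1.copy()
        model.gpr["R3"] = [frozenset({"g4"})]  # g4 now catalyzes R3 and R4
        out = gene_level_controlling(
            {"R3": {"count": 1, "origin": "MDS"},
             "R4": {"count": 5, "origin": "indispensable"}}, model)
        assert out["g4"] == {"count": 5, "origin": "both"}

    def test_gene_without_controlling_reactions_absent(self, toy1):
        assert "g1" not in gene_level_controlling(
            {"R4": {"count": 1, "origin": "MDS"}}, toy1)

    def test_accepts_bare_reaction_set(self, toy1):
        out = gene_level_controlling({"R2"}, toy1)
        assert set(out) == {"g2"}
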