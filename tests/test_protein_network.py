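import itertools
import math

import numpy as np
import pytest
from scipy.stats import hypergeom as scipy_hypergeom

from viroturn import (
    GraphError,
    LineageSpec,
    SortedLibrary,
    SyntheticCommunitySpec,
    build_network,
    cluster_genomes,
    hypergeom_edge,
    mcl,
    simulate,
)
from viroturn.pipeline import call_simulated, network_clusters


def _clique(nodes, weight=1.0):
    return [(u, v, weight) for u, v in itertools.combinations(nodes, 2)]


class TestHypergeomEdge:
    def test_zero_shared_gives_p_one(self):
        assert hypergeom_edge(0, 5, 5, 20) == (1.0, 0.0)

    def test_forced_full_overlap_gives_p_one(self):
        p, w = hypergeom_edge(7, 7, 7, 7)
        assert p == pytest.approx(1.0)
        assert w == pytest.approx(0.0)

    def test_exact_enumeration_example(self):
        # a=3, b=3, M=10, c=2: (C(3,2)C(7,1) + C(3,3)C(7,0)) / C(10,3) = 22/120
        p, _ = hypergeom_edge(2, 3, 3, 10)
        assert p == pytest.approx(22 / 120, abs=1e-12)

    def test_invalid_c_raises(self):
        with pytest.raises(ValueError):
            hypergeom_edge(4, 3, 5, 10)

    def test_matches_exhaustive_enumeration_small_M(self):
        # independent oracle: exact tail from math.comb
        for M in range(1, 13):
            for a in range(M + 1):
                for b in range(M + 1):
                    for c in range(min(a, b) + 1):
                        expected = sum(
                            math.comb(a, k) * math.comb(M - a, b - k)
                            for k in range(c, min(a, b) + 1)
                        ) / math.comb(M, b)
                        p, _ = hypergeom_edge(c, a, b, M)
                        assert abs(p - expected) < 1e-12, (c, a, b, M)

    def test_matches_scipy_tail(self):
        for c, a, b, M in [(3, 10, 12, 40), (1, 4, 4, 100), (8, 20, 9, 60)]:
            p, _ = hypergeom_edge(c, a, b, M)
            assert p == pytest.approx(scipy_hypergeom.sf(c - 1, M, a, b), rel=1e-10)

    def test_weight_capped(self):
        p, w = hypergeom_edge(200, 200, 200, 100000)
        assert p >= 0.0
        assert w <= 300.0


def _reference_mcl(nodes, edges, inflation=2.0, iters=200):
    """Independent plain-python MCL oracle (no shared code with the package)."""
    idx = {n: i for i, n in enumerate(sorted(nodes))}
    n = len(idx)
    m = [[0.0] * n for _ in range(n)]
    for u, v, w in edges:
        m[idx[u]][idx[v]] = w
        m[idx[v]][idx[u]] = w
    for j in range(n):
        col_max = max(m[i][j] for i in range(n))
        m[j][j] = col_max if col_max > 0 else 1.0
    for j in range(n):
        s = sum(m[i][j] for i in range(n))
        for i in range(n):
            m[i][j] /= s
    for _ in range(iters):
        sq = [[sum(m[i][k] * m[k][j] for k in range(n)) for j in range(n)] for i in range(n)]
        for j in range(n):
            col = [sq[i][j] ** inflation for i in range(n)]
            s = sum(col)
            for i in range(n):
                sq[i][j] = col[i] / s if s else 0.0
        if max(abs(sq[i][j] - m[i][j]) for i in range(n) for j in range(n)) < 1e-8:
            m = sq
            break
        m = sq
    # clusters = components of the nonzero structure
    names = sorted(nodes)
    adj = {u: set() for u in names}
    for i, u in enumerate(names):
        for j, v in enumerate(names):
            if i != j and (m[i][j] > 1e-6 or m[j][i] > 1e-6):
                adj[u].add(v)
                adj[v].add(u)
    seen, clusters = set(), []
    for u in names:
        if u in seen:
            continue
        stack, comp = [u], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        clusters.append(frozenset(comp))
    return set(clusters)


class TestMCL:
    def test_two_disjoint_cliques(self):
        edges = _clique("abcd") + _clique("efgh")
        parts = mcl("abcdefgh", edges)
        assert {frozenset(p) for p in parts} == {frozenset("abcd"), frozenset("efgh")}

    def test_single_edge_single_cluster(self):
        assert [sorted(c) for c in mcl("ab", [("a", "b", 1.0)])] == [["a", "b"]]

    def test_isolated_node_is_singleton(self):
        parts = mcl(["a", "b", "z"], [("a", "b", 1.0)])
        assert {frozenset(p) for p in parts} == {frozenset("ab"), frozenset("z")}

    def test_bridged_cliques_match_reference_oracle(self):
        edges = _clique("abcd") + _clique("efgh") + [("d", "e", 1.0)]
        parts = {frozenset(p) for p in mcl("abcdefgh", edges, inflation=2.0)}
        assert parts == _reference_mcl("abcdefgh", edges, inflation=2.0)
        assert parts == {frozenset("abcd"), frozenset("efgh")}

    def test_matches_reference_oracle_on_random_graphs(self, rng):
        nodes = list("abcdefghij")
        for _ in range(10):
            edges = []
            for u, v in itertools.combinations(nodes, 2):
                if rng.random() < 0.3:
                    edges.append((u, v, float(rng.integers(1, 5))))
            parts = {frozenset(p) for p in mcl(nodes, edges)}
            assert parts == _reference_mcl(nodes, edges)

    def test_output_is_partition(self, rng):
        nodes = [f"n{i}" for i in range(30)]
        edges = [
            (u, v, float(rng.integers(1, 4)))
            for u, v in itertools.combinations(nodes, 2)
            if rng.random() < 0.15
        ]
        parts = mcl(nodes, edges)
        flat = [n for p in parts for n in p]
        assert sorted(flat) == sorted(nodes)
        assert len(flat) == len(set(flat))

    def test_low_inflation_equals_connected_components(self):
        # uniform weights, inflation -> 1+: clusters are the graph components
        edges = (
            _clique("abc") + _clique("def") + [("a", "c", 1.0), ("x", "y", 1.0)]
        )
        parts = mcl("abcdefxy", edges, inflation=1.01, max_iter=2000, tol=1e-10)
        assert {frozenset(p) for p in parts} == {
            frozenset("abc"), frozenset("def"), frozenset("xy")
        }

    def test_input_order_invariance(self, rng):
        nodes = list("abcdefgh")
        edges = _clique("abcd") + _clique("efgh") + [("d", "e", 1.0)]
        baseline = mcl(nodes, edges)
        for _ in range(5):
            shuffled_nodes = list(nodes)
            rng.shuffle(shuffled_nodes)
            shuffled_edges = list(edges)
            rng.shuffle(shuffled_edges)
            assert mcl(shuffled_nodes, shuffled_edges) == baseline

    def test_asymmetric_weights_rejected(self):
        with pytest.raises(GraphError):
            mcl("ab", [("a", "b", 1.0), ("b", "a", 2.0)])

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(GraphError):
            mcl("ab", [("a", "b", 0.0)])


class TestBuildNetwork:
    def test_no_shared_pcs_no_edges(self):
        net = build_network({"g1": {"A", "B"}, "g2": {"C", "D"}})
        assert net.edges == []

    def test_identical_repertoires_maximal_weight(self):
        pcs = {f"P{i}" for i in range(10)}
        net = build_network({"g1": set(pcs), "g2": set(pcs)}, total_pcs=100)
        (edge,) = net.edges
        p_min, w_max = hypergeom_edge(10, 10, 10, 100)
        assert edge[3] == pytest.approx(p_min)
        assert edge[4] == pytest.approx(w_max)

    def test_shared_core_keeps_all_pairwise_edges(self):
        core = {f"C{i}" for i in range(5)}
        genomes = {
            "g1": core | {"X1", "X2"},
            "g2": core | {"Y1"},
            "g3": core | {"Z1", "Z2", "Z3"},
        }
        # enumeration: sharing 5 of ~7 PCs out of M=50 is far below p=0.1
        p, _ = hypergeom_edge(5, 7, 6, 50)
        assert p < 0.1
        net = build_network(genomes, min_weight=1.0, total_pcs=50)
        assert len(net.edges) == 3

    def test_zero_protein_genome_excluded(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="viroturn"):
            net = build_network({"g1": {"A"}, "empty": set()})
        assert net.nodes == ["g1"]
        assert "empty" in caplog.text


class TestClusterGenomes:
    def test_two_components_two_clusters(self):
        net = build_network(
            {"g1": {"A", "B"}, "g2": {"A", "B"}, "g3": {"C", "D"}, "g4": {"C", "D"}},
            total_pcs=40,
        )
        clusters = cluster_genomes(net)
        assert {frozenset(c.members) for c in clusters} == {
            frozenset({"g1", "g2"}), frozenset({"g3", "g4"})
        }

    def test_singleton_genome_own_cluster(self):
        net = build_network({"g1": {"A", "B"}, "g2": {"A", "B"}, "solo": {"Q"}}, total_pcs=40)
        clusters = cluster_genomes(net)
        assert any(c.members == ["solo"] for c in clusters)

    def test_labels_by_decreasing_size(self):
        net = build_network(
            {
                "g1": {"A", "B"}, "g2": {"A", "B"}, "g3": {"A", "B"},
                "h1": {"C", "D"}, "h2": {"C", "D"},
            },
            total_pcs=40,
        )
        clusters = cluster_genomes(net)
        assert clusters[0].cluster_id == "VC_001"
        assert len(clusters[0].members) == 3

    def test_reference_members_excluded_from_counts(self):
        net = build_network(
            {"g1": {"A", "B"}, "g2": {"A", "B"}, "ref1": {"A", "B"}}, total_pcs=40
        )
        (cluster,) = cluster_genomes(
            net,
            member_library={"g1": "vp", "g2": "vi"},
            reference_ids={"ref1"},
        )
        assert cluster.per_library_counts == {"vp": 1, "vi": 1}
        assert cluster.reference_members == ["ref1"]
        assert cluster.n_counted == 2

    def test_ground_truth_lineage_recovery(self):
        # 3 lineages with strong within-lineage protein sharing: genome
        # clusters equal lineages (adjusted Rand index 1)
        from sklearn.metrics import adjusted_rand_score

        spec = SyntheticCommunitySpec(
            lineages=[
                LineageSpec("L1", "viral", 1 / 3, turnover_theta=0.8),
                LineageSpec("L2", "viral", 1 / 3, turnover_theta=0.5),
                LineageSpec("L3", "viral", 1 / 3, turnover_theta=0.2),
            ],
            libraries=[
                SortedLibrary("vp", "viral_progeny", 120),
                SortedLibrary("vi", "pre_existing_viruses", 60),
            ],
            seed=13,
        )
        _, _, result = simulate(spec)
        contigs = call_simulated(result)
        clusters = network_clusters(contigs, result)
        lineage_of = dict(zip(result.metadata.contig_id, result.metadata.lineage_id))
        members = [m for c in clusters for m in c.members]
        truth = [lineage_of[m] for m in members]
        predicted = [c.cluster_id for c in clusters for _ in c.members]
        assert adjusted_rand_score(truth, predicted) == 1.0
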