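"""Distances, parsimony connection limit, and network construction."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

import cpnet as cp
from cpnet.network import parsimony_probability

# frozen reference values for the parsimony connection limit at 0.95,
# computed from the same mutation model by direct evaluation and
# cross-checked against the Monte-Carlo oracle below
LIMIT_95 = {100: 3, 2000: 14, 4599: 21}


def _matrix_from_vectors(vectors):
    labels = sorted(vectors)
    n = len(next(iter(vectors.values())))
    events = []
    for j in range(n):
        states = {lab: vectors[lab][j] for lab in labels}
        events.append(cp.VariantEvent("r", "substitution", (j + 1, j + 1),
                                      states))
    return cp.HaplotypeMatrix(events, dict(sorted(vectors.items())))


class TestPairwiseDistance:
    @pytest.mark.parametrize("pair", [("E", "F"), ("E", "M"), ("E", "N"),
                                      ("E", "V"), ("A", "B"), ("A", "C"),
                                      ("L", "P"), ("L", "U"), ("S", "T")])
    def test_published_identities_under_missing_mode(self, study_matrix, pair):
        a, b = pair
        assert cp.pairwise_distance(study_matrix.haplotypes[a],
                                    study_matrix.haplotypes[b],
                                    cp.IndelMode.missing) == 0

    def test_identity_is_zero_in_every_mode(self, study_matrix):
        v = study_matrix.haplotypes["E"]
        for mode in cp.IndelMode:
            assert cp.pairwise_distance(v, v, mode) == 0

    def test_e_f_differ_by_one_indel_as_fifth_state(self, study_matrix):
        # E and F differ only at the 1-bp indel at rps16 column 533
        d = cp.pairwise_distance(study_matrix.haplotypes["E"],
                                 study_matrix.haplotypes["F"],
                                 cp.IndelMode.fifth_state)
        assert d == 1

    def test_no_distinct_pair_merges_under_fifth_state(self, study_matrix):
        dm = cp.distance_matrix(study_matrix, cp.IndelMode.fifth_state)
        off_diag = dm.steps[~np.eye(len(dm.labels), dtype=bool)]
        assert (off_diag > 0).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(cp.CpnetError):
            cp.pairwise_distance(("A",), ("A", "C"), cp.IndelMode.missing)


class TestParsimonyLimit:
    def test_single_steps_always_joinable_at_moderate_length(self):
        for length in (100, 500, 4599):
            assert cp.connection_limit(length, 0.95) >= 1

    @pytest.mark.parametrize("length,limit", sorted(LIMIT_95.items()))
    def test_frozen_limits(self, length, limit):
        assert cp.connection_limit(length, 0.95) == limit

    def test_monotone_in_length_and_confidence(self):
        assert cp.connection_limit(2000, 0.95) <= \
            cp.connection_limit(4599, 0.95)
        assert cp.connection_limit(4599, 0.99) <= \
            cp.connection_limit(4599, 0.95)
        js = [parsimony_probability(4599, j) for j in range(1, 25)]
        assert all(a >= b for a, b in zip(js, js[1:]))

    def test_probability_matches_monte_carlo_oracle(self):
        """Simulate the generative model: Poisson mutation count, uniform
        site usage, symmetric 4-state chain; estimate P(count == j and all
        sites distinct | j sites visibly differ)."""
        m, j, reps = 150, 3, 40_000
        rng = np.random.default_rng(17)
        lam = -0.75 * m * math.log1p(-4.0 * (j / m) / 3.0)
        pars = vis = 0
        for M in rng.poisson(lam, reps):
            if M < j:
                continue
            sites = np.sort(rng.integers(0, m, M))
            jumps = rng.integers(1, 4, M)
            uniq, idx = np.unique(sites, return_index=True)
            final = np.add.reduceat(jumps, idx) % 4
            if int((final != 0).sum()) == j:
                vis += 1
                if M == j and len(uniq) == j:
                    pars += 1
        est = pars / vis
        se = math.sqrt(est * (1 - est) / vis)
        exact = parsimony_probability(m, j)
        assert abs(est - exact) < max(4 * se, 0.006)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(cp.CpnetError):
            cp.connection_limit(float("nan"))
        with pytest.raises(cp.CpnetError):
            cp.connection_limit(1000, confidence=1.5)


class TestBuildNetwork:
    def test_published_merge_sets(self, collapsed):
        net = cp.build_network(collapsed, cp.IndelMode.missing)
        groups = sorted(net.merged_labels(n) for n in net.sampled_nodes)
        multi = [g for g in groups if len(g) > 1]
        assert multi == [("A", "B", "C"), ("E", "F", "M", "N", "V"),
                         ("L", "P", "U"), ("S", "T")]
        assert len(net.sampled_nodes) == 23 - 9  # 23 minus merge-absorbed

    def test_merged_node_frequencies_sum_samples(self, collapsed):
        net = cp.build_network(collapsed, cp.IndelMode.missing)
        total = sum(net.graph.nodes[n]["frequency"]
                    for n in net.sampled_nodes)
        assert total == 86

    def test_no_merges_under_fifth_state(self, collapsed):
        net = cp.build_network(collapsed, cp.IndelMode.fifth_state)
        assert len(net.sampled_nodes) == 23

    def test_two_haplotypes_at_distance_three(self):
        m = _matrix_from_vectors({"A": ("A", "A", "A"),
                                  "B": ("C", "C", "C")})
        net = cp.build_network(m, cp.IndelMode.fifth_state, fixed_limit=5)
        assert len(net.inferred_nodes) == 2
        assert net.graph.number_of_edges() == 3
        assert nx.shortest_path_length(net.graph, "A", "B") == 3

    def test_triangle_distances_1_1_2_connect_through_hub(self):
        m = _matrix_from_vectors({"A": ("A", "A"), "B": ("C", "A"),
                                  "C": ("A", "C")})
        # d(B,A)=1, d(A,C)=1, d(B,C)=2: the distance-2 pair goes through A
        net = cp.build_network(m, cp.IndelMode.fifth_state, fixed_limit=5)
        assert net.inferred_nodes == []
        assert sorted(map(tuple, map(sorted, net.graph.edges()))) == \
            [("A", "B"), ("A", "C")]

    def test_cycle_of_unit_steps_keeps_reticulation(self):
        # four haplotypes on a square: consecutive pairs differ by 1,
        # diagonals by 2; all four unit edges must survive
        m = _matrix_from_vectors({"A": ("A", "A"), "B": ("C", "A"),
                                  "C": ("C", "C"), "D": ("A", "C")})
        net = cp.build_network(m, cp.IndelMode.fifth_state, fixed_limit=5)
        edges = sorted(map(tuple, map(sorted, net.graph.edges())))
        assert edges == [("A", "B"), ("A", "D"), ("B", "C"), ("C", "D")]

    def test_pairs_beyond_limit_stay_disconnected(self):
        m = _matrix_from_vectors({"A": ("A", "A", "A"),
                                  "B": ("C", "C", "C")})
        net = cp.build_network(m, cp.IndelMode.fifth_state, fixed_limit=2)
        assert len(net.components()) == 2

    def test_path_length_at_least_matrix_distance(self, collapsed):
        net = cp.build_network(collapsed, cp.IndelMode.missing)
        dm = cp.distance_matrix(collapsed, cp.IndelMode.missing)
        rep = {}
        for n in net.sampled_nodes:
            for lab in net.merged_labels(n):
                rep[lab] = n
        direct = {tuple(sorted((a, b))): d for a, b, d in net.links}
        for a, b in itertools.combinations(dm.labels, 2):
            if rep[a] == rep[b]:
                continue
            d = dm.get(a, b)
            path = nx.shortest_path_length(net.graph, rep[a], rep[b])
            assert path >= min(d, 1)  # merged-node distances use group min
            key = tuple(sorted((rep[a], rep[b])))
            if key in direct:
                assert nx.shortest_path_length(net.graph, *key) == \
                    direct[key]

    def test_single_haplotype_network(self):
        m = cp.HaplotypeMatrix([], {"A": ()})
        net = cp.build_network(m, cp.IndelMode.missing, fixed_limit=1)
        assert net.sampled_nodes == ["A"]
        assert net.graph.number_of_edges() == 0


def _oracle_links(labels, dist, limit):
    """Independent link-level re-derivation: accept each pair (ascending
    distance, lexicographic ties) whose current weighted network distance
    exceeds its mutational distance; relax an all-pairs table after each
    acceptance."""
    INF = float("inf")
    D = {(a, b): (0.0 if a == b else INF)
         for a in labels for b in labels}
    links = []
    pairs = sorted((dist[a, b], a, b)
                   for a, b in itertools.combinations(labels, 2))
    for d, a, b in pairs:
        if d > limit or D[a, b] <= d:
            continue
        links.append((a, b, d))
        for x in labels:
            for y in labels:
                nd = min(D[x, y], D[x, a] + d + D[b, y],
                         D[x, b] + d + D[a, y])
                D[x, y] = D[y, x] = nd
    return links


class TestSmallCaseOracles:
    @pytest.mark.parametrize("seed", range(12))
    def test_links_match_independent_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        n_hap = int(rng.integers(3, 7))
        n_ev = int(rng.integers(3, 9))
        vectors = {}
        seen = set()
        while len(vectors) < n_hap:
            vec = tuple("ACGT"[i] for i in rng.integers(0, 2, n_ev))
            if vec not in seen:
                seen.add(vec)
                vectors[f"H{len(vectors)}"] = vec
        m = _matrix_from_vectors(vectors)
        net = cp.build_network(m, cp.IndelMode.fifth_state, fixed_limit=n_ev)
        dm = cp.distance_matrix(m, cp.IndelMode.fifth_state)
        dist = {(a, b): dm.get(a, b) for a in dm.labels for b in dm.labels}
        assert net.links == _oracle_links(sorted(vectors), dist, n_ev)

    @pytest.mark.parametrize("seed", range(10))
    def test_unique_distance_links_equal_minimum_spanning_tree(self, seed):
        rng = np.random.default_rng(100 + seed)
        n_hap = int(rng.integers(3, 5))
        length = 40
        for _attempt in range(500):
            # sparse mutants of a shared reference give well-spread
            # pairwise distances
            ref = tuple("ACGT"[i] for i in rng.integers(0, 4, length))
            vectors = {}
            for h in range(n_hap):
                k = int(rng.integers(1, 13))
                cols = rng.choice(length, size=k, replace=False)
                vec = list(ref)
                for c in cols:
                    vec[c] = "ACGT"[(("ACGT".index(vec[c]) +
                                     int(rng.integers(1, 4))) % 4)]
                vectors[f"H{h}"] = tuple(vec)
            m = _matrix_from_vectors(vectors)
            dm = cp.distance_matrix(m, cp.IndelMode.fifth_state)
            dists = [dm.get(a, b) for a, b in
                     itertools.combinations(dm.labels, 2)]
            if len(set(dists)) == len(dists) and 0 not in dists:
                break
        else:
            raise AssertionError("no unique-distance draw found")
        net = cp.build_network(m, cp.IndelMode.fifth_state, fixed_limit=30)
        g = nx.Graph()
        for a, b in itertools.combinations(dm.labels, 2):
            g.add_edge(a, b, weight=dm.get(a, b))
        mst = {tuple(sorted(e)) for e in
               nx.minimum_spanning_tree(g).edges()}
        got = {tuple(sorted((a, b))) for a, b, _ in net.links}
        assert mst <= got
        # extras are reticulations: their distance is shorter than the
        # MST path between their endpoints
        t = nx.minimum_spanning_tree(g)
        for a, b, d in net.links:
            if tuple(sorted((a, b))) not in mst:
                path = nx.shortest_path(t, a, b)
                w = sum(t[u][v]["weight"]
                        for u, v in zip(path, path[1:]))
                assert w > d


class TestExport:
    def test_graphml_round_trip(self, collapsed, tmp_path):
        net = cp.build_network(collapsed, cp.IndelMode.missing)
        p = tmp_path / "net.graphml"
        cp.export_network(net, p, format="graphml")
        back = cp.read_network(p)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert {tuple(sorted(e)) for e in back.graph.edges()} == \
            {tuple(sorted(e)) for e in net.graph.edges()}
        assert back.connection_limit == net.connection_limit
        assert back.mode == net.mode
        for n in net.graph.nodes:
            assert back.graph.nodes[n]["labels"] == \
                net.graph.nodes[n]["labels"]

    def test_single_node_export(self, tmp_path):
        m = cp.HaplotypeMatrix([], {"A": ()})
        net = cp.build_network(m, cp.IndelMode.missing, fixed_limit=1)
        p = tmp_path / "one.edges"
        cp.export_network(net, p, format="edge_list")
        nodes = (tmp_path / "one.edges.nodes.tsv").read_text().splitlines()
        assert len(nodes) == 2  # header + 1 node
        assert p.read_text().count("\t") == 0

    def test_sampled_node_count_after_merging(self, collapsed, tmp_path):
        net = cp.build_network(collapsed, cp.IndelMode.missing)
        p = tmp_path / "net.edges"
        cp.export_network(net, p, format="edge_list")
        rows = (tmp_path / "net.edges.nodes.tsv").read_text().splitlines()
        sampled = [r for r in rows[1:] if r.endswith("\t1")]
        assert len(sampled) == 14
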