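"""Median-joining network construction, MP post-processing and rooting."""

from collections import Counter

import networkx as nx
import numpy as np
import pytest

from svakit.mj_network import (
    condense_characters,
    median_joining,
    mp_postprocess,
    network_cost,
    root_network,
)

from _oracles import (
    network_splits,
    random_compatible_matrix,
    steiner_minimal_cost,
)


def _graph_key(g):
    return (frozenset(g.nodes), frozenset(frozenset(e) for e in g.edges))


def _canon_split(s, taxa):
    comp = frozenset(taxa - s)
    return min([s, comp], key=lambda x: (len(x), sorted(x)))


class TestCondense:
    def test_identical_sequences_collapse(self):
        m = condense_characters({"a": "ACGT", "b": "ACGT"})
        assert m.n_hap == 1
        assert m.haplotypes.shape[1] == 0
        assert m.labels == [["a", "b"]]

    def test_variable_columns_only(self):
        m = condense_characters({"x": "AAA", "y": "AAT", "z": "TAA"})
        assert m.haplotypes.shape[1] == 2

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            condense_characters({"a": "ACG", "b": "ACGT"})

    def test_condensation_preserves_hamming_distances(self, rng):
        for _ in range(10):
            n, L = int(rng.integers(3, 8)), int(rng.integers(5, 30))
            seqs = {
                f"s{i}": "".join(rng.choice(list("ACGT-"), L)) for i in range(n)
            }
            m = condense_characters(seqs)
            vec = {lab: row for row, labs in zip(m.haplotypes, m.labels) for lab in labs}
            names = sorted(seqs)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    a, b = names[i], names[j]
                    direct = sum(1 for x, y in zip(seqs[a], seqs[b]) if x != y)
                    condensed = float(m.weights[vec[a] != vec[b]].sum())
                    assert condensed == direct


class TestMedianJoining:
    def test_two_haplotypes_single_link(self):
        m = condense_characters({"a": "AAAACC", "b": "TTTTCC"})
        net = median_joining(m)
        assert net.number_of_nodes() == 2
        ((u, v, w),) = net.edges(data="weight")
        assert w == 4

    def test_three_binary_star_median(self):
        # 110/101/011: the true median 111 beats the spanning path (cost 3 < 4)
        m = condense_characters({"x": "TTA", "y": "TAT", "z": "ATT"})
        net = median_joining(m)
        medians = [n for n, d in net.nodes(data=True) if not d["sampled"]]
        assert len(medians) == 1
        assert sorted(w for _, _, w in net.edges(data="weight")) == [1, 1, 1]
        assert network_cost(net) == 3
        # exhaustive Steiner enumeration over all 2^3 states agrees
        assert steiner_minimal_cost([(1, 1, 0), (1, 0, 1), (0, 1, 1)], np.ones(3)) == 3

    def test_compatible_characters_give_perfect_phylogeny(self, rng):
        n_ok = 0
        for _ in range(100):
            nt = int(rng.integers(3, 13))
            nc = int(rng.integers(2, 21))
            seqs, splits = random_compatible_matrix(rng, nt, nc)
            if not any(len(set(col)) > 1 for col in zip(*seqs.values())):
                continue
            mat = condense_characters(seqs)
            net = mp_postprocess(median_joining(mat), mat)
            assert nx.is_tree(net)
            taxa = set(seqs)
            got = Counter()
            for s, w in network_splits(net, taxa):
                got[_canon_split(s, taxa)] += w
            want = Counter()
            for s in splits:
                want[_canon_split(s, taxa)] += 1
            assert got == want
            n_ok += 1
        assert n_ok >= 90

    def test_cost_matches_exhaustive_steiner(self, rng):
        for _ in range(40):
            m = int(rng.integers(4, 9))
            k = int(rng.integers(2, 6))
            haps = set()
            while len(haps) < k:
                haps.add(tuple(int(x) for x in rng.integers(0, 2, size=m)))
            seqs = {
                f"h{i}": "".join("T" if x else "A" for x in h)
                for i, h in enumerate(sorted(haps))
            }
            mat = condense_characters(seqs)
            if mat.haplotypes.shape[1] == 0:
                continue
            net = mp_postprocess(median_joining(mat), mat)
            oracle = steiner_minimal_cost(
                [tuple(int(x) for x in r) for r in mat.haplotypes], mat.weights
            )
            assert network_cost(net) == pytest.approx(oracle)

    def test_contains_mst_of_sampled_haplotypes(self, rng):
        for _ in range(20):
            n, L = int(rng.integers(3, 9)), int(rng.integers(8, 25))
            seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), L)) for i in range(n)}
            mat = condense_characters(seqs)
            if mat.n_hap < 2:
                continue
            net = median_joining(mat)
            assert nx.is_connected(net)
            sampled = [n_ for n_, d in net.nodes(data=True) if d["sampled"]]
            assert len(sampled) == mat.n_hap
            # spanning structure within the network is never longer than a
            # direct MST over the sampled haplotypes
            g = nx.Graph()
            for i in range(mat.n_hap):
                for j in range(i + 1, mat.n_hap):
                    g.add_edge(i, j, weight=mat.distance(mat.haplotypes[i], mat.haplotypes[j]))
            direct = sum(w for _, _, w in nx.minimum_spanning_tree(g).edges(data="weight"))
            assert network_cost(net) <= direct

    def test_gap_state_separates_deletion_haplotypes(self):
        seqs = {
            "D1": "ACGTACGTAC",
            "D2": "ACGT----AC",
        }
        m = condense_characters(seqs)
        net = median_joining(m)
        ((u, v, w),) = net.edges(data="weight")
        assert w == 4  # the deletion columns separate the two

    def test_epsilon_must_be_nonnegative(self):
        m = condense_characters({"a": "AT", "b": "TA"})
        with pytest.raises(ValueError):
            median_joining(m, epsilon=-1)


class TestMpPostprocess:
    def test_tree_input_unchanged(self, rng):
        seqs, _ = random_compatible_matrix(rng, 6, 8)
        mat = condense_characters(seqs)
        net = median_joining(mat)
        post = mp_postprocess(net, mat)
        post2 = mp_postprocess(post, mat)
        assert _graph_key(post) == _graph_key(post2)

    def test_never_removes_sampled(self, rng):
        for _ in range(10):
            n, L = int(rng.integers(3, 7)), int(rng.integers(6, 16))
            seqs = {f"s{i}": "".join(rng.choice(list("AT"), L)) for i in range(n)}
            mat = condense_characters(seqs)
            net = median_joining(mat)
            post = mp_postprocess(net, mat)
            sampled = {n_ for n_, d in net.nodes(data=True) if d["sampled"]}
            assert sampled <= set(post.nodes)
            # total spanning length within the network is unchanged
            assert network_cost(post) == pytest.approx(network_cost(net))

    def test_four_cycle_keeps_both_parsimonious_paths(self):
        # two haplotypes differing at two characters: both orders are equally
        # parsimonious; the square (via both medians) must be retained
        seqs = {"a": "AA", "b": "TT"}
        mat = condense_characters(seqs)
        net = median_joining(mat)
        post = mp_postprocess(net, mat)
        # direct link of weight 2 is itself a shortest tree: medians optional
        assert network_cost(post) == 2


class TestRooting:
    def test_root_flag_and_distances(self, rng):
        seqs, _ = random_compatible_matrix(rng, 6, 10)
        mat = condense_characters(seqs)
        net = mp_postprocess(median_joining(mat), mat)
        rooted = root_network(net, "t0")
        assert _graph_key(rooted) == _graph_key(net)
        roots = [n for n, d in rooted.nodes(data=True) if d.get("is_root")]
        assert len(roots) == 1
        # distances equal an independent all-pairs shortest path computation
        sp = nx.single_source_dijkstra_path_length(net, roots[0], weight="weight")
        for n, d in rooted.nodes(data=True):
            assert d["dist_to_root"] == pytest.approx(sp[n])

    def test_missing_outgroup_errors(self):
        m = condense_characters({"a": "AT", "b": "TA"})
        net = median_joining(m)
        with pytest.raises(ValueError, match="outgroup"):
            root_network(net, "zz")
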