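"""Median-joining haplotype networks with parsimony post-processing.

The construction follows the classical median-joining scheme: build the
minimum spanning network (union of all minimum spanning trees, relaxed
by a tolerance epsilon) over the current node set, generate quasi-median
vectors from triplets formed by each network link plus a third node, add
the cheapest new medians, and iterate to a fixed point; obsolete median
vectors (degree <= 2, hence never useful as Steiner points) are purged.

Parsimony ("MP") post-processing then retains exactly the links and
median vectors lying on at least one most-parsimonious (minimum-length
Steiner) tree connecting the sampled haplotypes within the network.

Gaps are treated as a fifth character state so that hallmark deletions
separate subfamilies in the network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

MEDIAN_CAP = 10_000
_MP_MEDIAN_LIMIT = 16  # subset enumeration guard for MP post-processing


@dataclass
class CharacterMatrix:
    """Condensed variable-column character data.

    Rows are distinct haplotypes; identical input sequences are
    collapsed (labels kept, multiplicity recorded). Identical columns
    are merged with summed weight; ``positions`` maps each condensed
    column back to the original 1-based alignment columns it represents.
    """

    haplotypes: np.ndarray  # (n_hap, n_col) uint8 state codes
    labels: list[list[str]]  # input labels per haplotype
    weights: np.ndarray  # per condensed column
    positions: list[list[int]]  # original columns per condensed column
    state_alphabet: str = "ACGT-"

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    def distance(self, u: np.ndarray, v: np.ndarray) -> int:
        return int(self.weights[u != v].sum())


def condense_characters(sequences: dict[str, str]) -> CharacterMatrix:
    """Condense equal-length aligned sequences to variable weighted columns."""
    labels = sorted(sequences)
    seqs = [sequences[l].upper() for l in labels]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    alphabet = "ACGT-"
    mat = np.zeros((len(seqs), lengths.pop()), dtype=np.uint8)
    for i, s in enumerate(seqs):
        for j, ch in enumerate(s):
            if ch not in alphabet:
                raise ValueError(f"unsupported state {ch!r} (gaps are '-')")
            mat[i, j] = alphabet.index(ch)
    # variable columns
    variable = [j for j in range(mat.shape[1]) if len(set(mat[:, j])) > 1]
    # merge identical columns
    col_map: dict[tuple, list[int]] = {}
    for j in variable:
        col_map.setdefault(tuple(mat[:, j]), []).append(j + 1)
    cols = sorted(col_map.items(), key=lambda kv: kv[1][0])
    cond = (
        np.array([k for k, _ in cols], dtype=np.uint8).T
        if cols
        else np.zeros((len(seqs), 0), dtype=np.uint8)
    )
    weights = np.array([len(v) for _, v in cols], dtype=float)
    positions = [v for _, v in cols]
    # collapse identical haplotypes
    hap_map: dict[tuple, list[str]] = {}
    order: list[tuple] = []
    for i, lab in enumerate(labels):
        key = tuple(cond[i])
        if key not in hap_map:
            hap_map[key] = []
            order.append(key)
        hap_map[key].append(lab)
    haps = np.array(order, dtype=np.uint8) if order else np.zeros((0, 0), dtype=np.uint8)
    if haps.ndim == 1:
        haps = haps.reshape(len(order), 0)
    return CharacterMatrix(
        haplotypes=haps,
        labels=[hap_map[k] for k in order],
        weights=weights,
        positions=positions,
    )


class HaplotypeNetwork(nx.Graph):
    """Undirected weighted graph; nodes carry 'vector', 'sampled', 'labels'."""

    root: Optional[str] = None


def _node_id(vec: tuple) -> str:
    return ",".join(str(int(x)) for x in vec)


def _distances(vectors: np.ndarray, weights: np.ndarray) -> np.ndarray:
    diff = vectors[:, None, :] != vectors[None, :, :]
    return (diff * weights[None, None, :]).sum(axis=2)


def _minimum_spanning_network(vectors: np.ndarray, weights: np.ndarray, epsilon: float):
    """Edge list of the epsilon-relaxed minimum spanning network.

    An edge is included iff its weight is within epsilon of the minimax
    path weight between its endpoints (epsilon 0 = union of all MSTs).
    """
    n = len(vectors)
    dist = _distances(vectors, weights)
    if n == 1:
        return [], dist
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=dist[i, j])
    mst = nx.minimum_spanning_tree(g)
    # minimax path weights on the MST
    minimax = np.zeros((n, n))
    for i in range(n):
        stack = [(i, -1, 0.0)]
        while stack:
            u, parent, mx = stack.pop()
            minimax[i, u] = mx
            for v in mst.neighbors(u):
                if v != parent:
                    stack.append((v, u, max(mx, mst[u][v]["weight"])))
    edges = [
        (i, j, dist[i, j])
        for i in range(n)
        for j in range(i + 1, n)
        if dist[i, j] <= minimax[i, j] + epsilon
    ]
    return edges, dist


def _quasi_medians(u: np.ndarray, v: np.ndarray, w: np.ndarray) -> list[tuple]:
    """Per-column majority where one exists, else all observed-state combinations."""
    free_cols = []
    base = np.empty(len(u), dtype=np.uint8)
    for j in range(len(u)):
        states = (u[j], v[j], w[j])
        counts: dict[int, int] = {}
        for s in states:
            counts[s] = counts.get(s, 0) + 1
        maj = max(counts.items(), key=lambda kv: kv[1])
        if maj[1] >= 2:
            base[j] = maj[0]
        else:
            free_cols.append((j, sorted(set(states))))
    if not free_cols:
        return [tuple(base)]
    if len(free_cols) > 3:  # combinatorial guard; such triplets carry no signal
        return [tuple(base)]
    out = []
    for combo in itertools.product(*(opts for _, opts in free_cols)):
        vec = base.copy()
        for (j, _), s in zip(free_cols, combo):
            vec[j] = s
        out.append(tuple(vec))
    return out


def median_joining(matrix: CharacterMatrix, epsilon: float = 0.0) -> HaplotypeNetwork:
    """Median-joining network of the sampled haplotypes.

    Iterates minimum-spanning-network construction and quasi-median
    addition to a fixed point, then purges median vectors of degree
    <= 2 (a Steiner point is only useful with degree >= 3). The final
    network contains every sampled haplotype and at least one minimum
    spanning tree of them.
    """
    if matrix.n_hap < 1:
        raise ValueError("need at least one haplotype")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    from scipy.sparse.csgraph import minimum_spanning_tree as _scipy_mst

    weights = matrix.weights
    vectors = [tuple(int(x) for x in row) for row in matrix.haplotypes]
    sampled = set(vectors)
    if len(sampled) != len(vectors):
        raise ValueError("haplotypes must be distinct after condensing")
    current = list(vectors)

    def spanning_cost(vecs: list[tuple]) -> float:
        arr = np.array(vecs, dtype=np.uint8)
        if arr.ndim == 1:
            arr = arr.reshape(len(vecs), 0)
        return float(_scipy_mst(_distances(arr, weights)).sum())

    while True:
        arr = np.array(current, dtype=np.uint8)
        if arr.ndim == 1:
            arr = arr.reshape(len(current), 0)
        edges, dist = _minimum_spanning_network(arr, weights, epsilon)
        current_set = set(current)
        candidates: set[tuple] = set()
        for (i, j, _), k in itertools.product(edges, range(len(current))):
            if k == i or k == j:
                continue
            for med in _quasi_medians(arr[i], arr[j], arr[k]):
                if med not in current_set:
                    candidates.add(med)
        if not candidates:
            break
        # add the median vectors that most reduce the spanning cost of the
        # node set (all ties at once - tied medians act as mutual stepping
        # stones) and iterate to a fixed point
        base = spanning_cost(current)
        scored = sorted((spanning_cost(current + [med]), med) for med in candidates)
        if scored and scored[0][0] < base - 1e-9:
            best = scored[0][0]
            current.extend(med for c, med in scored if abs(c - best) <= 1e-9)
        else:
            # stuck: drop obsolete medians first - they distort the marginal
            # cost of further candidates - and retry from the purged core
            core = _purge_medians(current, sampled, weights)
            if len(core) < len(current):
                current = core
                continue
            # some Steiner configurations only pay off as a pair of medians:
            # bounded two-step lookahead over the most promising candidates
            ranked = [med for _, med in scored[:40]]
            pair_found = False
            for ia in range(len(ranked)):
                for ib in range(ia + 1, len(ranked)):
                    c = spanning_cost(current + [ranked[ia], ranked[ib]])
                    if c < base - 1e-9:
                        current.extend([ranked[ia], ranked[ib]])
                        pair_found = True
                        break
                if pair_found:
                    break
            if not pair_found:
                break
        if len(current) > MEDIAN_CAP:
            raise RuntimeError(f"median vector cap ({MEDIAN_CAP}) exceeded")

    # purge obsolete medians: keep the median subset minimizing the length
    # of the spanning structure over the node set (exact for small median
    # counts, steepest-descent greedy beyond)
    current = _purge_medians(current, sampled, weights)

    net = HaplotypeNetwork()
    label_of = {tuple(int(x) for x in row): labs for row, labs in zip(matrix.haplotypes, matrix.labels)}
    for vec in current:
        nid = _node_id(vec)
        net.add_node(
            nid,
            vector=vec,
            sampled=vec in sampled,
            labels=label_of.get(vec, []),
        )
    arr = np.array(current, dtype=np.uint8)
    if arr.ndim == 1:
        arr = arr.reshape(len(current), 0)
    edges, _ = _minimum_spanning_network(arr, weights, epsilon)
    for i, j, w in edges:
        net.add_edge(_node_id(current[i]), _node_id(current[j]), weight=float(w))
    return net


_EXACT_PURGE_LIMIT = 12


def _purge_medians(current: list[tuple], sampled: set, weights: np.ndarray) -> list[tuple]:
    from scipy.sparse.csgraph import minimum_spanning_tree as _scipy_mst

    arr = np.array(current, dtype=np.uint8)
    if arr.ndim == 1:
        arr = arr.reshape(len(current), 0)
    D = _distances(arr, weights)

    def cost(idx: tuple[int, ...]) -> float:
        if len(idx) == 1:
            return 0.0
        sub = D[np.ix_(idx, idx)]
        return float(_scipy_mst(sub).sum())

    term_idx = tuple(i for i, v in enumerate(current) if v in sampled)
    med_idx = [i for i, v in enumerate(current) if v not in sampled]
    if not med_idx:
        return current
    if len(med_idx) <= _EXACT_PURGE_LIMIT:
        best = None
        for r in range(len(med_idx) + 1):
            for sub in itertools.combinations(med_idx, r):
                c = cost(term_idx + sub)
                key = (c, r, sub)
                if best is None or key < best:
                    best = key
        keep = set(best[2])
        return [v for i, v in enumerate(current) if i in keep or v in sampled]
    # steepest-descent greedy: repeatedly drop the median whose removal
    # lowers (or least increases, up to equality) the spanning cost
    active = list(term_idx) + med_idx
    while True:
        base = cost(tuple(active))
        best_drop, best_cost = None, None
        for i in active:
            if current[i] in sampled:
                continue
            trial = tuple(j for j in active if j != i)
            c = cost(trial)
            if c <= base + 1e-9 and (best_cost is None or c < best_cost):
                best_drop, best_cost = i, c
        if best_drop is None:
            break
        active = [j for j in active if j != best_drop]
    keep = set(active)
    return [v for i, v in enumerate(current) if i in keep]


def _edges_in_some_mst(g: nx.Graph) -> set[frozenset]:
    """Edges that appear in at least one MST of g (cut criterion)."""
    out = set()
    for u, v, w in g.edges(data="weight"):
        lighter = nx.Graph()
        lighter.add_nodes_from(g.nodes)
        lighter.add_edges_from(
            (a, b) for a, b, ww in g.edges(data="weight") if ww < w
        )
        comp = nx.node_connected_component(lighter, u)
        if v not in comp:
            out.add(frozenset((u, v)))
    return out


def mp_postprocess(network: HaplotypeNetwork, matrix: Optional[CharacterMatrix] = None) -> HaplotypeNetwork:
    """Keep only links/medians on at least one most-parsimonious tree.

    A most-parsimonious tree is a minimum-total-weight subtree of the
    network spanning all sampled haplotypes (median vectors optional,
    acting as Steiner points). Implemented by exact enumeration over
    median-vector subsets; sampled haplotypes are never removed.
    """
    terminals = [n for n, d in network.nodes(data=True) if d.get("sampled")]
    medians = [n for n, d in network.nodes(data=True) if not d.get("sampled")]
    if len(medians) > _MP_MEDIAN_LIMIT:
        raise RuntimeError(
            f"MP post-processing limited to {_MP_MEDIAN_LIMIT} median vectors "
            f"(got {len(medians)})"
        )
    best_cost = np.inf
    optimal: list[tuple[tuple, nx.Graph]] = []
    for r in range(len(medians) + 1):
        for subset in itertools.combinations(medians, r):
            nodes = terminals + list(subset)
            sub = network.subgraph(nodes)
            if len(nodes) > 1 and not nx.is_connected(sub):
                continue
            mst = nx.minimum_spanning_tree(sub)
            cost = sum(w for _, _, w in mst.edges(data="weight"))
            # an MST spanning useless medians is never cheaper; still must
            # check every subset for ties at equal cost
            if cost < best_cost - 1e-9:
                best_cost = cost
                optimal = [(subset, sub)]
            elif abs(cost - best_cost) <= 1e-9:
                optimal.append((subset, sub))
    keep_edges: set[frozenset] = set()
    keep_nodes: set = set(terminals)
    for subset, sub in optimal:
        mst_cost = sum(
            w for _, _, w in nx.minimum_spanning_tree(sub).edges(data="weight")
        )
        if abs(mst_cost - best_cost) > 1e-9:
            continue
        for e in _edges_in_some_mst(sub):
            keep_edges.add(e)
        keep_nodes.update(subset)
    pruned = HaplotypeNetwork()
    for n in keep_nodes:
        pruned.add_node(n, **network.nodes[n])
    for e in keep_edges:
        u, v = tuple(e)
        pruned.add_edge(u, v, weight=network[u][v]["weight"])
    pruned.root = getattr(network, "root", None)
    return pruned


def network_cost(network: HaplotypeNetwork) -> float:
    """Length of the shortest tree within the network spanning its nodes."""
    mst = nx.minimum_spanning_tree(network)
    return float(sum(w for _, _, w in mst.edges(data="weight")))


def root_network(network: HaplotypeNetwork, outgroup_label: str) -> HaplotypeNetwork:
    """Root on the sampled node carrying ``outgroup_label``; topology unchanged.

    Each node receives a 'dist_to_root' attribute (weighted shortest
    path) and each link a 'toward_root' endpoint.
    """
    root_node = None
    for n, d in network.nodes(data=True):
        if d.get("sampled") and outgroup_label in d.get("labels", []):
            root_node = n
            break
    if root_node is None:
        raise ValueError(f"outgroup {outgroup_label!r} not among sampled nodes")
    rooted = network.copy()
    rooted.__class__ = HaplotypeNetwork
    dists = nx.single_source_dijkstra_path_length(rooted, root_node, weight="weight")
    nx.set_node_attributes(rooted, dists, "dist_to_root")
    nx.set_node_attributes(rooted, False, "is_root")
    rooted.nodes[root_node]["is_root"] = True
    for u, v in rooted.edges:
        rooted[u][v]["toward_root"] = u if dists[u] <= dists[v] else v
    rooted.root = root_node
    return rooted


def export_edge_list(network: HaplotypeNetwork):
    import pandas as pd

    rows = [
        {
            "node_a": u,
            "node_b": v,
            "weight": d["weight"],
            "sampled_a": network.nodes[u].get("sampled", False),
            "sampled_b": network.nodes[v].get("sampled", False),
        }
        for u, v, d in network.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "sampled_a", "sampled_b"])


def export_graphml(network: HaplotypeNetwork, path) -> None:
    g = nx.Graph()
    for n, d in network.nodes(data=True):
        g.add_node(
            n,
            sampled=bool(d.get("sampled", False)),
            labels=";".join(d.get("labels", [])),
        )
    for u, v, d in network.edges(data=True):
        g.add_edge(u, v, weight=float(d["weight"]))
    nx.write_graphml(g, str(path))
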