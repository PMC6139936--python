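"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import heapq
import itertools

import numpy as np

NEG = float("-inf")


def semiglobal_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -6.0,
    gap_extend: float = -1.0,
) -> float:
    """Exhaustive affine-gap overlap-alignment score (end gaps free on both
    sequences; a gap of length L costs open + (L-1)*extend)."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)

    def best0(i, j):
        v = max(M[i][j], X[i][j], Y[i][j])
        if i == 0 or j == 0:
            v = max(v, 0.0)  # free leading end gap
        return v

    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = match if a[i - 1] == b[j - 1] else mismatch
                M[i][j] = s + best0(i - 1, j - 1)
            if i > 0:
                X[i][j] = max(
                    (M[i - 1][j] + gap_open) if M[i - 1][j] > NEG else NEG,
                    (X[i - 1][j] + gap_extend) if X[i - 1][j] > NEG else NEG,
                    (Y[i - 1][j] + gap_open) if Y[i - 1][j] > NEG else NEG,
                )
            if j > 0:
                Y[i][j] = max(
                    (M[i][j - 1] + gap_open) if M[i][j - 1] > NEG else NEG,
                    (X[i][j - 1] + gap_open) if X[i][j - 1] > NEG else NEG,
                    (Y[i][j - 1] + gap_extend) if Y[i][j - 1] > NEG else NEG,
                )
    best = 0.0  # empty overlap
    for i in range(n + 1):
        best = max(best, M[i][m], X[i][m], Y[i][m])
    for j in range(m + 1):
        best = max(best, M[n][j], X[n][j], Y[n][j])
    return best


def steiner_minimal_cost(terminals: list[tuple], weights: np.ndarray) -> float:
    """Dreyfus-Wagner minimum Steiner tree cost over the full state
    hypercube {0,1}^m with weighted coordinate flips."""
    m = len(weights)
    V = 1 << m
    term_ids = sorted({_pack(t) for t in terminals})
    t = len(term_ids)
    if t == 1:
        return 0.0

    def neighbors(v):
        for c in range(m):
            yield v ^ (1 << c), float(weights[c])

    # S[mask][v]: min cost of tree spanning terminal subset `mask` plus node v
    full = (1 << t) - 1
    S = [dict() for _ in range(1 << t)]
    for i, tid in enumerate(term_ids):
        S[1 << i] = {v: _dijkstra_dist(tid, v, m, weights) for v in range(V)}
    for mask in range(1, full + 1):
        if mask & (mask - 1) == 0 or mask == 0:
            continue
        base = {}
        sub = (mask - 1) & mask
        while sub:
            comp = mask ^ sub
            if sub < comp:
                a, b = S[sub], S[comp]
                for v in range(V):
                    c = a[v] + b[v]
                    if c < base.get(v, np.inf):
                        base[v] = c
            sub = (sub - 1) & mask
        # Dijkstra relaxation from the merged costs
        dist = dict(base)
        pq = [(c, v) for v, c in base.items()]
        heapq.heapify(pq)
        while pq:
            c, v = heapq.heappop(pq)
            if c > dist.get(v, np.inf):
                continue
            for u, w in neighbors(v):
                nc = c + w
                if nc < dist.get(u, np.inf):
                    dist[u] = nc
                    heapq.heappush(pq, (nc, u))
        S[mask] = {v: dist.get(v, np.inf) for v in range(V)}
    return min(S[full][v] for v in term_ids)


def _pack(state: tuple) -> int:
    v = 0
    for i, s in enumerate(state):
        if s:
            v |= 1 << i
    return v


def _dijkstra_dist(src: int, dst: int, m: int, weights: np.ndarray) -> float:
    # weighted Hamming on the hypercube = sum of weights of differing bits
    diff = src ^ dst
    return float(sum(weights[c] for c in range(m) if diff & (1 << c)))


def random_compatible_matrix(rng: np.random.Generator, n_taxa: int, n_chars: int):
    """Binary character matrix whose characters are pairwise compatible,
    built by dropping characters on edges of a random taxon tree.
    Returns (sequences dict, list of derived taxon frozensets per char)."""
    import networkx as nx

    taxa = [f"t{i}" for i in range(n_taxa)]
    # random recursive bipartition tree over taxa
    tree = nx.Graph()
    next_internal = [0]

    def build(group, parent):
        if len(group) == 1:
            tree.add_edge(parent, group[0])
            return
        node = f"i{next_internal[0]}"
        next_internal[0] += 1
        tree.add_edge(parent, node)
        k = int(rng.integers(1, len(group)))
        idx = rng.permutation(len(group))
        build([group[i] for i in idx[:k]], node)
        build([group[i] for i in idx[k:]], node)

    root = "root"
    build(taxa, root)
    edges = [e for e in tree.edges if root not in e]
    if not edges:
        edges = list(tree.edges)
    splits = []
    cols = []
    for _ in range(n_chars):
        u, v = edges[int(rng.integers(len(edges)))]
        # derived side: taxa below the edge (away from root)
        t2 = tree.copy()
        t2.remove_edge(u, v)
        comp_u = nx.node_connected_component(t2, u)
        below = comp_u if root not in comp_u else nx.node_connected_component(t2, v)
        derived = frozenset(t for t in taxa if t in below)
        if len(derived) in (0, len(taxa)):
            continue
        splits.append(derived)
        cols.append([1 if t in derived else 0 for t in taxa])
    seqs = {
        t: "".join("T" if col[i] else "A" for col in cols)
        for i, t in enumerate(taxa)
    }
    return seqs, splits


def network_splits(net, taxa: set[str]):
    """Multiset of (frozenset of labels, weight) splits induced by tree edges."""
    import networkx as nx

    assert nx.is_tree(net)
    out = []
    for u, v, w in net.edges(data="weight"):
        g = net.copy()
        g.remove_edge(u, v)
        side = nx.node_connected_component(g, u)
        labels = frozenset(
            lab for n in side for lab in net.nodes[n].get("labels", [])
        )
        labels = labels if len(labels) <= len(taxa) - len(labels) else frozenset(taxa - labels)
        out.append((labels, int(w)))
    return out
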