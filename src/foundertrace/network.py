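"""Haplotype network construction and rooting.

Implements the two parsimony network flavours used in founder analysis:

* **median-joining networks** for multistate data (Y-STR repeat profiles,
  single-step mutation model) and for binary haplotypes;
* **reduced-median networks** for binary (derived vs. ancestral) HVS-I
  haplotypes, with reticulations resolved in favour of recurrence of the
  lower-weight (faster-mutating) character.

Both produce a :class:`HaplotypeNetwork` whose public graph satisfies the
single-step invariant: every edge connects two states that differ at exactly
one character by exactly one step (one base change, or one repeat unit).
Multi-step links between retained states are expanded through inferred
intermediate nodes.

The module also houses the iterative STR re-weighting scheme (start from a
flat weight of 10, count per-locus changes on the network, map counts onto
[1, 10] reversed, rebuild until stable) and network rooting (weighted
midpoint, or nearest node to an outgroup consensus profile), which extracts
the most-parsimonious spanning tree used downstream for founder dating.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree as _sp_mst

from .types import DELETION, HVSIHaplotype, STRProfile

_TOL = 1e-9

Datum = Union[HVSIHaplotype, STRProfile]


# ---------------------------------------------------------------------------
# encoding


def encode_binary(haps: Sequence[HVSIHaplotype]):
    """Encode haplotypes as a binary matrix over derived-variant characters.

    Each distinct ``(position, state)`` variant becomes one binary character
    (multistate positions therefore split into one character per derived
    state). Returns (character names, matrix).
    """
    chars = sorted({v for h in haps for v in h.variants})
    names = [f"{p}{'d' if s == DELETION else s}" for p, s in chars]
    index = {c: i for i, c in enumerate(chars)}
    X = np.zeros((len(haps), len(chars)), dtype=np.int16)
    for r, h in enumerate(haps):
        for v in h.variants:
            X[r, index[v]] = 1
    return names, X


def encode_str(profiles: Sequence[STRProfile]):
    """Encode STR profiles as a repeat-count matrix over the shared loci."""
    loci = sorted(profiles[0].repeats)
    X = np.zeros((len(profiles), len(loci)), dtype=np.int16)
    for r, p in enumerate(profiles):
        if sorted(p.repeats) != loci:
            raise ValueError(
                f"profile {p.sample_id!r} has a different locus set"
            )
        for c, locus in enumerate(loci):
            X[r, c] = p.repeats[locus]
    return list(loci), X


def _label_of(state: np.ndarray, names: Sequence[str], marker: str) -> str:
    if marker == "binary":
        on = [names[i] for i in np.flatnonzero(state)]
        return " ".join(on) if on else "ref"
    return "-".join(str(int(x)) for x in state)


# ---------------------------------------------------------------------------
# distances / minimum spanning structures


def _distance_matrix(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted single-step distances: sum_c w_c * |x_uc - x_vc|."""
    n = len(X)
    if n == 0 or X.shape[1] == 0:
        return np.zeros((n, n))
    Xf = X.astype(float)
    if np.all((X == 0) | (X == 1)):
        Xw = Xf * w
        G = Xw @ Xf.T
        r = Xw.sum(axis=1)
        D = r[:, None] + r[None, :] - 2.0 * G
    else:
        D = np.zeros((n, n))
        for c in range(X.shape[1]):
            D += w[c] * np.abs(Xf[:, c, None] - Xf[None, :, c])
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


class _DSU:
    def __init__(self, n: int):
        self.p = list(range(n))

    def find(self, i: int) -> int:
        while self.p[i] != i:
            self.p[i] = self.p[self.p[i]]
            i = self.p[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.p[max(ri, rj)] = min(ri, rj)


def _connection_levels(D: np.ndarray) -> np.ndarray:
    """lambda[i, j] = distance level at which i and j first become connected
    when links are admitted in order of increasing weighted distance."""
    n = len(D)
    lam = np.zeros((n, n))
    if n <= 1:
        return lam
    dsu = _DSU(n)
    iu, ju = np.triu_indices(n, 1)
    pending = np.ones(len(iu), dtype=bool)
    for level in np.unique(D[iu, ju]):
        at = (D[iu, ju] == level)
        for i, j in zip(iu[at], ju[at]):
            dsu.union(i, j)
        roots = np.array([dsu.find(i) for i in range(n)])
        joined = pending & (roots[iu] == roots[ju])
        lam[iu[joined], ju[joined]] = level
        lam[ju[joined], iu[joined]] = level
        pending &= ~joined
        if not pending.any():
            break
    return lam


def _msn_edges(D: np.ndarray, epsilon: float) -> list[tuple[int, int]]:
    """Epsilon-relaxed minimum spanning network: links whose cost does not
    exceed the level at which their endpoints' components merge, plus eps.
    With epsilon 0 this is the union of all minimum spanning trees."""
    n = len(D)
    if n <= 1:
        return []
    lam = _connection_levels(D)
    iu, ju = np.triu_indices(n, 1)
    keep = D[iu, ju] <= lam[iu, ju] + epsilon + _TOL
    return [(int(i), int(j)) for i, j in zip(iu[keep], ju[keep])]


def _mst_cost(D: np.ndarray) -> float:
    if len(D) <= 1:
        return 0.0
    return float(_sp_mst(D).sum())


# ---------------------------------------------------------------------------
# median-joining core


def _median3(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    return np.sort(np.stack([a, b, c]), axis=0)[1]


def _dist_to(state: np.ndarray, X: np.ndarray, w: np.ndarray) -> np.ndarray:
    return np.abs(X.astype(float) - state.astype(float)) @ w


def _build_core(X_obs: np.ndarray, w: np.ndarray, epsilon: float,
                max_rounds: int = 25):
    """Iteratively add beneficial median (Steiner) vectors and prune.

    Returns (states, kinds, edges) where kinds marks observed vs. inferred
    median vectors and edges index into states.
    """
    X = np.unique(X_obs, axis=0)
    n_obs = len(X)
    kinds = ["observed"] * n_obs
    seen = {row.tobytes() for row in X}

    for _ in range(max_rounds):
        D = _distance_matrix(X, w)
        edges = _msn_edges(D, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(X))}
        for i, j in edges:
            adj[i].add(j)
            adj[j].add(i)
        new: dict[bytes, np.ndarray] = {}
        for i, j in edges:
            for k in sorted((adj[i] | adj[j]) - {i, j}):
                m = _median3(X[i], X[j], X[k])
                key = m.tobytes()
                if key in seen or key in new:
                    continue
                dij, dik, djk = D[i, j], D[i, k], D[j, k]
                mst3 = dij + dik + djk - max(dij, dik, djk)
                connect = float((_dist_to(m, X[[i, j, k]], w)).sum())
                if connect < mst3 - _TOL:
                    new[key] = m
        if not new:
            break
        added = [new[k] for k in sorted(new)]
        X = np.vstack([X, np.stack(added)])
        kinds += ["median"] * len(added)
        seen.update(new)

    # retain only the subset of median vectors that minimises the spanning
    # cost (exact on small inputs, best-improvement greedy otherwise);
    # redundant medians would otherwise inflate the network
    med_idx = [i for i, k in enumerate(kinds) if k == "median"]
    if med_idx:
        obs_idx = [i for i, k in enumerate(kinds) if k == "observed"]
        D_full = _distance_matrix(X, w)
        if len(X) <= 40 and len(med_idx) <= 12:
            best = None
            for mask in range(2 ** len(med_idx)):
                subset = [med_idx[b] for b in range(len(med_idx))
                          if (mask >> b) & 1]
                sel = obs_idx + subset
                cost = _mst_cost(D_full[np.ix_(sel, sel)])
                key = (round(cost / _TOL), len(subset), tuple(subset))
                if best is None or key < best[0]:
                    best = (key, sel)
            sel = sorted(best[1])
        else:
            sel = list(range(len(X)))
            while True:
                base = _mst_cost(D_full[np.ix_(sel, sel)])
                cand = None
                for pos, i in enumerate(sel):
                    if kinds[i] != "median":
                        continue
                    rest = sel[:pos] + sel[pos + 1:]
                    cost = _mst_cost(D_full[np.ix_(rest, rest)])
                    if cost <= base + _TOL and (cand is None
                                                or cost < cand[0]):
                        cand = (cost, pos)
                if cand is None:
                    break
                sel.pop(cand[1])
        X, kinds = X[sel], [kinds[i] for i in sel]

    D = _distance_matrix(X, w)
    edges = _msn_edges(D, epsilon)
    return X, kinds, edges, D


def _step_path(a: np.ndarray, b: np.ndarray, marker: str):
    """Yield (intermediate_state, char_index) single steps from a to b.

    Binary states lose derived characters before gaining new ones (so
    inferred intermediates are the more ancestral states); STR loci step by
    one repeat at a time. Characters are processed in index order.
    """
    cur = a.copy()
    diffs = list(np.flatnonzero(a != b))
    if marker == "binary":
        diffs = ([c for c in diffs if a[c] == 1 and b[c] == 0]
                 + [c for c in diffs if a[c] == 0 and b[c] == 1])
    for c in diffs:
        step = 1 if b[c] > cur[c] else -1
        while cur[c] != b[c]:
            cur[c] += step
            yield cur.copy(), c


# ---------------------------------------------------------------------------
# public containers


@dataclass
class WeightScheme:
    """Per-character weights in [1, 10] plus re-weighting iteration state."""

    weights: dict[str, float]
    iteration_count: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        for name, w in self.weights.items():
            if not (1.0 <= w <= 10.0):
                raise ValueError(f"weight for {name!r} outside [1, 10]: {w}")


class HaplotypeNetwork:
    """A parsimony haplotype network.

    ``graph`` is the expanded, single-step network (public view); nodes are
    state labels carrying ``kind`` (observed / median / intermediate),
    ``count`` and ``samples``. The pre-expansion core (retained state
    vectors and their weighted links) is kept for cost accounting and for
    most-parsimonious spanning-tree extraction.
    """

    def __init__(self, graph: nx.Graph, characters: list[str],
                 weights: dict[str, float], marker: str,
                 states: dict[str, np.ndarray],
                 core_edges: list[tuple[str, str, float]]):
        self.graph = graph
        self.characters = characters
        self.character_weights = weights
        self.marker = marker
        self.states = states
        self.core_edges = core_edges

    @property
    def n_observed(self) -> int:
        return sum(1 for _, d in self.graph.nodes(data=True)
                   if d.get("kind") == "observed")

    def total_cost(self) -> float:
        """Length of the most-parsimonious spanning tree extractable from
        the network (weighted steps). A reticulation contributes only one
        of its alternative paths to this cost."""
        labels = sorted({u for e in self.core_edges for u in e[:2]})
        if not labels:
            return 0.0
        idx = {l: i for i, l in enumerate(labels)}
        dsu = _DSU(len(labels))
        cost = 0.0
        for u, v, c in sorted(self.core_edges, key=lambda e: (e[2], e[0], e[1])):
            if dsu.find(idx[u]) != dsu.find(idx[v]):
                dsu.union(idx[u], idx[v])
                cost += c
        return cost

    def node_samples(self, label: str) -> list[tuple[str, str, str]]:
        return list(self.graph.nodes[label].get("samples", ()))


def _assemble_network(data: Sequence[Datum], names, X_rows, X, kinds, edges,
                      w, marker) -> HaplotypeNetwork:
    labels = [_label_of(X[i], names, marker) for i in range(len(X))]
    states = {labels[i]: X[i].copy() for i in range(len(X))}
    G = nx.Graph()
    for i, lbl in enumerate(labels):
        G.add_node(lbl, kind=kinds[i], count=0, samples=[])
    # attach samples to their observed state nodes
    for r, item in enumerate(data):
        lbl = _label_of(X_rows[r], names, marker)
        G.nodes[lbl]["count"] += 1
        G.nodes[lbl]["samples"].append(
            (item.sample_id, item.role, item.population))
    core_edges = []
    wts = np.asarray(w, dtype=float)
    for i, j in edges:
        a, b = sorted((labels[i], labels[j]))
        cost = float(_dist_to(states[a], states[b][None, :], wts)[0])
        core_edges.append((a, b, cost))
        prev = a
        for inter, c in _step_path(states[a], states[b], marker):
            lbl = _label_of(inter, names, marker)
            if lbl not in G:
                G.add_node(lbl, kind="intermediate", count=0, samples=[])
                states[lbl] = inter.copy()
            G.add_edge(prev, lbl, character=names[c], weight=float(wts[c]))
            prev = lbl
    return HaplotypeNetwork(G, list(names), dict(zip(names, wts)), marker,
                            states, core_edges)


def _prepare(data: Sequence[Datum], weights):
    if not data:
        raise ValueError("cannot build a network from an empty input")
    if isinstance(data[0], STRProfile):
        names, X = encode_str(data)  # type: ignore[arg-type]
        marker = "str"
        default_w = 10.0
    else:
        names, X = encode_binary(data)  # type: ignore[arg-type]
        marker = "binary"
        default_w = 1.0
    if weights is None:
        w = np.full(len(names), default_w)
    elif isinstance(weights, WeightScheme):
        w = np.array([weights.weights.get(n, default_w) for n in names])
    else:
        w = np.array([float(weights.get(n, default_w)) for n in names])
    return names, X, w, marker


def median_joining_network(data: Sequence[Datum],
                           weights: Optional[Union[WeightScheme, dict]] = None,
                           epsilon: float = 0) -> HaplotypeNetwork:
    """Build a median-joining network of STR profiles or HVS-I haplotypes.

    Median (consensus) vectors of mutually close state triples are added
    whenever they shorten the connection, then links are taken from the
    epsilon-relaxed minimum spanning network. ``epsilon=0`` (default) gives
    the sparsest network.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    names, X_rows, w, marker = _prepare(data, weights)
    X, kinds, edges, _ = _build_core(X_rows, w, float(epsilon))
    return _assemble_network(data, names, X_rows, X, kinds, edges, w, marker)


def reduced_median_network(data: Sequence[HVSIHaplotype],
                           weights: Optional[Union[WeightScheme, dict]] = None
                           ) -> HaplotypeNetwork:
    """Build a reduced-median network of binary (derived/ancestral) data.

    Conflict-free data yield the unique perfect phylogeny. Where characters
    conflict, reticulations whose alternative resolutions differ in weighted
    cost are resolved in favour of recurrence of the lower-weight (faster)
    character; equal-cost reticulations are retained.
    """
    names, X_rows, w, marker = _prepare(data, weights)
    if marker != "binary" or not np.all((X_rows == 0) | (X_rows == 1)):
        raise ValueError("reduced-median networks need binary characters")
    X, kinds, edges, _ = _build_core(X_rows, w, epsilon=0.0)
    net = _assemble_network(data, names, X_rows, X, kinds, edges, w, marker)
    G = net.graph
    # resolve reticulations: drop one edge of the heaviest character in any
    # cycle whose characters are not all equally weighted
    while True:
        cycles = nx.cycle_basis(G)
        resolved = False
        for cyc in cycles:
            ring = [(cyc[i], cyc[(i + 1) % len(cyc)]) for i in range(len(cyc))]
            ring = [tuple(sorted(e)) for e in ring]
            costs = {e: G.edges[e]["weight"] for e in ring}
            if max(costs.values()) > min(costs.values()) + _TOL:
                heavy = max(costs.values())
                victim = max(e for e, c in costs.items()
                             if abs(c - heavy) <= _TOL)
                G.remove_edge(*victim)
                resolved = True
                break
        if not resolved:
            break
    # prune inferred nodes left dangling by the reduction
    while True:
        dangling = [n for n, d in G.nodes(data=True)
                    if d["kind"] != "observed" and G.degree(n) <= 1]
        if not dangling:
            break
        G.remove_nodes_from(dangling)
    net.core_edges = [(u, v, G.edges[u, v]["weight"])
                      for u, v in G.edges]
    return net


# ---------------------------------------------------------------------------
# iterative STR weighting


def _counts_to_weights(counts: dict[str, int], top: float = 10.0) -> dict[str, float]:
    cmin, cmax = min(counts.values()), max(counts.values())
    if cmax == cmin:
        return {k: top for k in counts}
    return {
        k: float(np.clip(round(top - (top - 1.0) * (c - cmin) / (cmax - cmin)),
                         1.0, top))
        for k, c in counts.items()
    }


def iterate_str_weights(profiles: Sequence[STRProfile],
                        initial_weight: float = 10.0,
                        max_iter: int = 10,
                        epsilon: float = 0
                        ) -> tuple[WeightScheme, HaplotypeNetwork]:
    """Iteratively re-weight STR loci from their network change counts.

    Starting from a flat weight (10) for every locus, the network is built,
    the occurrences of each locus' changes across the (full, reticulated)
    network are counted, counts are mapped linearly and in reverse onto
    [1, 10] (most changes -> 1, fewest -> 10, rounded), and the network is
    rebuilt, until the edge set is stable between successive iterations or
    ``max_iter`` is reached (then flagged unconverged, not an error).
    """
    distinct = {tuple(sorted(p.repeats.items())) for p in profiles}
    if len(distinct) < 2:
        raise ValueError("need at least two distinct profiles to weight")
    loci = sorted(profiles[0].repeats)
    weights = {l: float(initial_weight) for l in loci}

    def edge_set(net: HaplotypeNetwork):
        return {(min(u, v), max(u, v), net.graph.edges[u, v]["character"])
                for u, v in net.graph.edges}

    net_prev = median_joining_network(profiles, weights, epsilon)
    for iteration in range(1, max_iter + 1):
        counts = {l: 0 for l in loci}
        counts.update(Counter(d["character"]
                              for _, _, d in net_prev.graph.edges(data=True)))
        weights = _counts_to_weights(counts, top=float(initial_weight))
        net = median_joining_network(profiles, weights, epsilon)
        if edge_set(net) == edge_set(net_prev):
            return WeightScheme(weights, iteration, True), net
        net_prev = net
    return WeightScheme(weights, max_iter, False), net_prev


# ---------------------------------------------------------------------------
# rooting


class RootedTree:
    """A rooted most-parsimonious spanning tree extracted from a network.

    Edges point from parent to child and are single mutation steps; node
    attributes (``kind``, ``count``, ``samples``) are carried over from the
    network.
    """

    def __init__(self, digraph: nx.DiGraph, root: str,
                 characters: list[str], marker: str):
        self.graph = digraph
        self.root = root
        self.characters = characters
        self.marker = marker
        self._depth: Optional[dict[str, int]] = None

    def parent(self, node: str) -> Optional[str]:
        preds = list(self.graph.predecessors(node))
        return preds[0] if preds else None

    def children(self, node: str) -> list[str]:
        return sorted(self.graph.successors(node))

    def depth_steps(self, node: str) -> int:
        """Mutational steps (edge count) from the root to ``node``."""
        if self._depth is None:
            self._depth = {self.root: 0}
            for u, v in nx.bfs_edges(self.graph, self.root):
                self._depth[v] = self._depth[u] + 1
        return self._depth[node]

    def steps_between(self, ancestor: str, node: str) -> int:
        return self.depth_steps(node) - self.depth_steps(ancestor)

    def to_newick(self) -> str:
        import dendropy

        tree = dendropy.Tree()
        seed = tree.seed_node
        nodes = {self.root: seed}
        seed.label = self.root
        for u, v in nx.bfs_edges(self.graph, self.root):
            child = dendropy.Node(label=v)
            child.edge.length = 1.0
            nodes[u].add_child(child)
            nodes[v] = child
        return tree.as_string(schema="newick", suppress_rooting=False,
                              suppress_leaf_node_labels=False,
                              suppress_internal_node_labels=False).strip()


def _spanning_graph(network: HaplotypeNetwork) -> nx.Graph:
    """Most-parsimonious (minimum weighted cost) spanning tree of the
    network, expanded to single-step edges."""
    labels = sorted({u for e in network.core_edges for u in e[:2]})
    if not labels:
        labels = sorted(network.graph.nodes)
    idx = {l: i for i, l in enumerate(labels)}
    dsu = _DSU(len(labels))
    chosen = []
    for u, v, c in sorted(network.core_edges, key=lambda e: (e[2], e[0], e[1])):
        if dsu.find(idx[u]) != dsu.find(idx[v]):
            dsu.union(idx[u], idx[v])
            chosen.append((u, v))
    T = nx.Graph()
    names = network.characters
    wts = network.character_weights
    for lbl in labels:
        T.add_node(lbl, **{k: network.graph.nodes[lbl].get(k)
                           for k in ("kind", "count", "samples")})
    states = dict(network.states)
    for u, v in chosen:
        prev = u
        for inter, c in _step_path(states[u], states[v], network.marker):
            lbl = _label_of(inter, names, network.marker)
            if lbl not in T:
                T.add_node(lbl, kind="intermediate", count=0, samples=[])
                states[lbl] = inter.copy()
            T.add_edge(prev, lbl, character=names[c],
                       weight=float(wts[names[c]]))
            prev = lbl
    if T.number_of_nodes() and not nx.is_tree(T):
        T = nx.minimum_spanning_tree(T, weight="weight")
    network.states.update(states)
    return T


def _outgroup_state(network: HaplotypeNetwork, outgroup: Datum) -> np.ndarray:
    names = network.characters
    if isinstance(outgroup, STRProfile):
        missing = [n for n in names if n not in outgroup.repeats]
        if missing:
            raise ValueError(f"outgroup profile lacks loci {missing}")
        return np.array([outgroup.repeats[n] for n in names], dtype=np.int16)
    state = np.zeros(len(names), dtype=np.int16)
    index = {n: i for i, n in enumerate(names)}
    for pos, s in outgroup.variants:
        tok = f"{pos}{'d' if s == DELETION else s}"
        if tok in index:
            state[index[tok]] = 1
    return state


def root_network(network: HaplotypeNetwork, method: str = "midpoint",
                 outgroup: Optional[Datum] = None) -> RootedTree:
    """Root a network, returning its most-parsimonious spanning tree.

    ``midpoint``: the root is the tree node minimising the maximum weighted
    path length to any leaf (a midpoint falling inside an edge is snapped to
    the nearer incident node, so the root is always a haplotype state).
    ``outgroup_consensus``: the root is the network node nearest to the
    given outgroup profile (e.g. the per-locus modal repeats of the closest
    sister clade); observed nodes win ties.
    """
    if not nx.is_connected(network.graph):
        raise ValueError("cannot root a disconnected network")
    T = _spanning_graph(network)
    if T.number_of_nodes() == 0:
        raise ValueError("empty network")
    if T.number_of_nodes() == 1:
        root = next(iter(T.nodes))
    elif method == "midpoint":
        leaves = [n for n in T.nodes if T.degree(n) == 1]
        ecc = {n: 0.0 for n in T.nodes}
        for leaf in leaves:
            dist = nx.single_source_dijkstra_path_length(T, leaf,
                                                         weight="weight")
            for n, d in dist.items():
                ecc[n] = max(ecc[n], d)
        root = min(T.nodes, key=lambda n: (ecc[n], n))
    elif method == "outgroup_consensus":
        if outgroup is None:
            raise ValueError("outgroup_consensus rooting needs an outgroup")
        og = _outgroup_state(network, outgroup)
        w = np.array([network.character_weights[c]
                      for c in network.characters])
        best = None
        for n in sorted(T.nodes):
            d = float(np.abs(network.states[n].astype(float)
                             - og.astype(float)) @ w)
            key = (d, T.nodes[n].get("kind") != "observed", n)
            if best is None or key < best[0]:
                best = (key, n)
        root = best[1]
    else:
        raise ValueError(f"unknown rooting method {method!r}")
    D = nx.DiGraph()
    for n, d in T.nodes(data=True):
        D.add_node(n, **d)
    for u, v in nx.bfs_edges(T, root):
        D.add_edge(u, v, **T.edges[u, v])
    return RootedTree(D, root, list(network.characters), network.marker)
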