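"""Median-joining networks of haplotypes and ancestral/derived classification.

Within a selection signal, the distinct male haplotypes (focal breeds plus
outgroup males) are collapsed into nodes weighted by their counts, connected
into a median-joining network: the minimum-spanning network (MSN, all edges
tied for inclusion in some minimum spanning tree, within tolerance
``epsilon``) augmented iteratively with inferred median (consensus) nodes of
node triplets whenever adding one shortens the network.  The "favourable"
group is the most frequent haplotype plus every observed haplotype within
three mutations of it; the swept haplotype is classified *ancestral* when
the most common outgroup haplotype falls inside that group and *derived*
when it lies outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class HaploNode:
    haplotype: tuple            # binary states
    count: int = 0
    pop_counts: dict = field(default_factory=dict)
    is_median: bool = False
    is_outgroup_major: bool = False

    @property
    def key(self):
        return self.haplotype


def unique_haplotypes(haps, labels, window=None):
    """Collapse identical haplotype rows into counted nodes.

    ``haps`` is an (n_haplotypes, n_snps) binary matrix (one row per male
    haplotype), ``labels`` the population label per row, ``window`` an
    optional ``(first, last)`` closed column span.  Rows containing missing
    calls are excluded with a warning-level log.  Node per-population counts
    sum to the number of retained rows.
    """
    haps = np.asarray(haps)
    if window is not None:
        haps = haps[:, window[0]:window[1] + 1]
    nodes: dict[tuple, HaploNode] = {}
    n_dropped = 0
    for row, lab in zip(haps, labels):
        if (row == MISSING).any():
            n_dropped += 1
            continue
        key = tuple(int(x) for x in row)
        node = nodes.get(key)
        if node is None:
            node = nodes[key] = HaploNode(haplotype=key)
        node.count += 1
        node.pop_counts[lab] = node.pop_counts.get(lab, 0) + 1
    if n_dropped:
        import warnings

        warnings.warn(f"excluded {n_dropped} haplotypes with missing calls")
    return list(nodes.values())


def _hamming(a, b) -> int:
    return int(sum(x != y for x, y in zip(a, b)))


def minimum_spanning_network(keys, epsilon: int = 0) -> nx.Graph:
    """All edges within ``epsilon`` of feasibility for a minimum spanning tree.

    Kruskal-style sweep over ascending Hamming distances: an edge of weight
    ``w`` joins the network if its endpoints are in different connected
    components once all edges of weight < ``w - epsilon`` are in place.
    With ``epsilon = 0`` this is the classic minimum-spanning network.
    """
    g = nx.Graph()
    g.add_nodes_from(keys)
    if len(keys) < 2:
        return g
    edges = sorted(
        ((_hamming(a, b), a, b) for a, b in combinations(keys, 2)),
        key=lambda e: e[0],
    )
    for w, a, b in edges:
        short = nx.Graph()
        short.add_nodes_from(keys)
        short.add_edges_from((x, y) for ww, x, y in edges if ww < w - epsilon)
        if not nx.has_path(short, a, b):
            g.add_edge(a, b, weight=w)
    return g


def _consensus(a, b, c):
    return tuple(int(round((x + y + z) >= 2)) for x, y, z in zip(a, b, c))


def _network_length(g: nx.Graph) -> int:
    t = nx.minimum_spanning_tree(g, weight="weight")
    return int(sum(d["weight"] for _, _, d in t.edges(data=True)))


@dataclass
class HaploNetwork:
    nodes: list                       # HaploNode, observed + medians
    graph: nx.Graph                   # keys -> edges with 'weight'

    @property
    def connected(self) -> bool:
        return nx.is_connected(self.graph) if len(self.graph) else True

    def node_by_key(self, key):
        for n in self.nodes:
            if n.key == key:
                return n
        raise KeyError(key)


def median_joining_network(nodes, epsilon: int = 0) -> HaploNetwork:
    """Bandelt median-joining network over observed haplotype nodes.

    Iterates: build the minimum-spanning network over the current node set;
    propose the consensus (majority-state) vector of every node triplet; add
    any median that strictly shortens the minimum spanning tree; repeat
    until no median helps.  Median nodes carry count 0.  The result is
    connected by construction.
    """
    if len(nodes) < 1:
        raise ValueError("need at least one haplotype node")
    observed = {n.key: n for n in nodes}
    keys = set(observed)
    if len(keys) == 1:
        g = nx.Graph()
        g.add_nodes_from(keys)
        return HaploNetwork(nodes=list(nodes), graph=g)
    medians: dict[tuple, HaploNode] = {}
    for _ in range(64):  # convergence bound; tiny haplotype sets in practice
        current = list(keys | set(medians))
        full = nx.Graph()
        full.add_nodes_from(current)
        for a, b in combinations(current, 2):
            full.add_edge(a, b, weight=_hamming(a, b))
        base_len = _network_length(full)
        best = None
        for a, b, c in combinations(current, 3):
            m = _consensus(a, b, c)
            if m in current or m in (a, b, c):
                continue
            trial = full.copy()
            for k in current:
                trial.add_edge(m, k, weight=_hamming(m, k))
            new_len = _network_length(trial)
            # a median must strictly shorten the network (epsilon relaxes
            # only edge retention in the MSN, not median acceptance)
            if new_len < base_len and (best is None or new_len < best[0]):
                best = (new_len, m)
        if best is None:
            break
        medians[best[1]] = HaploNode(haplotype=best[1], is_median=True)
    # final graph: MSN over observed + retained medians, pruning useless medians
    all_keys = list(keys | set(medians))
    g = minimum_spanning_network(all_keys, epsilon=epsilon)
    # prune median nodes that no longer shorten or connect the network
    changed = True
    while changed:
        changed = False
        for m in [k for k in g.nodes if k in medians]:
            rest = [k for k in g.nodes if k != m]
            sub = minimum_spanning_network(rest, epsilon=epsilon)
            if _network_length(sub) <= _network_length(g):
                g = sub
                del medians[m]
                changed = True
                break
    out_nodes = list(nodes) + list(medians.values())
    return HaploNetwork(nodes=out_nodes, graph=g)


def mark_outgroup_major(net: HaploNetwork, outgroup_label: str = "mouflon"):
    """Flag the node(s) carrying the largest outgroup count."""
    best = 0
    for n in net.nodes:
        n.is_outgroup_major = False
        best = max(best, n.pop_counts.get(outgroup_label, 0))
    if best == 0:
        raise ValueError("no outgroup haplotypes in the network")
    winners = [n for n in net.nodes if n.pop_counts.get(outgroup_label, 0) == best]
    for n in winners:
        n.is_outgroup_major = True
    return winners


def favourable_group(net: HaploNetwork, max_mutations: int = 3, distance: str = "path"):
    """The most frequent haplotype plus neighbours within ``max_mutations``.

    ``distance="path"`` measures mutation distance along shortest network
    paths (median nodes may lie on the path); ``"hamming"`` uses direct
    sequence distance.  Ties for the most frequent node seed the group
    jointly (the tie is reported via the returned ``seeds``).

    Returns ``(group_nodes, seeds)`` with only observed nodes in the group.
    """
    observed = [n for n in net.nodes if not n.is_median]
    top = max(n.count for n in observed)
    seeds = [n for n in observed if n.count == top]
    group = set()
    for seed in seeds:
        for n in observed:
            if n.key == seed.key:
                group.add(n.key)
                continue
            if distance == "hamming":
                d = _hamming(seed.key, n.key)
            else:
                try:
                    d = nx.shortest_path_length(net.graph, seed.key, n.key, weight="weight")
                except nx.NetworkXNoPath:
                    continue
            if d <= max_mutations:
                group.add(n.key)
    return [n for n in observed if n.key in group], seeds


def classify_origin(net: HaploNetwork, group, outgroup_label: str = "mouflon") -> str:
    """Call the swept haplotype ancestral or derived.

    *ancestral* when the most common outgroup haplotype is inside the
    favourable group, *derived* when outside, *ambiguous* when outgroup
    ties straddle the boundary.
    """
    winners = mark_outgroup_major(net, outgroup_label)
    group_keys = {n.key for n in group}
    inside = [w for w in winners if w.key in group_keys]
    if len(inside) == len(winners):
        return "ancestral"
    if not inside:
        return "derived"
    return "ambiguous"


def breed_evenness(group, net: HaploNetwork, exclude=("mouflon",)) -> pd.DataFrame:
    """Per-population share of haplotypes falling inside the favourable group.

    share(pop) = (pop haplotypes in group) / (pop haplotypes in network).
    The max/min share ratio summarizes evenness (1 = perfectly even;
    populations with zero share make the ratio infinite).
    """
    if not group:
        raise ValueError("favourable group is empty")
    tot: dict[str, int] = {}
    ing: dict[str, int] = {}
    group_keys = {n.key for n in group}
    for n in net.nodes:
        for pop, c in n.pop_counts.items():
            if pop in exclude:
                continue
            tot[pop] = tot.get(pop, 0) + c
            if n.key in group_keys:
                ing[pop] = ing.get(pop, 0) + c
    rows = [(pop, ing.get(pop, 0), t, ing.get(pop, 0) / t) for pop, t in sorted(tot.items())]
    df = pd.DataFrame(rows, columns=["population", "in_group", "total", "share"])
    shares = df["share"].to_numpy()
    df.attrs["evenness_ratio"] = float(shares.max() / shares.min()) if shares.min() > 0 else float("inf")
    return df


def to_edge_list(net: HaploNetwork) -> pd.DataFrame:
    keymap = {n.key: i for i, n in enumerate(net.nodes)}
    rows = [
        (keymap[a], keymap[b], d["weight"])
        for a, b, d in net.graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])


def nodes_frame(net: HaploNetwork) -> pd.DataFrame:
    pops = sorted({p for n in net.nodes for p in n.pop_counts})
    rows = []
    for i, n in enumerate(net.nodes):
        rows.append(
            [i, "".join(map(str, n.haplotype)), n.count, n.is_median, n.is_outgroup_major]
            + [n.pop_counts.get(p, 0) for p in pops]
        )
    return pd.DataFrame(rows, columns=["node", "haplotype", "count", "is_median", "is_outgroup_major"] + pops)


def write_gml(net: HaploNetwork, path):
    g = nx.Graph()
    keymap = {n.key: i for i, n in enumerate(net.nodes)}
    for n in net.nodes:
        g.add_node(keymap[n.key], haplotype="".join(map(str, n.haplotype)),
                   count=n.count, is_median=int(n.is_median))
    for a, b, d in net.graph.edges(data=True):
        g.add_edge(keymap[a], keymap[b], weight=int(d["weight"]))
    nx.write_gml(g, str(path))
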