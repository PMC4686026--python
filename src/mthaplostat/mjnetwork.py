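"""Median-joining haplotype networks.

The network is built over haplotype profiles (states at the shared
polymorphic columns) under Hamming distance, with the gap "-" treated as a
fifth character state.  Construction alternates two steps until it
stabilises:

1. the epsilon-relaxed minimum spanning network (MSN) over the current node
   set — the union of all minimum spanning trees, relaxed so that a link
   u–v of length d is kept whenever d <= bottleneck(u, v) + epsilon, where
   bottleneck(u, v) is the largest step on the minimax path between u and v;
2. for every triple of nodes connected within the MSN, the column-wise
   majority-consensus median is added as an unobserved "median vector"
   node whenever it strictly shortens the local three-node subtree.

Obsolete median vectors (unobserved nodes of degree <= 1) are pruned and the
MSN is rebuilt, so every retained median lies on a path between observed
haplotypes.  Ties (median state when all three parents disagree; insertion
order) are broken lexicographically on sorted node-name triples, making the
construction deterministic for a fixed input ordering.
"""

from __future__ import annotations

import itertools
from typing import Mapping

import networkx as nx

from .io import HaplotypeCatalog


class NetworkError(ValueError):
    pass


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _msn_edges(
    profiles: Mapping[str, str], epsilon: int
) -> list[tuple[str, str, int]]:
    """Epsilon-relaxed minimum spanning network over the given profiles."""
    names = sorted(profiles)
    dist = {
        (u, v): hamming(profiles[u], profiles[v])
        for u, v in itertools.combinations(names, 2)
    }
    # A minimum spanning tree gives every pairwise bottleneck (minimax) value.
    complete = nx.Graph()
    complete.add_nodes_from(names)
    for (u, v), d in dist.items():
        complete.add_edge(u, v, weight=d)
    mst = nx.minimum_spanning_tree(complete, algorithm="kruskal")
    bottleneck: dict[tuple[str, str], int] = {}
    for root in names:
        # DFS over the MST tracking the max edge weight seen from root.
        stack = [(root, None, 0)]
        while stack:
            node, parent, best = stack.pop()
            if node != root:
                key = (root, node) if root < node else (node, root)
                bottleneck[key] = best
            for nb in mst.neighbors(node):
                if nb != parent:
                    w = mst[node][nb]["weight"]
                    stack.append((nb, node, max(best, w)))
    edges = []
    for (u, v), d in dist.items():
        if d <= bottleneck[(u, v)] + epsilon:
            edges.append((u, v, d))
    return edges


def _majority_median(a: str, b: str, c: str) -> str:
    """Column-wise majority state of three profiles; 3-way ties take the
    first profile's state (callers order profiles lexicographically)."""
    out = []
    for x, y, z in zip(a, b, c):
        if y == z:
            out.append(y)
        else:
            out.append(x)  # covers x==y, x==z and the all-distinct tie
    return "".join(out)


def median_joining_network(
    catalog: HaplotypeCatalog,
    counts: Mapping[str, int] | None = None,
    epsilon: int = 0,
    region_shares: Mapping[str, Mapping[str, float]] | None = None,
    max_rounds: int = 50,
) -> nx.Graph:
    """Median-joining network over the catalog's haplotypes.

    Returns an undirected :class:`networkx.Graph` whose nodes carry
    ``kind`` ("observed" or "median"), ``count`` (0 for median vectors) and
    optional per-region share attributes; edges carry ``weight`` = number of
    mutational steps (>= 1).
    """
    if len(catalog) < 2:
        raise NetworkError("a network needs at least 2 haplotypes")
    if epsilon < 0:
        raise NetworkError("epsilon must be non-negative")

    profiles: dict[str, str] = {n: catalog.states[n] for n in catalog.names}
    observed = set(catalog.names)
    vectors = {v for v in profiles.values()}
    mv_serial = itertools.count(1)

    for _ in range(max_rounds):
        edges = _msn_edges(profiles, epsilon)
        adjacency: dict[str, set[str]] = {n: set() for n in profiles}
        for u, v, _d in edges:
            adjacency[u].add(v)
            adjacency[v].add(u)

        # Feasible triples: connected as a path or triangle within the MSN,
        # visited in lexicographic order of the sorted name triple.
        added = False
        for trip in itertools.combinations(sorted(profiles), 3):
            a, b, c = trip
            n_links = sum(
                1 for u, v in itertools.combinations(trip, 2) if v in adjacency.get(u, ())
            )
            if n_links < 2:
                continue
            med = _majority_median(profiles[a], profiles[b], profiles[c])
            if med in vectors:
                continue
            steiner = sum(hamming(med, profiles[x]) for x in trip)
            pairwise = [
                hamming(profiles[u], profiles[v])
                for u, v in itertools.combinations(trip, 2)
            ]
            local_mst = sum(pairwise) - max(pairwise)
            if steiner < local_mst:
                name = f"mv{next(mv_serial)}"
                profiles[name] = med
                vectors.add(med)
                added = True
        if not added:
            break
        # Prune obsolete median vectors: unobserved nodes that end up with
        # degree <= 1 after the next MSN rebuild contribute nothing.
        while True:
            edges = _msn_edges(profiles, epsilon)
            degree: dict[str, int] = {n: 0 for n in profiles}
            for u, v, _d in edges:
                degree[u] += 1
                degree[v] += 1
            obsolete = [
                n for n in profiles if n not in observed and degree[n] <= 1
            ]
            if not obsolete:
                break
            for n in obsolete:
                vectors.discard(profiles[n])
                del profiles[n]

    graph = nx.Graph()
    counts = counts or {}
    for name, vec in profiles.items():
        attrs = {
            "kind": "observed" if name in observed else "median",
            "count": int(counts.get(name, 0)) if name in observed else 0,
            "profile": vec,
        }
        if region_shares and name in region_shares:
            for region, share in region_shares[name].items():
                attrs[f"share_{region}"] = float(share)
        graph.add_node(name, **attrs)
    for u, v, d in _msn_edges(profiles, epsilon):
        graph.add_edge(u, v, weight=int(d))
    return graph


def export_network(graph: nx.Graph, path, fmt: str = "tsv") -> None:
    """Write the network as an edge-list TSV (with a node block) or GraphML."""
    if fmt == "graphml":
        nx.write_graphml(graph, str(path))
        return
    if fmt != "tsv":
        raise NetworkError(f"unknown network format {fmt!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#nodes\n")
        attr_keys = sorted({k for _, d in graph.nodes(data=True) for k in d})
        fh.write("name\t" + "\t".join(attr_keys) + "\n")
        for name in sorted(graph.nodes):
            data = graph.nodes[name]
            fh.write(
                name + "\t" + "\t".join(str(data.get(k, "")) for k in attr_keys) + "\n"
            )
        fh.write("#edges\n")
        fh.write("source\ttarget\tweight\n")
        for u, v, d in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['weight']}\n")


def read_network(path, fmt: str = "tsv") -> nx.Graph:
    """Re-import a network written by :func:`export_network`."""
    if fmt == "graphml":
        return nx.read_graphml(str(path))
    if fmt != "tsv":
        raise NetworkError(f"unknown network format {fmt!r}")
    graph = nx.Graph()
    section = None
    header: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line == "#nodes":
                section, header = "nodes", []
                continue
            if line == "#edges":
                section, header = "edges", []
                continue
            cells = line.split("\t")
            if not header:
                header = cells
                continue
            if section == "nodes":
                name, values = cells[0], cells[1:]
                attrs = {}
                for key, raw in zip(header[1:], values):
                    if key == "count":
                        attrs[key] = int(raw)
                    elif key.startswith("share_"):
                        attrs[key] = float(raw) if raw else 0.0
                    else:
                        attrs[key] = raw
                graph.add_node(name, **attrs)
            elif section == "edges":
                graph.add_edge(cells[0], cells[1], weight=int(cells[2]))
    return graph
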