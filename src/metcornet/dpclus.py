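"""DPClus: density- and periphery-tracking graph clustering.

DPClus extracts densely connected node sets from a simple undirected graph
by seeded growth.  Edges are weighted by the number of common neighbours of
their endpoints and nodes by the sum of incident edge weights; the heaviest
node seeds a cluster, which grows by admitting periphery nodes that keep
the cluster density ``d = 2E_k / (|N_k| (|N_k| - 1))`` at or above ``d_in``
and whose cluster property

    cp(n, k) = E_nk / (d_k * |N_k|)

(edges from candidate n into cluster k, normalized by cluster density times
cluster size) is at least ``cp_in``.  Emitted clusters are removed from the
working graph and the loop repeats until no edges remain.  In overlapping
mode each emitted cluster is additionally extended in the original graph by
re-admitting removed neighbours that still meet both conditions, so
clusters may share nodes — mirroring the overlap of real metabolic
pathways.

Tie-breaking is totally ordered (weight, then degree, then lexicographic
id), so results are deterministic.  This is a reconstruction of the
published algorithm's behaviour from its defining quantities; defaults are
cp_in = 0.5, d_in = 0.5, overlapping on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "DPClusParams",
    "Cluster",
    "edge_node_weights",
    "cluster_density",
    "cluster_property",
    "run_dpclus",
    "unclustered_nodes",
    "cluster_adjacency",
]


@dataclass
class DPClusParams:
    cp_in: float = 0.5
    d_in: float = 0.5
    overlapping: bool = True
    min_cluster_size: int = 2

    def validate(self) -> None:
        if not (0.0 < self.cp_in <= 1.0):
            raise ValueError("cp_in must be in (0, 1]")
        if not (0.0 < self.d_in <= 1.0):
            raise ValueError("d_in must be in (0, 1]")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class Cluster:
    """One emitted cluster with its growth provenance.

    ``members`` includes overlapping-mode extensions; ``extended_members``
    is the subset added during extension.  ``density`` is measured within
    the original graph.  ``trace`` records (node, cp, density-after) at
    each growth/extension step, for auditing the admission conditions.
    """

    members: frozenset
    density: float
    seed_node: object
    extended_members: frozenset = frozenset()
    trace: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def core_members(self) -> frozenset:
        return self.members - self.extended_members


def edge_node_weights(graph: nx.Graph):
    """Common-neighbour edge weights and summed node weights."""
    adj = {n: set(graph[n]) for n in graph}
    edge_w = {}
    node_w = {n: 0 for n in graph}
    for u, v in graph.edges:
        w = len(adj[u] & adj[v])
        edge_w[(u, v)] = edge_w[(v, u)] = w
        node_w[u] += w
        node_w[v] += w
    return edge_w, node_w


def cluster_density(cluster, graph: nx.Graph) -> float:
    """2E / (N (N-1)) within the node set; singletons count as density 1."""
    k = len(cluster)
    if k < 2:
        return 1.0
    e = graph.subgraph(cluster).number_of_edges()
    return 2.0 * e / (k * (k - 1))


def cluster_property(node, cluster, graph: nx.Graph) -> float:
    """cp = E_nk / (d_k * |N_k|) for a candidate node outside the cluster."""
    if node in cluster:
        raise ValueError("candidate node is already a cluster member")
    d_k = cluster_density(cluster, graph)
    if d_k <= 0:
        raise ValueError("cluster density is zero; cp undefined")
    e_nk = sum(1 for nb in graph[node] if nb in cluster)
    return e_nk / (d_k * len(cluster))


def _edges_into(node, cluster, graph) -> int:
    return sum(1 for nb in graph[node] if nb in cluster)


def _grow(cluster: set, graph: nx.Graph, node_w, params: DPClusParams, trace):
    """Admit qualifying periphery nodes until none qualifies.

    Candidates are the cluster's neighbours ordered by (edges-into-cluster
    desc, node weight desc, id asc); the first candidate keeping density
    >= d_in with cp >= cp_in is added, then the periphery is recomputed.
    """
    n_internal = graph.subgraph(cluster).number_of_edges()
    while True:
        periphery = set()
        for c in cluster:
            periphery.update(graph[c])
        periphery -= cluster
        if not periphery:
            return
        d_k = 1.0 if len(cluster) < 2 else (
            2.0 * n_internal / (len(cluster) * (len(cluster) - 1))
        )
        candidates = sorted(
            periphery,
            key=lambda n: (-_edges_into(n, cluster, graph),
                           -node_w.get(n, 0), str(n)),
        )
        added = False
        for cand in candidates:
            e_in = _edges_into(cand, cluster, graph)
            k_new = len(cluster) + 1
            d_new = 2.0 * (n_internal + e_in) / (k_new * (k_new - 1))
            if d_new < params.d_in:
                continue
            cp = e_in / (d_k * len(cluster))
            if cp < params.cp_in:
                continue
            cluster.add(cand)
            n_internal += e_in
            trace.append((cand, cp, d_new))
            added = True
            break
        if not added:
            return


def run_dpclus(graph: nx.Graph, params: DPClusParams | None = None) -> list[Cluster]:
    """Extract clusters from a simple undirected graph.

    Loops on a working copy until it is edgeless: re-weight, seed at the
    heaviest node (ties: higher degree, then lexicographic id), grow,
    emit if the cluster reaches ``min_cluster_size``, then remove its core
    members.  In overlapping mode each emitted cluster is extended in the
    original graph (extension never alters the working copy).
    """
    params = params or DPClusParams()
    params.validate()
    if any(u == v for u, v in graph.edges):
        raise ValueError("graph must be simple (no self-loops)")
    work = nx.Graph(graph)
    orig_node_w = edge_node_weights(graph)[1] if params.overlapping else None
    clusters: list[Cluster] = []

    while work.number_of_edges() > 0:
        _, node_w = edge_node_weights(work)
        seed = min(
            work.nodes,
            key=lambda n: (-node_w[n], -work.degree(n), str(n)),
        )
        trace: list = []
        cluster = {seed}
        _grow(cluster, work, node_w, params, trace)
        core = frozenset(cluster)

        if len(core) >= params.min_cluster_size:
            members = set(core)
            extended: set = set()
            if params.overlapping:
                ext_trace: list = []
                _extend(members, extended, graph, orig_node_w, params, ext_trace)
                trace = trace + ext_trace
            clusters.append(Cluster(
                members=frozenset(members),
                density=cluster_density(members, graph),
                seed_node=seed,
                extended_members=frozenset(extended),
                trace=trace,
            ))
        work.remove_nodes_from(core)
    return clusters


def _extend(members: set, extended: set, graph: nx.Graph, node_w,
            params: DPClusParams, trace):
    """Overlapping-mode extension, evaluated in the original graph."""
    n_internal = graph.subgraph(members).number_of_edges()
    while True:
        periphery = set()
        for c in members:
            periphery.update(graph[c])
        periphery -= members
        if not periphery:
            return
        d_k = 1.0 if len(members) < 2 else (
            2.0 * n_internal / (len(members) * (len(members) - 1))
        )
        candidates = sorted(
            periphery,
            key=lambda n: (-_edges_into(n, members, graph),
                           -node_w.get(n, 0), str(n)),
        )
        added = False
        for cand in candidates:
            e_in = _edges_into(cand, members, graph)
            k_new = len(members) + 1
            d_new = 2.0 * (n_internal + e_in) / (k_new * (k_new - 1))
            if d_new < params.d_in:
                continue
            cp = e_in / (d_k * len(members))
            if cp < params.cp_in:
                continue
            members.add(cand)
            extended.add(cand)
            n_internal += e_in
            trace.append((cand, cp, d_new))
            added = True
            break
        if not added:
            return


def unclustered_nodes(graph: nx.Graph, clusters) -> frozenset:
    """Nodes of the graph belonging to no emitted cluster."""
    covered: set = set()
    for c in clusters:
        covered |= set(c.members)
    return frozenset(graph.nodes) - covered


def cluster_adjacency(clusters, graph: nx.Graph) -> nx.Graph:
    """Cluster-level graph: clusters are adjacent iff they share a member
    or at least one original edge runs between them."""
    g = nx.Graph()
    g.add_nodes_from(range(len(clusters)))
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            mi, mj = clusters[i].members, clusters[j].members
            if mi & mj:
                g.add_edge(i, j, shared=len(mi & mj))
                continue
            n_bridge = sum(
                1 for u in mi for v in graph[u] if v in mj
            )
            if n_bridge:
                g.add_edge(i, j, bridges=n_bridge)
    return g
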