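"""Structural comparison of phenotype-specific correlation networks.

Given posterior-median networks and a set of important seed taxa, a
thresholded subnetwork is extracted around the seeds (nodes strongly
correlated with a seed, edges above the absolute-weight threshold),
partitioned into communities by weighted modularity maximization, and
summarized by node / edge / inter-cluster link counts.

Modularity uses absolute edge weights as connection strengths (edge signs
are kept for reporting only).  Community detection is exact (exhaustive
set-partition enumeration with pruning) for small graphs and greedy
agglomerative (Clauset-Newman-Moore) above that.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from networkx.algorithms.community import greedy_modularity_communities, modularity

from .graph_dataset import CorrelationNetwork

#: Largest node count for which exact modularity enumeration is attempted
#: (Bell(10) ~ 1.2e5 partitions; beyond that greedy agglomeration is used).
EXACT_MODULARITY_MAX_NODES = 10


@dataclass
class NetworkComparison:
    """Structural counts for a pair of extracted subnetworks."""

    seeds: list[int]
    threshold: float
    stats_a: dict
    stats_b: dict


def extract_subnetwork(
    network: CorrelationNetwork, seeds, threshold: float
) -> CorrelationNetwork:
    """Seed neighborhood at an absolute-correlation threshold.

    Keeps the seed nodes plus every node with |edge| > threshold to a seed,
    then keeps all edges among retained nodes with |weight| > threshold.
    Non-seed nodes left isolated are dropped; isolated seeds are kept.
    """
    seeds = sorted(int(s) for s in seeds)
    p = network.n_nodes
    for s in seeds:
        if not 0 <= s < p:
            raise ValueError(f"unknown seed node {s}")
    A = network.adjacency
    strong = np.abs(A) > threshold
    neighbor = np.zeros(p, dtype=bool)
    neighbor[seeds] = True
    for s in seeds:
        neighbor |= strong[s]
    kept_edges = strong & np.outer(neighbor, neighbor)
    # isolated non-seed nodes are dropped
    keep = neighbor & (kept_edges.any(axis=1) | np.isin(np.arange(p), seeds))
    idx = np.flatnonzero(keep)
    sub = A[np.ix_(idx, idx)] * kept_edges[np.ix_(idx, idx)]
    return CorrelationNetwork(
        taxon_ids=[network.taxon_ids[i] for i in idx],
        adjacency=sub,
        label=network.label,
    )


def _abs_graph(network: CorrelationNetwork) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(network.n_nodes))
    A = network.adjacency
    for i in range(network.n_nodes):
        for j in range(i + 1, network.n_nodes):
            if A[i, j] != 0:
                G.add_edge(i, j, weight=abs(A[i, j]))
    return G


def _partitions(items: list[int]):
    """All set partitions of ``items`` (recursive; first element anchored)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def _exact_communities(G: nx.Graph) -> list[set]:
    best_q, best = -np.inf, None
    nodes = list(G.nodes)
    for part in _partitions(nodes):
        q = modularity(G, [set(c) for c in part], weight="weight")
        if q > best_q + 1e-12:
            best_q, best = q, part
    return [set(c) for c in best]


def detect_communities(
    network: CorrelationNetwork, exact_max_nodes: int = EXACT_MODULARITY_MAX_NODES
) -> list[int]:
    """Partition nodes by maximizing weighted modularity on |weights|.

    Returns a cluster index per node.  Exact enumeration for graphs up to
    ``exact_max_nodes`` nodes, greedy modularity agglomeration otherwise.
    """
    if network.n_nodes == 0:
        raise ValueError("cannot detect communities of an empty network")
    G = _abs_graph(network)
    if G.number_of_edges() == 0:
        return list(range(network.n_nodes))
    if network.n_nodes <= exact_max_nodes:
        comms = _exact_communities(G)
    else:
        comms = [set(c) for c in greedy_modularity_communities(G, weight="weight")]
    assignment = [0] * network.n_nodes
    for ci, comm in enumerate(comms):
        for v in comm:
            assignment[v] = ci
    return assignment


def _network_stats(network: CorrelationNetwork, exact_max_nodes: int) -> dict:
    A = network.adjacency
    n_nodes = network.n_nodes
    iu = np.triu_indices(n_nodes, k=1)
    n_edges = int(np.count_nonzero(A[iu]))
    clusters = detect_communities(network, exact_max_nodes)
    inter = 0
    for i, j in zip(*iu):
        if A[i, j] != 0 and clusters[i] != clusters[j]:
            inter += 1
    return {
        "n_nodes": n_nodes,
        "n_edges": n_edges,
        "clusters": clusters,
        "n_clusters": len(set(clusters)),
        "inter_cluster_links": inter,
        "taxon_ids": list(network.taxon_ids),
    }


def compare_networks(
    a: CorrelationNetwork,
    b: CorrelationNetwork,
    seeds,
    threshold: float = 0.4,
    exact_max_nodes: int = EXACT_MODULARITY_MAX_NODES,
) -> NetworkComparison:
    """Extract, cluster and count both networks around the same seed set."""
    if a.taxon_ids != b.taxon_ids:
        raise ValueError("networks must share the taxon universe")
    sub_a = extract_subnetwork(a, seeds, threshold)
    sub_b = extract_subnetwork(b, seeds, threshold)
    return NetworkComparison(
        seeds=sorted(int(s) for s in seeds),
        threshold=threshold,
        stats_a=_network_stats(sub_a, exact_max_nodes),
        stats_b=_network_stats(sub_b, exact_max_nodes),
    )
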