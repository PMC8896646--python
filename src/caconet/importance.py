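"""Explaining network predictions by node knock-out.

Knocking out a node sets every edge weight incident to it to zero (the
taxon becomes uncorrelated with the rest of the community).  The effect on
the classifier is measured by the log-odds ratio

    LOR = logit(p_knockout) - logit(p),

where p is the predicted 'diseased' probability of the intact network.
Single-node scores rank taxa individually; a greedy forward search builds
the n most important nodes jointly (each step adds the node whose
cumulative knock-out maximizes |LOR| against the intact network), and
per-run searches are aggregated into frequency-of-occurrence tables
across repeated classifier runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dgcnn import DgcnnModel, forward
from .graph_dataset import CorrelationNetwork

#: Softmax saturation guard: probabilities are clamped to this band before
#: the logit so LORs stay finite for near-perfect classifiers.
PROB_CLAMP = 1e-7


@dataclass
class ImportanceResult:
    """Greedy knock-out search output for one network."""

    network_id: str | int
    ordered_nodes: list[int]
    lor_per_step: list[float]
    single_node_lor: list[tuple[int, float]] | None = None


@dataclass
class FrequencyTable:
    """Occurrence counts of nodes in per-run k-node importance sets."""

    k: int
    counts: dict[int, int] = field(default_factory=dict)
    n_runs: int = 0


def _logit(p: float) -> float:
    p = min(max(p, PROB_CLAMP), 1.0 - PROB_CLAMP)
    return float(np.log(p / (1.0 - p)))


def knockout_nodes(network: CorrelationNetwork, nodes) -> CorrelationNetwork:
    """Zero the rows and columns of every node in ``nodes``; idempotent."""
    nodes = list(nodes)
    p = network.n_nodes
    for v in nodes:
        if not 0 <= int(v) < p:
            raise ValueError(f"unknown node index {v} (network has {p} nodes)")
    out = network.copy()
    idx = np.asarray(nodes, dtype=int)
    if idx.size:
        out.adjacency[idx, :] = 0.0
        out.adjacency[:, idx] = 0.0
    return out


def log_odds_ratio(model: DgcnnModel, network: CorrelationNetwork, nodes) -> float:
    """logit(p after knocking out ``nodes``) - logit(p intact)."""
    p0 = forward(model, network).p_disease
    p1 = forward(model, knockout_nodes(network, nodes)).p_disease
    return _logit(p1) - _logit(p0)


def _all_singleton_lors(model: DgcnnModel, network: CorrelationNetwork) -> np.ndarray:
    """Vectorized LORs of every singleton knock-out (one batched forward)."""
    p = network.n_nodes
    stack = np.repeat(network.adjacency[None], p, axis=0)
    for v in range(p):
        stack[v, v, :] = 0.0
        stack[v, :, v] = 0.0
    probs = model.predict_proba(np.concatenate([network.adjacency[None], stack]))
    logits = np.log(np.clip(probs[:, 1], PROB_CLAMP, 1 - PROB_CLAMP)
                    / np.clip(1 - probs[:, 1], PROB_CLAMP, 1 - PROB_CLAMP))
    return logits[1:] - logits[0]


def single_node_importance(
    model: DgcnnModel, network: CorrelationNetwork
) -> list[tuple[int, float]]:
    """Every node scored by |LOR| of its singleton knock-out, descending;
    ties broken by ascending node index."""
    lors = _all_singleton_lors(model, network)
    order = np.lexsort((np.arange(lors.size), -np.abs(lors)))
    return [(int(v), float(lors[v])) for v in order]


def greedy_n_node(
    model: DgcnnModel, network: CorrelationNetwork, n: int,
    network_id: str | int = 0,
) -> ImportanceResult:
    """Greedy n-node importance search.

    Step 1 picks the node with the largest singleton |LOR|; step i adds the
    node maximizing the |LOR| of the cumulative knock-out set, always
    measured against the intact network's prediction.  Ties break toward
    the smaller node index.
    """
    p = network.n_nodes
    if not 1 <= n <= p:
        raise ValueError(f"n must lie in [1, {p}]")
    base_logit = _logit(forward(model, network).p_disease)
    singles = single_node_importance(model, network)
    chosen = [singles[0][0]]
    lor_steps = [abs(singles[0][1])]
    remaining = [v for v in range(p) if v != chosen[0]]
    while len(chosen) < n:
        stack = []
        for v in remaining:
            net_v = knockout_nodes(network, chosen + [v])
            stack.append(net_v.adjacency)
        probs = model.predict_proba(np.asarray(stack))[:, 1]
        logits = np.log(np.clip(probs, PROB_CLAMP, 1 - PROB_CLAMP)
                        / np.clip(1 - probs, PROB_CLAMP, 1 - PROB_CLAMP))
        lors = np.abs(logits - base_logit)
        best = int(np.lexsort((np.asarray(remaining), -lors))[0])
        chosen.append(remaining[best])
        lor_steps.append(float(lors[best]))
        remaining.pop(best)
    return ImportanceResult(
        network_id=network_id,
        ordered_nodes=chosen,
        lor_per_step=lor_steps,
        single_node_lor=singles,
    )


def run_importance(
    model: DgcnnModel,
    networks: list[CorrelationNetwork],
    n: int,
    subsample: int = 50,
    seed: int = 0,
) -> ImportanceResult:
    """Run-level greedy importance over a random subsample of networks.

    At each greedy step the objective is the median across the subsampled
    networks of the cumulative knock-out |LOR| (against each network's own
    intact prediction); this produces one nested chain of node sets per
    classifier run, matching the selection of the top k nodes by largest
    median absolute LOR.
    """
    rng = np.random.default_rng(seed)
    if subsample < len(networks):
        idx = rng.choice(len(networks), size=subsample, replace=False)
        nets = [networks[i] for i in idx]
    else:
        nets = list(networks)
    p = nets[0].n_nodes
    if not 1 <= n <= p:
        raise ValueError(f"n must lie in [1, {p}]")
    base = np.array([_logit(forward(model, net).p_disease) for net in nets])
    chosen: list[int] = []
    lor_steps: list[float] = []
    remaining = list(range(p))
    while len(chosen) < n:
        med = np.empty(len(remaining))
        for j, v in enumerate(remaining):
            stack = np.asarray([knockout_nodes(net, chosen + [v]).adjacency for net in nets])
            probs = model.predict_proba(stack)[:, 1]
            logits = np.log(np.clip(probs, PROB_CLAMP, 1 - PROB_CLAMP)
                            / np.clip(1 - probs, PROB_CLAMP, 1 - PROB_CLAMP))
            med[j] = np.median(np.abs(logits - base))
        best = int(np.lexsort((np.asarray(remaining), -med))[0])
        chosen.append(remaining[best])
        lor_steps.append(float(med[best]))
        remaining.pop(best)
    return ImportanceResult(network_id="run", ordered_nodes=chosen, lor_per_step=lor_steps)


def aggregate_importance(results: list[ImportanceResult], k: int) -> FrequencyTable:
    """Count how often each node appears in the first-k prefix of each
    run's greedy chain.  Because prefixes are nested, the k-node set of any
    run is a subset of its (k+1)-node set."""
    if not results:
        raise ValueError("no importance results to aggregate")
    for res in results:
        if len(res.ordered_nodes) < k:
            raise ValueError(
                f"run {res.network_id!r} holds only {len(res.ordered_nodes)} nodes; "
                f"k = {k} requested"
            )
    counts: dict[int, int] = {}
    for res in results:
        for v in res.ordered_nodes[:k]:
            counts[v] = counts.get(v, 0) + 1
    return FrequencyTable(k=k, counts=counts, n_runs=len(results))
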