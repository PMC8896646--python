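"""Labeled correlation-network datasets for graph-level classification.

A :class:`CorrelationNetwork` is one posterior draw of a taxon-taxon
correlation matrix, treated as a weighted signed graph with a phenotype
label.  A :class:`GraphDataset` stacks many such networks over a shared
taxon set, balanced across the two phenotype classes, together with the
shared node-information matrix (the identity, so the classifier can rely
on correlation structure alone).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class CorrelationNetwork:
    """Weighted signed symmetric graph over a fixed taxon set.

    adjacency: symmetric matrix with entries in [-1, 1] and zero diagonal.
    label: phenotype (0 = healthy/control, 1 = disease/case) or None.
    """

    taxon_ids: list[str]
    adjacency: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        p = len(self.taxon_ids)
        if self.adjacency.shape != (p, p):
            raise ValueError("adjacency shape does not match taxon count")
        if not np.allclose(self.adjacency, self.adjacency.T, atol=1e-9):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.abs(np.diag(self.adjacency)) > 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any(np.abs(self.adjacency) > 1 + 1e-9):
            raise ValueError("correlation weights must lie in [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.taxon_ids)

    def copy(self) -> "CorrelationNetwork":
        return replace(self, adjacency=self.adjacency.copy())


@dataclass
class GraphDataset:
    """Class-balanced stack of correlation networks sharing one taxon set."""

    networks: list[CorrelationNetwork]
    node_info: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.networks:
            raise ValueError("dataset must contain at least one network")
        taxa = self.networks[0].taxon_ids
        for net in self.networks:
            if net.taxon_ids != taxa:
                raise ValueError("all networks must share the same taxon set")
            if net.label is None:
                raise ValueError("all networks must be labeled")
        if self.node_info is None:
            self.node_info = np.eye(len(taxa))

    @property
    def taxon_ids(self) -> list[str]:
        return self.networks[0].taxon_ids

    @property
    def labels(self) -> np.ndarray:
        return np.array([net.label for net in self.networks], dtype=int)

    @property
    def adjacency_stack(self) -> np.ndarray:
        return np.stack([net.adjacency for net in self.networks])

    def __len__(self) -> int:
        return len(self.networks)

    def subset(self, idx) -> "GraphDataset":
        idx = np.asarray(idx)
        return GraphDataset(
            networks=[self.networks[i] for i in idx], node_info=self.node_info
        )


def assemble_dataset(
    group0: list[CorrelationNetwork],
    group1: list[CorrelationNetwork],
    seed: int = 0,
) -> GraphDataset:
    """Combine per-phenotype network draws into a balanced labeled dataset.

    The larger group is randomly downsampled (seeded) to the size of the
    smaller one, so class balance is exactly 0.5.  Labels are forced to
    0 for ``group0`` and 1 for ``group1``.
    """
    if not group0 or not group1:
        raise ValueError("both phenotype groups must be non-empty")
    t0, t1 = group0[0].taxon_ids, group1[0].taxon_ids
    if t0 != t1:
        diff = sorted(set(t0).symmetric_difference(t1))
        raise ValueError(f"taxon sets differ between groups: {diff[:10]}")
    rng = np.random.default_rng(seed)
    n = min(len(group0), len(group1))

    def pick(group):
        if len(group) == n:
            return list(group)
        idx = rng.choice(len(group), size=n, replace=False)
        return [group[i] for i in sorted(idx)]

    networks = [replace(net, label=0) for net in pick(group0)]
    networks += [replace(net, label=1) for net in pick(group1)]
    return GraphDataset(networks=networks)


def train_val_split(
    dataset: GraphDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[GraphDataset, GraphDataset]:
    """Stratified seeded split; the train side takes floor(fraction * n_class)
    networks of each class and the validation side the rest."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    train_idx: list[int] = []
    val_idx: list[int] = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        if members.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 networks; cannot split")
        perm = rng.permutation(members)
        n_train = int(np.floor(train_fraction * members.size))
        train_idx.extend(perm[:n_train].tolist())
        val_idx.extend(perm[n_train:].tolist())
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(val_idx))


def save_dataset(dataset: GraphDataset, prefix) -> None:
    """Serialize as a compressed array archive plus a JSON manifest."""
    np.savez_compressed(
        f"{prefix}.npz",
        adjacency=dataset.adjacency_stack,
        labels=dataset.labels,
        node_info=dataset.node_info,
    )
    with open(f"{prefix}.json", "w") as fh:
        json.dump({"taxon_ids": dataset.taxon_ids, "n_networks": len(dataset)}, fh)


def load_dataset(prefix) -> GraphDataset:
    arrays = np.load(f"{prefix}.npz")
    with open(f"{prefix}.json") as fh:
        manifest = json.load(fh)
    taxa = manifest["taxon_ids"]
    networks = [
        CorrelationNetwork(taxon_ids=taxa, adjacency=a, label=int(lbl))
        for a, lbl in zip(arrays["adjacency"], arrays["labels"])
    ]
    return GraphDataset(networks=networks, node_info=arrays["node_info"])
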