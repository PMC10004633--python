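"""Reading, writing and splitting graph-classification datasets.

Datasets follow the plain-text TUDataset convention: a dataset ``DS`` in a
directory is described by four files,

* ``DS_A.txt`` — one ``i, j`` edge line per directed edge, node indices
  1-based and global over the whole dataset;
* ``DS_graph_indicator.txt`` — for each node, the (1-based) id of the graph
  it belongs to;
* ``DS_graph_labels.txt`` — one class label per graph;
* ``DS_node_labels.txt`` — one categorical label per node.

Internally graphs use 0-based per-graph node indices, undirected deduplicated
edge sets, and dense 0-based label codes (original label values may be
arbitrary integers such as ``{-1, 1}``).  Self-loop lines in input files are
dropped and counted in the log: the convolution layer adds its own
self-connection, and keeping file self-loops would double-aggregate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

logger = logging.getLogger("dgcnn2")

__all__ = [
    "DatasetFormatError",
    "GraphInputError",
    "LabeledGraph",
    "GraphDataset",
    "read_tudataset",
    "write_tudataset",
    "one_hot_features",
    "stratified_kfold",
]


class GraphInputError(ValueError):
    """Invalid argument to a graph operation (bad shape, label, fold count...)."""


class DatasetFormatError(ValueError):
    """A dataset file violates the TUDataset text format."""


@dataclass(frozen=True)
class LabeledGraph:
    """One undirected graph with categorical node labels and a class label.

    ``edges`` holds each undirected edge exactly once as an ``(i, j)`` tuple
    with ``i < j``; node indices are 0-based and local to the graph.
    """

    node_count: int
    edges: frozenset
    node_labels: tuple
    class_label: int

    def __post_init__(self):
        if self.node_count < 1:
            raise GraphInputError("node_count must be positive")
        if len(self.node_labels) != self.node_count:
            raise GraphInputError(
                f"got {len(self.node_labels)} node labels for "
                f"{self.node_count} nodes"
            )
        for (i, j) in self.edges:
            if i == j:
                raise GraphInputError(f"self-loop ({i},{j}) not allowed")
            if not (0 <= i < j < self.node_count):
                raise GraphInputError(f"edge ({i},{j}) out of range or unordered")

    @staticmethod
    def from_edge_list(node_count, edge_list, node_labels, class_label):
        """Build from any iterable of pairs; orientation and duplicates are normalised."""
        edges = frozenset(
            (min(i, j), max(i, j)) for i, j in edge_list if i != j
        )
        return LabeledGraph(node_count, edges, tuple(int(x) for x in node_labels),
                            int(class_label))

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix (no self-connections)."""
        a = np.zeros((self.node_count, self.node_count))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def degree(self) -> np.ndarray:
        d = np.zeros(self.node_count)
        for i, j in self.edges:
            d[i] += 1
            d[j] += 1
        return d

    def permuted(self, perm: Sequence[int]) -> "LabeledGraph":
        """Relabel nodes so that old node ``v`` becomes ``perm[v]``."""
        perm = list(perm)
        labels = [0] * self.node_count
        for old, new in enumerate(perm):
            labels[new] = self.node_labels[old]
        edges = [(perm[i], perm[j]) for i, j in self.edges]
        return LabeledGraph.from_edge_list(self.node_count, edges, labels,
                                           self.class_label)


@dataclass
class GraphDataset:
    """Ordered collection of :class:`LabeledGraph` sharing a label alphabet."""

    graphs: list
    alphabet_size: int
    n_classes: int
    name: str = "dataset"

    def __post_init__(self):
        if self.alphabet_size < 1:
            raise GraphInputError("alphabet_size must be positive")
        for g in self.graphs:
            if any(l < 0 or l >= self.alphabet_size for l in g.node_labels):
                raise GraphInputError("node label outside alphabet")
            if not (0 <= g.class_label < self.n_classes):
                raise GraphInputError("class label outside class set")

    def __len__(self):
        return len(self.graphs)

    def __getitem__(self, idx):
        return self.graphs[idx]

    def class_labels(self) -> np.ndarray:
        return np.array([g.class_label for g in self.graphs], dtype=int)

    def subset(self, indices, name=None) -> "GraphDataset":
        return GraphDataset([self.graphs[i] for i in indices],
                            self.alphabet_size, self.n_classes,
                            name or self.name)


def one_hot_features(graph: LabeledGraph, alphabet_size: int) -> np.ndarray:
    """One-hot encode the node labels: row ``i`` is the indicator of label ``i``."""
    labels = np.asarray(graph.node_labels, dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() >= alphabet_size):
        raise GraphInputError(
            f"node label {labels.max()} outside alphabet of size {alphabet_size}"
        )
    x = np.zeros((graph.node_count, alphabet_size))
    x[np.arange(graph.node_count), labels] = 1.0
    return x


def _read_int_lines(path: Path) -> list:
    if not path.exists():
        raise GraphInputError(f"missing dataset file: {path}")
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                values.append(int(line))
    return values


def _dense_codes(values) -> dict:
    """Map arbitrary integer label values to dense 0-based codes, preserving sorted order."""
    return {v: c for c, v in enumerate(sorted(set(values)))}


def read_tudataset(directory, dataset_name: str) -> GraphDataset:
    """Read a TUDataset-format dataset from ``directory``.

    Edges listed in one or both directions collapse to a single undirected
    pair; self-loops are dropped (the model adds self-connections itself);
    graph and node label values are remapped to dense 0-based codes.
    """
    directory = Path(directory)
    prefix = directory / dataset_name
    indicator = _read_int_lines(Path(f"{prefix}_graph_indicator.txt"))
    graph_label_vals = _read_int_lines(Path(f"{prefix}_graph_labels.txt"))
    node_label_vals = _read_int_lines(Path(f"{prefix}_node_labels.txt"))

    n_nodes = len(indicator)
    if len(node_label_vals) != n_nodes:
        raise DatasetFormatError(
            f"{dataset_name}: {len(node_label_vals)} node labels for {n_nodes} nodes"
        )
    graph_ids = sorted(set(indicator))
    n_graphs = len(graph_ids)
    if graph_ids != list(range(1, n_graphs + 1)):
        raise DatasetFormatError(f"{dataset_name}: graph indicator ids not 1..{n_graphs}")
    if len(graph_label_vals) != n_graphs:
        raise DatasetFormatError(
            f"{dataset_name}: {len(graph_label_vals)} graph labels for {n_graphs} graphs"
        )

    # Global 1-based node index -> (graph index, local 0-based index).
    local_index = np.empty(n_nodes, dtype=int)
    graph_of = np.asarray(indicator, dtype=int) - 1
    counts = np.zeros(n_graphs, dtype=int)
    for v in range(n_nodes):
        local_index[v] = counts[graph_of[v]]
        counts[graph_of[v]] += 1

    edge_path = Path(f"{prefix}_A.txt")
    if not edge_path.exists():
        raise GraphInputError(f"missing dataset file: {edge_path}")
    edge_sets = [set() for _ in range(n_graphs)]
    n_self_loops = 0
    with open(edge_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise DatasetFormatError(
                    f"{dataset_name}_A.txt line {lineno}: expected 'i, j', got {line!r}"
                )
            u, v = int(parts[0]) - 1, int(parts[1]) - 1
            if not (0 <= u < n_nodes and 0 <= v < n_nodes):
                raise DatasetFormatError(
                    f"{dataset_name}_A.txt line {lineno}: node index out of range"
                )
            if graph_of[u] != graph_of[v]:
                raise DatasetFormatError(
                    f"{dataset_name}_A.txt line {lineno}: edge spans graphs "
                    f"{graph_of[u] + 1} and {graph_of[v] + 1}"
                )
            if u == v:
                n_self_loops += 1
                continue
            i, j = int(local_index[u]), int(local_index[v])
            edge_sets[graph_of[u]].add((min(i, j), max(i, j)))
    if n_self_loops:
        logger.info("%s: dropped %d self-loop line(s)", dataset_name, n_self_loops)

    class_code = _dense_codes(graph_label_vals)
    label_code = _dense_codes(node_label_vals)
    node_labels_per_graph = [[] for _ in range(n_graphs)]
    for v in range(n_nodes):
        node_labels_per_graph[graph_of[v]].append(label_code[node_label_vals[v]])

    graphs = [
        LabeledGraph(int(counts[g]), frozenset(edge_sets[g]),
                     tuple(node_labels_per_graph[g]),
                     class_code[graph_label_vals[g]])
        for g in range(n_graphs)
    ]
    return GraphDataset(graphs, alphabet_size=len(label_code),
                        n_classes=len(class_code), name=dataset_name)


def write_tudataset(dataset: GraphDataset, directory, dataset_name=None) -> None:
    """Write ``dataset`` in TUDataset format, emitting each edge in both directions."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = dataset_name or dataset.name
    prefix = directory / name

    offsets = np.cumsum([0] + [g.node_count for g in dataset.graphs])
    with open(f"{prefix}_A.txt", "w") as fh:
        for gi, g in enumerate(dataset.graphs):
            base = offsets[gi] + 1  # 1-based global
            for i, j in sorted(g.edges):
                fh.write(f"{base + i}, {base + j}\n")
                fh.write(f"{base + j}, {base + i}\n")
    with open(f"{prefix}_graph_indicator.txt", "w") as fh:
        for gi, g in enumerate(dataset.graphs, start=1):
            fh.writelines(f"{gi}\n" for _ in range(g.node_count))
    with open(f"{prefix}_graph_labels.txt", "w") as fh:
        fh.writelines(f"{g.class_label}\n" for g in dataset.graphs)
    with open(f"{prefix}_node_labels.txt", "w") as fh:
        for g in dataset.graphs:
            fh.writelines(f"{l}\n" for l in g.node_labels)


def stratified_kfold(dataset: GraphDataset, n_folds: int, seed: int,
                     stratified: bool = True) -> list:
    """Seeded k-fold split of graph indices, stratified by class label.

    Falls back to an unstratified split (with a logged warning) when some
    class has fewer members than ``n_folds``.  Returns a list of
    ``(train_indices, test_indices)`` arrays whose test folds partition
    ``range(len(dataset))``.
    """
    n = len(dataset)
    if n_folds < 2:
        raise GraphInputError("n_folds must be at least 2")
    if n_folds > n:
        raise GraphInputError(f"n_folds={n_folds} exceeds dataset size {n}")
    y = dataset.class_labels()
    _, class_counts = np.unique(y, return_counts=True)
    if stratified and class_counts.min() < n_folds:
        logger.warning(
            "smallest class has %d members < %d folds; "
            "falling back to unstratified k-fold", class_counts.min(), n_folds,
        )
        stratified = False
    if stratified:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in splitter.split(np.zeros(n), y)]
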