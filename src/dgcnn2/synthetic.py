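"""Synthetic labeled-graph datasets with controllable class structure.

The canonical generator emulates small molecular-graph benchmarks: each graph
is an Erdős–Rényi draw whose edge probability depends on the class, so class
membership is encoded in edge density — a structure a degree/attention-driven
aggregator can detect even without node-label signal.  A second, orthogonal
signal channel couples node labels to the class through
``label_class_correlation``.

A single global seed drives per-graph substreams (``numpy.random.SeedSequence``
spawning), so inserting or removing one graph never shifts the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_io import GraphDataset, GraphInputError, LabeledGraph

__all__ = ["SyntheticSpec", "generate_er_density_dataset", "dataset_summary"]


@dataclass
class SyntheticSpec:
    """Parameters of the ER density-contrast generator."""

    n_graphs: int = 200
    n_classes: int = 2
    node_count_range: tuple = (15, 25)
    edge_prob_by_class: tuple = (0.10, 0.30)
    alphabet_size: int = 3
    label_class_correlation: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_graphs < 1:
            raise GraphInputError("n_graphs must be positive")
        if self.n_classes < 2:
            raise GraphInputError("need at least 2 classes")
        lo, hi = self.node_count_range
        if lo < 1 or hi < lo:
            raise GraphInputError(f"empty node_count_range {self.node_count_range}")
        if len(self.edge_prob_by_class) != self.n_classes:
            raise GraphInputError("need one edge probability per class")
        if any(not (0.0 < p < 1.0) for p in self.edge_prob_by_class):
            raise GraphInputError("edge probabilities must lie in (0,1)")
        if not (0.0 <= self.label_class_correlation <= 1.0):
            raise GraphInputError("label_class_correlation must lie in [0,1]")


def _er_graph(rng: np.random.Generator, n: int, p: float, cls: int,
              alphabet_size: int, corr: float) -> LabeledGraph:
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < p
    edges = frozenset(zip(iu[keep].tolist(), ju[keep].tolist()))
    biased = rng.random(n) < corr
    labels = np.where(biased, cls % alphabet_size, rng.integers(0, alphabet_size, n))
    return LabeledGraph(n, edges, tuple(int(l) for l in labels), cls)


def generate_er_density_dataset(spec: SyntheticSpec) -> GraphDataset:
    """Generate ``spec.n_graphs`` class-balanced ER graphs, reproducibly from the seed.

    Graph ``i`` has class ``i % n_classes`` (balanced to within one), a node
    count drawn uniformly from ``node_count_range``, and edge probability
    ``edge_prob_by_class[class]``.
    """
    lo, hi = spec.node_count_range
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_graphs)
    graphs = []
    for i in range(spec.n_graphs):
        rng = np.random.default_rng(children[i])
        cls = i % spec.n_classes
        n = int(rng.integers(lo, hi + 1))
        graphs.append(_er_graph(rng, n, spec.edge_prob_by_class[cls], cls,
                                spec.alphabet_size, spec.label_class_correlation))
    return GraphDataset(graphs, alphabet_size=spec.alphabet_size,
                        n_classes=spec.n_classes, name="synthetic_er")


def dataset_summary(dataset: GraphDataset) -> dict:
    """Benchmark-table style summary: graph/class counts, node-count stats, alphabet."""
    if len(dataset) == 0:
        raise GraphInputError("empty dataset")
    counts = np.array([g.node_count for g in dataset.graphs])
    return {
        "graphs": len(dataset),
        "classes": dataset.n_classes,
        "nodes_max": int(counts.max()),
        "nodes_avg": float(counts.mean()),
        "node_labels": dataset.alphabet_size,
    }
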