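import numpy as np
import pytest

from dgcnn2 import (GraphDataset, LabeledGraph, SyntheticSpec,
                    generate_er_density_dataset, make_model_config)


@pytest.fixture
def two_graph_dataset():
    """The canonical 2-graph fixture: a 3-node path and a 2-node edge."""
    g1 = LabeledGraph.from_edge_list(3, [(0, 1), (1, 2)], [0, 0, 1], 0)
    g2 = LabeledGraph.from_edge_list(2, [(0, 1)], [0, 1], 1)
    return GraphDataset([g1, g2], alphabet_size=2, n_classes=2, name="tiny")


@pytest.fixture
def tudataset_dir(tmp_path):
    """Write the 2-graph fixture in raw TUDataset text form (both directions,
    original label values 1/2 and graph labels 1/2)."""
    d = tmp_path / "TINY"
    d.mkdir()
    (d / "TINY_A.txt").write_text(
        "1, 2\n2, 1\n2, 3\n3, 2\n4, 5\n5, 4\n")
    (d / "TINY_graph_indicator.txt").write_text("1\n1\n1\n2\n2\n")
    (d / "TINY_graph_labels.txt").write_text("1\n2\n")
    (d / "TINY_node_labels.txt").write_text("1\n1\n2\n1\n2\n")
    return d


@pytest.fixture(scope="session")
def small_er_dataset():
    """40 small ER graphs with a density contrast, reused across tests."""
    spec = SyntheticSpec(n_graphs=40, node_count_range=(8, 14),
                         edge_prob_by_class=(0.15, 0.45), seed=11)
    return generate_er_density_dataset(spec)


@pytest.fixture
def tiny_model_config():
    return make_model_config(n_classes=2, stage1_depth=2, stage2_depth=2,
                             hidden_channels=6, stage1_out_channels=3,
                             sortpool_k=10, dropout_rate=0.0)


def random_graph(rng, n_max=8, n_min=2, edge_prob=0.4):
    """Random small labeled graph for property tests."""
    n = int(rng.integers(n_min, n_max + 1))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                edges.append((i, j))
    labels = rng.integers(0, 2, size=n)
    return LabeledGraph.from_edge_list(n, edges, labels.tolist(), 0)
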