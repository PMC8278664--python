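import networkx as nx
import numpy as np
import pandas as pd
import pytest

import omicblocks as ob


@pytest.fixture(scope="session")
def default_dataset():
    """One default simulated dataset, QC'd, reused across read-only tests."""
    data = ob.simulate_dataset(seed=7)
    g = ob.qc_genotypes(data.genotypes)
    return data, g


@pytest.fixture()
def triangle_graph():
    net = nx.Graph()
    for a, b in [("A", "B"), ("B", "C"), ("A", "C")]:
        net.add_edge(a, b, weight=1.0)
    return net


def make_clique_graph(cliques, weight=0.9):
    """Vertex-disjoint cliques with uniform edge weight."""
    net = nx.Graph()
    for members in cliques:
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                net.add_edge(members[i], members[j], weight=weight)
    return net


def jaccard(a, b):
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)


def causal_clusters_selected(selected, truth, min_jaccard=0.5):
    """Every planted causal cluster matched (Jaccard) by a selected cluster."""
    for tc in truth.causal_clusters:
        tset = {g for g, c in truth.cluster_of_gene.items() if c == tc}
        if not any(jaccard(c.genes, tset) >= min_jaccard for c in selected):
            return False
    return True
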