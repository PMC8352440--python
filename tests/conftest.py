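import numpy as np
import pytest

from netprior import candidates as cand_mod
from netprior import features as feat_mod
from netprior import predict as pred_mod
from netprior.io import DiseaseGeneAssociations, DiseaseSimilarityTable, GeneNetwork
from netprior.synthetic import BenchmarkConfig, generate


def make_network(edges) -> GeneNetwork:
    net = GeneNetwork()
    for u, v, w in edges:
        net.add_edge(u, v, w)
    return net


@pytest.fixture
def path_network() -> GeneNetwork:
    """A-B (1.0), B-C (2.0), A-C (4.0), C-D (1.0): shortest A->D is 4.0."""
    return make_network([("A", "B", 1.0), ("B", "C", 2.0),
                         ("A", "C", 4.0), ("C", "D", 1.0)])


@pytest.fixture
def toy_assoc() -> DiseaseGeneAssociations:
    return DiseaseGeneAssociations(entries=[
        ("IBD", "g1"), ("IBD", "g2"),
        ("D1", "g1"), ("D1", "g3"),
        ("D2", "g3"), ("D2", "g4"),
    ])


@pytest.fixture
def toy_sim() -> DiseaseSimilarityTable:
    t = DiseaseSimilarityTable()
    t.add("IBD", "D1", 0.08)
    t.add("IBD", "D2", 0.05)
    return t


class Bench:
    """Default-config benchmark instance with the derived pipeline objects."""

    def __init__(self, truth):
        self.truth = truth
        self.similar = cand_mod.select_similar_diseases(
            truth.similarities, truth.target_disease
        )
        self.cand = cand_mod.collect_candidates(
            truth.associations, self.similar, truth.target_disease
        )
        self.features = feat_mod.build_feature_matrix(
            truth.network, self.cand, truth.associations
        )
        self.negatives = pred_mod.sample_negatives(
            self.cand.candidate_genes, self.cand.positive_genes,
            seed=truth.config.seed,
        )


@pytest.fixture(scope="session")
def bench(tmp_path_factory) -> Bench:
    truth = generate(BenchmarkConfig(), tmp_path_factory.mktemp("bench"))
    return Bench(truth)


def random_connected_network(rng: np.random.Generator, n_max: int = 8) -> GeneNetwork:
    """Small random connected weighted graph for oracle comparisons."""
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"n{i}" for i in range(n)]
    net = GeneNetwork()
    order = list(rng.permutation(n))
    for prev, nxt in zip(order, order[1:]):  # random spanning tree
        net.add_edge(nodes[prev], nodes[nxt], float(rng.uniform(0.1, 2.0)))
    for i in range(n):
        for j in range(i + 1, n):
            if not net.graph.has_edge(nodes[i], nodes[j]) and rng.random() < 0.4:
                net.add_edge(nodes[i], nodes[j], float(rng.uniform(0.1, 2.0)))
    return net
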