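"""Shortest-path feature extraction on the weighted gene network.

Each candidate gene is described by one feature per similar disease: the
length of the shortest weighted path from the gene to the nearest gene of
that disease, or a fixed membership value (default 1.0) if the gene itself
belongs to the disease. Path lengths are sums of per-edge lengths derived
from the interaction weights; the raw genes x diseases matrix is then
z-scored column-wise, F' = (F - mean(F)) / sd(F).

Dijkstra is implemented here directly (label-setting with a binary heap)
because deterministic tie-breaking — frontier ties resolved by
lexicographic gene id — is part of the contract: predecessor trees are
bit-identical across runs and platforms.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .candidates import CandidateSet
from .io import DiseaseGeneAssociations, GeneNetwork, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "TRANSFORMS",
    "edge_length",
    "ShortestPathLabels",
    "dijkstra",
    "gene_disease_feature",
    "FeatureMatrix",
    "build_feature_matrix",
]

#: Supported weight-to-length transforms. ``identity`` treats the stated
#: weight itself as the length; the others invert "strength" semantics
#: (higher weight = closer) into lengths.
TRANSFORMS = ("identity", "reciprocal", "neg_log", "one_minus")


def edge_length(weight: float, transform: str = "identity") -> float:
    """Map an interaction weight to a positive path length.

    ``one_minus`` and ``neg_log`` require weight < 1 so that the resulting
    length stays strictly positive.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")
    if not (weight > 0):
        raise ValidationError(f"edge weight {weight} must be positive")
    if transform == "identity":
        return float(weight)
    if transform == "reciprocal":
        return 1.0 / float(weight)
    if weight >= 1.0:
        raise ValidationError(
            f"transform {transform!r} requires weight < 1 to keep the edge "
            f"length positive; got weight {weight}"
        )
    if transform == "neg_log":
        return -math.log(weight)
    return 1.0 - float(weight)  # one_minus


def _length_adjacency(
    network: GeneNetwork, transform: str
) -> dict[str, list[tuple[str, float]]]:
    """Adjacency lists of (neighbor, length), neighbors sorted for determinism."""
    adj: dict[str, list[tuple[str, float]]] = {g: [] for g in network.graph.nodes}
    for u, v, w in network.edges():
        length = edge_length(w, transform)
        adj[u].append((v, length))
        adj[v].append((u, length))
    for g in adj:
        adj[g].sort()
    return adj


@dataclass
class ShortestPathLabels:
    """Single-source shortest-path labels (d_t, p_t).

    ``d`` maps each reachable gene to its shortest path length from
    ``source`` (d[source] = 0); ``p`` maps it to its predecessor on that
    path (p[source] is None). Unreachable genes are absent from both.
    """

    source: str
    d: dict[str, float] = field(default_factory=dict)
    p: dict[str, str | None] = field(default_factory=dict)

    def path_to(self, target: str) -> list[str]:
        """Reconstruct the source->target path by following predecessors."""
        if target not in self.d:
            raise KeyError(f"{target!r} unreachable from {self.source!r}")
        path = [target]
        while path[-1] != self.source:
            path.append(self.p[path[-1]])  # type: ignore[arg-type]
        path.reverse()
        return path


def dijkstra(
    network: GeneNetwork,
    source: str,
    transform: str = "identity",
    _adjacency: dict[str, list[tuple[str, float]]] | None = None,
) -> ShortestPathLabels:
    """Single-source Dijkstra over the weighted gene network.

    Label-setting: initialise d[source] = 0 and all other labels to
    infinity, then repeatedly settle the unmarked gene with the smallest
    tentative distance and relax its neighbours,
    d_j = min(d_j, d_k + w(k, j)). Frontier ties (equal tentative distance)
    are settled in lexicographic gene-id order, and on an equal-length
    alternative path the first-found predecessor is kept, so the
    predecessor tree is deterministic.
    """
    if source not in network.graph:
        raise KeyError(f"source gene {source!r} not in network")
    adj = _adjacency if _adjacency is not None else _length_adjacency(network, transform)
    labels = ShortestPathLabels(source=source)
    dist: dict[str, float] = {source: 0.0}
    pred: dict[str, str | None] = {source: None}
    settled: set[str] = set()
    heap: list[tuple[float, str]] = [(0.0, source)]
    while heap:
        d_u, u = heapq.heappop(heap)
        if u in settled or d_u > dist[u]:
            continue
        settled.add(u)
        for v, length in adj[u]:
            if v in settled:
                continue
            nd = d_u + length
            if nd < dist.get(v, math.inf):
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
    labels.d = dist
    labels.p = pred
    return labels


def gene_disease_feature(
    labels: ShortestPathLabels,
    gene: str,
    disease_genes: set[str],
    member: bool,
    membership_value: float = 1.0,
) -> float:
    """Raw feature of one gene for one disease dimension.

    A gene belonging to the disease gets the fixed ``membership_value``;
    otherwise the feature is the shortest-path distance to the nearest gene
    of the disease. Returns ``inf`` when no disease gene is reachable; the
    matrix builder replaces infinities with a per-column sentinel before
    normalization.
    """
    if not disease_genes:
        raise ValueError("disease gene set is empty")
    if member:
        return float(membership_value)
    best = math.inf
    for g in disease_genes:
        d = labels.d.get(g, math.inf)
        if d < best:
            best = d
    return best


@dataclass
class FeatureMatrix:
    """Candidate genes x similar diseases feature matrix.

    ``raw`` holds distances / membership values / imputed sentinels;
    ``normalized`` is the column-wise z-score of ``raw`` using the sample
    standard deviation (ddof=1), with zero-variance columns mapped to zeros.
    The target disease has no column: its distances would encode the label.
    """

    genes: list[str]
    dimensions: list[str]
    raw: np.ndarray
    normalized: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    _row_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._row_index:
            self._row_index = {g: i for i, g in enumerate(self.genes)}

    def row(self, gene: str) -> np.ndarray:
        return self.normalized[self._row_index[gene]]

    def rows(self, genes: list[str]) -> np.ndarray:
        return self.normalized[[self._row_index[g] for g in genes]]

    @property
    def shape(self) -> tuple[int, int]:
        return self.normalized.shape


#: Multiplier applied to a column's largest finite raw value to impute
#: unreachable entries: farther than anything observed, but finite.
UNREACHABLE_FACTOR = 1.5


def zscore_columns(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column z-scores with sample sd; zero-variance columns become zeros."""
    raw = np.asarray(raw, dtype=float)
    means = raw.mean(axis=0)
    if raw.shape[0] > 1:
        sds = raw.std(axis=0, ddof=1)
    else:
        sds = np.zeros(raw.shape[1])
    normalized = np.zeros_like(raw)
    ok = sds > 0
    normalized[:, ok] = (raw[:, ok] - means[ok]) / sds[ok]
    return normalized, means, sds


def build_feature_matrix(
    network: GeneNetwork,
    candidates: CandidateSet,
    assoc: DiseaseGeneAssociations,
    transform: str = "identity",
    membership_value: float = 1.0,
) -> FeatureMatrix:
    """Run Dijkstra from every candidate gene and assemble the matrix.

    Rows are the candidate genes in sorted order (the matrix is therefore
    invariant to candidate input order); columns are the similar diseases,
    in their similarity order, excluding the target and any disease without
    association records. Candidate genes absent from the network get
    sentinel distances in every column (logged, not an error).
    """
    target = candidates.target_disease
    dimensions: list[str] = []
    disease_sets: list[set[str]] = []
    for d in candidates.similar_diseases:
        if d == target:
            continue
        genes_d = assoc.genes_of(d)
        if not genes_d:
            logger.warning("disease %r has no genes; dimension dropped", d)
            continue
        dimensions.append(d)
        disease_sets.append(genes_d)
    if not dimensions:
        raise ValueError("no usable disease dimensions for feature extraction")

    genes = sorted(candidates.candidate_genes)
    adjacency = _length_adjacency(network, transform)
    raw = np.full((len(genes), len(dimensions)), math.inf)
    n_missing = 0
    for i, gene in enumerate(genes):
        if gene not in network.graph:
            n_missing += 1
            for j, dset in enumerate(disease_sets):
                if gene in dset:
                    raw[i, j] = membership_value
            continue
        labels = dijkstra(network, gene, transform, _adjacency=adjacency)
        for j, dset in enumerate(disease_sets):
            raw[i, j] = gene_disease_feature(
                labels, gene, dset, member=gene in dset,
                membership_value=membership_value,
            )
    if n_missing:
        logger.warning(
            "%d candidate genes absent from the network; their distances "
            "are imputed sentinels", n_missing,
        )

    # per-column unreachable imputation: 1.5 x the largest finite value
    for j in range(raw.shape[1]):
        col = raw[:, j]
        bad = ~np.isfinite(col)
        if bad.any():
            finite = col[~bad]
            sentinel = UNREACHABLE_FACTOR * finite.max() if finite.size else 0.0
            col[bad] = sentinel

    normalized, means, sds = zscore_columns(raw)
    return FeatureMatrix(
        genes=genes,
        dimensions=dimensions,
        raw=raw,
        normalized=normalized,
        column_means=means,
        column_sds=sds,
    )
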