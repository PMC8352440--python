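"""Readers and writers for the pipeline's tabular formats.

All formats are plain UTF-8 TSV. Lines starting with ``#`` are comments and
are skipped everywhere. Gene and disease identifiers are opaque,
case-sensitive strings; no identifier-namespace conversion is attempted.

Three input formats are supported:

* disease similarities — ``disease_a<TAB>disease_b<TAB>similarity`` with
  similarity in [0, 1] (SemFunSim-style output);
* disease-gene associations — ``disease_id<TAB>gene_id`` (DisGeNET-export
  style);
* weighted gene network — ``gene_a<TAB>gene_b<TAB>weight`` with weight > 0
  (HumanNet-style edge list).

A header row is optional and auto-detected: for three-column files a
non-numeric third field marks a header; for the two-column association
format only the literal header ``disease_id<TAB>gene_id`` (case-insensitive)
is recognised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "ParseError",
    "ValidationError",
    "DiseaseSimilarityTable",
    "DiseaseGeneAssociations",
    "GeneNetwork",
    "read_similarities",
    "write_similarities",
    "read_associations",
    "write_associations",
    "read_network",
    "write_network",
    "read_feature_table",
    "write_feature_table",
    "read_gene_list",
    "write_gene_list",
    "read_model",
    "write_model",
    "write_ranking",
]


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed input violates a format invariant."""


def _fmt(x: float) -> str:
    """Shortest round-tripping decimal representation of a float."""
    return format(float(x), ".17g")


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, tab-split fields) for non-comment lines."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


# ---------------------------------------------------------------------------
# disease-disease similarities
# ---------------------------------------------------------------------------


@dataclass
class DiseaseSimilarityTable:
    """Sparse table of pairwise disease similarities in [0, 1].

    Absent pairs are treated as similarity 0 (unknown). At most one record
    exists per unordered disease pair.
    """

    records: list[tuple[str, str, float]] = field(default_factory=list)
    _index: dict[tuple[str, str], float] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index and self.records:
            for a, b, s in self.records:
                self._index[self._key(a, b)] = s

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    @property
    def diseases(self) -> set[str]:
        return {d for a, b, _ in self.records for d in (a, b)}

    def similarity(self, a: str, b: str) -> float:
        return self._index.get(self._key(a, b), 0.0)

    def neighbors(self, disease: str) -> list[tuple[str, float]]:
        """All diseases with a recorded similarity to ``disease``."""
        out = []
        for a, b, s in self.records:
            if a == disease:
                out.append((b, s))
            elif b == disease:
                out.append((a, s))
        return out

    def add(self, a: str, b: str, similarity: float) -> None:
        if not (0.0 <= similarity <= 1.0):
            raise ValidationError(
                f"similarity {similarity!r} for pair ({a}, {b}) outside [0, 1]"
            )
        key = self._key(a, b)
        if key in self._index:
            if self._index[key] != similarity:
                raise ValidationError(
                    f"conflicting similarities for pair ({a}, {b}): "
                    f"{self._index[key]} vs {similarity}"
                )
            return
        self._index[key] = similarity
        self.records.append((a, b, similarity))

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiseaseSimilarityTable):
            return NotImplemented
        return self._index == other._index


def read_similarities(path: str | Path) -> DiseaseSimilarityTable:
    """Read a ``disease_a  disease_b  similarity`` TSV.

    Rows with a similarity outside [0, 1] and duplicate unordered pairs with
    conflicting values raise :class:`ValidationError`; malformed rows raise
    :class:`ParseError` naming the line number.
    """
    table = DiseaseSimilarityTable()
    first = True
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 tab-separated columns")
        a, b, raw = fields[0].strip(), fields[1].strip(), fields[2].strip()
        if first:
            first = False
            try:
                float(raw)
            except ValueError:
                continue  # header row
        try:
            s = float(raw)
        except ValueError as exc:
            raise ParseError(
                f"{path}:{lineno}: similarity {raw!r} is not a number"
            ) from exc
        if not a or not b:
            raise ParseError(f"{path}:{lineno}: blank disease identifier")
        if not (0.0 <= s <= 1.0):
            raise ValidationError(
                f"{path}:{lineno}: similarity {s} outside [0, 1]"
            )
        try:
            table.add(a, b, s)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return table


def write_similarities(table: DiseaseSimilarityTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease_a\tdisease_b\tsimilarity\n")
        for a, b, s in sorted(
            (table._key(a, b) + (s,)) for a, b, s in table.records
        ):
            fh.write(f"{a}\t{b}\t{_fmt(s)}\n")


# ---------------------------------------------------------------------------
# disease-gene associations
# ---------------------------------------------------------------------------


@dataclass
class DiseaseGeneAssociations:
    """Disease-to-gene membership map.

    ``entry_count`` counts distinct (disease, gene) pairs — catalogue
    "entries" — while ``unique_gene_count`` counts distinct genes, so
    unique_gene_count <= entry_count whenever diseases share genes.
    """

    entries: list[tuple[str, str]] = field(default_factory=list)
    _by_disease: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._by_disease and self.entries:
            seen: set[tuple[str, str]] = set()
            deduped = []
            for d, g in self.entries:
                if (d, g) in seen:
                    continue
                seen.add((d, g))
                deduped.append((d, g))
                self._by_disease.setdefault(d, set()).add(g)
            self.entries = deduped

    @property
    def diseases(self) -> set[str]:
        return set(self._by_disease)

    @property
    def entry_count(self) -> int:
        return len(self.entries)

    @property
    def unique_gene_count(self) -> int:
        return len({g for _, g in self.entries})

    def genes_of(self, disease: str) -> set[str]:
        return set(self._by_disease.get(disease, set()))

    def __contains__(self, disease: str) -> bool:
        return disease in self._by_disease

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiseaseGeneAssociations):
            return NotImplemented
        return set(self.entries) == set(other.entries)


def read_associations(path: str | Path) -> DiseaseGeneAssociations:
    """Read a ``disease_id  gene_id`` TSV; duplicate lines collapse."""
    entries: list[tuple[str, str]] = []
    first = True
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
        d, g = fields[0].strip(), fields[1].strip()
        if first:
            first = False
            if d.lower() == "disease_id" and g.lower() == "gene_id":
                continue  # header row
        if not d or not g:
            raise ParseError(f"{path}:{lineno}: blank disease or gene field")
        entries.append((d, g))
    return DiseaseGeneAssociations(entries=entries)


def write_associations(assoc: DiseaseGeneAssociations, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease_id\tgene_id\n")
        for d, g in sorted(set(assoc.entries)):
            fh.write(f"{d}\t{g}\n")


# ---------------------------------------------------------------------------
# weighted gene network
# ---------------------------------------------------------------------------


@dataclass
class GeneNetwork:
    """Undirected weighted gene interaction network.

    Backed by a :class:`networkx.Graph`; edge attribute ``weight`` is the
    (unitless, positive) interaction strength.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, float]]:
        return [
            (min(u, v), max(u, v), d["weight"])
            for u, v, d in self.graph.edges(data=True)
        ]

    def weight(self, u: str, v: str) -> float:
        return self.graph[u][v]["weight"]

    def add_edge(self, u: str, v: str, weight: float) -> None:
        if u == v:
            raise ValidationError(f"self-loop on gene {u!r}")
        if not (weight > 0):
            raise ValidationError(
                f"edge ({u}, {v}) has non-positive weight {weight}"
            )
        if self.graph.has_edge(u, v):
            if self.graph[u][v]["weight"] != weight:
                raise ValidationError(
                    f"conflicting duplicate edge ({u}, {v}): "
                    f"{self.graph[u][v]['weight']} vs {weight}"
                )
            return
        self.graph.add_edge(u, v, weight=weight)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return set(self.edges()) == set(other.edges()) and self.nodes == other.nodes


def read_network(path: str | Path) -> GeneNetwork:
    """Read a ``gene_a  gene_b  weight`` TSV into an undirected network."""
    net = GeneNetwork()
    first = True
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 tab-separated columns")
        u, v, raw = fields[0].strip(), fields[1].strip(), fields[2].strip()
        if first:
            first = False
            try:
                float(raw)
            except ValueError:
                continue  # header row
        try:
            w = float(raw)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: weight {raw!r} is not a number") from exc
        if not u or not v:
            raise ParseError(f"{path}:{lineno}: blank gene identifier")
        try:
            net.add_edge(u, v, w)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return net


def write_network(net: GeneNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for u, v, w in sorted(net.edges()):
            fh.write(f"{u}\t{v}\t{_fmt(w)}\n")
    # isolated nodes are not representable in an edge list; none are written


# ---------------------------------------------------------------------------
# feature matrix, gene lists, model file, ranking
# ---------------------------------------------------------------------------


def write_feature_table(
    genes: Sequence[str],
    dimensions: Sequence[str],
    values: np.ndarray,
    path: str | Path,
) -> None:
    """Write a genes x diseases matrix as TSV (first column ``gene_id``)."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(genes), len(dimensions)):
        raise ValueError(
            f"matrix shape {values.shape} does not match "
            f"{len(genes)} genes x {len(dimensions)} dimensions"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(dimensions) + "\n")
        for i, g in enumerate(genes):
            fh.write(g + "\t" + "\t".join(_fmt(x) for x in values[i]) + "\n")


def read_feature_table(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read a feature TSV; returns (genes, dimensions, values)."""
    genes: list[str] = []
    rows: list[list[float]] = []
    dimensions: list[str] | None = None
    for lineno, fields in _data_lines(path):
        if dimensions is None:
            if fields[0].strip() != "gene_id":
                raise ParseError(
                    f"{path}:{lineno}: feature table must start with a "
                    "'gene_id' header row"
                )
            dimensions = [f.strip() for f in fields[1:]]
            continue
        if len(fields) != len(dimensions) + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {len(dimensions) + 1} columns, "
                f"got {len(fields)}"
            )
        genes.append(fields[0].strip())
        try:
            rows.append([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric feature value") from exc
    if dimensions is None:
        raise ParseError(f"{path}: empty feature table")
    return genes, dimensions, np.asarray(rows, dtype=float)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; comments and blanks skipped; order preserved."""
    genes: list[str] = []
    seen: set[str] = set()
    for _, fields in _data_lines(path):
        g = fields[0].strip()
        if g and g not in seen:
            seen.add(g)
            genes.append(g)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_model(results, path: str | Path) -> None:
    """Serialise a fitted LS-SVM to a documented key-value text format.

    Stores sigma, gamma, bias, the feature dimensions, and one
    ``gene_id  label  coefficient`` row per training gene. Training feature
    vectors are *not* stored; scoring reloads them from the feature table by
    gene id.
    """
    if results.gene_ids is None:
        raise ValueError("results carry no training gene ids; cannot serialise")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# netprior LS-SVM model\n")
        fh.write(f"sigma\t{_fmt(results.sigma)}\n")
        fh.write(f"gamma\t{_fmt(results.gamma)}\n")
        fh.write(f"b\t{_fmt(results.b)}\n")
        fh.write("dimensions\t" + ",".join(results.dimensions or []) + "\n")
        fh.write("# gene_id\tlabel\tcoefficient\n")
        for g, y, a in zip(results.gene_ids, results.model.y, results.a):
            fh.write(f"{g}\t{int(y):+d}\t{_fmt(a)}\n")


def read_model(path: str | Path) -> dict:
    """Read a model file back into a plain dict.

    Returns keys ``sigma``, ``gamma``, ``b``, ``dimensions`` (list),
    ``gene_ids``, ``labels`` and ``a`` (numpy arrays).
    """
    meta: dict[str, float] = {}
    dimensions: list[str] = []
    gene_ids: list[str] = []
    labels: list[int] = []
    coeffs: list[float] = []
    for lineno, fields in _data_lines(path):
        key = fields[0].strip()
        if key in ("sigma", "gamma", "b"):
            meta[key] = float(fields[1])
        elif key == "dimensions":
            dimensions = [d for d in fields[1].split(",") if d] if len(fields) > 1 else []
        else:
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected gene/label/coefficient row")
            gene_ids.append(key)
            labels.append(int(fields[1]))
            coeffs.append(float(fields[2]))
    for k in ("sigma", "gamma", "b"):
        if k not in meta:
            raise ParseError(f"{path}: missing {k!r} in model file")
    return {
        "sigma": meta["sigma"],
        "gamma": meta["gamma"],
        "b": meta["b"],
        "dimensions": dimensions,
        "gene_ids": gene_ids,
        "labels": np.asarray(labels, dtype=float),
        "a": np.asarray(coeffs, dtype=float),
    }


def write_ranking(ranking, path: str | Path) -> None:
    """Write a ranking as ``gene_id  score  rank`` with threshold metadata."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# threshold\t{_fmt(ranking.threshold)}\n")
        fh.write(f"# nominated\t{len(ranking.nominated)}\n")
        fh.write("gene_id\tscore\trank\n")
        for rank, (gene, score) in enumerate(ranking.entries, start=1):
            fh.write(f"{gene}\t{_fmt(score)}\t{rank}\n")
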