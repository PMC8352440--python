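"""Similar-disease selection and candidate gene pool assembly.

Guilt-by-association starts from the premise that similar diseases share
genes: every gene known to be associated with a disease similar to the
target is a candidate for association with the target itself. The target's
own known genes are the positive training examples and are part of the
candidate pool (they are candidates whose label happens to be known).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .io import DiseaseGeneAssociations, DiseaseSimilarityTable

logger = logging.getLogger(__name__)

__all__ = ["CandidateSet", "select_similar_diseases", "collect_candidates",
           "write_candidates", "read_candidates"]


@dataclass
class CandidateSet:
    """Candidate gene pool for one target disease.

    similar_diseases is ordered by descending similarity to the target
    (ties broken lexicographically) and never contains the target itself.
    entry_count counts (disease, gene) memberships among the similar
    diseases, so entry_count exceeds the unique candidate count whenever
    similar diseases share genes.
    """

    target_disease: str
    similar_diseases: list[str]
    candidate_genes: set[str]
    positive_genes: set[str]
    entry_count: int
    similarities: dict[str, float] = field(default_factory=dict)

    @property
    def unique_gene_count(self) -> int:
        return len(self.candidate_genes)


def select_similar_diseases(
    sim: DiseaseSimilarityTable,
    target: str,
    min_similarity: float = 0.0,
    max_n: int | None = None,
) -> list[str]:
    """Diseases similar to ``target``, most similar first.

    A disease qualifies if it has a recorded positive similarity to the
    target that is at least ``min_similarity``. Ties are broken
    lexicographically by disease id; ``max_n`` truncates the list. A target
    absent from the table yields an empty list with a logged warning.
    """
    if min_similarity < 0:
        raise ValueError("min_similarity must be >= 0")
    if target not in sim.diseases:
        logger.warning("target disease %r absent from similarity table", target)
        return []
    pairs = [
        (d, s)
        for d, s in sim.neighbors(target)
        if d != target and s > 0 and s >= min_similarity
    ]
    pairs.sort(key=lambda ds: (-ds[1], ds[0]))
    diseases = [d for d, _ in pairs]
    return diseases[:max_n] if max_n is not None else diseases


def collect_candidates(
    assoc: DiseaseGeneAssociations,
    similar: list[str],
    target: str,
    similarities: dict[str, float] | None = None,
) -> CandidateSet:
    """Assemble the candidate pool from the similar diseases' gene sets.

    The pool is the union of the similar diseases' gene sets plus the
    target's own known genes (the positives). Similar diseases without
    association records are skipped with a warning — mirroring real
    catalogues where disease subtypes often have no entries of their own.
    """
    candidate_genes: set[str] = set()
    entry_count = 0
    for d in similar:
        if d == target:
            continue
        if d not in assoc:
            logger.warning("similar disease %r has no association records; skipped", d)
            continue
        genes = assoc.genes_of(d)
        candidate_genes |= genes
        entry_count += len(genes)
    positives = assoc.genes_of(target)
    if not positives:
        logger.warning("target disease %r has no known genes", target)
    candidate_genes |= positives
    return CandidateSet(
        target_disease=target,
        similar_diseases=[d for d in similar if d != target],
        candidate_genes=candidate_genes,
        positive_genes=positives,
        entry_count=entry_count,
        similarities=dict(similarities or {}),
    )


def write_candidates(cand: CandidateSet, path: str | Path) -> None:
    """Persist a candidate set as TSV with metadata comment lines."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# target\t{cand.target_disease}\n")
        fh.write("# similar\t" + ",".join(cand.similar_diseases) + "\n")
        fh.write(f"# entry_count\t{cand.entry_count}\n")
        fh.write("gene_id\tis_positive\n")
        for g in sorted(cand.candidate_genes):
            fh.write(f"{g}\t{int(g in cand.positive_genes)}\n")


def read_candidates(path: str | Path) -> CandidateSet:
    target = ""
    similar: list[str] = []
    entry_count = 0
    genes: set[str] = set()
    positives: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                fields = line[1:].strip().split("\t")
                if fields[0] == "target" and len(fields) > 1:
                    target = fields[1]
                elif fields[0] == "similar" and len(fields) > 1:
                    similar = [d for d in fields[1].split(",") if d]
                elif fields[0] == "entry_count" and len(fields) > 1:
                    entry_count = int(fields[1])
                continue
            if not line.strip() or line.startswith("gene_id\t"):
                continue
            g, flag = line.split("\t")[:2]
            genes.add(g)
            if flag.strip() == "1":
                positives.add(g)
    return CandidateSet(
        target_disease=target,
        similar_diseases=similar,
        candidate_genes=genes,
        positive_genes=positives,
        entry_count=entry_count,
    )
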