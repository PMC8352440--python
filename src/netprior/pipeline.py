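"""One-call orchestration of the full prioritization pipeline.

Chains candidate selection, feature extraction, cross-validated
evaluation and final-model ranking; mainly a convenience for benchmark
studies and scripts. On synthetic benchmarks it additionally measures
recovery of the held-out target genes against the generator's ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import candidates as cand_mod
from . import evaluate as eval_mod
from . import features as feat_mod
from . import predict as pred_mod
from .evaluate import CVResult
from .features import FeatureMatrix
from .io import DiseaseGeneAssociations, DiseaseSimilarityTable, GeneNetwork
from .lssvm import LSSVMResults
from .predict import Ranking
from .synthetic import BenchmarkConfig, BenchmarkTruth, generate


@dataclass
class PipelineRun:
    """Everything one end-to-end run produced."""

    target: str
    candidates: cand_mod.CandidateSet
    features: FeatureMatrix
    negatives: set[str]
    cv: CVResult
    final_model: LSSVMResults
    ranking: Ranking
    truth: BenchmarkTruth | None = field(default=None, repr=False)

    @property
    def heldout_in_ranking(self) -> set[str]:
        """Held-out target genes that actually entered the scored pool."""
        if self.truth is None:
            return set()
        scored = {g for g, _ in self.ranking.entries}
        return self.truth.heldout_targets & scored

    def heldout_recovery(self, top_fraction: float = 0.2) -> tuple[int, int]:
        """(recovered, present): held-out genes in the top fraction vs scored."""
        present = self.heldout_in_ranking
        top = self.ranking.top_fraction(top_fraction)
        return len(present & top), len(present)


def run(
    network: GeneNetwork,
    associations: DiseaseGeneAssociations,
    similarities: DiseaseSimilarityTable,
    target: str,
    min_similarity: float = 0.0,
    transform: str = "identity",
    membership_value: float = 1.0,
    k: int = 10,
    gamma: float = 1.0,
    sigma: float | None = None,
    threshold: float = 0.0,
    seed: int = 0,
    stratified: bool = True,
    truth: BenchmarkTruth | None = None,
) -> PipelineRun:
    """Run candidate selection -> features -> CV -> final ranking.

    Negatives are balanced with the positives and sampled with ``seed``,
    which also seeds the fold assignment. Stratified folds are the default
    here because desk-scale benchmarks have few labeled genes.
    """
    similar = cand_mod.select_similar_diseases(similarities, target, min_similarity)
    cand = cand_mod.collect_candidates(
        associations, similar, target,
        similarities={d: similarities.similarity(target, d) for d in similar},
    )
    fm = feat_mod.build_feature_matrix(
        network, cand, associations,
        transform=transform, membership_value=membership_value,
    )
    # balanced negatives, capped by the available unlabeled pool (sparse
    # similarity tables can leave fewer unlabeled candidates than positives)
    n_unlabeled = len(cand.candidate_genes - cand.positive_genes)
    negatives = pred_mod.sample_negatives(
        cand.candidate_genes, cand.positive_genes,
        n=min(len(cand.positive_genes), max(n_unlabeled - 1, 1)), seed=seed,
    )
    cv = eval_mod.cross_validate(
        fm, cand.positive_genes, negatives, k=k, gamma=gamma, sigma=sigma,
        seed=seed, stratified=stratified,
    )
    final = pred_mod.fit_final_model(
        fm, cand.positive_genes, negatives, gamma=gamma, sigma=sigma
    )
    ranking = pred_mod.score_unlabeled(
        final, fm, cand.positive_genes | negatives, threshold
    )
    return PipelineRun(
        target=target, candidates=cand, features=fm, negatives=negatives,
        cv=cv, final_model=final, ranking=ranking, truth=truth,
    )


def run_synthetic(config: BenchmarkConfig, out_dir, **kwargs) -> PipelineRun:
    """Generate a planted benchmark and run the full pipeline on it."""
    truth = generate(config, out_dir)
    kwargs.setdefault("seed", config.seed)
    return run(
        truth.network, truth.associations, truth.similarities,
        truth.target_disease, truth=truth, **kwargs,
    )
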