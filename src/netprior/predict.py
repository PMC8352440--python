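"""Final-model training and ranking of unlabeled candidate genes.

This is a positive-unlabeled task: only the target disease's known genes
are labeled positive. Negatives are drawn uniformly from the unlabeled
candidates (balanced with the positives by default), the LS-SVM is trained
on all labeled genes, and every remaining candidate is scored and ranked.
Genes whose decision score clears the threshold (default 0, the class
boundary) are nominated as novel disease-gene candidates. Sampled
negatives may contain hidden true positives; repeating the sampling and
reporting nomination frequencies quantifies that contamination.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix
from .lssvm import LSSVM, LSSVMResults

__all__ = ["sample_negatives", "Ranking", "fit_final_model",
           "score_unlabeled", "nomination_frequencies"]


def sample_negatives(
    candidates: set[str],
    positives: set[str],
    n: int | None = None,
    seed: int = 0,
) -> set[str]:
    """Uniform sample (without replacement) of presumed negatives.

    Drawn from ``candidates`` minus ``positives``; ``n`` defaults to the
    number of positives (balanced classes). Deterministic given the seed.
    """
    pool = sorted(set(candidates) - set(positives))
    if n is None:
        n = len(set(positives))
    if n > len(pool):
        raise ValueError(
            f"cannot sample {n} negatives from a pool of {len(pool)} "
            "unlabeled candidates"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(pool), size=n, replace=False)
    return {pool[i] for i in picked}


@dataclass
class Ranking:
    """Scored unlabeled genes, best first.

    Entries are sorted by descending score with ties broken
    lexicographically by gene id; ``nominated`` is the prefix whose scores
    reach the threshold.
    """

    entries: list[tuple[str, float]]
    threshold: float
    nominated: set[str]

    @classmethod
    def from_scores(cls, scored: dict[str, float], threshold: float = 0.0) -> "Ranking":
        entries = sorted(scored.items(), key=lambda gs: (-gs[1], gs[0]))
        nominated = {g for g, s in entries if s >= threshold}
        return cls(entries=entries, threshold=threshold, nominated=nominated)

    def rank_of(self, gene: str) -> int:
        """1-based position of a gene in the ranking."""
        for i, (g, _) in enumerate(self.entries, start=1):
            if g == gene:
                return i
        raise KeyError(gene)

    def top_fraction(self, fraction: float) -> set[str]:
        """Genes in the top ``fraction`` of the ranking (at least one)."""
        n = max(1, int(np.ceil(fraction * len(self.entries))))
        return {g for g, _ in self.entries[:n]}


def fit_final_model(
    features: FeatureMatrix,
    positives: set[str],
    negatives: set[str],
    gamma: float = 1.0,
    sigma: float | None = None,
) -> LSSVMResults:
    """Train the LS-SVM on all labeled genes to score the unlabeled pool."""
    positives, negatives = set(positives), set(negatives)
    if positives & negatives:
        raise ValueError("positives and negatives overlap")
    train = sorted(positives | negatives)
    X = features.rows(train)
    y = np.array([1.0 if g in positives else -1.0 for g in train])
    return LSSVM(X, y, gamma=gamma, sigma=sigma).fit(
        gene_ids=train, dimensions=features.dimensions
    )


def score_unlabeled(
    results: LSSVMResults,
    features: FeatureMatrix,
    labeled: set[str],
    threshold: float = 0.0,
) -> Ranking:
    """Score every candidate outside the labeled set and rank them."""
    unlabeled = [g for g in features.genes if g not in labeled]
    if not unlabeled:
        raise ValueError("no unlabeled genes to score")
    scores = results.decision(features.rows(unlabeled))
    return Ranking.from_scores(
        dict(zip(unlabeled, np.asarray(scores, dtype=float))), threshold
    )


def nomination_frequencies(
    features: FeatureMatrix,
    candidates: set[str],
    positives: set[str],
    n_resamples: int = 10,
    gamma: float = 1.0,
    sigma: float | None = None,
    threshold: float = 0.0,
    seed: int = 0,
) -> dict[str, float]:
    """Per-gene nomination frequency over repeated negative samplings.

    Each repetition redraws the balanced negatives, retrains the final
    model and re-nominates; the returned frequency estimates how robust a
    nomination is to the arbitrary choice of presumed negatives.
    """
    counts: Counter[str] = Counter()
    for r in range(n_resamples):
        negatives = sample_negatives(candidates, positives, seed=seed + r)
        res = fit_final_model(features, positives, negatives, gamma=gamma, sigma=sigma)
        ranking = score_unlabeled(res, features, positives | negatives, threshold)
        counts.update(ranking.nominated)
    return {g: counts[g] / n_resamples for g in counts}
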