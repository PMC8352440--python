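"""k-fold cross-validation and threshold-free ranking metrics.

The CV protocol mirrors the standard disease-gene evaluation: the labeled
genes are split into k random groups, each group is held out once while the
LS-SVM is trained on the other k-1, and the held-out decision scores are
pooled into a single ROC and precision-recall curve. AUC is computed by the
Mann-Whitney rank formula (ties credited 1/2) and AUPR by step-wise average
precision; both are also available as explicit curve points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .features import FeatureMatrix
from .lssvm import LSSVM

__all__ = [
    "kfold_split",
    "stratified_kfold_split",
    "roc_auc",
    "pr_auc",
    "CVResult",
    "cross_validate",
    "plot_curves",
]


def kfold_split(items: list[str], k: int, seed: int) -> dict[str, int]:
    """Random assignment of items to k folds of near-equal size.

    Fold sizes differ by at most one (the first ``n mod k`` folds get the
    extra item). The assignment is a deterministic function of the item
    order, k and the seed.
    """
    n = len(items)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of items ({n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    assignment: dict[str, int] = {}
    pos = 0
    for fold, size in enumerate(sizes):
        for idx in order[pos:pos + size]:
            assignment[items[idx]] = fold
        pos += size
    return assignment


def stratified_kfold_split(
    items: list[str], labels: dict[str, int], k: int, seed: int
) -> dict[str, int]:
    """Class-balanced fold assignment (round-robin within each class)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    start = 0
    for cls in sorted(set(labels.values())):
        members = [g for g in items if labels[g] == cls]
        order = rng.permutation(len(members))
        for j, idx in enumerate(order):
            assignment[members[idx]] = (start + j) % k
        start += len(members)  # offset so small classes spread over folds
    return assignment


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = labels == 1
    neg = labels == -1
    if not (pos | neg).all():
        raise ValueError("labels must be coded +1 / -1")
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    return pos, neg


def roc_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC curve points and AUC.

    AUC is the Mann-Whitney statistic P(score+ > score-) + 1/2 P(tie),
    computed from midranks; the curve increments TP and FP simultaneously
    at tied thresholds, so its trapezoidal area equals the rank AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, neg = _check_labels(labels)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    ranks = rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            if labels[order[j]] == 1:
                tp += 1
            else:
                fp += 1
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points, float(auc)


def pr_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """Precision-recall curve points and step-wise area (average precision).

    One (recall, precision) point per distinct threshold; the area is
    sum_i (R_i - R_{i-1}) * P_i, which avoids the optimism of trapezoidal
    interpolation in PR space. The curve is anchored at (0, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, _ = _check_labels(labels)
    n_pos = int(pos.sum())

    order = np.argsort(-scores, kind="stable")
    points: list[tuple[float, float]] = [(0.0, 1.0)]
    tp = fp = 0
    area = 0.0
    prev_recall = 0.0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            if labels[order[j]] == 1:
                tp += 1
            else:
                fp += 1
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        points.append((recall, precision))
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return points, float(area)


@dataclass
class CVResult:
    """Pooled k-fold cross-validation outcome.

    Every labeled gene is tested exactly once; ``pooled_scores`` holds one
    (gene, score, label) triple per gene, scored by the model trained on
    the other folds.
    """

    k: int
    seed: int
    fold_assignments: dict[str, int]
    pooled_scores: list[tuple[str, float, int]]
    roc_points: list[tuple[float, float]] = field(repr=False, default_factory=list)
    pr_points: list[tuple[float, float]] = field(repr=False, default_factory=list)
    auc: float = float("nan")
    aupr: float = float("nan")

    def summary(self) -> str:
        labels = np.array([y for _, _, y in self.pooled_scores])
        lines = [
            f"{self.k}-fold cross-validation (seed {self.seed})",
            "=" * 38,
            f"{'labeled genes':<24}{len(self.pooled_scores):>14d}",
            f"{'positives / negatives':<24}"
            f"{int((labels == 1).sum()):>7d}{int((labels == -1).sum()):>7d}",
            f"{'AUC (ROC)':<24}{self.auc:>14.4f}",
            f"{'AUPR':<24}{self.aupr:>14.4f}",
        ]
        return "\n".join(lines)

    def write_report(self, path: str | Path) -> None:
        from .io import _fmt
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# k\t{self.k}\n# seed\t{self.seed}\n")
            fh.write(f"# auc\t{_fmt(self.auc)}\n# aupr\t{_fmt(self.aupr)}\n")
            fh.write("gene_id\tfold\tscore\tlabel\n")
            for g, s, y in self.pooled_scores:
                fh.write(f"{g}\t{self.fold_assignments[g]}\t{_fmt(s)}\t{y:+d}\n")

    def write_curves(self, roc_path: str | Path, pr_path: str | Path) -> None:
        from .io import _fmt
        with open(roc_path, "w", encoding="utf-8") as fh:
            fh.write("fpr\ttpr\n")
            for x, y in self.roc_points:
                fh.write(f"{_fmt(x)}\t{_fmt(y)}\n")
        with open(pr_path, "w", encoding="utf-8") as fh:
            fh.write("recall\tprecision\n")
            for x, y in self.pr_points:
                fh.write(f"{_fmt(x)}\t{_fmt(y)}\n")


def cross_validate(
    features: FeatureMatrix,
    positives: set[str],
    negatives: set[str],
    k: int = 10,
    gamma: float = 1.0,
    sigma: float | None = None,
    seed: int = 0,
    stratified: bool = False,
) -> CVResult:
    """Pooled k-fold CV of the LS-SVM on labeled candidate genes.

    ``sigma=None`` applies the median-distance heuristic on each training
    split. Plain random folds can by chance contain a single class on small
    data, which is rejected with advice to pass ``stratified=True``.
    """
    positives, negatives = set(positives), set(negatives)
    if positives & negatives:
        raise ValueError("positives and negatives overlap")
    missing = (positives | negatives) - set(features.genes)
    if missing:
        raise ValueError(f"labeled genes missing from the feature matrix: {sorted(missing)[:5]}")
    items = sorted(positives | negatives)
    label_of = {g: (1 if g in positives else -1) for g in items}
    if stratified:
        folds = stratified_kfold_split(items, label_of, k, seed)
    else:
        folds = kfold_split(items, k, seed)
    for fold in range(k):
        fold_labels = {label_of[g] for g in items if folds[g] == fold}
        if len(fold_labels) < 2:
            raise ValueError(
                f"fold {fold} contains a single class; use stratified=True "
                "(CLI: --stratified) on small or imbalanced data"
            )
    pooled: list[tuple[str, float, int]] = []
    for fold in range(k):
        test = [g for g in items if folds[g] == fold]
        train = [g for g in items if folds[g] != fold]
        X_tr = features.rows(train)
        y_tr = np.array([label_of[g] for g in train], dtype=float)
        res = LSSVM(X_tr, y_tr, gamma=gamma, sigma=sigma).fit()
        scores = res.decision(features.rows(test))
        pooled.extend((g, float(s), label_of[g]) for g, s in zip(test, scores))
    pooled.sort(key=lambda t: t[0])
    s = np.array([x for _, x, _ in pooled])
    y = np.array([x for _, _, x in pooled])
    roc_points, auc = roc_auc(s, y)
    pr_points, aupr = pr_auc(s, y)
    return CVResult(
        k=k, seed=seed, fold_assignments=folds, pooled_scores=pooled,
        roc_points=roc_points, pr_points=pr_points, auc=auc, aupr=aupr,
    )


def plot_curves(cv: CVResult, path: str | Path) -> None:
    """Save ROC and PR curves side by side as an image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(*zip(*cv.roc_points), lw=1.5)
    ax1.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax1.set_xlabel("False positive rate")
    ax1.set_ylabel("True positive rate")
    ax1.set_title(f"ROC (AUC = {cv.auc:.3f})")
    ax2.plot(*zip(*cv.pr_points), lw=1.5)
    ax2.set_xlabel("Recall")
    ax2.set_ylabel("Precision")
    ax2.set_ylim(0, 1.05)
    ax2.set_title(f"PR (AUPR = {cv.aupr:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
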