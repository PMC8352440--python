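"""Fold assignment, ROC/PR metrics against oracles, cross-validation."""

import itertools

import numpy as np
import pytest

from netprior.evaluate import (
    cross_validate,
    kfold_split,
    pr_auc,
    roc_auc,
    stratified_kfold_split,
)


class TestKFoldSplit:
    def test_even_division(self):
        items = [f"g{i}" for i in range(10)]
        folds = kfold_split(items, k=5, seed=0)
        sizes = np.bincount(list(folds.values()), minlength=5)
        assert sorted(sizes) == [2, 2, 2, 2, 2]

    def test_remainder_rule(self):
        items = [f"g{i}" for i in range(11)]
        folds = kfold_split(items, k=5, seed=0)
        sizes = sorted(np.bincount(list(folds.values()), minlength=5))
        assert sizes == [2, 2, 2, 2, 3]

    def test_deterministic_and_seed_sensitive(self):
        items = [f"g{i}" for i in range(23)]
        base = kfold_split(items, k=4, seed=5)
        assert kfold_split(items, k=4, seed=5) == base
        different = sum(kfold_split(items, k=4, seed=s) != base
                        for s in range(20) if s != 5)
        assert different >= 18  # distinct seeds almost always reshuffle

    def test_every_item_assigned_once(self):
        items = [f"g{i}" for i in range(17)]
        folds = kfold_split(items, k=5, seed=1)
        assert set(folds) == set(items)

    @pytest.mark.parametrize("n,k", [(3, 4), (5, 1)])
    def test_bad_k_rejected(self, n, k):
        with pytest.raises(ValueError):
            kfold_split([f"g{i}" for i in range(n)], k=k, seed=0)

    def test_stratified_folds_have_both_classes(self):
        items = [f"g{i}" for i in range(20)]
        labels = {g: (1 if i < 10 else -1) for i, g in enumerate(items)}
        folds = stratified_kfold_split(items, labels, k=5, seed=3)
        for fold in range(5):
            classes = {labels[g] for g in items if folds[g] == fold}
            assert classes == {1, -1}


def pair_counting_auc(scores, labels):
    """Oracle: exhaustive concordant/tied pair counting."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == -1]
    total = 0.0
    for sp, sn in itertools.product(pos, neg):
        if sp > sn:
            total += 1.0
        elif sp == sn:
            total += 0.5
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.3, 0.1], [1, 1, -1, -1])
        assert auc == 1.0

    def test_inverted_labels(self):
        _, auc = roc_auc([0.9, 0.8, 0.3, 0.1], [-1, -1, 1, 1])
        assert auc == 0.0

    def test_worked_example_three_quarters(self):
        _, auc = roc_auc([0.9, 0.3, 0.6, 0.2], [1, 1, -1, -1])
        assert auc == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        scores = rng.integers(0, 6, size=n).astype(float)  # many ties
        labels = rng.choice([1, -1], size=n)
        if len(set(labels)) < 2:
            labels[0] = -labels[0]
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)

    def test_complement_identity_exact(self):
        rng = np.random.default_rng(42)
        scores = rng.normal(size=25)
        labels = rng.choice([1, -1], size=25)
        labels[0], labels[1] = 1, -1
        _, auc = roc_auc(scores, labels)
        _, auc_flipped = roc_auc(scores, -labels)
        assert auc + auc_flipped == 1.0

    def test_curve_endpoints_and_trapezoid_area(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 4, size=20).astype(float)
        labels = rng.choice([1, -1], size=20)
        labels[:2] = [1, -1]
        points, auc = roc_auc(scores, labels)
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)
        xs, ys = zip(*points)
        assert np.trapezoid(ys, xs) == pytest.approx(auc, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(9)
        for _ in range(5):
            scores = rng.normal(size=30)
            labels = rng.choice([1, -1], size=30)
            labels[:2] = [1, -1]
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestPrAuc:
    def test_perfect_separation(self):
        _, aupr = pr_auc([0.9, 0.8, 0.3, 0.1], [1, 1, -1, -1])
        assert aupr == 1.0

    def test_constant_scores_give_prevalence(self):
        _, aupr = pr_auc([0.5] * 10, [1, 1, 1, -1, -1, -1, -1, -1, -1, -1])
        assert aupr == pytest.approx(0.3)

    def test_worked_example_ten_twelfths(self):
        _, aupr = pr_auc([0.9, 0.3, 0.6, 0.2], [1, 1, -1, -1])
        assert aupr == pytest.approx(10.0 / 12.0)

    def test_matches_sklearn_average_precision(self):
        from sklearn.metrics import average_precision_score
        rng = np.random.default_rng(21)
        for _ in range(10):
            scores = rng.normal(size=25)
            labels = rng.choice([1, -1], size=25)
            labels[:2] = [1, -1]
            _, aupr = pr_auc(scores, labels)
            assert aupr == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12
            )

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_auc([0.1, 0.2], [-1, -1])

    def test_curve_anchored_and_in_unit_square(self):
        points, aupr = pr_auc([0.9, 0.3, 0.6, 0.2], [1, 1, -1, -1])
        assert points[0] == (0.0, 1.0)
        assert all(0 <= r <= 1 and 0 <= p <= 1 for r, p in points)
        assert 0 < aupr <= 1


class TestCrossValidate:
    def test_deterministic_given_seed(self, bench):
        kwargs = dict(k=10, seed=7, stratified=True)
        a = cross_validate(bench.features, bench.cand.positive_genes,
                          bench.negatives, **kwargs)
        b = cross_validate(bench.features, bench.cand.positive_genes,
                          bench.negatives, **kwargs)
        assert a.fold_assignments == b.fold_assignments
        assert a.pooled_scores == b.pooled_scores
        assert a.auc == b.auc and a.aupr == b.aupr

    def test_every_gene_tested_once_and_labels_conserved(self, bench):
        cv = cross_validate(bench.features, bench.cand.positive_genes,
                            bench.negatives, k=10, seed=7, stratified=True)
        tested = [g for g, _, _ in cv.pooled_scores]
        assert sorted(tested) == sorted(bench.cand.positive_genes | bench.negatives)
        labels = sorted(y for _, _, y in cv.pooled_scores)
        expected = sorted([1] * len(bench.cand.positive_genes)
                          + [-1] * len(bench.negatives))
        assert labels == expected

    def test_signal_beats_shuffled_null(self, bench):
        """Planted labels score far above the permutation null."""
        cv = cross_validate(bench.features, bench.cand.positive_genes,
                            bench.negatives, k=10, seed=7, stratified=True)
        items = sorted(bench.cand.positive_genes | bench.negatives)
        n_pos = len(bench.cand.positive_genes)
        null_aucs = []
        for s in range(10):
            rng = np.random.default_rng(s)
            perm = rng.permutation(len(items))
            pos_s = {items[i] for i in perm[:n_pos]}
            cv_null = cross_validate(bench.features, pos_s, set(items) - pos_s,
                                     k=10, seed=7, stratified=True)
            null_aucs.append(cv_null.auc)
        assert abs(float(np.mean(null_aucs)) - 0.5) <= 0.1
        assert cv.auc > max(0.7, float(np.mean(null_aucs)) + 0.15)

    def test_one_class_fold_advises_stratification(self):
        from netprior.features import FeatureMatrix
        rng = np.random.default_rng(0)
        # two tight clusters; tiny classes force one-class folds often
        genes = [f"g{i}" for i in range(6)]
        X = rng.normal(size=(6, 2))
        fm = FeatureMatrix(genes=genes, dimensions=["D1", "D2"], raw=X,
                           normalized=X, column_means=X.mean(0),
                           column_sds=X.std(0, ddof=1))
        failed = False
        for seed in range(30):
            try:
                cross_validate(fm, {"g0"}, set(genes[1:]), k=3, seed=seed)
            except ValueError as exc:
                assert "stratified" in str(exc)
                failed = True
                break
        assert failed  # a singleton class cannot fill 3 plain random folds

    def test_overlapping_label_sets_rejected(self, bench):
        with pytest.raises(ValueError):
            cross_validate(bench.features, {"G0000"}, {"G0000"}, k=2, seed=0)

    def test_summary_reports_metrics(self, bench):
        cv = cross_validate(bench.features, bench.cand.positive_genes,
                            bench.negatives, k=5, seed=1, stratified=True)
        assert "AUC" in cv.summary() and "AUPR" in cv.summary()


class TestMetricProperties:
    """Invariants over arbitrary score/label inputs."""

    from hypothesis import given, settings, strategies as st

    scores_labels = st.lists(
        st.tuples(st.integers(0, 5), st.sampled_from([1, -1])),
        min_size=4, max_size=30,
    ).filter(lambda sl: len({y for _, y in sl}) == 2)

    @given(scores_labels)
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_auc_equals_pair_counting_and_complement(self, sl):
        scores = [float(s) for s, _ in sl]
        labels = [y for _, y in sl]
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)
        _, flipped = roc_auc(scores, [-y for y in labels])
        assert auc + flipped == 1.0

    @given(scores_labels)
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_aupr_matches_sklearn_and_stays_in_range(self, sl):
        from sklearn.metrics import average_precision_score
        scores = [float(s) for s, _ in sl]
        labels = [y for _, y in sl]
        _, aupr = pr_auc(scores, labels)
        assert 0.0 < aupr <= 1.0
        assert aupr == pytest.approx(
            average_precision_score(labels, scores), abs=1e-12
        )
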