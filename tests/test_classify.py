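"""Cross-validated one-versus-one logistic models: CV mechanics, ROC
primitives against brute-force oracles, leakage control, held-out scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cffrag.classify import (PairwiseFragmentomicClassifier, apply_heldout,
                             comparisons_for, fit_ovo, ovo_report,
                             repeated_stratified_cv, roc_auc,
                             youden_threshold)


def brute_force_auc(scores, labels):
    """Pair counting over every (positive, negative) pair; ties count 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


def brute_force_youden(scores, labels):
    """Exhaustive maximization of J over midpoint cutpoints."""
    scores = np.asarray(scores, float)
    pos = np.asarray(labels, bool)
    uniq = np.unique(scores)
    cands = [(uniq[:-1] + uniq[1:]) / 2, uniq[:1]][len(uniq) == 1]
    best = (-np.inf, None)
    for t in cands:
        sens = ((scores >= t) & pos).sum() / pos.sum()
        spec = ((scores < t) & ~pos).sum() / (~pos).sum()
        j = sens + spec - 1
        if j > best[0] + 1e-12:
            best = (j, t)
    return best


class TestCVSplits:
    def test_exact_stratification(self):
        labels = np.array(["A"] * 10 + ["B"] * 10)
        for _, _, train, test in repeated_stratified_cv(labels, 2, 5, seed=0):
            assert (labels[test] == "A").sum() == 2
            assert (labels[test] == "B").sum() == 2

    def test_partition_and_determinism(self):
        labels = np.array(["A"] * 13 + ["B"] * 9)
        folds1 = [(r, f, tuple(te)) for r, f, _, te in
                  repeated_stratified_cv(labels, 3, 5, seed=1)]
        folds2 = [(r, f, tuple(te)) for r, f, _, te in
                  repeated_stratified_cv(labels, 3, 5, seed=1)]
        folds3 = [(r, f, tuple(te)) for r, f, _, te in
                  repeated_stratified_cv(labels, 3, 5, seed=2)]
        assert folds1 == folds2
        assert folds1 != folds3
        for r in range(3):
            tests = [set(te) for rr, _, te in folds1 if rr == r]
            assert set().union(*tests) == set(range(22))
            assert sum(len(t) for t in tests) == 22  # disjoint

    def test_small_class_error_names_class(self):
        labels = np.array(["A"] * 10 + ["B"] * 3)
        with pytest.raises(ValueError, match="'B'"):
            list(repeated_stratified_cv(labels, 1, 5))


class TestROCPrimitives:
    def test_separable_and_tied(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    def test_youden_separable_tie_rule(self):
        t, sens, spec = youden_threshold([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert t == pytest.approx(0.5)  # lowest midpoint attaining J=1
        assert sens == 1.0 and spec == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_youden_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed + 100)
        scores = np.round(rng.random(30), 1)
        labels = rng.random(30) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        t, sens, spec = youden_threshold(scores, labels)
        j_best, t_best = brute_force_youden(scores, labels)
        assert sens + spec - 1 == pytest.approx(j_best, abs=1e-12)
        assert t == pytest.approx(t_best, abs=1e-12)

    def test_label_inversion_symmetry(self):
        rng = np.random.default_rng(3)
        scores = rng.random(20)
        labels = rng.random(20) < 0.5
        labels[0], labels[1] = True, False
        j1, _ = brute_force_youden(scores, labels)
        # inverted roles with inverted score direction give the same J
        j2, _ = brute_force_youden(-scores, ~labels)
        assert j1 == pytest.approx(j2, abs=1e-12)


def _separable(n=20, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array(["healthy"] * (n // 2) + ["MPNST"] * (n // 2))
    X = np.where((y == "MPNST")[:, None], rng.normal(4, 0.5, (n, 2)),
                 rng.normal(-4, 0.5, (n, 2)))
    return X, y


class TestClassifier:
    def test_separable_auc_one_and_calls_correct(self):
        X, y = _separable()
        clf = PairwiseFragmentomicClassifier(n_repeats=3, random_state=0).fit(X, y)
        assert clf.auc_ == 1.0
        assert clf.classes_[1] == "MPNST"  # more-malignant label scores high
        pos = clf.sample_scores_[y == "MPNST"]
        neg = clf.sample_scores_[y == "healthy"]
        assert (pos >= clf.threshold_).all() and (neg < clf.threshold_).all()

    def test_no_leakage_from_test_fold(self):
        """Coefficients fitted on a training fold are unchanged when
        test-fold rows are altered or deleted."""
        X, y = _separable(20, seed=1)
        clf = PairwiseFragmentomicClassifier(random_state=0)
        y01 = (y == "MPNST").astype(int)
        train_idx = np.arange(12)
        _, lam1, m1 = clf._fit_single_fold(X, y01, train_idx, fold_seed=7)
        X2 = X.copy()
        X2[15:] += 100.0  # perturb only non-training rows
        _, lam2, m2 = clf._fit_single_fold(X2, y01, train_idx, fold_seed=7)
        assert lam1 == lam2
        np.testing.assert_array_equal(m1.coef_, m2.coef_)
        np.testing.assert_array_equal(m1.intercept_, m2.intercept_)

    def test_duplicating_samples_stable_scores(self):
        X, y = _separable(20, seed=2)
        a = PairwiseFragmentomicClassifier(n_repeats=5, random_state=0).fit(X, y)
        Xd = np.vstack([X, X])
        yd = np.concatenate([y, y])
        b = PairwiseFragmentomicClassifier(n_repeats=5, random_state=0).fit(Xd, yd)
        diff = np.abs(a.sample_scores_ - b.sample_scores_[:len(y)]).mean()
        assert diff < 0.05

    def test_non_finite_features_named(self):
        X, y = _separable()
        X[3, 1] = np.nan
        with pytest.raises(ValueError, match="sample 3"):
            PairwiseFragmentomicClassifier().fit(X, y)

    def test_more_than_two_classes_rejected(self):
        X = np.zeros((6, 2))
        with pytest.raises(ValueError, match="2 classes"):
            PairwiseFragmentomicClassifier().fit(X, ["a"] * 2 + ["b"] * 2 + ["c"] * 2)


class TestHeldout:
    def test_training_row_scores_identically(self):
        X, y = _separable()
        clf = PairwiseFragmentomicClassifier(n_repeats=2, random_state=0).fit(X, y)
        full = clf.score_samples(X)
        again = apply_heldout(clf, X[:3])
        np.testing.assert_allclose(again["score"], full[:3], atol=1e-9)

    def test_empty_heldout(self):
        X, y = _separable()
        clf = PairwiseFragmentomicClassifier(n_repeats=2, random_state=0).fit(X, y)
        out = apply_heldout(clf, np.empty((0, 2)))
        assert len(out) == 0

    def test_dimension_mismatch_rejected(self):
        X, y = _separable()
        clf = PairwiseFragmentomicClassifier(n_repeats=2, random_state=0).fit(X, y)
        with pytest.raises(ValueError, match="dimension"):
            clf.score_samples(np.zeros((2, 5)))

    def test_low_tumor_heldout_called_negative(self):
        """Synthetic on-treatment samples with tumor content near zero score
        below the healthy-vs-MPNST threshold for the length-NMF family."""
        from cffrag.lengths import normalize_rows
        from cffrag.simulate import SimulationConfig, simulate_length_matrix
        cfg = SimulationConfig(
            n_per_group={"healthy": 10, "MPNST": 10, "MPNST_on_treatment": 8},
            n_fragments=20_000, seed=5,
            tumor_content_by_label={"healthy": 0.0, "MPNST": 0.25,
                                    "MPNST_on_treatment": 0.005})
        counts, sheet = simulate_length_matrix(
            cfg, labels_out=["healthy", "MPNST", "MPNST_on_treatment"])
        freq = pd.DataFrame(normalize_rows(counts), index=counts.index)
        labels = sheet.set_index("sample_id")["label"]
        train = labels[labels.isin(["healthy", "MPNST"])].index
        held = labels[labels == "MPNST_on_treatment"].index
        clf = fit_ovo(freq.loc[train], labels.loc[train].to_numpy(), "healthy",
                      "MPNST", family="length_nmf", n_repeats=3, random_state=0)
        out = apply_heldout(clf, freq.loc[held])
        assert (out["call"] == "healthy").mean() > 0.5


class TestReport:
    def test_six_comparisons_for_four_labels(self):
        labels = ["healthy", "PN", "AN", "MPNST"]
        pairs = comparisons_for(labels)
        assert len(pairs) == 6
        # each pair ordered (less, more) malignant
        assert ("healthy", "MPNST") in pairs and ("PN", "AN") in pairs

    def test_auc_matrix_filled_once(self):
        rng = np.random.default_rng(0)
        y = np.repeat(["healthy", "PN", "AN", "MPNST"], 8)
        order = {"healthy": 0, "PN": 1, "AN": 2, "MPNST": 3}
        X = rng.normal(0, 1, (len(y), 2))
        X[:, 0] += [order[l] for l in y]
        tables, scores, models = ovo_report({"raw": X}, y, n_repeats=2,
                                            random_state=1)
        auc = tables["raw"]
        assert auc.notna().sum().sum() == 6
        assert len(models) == 6
        # long table: every sample appears once per comparison it belongs to
        assert len(scores) == 6 * 16
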