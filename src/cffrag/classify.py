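"""One-versus-one logistic classification of cfDNA fragmentomic features.

Each pair of cohort labels gets its own L2-regularized logistic model,
evaluated with ten repeats of stratified 5-fold cross-validation.  All
preprocessing that could leak information across samples — PCA of the
bin-ratio block, fragment-length NMF, founder-profile NMF — is refit inside
every training fold; test-fold samples are projected onto the frozen
training-fold artifacts.  A sample's final score is the median of its
test-fold scores across repeats; discriminative power is summarized by ROC
AUC and an operating threshold chosen by Youden's J.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .lengths import LengthNMF
from .motifs import EndMotifNMF

#: Cohort labels ordered from least to most malignant; in any pairwise
#: comparison the more-malignant label is scored toward 1.
MALIGNANCY_ORDER = ["healthy", "MPNST_NED", "PN", "MPNST_on_treatment", "AN", "MPNST"]

FEATURE_FAMILIES = ("raw", "mds", "binwise", "fprofile", "length_nmf")

DEFAULT_LAMBDA_GRID = np.logspace(-3, 3, 13)


# ---------------------------------------------------------------------------
# ROC primitives
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """ROC AUC via the rank-sum (Mann-Whitney) formula, ties counted 1/2.

    ``labels`` are truthy for the positive class; both classes must be
    present.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def youden_threshold(scores, labels) -> tuple[float, float, float]:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    Candidate cutpoints are midway between consecutive distinct scores; a
    sample is called positive when its score >= threshold.  Ties in J go to
    the lowest threshold.  Returns (threshold, sensitivity, specificity).
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels).astype(bool)
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present to choose a threshold")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        candidates = np.array([uniq[0]])
    else:
        candidates = (uniq[:-1] + uniq[1:]) / 2
    best = None
    for t in candidates:
        called = scores >= t
        sens = (called & pos).sum() / pos.sum()
        spec = (~called & ~pos).sum() / (~pos).sum()
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    _, t, sens, spec = best
    return float(t), float(sens), float(spec)


def repeated_stratified_cv(labels, n_repeats: int = 10, n_folds: int = 5,
                           seed: int | None = 0):
    """Fold assignments of ten-repeat stratified k-fold CV.

    Yields (repeat, fold, train_idx, test_idx); class proportions per fold
    are within one sample of the overall proportions.  Deterministic given
    the seed.
    """
    labels = np.asarray(labels)
    for cls, count in zip(*np.unique(labels, return_counts=True)):
        if count < n_folds:
            raise ValueError(
                f"class {cls!r} has {count} samples, fewer than n_folds={n_folds}")
    splitter = RepeatedStratifiedKFold(n_splits=n_folds, n_repeats=n_repeats,
                                       random_state=seed)
    for i, (train, test) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
        yield i // n_folds, i % n_folds, train, test


# ---------------------------------------------------------------------------
# per-family preprocessing (always refit on training folds only)
# ---------------------------------------------------------------------------

class _Preprocessor:
    """Fold-level feature preprocessing: family-specific reduction followed
    by standardization."""

    def __init__(self, family, seed, *, pca_variance, n_ratio_cols,
                 nmf_components, n_profiles, profile_indices,
                 nmf_restarts, nmf_max_iter, nmf_tol):
        self.family = family
        self.seed = seed
        self.pca_variance = pca_variance
        self.n_ratio_cols = n_ratio_cols
        self.nmf_components = nmf_components
        self.n_profiles = n_profiles
        self.profile_indices = profile_indices
        self.nmf_restarts = nmf_restarts
        self.nmf_max_iter = nmf_max_iter
        self.nmf_tol = nmf_tol

    def fit_transform_train(self, X: np.ndarray) -> np.ndarray:
        if self.family == "binwise":
            n_ratio = self.n_ratio_cols if self.n_ratio_cols is not None else X.shape[1]
            ratio, rest = X[:, :n_ratio], X[:, n_ratio:]
            max_pc = min(ratio.shape) - 1
            self._pca = PCA(n_components=min(self.pca_variance, 0.999),
                            svd_solver="full") if max_pc >= 1 else None
            reduced = self._pca.fit_transform(ratio) if self._pca is not None else ratio
            Xt = np.hstack([reduced, rest])
        elif self.family == "length_nmf":
            self._nmf = LengthNMF(n_components=self.nmf_components,
                                  n_restarts=self.nmf_restarts,
                                  max_iter=self.nmf_max_iter, tol=self.nmf_tol,
                                  random_state=self.seed).fit(X)
            Xt = self._nmf.transform(X)
        elif self.family == "fprofile":
            self._nmf = EndMotifNMF(n_profiles=self.n_profiles,
                                    n_restarts=self.nmf_restarts,
                                    max_iter=self.nmf_max_iter, tol=self.nmf_tol,
                                    random_state=self.seed).fit(X)
            Xt = self._nmf.transform(X)
            if self.profile_indices is not None:
                Xt = Xt[:, list(np.atleast_1d(self.profile_indices))]
        else:  # raw / mds
            Xt = X
        self._scaler = StandardScaler().fit(Xt)
        return self._scaler.transform(Xt)

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.family == "binwise":
            n_ratio = self.n_ratio_cols if self.n_ratio_cols is not None else X.shape[1]
            ratio, rest = X[:, :n_ratio], X[:, n_ratio:]
            reduced = self._pca.transform(ratio) if self._pca is not None else ratio
            Xt = np.hstack([reduced, rest])
        elif self.family in ("length_nmf", "fprofile"):
            Xt = self._nmf.transform(X)
            if self.family == "fprofile" and self.profile_indices is not None:
                Xt = Xt[:, list(np.atleast_1d(self.profile_indices))]
        else:
            Xt = X
        return self._scaler.transform(Xt)


class _RidgeLogit:
    """L2-penalized logistic regression solved by L-BFGS.

    Minimizes sum_i log(1 + exp(-s_i (x_i . w + b))) + (lam / 2) ||w||^2
    (intercept unpenalized), matching the lambda = 1/C convention.  A tiny
    dedicated solver: fold matrices here are a few dozen rows wide and the
    inner grid search fits thousands of them.
    """

    def __init__(self, lam: float):
        self.lam = lam

    def fit(self, X, y, warm=None):
        X = np.asarray(X, dtype=float)
        sgn = 2.0 * np.asarray(y, dtype=float) - 1.0
        d = X.shape[1]

        def fg(wb):
            w, b = wb[:d], wb[d]
            z = sgn * (X @ w + b)
            loss = np.logaddexp(0.0, -z).sum() + 0.5 * self.lam * (w @ w)
            gz = -expit(-z) * sgn
            return loss, np.append(X.T @ gz + self.lam * w, gz.sum())

        x0 = np.zeros(d + 1) if warm is None else np.asarray(warm, dtype=float)
        res = minimize(fg, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 200, "gtol": 1e-8})
        self._params = res.x
        self.coef_ = res.x[None, :d]
        self.intercept_ = res.x[d:]
        return self

    def decision_function(self, X):
        return np.asarray(X, dtype=float) @ self.coef_[0] + self.intercept_[0]

    def predict_proba(self, X):
        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])


@dataclass
class FoldRecord:
    repeat: int
    fold: int
    lam: float
    coef: np.ndarray
    intercept: float
    test_idx: np.ndarray = field(repr=False)


class PairwiseFragmentomicClassifier(BaseEstimator):
    """One-versus-one logistic model over a fragmentomic feature family.

    Parameters
    ----------
    family:
        "raw" (use X as-is), "mds" (scalar diversity score), "binwise"
        (bin-ratio block reduced by per-fold PCA to 90% variance plus arm
        z-scores passed through; give ``n_ratio_cols``), "fprofile"
        (motif spectra -> per-fold founder-profile NMF contributions), or
        "length_nmf" (length-frequency rows -> per-fold NMF weights).
    lambda_grid:
        Regularization strengths (lambda = 1/C); the inner stratified
        ``inner_folds``-fold grid search picks the lambda maximizing mean
        inner AUC (ties to the stronger regularization).
    n_repeats, n_folds:
        Outer CV protocol; defaults are ten repeats of stratified 5-fold.

    Fitted attributes: ``sample_scores_`` (per-sample median test-fold
    score), ``auc_``, ``threshold_`` / ``sensitivity_`` / ``specificity_``
    (Youden), ``cv_records_`` (per-fold lambda and coefficients), and a
    deployable model refit on all training samples for held-out scoring.
    """

    def __init__(self, family: str = "raw", n_repeats: int = 10,
                 n_folds: int = 5, lambda_grid=None, inner_folds: int = 3,
                 random_state: int | None = 0, positive_label=None,
                 pca_variance: float = 0.9, n_ratio_cols: int | None = None,
                 nmf_components: int = 2, n_profiles: int = 6,
                 profile_indices=None, nmf_restarts: int = 1,
                 nmf_max_iter: int = 500, nmf_tol: float = 1e-5):
        self.family = family
        self.n_repeats = n_repeats
        self.n_folds = n_folds
        self.lambda_grid = lambda_grid
        self.inner_folds = inner_folds
        self.random_state = random_state
        self.positive_label = positive_label
        self.pca_variance = pca_variance
        self.n_ratio_cols = n_ratio_cols
        self.nmf_components = nmf_components
        self.n_profiles = n_profiles
        self.profile_indices = profile_indices
        self.nmf_restarts = nmf_restarts
        self.nmf_max_iter = nmf_max_iter
        self.nmf_tol = nmf_tol

    # -- helpers ----------------------------------------------------------

    def _grid(self) -> np.ndarray:
        return (DEFAULT_LAMBDA_GRID if self.lambda_grid is None
                else np.asarray(self.lambda_grid, dtype=float))

    def _positive(self, classes) -> object:
        if self.positive_label is not None:
            if self.positive_label not in classes:
                raise ValueError(f"positive_label {self.positive_label!r} not in data")
            return self.positive_label
        order = {l: i for i, l in enumerate(MALIGNANCY_ORDER)}
        return max(classes, key=lambda c: (order.get(c, -1), str(c)))

    def _preprocessor(self, seed) -> _Preprocessor:
        if self.family not in FEATURE_FAMILIES:
            raise ValueError(f"unknown feature family {self.family!r}")
        return _Preprocessor(
            self.family, seed, pca_variance=self.pca_variance,
            n_ratio_cols=self.n_ratio_cols, nmf_components=self.nmf_components,
            n_profiles=self.n_profiles, profile_indices=self.profile_indices,
            nmf_restarts=self.nmf_restarts, nmf_max_iter=self.nmf_max_iter,
            nmf_tol=self.nmf_tol)

    def _fit_single_fold(self, X, y, train_idx, fold_seed):
        """Fit preprocessing + inner-grid lambda selection + logistic on one
        training fold.  Depends only on the training rows and the fold seed,
        never on the test fold (the no-leakage contract).

        The lambda grid is searched by inner stratified CV maximizing mean
        ROC AUC.  Ties resolve toward the weakest regularization: AUC is
        scale-invariant, so on separable folds every lambda ties at 1 and
        only the least-shrunk fit yields scores whose between-class signal
        dominates fold-to-fold calibration jitter.
        """
        pre = self._preprocessor(fold_seed)
        y_tr = y[train_idx]
        Xt = pre.fit_transform_train(X[train_idx])
        grid = np.sort(self._grid())[::-1]  # strongest regularization first
        k = int(min(self.inner_folds, np.bincount(y_tr).min()))
        if k < 2:
            lam = float(np.median(grid))
            return pre, lam, _RidgeLogit(lam).fit(Xt, y_tr)
        inner = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
        splits = list(inner.split(Xt, y_tr))
        mean_auc = np.zeros(len(grid))
        for tr, va in splits:
            if len(np.unique(y_tr[tr])) < 2 or len(np.unique(y_tr[va])) < 2:
                continue
            warm = None
            for j, lam in enumerate(grid):  # warm-started path
                model = _RidgeLogit(lam).fit(Xt[tr], y_tr[tr], warm=warm)
                warm = model._params
                mean_auc[j] += roc_auc(model.decision_function(Xt[va]),
                                       y_tr[va]) / len(splits)
        best = len(grid) - 1 - int(np.argmax(mean_auc[::-1]))  # ties -> weakest
        lam = float(grid[best])
        return pre, lam, _RidgeLogit(lam).fit(Xt, y_tr)

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.sample_ids_ = list(X.index)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.sample_ids_ = list(range(len(X)))
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y)
        if not np.isfinite(X).all():
            bad = np.argwhere(~np.isfinite(X))[0]
            raise ValueError(
                f"non-finite feature: sample {self.sample_ids_[bad[0]]}, column {bad[1]}")
        classes = sorted(np.unique(y).tolist())
        if len(classes) != 2:
            raise ValueError(f"expected exactly 2 classes, got {classes}")
        pos = self._positive(classes)
        neg = classes[0] if classes[1] == pos else classes[1]
        self.classes_ = np.array([neg, pos], dtype=object)
        y01 = (y == pos).astype(int)

        ss = np.random.SeedSequence(self.random_state)
        fold_seed_root = int(ss.generate_state(1)[0] % (2 ** 31))
        score_by_repeat = np.full((len(y), self.n_repeats), np.nan)
        self.cv_records_ = []
        for repeat, fold, train_idx, test_idx in repeated_stratified_cv(
                y, self.n_repeats, self.n_folds, seed=fold_seed_root):
            fold_seed = (fold_seed_root + 7919 * repeat + 104729 * fold) % (2 ** 31)
            pre, lam, clf = self._fit_single_fold(X, y01, train_idx, fold_seed)
            scores = clf.predict_proba(pre.transform(X[test_idx]))[:, 1]
            score_by_repeat[test_idx, repeat] = scores
            self.cv_records_.append(FoldRecord(repeat, fold, lam,
                                               clf.coef_.ravel().copy(),
                                               float(clf.intercept_[0]),
                                               test_idx.copy()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.sample_scores_ = np.nanmedian(score_by_repeat, axis=1)
        self.score_matrix_ = score_by_repeat
        self.auc_ = roc_auc(self.sample_scores_, y01)
        self.threshold_, self.sensitivity_, self.specificity_ = youden_threshold(
            self.sample_scores_, y01)

        # deployable model: preprocessing and lambda refit on all samples
        final_seed = (fold_seed_root + 15485863) % (2 ** 31)
        self._final_pre, self.lambda_, self._final_clf = self._fit_single_fold(
            X, y01, np.arange(len(y)), final_seed)
        self.n_features_in_ = X.shape[1]
        return self

    def score_samples(self, X) -> np.ndarray:
        """Score samples with the deployed (all-training-data) model."""
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if len(X) == 0:
            return np.array([])
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension {X.shape[1]} != fitted {self.n_features_in_}")
        return self._final_clf.predict_proba(self._final_pre.transform(X))[:, 1]

    def predict(self, X) -> np.ndarray:
        scores = self.score_samples(X)
        return np.where(scores >= self.threshold_, self.classes_[1],
                        self.classes_[0])


# ---------------------------------------------------------------------------
# module-level wrappers
# ---------------------------------------------------------------------------

def fit_ovo(features, labels, class_a, class_b, family: str = "raw",
            **kwargs) -> PairwiseFragmentomicClassifier:
    """Fit one pairwise comparison on the subset of samples with the two
    labels; all other rows are ignored."""
    labels = np.asarray(labels)
    sel = np.isin(labels, [class_a, class_b])
    X = features[sel] if not isinstance(features, pd.DataFrame) else features.loc[sel]
    clf = PairwiseFragmentomicClassifier(family=family, **kwargs)
    return clf.fit(X, labels[sel])


def apply_heldout(model: PairwiseFragmentomicClassifier, X,
                  sample_ids=None) -> pd.DataFrame:
    """Score held-out samples against the frozen model and Youden threshold;
    no refitting of any kind."""
    scores = model.score_samples(X)
    ids = (list(X.index) if isinstance(X, pd.DataFrame) and sample_ids is None
           else sample_ids if sample_ids is not None
           else list(range(len(scores))))
    calls = np.where(scores >= model.threshold_, model.classes_[1],
                     model.classes_[0]) if len(scores) else np.array([])
    return pd.DataFrame({"sample_id": ids, "score": scores, "call": calls})


def comparisons_for(labels) -> list[tuple[str, str]]:
    """All unordered label pairs, each ordered (less, more) malignant."""
    order = {l: i for i, l in enumerate(MALIGNANCY_ORDER)}
    present = sorted(set(labels), key=lambda c: (order.get(c, -1), str(c)))
    return list(itertools.combinations(present, 2))


def ovo_report(features_by_family: dict[str, object], labels,
               comparisons=None, random_state: int | None = 0,
               family_kwargs: dict[str, dict] | None = None,
               **common_kwargs):
    """Fit every comparison x feature family; return the AUC matrices, a
    long-format per-sample score table, and the fitted models.

    ``features_by_family`` maps family name to its feature container (full
    cohort rows, aligned with ``labels``).
    """
    labels = np.asarray(labels)
    if comparisons is None:
        comparisons = comparisons_for(labels)
    family_kwargs = family_kwargs or {}
    present = sorted(set(itertools.chain.from_iterable(comparisons)))
    auc_tables = {}
    models = {}
    rows = []
    for family, X in features_by_family.items():
        auc = pd.DataFrame(np.nan, index=present, columns=present)
        for a, b in comparisons:
            kwargs = dict(common_kwargs)
            kwargs.update(family_kwargs.get(family, {}))
            clf = fit_ovo(X, labels, a, b, family=family,
                          random_state=random_state, **kwargs)
            models[(family, a, b)] = clf
            auc.loc[a, b] = clf.auc_
            for sid, score in zip(clf.sample_ids_, clf.sample_scores_):
                rows.append((sid, f"{a}_vs_{b}", family, score))
        auc_tables[family] = auc
    score_table = pd.DataFrame(rows, columns=["sample_id", "comparison",
                                              "family", "score"])
    return auc_tables, score_table, models
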