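"""NMF deconvolution of cfDNA fragment-length distributions.

Per-sample fragment-length histograms over 30-700 bp are treated as an
admixture of non-negative length "signatures" (cfDNA sources) with
per-sample weights.  In the two-component summary mode, the signature with
a left-shifted peak and stronger 10 bp periodicity is taken as the
tumor-derived source; its normalized weight is the sample's tumor
contribution.  With more components, the weight matrix itself is the
feature set for downstream classification.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .motifs import _best_kl_nmf, _nnls_rows
from .simulate import LENGTH_MAX, LENGTH_MIN, LENGTHS

N_LENGTH_BINS = LENGTH_MAX - LENGTH_MIN + 1  # 671


def length_histogram(lengths) -> np.ndarray:
    """Integer counts over lengths 30..700 inclusive (671 bins).

    Input may be an iterable of fragment lengths or a fragment DataFrame
    with a ``length`` column; fragments are expected pre-filtered to the
    30-700 range.
    """
    if isinstance(lengths, pd.DataFrame):
        lengths = lengths["length"]
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("no fragments: cannot form a length histogram")
    if lengths.min() < LENGTH_MIN or lengths.max() > LENGTH_MAX:
        raise ValueError(f"lengths outside [{LENGTH_MIN}, {LENGTH_MAX}]; filter first")
    return np.bincount(lengths - LENGTH_MIN, minlength=N_LENGTH_BINS)


def length_matrix(fragments_by_sample: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """n x 671 count matrix, rows indexed by sample id, columns 30..700."""
    return pd.DataFrame(
        {sid: length_histogram(df) for sid, df in fragments_by_sample.items()},
        index=LENGTHS).T


def normalize_rows(counts) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("zero-count histogram row")
    return counts / totals


def detrended_autocorrelation(density: np.ndarray, lag: int = 10,
                              lo: int = 80, hi: int = 160) -> float:
    """Autocorrelation at ``lag`` of a length density over the
    sub-mononucleosomal [lo, hi] bp window after removing the smooth trend
    (centered moving average, window = lag).  Detrending is what exposes
    the 10 bp fragmentation ladder: the raw density is dominated by the
    broad nucleosomal hump, which correlates strongly at every short lag."""
    seg = np.asarray(density, dtype=float)[lo - LENGTH_MIN:hi - LENGTH_MIN + 1]
    kernel = np.ones(lag) / lag
    trend = np.convolve(seg, kernel, mode="same")
    seg = seg - trend
    denom = (seg * seg).sum()
    if denom <= 0:
        return 0.0
    return float((seg[:-lag] * seg[lag:]).sum() / denom)


def periodicity_score(signature: np.ndarray, lag: int = 10,
                      lo: int = 80, hi: int = 160) -> float:
    """10 bp-ladder strength of a length signature: detrended
    autocorrelation at lag 10 over 80-160 bp (tumor-derived cfDNA hallmark)."""
    return detrended_autocorrelation(signature, lag=lag, lo=lo, hi=hi)


def signature_mean_length(signature: np.ndarray) -> float:
    signature = np.asarray(signature, dtype=float)
    return float((signature * LENGTHS).sum() / signature.sum())


class LengthNMF(BaseEstimator, TransformerMixin):
    """Fragment-length signature model.

    KL-divergence multiplicative-update NMF of the n x 671 row-normalized
    length-frequency matrix, random initialization, best of ``n_restarts``
    restarts.  Signatures are stored row-stochastic (each sums to 1) with
    training weights rescaled compensatingly — a pure gauge change that
    leaves the reconstruction W . S untouched.

    ``transform`` projects new samples onto the frozen signatures by
    non-negative least squares, returning raw non-negative weights.
    """

    def __init__(self, n_components: int = 2, n_restarts: int = 5,
                 max_iter: int = 2000, tol: float = 1e-6,
                 random_state: int | None = 0):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x lengths)")
        k = self.n_components
        if not 2 <= k <= min(X.shape[0], 20):
            raise ValueError(
                f"n_components={k} must lie in [2, min(n_samples, 20)]")
        if (X < 0).any():
            raise ValueError("X must be non-negative")
        W, S, err = _best_kl_nmf(X, k, self.n_restarts, self.max_iter,
                                 self.tol, self.random_state)
        row_sums = S.sum(axis=1)
        row_sums[row_sums == 0] = 1.0
        self.signatures_ = S / row_sums[:, None]
        self.weights_ = W * row_sums[None, :]
        self.reconstruction_err_ = err
        self.tumor_component_ = None
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "signatures_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.signatures_.shape[1]:
            raise ValueError("feature dimension mismatch with fitted signatures")
        # raw non-negative projection weights (not normalized): the
        # classifier standardizes downstream, the tumor-contribution
        # summary normalizes per sample.
        out = np.empty((X.shape[0], self.signatures_.shape[0]))
        for i, row in enumerate(X):
            from scipy.optimize import nnls
            c, _ = nnls(self.signatures_.T, row)
            out[i] = c
        return out

    def identify_tumor_component(self) -> int:
        """Index of the tumor-like signature in the two-component model.

        The tumor source is the signature maximizing the 10 bp periodicity
        score; ties are broken toward the smaller mean fragment length.
        Only defined for k = 2 — with more components, classification uses
        the full weight matrix instead.
        """
        check_is_fitted(self, "signatures_")
        if self.signatures_.shape[0] != 2:
            raise ValueError(
                "tumor-component identification is defined for the 2-component "
                "summary model; use the weight matrix for classification at k > 2")
        per = np.array([periodicity_score(s) for s in self.signatures_])
        mean_len = np.array([signature_mean_length(s) for s in self.signatures_])
        if np.allclose(self.signatures_[0], self.signatures_[1], atol=1e-12):
            warnings.warn("identical signatures: tumor component is ambiguous")
            self.tumor_component_ = 0
            return 0
        candidates = np.flatnonzero(np.isclose(per, per.max(), atol=1e-9))
        idx = int(candidates[np.argmin(mean_len[candidates])])
        self.tumor_component_ = idx
        return idx

    def tumor_contribution(self, X=None) -> np.ndarray:
        """Normalized tumor-source weight per sample, in [0, 1].

        Computed as w_tumor / sum(w) from the training weights, or from
        NNLS-projected weights of ``X`` when given.
        """
        if self.tumor_component_ is None:
            self.identify_tumor_component()
        W = self.weights_ if X is None else self.transform(X)
        totals = W.sum(axis=1)
        out = np.full(len(W), np.nan)
        nz = totals > 0
        out[nz] = W[nz, self.tumor_component_] / totals[nz]
        if (~nz).any():
            warnings.warn("all-zero weight rows: tumor contribution undefined (NaN)")
        return out


def fit_length_nmf(freq_matrix, n_components: int = 2, seed: int | None = 0,
                   **kwargs) -> LengthNMF:
    return LengthNMF(n_components=n_components, random_state=seed,
                     **kwargs).fit(np.asarray(freq_matrix, float))


def identify_tumor_component(model: LengthNMF) -> int:
    return model.identify_tumor_component()


def tumor_contribution(model: LengthNMF, X=None) -> np.ndarray:
    return model.tumor_contribution(X)


def select_k(freq_matrix, labels, k_range=range(2, 21), seed: int = 0,
             n_repeats: int = 10, n_folds: int = 5, **clf_kwargs):
    """Choose the component count maximizing cross-validated ROC AUC.

    For each k, fits the length-NMF inside the classifier's training folds
    and records the repeated-CV AUC of the two-class comparison; returns
    (best_k, DataFrame of per-k AUCs).  Ties go to the smaller k.
    """
    from .classify import PairwiseFragmentomicClassifier

    freq_matrix = np.asarray(freq_matrix, float)
    labels = np.asarray(labels)
    records = []
    for k in k_range:
        if k > min(20, freq_matrix.shape[0]):
            warnings.warn(f"skipping k={k}: exceeds sample count")
            continue
        try:
            clf = PairwiseFragmentomicClassifier(
                family="length_nmf", nmf_components=k, n_repeats=n_repeats,
                n_folds=n_folds, random_state=seed, **clf_kwargs)
            clf.fit(freq_matrix, labels)
            records.append((k, clf.auc_))
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"skipping k={k}: {exc}")
    if not records:
        raise ValueError("no component count could be fitted")
    table = pd.DataFrame(records, columns=["k", "auc"])
    best = table.loc[table["auc"].idxmax(), "k"]  # idxmax -> first max -> smallest k
    return int(best), table
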