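"""cfDNA fragment end-motif analysis.

Each fragment end contributes the 4-mer of reference sequence read 5'->3'
on its template strand; a sample's motif spectrum is the frequency vector
over the 256 possible 4-mers.  Three summaries are provided:

* the motif diversity score (MDS): Shannon entropy of the spectrum
  normalized to [0, 1] by the 8-bit maximum,
* "founder" end-motif profiles (F-profiles): NMF signatures over the 256
  motifs, capturing distinct nuclease cutting preferences, and
* per-sample F-profile contributions by non-negative least squares against
  fixed profiles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import NMF
from sklearn.utils.validation import check_is_fitted

from .simulate import MOTIFS


def motif_spectrum(fragments: pd.DataFrame) -> pd.Series:
    """Motif frequency vector over the 256 4-mers (lexicographic order).

    Both fragment ends are counted where a motif is present; frequencies
    are counts divided by the total number of counted ends.
    """
    counts = motif_counts(fragments)
    total = counts.sum()
    if total == 0:
        raise ValueError("no motif observations: cannot form a spectrum")
    return counts / total


def motif_counts(fragments: pd.DataFrame) -> pd.Series:
    ends = pd.concat([fragments["motif5p_left"], fragments["motif5p_right"]])
    ends = ends.dropna()
    counts = ends.value_counts().reindex(MOTIFS, fill_value=0)
    counts.index.name = None
    return counts.astype(int)


def spectra_matrix(fragments_by_sample: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """n x 256 motif-frequency matrix, rows indexed by sample id."""
    return pd.DataFrame(
        {sid: motif_spectrum(df) for sid, df in fragments_by_sample.items()}
    ).T[MOTIFS]


def motif_diversity_score(spectrum) -> float:
    """Normalized Shannon entropy of a motif spectrum, on [0, 1].

    MDS = -sum p_i log2 p_i / log2 256, with 0 log 0 = 0 and no
    pseudocounts; 1 for the uniform spectrum, 0 for a point mass.
    """
    p = np.asarray(spectrum, dtype=float)
    if (p < 0).any():
        raise ValueError("spectrum must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("spectrum has zero mass")
    p = p / total
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum() / np.log2(256))


def _nnls_rows(X: np.ndarray, profiles: np.ndarray) -> np.ndarray:
    """Row-wise NNLS of X (n x m) onto profiles (K x m), normalized to sum 1."""
    coefs = np.empty((X.shape[0], profiles.shape[0]))
    for i, row in enumerate(X):
        c, _ = nnls(profiles.T, row)
        s = c.sum()
        if s <= 0:
            warnings.warn("all-zero NNLS solution; falling back to uniform contributions")
            c = np.full_like(c, 1.0 / len(c))
            s = 1.0
        coefs[i] = c / s
    return coefs


class EndMotifNMF(BaseEstimator, TransformerMixin):
    """Founder end-motif profile model.

    Factorizes an n x 256 motif-frequency matrix M ~ W . F with F a
    ``n_profiles`` x 256 non-negative matrix (KL divergence, multiplicative
    updates, random initialization; best of ``n_restarts`` restarts kept).
    After fitting, F rows are normalized to sum to 1 with W rescaled
    compensatingly, so each profile is itself a motif distribution.

    ``transform`` returns per-sample profile contributions (fractions
    summing to 1) by non-negative least squares against the frozen
    profiles — the deployment path for held-out samples.
    """

    def __init__(self, n_profiles: int = 6, n_restarts: int = 10,
                 max_iter: int = 1000, tol: float = 1e-6,
                 random_state: int | None = 0):
        self.n_profiles = n_profiles
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x motifs)")
        if self.n_profiles < 1 or self.n_profiles > X.shape[0]:
            raise ValueError(
                f"n_profiles={self.n_profiles} must lie in [1, n_samples={X.shape[0]}]")
        if (X < 0).any():
            raise ValueError("X must be non-negative")
        W, F, err = _best_kl_nmf(X, self.n_profiles, self.n_restarts,
                                 self.max_iter, self.tol, self.random_state)
        row_sums = F.sum(axis=1)
        row_sums[row_sums == 0] = 1.0
        self.profiles_ = F / row_sums[:, None]
        self.weights_ = W * row_sums[None, :]
        self.reconstruction_err_ = err
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "profiles_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.profiles_.shape[1]:
            raise ValueError("feature dimension mismatch with fitted profiles")
        return _nnls_rows(X, self.profiles_)


def _best_kl_nmf(X, k, n_restarts, max_iter, tol, random_state):
    """KL-divergence multiplicative-update NMF, best of several restarts."""
    ss = np.random.SeedSequence(random_state)
    best = None
    for child in ss.spawn(max(1, n_restarts)):
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sklearn convergence chatter
            model = NMF(n_components=k, init="random", solver="mu",
                        beta_loss="kullback-leibler", max_iter=max_iter,
                        tol=tol, random_state=seed)
            W = model.fit_transform(X)
        if best is None or model.reconstruction_err_ < best[2]:
            best = (W, model.components_, model.reconstruction_err_)
    return best


def fit_fprofiles(spectra, n_profiles: int = 6, **kwargs) -> EndMotifNMF:
    """Fit founder profiles on a spectra matrix (n x 256)."""
    return EndMotifNMF(n_profiles=n_profiles, **kwargs).fit(np.asarray(spectra, float))


def fprofile_contributions(spectrum, profiles, percent: bool = True) -> np.ndarray:
    """NNLS contributions of fixed profiles to one spectrum.

    Solves argmin_{c>=0} ||spectrum - c^T profiles||_2 and normalizes; by
    default the result is on the percent scale (sums to 100).
    """
    spectrum = np.atleast_2d(np.asarray(spectrum, dtype=float))
    profiles = np.asarray(profiles, dtype=float)
    c = _nnls_rows(spectrum, profiles)[0]
    return c * 100.0 if percent else c
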