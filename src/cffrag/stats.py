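"""Cohort-level statistical comparisons.

Two-sample Kolmogorov-Smirnov tests on fragment-length distributions,
Kruskal-Wallis omnibus tests with Dunn post-hoc pairwise comparisons,
leave-one-out Wilcoxon rank-sum scans, and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


def _adjust(p, method: str) -> np.ndarray:
    """Multiple-testing adjustment: BH step-up, Holm step-down, or
    Bonferroni (textbook formulas; clipped to 1)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    out = np.empty(n)
    if method == "bh":
        ranked = p[order] * n / np.arange(1, n + 1)
        out[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    elif method == "holm":
        ranked = p[order] * (n - np.arange(n))
        out[order] = np.maximum.accumulate(ranked)
    elif method == "bonferroni":
        out = p * n
    else:
        raise ValueError(f"unknown adjustment {method!r}")
    return np.minimum(out, 1.0)


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    groups: tuple
    n: tuple
    adjustment: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def as_row(self) -> dict:
        return {"test": self.test_name, "groups": "|".join(map(str, self.groups)),
                "n": "|".join(map(str, self.n)), "statistic": self.statistic,
                "p_value": self.p_value, "adjustment": self.adjustment or ""}


def ks_two_sample(a, b, group_names=("a", "b")) -> TestResult:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b|, asymptotic p-value.

    Fragment-count sample sizes in this context are large, so the
    asymptotic two-sided distribution is appropriate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, method="asymp")
    return TestResult("ks_two_sample", float(res.statistic), float(res.pvalue),
                      tuple(group_names), (a.size, b.size))


def kruskal_dunn(groups: dict, adjust: str = "holm"
                 ) -> tuple[TestResult, list[TestResult]]:
    """Kruskal-Wallis H (tie-corrected) with Dunn pairwise post-hoc tests.

    Dunn z statistics compare mean ranks on the pooled ranking:
    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    where T = sum(t^3 - t) / (12 (N - 1)) corrects for ties.  Pairwise
    p-values are adjusted by ``adjust`` (holm default; bh / bonferroni
    accepted).
    """
    names = list(groups)
    if len(names) < 3:
        raise ValueError("need >= 3 groups; use a rank-sum test for two")
    values = [np.asarray(groups[g], dtype=float) for g in names]
    if any(v.size == 0 for v in values):
        raise ValueError("all groups must be non-empty")
    all_tied = len(np.unique(np.concatenate(values))) == 1
    if all_tied:
        omnibus = TestResult("kruskal_wallis", 0.0, 1.0, tuple(names),
                             tuple(v.size for v in values))
    else:
        h, p = sps.kruskal(*values)
        omnibus = TestResult("kruskal_wallis", float(h), float(p), tuple(names),
                             tuple(v.size for v in values))

    pooled = np.concatenate(values)
    ranks = sps.rankdata(pooled)
    n_tot = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum() / (12 * (n_tot - 1))
                if n_tot > 1 else 0.0)
    mean_ranks, sizes = {}, {}
    offset = 0
    for g, v in zip(names, values):
        mean_ranks[g] = ranks[offset:offset + v.size].mean()
        sizes[g] = v.size
        offset += v.size

    pairs = list(itertools.combinations(names, 2))
    zs, ps = [], []
    for g1, g2 in pairs:
        var = (n_tot * (n_tot + 1) / 12 - tie_term) * (1 / sizes[g1] + 1 / sizes[g2])
        z = 0.0 if var <= 0 else (mean_ranks[g1] - mean_ranks[g2]) / np.sqrt(var)
        zs.append(z)
        ps.append(1.0 if var <= 0 else 2 * sps.norm.sf(abs(z)))
    adj = _adjust(ps, adjust)
    pairwise = [TestResult("dunn", float(z), float(p_adj), (g1, g2),
                           (sizes[g1], sizes[g2]), adjustment=adjust,
                           extra={"p_raw": float(p_raw)})
                for (g1, g2), z, p_raw, p_adj in zip(pairs, zs, ps, adj)]
    return omnibus, pairwise


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test; exact null
    distribution for small tie-free samples, normal approximation with
    continuity/tie correction otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult("wilcoxon_rank_sum", float(res.statistic),
                      float(res.pvalue), ("a", "b"), (a.size, b.size))


def loo_wilcoxon_scan(reference, comparison) -> pd.DataFrame:
    """Leave-one-out Wilcoxon rank-sum scan.

    For each sample left out of the comparison group, the remaining
    comparison values are tested against the full reference group; returns
    -log10 p per left-out sample.
    """
    reference = np.asarray(reference, dtype=float)
    comparison = np.asarray(comparison, dtype=float)
    if reference.size < 2:
        raise ValueError("reference group must have >= 2 samples")
    if comparison.size < 2:
        raise ValueError("comparison group must have >= 2 samples")
    rows = []
    for i in range(comparison.size):
        rest = np.delete(comparison, i)
        res = wilcoxon_rank_sum(reference, rest)
        rows.append((i, res.statistic, res.p_value,
                     -np.log10(max(res.p_value, np.finfo(float).tiny))))
    return pd.DataFrame(rows, columns=["left_out", "statistic", "p_value",
                                       "neg_log10_p"])


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return _adjust(p, "bh")


def results_table(results) -> pd.DataFrame:
    """Tidy CSV-ready table of TestResults."""
    return pd.DataFrame([r.as_row() for r in results])
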