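"""Bin-wise fragmentation profiles.

Per sample, fragments are GC-reweighted toward a healthy-cohort target GC
distribution (100 discrete strata), assigned to non-overlapping 5 Mb
genomic bins by their midpoint, and summarized as the ratio of short
(100-150 bp) to long (151-220 bp) weighted fragment mass per bin.  The
per-sample ratio profile is standardized within sample; companion
chromosome-arm z-scores are computed from LOESS GC-residualized short and
long counts, center-scaled by the healthy-control arm mean and standard
deviation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

SHORT_WINDOW = (100, 150)
LONG_WINDOW = (151, 220)
N_GC_STRATA = 100

#: Non-acrocentric autosomal arms of the human genome: 22 autosomes x 2
#: arms minus the five acrocentric p arms (13p, 14p, 15p, 21p, 22p).
ACROCENTRIC_P = {"chr13p", "chr14p", "chr15p", "chr21p", "chr22p",
                 "13p", "14p", "15p", "21p", "22p"}


def read_bins(path, min_gc: float = 0.3, min_mappability: float = 0.9) -> pd.DataFrame:
    """Read a bin table (chrom, start, end, bin_id, gc, mappability) and
    apply the inclusion filters (mean GC >= 0.3, mean mappability >= 0.9)."""
    bins = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "gc", "mappability"}
    missing = required - set(bins.columns)
    if missing:
        raise ValueError(f"bin table missing columns: {sorted(missing)}")
    if "bin_id" not in bins.columns:
        bins["bin_id"] = [f"{r.chrom}:{r.start}-{r.end}" for r in bins.itertuples()]
    return filter_bins(bins, min_gc, min_mappability)


def filter_bins(bins: pd.DataFrame, min_gc: float = 0.3,
                min_mappability: float = 0.9) -> pd.DataFrame:
    keep = (bins["gc"] >= min_gc) & (bins["mappability"] >= min_mappability)
    return bins[keep].reset_index(drop=True)


def make_bins(chrom_sizes: dict[str, int], bin_size: int = 5_000_000) -> pd.DataFrame:
    """Tile chromosomes into bins from position 0; the terminal partial bin
    is kept (it is subject to the same GC/mappability filters as any other)."""
    rows = []
    for chrom, size in chrom_sizes.items():
        for start in range(0, size, bin_size):
            rows.append((chrom, start, min(start + bin_size, size)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["bin_id"] = [f"{r.chrom}:{r.start}-{r.end}" for r in df.itertuples()]
    return df


# ---------------------------------------------------------------------------
# GC reweighting
# ---------------------------------------------------------------------------

def gc_strata(gc: np.ndarray) -> np.ndarray:
    """Assign GC fractions to 1 of 100 discrete strata between 0 and 1."""
    return np.clip((np.asarray(gc, float) * N_GC_STRATA).astype(int), 0,
                   N_GC_STRATA - 1)


def gc_density(gc: np.ndarray) -> np.ndarray:
    """Empirical GC density over the 100 strata (sums to 1)."""
    counts = np.bincount(gc_strata(gc), minlength=N_GC_STRATA).astype(float)
    return counts / counts.sum()


def target_gc_distribution(healthy_gc: list[np.ndarray]) -> np.ndarray:
    """Target GC density: per-stratum median across healthy samples'
    densities, renormalized to sum to 1."""
    if not healthy_gc:
        raise ValueError("need at least one healthy sample")
    densities = np.vstack([gc_density(g) for g in healthy_gc])
    med = np.median(densities, axis=0)
    total = med.sum()
    if total <= 0:
        raise ValueError("degenerate target GC distribution")
    return med / total


def gc_strata_weights(sample_gc: np.ndarray, target: np.ndarray,
                      cap: float = 10.0) -> np.ndarray:
    """Per-fragment importance weights matching the sample GC distribution
    to the target: weight = target density / sample density of the
    fragment's stratum, capped at ``cap``."""
    target = np.asarray(target, float)
    if target.shape != (N_GC_STRATA,):
        raise ValueError(f"target must have {N_GC_STRATA} strata")
    if np.isclose(target.max(), 1.0):
        warnings.warn("degenerate GC target: all mass in one stratum")
    strata = gc_strata(sample_gc)
    dens = gc_density(sample_gc)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dens > 0, target / np.maximum(dens, 1e-300), 0.0)
    return np.minimum(ratio[strata], cap)


# ---------------------------------------------------------------------------
# bin ratios
# ---------------------------------------------------------------------------

def assign_bins(fragments: pd.DataFrame, bins: pd.DataFrame) -> np.ndarray:
    """Index into ``bins`` of the bin containing each fragment's midpoint;
    -1 where the midpoint falls in no included bin."""
    out = np.full(len(fragments), -1, dtype=int)
    mid = ((fragments["start"].to_numpy() + fragments["end"].to_numpy()) // 2)
    chroms = fragments["chrom"].to_numpy()
    for chrom, grp in bins.groupby("chrom", sort=False):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        pos = np.searchsorted(starts, mid[sel], side="right") - 1
        ok = (pos >= 0) & (mid[sel] < ends[np.clip(pos, 0, len(ends) - 1)])
        res = np.where(ok, grp.index.to_numpy()[np.clip(pos, 0, len(ends) - 1)], -1)
        out[sel] = res
    return out


def bin_weights(fragments: pd.DataFrame, weights: np.ndarray,
                bins: pd.DataFrame, short=SHORT_WINDOW,
                long=LONG_WINDOW) -> pd.DataFrame:
    """GC-adjusted short and long fragment mass per bin.

    Returns a DataFrame indexed like ``bins`` with columns ``short_weight``
    and ``long_weight``; fragments outside both windows contribute to
    neither.
    """
    weights = np.asarray(weights, float)
    if "length" in fragments.columns:
        lengths = fragments["length"].to_numpy()
    else:
        lengths = (fragments["end"] - fragments["start"]).to_numpy()
    idx = assign_bins(fragments, bins)
    out = pd.DataFrame(0.0, index=bins.index,
                       columns=["short_weight", "long_weight"])
    for col, (lo, hi) in (("short_weight", short), ("long_weight", long)):
        sel = (lengths >= lo) & (lengths <= hi) & (idx >= 0)
        out[col] = np.bincount(idx[sel], weights=weights[sel],
                               minlength=len(bins))[bins.index]
    return out


def bin_ratios(fragments: pd.DataFrame, weights: np.ndarray,
               bins: pd.DataFrame, short=SHORT_WINDOW,
               long=LONG_WINDOW) -> pd.Series:
    """Raw short/long ratio per bin; NaN where the long mass is zero."""
    bw = bin_weights(fragments, weights, bins, short, long)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bw["long_weight"] > 0,
                         bw["short_weight"] / bw["long_weight"], np.nan)
    return pd.Series(ratio, index=bins["bin_id"].to_numpy(), name="ratio")


def normalize_profile(ratios: pd.Series) -> pd.Series:
    """Within-sample standardization of the ratio profile (library-size
    normalization): subtract the mean, divide by the standard deviation."""
    vals = ratios.to_numpy(dtype=float)
    mu = np.nanmean(vals)
    sd = np.nanstd(vals)
    if sd == 0 or np.isnan(sd):
        return pd.Series(np.zeros_like(vals), index=ratios.index, name=ratios.name)
    return (ratios - mu) / sd


def impute_missing(ratio_matrix: pd.DataFrame,
                   train_medians: pd.Series | None = None) -> pd.DataFrame:
    """Fill missing bin ratios with the (training-cohort) per-bin median."""
    med = train_medians if train_medians is not None else ratio_matrix.median(axis=0)
    return ratio_matrix.fillna(med).fillna(0.0)


# ---------------------------------------------------------------------------
# arm z-scores
# ---------------------------------------------------------------------------

def assign_arms(bins: pd.DataFrame, arms: pd.DataFrame) -> pd.Series:
    """Arm name per bin (by bin midpoint), excluding acrocentric p arms."""
    mids = (bins["start"] + bins["end"]) // 2
    out = pd.Series(index=bins.index, dtype=object)
    for row in arms.itertuples():
        sel = (bins["chrom"] == row.chrom) & (mids >= row.start) & (mids < row.end)
        out[sel] = row.arm
    out[out.isin(ACROCENTRIC_P)] = None
    return out


def loess_residuals(values: np.ndarray, gc: np.ndarray,
                    frac: float = 0.75) -> np.ndarray:
    """Residuals of per-bin counts against bin GC via LOESS (degree-1
    locally weighted regression); with constant GC the fit is the mean."""
    values = np.asarray(values, float)
    gc = np.asarray(gc, float)
    if np.ptp(gc) == 0:
        return values - values.mean()
    fit = lowess(values, gc, frac=frac, return_sorted=False)
    return values - fit


class ArmZScorer:
    """Center-scale per-arm GC-residualized counts by the healthy cohort.

    ``fit`` takes per-arm short/long values of healthy controls (DataFrames
    samples x arms); ``transform`` returns z = (value - healthy mean) /
    healthy sd per arm.  Arms with zero healthy sd are dropped with a
    warning.
    """

    def fit(self, healthy_short: pd.DataFrame, healthy_long: pd.DataFrame):
        if len(healthy_short) < 2:
            raise ValueError("healthy reference needs >= 2 samples per arm")
        self.mean_short_ = healthy_short.mean(axis=0)
        self.sd_short_ = healthy_short.std(axis=0, ddof=1)
        self.mean_long_ = healthy_long.mean(axis=0)
        self.sd_long_ = healthy_long.std(axis=0, ddof=1)
        bad = (self.sd_short_ == 0) | (self.sd_long_ == 0)
        if bad.any():
            warnings.warn(f"dropping arms with zero healthy sd: {list(bad[bad].index)}")
        self.arms_ = list(self.sd_short_.index[~bad])
        return self

    def transform(self, short: pd.DataFrame, long: pd.DataFrame) -> pd.DataFrame:
        z_s = (short[self.arms_] - self.mean_short_[self.arms_]) / self.sd_short_[self.arms_]
        z_l = (long[self.arms_] - self.mean_long_[self.arms_]) / self.sd_long_[self.arms_]
        z_s.columns = [f"z_short_{a}" for a in self.arms_]
        z_l.columns = [f"z_long_{a}" for a in self.arms_]
        return pd.concat([z_s, z_l], axis=1)


def arm_level_counts(fragments: pd.DataFrame, weights: np.ndarray,
                     bins: pd.DataFrame, arms: pd.DataFrame,
                     loess_frac: float = 0.75) -> tuple[pd.Series, pd.Series]:
    """Per-arm GC-residualized short and long counts for one sample.

    Bin-level short/long mass is residualized against bin GC by LOESS
    across bins, then summed within arms (residualize-then-aggregate).
    """
    bw = bin_weights(fragments, weights, bins)
    arm_of_bin = assign_arms(bins, arms)
    res_s = loess_residuals(bw["short_weight"].to_numpy(), bins["gc"].to_numpy(),
                            frac=loess_frac)
    res_l = loess_residuals(bw["long_weight"].to_numpy(), bins["gc"].to_numpy(),
                            frac=loess_frac)
    keep = arm_of_bin.notna()
    grp = arm_of_bin[keep]
    short = pd.Series(res_s[keep.to_numpy()]).groupby(grp.to_numpy()).sum()
    long = pd.Series(res_l[keep.to_numpy()]).groupby(grp.to_numpy()).sum()
    return short, long


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

def binwise_feature_matrix(fragments_by_sample: dict[str, pd.DataFrame],
                           bins: pd.DataFrame, arms: pd.DataFrame,
                           healthy_ids: list[str],
                           max_missing: float = 0.2,
                           gc_cap: float = 10.0,
                           loess_frac: float = 0.75
                           ) -> tuple[pd.DataFrame, int]:
    """Assemble the bin-ratio + arm-z feature matrix for classification.

    Returns (features DataFrame indexed by sample, n_ratio_cols).  The
    first ``n_ratio_cols`` columns are the standardized (and median-imputed)
    bin-ratio profile — the block the classifier reduces by PCA inside its
    training folds; the remaining columns are arm z-scores against the
    healthy controls in ``healthy_ids``.
    """
    if len(fragments_by_sample) < 2:
        raise ValueError("need >= 2 samples")
    missing_h = [h for h in healthy_ids if h not in fragments_by_sample]
    if missing_h:
        raise ValueError(f"healthy ids absent from cohort: {missing_h}")
    target = target_gc_distribution(
        [fragments_by_sample[h]["gc"].to_numpy() for h in healthy_ids])

    ratio_rows, short_rows, long_rows = {}, {}, {}
    for sid, frags in fragments_by_sample.items():
        w = gc_strata_weights(frags["gc"].to_numpy(), target, cap=gc_cap)
        ratios = bin_ratios(frags, w, bins)
        frac_missing = ratios.isna().mean()
        if frac_missing > max_missing:
            raise ValueError(
                f"sample {sid}: {frac_missing:.0%} of bins missing exceeds "
                f"{max_missing:.0%}")
        ratio_rows[sid] = normalize_profile(ratios)
        s, l = arm_level_counts(frags, w, bins, arms, loess_frac=loess_frac)
        short_rows[sid], long_rows[sid] = s, l

    ratio_df = pd.DataFrame(ratio_rows).T
    ratio_df = impute_missing(ratio_df)
    short_df = pd.DataFrame(short_rows).T
    long_df = pd.DataFrame(long_rows).T
    scorer = ArmZScorer().fit(short_df.loc[healthy_ids], long_df.loc[healthy_ids])
    z_df = scorer.transform(short_df, long_df)
    features = pd.concat([ratio_df, z_df], axis=1)
    return features, ratio_df.shape[1]
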