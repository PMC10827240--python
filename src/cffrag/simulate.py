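"""Synthetic plasma cfDNA cohort generator.

Emulates the statistical structure of cell-free DNA fragment collections in a
hereditary tumor-predisposition cohort with four clinical states (healthy,
plexiform neurofibroma PN, atypical neurofibroma AN, malignant peripheral
nerve sheath tumor MPNST) plus two post-treatment states (MPNST_on_treatment,
MPNST_NED).  Each sample's fragments are drawn from a two-source admixture:

* a "healthy" fragment-length law peaked at the mononucleosomal 167 bp, and
* a "tumor" law with a left-shifted mode and a 10 bp periodic modulation of
  the sub-mononucleosomal density, the hallmarks of circulating tumor DNA;

per-sample mixing weights (tumor content) increase along the malignancy
spectrum healthy < PN < AN < MPNST.  End motifs are drawn from a mixture of
"founder" motif profiles over the 256 possible 5' 4-mers, with label-specific
mixing; bin-wise short-fragment enrichment is planted in designated genomic
bins through label-specific multipliers on the tumor-source propensity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

LENGTH_MIN = 30
LENGTH_MAX = 700
LENGTHS = np.arange(LENGTH_MIN, LENGTH_MAX + 1)

#: All 4-mers over {A,C,G,T} in lexicographic order (AAAA .. TTTT).
MOTIFS = ["".join(p) for p in itertools.product("ACGT", repeat=4)]
MOTIF_INDEX = {m: i for i, m in enumerate(MOTIFS)}

#: Cohort labels in increasing order of malignancy (training classes).
LABELS = ["healthy", "PN", "AN", "MPNST"]
HELDOUT_LABELS = ["MPNST_on_treatment", "MPNST_NED"]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "gc", "motif5p_left", "motif5p_right"]


@dataclass(frozen=True)
class LengthParams:
    """Parameters of the discretized skew-normal fragment-length law.

    ``mode`` is the location of the density maximum in bp; ``scale`` the
    skew-normal scale; ``skew`` the shape (negative = left shoulder, as seen
    in plasma cfDNA); ``periodicity`` the amplitude in [0, 1] of a cosine
    modulation with 10 bp period applied below ``periodic_below`` bp.
    """

    mode: float = 167.0
    scale: float = 25.0
    skew: float = -4.0
    periodicity: float = 0.0
    period: float = 10.0
    periodic_below: int = 160


@dataclass(frozen=True)
class GenomeConfig:
    """Toy genome used to place synthetic fragments.

    ``n_chrom`` chromosomes of equal ``chrom_length``, tiled into
    ``bin_size`` bins; the centromere sits at the midpoint so each
    chromosome contributes a p and a q arm.
    """

    n_chrom: int = 4
    chrom_length: int = 60_000_000
    bin_size: int = 5_000_000

    @property
    def chroms(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def bins(self) -> pd.DataFrame:
        rows = []
        for c in self.chroms:
            for start in range(0, self.chrom_length, self.bin_size):
                end = min(start + self.bin_size, self.chrom_length)
                rows.append((c, start, end))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df["bin_id"] = [f"{r.chrom}:{r.start}-{r.end}" for r in df.itertuples()]
        # flat GC / mappability: synthetic bins all pass inclusion filters
        df["gc"] = 0.45
        df["mappability"] = 0.95
        return df

    def arms(self) -> pd.DataFrame:
        mid = self.chrom_length // 2
        rows = []
        for c in self.chroms:
            rows.append((c, 0, mid, f"{c}p"))
            rows.append((c, mid, self.chrom_length, f"{c}q"))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "arm"])


def default_founder_profiles(k: int = 6, concentration: float = 1.2,
                             seed: int = 20_240_301) -> np.ndarray:
    """K row-stochastic founder end-motif profiles over the 256 4-mers.

    Profiles are Dirichlet draws (fixed internal seed so the defaults are a
    constant of the package, not of the cohort seed), with the last profile
    re-weighted toward CC-initial ("CCNN") motifs, mirroring the
    DNASE1L3-like cutting preference expected of one founder process.
    """
    rng = np.random.default_rng(seed)
    profiles = rng.dirichlet(np.full(256, concentration), size=k)
    cc = np.array([m.startswith("CC") for m in MOTIFS])
    profiles[-1, cc] *= 8.0
    profiles /= profiles.sum(axis=1, keepdims=True)
    return profiles


def _default_founder_mixes(k: int = 6) -> dict[str, np.ndarray]:
    """Label-specific founder mixing weights on the K-simplex.

    The CCNN-enriched final profile loses weight, and the first profile
    gains weight, with malignancy — a monotone, recoverable contrast.
    """
    base = np.full(k, 1.0 / k)
    mixes = {}
    shift = {"healthy": 0.0, "PN": 0.04, "AN": 0.08, "MPNST": 0.16,
             "MPNST_on_treatment": 0.06, "MPNST_NED": 0.02}
    for label, s in shift.items():
        m = base.copy()
        m[0] += s
        m[-1] -= s * 0.75
        m[1] -= s * 0.25
        mixes[label] = m / m.sum()
    return mixes


def _default_bin_multipliers(labels: dict[str, float], n_bins: int,
                             planted_bins: tuple[int, ...]) -> dict[str, np.ndarray]:
    mult = {"healthy": 1.0, "PN": 1.5, "AN": 2.0, "MPNST": 3.0,
            "MPNST_on_treatment": 1.5, "MPNST_NED": 1.0}
    out = {}
    for label in labels:
        a = np.ones(n_bins)
        a[list(planted_bins)] = mult.get(label, 1.0)
        out[label] = a
    return out


@dataclass
class SimulationConfig:
    """Full description of a synthetic cohort.

    Defaults reproduce the cohort structure of the study the generator
    emulates: group sizes healthy 21 / PN 69 / AN 17 / MPNST 35 (plus 10
    on-treatment and 15 NED held-out samples) and a tumor-content ordering
    healthy < PN < AN < MPNST.
    """

    n_per_group: dict[str, int] = field(default_factory=lambda: {
        "healthy": 21, "PN": 69, "AN": 17, "MPNST": 35,
        "MPNST_on_treatment": 10, "MPNST_NED": 15})
    n_fragments: int = 100_000
    tumor_content_by_label: dict[str, float] = field(default_factory=lambda: {
        "healthy": 0.0, "PN": 0.02, "AN": 0.06, "MPNST": 0.20,
        "MPNST_on_treatment": 0.04, "MPNST_NED": 0.01})
    tumor_content_cv: float = 0.35     # per-sample lognormal spread around the label mean
    healthy_length: LengthParams = field(default_factory=LengthParams)
    tumor_mode_shift: float = -20.0
    tumor_periodicity: float = 0.5
    founder_profiles: np.ndarray = field(default_factory=default_founder_profiles)
    founder_mix_by_label: dict[str, np.ndarray] = field(default_factory=_default_founder_mixes)
    planted_bins: tuple[int, ...] = (3, 11, 17, 25, 33, 41)
    bin_aberration_by_label: dict[str, np.ndarray] | None = None
    gc_beta: tuple[float, float] = (16.0, 22.0)   # Beta params, mean ~0.42
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    seed: int = 0

    def __post_init__(self):
        self.founder_profiles = np.asarray(self.founder_profiles, dtype=float)
        validate_config(self)
        if self.bin_aberration_by_label is None:
            n_bins = len(self.genome.bins())
            self.bin_aberration_by_label = _default_bin_multipliers(
                self.tumor_content_by_label, n_bins, self.planted_bins)

    @property
    def tumor_length(self) -> LengthParams:
        return replace(self.healthy_length,
                       mode=self.healthy_length.mode + self.tumor_mode_shift,
                       periodicity=self.tumor_periodicity)

    def to_yaml(self, path) -> None:
        d = {
            "n_per_group": dict(self.n_per_group),
            "n_fragments": int(self.n_fragments),
            "tumor_content_by_label": {k: float(v) for k, v in self.tumor_content_by_label.items()},
            "tumor_content_cv": float(self.tumor_content_cv),
            "healthy_length": {k: float(getattr(self.healthy_length, k))
                               for k in ("mode", "scale", "skew", "periodicity", "period", "periodic_below")},
            "tumor_mode_shift": float(self.tumor_mode_shift),
            "tumor_periodicity": float(self.tumor_periodicity),
            "founder_profiles": self.founder_profiles.tolist(),
            "founder_mix_by_label": {k: np.asarray(v, float).tolist()
                                     for k, v in self.founder_mix_by_label.items()},
            "planted_bins": list(self.planted_bins),
            "gc_beta": list(self.gc_beta),
            "genome": {"n_chrom": self.genome.n_chrom,
                       "chrom_length": self.genome.chrom_length,
                       "bin_size": self.genome.bin_size},
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


def validate_config(config: "SimulationConfig") -> None:
    """Reject configurations violating the generator's invariants."""
    for label, w in config.tumor_content_by_label.items():
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"tumor content for {label!r} must lie in [0, 1], got {w}")
    order = [config.tumor_content_by_label.get(l) for l in LABELS
             if l in config.tumor_content_by_label]
    if any(a > b for a, b in zip(order, order[1:])):
        raise ValueError(
            "tumor content must be non-decreasing along healthy <= PN <= AN <= MPNST")
    F = config.founder_profiles
    if F.ndim != 2 or F.shape[1] != 256:
        raise ValueError(f"founder_profiles must be K x 256, got {F.shape}")
    if (F < 0).any():
        raise ValueError("founder_profiles must be non-negative")
    if not np.allclose(F.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("founder profile rows must sum to 1 (within 1e-9)")
    for label, mix in config.founder_mix_by_label.items():
        mix = np.asarray(mix, float)
        if (mix < 0).any():
            raise ValueError(f"founder mix for {label!r} has negative entries")
        if not np.isclose(mix.sum(), 1.0, atol=1e-9):
            raise ValueError(f"founder mix for {label!r} must sum to 1 (within 1e-9)")
    if config.n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if all(n == 0 for n in config.n_per_group.values()):
        raise ValueError("at least one cohort label must have n_per_group > 0")


# ---------------------------------------------------------------------------
# length model
# ---------------------------------------------------------------------------

def _skewnorm_mode_offset(skew: float, scale: float) -> float:
    """Mode of skewnorm(a=skew, loc=0, scale=scale), located numerically."""
    x = np.linspace(-4 * scale, 4 * scale, 8001)
    return float(x[np.argmax(stats.skewnorm.pdf(x, a=skew, scale=scale))])


def length_pmf(params: LengthParams) -> np.ndarray:
    """Discrete fragment-length law on [30, 700] with the requested mode.

    Skew-normal density, shifted so its maximum falls at ``params.mode``,
    then (optionally) modulated by ``1 + A cos(2 pi l / period)`` below
    ``periodic_below`` bp and renormalized.
    """
    loc = params.mode - _skewnorm_mode_offset(params.skew, params.scale)
    pmf = stats.skewnorm.pdf(LENGTHS, a=params.skew, loc=loc, scale=params.scale)
    if params.periodicity:
        mod = 1.0 + params.periodicity * np.cos(2 * np.pi * LENGTHS / params.period)
        pmf = np.where(LENGTHS < params.periodic_below, pmf * mod, pmf)
    total = pmf.sum()
    if total <= 0:
        raise ValueError("degenerate length law: zero mass on [30, 700]")
    return pmf / total


def mixture_length_pmf(healthy: LengthParams, tumor: LengthParams,
                       tumor_weight: float) -> np.ndarray:
    if not 0.0 <= tumor_weight <= 1.0:
        raise ValueError(f"tumor_weight must lie in [0, 1], got {tumor_weight}")
    return (1.0 - tumor_weight) * length_pmf(healthy) + tumor_weight * length_pmf(tumor)


def simulate_length_distribution(healthy: LengthParams, tumor: LengthParams,
                                 tumor_weight: float, n: int,
                                 rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` fragment lengths from the healthy/tumor mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pmf = mixture_length_pmf(healthy, tumor, tumor_weight)
    return rng.choice(LENGTHS, size=n, p=pmf)


# ---------------------------------------------------------------------------
# motif model
# ---------------------------------------------------------------------------

def simulate_motifs(founder_profiles: np.ndarray, mix: np.ndarray, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` motif indices (0..255) from the mixture mix^T . F."""
    founder_profiles = np.asarray(founder_profiles, float)
    mix = np.asarray(mix, float)
    if (mix < 0).any():
        raise ValueError("mixture entries must be non-negative")
    if not np.isclose(mix.sum(), 1.0, atol=1e-9):
        raise ValueError("mixture must sum to 1")
    if not np.allclose(founder_profiles.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("founder profile rows must sum to 1")
    p = mix @ founder_profiles
    return rng.choice(256, size=n, p=p / p.sum())


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSample:
    sample_id: str
    label: str
    true_tumor_weight: float
    fragments: pd.DataFrame


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    samples: list[SyntheticSample]

    @property
    def sample_sheet(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.sample_id, s.label, s.true_tumor_weight) for s in self.samples],
            columns=["sample_id", "label", "true_tumor_weight"])

    def fragments_by_sample(self) -> dict[str, pd.DataFrame]:
        return {s.sample_id: s.fragments for s in self.samples}

    def write(self, outdir) -> None:
        """Write fragment tables (TSV), sample sheet (CSV), and config YAML."""
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s in self.samples:
            s.fragments.to_csv(outdir / f"{s.sample_id}.fragments.tsv",
                               sep="\t", index=False)
        self.sample_sheet.to_csv(outdir / "sample_sheet.csv", index=False)
        self.config.to_yaml(outdir / "config.yaml")
        self.config.genome.bins().to_csv(outdir / "bins.tsv", sep="\t", index=False)
        self.config.genome.arms().to_csv(outdir / "arms.tsv", sep="\t", index=False)


def _sample_tumor_weight(mean: float, cv: float, rng: np.random.Generator) -> float:
    """Per-sample tumor content: lognormal spread around the label mean."""
    if mean <= 0:
        return 0.0
    sigma = np.sqrt(np.log1p(cv ** 2))
    w = mean * rng.lognormal(-sigma ** 2 / 2, sigma)
    return float(np.clip(w, 0.0, 1.0))


def _simulate_sample(config: SimulationConfig, sample_id: str, label: str,
                     rng: np.random.Generator) -> SyntheticSample:
    n = config.n_fragments
    bins = config.genome.bins()
    n_bins = len(bins)
    w = _sample_tumor_weight(config.tumor_content_by_label[label],
                             config.tumor_content_cv, rng)

    bin_idx = rng.integers(0, n_bins, size=n)
    mult = config.bin_aberration_by_label[label]
    p_tumor = np.clip(w * mult[bin_idx], 0.0, 1.0)
    is_tumor = rng.random(n) < p_tumor

    lengths = np.empty(n, dtype=np.int64)
    pmf_h = length_pmf(config.healthy_length)
    pmf_t = length_pmf(config.tumor_length)
    n_t = int(is_tumor.sum())
    if n_t < n:
        lengths[~is_tumor] = rng.choice(LENGTHS, size=n - n_t, p=pmf_h)
    if n_t:
        lengths[is_tumor] = rng.choice(LENGTHS, size=n_t, p=pmf_t)

    starts = (bins["start"].to_numpy()[bin_idx]
              + rng.integers(0, config.genome.bin_size - LENGTH_MAX, size=n))
    ends = starts + lengths
    gc = rng.beta(*config.gc_beta, size=n)

    mix = np.asarray(config.founder_mix_by_label[label], float)
    motif_idx = simulate_motifs(config.founder_profiles, mix, 2 * n, rng)
    motifs = np.asarray(MOTIFS, dtype=object)[motif_idx]

    frags = pd.DataFrame({
        "chrom": bins["chrom"].to_numpy()[bin_idx],
        "start": starts,
        "end": ends,
        "gc": np.round(gc, 4),
        "motif5p_left": motifs[:n],
        "motif5p_right": motifs[n:],
    })
    frags = frags.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return SyntheticSample(sample_id, label, w, frags)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort, deterministically given the seed.

    Each sample gets its own RNG substream derived from the cohort seed and
    a running sample counter, so cohorts are reproducible under any
    evaluation order.
    """
    validate_config(config)
    samples = []
    counter = 0
    for label in LABELS + HELDOUT_LABELS:
        n_samples = config.n_per_group.get(label, 0)
        for _ in range(n_samples):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(counter,)))
            sample_id = f"S{counter:04d}_{label}"
            samples.append(_simulate_sample(config, sample_id, label, rng))
            counter += 1
    if not samples:
        raise ValueError("configuration produced zero samples")
    return SyntheticCohort(config, samples)


# ---------------------------------------------------------------------------
# fast matrix-level paths (histograms drawn directly, no per-fragment tables)
# ---------------------------------------------------------------------------

def simulate_length_matrix(config: SimulationConfig,
                           labels_out: list[str] | None = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample length-count matrix drawn multinomially from the mixture law.

    Equivalent in distribution to histogramming ``simulate_cohort`` fragments
    (without bin-level aberrations) but orders of magnitude faster; used for
    simulation studies that only need length spectra.  Returns (counts
    DataFrame indexed by sample over columns 30..700, sample sheet).
    """
    validate_config(config)
    pmf_h = length_pmf(config.healthy_length)
    pmf_t = length_pmf(config.tumor_length)
    rows, meta = [], []
    counter = 0
    for label in labels_out or (LABELS + HELDOUT_LABELS):
        for _ in range(config.n_per_group.get(label, 0)):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(counter,)))
            w = _sample_tumor_weight(config.tumor_content_by_label[label],
                                     config.tumor_content_cv, rng)
            pmf = (1 - w) * pmf_h + w * pmf_t
            rows.append(rng.multinomial(config.n_fragments, pmf))
            meta.append((f"S{counter:04d}_{label}", label, w))
            counter += 1
    sheet = pd.DataFrame(meta, columns=["sample_id", "label", "true_tumor_weight"])
    counts = pd.DataFrame(rows, index=sheet["sample_id"].to_list(),
                          columns=LENGTHS)
    return counts, sheet


def simulate_motif_matrix(config: SimulationConfig,
                          labels_out: list[str] | None = None,
                          n_ends: int | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample motif-count matrix drawn multinomially from mix^T . F."""
    validate_config(config)
    n_ends = n_ends if n_ends is not None else 2 * config.n_fragments
    rows, meta = [], []
    counter = 0
    for label in labels_out or (LABELS + HELDOUT_LABELS):
        mix = np.asarray(config.founder_mix_by_label[label], float)
        p = mix @ config.founder_profiles
        p = p / p.sum()
        for _ in range(config.n_per_group.get(label, 0)):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(counter,)))
            rows.append(rng.multinomial(n_ends, p))
            meta.append((f"S{counter:04d}_{label}", label))
            counter += 1
    sheet = pd.DataFrame(meta, columns=["sample_id", "label"])
    counts = pd.DataFrame(rows, index=sheet["sample_id"].to_list(), columns=MOTIFS)
    return counts, sheet
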