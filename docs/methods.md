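# Methods

## Problem setting

Plasma cell-free DNA (cfDNA) is an admixture of fragments released by many
tissues. Tumor-derived fragments are on average shorter than
healthy-tissue cfDNA, carry a stronger 10 bp sub-mononucleosomal
fragmentation ladder, and differ in the nuclease cutting preferences
visible at fragment ends. `cffrag` quantifies three fragment-level feature
families — binned short/long fragment-ratio profiles, 4-mer end-motif
spectra, and NMF deconvolution of fragment-length histograms — and uses
them in pairwise logistic classification of clinical states in an NF1
peripheral-nerve-tumor cohort (healthy, PN, AN, MPNST, plus held-out
on-treatment and no-evidence-of-disease groups).

## Fragment model and filters

A fragment is a 0-based half-open interval with GC fraction and,
optionally, the two 5' terminal 4-mers. From alignments, one record is
emitted per properly paired, primary, non-duplicate pair; "perfect
alignment" (the gate for motif extraction) is operationalized strictly:
both mates primary and mapped, CIGAR entirely aligned-match, and zero edit
distance when the NM tag is present. Both ends yield motifs read 5'→3' on
their template strand: the left motif is the first four reference bases of
the interval, the right motif the reverse complement of the last four;
ambiguous (N) bases suppress that end's motif. Counting both ends doubles
the signal and matches the founder-profile end-motif literature.
Analysis-ready fragments are restricted to lengths 30–700 bp (inclusive);
blacklist exclusion and autosome restriction are optional filters, and a
separate 90–150 bp size selection is provided as the export step feeding
external copy-number tumor-fraction tools. Libraries pass QC only with
>80% mapped bases, <0.3% error rate, >85% unique reads and >75% Q30 bases
(strict inequalities).

## Bin-wise fragmentation profiles

The genome is tiled into non-overlapping 5 Mb bins from position 0 of each
chromosome (the terminal partial bin is kept); bins with mean GC < 0.3 or
mean mappability < 0.9 are excluded. Fragment-level GC correction is
importance reweighting over 100 discrete GC strata: the target density is
the per-stratum median of the healthy controls' GC densities
(renormalized), and each fragment's weight is target density / sample
density of its stratum, capped at 10 for variance control (strata with no
sample mass contribute nothing). When no weight is capped this makes the
weighted sample GC histogram equal the target on the sample's support —
an identity the tests verify to total variation 1e-6.

Per bin, the short (100–150 bp) and long (151–220 bp) weighted masses form
the ratio short/long; fragments are assigned to the bin containing their
midpoint, avoiding double counting at bin edges. The per-sample ratio
profile is standardized within sample (subtract mean, divide by sd) as the
library-size normalization; missing ratios (zero long mass) are imputed
with the training-cohort per-bin median because PCA needs complete
matrices. Arm-level z-scores are computed residualize-then-aggregate:
bin-level short and long masses are residualized against bin GC by LOESS
(degree 1, span 0.75 — the conventional default; with constant GC the fit
reduces to the mean), summed within non-acrocentric autosomal arms (39
arms in the human genome: 22 autosomes × 2 minus 13p, 14p, 15p, 21p, 22p;
the synthetic genome has no acrocentric arms), and center-scaled by the
healthy-control mean and sd per arm. Arms with zero healthy sd are dropped
with a warning.

## End motifs

A sample's motif spectrum is the frequency vector over the 256 4-mers in
lexicographic order, counting every present end. The motif diversity
score is normalized Shannon entropy, MDS = −Σ pᵢ log₂ pᵢ / log₂ 256, with
0·log 0 = 0 and no pseudocounts, so 1 is the uniform spectrum and 0 a
point mass. Founder profiles (F-profiles) are the components of a
KL-divergence NMF of the n×256 spectra matrix (multiplicative updates,
random initialization, best of 10 restarts); rows of the profile matrix
are normalized to sum to 1 with the weights rescaled compensatingly, a
pure gauge choice. K defaults to 6 profiles; the synthetic generator's
sixth default profile is enriched for CC-initial motifs so the
DNASE1L3-like contrast is recoverable. Per-sample contributions to fixed
profiles are obtained by non-negative least squares and normalized (an
all-zero solution falls back to uniform with a warning); contributions are
scale-invariant in the input spectrum.

## Fragment-length deconvolution

Per-sample length histograms over 30–700 bp (671 columns, zero-count
columns retained so dimensions align) are row-normalized and factorized by
KL-divergence NMF (multiplicative updates, tol 1e-6, max 2000 iterations,
5 random restarts keeping the best divergence at module level; the
classifier's fold-level fits use 1 restart and a lighter tolerance since
they are repeated 50 times per comparison). Signatures are stored
row-stochastic. In the two-component summary model the tumor source is
identified as the signature maximizing a 10 bp periodicity score — the
autocorrelation at lag 10 of the 80–160 bp signature segment after
removing the smooth trend with a centered 10 bp moving average — with
ties broken toward the smaller mean length. Detrending matters: the raw
density is dominated by the broad nucleosomal hump, which autocorrelates
strongly at every short lag, while the ladder survives detrending only at
multiples of 10 bp. A sample's tumor contribution is the tumor-component
weight divided by the sum of its weights. With more components the weight
matrix itself is the classifier feature set; the component count can be
chosen per comparison by cross-validated AUC (`select_k`, ties to the
smaller k).

## Classification

Each pair of cohort labels gets an L2-regularized logistic model evaluated
with ten repeats of stratified 5-fold cross-validation (class proportions
preserved per fold; folds deterministic given the seed). Everything that
could leak across samples — PCA of the bin-ratio block to 90% explained
variance, length-NMF signatures, founder profiles, feature scaling — is
refit inside each training fold, and test-fold samples are projected onto
the frozen artifacts (NNLS for NMF weights). The regularization strength
lambda is chosen per fold from 13 log-spaced points over [1e-3, 1e3] by
inner stratified 3-fold CV maximizing mean AUC; ties resolve toward the
weakest regularization, because AUC is scale-invariant — on separable
folds every lambda ties at AUC 1 and only the least-shrunk fit keeps the
between-class signal above fold-to-fold calibration jitter when scores
are pooled. The inner solve is a dedicated L-BFGS implementation of the
penalized logistic objective (lambda = 1/C, intercept unpenalized),
warm-started along the lambda path.

A sample's final score is the median of its test-fold scores across the
ten repeats (each sample appears exactly once per repeat). The positive
class is the more-malignant label of the pair, so scores near 1 mean
malignant. Discrimination is summarized by ROC AUC (rank-sum formula,
ties ½) and the operating threshold by Youden's J maximized over
cutpoints midway between consecutive distinct scores (ties to the lowest
threshold; a sample is called positive at score ≥ threshold). A
deployable model is refit on all training samples with its own inner
lambda selection; held-out samples (on-treatment, NED) are scored against
it and called at the stored threshold without any refitting.

## Cohort statistics

KS tests use the asymptotic two-sided distribution (fragment-scale sample
sizes); Kruskal–Wallis uses the tie-corrected H; Dunn pairwise z
statistics compare mean ranks on the pooled ranking with tie correction,
adjusted by Holm by default (BH and Bonferroni available — the adjustment
is a configuration choice). The leave-one-out Wilcoxon scan tests, for
each left-out sample of the comparison group, the remaining values
against the full reference group, reporting −log₁₀ p. Wilcoxon uses the
exact null distribution for small tie-free samples and the
continuity-corrected normal approximation otherwise. KS tests pool
fragments per cohort by default; per-sample testing is available.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not raw sequencing. Fragment lengths follow a discretized skew-normal law
(scale 25, shape −4 for the left shoulder) with the healthy mode at the
mononucleosomal 167 bp; the tumor law is the same family shifted −20 bp
with a cosine modulation of period 10 bp and amplitude 0.5 below 160 bp,
truncated to [30, 700]. Each sample mixes the two laws with a tumor
weight drawn lognormally (CV 0.35) around its label mean: healthy 0.00,
PN 0.02, AN 0.06, MPNST 0.20, on-treatment 0.04, NED 0.01. The source
study reports no absolute tumor contents per label, so these means are
free parameters chosen once to be realistic for low-burden neurofibromas
versus macroscopic sarcomas and to respect the ordering
healthy < PN < AN < MPNST; they were not revisited. Default group sizes
mirror the study cohort (21/69/17/35 plus 10 on-treatment and 15 NED).

End motifs are drawn i.i.d. per end from mixᵀ·F with six default founder
profiles (Dirichlet draws under a fixed internal seed, the last
re-weighted toward CCNN motifs) and label-specific mixes that shift
monotonically with malignancy. Fragments are placed uniformly across a
toy genome (four 60 Mb chromosomes, twelve 5 Mb bins each, centromere at
the midpoint); bin aberrations act as label-specific multipliers on the
probability that a fragment drawn in that bin is tumor-derived
(P(tumor|bin) = clip(w·a_bin, 0, 1)), with multipliers 3/2/1.5 for
MPNST/AN/PN in six planted bins — this is what creates recoverable
bin-ratio aberrations. GC fractions are Beta(16, 22) (mean ≈ 0.42),
independent of length. One RNG substream per sample, derived from the
cohort seed and a sample counter, makes cohorts byte-identical across
runs and robust to evaluation order.

What the generator does **not** emulate: sequencing error, alignment
artifacts, duplicate structure, GC–length coupling, copy-number profiles,
within-genome GC variation (synthetic bins share one GC value), or
between-patient biological heterogeneity beyond the tumor-weight spread.
Passing tests therefore demonstrate that the pipeline recovers the
planted statistical structure faithfully and without leakage — not that
real plasma cohorts achieve any particular accuracy.

## Problem sizes in tests and the acceptance script

Simulation studies use cohorts sized for the property being tested:
weight-recovery runs use 60 samples × 1e5 fragments over 50 seeds
(tests) or 20 seeds (acceptance script); the detectability-ordering study
uses 12 samples per label × 1e4 fragments over 20 (tests) or 10
(acceptance script) seeds, with single-restart fold-level NMF; null
calibration uses 1000 replicates per test. Fold-level NMF restarts and
iteration caps are exposed as classifier parameters so heavier settings
can be used when model quality, not protocol verification, is the goal.

## Known limitations

* The two fragment ends are sampled independently in the generator;
  real fragments correlate end motifs with fragment length and position.
* LOESS residualization is degenerate on the synthetic genome's constant
  bin GC (it reduces to mean-centering); the real-genome path is
  exercised through the linear-data equivalence test instead.
* Youden thresholds on small cohorts are high-variance; they are always
  re-derived per cohort and never reused as constants.
* `select_k` refits the NMF for every candidate k inside every training
  fold; for the full 2..20 range this is the dominant cost and is left to
  the user's budget.
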