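# cffrag — plasma cfDNA fragmentomics for peripheral nerve sheath tumors

Patients with neurofibromatosis type 1 (NF1) progress along a spectrum of
peripheral nerve sheath tumors: benign plexiform neurofibromas (PN),
pre-malignant atypical neurofibromas (AN), and malignant peripheral nerve
sheath tumors (MPNST). Copy-number-based liquid biopsy detects MPNST but
cannot separate the low-copy-number PN and AN states. `cffrag` implements a
fragmentomic alternative: it extracts fragment-level features from plasma
cell-free DNA (cfDNA) whole-genome sequencing and classifies samples among
clinical states with one-versus-one cross-validated logistic models.

The package is for computational biologists building or evaluating
cfDNA-based early-detection pipelines. It provides:

* **Fragment ingestion** (`cffrag.io`) — fragments from paired-end SAM/BAM
  (interval, GC, 5' end 4-mers from the reference for perfectly aligned
  pairs) or plain fragment tables; 30–700 bp length filter, blacklist and
  autosome filters, 90–150 bp in-silico size selection, and the library QC
  gate (>80% mapped bases, <0.3% error rate, >85% unique reads, >75% Q30).
* **Bin-wise fragmentation profiles** (`cffrag.binwise`) — GC-adjusted
  short (100–150 bp) to long (151–220 bp) fragment-ratio profiles in 5 Mb
  bins (bins with mean GC < 0.3 or mappability < 0.9 excluded), plus
  chromosome-arm z-scores from LOESS GC-residualized counts center-scaled
  by healthy controls.
* **End-motif analysis** (`cffrag.motifs`) — 256-motif 5' 4-mer spectra,
  the motif diversity score MDS = −Σ pᵢ log₂ pᵢ / log₂ 256 ∈ [0, 1], NMF
  "founder" end-motif profiles (F-profiles), and per-sample F-profile
  contributions by non-negative least squares.
* **Fragment-length deconvolution** (`cffrag.lengths`) — per-sample length
  histograms over 30–700 bp factorized by Kullback–Leibler NMF
  (multiplicative updates, random restarts) into length signatures and
  sample weights; in the two-component model the left-shifted, 10
  bp-periodic signature is the tumor source and its normalized weight the
  tumor contribution.
* **Classification** (`cffrag.classify`) — per label pair, an
  L2-regularized logistic model with ten repeats of stratified 5-fold CV;
  all preprocessing (PCA to 90% variance, NMF) is refit inside training
  folds; per-sample score = median test-fold score across repeats; ROC AUC
  and a Youden-index operating threshold; frozen models score held-out
  samples.
* **Cohort statistics** (`cffrag.stats`) — two-sample KS tests,
  Kruskal–Wallis with Dunn post-hoc, leave-one-out Wilcoxon scans,
  Benjamini–Hochberg adjustment.
* **Synthetic cohorts** (`cffrag.simulate`) — a generator whose samples
  mix a healthy length law (mode 167 bp) with a left-shifted, 10
  bp-periodic tumor law, founder-motif mixtures, and planted bin-level
  short-fragment enrichment, with tumor content ordered
  MPNST > AN > PN > healthy. Every downstream stage is testable against
  this ground truth.

## Worked example

```python
import numpy as np
from cffrag import LengthNMF, PairwiseFragmentomicClassifier
from cffrag.lengths import normalize_rows
from cffrag.simulate import SimulationConfig, simulate_length_matrix

cfg = SimulationConfig(n_per_group={"healthy": 30, "MPNST": 30},
                       n_fragments=100_000, seed=7)
counts, sheet = simulate_length_matrix(cfg, labels_out=["healthy", "MPNST"])
freq = normalize_rows(counts)

model = LengthNMF(n_components=2, random_state=3).fit(freq)
idx = model.identify_tumor_component()
r = np.corrcoef(model.tumor_contribution(), sheet["true_tumor_weight"])[0, 1]
print(f"tumor component: {idx}, weight-recovery r = {r:.3f}")

clf = PairwiseFragmentomicClassifier(family="length_nmf", random_state=1)
clf.fit(freq, sheet["label"].to_numpy())
print(f"healthy vs MPNST AUC = {clf.auc_:.3f}, "
      f"Youden threshold = {clf.threshold_:.3f}")
```

Output:

```
tumor component: 1, weight-recovery r = 1.000
healthy vs MPNST AUC = 1.000, Youden threshold = 0.497
```

The fitted two-component model separates a smooth mononucleosomal
signature from a left-shifted periodic one; the normalized weight of the
periodic signature tracks each sample's true tumor fraction essentially
perfectly at this depth, and the cross-validated classifier separates the
two groups completely (AUC 1.0; the threshold is the score cutpoint
maximizing sensitivity + specificity − 1).

A full run (simulate → features → train → report) is available from the
command line:

```bash
cffrag run --out runs/demo --seed 7
```

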