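"""End-to-end pipeline orchestration.

simulate (or ingest) -> filter -> feature extraction (length histograms,
end-motif spectra, MDS, bin-wise profiles) -> one-versus-one training ->
scoring and reports, with a manifest capturing configuration, seeds and
output checksums.  Reruns with an identical configuration produce
numerically identical outputs.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binwise import binwise_feature_matrix
from .classify import apply_heldout, comparisons_for, ovo_report
from .io import filter_fragments, read_fragment_table
from .lengths import length_matrix, normalize_rows
from .motifs import motif_diversity_score, spectra_matrix
from .simulate import (HELDOUT_LABELS, LABELS, GenomeConfig, SimulationConfig,
                       simulate_cohort)
from .stats import kruskal_dunn, ks_two_sample, results_table

DEFAULT_CONFIG = {
    "mode": "synthetic",
    "input_dir": None,
    "families": ["length_nmf", "fprofile", "mds", "binwise"],
    "comparisons": None,
    "seed": 0,
    "simulation": {},
    "filters": {"min_len": 30, "max_len": 700, "autosomes_only": False},
    "classifier": {"n_repeats": 10, "n_folds": 5, "inner_folds": 3,
                   "lambda_grid": None, "nmf_components": 2, "n_profiles": 6,
                   "nmf_restarts": 2, "nmf_max_iter": 600,
                   "pca_variance": 0.9},
}

_SIMULATION_KEYS = {"n_per_group", "n_fragments", "tumor_content_by_label",
                    "tumor_content_cv", "tumor_mode_shift", "tumor_periodicity",
                    "planted_bins", "gc_beta", "genome", "seed"}


class ConfigError(ValueError):
    pass


def _check_keys(section: dict, allowed, where: str, errors: list):
    for key in section:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            errors.append(f"unknown key {key!r} in {where}{suffix}")


def validate_config(config: dict) -> dict:
    """Range-check every parameter and reject unknown keys; returns the
    merged (defaults + overrides) configuration."""
    errors: list[str] = []
    _check_keys(config, DEFAULT_CONFIG, "config", errors)
    merged = {**DEFAULT_CONFIG, **config}
    for section in ("filters", "classifier", "simulation"):
        base = DEFAULT_CONFIG.get(section) or {}
        merged[section] = {**base, **(config.get(section) or {})}
    _check_keys(merged["filters"], DEFAULT_CONFIG["filters"], "filters", errors)
    _check_keys(merged["classifier"], DEFAULT_CONFIG["classifier"], "classifier", errors)
    _check_keys(merged["simulation"], _SIMULATION_KEYS, "simulation", errors)

    if merged["mode"] not in ("synthetic", "fragment_tables"):
        errors.append(f"mode must be synthetic or fragment_tables, got {merged['mode']!r}")
    if merged["mode"] == "fragment_tables":
        if not merged["input_dir"]:
            errors.append("fragment_tables mode requires input_dir")
        elif not Path(merged["input_dir"]).exists():
            errors.append(f"input_dir does not exist: {merged['input_dir']}")
    if not isinstance(merged["seed"], (int, np.integer)):
        errors.append(f"seed must be an integer, got {merged['seed']!r}")
    clf = merged["classifier"]
    for key, lo in (("n_repeats", 1), ("n_folds", 2), ("inner_folds", 2),
                    ("nmf_components", 2), ("n_profiles", 1)):
        if not (isinstance(clf[key], (int, np.integer)) and clf[key] >= lo):
            errors.append(f"classifier.{key} must be an integer >= {lo}, got {clf[key]!r}")
    flt = merged["filters"]
    if flt["min_len"] > flt["max_len"]:
        errors.append("filters.min_len exceeds filters.max_len")
    bad_fam = set(merged["families"]) - {"length_nmf", "fprofile", "mds", "binwise"}
    if bad_fam:
        errors.append(f"unknown feature families: {sorted(bad_fam)}")
    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return merged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: dict, outdir: Path):
    """Simulate or read the cohort; returns (fragments_by_sample, sheet,
    bins, arms)."""
    if config["mode"] == "synthetic":
        sim = dict(config["simulation"])
        genome = sim.pop("genome", None)
        if isinstance(genome, dict):
            sim["genome"] = GenomeConfig(**genome)
        sim.setdefault("seed", config["seed"])
        if "planted_bins" in sim:
            sim["planted_bins"] = tuple(sim["planted_bins"])
        if "gc_beta" in sim:
            sim["gc_beta"] = tuple(sim["gc_beta"])
        sim_config = SimulationConfig(**sim)
        cohort = simulate_cohort(sim_config)
        cohort.write(outdir / "fragments")
        return (cohort.fragments_by_sample(), cohort.sample_sheet,
                sim_config.genome.bins(), sim_config.genome.arms())
    indir = Path(config["input_dir"])
    sheet = pd.read_csv(indir / "sample_sheet.csv")
    frags = {sid: read_fragment_table(indir / f"{sid}.fragments.tsv")
             for sid in sheet["sample_id"]}
    bins = pd.read_csv(indir / "bins.tsv", sep="\t", dtype={"chrom": str})
    arms = pd.read_csv(indir / "arms.tsv", sep="\t", dtype={"chrom": str})
    return frags, sheet, bins, arms


def run_pipeline(config: dict, outdir) -> Path:
    """Run the full analysis into ``outdir``; returns the run directory."""
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config))

    frags, sheet, bins, arms = _load_inputs(config, outdir)
    flt = config["filters"]
    frags = {sid: filter_fragments(df, min_len=flt["min_len"],
                                   max_len=flt["max_len"],
                                   autosomes_only=flt["autosomes_only"])
             for sid, df in frags.items()}
    sheet.to_csv(outdir / "sample_sheet.csv", index=False)
    labels = sheet.set_index("sample_id")["label"]
    train_ids = labels[labels.isin(LABELS)].index.to_list()
    heldout_ids = labels[labels.isin(HELDOUT_LABELS)].index.to_list()
    healthy_ids = labels[labels == "healthy"].index.to_list()

    features: dict[str, pd.DataFrame] = {}
    fam_kwargs: dict[str, dict] = {}
    enabled = config["families"]
    counts = lengths_freq = spectra = None
    if {"length_nmf"} & set(enabled):
        counts = length_matrix(frags)
        counts.to_csv(outdir / "length_counts.csv")
        lengths_freq = pd.DataFrame(normalize_rows(counts), index=counts.index,
                                    columns=counts.columns)
        features["length_nmf"] = lengths_freq
    if {"fprofile", "mds"} & set(enabled):
        spectra = spectra_matrix(frags)
        spectra.to_csv(outdir / "motif_spectra.csv")
    if "fprofile" in enabled:
        features["fprofile"] = spectra
    if "mds" in enabled:
        mds = spectra.apply(motif_diversity_score, axis=1).to_frame("mds")
        mds.to_csv(outdir / "mds.csv")
        features["mds"] = mds
    if "binwise" in enabled:
        bw, n_ratio = binwise_feature_matrix(frags, bins, arms, healthy_ids)
        bw.to_csv(outdir / "binwise_features.csv")
        features["binwise"] = bw
        fam_kwargs["binwise"] = {"n_ratio_cols": n_ratio}

    clf_cfg = dict(config["classifier"])
    nmf_components = clf_cfg.pop("nmf_components")
    n_profiles = clf_cfg.pop("n_profiles")
    fam_kwargs.setdefault("length_nmf", {})["nmf_components"] = nmf_components
    fam_kwargs.setdefault("fprofile", {})["n_profiles"] = n_profiles

    train_features = {fam: X.loc[train_ids] for fam, X in features.items()}
    comparisons = config["comparisons"] or comparisons_for(labels.loc[train_ids])
    comparisons = [tuple(c) for c in comparisons]
    auc_tables, score_table, models = ovo_report(
        train_features, labels.loc[train_ids].to_numpy(),
        comparisons=comparisons, random_state=config["seed"],
        family_kwargs=fam_kwargs, **clf_cfg)
    for fam, table in auc_tables.items():
        table.to_csv(outdir / f"auc_matrix_{fam}.csv")
    score_table.to_csv(outdir / "scores.csv", index=False)

    if heldout_ids:
        rows = []
        for (fam, a, b), model in models.items():
            out = apply_heldout(model, features[fam].loc[heldout_ids])
            out.insert(1, "comparison", f"{a}_vs_{b}")
            out.insert(2, "family", fam)
            rows.append(out)
        pd.concat(rows).to_csv(outdir / "heldout_scores.csv", index=False)

    stats_results = []
    if "mds" in features and labels.loc[train_ids].nunique() >= 3:
        groups = {lab: features["mds"].loc[labels.index[labels == lab], "mds"].to_numpy()
                  for lab in sorted(labels.loc[train_ids].unique())}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            omnibus, pairwise = kruskal_dunn(groups)
        stats_results.extend([omnibus, *pairwise])
    pooled = {lab: np.concatenate([frags[s]["length"].to_numpy()
                                   for s in labels.index[labels == lab]])
              for lab in sorted(labels.loc[train_ids].unique())}
    for a, b in comparisons:
        if a in pooled and b in pooled:
            stats_results.append(ks_two_sample(pooled[a], pooled[b], (a, b)))
    if stats_results:
        results_table(stats_results).to_csv(outdir / "stats.csv", index=False)

    manifest = {
        "cffrag_version": __version__,
        "seed": config["seed"],
        "config": config,
        "comparisons": [list(c) for c in comparisons],
        "n_samples": int(len(sheet)),
        "outputs": {p.name: _sha256(p) for p in sorted(outdir.glob("*.csv"))},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
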