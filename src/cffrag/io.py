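"""Fragment ingestion and filtering.

A "fragment" is one sequenced cfDNA molecule: a 0-based half-open genomic
interval plus its GC fraction and, when the pair aligned perfectly, the
4-mer of reference sequence at each 5' end.  Fragments live in pandas
DataFrames with columns ``chrom, start, end, gc, motif5p_left,
motif5p_right`` (motifs absent = NaN/"."), plus a derived ``length`` column.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import FRAGMENT_COLUMNS

MOTIF_RE = re.compile(r"^[ACGT]{4}$")
AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}

_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FragmentTableError(ValueError):
    """Raised when a fragment table is malformed beyond the tolerated rate."""


@dataclass(frozen=True)
class SampleQC:
    """Library-level sequencing QC metrics, all on the percent scale
    (except ``error_rate``, itself a percentage as reported by samtools)."""

    pct_mapped_bases: float
    error_rate: float
    pct_unique_reads: float
    pct_q30: float


QC_RULES = {
    "pct_mapped_bases": (">", 80.0),
    "error_rate": ("<", 0.3),
    "pct_unique_reads": (">", 85.0),
    "pct_q30": (">", 75.0),
}


def qc_gate(qc: SampleQC | dict) -> tuple[bool, list[str]]:
    """Library retention gate: >80% mapped bases, <0.3% error rate,
    >85% unique reads, >75% Q30 bases (all strict inequalities).

    Returns (passed, reasons); reasons list every violated rule.
    """
    reasons = []
    for metric, (op, cutoff) in QC_RULES.items():
        value = qc.get(metric) if isinstance(qc, dict) else getattr(qc, metric, None)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            reasons.append(f"missing metric: {metric}")
            continue
        ok = value > cutoff if op == ">" else value < cutoff
        if not ok:
            reasons.append(f"{metric} = {value} violates {metric} {op} {cutoff}")
    return (not reasons, reasons)


# ---------------------------------------------------------------------------
# fragment tables
# ---------------------------------------------------------------------------

def _validate_fragments(df: pd.DataFrame) -> pd.Series:
    """Boolean mask of valid rows; motifs may be absent but not malformed."""
    ok = (df["end"] > df["start"]) & df["gc"].between(0.0, 1.0)
    for col in ("motif5p_left", "motif5p_right"):
        m = df[col].astype("string")
        absent = m.isna() | (m == ".") | (m == "")
        valid_motif = m.fillna("").str.fullmatch(r"[ACGT]{4}").fillna(False)
        ok &= absent | valid_motif
    return ok


def _normalize_motifs(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("motif5p_left", "motif5p_right"):
        m = df[col].astype("string")
        df[col] = m.mask(m.isin([".", ""]))
    return df


def read_fragment_table(path, max_bad_fraction: float = 0.01) -> pd.DataFrame:
    """Read a per-fragment TSV, validating every row.

    Malformed rows (end <= start, GC outside [0,1], non-ACGT motifs) are
    reported with their 1-based line numbers and dropped; if more than
    ``max_bad_fraction`` of rows are bad the whole table is rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FragmentTableError(f"{path}: missing columns {missing}")
    ok = _validate_fragments(df)
    if not ok.all():
        bad_lines = (df.index[~ok] + 2).tolist()  # +2: header + 1-based
        frac = len(bad_lines) / len(df)
        msg = (f"{path}: {len(bad_lines)} malformed rows "
               f"(lines {bad_lines[:10]}{'...' if len(bad_lines) > 10 else ''})")
        if frac > max_bad_fraction:
            raise FragmentTableError(msg + f"; {frac:.1%} exceeds tolerance")
        warnings.warn(msg + "; dropped")
        df = df[ok].reset_index(drop=True)
    df = _normalize_motifs(df)
    df["length"] = df["end"] - df["start"]
    return df


def write_fragment_table(df: pd.DataFrame, path) -> None:
    out = df[FRAGMENT_COLUMNS].copy()
    for col in ("motif5p_left", "motif5p_right"):
        out[col] = out[col].fillna(".")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def _pair_is_perfect(read, mate) -> bool:
    """Strict reading of "perfect alignment": both mates primary and mapped,
    CIGAR entirely aligned-match, and zero edit distance when NM is present."""
    for r in (read, mate):
        if r.cigartuples is None:
            return False
        if any(op not in (0, 7) for op, _ in r.cigartuples):  # M or =
            return False
        if r.has_tag("NM") and r.get_tag("NM") != 0:
            return False
    return True


def fragments_from_alignments(alignment_path, reference_path) -> pd.DataFrame:
    """Extract fragments from a paired-end SAM/BAM against a FASTA reference.

    One record per properly paired, primary, non-duplicate pair; the
    fragment interval is [leftmost start, rightmost end).  GC is computed
    from reference bases over the interval.  End motifs (first four
    reference bases; reverse complement of the last four) are populated only
    for pairs passing the perfect-alignment condition and containing no
    ambiguous base in the terminal 4-mer.
    """
    import pysam
    from pyfaidx import Fasta

    ref = Fasta(str(reference_path), sequence_always_upper=True)
    mode = "rb" if str(alignment_path).endswith(".bam") else "r"
    pending: dict[str, object] = {}
    rows = []
    with pysam.AlignmentFile(str(alignment_path), mode) as af:
        contigs = set(af.references)
        missing = contigs - set(ref.keys())
        if missing:
            raise ValueError(f"contigs absent from reference: {sorted(missing)}")
        for read in af:
            if (read.is_unmapped or read.mate_is_unmapped
                    or not read.is_proper_pair or read.is_secondary
                    or read.is_supplementary or read.is_duplicate):
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            chrom = read.reference_name
            start = min(read.reference_start, mate.reference_start)
            end = max(read.reference_end, mate.reference_end)
            seq = str(ref[chrom][start:end])
            at = seq.count("A") + seq.count("T")
            gcc = seq.count("G") + seq.count("C")
            gc = gcc / (at + gcc) if at + gcc else np.nan
            left = right = None
            if _pair_is_perfect(read, mate) and end - start >= 4:
                lm, rm = seq[:4], reverse_complement(seq[-4:])
                left = lm if MOTIF_RE.match(lm) else None
                right = rm if MOTIF_RE.match(rm) else None
            rows.append((chrom, start, end, round(gc, 4), left, right))
    df = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    df["gc"] = df["gc"].astype(float)
    df = _normalize_motifs(df)
    df["length"] = df["end"] - df["start"]
    return df


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={0: str})
    return df


def _overlaps_blacklist(df: pd.DataFrame, blacklist: pd.DataFrame) -> np.ndarray:
    """Vectorized interval-overlap test per chromosome.

    A fragment [s, e) overlaps some blacklist interval [bs, be) iff among
    intervals with bs < e the running maximum of be exceeds s.
    """
    hit = np.zeros(len(df), dtype=bool)
    for chrom, bl in blacklist.groupby("chrom"):
        sel = df["chrom"].to_numpy() == chrom
        if not sel.any():
            continue
        bl = bl.sort_values("start")
        starts = bl["start"].to_numpy()
        cummax_end = np.maximum.accumulate(bl["end"].to_numpy())
        idx = np.searchsorted(starts, df.loc[sel, "end"].to_numpy(), side="left")
        frag_hit = np.zeros(sel.sum(), dtype=bool)
        nz = idx > 0
        frag_hit[nz] = cummax_end[idx[nz] - 1] > df.loc[sel, "start"].to_numpy()[nz]
        hit[sel] = frag_hit
    return hit


def filter_fragments(df: pd.DataFrame, min_len: int = 30, max_len: int = 700,
                     blacklist: pd.DataFrame | str | Path | None = None,
                     autosomes_only: bool = False,
                     return_tally: bool = False):
    """Length filter (inclusive bounds), blacklist exclusion, autosome
    restriction.  Returns the filtered frame (and a kept/dropped tally)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    if "length" not in df.columns:
        df = df.assign(length=df["end"] - df["start"])
    keep = df["length"].between(min_len, max_len)
    tally = {"input": len(df), "length_dropped": int((~keep).sum())}
    if autosomes_only:
        auto = df["chrom"].isin(AUTOSOMES)
        tally["non_autosome_dropped"] = int((keep & ~auto).sum())
        keep &= auto
    if blacklist is not None:
        if not isinstance(blacklist, pd.DataFrame):
            blacklist = read_bed(blacklist)
        if len(blacklist):
            bl_hit = _overlaps_blacklist(df, blacklist)
            tally["blacklist_dropped"] = int((keep & bl_hit).sum())
            keep &= ~bl_hit
    out = df[keep].reset_index(drop=True)
    tally["kept"] = len(out)
    return (out, tally) if return_tally else out


def size_select(df: pd.DataFrame, lo: int = 90, hi: int = 150) -> pd.DataFrame:
    """In-silico ctDNA enrichment: retain fragments with lo <= length <= hi.

    This is the export step feeding external copy-number tumor-fraction
    tools, which expect the 90-150 bp window.
    """
    if lo > hi:
        raise ValueError(f"lo {lo} > hi {hi}")
    if "length" not in df.columns:
        df = df.assign(length=df["end"] - df["start"])
    return df[df["length"].between(lo, hi)].reset_index(drop=True)
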