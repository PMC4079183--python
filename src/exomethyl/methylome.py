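"""Per-exon CpG methylation and composition metrics from bisulfite calls.

The input is a base-resolution call table (chrom, pos, strand, coverage,
meth_reads; positions 1-based in the file).  Calls on the two strands of
a palindromic CpG are merged onto the plus-strand C position by summing
reads.  A CpG covered by at least ``min_coverage`` reads is a *sampled*
CpG; a sampled CpG whose methylation frequency (methylated reads /
coverage) is at least ``meth_threshold`` is a methylated CpG (mCG).

Per-exon metrics:

* mCG density = mCGs x 100 / sampled CpGs (alternate: x 100 / exon bp)
* CpG O/E     = observed CpGs x length / (#C x #G), sense strand
* G+C content and CpG density (CpGs per bp)

Exons pass QC when their coding length exceeds ``min_length`` (strictly)
and they contain at least ``min_sampled`` sampled CpGs.  Undefined
metrics propagate as NaN, never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_MIN_COVERAGE = 5
DEFAULT_METH_THRESHOLD = 0.80
DEFAULT_MIN_SAMPLED = 10
DEFAULT_MIN_LENGTH = 80

CALL_COLUMNS = ["chrom", "pos", "strand", "coverage", "meth_reads"]


@dataclass(frozen=True)
class CpGSite:
    """Merged bisulfite call at the plus-strand C of one CpG (0-based)."""

    chrom: str
    pos: int
    coverage: int
    meth_reads: int

    def __post_init__(self) -> None:
        if self.meth_reads > self.coverage:
            raise ValueError(
                f"methylated reads {self.meth_reads} exceed coverage "
                f"{self.coverage} at {self.chrom}:{self.pos}"
            )

    @property
    def frequency(self) -> float:
        return self.meth_reads / self.coverage if self.coverage > 0 else math.nan


@dataclass
class ExonMethylationProfile:
    exon_key: tuple  # (gene_id, chrom, start, end)
    n_cpg: int
    n_sampled: int
    n_mcg: int
    mcg_density: float  # per 100 sampled CpGs
    mcg_density_bp: float  # per 100 bp
    cpg_oe: float
    gc_content: float
    cpg_density: float
    qc_pass: bool
    qc_reason: str


def load_methylation_calls(path: str | Path) -> pd.DataFrame:
    """Load a call table; validates counts and numeric fields.

    Returns the table with ``pos`` converted to 0-based.  Zero-coverage
    rows are retained (they are simply never sampled).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"call table missing columns: {missing}")
    if df.empty:
        return df.assign(pos=df.get("pos", pd.Series(dtype=int)))
    for col in ("pos", "coverage", "meth_reads"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"non-numeric values in column {col!r}")
    bad = df.index[df["meth_reads"] > df["coverage"]]
    if len(bad):
        raise ValueError(
            f"methylated reads exceed coverage at row {bad[0]} "
            f"({df.loc[bad[0], 'chrom']}:{df.loc[bad[0], 'pos']})"
        )
    df = df.copy()
    df["pos"] = df["pos"].astype(int) - 1
    return df


def merge_strands(calls: pd.DataFrame) -> pd.DataFrame:
    """Merge per-strand calls onto the plus-strand C position of each CpG.

    A minus-strand call at position p reports the C opposite the
    plus-strand G, i.e. the CpG whose plus-strand C sits at p - 1.
    Reads are summed before any thresholding.
    """
    if calls.empty:
        return pd.DataFrame(columns=["chrom", "pos", "coverage", "meth_reads"])
    df = calls.copy()
    minus = df["strand"] == "-"
    df.loc[minus, "pos"] = df.loc[minus, "pos"] - 1
    merged = (
        df.groupby(["chrom", "pos"], as_index=False)[["coverage", "meth_reads"]]
        .sum()
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    return merged


def select_sampled_cpgs(
    sites: pd.DataFrame, min_coverage: int = DEFAULT_MIN_COVERAGE
) -> pd.DataFrame:
    """Sites covered by at least ``min_coverage`` reads ("sampled CpGs")."""
    return sites[sites["coverage"] >= min_coverage]


def call_methylated(
    coverage, meth_reads, threshold: float = DEFAULT_METH_THRESHOLD
):
    """mCG call: methylation frequency >= threshold.  Sampled sites only."""
    coverage = np.asarray(coverage, dtype=float)
    meth_reads = np.asarray(meth_reads, dtype=float)
    if np.any(coverage <= 0):
        raise ValueError("methylation calling is defined only on sampled sites")
    return meth_reads / coverage >= threshold


def mcg_density(n_mcg: int, n_sampled: int) -> float:
    """Methylated CpGs per 100 sampled CpGs; NaN when nothing was sampled."""
    if n_sampled == 0:
        return math.nan
    return n_mcg * 100.0 / n_sampled


def mcg_density_per_bp(n_mcg: int, length: int) -> float:
    if length <= 0:
        return math.nan
    return n_mcg * 100.0 / length


def cpg_positions(seq: str) -> list[int]:
    """Indices of the C of every CpG in ``seq`` (overlapping scan)."""
    seq = seq.upper()
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


def cpg_oe(seq: str) -> float:
    """Observed/expected CpG ratio = n_CpG * L / (n_C * n_G), sense strand."""
    seq = seq.upper()
    if len(seq) < 2:
        return math.nan
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c == 0 or n_g == 0:
        return math.nan
    return len(cpg_positions(seq)) * len(seq) / (n_c * n_g)


def gc_content(seq: str) -> float:
    seq = seq.upper()
    if not seq:
        return math.nan
    return (seq.count("G") + seq.count("C")) / len(seq)


def exon_qc(
    length: int,
    n_sampled: int,
    min_length: int = DEFAULT_MIN_LENGTH,
    min_sampled: int = DEFAULT_MIN_SAMPLED,
) -> tuple[bool, str]:
    """QC verdict: length strictly > min_length and sampled >= min_sampled."""
    if length <= min_length:
        return False, f"length<={min_length}"
    if n_sampled < min_sampled:
        return False, f"sampled<{min_sampled}"
    return True, ""


def calls_lookup(merged: pd.DataFrame) -> dict:
    """Index a strand-merged call table by (chrom, pos) for fast lookup."""
    return {
        (c, p): (cov, m)
        for c, p, cov, m in zip(
            merged["chrom"], merged["pos"], merged["coverage"], merged["meth_reads"]
        )
    }


def exon_profile(
    exon_key: tuple,
    seq: str,
    genomic_c_positions: list[int],
    calls: pd.DataFrame | dict,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    meth_threshold: float = DEFAULT_METH_THRESHOLD,
    min_length: int = DEFAULT_MIN_LENGTH,
    min_sampled: int = DEFAULT_MIN_SAMPLED,
) -> ExonMethylationProfile:
    """Compute the per-exon methylation/composition profile.

    ``seq`` is the exon's sense-strand coding sequence and
    ``genomic_c_positions`` gives, for each CpG found in ``seq`` (in the
    order of :func:`cpg_positions`), the plus-strand genomic coordinate
    of its C — the key into the strand-merged ``calls`` table (a
    DataFrame, or the mapping from :func:`calls_lookup`).
    """
    length = len(seq)
    n_cpg = len(genomic_c_positions)
    chrom = exon_key[1]
    lookup = calls if isinstance(calls, dict) else calls_lookup(calls)
    cov = np.array([lookup.get((chrom, p), (0, 0))[0] for p in genomic_c_positions])
    meth = np.array([lookup.get((chrom, p), (0, 0))[1] for p in genomic_c_positions])
    sampled = cov >= min_coverage
    n_sampled = int(sampled.sum())
    if n_sampled:
        n_mcg = int(call_methylated(cov[sampled], meth[sampled], meth_threshold).sum())
    else:
        n_mcg = 0
    ok, reason = exon_qc(length, n_sampled, min_length, min_sampled)
    return ExonMethylationProfile(
        exon_key=exon_key,
        n_cpg=n_cpg,
        n_sampled=n_sampled,
        n_mcg=n_mcg,
        mcg_density=mcg_density(n_mcg, n_sampled),
        mcg_density_bp=mcg_density_per_bp(n_mcg, length),
        cpg_oe=cpg_oe(seq),
        gc_content=gc_content(seq),
        cpg_density=n_cpg / length if length else math.nan,
        qc_pass=ok,
        qc_reason=reason,
    )
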