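"""Per-exon dN / dS / dN/dS from pairwise ortholog alignments.

The estimator is Nei–Gojobori (1986) counting with a Jukes–Cantor
multiple-hit correction, applied exon-wise:

1.  The pairwise *protein* alignment is back-translated onto the two
    coding sequences (each residue replaced by its source codon, residue
    gaps becoming codon gaps; the translation is verified).
2.  Codon columns are assigned to exons according to the annotation: a
    codon split across an exon junction goes to the exon holding at
    least two of its reference bases.
3.  Each slice is frame-checked (no internal stop codons; gap runs are
    whole codons) before estimation.
4.  Synonymous/nonsynonymous *site* counts follow NG86 with mutations to
    stop codons excluded from the per-position denominator; *difference*
    counts average over all minimal mutational pathways between the two
    codons, pathways through stop codons excluded.
5.  p-distances are corrected with d = -(3/4) ln(1 - (4/3) p); p >= 3/4
    is reported as saturated.  omega = dN/dS when dS > 0.

At the divergence this pipeline targets (pairwise dS on the order of
0.1) counting estimators and ML estimators agree closely, and the
counting route is exactly testable against brute-force enumeration.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]  # the standard genetic code
STOP_CODONS = frozenset(_TABLE.stop_codons)
CODON_TO_AA = dict(_TABLE.forward_table)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))
BASES = "ACGT"
GAP_CODON = "---"


class BacktranslationError(ValueError):
    """Protein/CDS inconsistency during back-translation."""


@dataclass(frozen=True)
class SubstitutionCounts:
    """NG86 site and difference counts, summed over compared codons."""

    n_sites: float  # nonsynonymous sites N
    s_sites: float  # synonymous sites S
    n_diffs: float  # nonsynonymous differences Nd
    s_diffs: float  # synonymous differences Sd
    codons_compared: int = 0

    def __add__(self, other: "SubstitutionCounts") -> "SubstitutionCounts":
        return SubstitutionCounts(
            self.n_sites + other.n_sites,
            self.s_sites + other.s_sites,
            self.n_diffs + other.n_diffs,
            self.s_diffs + other.s_diffs,
            self.codons_compared + other.codons_compared,
        )


@dataclass(frozen=True)
class RateEstimate:
    dn: float
    ds: float
    omega: float  # NaN when undefined (dS = 0 or saturation)
    status: str = "ok"  # ok | saturated | undefined | no_data


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """(N, S) site counts for one sense codon.

    For each position, the fraction of single-base changes that are
    synonymous is computed over the changes that do not create a stop
    codon; S sums these fractions, N = 3 - S.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    if codon not in CODON_TO_AA:
        raise ValueError(f"ambiguous or invalid codon {codon!r}")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            valid += 1
            if CODON_TO_AA[mutant] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return 3.0 - s, s


@lru_cache(maxsize=None)
def ng86_differences(codon1: str, codon2: str) -> tuple[float, float]:
    """(Nd, Sd) averaged over minimal mutational pathways.

    Pathways passing through a stop codon are excluded.  When at least
    one pathway is valid, Nd + Sd equals the number of differing
    positions.  Raises ValueError when every pathway is blocked.
    """
    codon1, codon2 = codon1.upper(), codon2.upper()
    for c in (codon1, codon2):
        if c not in CODON_TO_AA:
            raise ValueError(f"ambiguous, invalid, or stop codon {c!r}")
    diff_positions = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_positions:
        return 0.0, 0.0
    total_n = total_s = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_positions):
        current = codon1
        path_n = path_s = 0.0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[current] == CODON_TO_AA[nxt]:
                path_s += 1
            else:
                path_n += 1
            current = nxt
        if ok:
            total_n += path_n
            total_s += path_s
            n_paths += 1
    if n_paths == 0:
        raise ValueError(
            f"all pathways between {codon1} and {codon2} pass through stops"
        )
    return total_n / n_paths, total_s / n_paths


def _is_clean(codon: str) -> bool:
    return codon in CODON_TO_AA


def count_substitutions(seq1: str, seq2: str) -> SubstitutionCounts:
    """Sum NG86 counts over a codon-aligned sequence pair.

    Columns with gaps, ambiguity, stop codons, or fully stop-blocked
    pathways are dropped pairwise.  Site counts are averaged over the
    two sequences, per NG86.
    """
    if len(seq1) != len(seq2) or len(seq1) % 3:
        raise ValueError("sequences must be codon-aligned and equal length")
    seq1, seq2 = seq1.upper(), seq2.upper()
    n_sites = s_sites = n_diffs = s_diffs = 0.0
    compared = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if not (_is_clean(c1) and _is_clean(c2)):
            continue
        if c1 == c2:
            nd = sd = 0.0
        else:
            try:
                nd, sd = ng86_differences(c1, c2)
            except ValueError:
                continue
        n1, s1 = ng86_sites(c1)
        n2, s2 = ng86_sites(c2)
        n_sites += (n1 + n2) / 2
        s_sites += (s1 + s2) / 2
        n_diffs += nd
        s_diffs += sd
        compared += 1
    return SubstitutionCounts(n_sites, s_sites, n_diffs, s_diffs, compared)


def jukes_cantor(p: float) -> float:
    """JC69 distance from a proportion of differing sites; NaN at p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def estimate_rates(counts: SubstitutionCounts) -> RateEstimate:
    """dN, dS and omega from summed NG86 counts (JC-corrected)."""
    if counts.codons_compared == 0 or counts.n_sites == 0 or counts.s_sites == 0:
        return RateEstimate(math.nan, math.nan, math.nan, "no_data")
    pn = counts.n_diffs / counts.n_sites
    ps = counts.s_diffs / counts.s_sites
    dn = jukes_cantor(pn)
    ds = jukes_cantor(ps)
    if math.isnan(dn) or math.isnan(ds):
        return RateEstimate(dn, ds, math.nan, "saturated")
    if ds == 0.0:
        return RateEstimate(dn, ds, math.nan, "undefined")
    return RateEstimate(dn, ds, dn / ds, "ok")


# ---------------------------------------------------------------------------
# alignment plumbing
# ---------------------------------------------------------------------------


def _translate(cds: str) -> str:
    if len(cds) % 3:
        raise BacktranslationError(f"CDS length {len(cds)} not divisible by 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        if codon in STOP_CODONS:
            aas.append("*")
        elif codon in CODON_TO_AA:
            aas.append(CODON_TO_AA[codon])
        else:
            aas.append("X")
    return "".join(aas)


def backtranslate_one(prot_aln: str, cds: str) -> str:
    """Replace each aligned residue by its source codon; verify translation."""
    cds = cds.upper()
    residues = prot_aln.replace("-", "")
    translation = _translate(cds)
    if translation.endswith("*"):
        translation = translation[:-1]
        cds = cds[:-3]
    if len(translation) != len(residues):
        raise BacktranslationError(
            f"CDS encodes {len(translation)} residues, alignment has {len(residues)}"
        )
    for i, (got, want) in enumerate(zip(translation, residues)):
        if got != want and want != "X" and got != "X":
            raise BacktranslationError(
                f"translation mismatch at residue {i + 1}: CDS gives {got}, "
                f"alignment has {want}"
            )
    out = []
    k = 0
    for ch in prot_aln:
        if ch == "-":
            out.append(GAP_CODON)
        else:
            out.append(cds[3 * k : 3 * k + 3])
            k += 1
    return "".join(out)


def backtranslate(
    prot_aln1: str, prot_aln2: str, cds1: str, cds2: str
) -> tuple[str, str]:
    """Codon alignment from a pairwise protein alignment and the two CDSs."""
    if len(prot_aln1) != len(prot_aln2):
        raise BacktranslationError("aligned proteins differ in length")
    return backtranslate_one(prot_aln1, cds1), backtranslate_one(prot_aln2, cds2)


def slice_exonwise(
    aligned1: str, aligned2: str, exon_lengths: list[int]
) -> list[tuple[str, str]]:
    """Split a codon alignment into per-exon slices.

    ``exon_lengths`` are the coding lengths (bp) of the reference
    (first) sequence's exons in transcript order; they must sum to the
    ungapped reference length.  Each codon column is assigned to the
    exon containing at least two of its reference bases; columns where
    the reference is gapped follow their preceding column.
    """
    ref_len = sum(exon_lengths)
    ungapped = len(aligned1.replace("-", ""))
    if ungapped != ref_len:
        raise ValueError(
            f"exon lengths sum to {ref_len} but reference has {ungapped} bases"
        )
    if len(aligned1) != len(aligned2) or len(aligned1) % 3:
        raise ValueError("alignment must be codon-aligned and equal length")

    # map each reference base index to its exon
    base_exon = []
    for idx, ln in enumerate(exon_lengths):
        base_exon.extend([idx] * ln)

    n_codons = len(aligned1) // 3
    if "-" not in aligned1:
        # gap-free fast path: base-to-exon assignment is non-decreasing,
        # so the majority exon of a codon is the middle base's exon
        be = np.asarray(base_exon)
        codon_exon = be.reshape(n_codons, 3)[:, 1].tolist()
    else:
        codon_exon = []
        base_ptr = 0
        for ci in range(n_codons):
            codon = aligned1[3 * ci : 3 * ci + 3]
            exons_here = []
            for ch in codon:
                if ch != "-":
                    exons_here.append(base_exon[base_ptr])
                    base_ptr += 1
            if not exons_here:
                codon_exon.append(codon_exon[-1] if codon_exon else 0)
                continue
            # >=2 of the codon's reference bases decide; a 2|1 split goes
            # to the exon holding the majority (ties impossible)
            counts: dict[int, int] = {}
            for e in exons_here:
                counts[e] = counts.get(e, 0) + 1
            codon_exon.append(max(counts, key=lambda e: (counts[e], -e)))

    slices = []
    for idx in range(len(exon_lengths)):
        cols = [ci for ci, e in enumerate(codon_exon) if e == idx]
        s1 = "".join(aligned1[3 * ci : 3 * ci + 3] for ci in cols)
        s2 = "".join(aligned2[3 * ci : 3 * ci + 3] for ci in cols)
        slices.append((s1, s2))
    return slices


def check_frame(seq1: str, seq2: str) -> str:
    """Frame check for one exon slice: 'pass' or a failure reason.

    Fails when either sequence contains an internal stop codon after gap
    removal, or when any gap run length is not a multiple of 3.
    """
    for seq in (seq1, seq2):
        run = 0
        for ch in seq + "x":
            if ch == "-":
                run += 1
            else:
                if run % 3:
                    return "frame_breaking_gap"
                run = 0
        ungapped = seq.replace("-", "").upper()
        # terminal stops are stripped before slicing, so any stop here is
        # internal to the CDS
        for i in range(0, len(ungapped) - 2, 3):
            if ungapped[i : i + 3] in STOP_CODONS:
                return "internal_stop"
    return "pass"


def exon_rates(
    aligned1: str, aligned2: str, exon_lengths: list[int]
) -> list[tuple[str, SubstitutionCounts | None, RateEstimate | None]]:
    """Slice, frame-check, and estimate rates for every exon.

    Returns one (frame_status, counts, rates) triple per exon; counts
    and rates are None for slices failing the frame check.
    """
    out = []
    for s1, s2 in slice_exonwise(aligned1, aligned2, exon_lengths):
        status = check_frame(s1, s2)
        if status != "pass":
            out.append((status, None, None))
            continue
        counts = count_substitutions(s1, s2)
        out.append((status, counts, estimate_rates(counts)))
    return out
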