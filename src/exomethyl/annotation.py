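"""Gene-model parsing and coding-exon classification.

Parses GFF3 gene annotations into :class:`GeneModel` objects, applies the
gene-level exclusions (non-coding-RNA / pseudogene overlap, single-exon
genes), and classifies each coding exon by its relative position in the
transcript (first / last / internal) and by its splice type (constitutive
vs alternative, CSE/ASE).

Position classes are assigned across the *collated* isoforms of a gene:
the coding exon closest to the most downstream 5'UTR end is "first", the
one closest to the most upstream 3'UTR start is "last", and the rest are
"internal".  When a stand-alone 5'UTR exon is followed by a second 5'UTR
juxtaposed to a coding exon, that coding exon is not part of the most
upstream exonic region and is marked ``excluded`` (and symmetrically at
the 3' end).

All internal coordinates are 0-based half-open; GFF3 I/O converts from
and to the 1-based inclusive convention.
"""

from __future__ import annotations

import tempfile
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd

STRANDS = ("+", "-")

#: feature types whose overlap with a gene triggers exclusion
NCRNA_TYPES = frozenset(
    {"ncRNA", "lnc_RNA", "tRNA", "rRNA", "snoRNA", "snRNA", "miRNA", "ncRNA_gene"}
)
PSEUDOGENE_TYPES = frozenset({"pseudogene", "pseudogenic_transcript"})


class AnnotationError(ValueError):
    """Raised for malformed annotation hierarchies (e.g. orphan mRNAs)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """One transcript isoform: exons plus their CDS / UTR decomposition."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval]
    utr5: list[GenomicInterval]
    utr3: list[GenomicInterval]

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    def coding_exons(self) -> list[GenomicInterval]:
        """Coding part of each exon (exon ∩ CDS), in transcription order."""
        out = []
        for exon in self.exons:
            for c in self.cds:
                if exon.overlaps(c):
                    out.append(
                        GenomicInterval(
                            exon.chrom,
                            max(exon.start, c.start),
                            min(exon.end, c.end),
                            exon.strand,
                        )
                    )
        out.sort(key=lambda iv: iv.start, reverse=(self.strand == "-"))
        return out

    @property
    def single_exon(self) -> bool:
        return len(self.exons) == 1


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel]
    overlaps_ncrna: bool = False
    overlaps_pseudogene: bool = False

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def single_exon(self) -> bool:
        """True when every isoform consists of a single exon."""
        return all(t.single_exon for t in self.transcripts)


@dataclass
class CodingExon:
    """A distinct coding exonic region of a gene, with its labels.

    ``interval`` is the coding part of the exon; ``length`` is therefore
    the coding length used for QC and for the length analyses.
    """

    gene_id: str
    interval: GenomicInterval
    position_class: str  # first | last | internal | excluded
    splice_class: str  # CSE | ASE
    flags: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.interval.length


def _iv(feature) -> GenomicInterval:
    # GFF3 is 1-based inclusive
    return GenomicInterval(feature.seqid, feature.start - 1, feature.end, feature.strand)


def parse_annotations(source: str | Path, from_string: bool = False) -> list[GeneModel]:
    """Parse a GFF3 file (or text, with ``from_string=True``) into gene models.

    Every mRNA must name an existing gene in its ``Parent`` attribute;
    orphans raise :class:`AnnotationError`.  Genes are flagged when their
    span overlaps an annotated non-coding RNA or pseudogene feature.
    """
    if from_string:
        # gffutils' from_string path writes a temp file itself on some
        # versions; go through an explicit temp file for portability.
        with tempfile.NamedTemporaryFile(
            "w", suffix=".gff3", delete=False
        ) as handle:
            handle.write(str(source))
            tmp = handle.name
        try:
            return parse_annotations(tmp)
        finally:
            os.unlink(tmp)

    db = gffutils.create_db(
        str(source),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )

    gene_ids = {g.id for g in db.features_of_type("gene")}
    transcripts_by_gene: dict[str, list[TranscriptModel]] = {g: [] for g in gene_ids}

    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        if not parents or parents[0] not in gene_ids:
            raise AnnotationError(
                f"mRNA {mrna.id!r} references missing gene {parents or '<none>'}"
            )
        gene_id = parents[0]
        exons, cds, utr5, utr3 = [], [], [], []
        for child in db.children(mrna, level=1):
            if child.featuretype == "exon":
                exons.append(_iv(child))
            elif child.featuretype == "CDS":
                cds.append(_iv(child))
            elif child.featuretype == "five_prime_UTR":
                utr5.append(_iv(child))
            elif child.featuretype == "three_prime_UTR":
                utr3.append(_iv(child))
            # other feature types are skipped
        if not exons:
            continue
        strand = exons[0].strand
        rev = strand == "-"
        for lst in (exons, cds, utr5, utr3):
            lst.sort(key=lambda iv: iv.start, reverse=rev)
        transcripts_by_gene[gene_id].append(
            TranscriptModel(mrna.id, gene_id, exons, cds, utr5, utr3)
        )

    noncoding = [
        _iv(f)
        for t in NCRNA_TYPES
        for f in db.features_of_type(t)
    ]
    pseudo = [
        _iv(f)
        for t in PSEUDOGENE_TYPES
        for f in db.features_of_type(t)
    ]

    genes = []
    for gene in db.features_of_type("gene"):
        txs = transcripts_by_gene[gene.id]
        if not txs:
            continue
        span = _iv(gene)
        genes.append(
            GeneModel(
                gene.id,
                txs,
                overlaps_ncrna=any(span.overlaps(iv) for iv in noncoding),
                overlaps_pseudogene=any(span.overlaps(iv) for iv in pseudo),
            )
        )
    genes.sort(key=lambda g: g.gene_id)
    return genes


def filter_genes(
    genes: Iterable[GeneModel],
) -> tuple[list[GeneModel], list[tuple[str, str]]]:
    """Apply gene-level exclusions; returns (retained, exclusion log).

    A gene is excluded when it overlaps a non-coding RNA or a pseudogene,
    or when *all* of its isoforms are single-exon.  One reason is logged
    per excluded gene.
    """
    retained, log = [], []
    for gene in genes:
        if gene.overlaps_ncrna:
            log.append((gene.gene_id, "overlaps_ncrna"))
        elif gene.overlaps_pseudogene:
            log.append((gene.gene_id, "overlaps_pseudogene"))
        elif gene.single_exon:
            log.append((gene.gene_id, "single_exon"))
        else:
            retained.append(gene)
    return retained, log


def _five_prime(iv: GenomicInterval) -> int:
    """Coordinate of the 5'-most base boundary in transcription direction."""
    return iv.start if iv.strand == "+" else iv.end


def _three_prime(iv: GenomicInterval) -> int:
    return iv.end if iv.strand == "+" else iv.start


def classify_splice_type(gene: GeneModel) -> dict[GenomicInterval, str]:
    """CSE iff an identical-coordinate coding exon occurs in every isoform."""
    per_tx = [set(t.coding_exons()) for t in gene.transcripts]
    universe = sorted(set().union(*per_tx))
    return {
        iv: "CSE" if all(iv in s for s in per_tx) else "ASE" for iv in universe
    }


def classify_exon_positions(gene: GeneModel) -> list[CodingExon]:
    """Label each distinct coding exon first / last / internal / excluded.

    Anchors are taken over the union of isoforms: the most downstream
    5'UTR end and the most upstream 3'UTR start (transcription-direction
    aware).  Genes lacking a 5'UTR (resp. 3'UTR) fall back to the most
    upstream (downstream) coding exon, flagged ``no_5utr`` / ``no_3utr``.
    """
    splice = classify_splice_type(gene)
    coding = sorted(splice, key=lambda iv: (iv.start, iv.end))
    if not coding:
        return []
    minus = gene.strand == "-"
    if minus:
        coding = coding[::-1]  # transcription order

    utr5_all = [iv for t in gene.transcripts for iv in t.utr5]
    utr3_all = [iv for t in gene.transcripts for iv in t.utr3]

    flags: dict[GenomicInterval, list[str]] = {iv: [] for iv in coding}

    # --- first exon ---------------------------------------------------
    if utr5_all:
        anchor5 = max(_three_prime(iv) for iv in utr5_all) if not minus else min(
            _three_prime(iv) for iv in utr5_all
        )
        first = min(coding, key=lambda iv: abs(_five_prime(iv) - anchor5))
    else:
        first = coding[0]
        flags[first].append("no_5utr")

    # --- last exon ----------------------------------------------------
    if utr3_all:
        anchor3 = min(_five_prime(iv) for iv in utr3_all) if not minus else max(
            _five_prime(iv) for iv in utr3_all
        )
        last = min(coding, key=lambda iv: abs(_three_prime(iv) - anchor3))
    else:
        last = coding[-1]
        flags[last].append("no_3utr")

    if first is last and len(coding) > 1:
        flags[first].append("coincident_terminal")

    # --- stand-alone UTR exclusions ----------------------------------
    first_excluded = _standalone_utr_upstream(gene, first, end5=True)
    last_excluded = _standalone_utr_upstream(gene, last, end5=False)

    out = []
    for iv in coding:
        if iv is first or iv == first:
            if first_excluded:
                cls, fl = "excluded", flags[iv] + ["non_upstream_first"]
            else:
                cls, fl = "first", flags[iv]
        elif iv == last:
            if last_excluded:
                cls, fl = "excluded", flags[iv] + ["non_downstream_last"]
            else:
                cls, fl = "last", flags[iv]
        else:
            cls, fl = "internal", flags[iv]
        out.append(CodingExon(gene.gene_id, iv, cls, splice[iv], tuple(fl)))
    return out


def _standalone_utr_upstream(gene: GeneModel, terminal: GenomicInterval, end5: bool) -> bool:
    """True when a stand-alone UTR exon sits beyond the terminal coding exon
    *and* a second UTR is juxtaposed to that coding exon within its own exon
    — the configuration under which the terminal exon is excluded."""
    minus = gene.strand == "-"
    for tx in gene.transcripts:
        utrs = tx.utr5 if end5 else tx.utr3
        if not utrs:
            continue
        # the containing exon of the terminal coding region
        host = next((e for e in tx.exons if e.overlaps(terminal)), None)
        if host is None:
            continue
        juxtaposed = any(u.overlaps(host) for u in utrs)
        if not juxtaposed:
            continue
        for exon in tx.exons:
            if exon == host or any(exon.overlaps(c) for c in tx.cds):
                continue  # not UTR-only
            if not any(u.overlaps(exon) for u in utrs):
                continue
            d_exon = _five_prime(exon) if end5 else _three_prime(exon)
            d_host = _five_prime(host) if end5 else _three_prime(host)
            beyond = (
                (d_exon < d_host) if (end5 != minus) else (d_exon > d_host)
            )
            if beyond:
                return True
    return False


def classify_genes(
    genes: Iterable[GeneModel], drop_no_utr: bool = False
) -> list[CodingExon]:
    """Classify every retained gene; optionally drop UTR-fallback exons."""
    out: list[CodingExon] = []
    for gene in genes:
        for ce in classify_exon_positions(gene):
            if drop_no_utr and ({"no_5utr", "no_3utr"} & set(ce.flags)):
                continue
            out.append(ce)
    return out


def coding_exon_table(exons: Sequence[CodingExon]) -> pd.DataFrame:
    """Tabulate classified coding exons (TSV-ready)."""
    rows = [
        {
            "gene_id": ce.gene_id,
            "chrom": ce.interval.chrom,
            "start": ce.interval.start,
            "end": ce.interval.end,
            "strand": ce.interval.strand,
            "position_class": ce.position_class,
            "splice_class": ce.splice_class,
            "length": ce.length,
            "flags": ",".join(ce.flags),
        }
        for ce in exons
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "chrom",
            "start",
            "end",
            "strand",
            "position_class",
            "splice_class",
            "length",
            "flags",
        ],
    )
    return df.sort_values(
        ["gene_id", "start", "end"], kind="stable"
    ).reset_index(drop=True)
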