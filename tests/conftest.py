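"""Shared fixtures: hand-built GFF3 gene models and small simulations."""

from __future__ import annotations

import numpy as np
import pytest

from exomethyl.pipeline import PipelineConfig, run_pipeline
from exomethyl.simulate import SimulationConfig, simulate_dataset


def _gff_line(chrom, ftype, start, end, strand, ident, parent=None):
    attrs = f"ID={ident}" if parent is None else f"ID={ident};Parent={parent}"
    return f"{chrom}\ttest\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"


# Five hand-built genes (1-based GFF coordinates):
#   geneA (+): three coding exons, UTRs on the terminal exons.
#   geneB (-): the same structure on the minus strand.
#   geneC (+): a stand-alone 5'UTR exon followed by a UTR+CDS exon, so the
#              would-be first coding exon is excluded.
#   geneD (+): two isoforms where the internal exon's 3' boundary shifts,
#              making both variants alternative (ASE).
#   geneE (+): single-exon gene (removed by the gene filter).
FIXTURE_GFF3 = "\n".join(
    ["##gff-version 3"]
    + [
        _gff_line("c1", "gene", 101, 650, "+", "geneA"),
        _gff_line("c1", "mRNA", 101, 650, "+", "geneA.t1", "geneA"),
        _gff_line("c1", "exon", 101, 250, "+", "geneA.t1.e1", "geneA.t1"),
        _gff_line("c1", "exon", 301, 420, "+", "geneA.t1.e2", "geneA.t1"),
        _gff_line("c1", "exon", 501, 650, "+", "geneA.t1.e3", "geneA.t1"),
        _gff_line("c1", "five_prime_UTR", 101, 160, "+", "geneA.t1.u5", "geneA.t1"),
        _gff_line("c1", "CDS", 161, 250, "+", "geneA.t1.c1", "geneA.t1"),
        _gff_line("c1", "CDS", 301, 420, "+", "geneA.t1.c2", "geneA.t1"),
        _gff_line("c1", "CDS", 501, 560, "+", "geneA.t1.c3", "geneA.t1"),
        _gff_line("c1", "three_prime_UTR", 561, 650, "+", "geneA.t1.u3", "geneA.t1"),
    ]
    + [
        _gff_line("c1", "gene", 1101, 1650, "-", "geneB"),
        _gff_line("c1", "mRNA", 1101, 1650, "-", "geneB.t1", "geneB"),
        _gff_line("c1", "exon", 1501, 1650, "-", "geneB.t1.e1", "geneB.t1"),
        _gff_line("c1", "exon", 1301, 1420, "-", "geneB.t1.e2", "geneB.t1"),
        _gff_line("c1", "exon", 1101, 1250, "-", "geneB.t1.e3", "geneB.t1"),
        _gff_line("c1", "five_prime_UTR", 1591, 1650, "-", "geneB.t1.u5", "geneB.t1"),
        _gff_line("c1", "CDS", 1501, 1590, "-", "geneB.t1.c1", "geneB.t1"),
        _gff_line("c1", "CDS", 1301, 1420, "-", "geneB.t1.c2", "geneB.t1"),
        _gff_line("c1", "CDS", 1191, 1250, "-", "geneB.t1.c3", "geneB.t1"),
        _gff_line("c1", "three_prime_UTR", 1101, 1190, "-", "geneB.t1.u3", "geneB.t1"),
    ]
    + [
        _gff_line("c1", "gene", 2101, 2700, "+", "geneC"),
        _gff_line("c1", "mRNA", 2101, 2700, "+", "geneC.t1", "geneC"),
        _gff_line("c1", "exon", 2101, 2160, "+", "geneC.t1.e1", "geneC.t1"),
        _gff_line("c1", "exon", 2201, 2350, "+", "geneC.t1.e2", "geneC.t1"),
        _gff_line("c1", "exon", 2401, 2520, "+", "geneC.t1.e3", "geneC.t1"),
        _gff_line("c1", "exon", 2601, 2700, "+", "geneC.t1.e4", "geneC.t1"),
        _gff_line("c1", "five_prime_UTR", 2101, 2160, "+", "geneC.t1.u5a", "geneC.t1"),
        _gff_line("c1", "five_prime_UTR", 2201, 2260, "+", "geneC.t1.u5b", "geneC.t1"),
        _gff_line("c1", "CDS", 2261, 2350, "+", "geneC.t1.c1", "geneC.t1"),
        _gff_line("c1", "CDS", 2401, 2520, "+", "geneC.t1.c2", "geneC.t1"),
        _gff_line("c1", "CDS", 2601, 2660, "+", "geneC.t1.c3", "geneC.t1"),
        _gff_line("c1", "three_prime_UTR", 2661, 2700, "+", "geneC.t1.u3", "geneC.t1"),
    ]
    + [
        _gff_line("c1", "gene", 3101, 3650, "+", "geneD"),
        _gff_line("c1", "mRNA", 3101, 3650, "+", "geneD.t1", "geneD"),
        _gff_line("c1", "exon", 3101, 3250, "+", "geneD.t1.e1", "geneD.t1"),
        _gff_line("c1", "exon", 3301, 3420, "+", "geneD.t1.e2", "geneD.t1"),
        _gff_line("c1", "exon", 3501, 3650, "+", "geneD.t1.e3", "geneD.t1"),
        _gff_line("c1", "five_prime_UTR", 3101, 3160, "+", "geneD.t1.u5", "geneD.t1"),
        _gff_line("c1", "CDS", 3161, 3250, "+", "geneD.t1.c1", "geneD.t1"),
        _gff_line("c1", "CDS", 3301, 3420, "+", "geneD.t1.c2", "geneD.t1"),
        _gff_line("c1", "CDS", 3501, 3560, "+", "geneD.t1.c3", "geneD.t1"),
        _gff_line("c1", "three_prime_UTR", 3561, 3650, "+", "geneD.t1.u3", "geneD.t1"),
        _gff_line("c1", "mRNA", 3101, 3650, "+", "geneD.t2", "geneD"),
        _gff_line("c1", "exon", 3101, 3250, "+", "geneD.t2.e1", "geneD.t2"),
        _gff_line("c1", "exon", 3301, 3390, "+", "geneD.t2.e2", "geneD.t2"),
        _gff_line("c1", "exon", 3501, 3650, "+", "geneD.t2.e3", "geneD.t2"),
        _gff_line("c1", "five_prime_UTR", 3101, 3160, "+", "geneD.t2.u5", "geneD.t2"),
        _gff_line("c1", "CDS", 3161, 3250, "+", "geneD.t2.c1", "geneD.t2"),
        _gff_line("c1", "CDS", 3301, 3390, "+", "geneD.t2.c2", "geneD.t2"),
        _gff_line("c1", "CDS", 3501, 3560, "+", "geneD.t2.c3", "geneD.t2"),
        _gff_line("c1", "three_prime_UTR", 3561, 3650, "+", "geneD.t2.u3", "geneD.t2"),
    ]
    + [
        _gff_line("c1", "gene", 4101, 4400, "+", "geneE"),
        _gff_line("c1", "mRNA", 4101, 4400, "+", "geneE.t1", "geneE"),
        _gff_line("c1", "exon", 4101, 4400, "+", "geneE.t1.e1", "geneE.t1"),
        _gff_line("c1", "five_prime_UTR", 4101, 4160, "+", "geneE.t1.u5", "geneE.t1"),
        _gff_line("c1", "CDS", 4161, 4340, "+", "geneE.t1.c1", "geneE.t1"),
        _gff_line("c1", "three_prime_UTR", 4341, 4400, "+", "geneE.t1.u3", "geneE.t1"),
    ]
) + "\n"


@pytest.fixture(scope="session")
def fixture_gff3() -> str:
    return FIXTURE_GFF3


@pytest.fixture(scope="session")
def fixture_genes():
    from exomethyl.annotation import parse_annotations

    return parse_annotations(FIXTURE_GFF3, from_string=True)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated bundle shared by read-only tests."""
    return simulate_dataset(SimulationConfig(n_genes=60, seed=101))


@pytest.fixture(scope="session")
def small_report():
    """A full pipeline run on a small simulated dataset."""
    cfg = PipelineConfig(
        simulation=SimulationConfig(n_genes=60, seed=101), seed=101
    )
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
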