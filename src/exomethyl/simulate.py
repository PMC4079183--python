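"""Synthetic annotation / methylome / ortholog / covariate generator.

Emits a complete, internally consistent input bundle for the pipeline —
GFF3 gene models with UTRs and isoforms, ancestral coding sequences,
two independently evolved ortholog lineages, per-strand bisulfite call
tables, and per-exon covariates — together with ground-truth tables for
recovery testing.

Model sketch
------------
* Gene models: 2+ coding exons per gene (count ~ 2 + Poisson), terminal
  UTRs attached to the first/last coding exon, optional stand-alone
  5'UTR exons (exercising the first-exon exclusion rule), and a second
  isoform skipping one frame-preserving internal exon for a configured
  fraction of genes (realizing ASEs).  Both strands are emitted.
* Ancestral CDS: first-order Markov chain over bases tuned to hit the
  configured G+C content and CpG rate; stop codons repaired in frame.
* Methylation: hierarchical beta model — each exon draws a methylation
  level from its position class's beta distribution, each CpG draws its
  methylation frequency around the exon level.  A CpG with frequency at
  or above the calling threshold is *truly* methylated.  Class means
  default to internal > last > first.
* Divergence: two descendant lineages evolve independently from the
  ancestor with per-site substitution probability mu, a
  transition/transversion weight kappa, and a multiplier lambda >= 1 on
  the C->T channel at the C of truly methylated CpGs (and the paired
  G->A channel).  Proposed nonsynonymous changes are accepted with the
  exon's acceptance probability (synonymous changes always accepted,
  stop-creating changes always rejected).  No indels, so orthologs stay
  trivially aligned.
* Bisulfite calls: per surviving CpG of the focal lineage, per-strand
  coverage ~ negative binomial and methylated reads ~ binomial(coverage,
  frequency).
* Covariates: expression (log-normal), repeat and disorder proportions
  (beta), with configurable coupling to exon length; acceptance
  probabilities may additionally be coupled to exon length or disorder
  (on the logit scale) to create confounded or mediated associations.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import methylome
from .evolution import CODON_TO_AA, _translate

BASES = "ACGT"
BASE_IDX = {b: i for i, b in enumerate(BASES)}
STOPS = {"TAA", "TAG", "TGA"}

CLASSES = ("first", "last", "internal")


@dataclass
class SimulationConfig:
    """All generator knobs; every field is YAML-serializable."""

    n_genes: int = 200
    exon_count_mean: float = 5.0  # coding exons per gene, min 2
    exon_length_mean: dict = field(
        default_factory=lambda: {"first": 283.0, "last": 283.0, "internal": 283.0}
    )
    exon_length_sigma: float = 0.45  # log-normal sigma
    exon_length_min: int = 60
    utr5_length: int = 120
    utr3_length: int = 150
    intron_length: int = 100
    intergenic_length: int = 200
    standalone_utr_fraction: float = 0.05
    ase_fraction: float = 0.15
    minus_strand_fraction: float = 0.3

    gc_content: float = 0.44
    cpg_rate: float = 0.035  # CpG dinucleotides per bp

    meth_mean: dict = field(
        default_factory=lambda: {"first": 0.25, "last": 0.45, "internal": 0.60}
    )
    meth_exon_concentration: float = 1.5
    meth_cpg_concentration: float = 8.0
    meth_call_threshold: float = 0.80  # mirror of the pipeline's calling rule

    coverage_mean: float = 20.0  # per strand mean is coverage_mean / 2
    coverage_dispersion: float = 5.0

    mu: float = 0.04  # per-site substitution probability per lineage
    kappa: float = 1.5  # transition/transversion weight
    cpg_lambda: float = 3.0  # C->T multiplier at truly methylated CpGs
    acceptance: dict = field(
        default_factory=lambda: {"first": 0.9, "last": 0.6, "internal": 0.3}
    )
    accept_length_effect: float = 0.0  # logit-scale effect of z(log length)
    accept_disorder_effect: float = 0.0  # logit-scale effect of z(disorder)

    expression_mu: float = 2.0
    expression_sigma: float = 1.0
    expression_length_effect: float = 0.0
    repeat_mean: float = 0.10
    repeat_concentration: float = 8.0
    repeat_length_effect: float = 0.0
    disorder_mean: float = 0.20
    disorder_concentration: float = 8.0
    disorder_length_effect: float = 0.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.cpg_lambda < 1.0:
            raise ValueError("cpg_lambda must be >= 1")
        for name in ("standalone_utr_fraction", "ase_fraction", "minus_strand_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for cls, a in self.acceptance.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"acceptance[{cls}] must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls(**yaml.safe_load(text))


@dataclass
class SimulatedDataset:
    """The emitted bundle, in memory.  ``write`` serializes to a directory."""

    config: SimulationConfig
    gff3: str
    cds_focal: dict  # gene_id -> str
    cds_ortholog: dict
    protein_alignments: dict  # gene_id -> (aln_focal, aln_ortholog); gap-free
    calls: pd.DataFrame  # chrom pos strand coverage meth_reads (pos 1-based)
    covariates: pd.DataFrame
    truth_exons: pd.DataFrame
    truth_cpgs: pd.DataFrame

    def write(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gff3": outdir / "annotation.gff3",
            "cds_focal": outdir / "cds_focal.fasta",
            "cds_ortholog": outdir / "cds_ortholog.fasta",
            "protein_alignments": outdir / "protein_alignments.fasta",
            "calls": outdir / "methylation_calls.tsv",
            "covariates": outdir / "covariates.tsv",
            "truth_exons": outdir / "truth_exons.tsv",
            "truth_cpgs": outdir / "truth_cpgs.tsv",
            "config": outdir / "sim_config.yaml",
        }
        paths["gff3"].write_text(self.gff3)
        paths["cds_focal"].write_text(_fasta(self.cds_focal))
        paths["cds_ortholog"].write_text(_fasta(self.cds_ortholog))
        aln = {}
        for gid, (a1, a2) in sorted(self.protein_alignments.items()):
            aln[f"{gid}|focal"] = a1
            aln[f"{gid}|ortholog"] = a2
        paths["protein_alignments"].write_text(_fasta(aln))
        self.calls.to_csv(paths["calls"], sep="\t", index=False)
        self.covariates.to_csv(paths["covariates"], sep="\t", index=False)
        self.truth_exons.to_csv(paths["truth_exons"], sep="\t", index=False)
        self.truth_cpgs.to_csv(paths["truth_cpgs"], sep="\t", index=False)
        paths["config"].write_text(self.config.to_yaml())
        return {k: str(v) for k, v in paths.items()}


def _fasta(records: dict) -> str:
    buf = io.StringIO()
    for name in sorted(records):
        buf.write(f">{name}\n")
        seq = records[name]
        for i in range(0, len(seq), 70):
            buf.write(seq[i : i + 70] + "\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass
class _ExonPlan:
    exon_id: str
    position_class: str  # intended label
    splice_class: str
    cds_offset: int  # offset of the exon's coding part within the CDS
    cds_length: int
    genomic_start: int  # of the coding part, 0-based half-open
    genomic_end: int


@dataclass
class _GenePlan:
    gene_id: str
    chrom: str
    strand: str
    standalone_utr: bool
    exons: list  # list[_ExonPlan], transcript order
    gff_lines: list

    @property
    def cds_length(self) -> int:
        return sum(e.cds_length for e in self.exons)


def simulate_gene_models(config: SimulationConfig, rng: np.random.Generator):
    """Lay out gene models on one chromosome; returns plans + GFF3 text.

    Intended position labels: the first/last coding exon of each gene,
    except that genes built with a stand-alone 5'UTR exon followed by a
    juxtaposed UTR+CDS exon have their first coding exon intended as
    ``excluded``.  One internal exon per selected gene is skipped in a
    second isoform (intended ASE).
    """
    chrom = "chr1"
    cursor = 1000
    plans: list[_GenePlan] = []
    lines = [
        "##gff-version 3",
    ]
    for gi in range(config.n_genes):
        gene_id = f"g{gi + 1:05d}"
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        n_cod = 2 + int(rng.poisson(max(config.exon_count_mean - 2.0, 0.0)))
        classes = (
            ["first"] + ["internal"] * (n_cod - 2) + ["last"]
        )
        lengths = []
        for cls in classes:
            mean = float(config.exon_length_mean[cls])
            sigma = config.exon_length_sigma
            ln = int(
                rng.lognormal(math.log(mean) - 0.5 * sigma**2, sigma)
            )
            lengths.append(max(config.exon_length_min, ln))
        # total CDS must be a whole number of codons
        rem = sum(lengths) % 3
        if rem:
            lengths[-1] += 3 - rem

        ase_idx = -1
        if n_cod >= 3 and rng.random() < config.ase_fraction:
            ase_idx = int(rng.integers(1, n_cod - 1))
            # the skipped exon must preserve frame in the skipping isoform
            rem = lengths[ase_idx] % 3
            if rem:
                lengths[ase_idx] += 3 - rem
                rem_total = sum(lengths) % 3
                if rem_total:
                    lengths[-1] += 3 - rem_total

        standalone = rng.random() < config.standalone_utr_fraction

        # build sense-order segment list: (kind, length)
        segments = []
        if standalone:
            segments.append(("utr5_standalone", config.utr5_length // 2))
            segments.append(("intron", config.intron_length))
            segments.append(("utr5_attached", config.utr5_length // 2))
        else:
            segments.append(("utr5_attached", config.utr5_length))
        for i, ln in enumerate(lengths):
            segments.append(("cds", ln))
            if i < n_cod - 1:
                segments.append(("intron", config.intron_length))
        segments.append(("utr3_attached", config.utr3_length))

        gene_len = sum(ln for _, ln in segments)
        gstart = cursor
        gend = cursor + gene_len
        cursor = gend + config.intergenic_length

        # assign genomic coordinates in sense order
        pos = gstart if strand == "+" else gend
        placed = []  # (kind, start, end) genomic, 0-based half-open
        for kind, ln in segments:
            if strand == "+":
                placed.append((kind, pos, pos + ln))
                pos += ln
            else:
                placed.append((kind, pos - ln, pos))
                pos -= ln

        # exon structure: stand-alone UTR exon; then exon1 = utr5 + cds1;
        # internal cds exons; last exon = cdsN + utr3
        exon_feats = []  # (start, end)
        utr5_feats, utr3_feats, cds_feats = [], [], []
        cds_placed = [p for p in placed if p[0] == "cds"]
        for kind, s, e in placed:
            if kind == "utr5_standalone":
                exon_feats.append((s, e))
                utr5_feats.append((s, e))
            elif kind == "utr5_attached":
                first_cds = cds_placed[0]
                exon_feats.append(
                    (min(s, first_cds[1]), max(e, first_cds[2]))
                )
                utr5_feats.append((s, e))
            elif kind == "cds":
                cds_feats.append((s, e))
            elif kind == "utr3_attached":
                last_cds = cds_placed[-1]
                exon_feats.append((min(s, last_cds[1]), max(e, last_cds[2])))
                utr3_feats.append((s, e))
        # internal cds exons (not merged with a UTR)
        for i, (_, s, e) in enumerate(cds_placed):
            if 0 < i < len(cds_placed) - 1:
                exon_feats.append((s, e))
        if len(cds_placed) == 1:  # cannot happen (n_cod >= 2) but keep safe
            pass
        exon_feats = sorted(set(exon_feats))

        def fmt(ftype, s, e, ident, parent=None):
            attrs = f"ID={ident}" if parent is None else f"ID={ident};Parent={parent}"
            return (
                f"{chrom}\texomethyl_sim\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}"
            )

        glines = [fmt("gene", gstart, gend, gene_id)]
        tx1 = f"{gene_id}.t1"
        glines.append(fmt("mRNA", gstart, gend, tx1, gene_id))
        for j, (s, e) in enumerate(exon_feats):
            glines.append(fmt("exon", s, e, f"{tx1}.exon{j + 1}", tx1))
        for j, (s, e) in enumerate(sorted(cds_feats)):
            glines.append(fmt("CDS", s, e, f"{tx1}.cds{j + 1}", tx1))
        for j, (s, e) in enumerate(sorted(utr5_feats)):
            glines.append(fmt("five_prime_UTR", s, e, f"{tx1}.u5.{j + 1}", tx1))
        for j, (s, e) in enumerate(sorted(utr3_feats)):
            glines.append(fmt("three_prime_UTR", s, e, f"{tx1}.u3.{j + 1}", tx1))

        if ase_idx >= 0:
            tx2 = f"{gene_id}.t2"
            skipped = cds_placed[ase_idx][1:]
            glines.append(fmt("mRNA", gstart, gend, tx2, gene_id))
            jj = 1
            for s, e in exon_feats:
                if (s, e) == tuple(skipped):
                    continue
                glines.append(fmt("exon", s, e, f"{tx2}.exon{jj}", tx2))
                jj += 1
            jj = 1
            for s, e in sorted(cds_feats):
                if (s, e) == tuple(skipped):
                    continue
                glines.append(fmt("CDS", s, e, f"{tx2}.cds{jj}", tx2))
                jj += 1
            for j, (s, e) in enumerate(sorted(utr5_feats)):
                glines.append(fmt("five_prime_UTR", s, e, f"{tx2}.u5.{j + 1}", tx2))
            for j, (s, e) in enumerate(sorted(utr3_feats)):
                glines.append(fmt("three_prime_UTR", s, e, f"{tx2}.u3.{j + 1}", tx2))

        exon_plans = []
        offset = 0
        for i, ((_, s, e), cls) in enumerate(zip(cds_placed, classes)):
            intended = cls
            if cls == "first" and standalone:
                intended = "excluded"
            exon_plans.append(
                _ExonPlan(
                    exon_id=f"{gene_id}.e{i + 1}",
                    position_class=intended,
                    splice_class="ASE" if i == ase_idx else "CSE",
                    cds_offset=offset,
                    cds_length=e - s,
                    genomic_start=s,
                    genomic_end=e,
                )
            )
            offset += e - s

        plans.append(
            _GenePlan(gene_id, chrom, strand, standalone, exon_plans, glines)
        )
        lines.extend(glines)

    return plans, "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# ancestral sequence
# ---------------------------------------------------------------------------


def simulate_ancestral_cds(
    length: int, config: SimulationConfig, rng: np.random.Generator
) -> str:
    """Stop-free open reading frame hitting the G+C and CpG targets.

    First-order Markov chain: base composition (pA, pC, pG, pT) with
    pC = pG = gc/2, and P(G | previous C) tuned so that the CpG rate
    equals ``config.cpg_rate``.  In-frame stop codons are repaired by
    replacing their leading T with C.
    """
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    pg_after_c = min(0.95, config.cpg_rate / p[1])
    from_c = p.copy()
    from_c[2] = 0.0
    from_c = from_c / from_c.sum() * (1.0 - pg_after_c)
    from_c[2] = pg_after_c

    cum_p = np.cumsum(p).tolist()
    cum_c = np.cumsum(from_c).tolist()
    u = rng.random(length)
    s: list[str] = []
    state = 0
    for i in range(length):
        cum = cum_c if state == 1 else cum_p
        x = u[i]
        state = 0 if x < cum[0] else 1 if x < cum[1] else 2 if x < cum[2] else 3
        s.append(BASES[state])
    for i in range(0, length - 2, 3):
        if "".join(s[i : i + 3]) in STOPS:
            s[i] = "C"
    return "".join(s)


# ---------------------------------------------------------------------------
# methylation assignment
# ---------------------------------------------------------------------------


def _exon_cpg_positions(plan: _GenePlan, cds: str) -> list[tuple[_ExonPlan, int]]:
    """CDS indices of the C of every within-exon CpG, with its exon.

    CpGs are scanned within each exon's sense sequence; dinucleotides
    spanning an exon junction are not genomic CpGs (an intron intervenes)
    and are skipped by construction.
    """
    out = []
    for exon in plan.exons:
        sub = cds[exon.cds_offset : exon.cds_offset + exon.cds_length]
        for i in methylome.cpg_positions(sub):
            out.append((exon, exon.cds_offset + i))
    return out


def genomic_plus_c_position(plan: _GenePlan, exon: _ExonPlan, cds_index: int) -> int:
    """Plus-strand genomic coordinate of the C of the CpG whose sense-strand
    C sits at ``cds_index`` (palindromy: on minus-strand genes the
    plus-strand C is one base 5'-ward of the sense C)."""
    offset = cds_index - exon.cds_offset
    if plan.strand == "+":
        return exon.genomic_start + offset
    sense_c = exon.genomic_end - 1 - offset
    return sense_c - 1


def assign_methylation(
    plans, ancestral: dict, config: SimulationConfig, rng: np.random.Generator
):
    """Draw per-exon methylation levels and per-CpG frequencies.

    Returns (records, exon_levels): records is a list per gene of
    (exon, cds_index, frequency, true_state); exon_levels maps exon_id
    to its latent methylation level.
    """
    nu_e = config.meth_exon_concentration
    nu_c = config.meth_cpg_concentration
    records: dict[str, list] = {}
    exon_levels: dict[str, float] = {}
    eps = 1e-3
    for plan in plans:
        cds = ancestral[plan.gene_id]
        recs = []
        for exon in plan.exons:
            cls = exon.position_class if exon.position_class in CLASSES else "first"
            m = float(config.meth_mean[cls])
            if m <= 0.0:
                level = 0.0
            elif m >= 1.0:
                level = 1.0
            else:
                level = float(rng.beta(m * nu_e, (1 - m) * nu_e))
            exon_levels[exon.exon_id] = level
        for exon, cds_index in _exon_cpg_positions(plan, cds):
            level = exon_levels[exon.exon_id]
            a = level * nu_c + eps
            b = (1 - level) * nu_c + eps
            freq = float(rng.beta(a, b))
            if level == 0.0:
                freq = 0.0
            elif level == 1.0:
                freq = 1.0
            recs.append(
                (exon, cds_index, freq, freq >= config.meth_call_threshold)
            )
        records[plan.gene_id] = recs
    return records, exon_levels


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def _acceptance_probs(
    plans, config: SimulationConfig, covariates: pd.DataFrame
) -> dict[str, float]:
    """Per-exon nonsynonymous acceptance probability.

    With no covariate/length effects this is exactly the class base
    value; otherwise base is moved on the logit scale by the configured
    effects of standardized log length and disorder proportion.
    """
    out = {}
    use_effects = config.accept_length_effect != 0.0 or config.accept_disorder_effect != 0.0
    if use_effects:
        cov = covariates.set_index("exon_id")
        loglen = np.log(cov["length"].astype(float))
        z_len = (loglen - loglen.mean()) / (loglen.std() or 1.0)
        dis = cov["disorder_prop"].astype(float)
        z_dis = (dis - dis.mean()) / (dis.std() or 1.0)
    for plan in plans:
        for exon in plan.exons:
            cls = exon.position_class if exon.position_class in CLASSES else "first"
            base = float(config.acceptance[cls])
            if not use_effects:
                out[exon.exon_id] = base
                continue
            base = min(max(base, 1e-3), 1 - 1e-3)
            logit = math.log(base / (1 - base))
            logit += config.accept_length_effect * float(z_len[exon.exon_id])
            logit += config.accept_disorder_effect * float(z_dis[exon.exon_id])
            out[exon.exon_id] = 1.0 / (1.0 + math.exp(-logit))
    return out


def _evolve_lineage(
    cds: str,
    meth_c: set[int],
    exon_of_base: np.ndarray,
    accept: list[float],
    config: SimulationConfig,
    rng: np.random.Generator,
    tally: dict,
):
    """Evolve one descendant from ``cds``; returns the new sequence.

    Substitution model: per site, target-specific rates mu * w / (kappa
    + 2) with w = kappa for the transition and 1 for each transversion;
    the C->T channel at the C of a truly methylated CpG (and the G->A
    channel at its paired G) is multiplied by lambda.  Nonsynonymous
    proposals are accepted with the exon's acceptance probability;
    stop-creating proposals are rejected.
    """
    L = len(cds)
    kappa = config.kappa
    lam = config.cpg_lambda
    mu = config.mu
    norm = kappa + 2.0
    # transitions: A<->G, C<->T
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}

    base_total = mu  # sum of channel weights normalized to mu
    meth_g = {i + 1 for i in meth_c}
    site_prob = np.full(L, base_total)
    boost = mu * (kappa * (lam - 1.0)) / norm
    for i in meth_c:
        site_prob[i] += boost
    for i in meth_g:
        if i < L:
            site_prob[i] += boost

    hits = np.nonzero(rng.random(L) < site_prob)[0]
    u_targets = rng.random(len(hits))
    seq = list(cds)
    for i, u in zip(hits, u_targets):
        ref = seq[i]
        # target weights
        weights = []
        targets = []
        for b in BASES:
            if b == ref:
                continue
            w = kappa if transition[ref] == b else 1.0
            if (i in meth_c and ref == "C" and b == "T") or (
                i in meth_g and ref == "G" and b == "A"
            ):
                w *= lam
            targets.append(b)
            weights.append(w)
        total = weights[0] + weights[1] + weights[2]
        x = u * total
        new = (
            targets[0]
            if x < weights[0]
            else targets[1]
            if x < weights[0] + weights[1]
            else targets[2]
        )
        codon_start = 3 * (i // 3)
        old_codon = "".join(seq[codon_start : codon_start + 3])
        new_codon = (
            old_codon[: i - codon_start] + new + old_codon[i - codon_start + 1 :]
        )
        if new_codon in STOPS:
            continue
        exon = int(exon_of_base[i])
        syn = CODON_TO_AA[old_codon] == CODON_TO_AA[new_codon]
        if not syn and rng.random() >= accept[exon]:
            continue
        seq[i] = new
        t = tally[exon]
        t["syn" if syn else "nonsyn"] += 1
        if ref == "C" and new == "T":
            if i in meth_c:
                t["ct_meth"] += 1
            else:
                t["ct_other"] += 1
    return "".join(seq)


def evolve_orthologs(
    plan: _GenePlan,
    cds: str,
    meth_records: list,
    accept_by_exon: dict[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
):
    """Two descendant lineages plus per-exon ground-truth tallies."""
    n_ex = len(plan.exons)
    exon_of_base = np.empty(len(cds), dtype=int)
    for idx, exon in enumerate(plan.exons):
        exon_of_base[exon.cds_offset : exon.cds_offset + exon.cds_length] = idx
    accept = [accept_by_exon[e.exon_id] for e in plan.exons]
    meth_c = {ci for _, ci, _, state in meth_records if state}
    tallies = [
        [
            {"syn": 0, "nonsyn": 0, "ct_meth": 0, "ct_other": 0}
            for _ in range(n_ex)
        ]
        for _ in range(2)
    ]
    focal = _evolve_lineage(cds, meth_c, exon_of_base, accept, config, rng, tallies[0])
    ortho = _evolve_lineage(cds, meth_c, exon_of_base, accept, config, rng, tallies[1])
    return focal, ortho, tallies


# ---------------------------------------------------------------------------
# bisulfite calls and covariates
# ---------------------------------------------------------------------------


def _nb_draw(rng, mean, dispersion, size):
    if mean <= 0:
        return np.zeros(size, dtype=int)
    r = dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def emit_bisulfite_calls(
    plans,
    focal_seqs: dict,
    meth_records: dict,
    exon_levels: dict,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-strand call rows for every CpG of the focal lineage.

    CpGs that survived from the ancestor keep their assigned frequency;
    CpGs created by mutation draw a fresh frequency around their exon's
    methylation level.  Coverage is negative binomial per strand;
    methylated reads are binomial(coverage, frequency).  Rows are sorted
    by coordinate; zero-coverage rows are retained.
    """
    nu_c = config.meth_cpg_concentration
    eps = 1e-3
    rows = []
    for plan in plans:
        focal = focal_seqs[plan.gene_id]
        assigned = {ci: freq for _, ci, freq, _ in meth_records[plan.gene_id]}
        for exon, cds_index in _exon_cpg_positions(plan, focal):
            if cds_index in assigned:
                freq = assigned[cds_index]
            else:
                level = exon_levels[exon.exon_id]
                if level == 0.0:
                    freq = 0.0
                elif level == 1.0:
                    freq = 1.0
                else:
                    freq = float(
                        rng.beta(level * nu_c + eps, (1 - level) * nu_c + eps)
                    )
            plus_c = genomic_plus_c_position(plan, exon, cds_index)
            cov = _nb_draw(rng, config.coverage_mean / 2.0, config.coverage_dispersion, 2)
            meth = [
                int(rng.binomial(c, freq)) if c > 0 else 0 for c in cov
            ]
            # plus-strand C at plus_c (1-based plus_c+1); minus-strand C
            # opposite the G, reported at plus_c+1 (1-based plus_c+2)
            rows.append((plan.chrom, plus_c + 1, "+", int(cov[0]), meth[0]))
            rows.append((plan.chrom, plus_c + 2, "-", int(cov[1]), meth[1]))
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "coverage", "meth_reads"]
    )
    return df.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(
        drop=True
    )


def simulate_covariates(
    plans, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Expression, repeat and disorder proportions per coding exon.

    Effects couple each covariate to standardized log exon length so
    confounder-control behavior can be exercised; at zero effects the
    covariates are independent of length.
    """
    exons = [(p, e) for p in plans for e in p.exons]
    lengths = np.array([e.cds_length for _, e in exons], dtype=float)
    loglen = np.log(lengths)
    z = (loglen - loglen.mean()) / (loglen.std() or 1.0)

    expr = rng.lognormal(
        config.expression_mu + config.expression_length_effect * z,
        config.expression_sigma,
    )

    def beta_with_effect(mean, conc, effect):
        m = np.clip(mean, 1e-3, 1 - 1e-3)
        logit = math.log(m / (1 - m)) + effect * z
        mm = 1.0 / (1.0 + np.exp(-logit))
        noise_conc = conc
        return rng.beta(mm * noise_conc + 1e-3, (1 - mm) * noise_conc + 1e-3)

    repeat = beta_with_effect(
        config.repeat_mean, config.repeat_concentration, config.repeat_length_effect
    )
    disorder = beta_with_effect(
        config.disorder_mean,
        config.disorder_concentration,
        config.disorder_length_effect,
    )
    return pd.DataFrame(
        {
            "gene_id": [p.gene_id for p, _ in exons],
            "exon_id": [e.exon_id for _, e in exons],
            "chrom": [p.chrom for p, _ in exons],
            "start": [e.genomic_start for _, e in exons],
            "end": [e.genomic_end for _, e in exons],
            "length": lengths.astype(int),
            "expression": expr,
            "repeat_prop": repeat,
            "disorder_prop": disorder,
        }
    )


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------


def simulate_dataset(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> SimulatedDataset:
    """Generate the full input bundle deterministically from the config."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    plans, gff3 = simulate_gene_models(config, rng)

    ancestral = {
        p.gene_id: simulate_ancestral_cds(p.cds_length, config, rng) for p in plans
    }
    meth_records, exon_levels = assign_methylation(plans, ancestral, config, rng)
    covariates = simulate_covariates(plans, config, rng)
    accept_by_exon = _acceptance_probs(plans, config, covariates)

    cds_focal, cds_ortholog, protein_alignments = {}, {}, {}
    truth_rows = []
    for plan in plans:
        focal, ortho, tallies = evolve_orthologs(
            plan,
            ancestral[plan.gene_id],
            meth_records[plan.gene_id],
            accept_by_exon,
            config,
            rng,
        )
        cds_focal[plan.gene_id] = focal
        cds_ortholog[plan.gene_id] = ortho
        protein_alignments[plan.gene_id] = (_translate(focal), _translate(ortho))
        meth_by_exon: dict[str, list] = {e.exon_id: [] for e in plan.exons}
        for exon, ci, freq, state in meth_records[plan.gene_id]:
            meth_by_exon[exon.exon_id].append(state)
        for idx, exon in enumerate(plan.exons):
            states = meth_by_exon[exon.exon_id]
            truth_rows.append(
                {
                    "gene_id": plan.gene_id,
                    "exon_id": exon.exon_id,
                    "chrom": plan.chrom,
                    "start": exon.genomic_start,
                    "end": exon.genomic_end,
                    "strand": plan.strand,
                    "intended_class": exon.position_class,
                    "intended_splice": exon.splice_class,
                    "length": exon.cds_length,
                    "meth_level": exon_levels[exon.exon_id],
                    "n_cpg_true": len(states),
                    "n_meth_true": int(sum(states)),
                    "acceptance": accept_by_exon[exon.exon_id],
                    "syn_subs": tallies[0][idx]["syn"] + tallies[1][idx]["syn"],
                    "nonsyn_subs": tallies[0][idx]["nonsyn"]
                    + tallies[1][idx]["nonsyn"],
                    "ct_meth": tallies[0][idx]["ct_meth"] + tallies[1][idx]["ct_meth"],
                    "ct_other": tallies[0][idx]["ct_other"]
                    + tallies[1][idx]["ct_other"],
                }
            )

    calls = emit_bisulfite_calls(
        plans, cds_focal, meth_records, exon_levels, config, rng
    )

    truth_cpg_rows = []
    for plan in plans:
        for exon, ci, freq, state in meth_records[plan.gene_id]:
            truth_cpg_rows.append(
                {
                    "gene_id": plan.gene_id,
                    "exon_id": exon.exon_id,
                    "chrom": plan.chrom,
                    "plus_c_pos": genomic_plus_c_position(plan, exon, ci),
                    "frequency": freq,
                    "true_methylated": bool(state),
                }
            )

    return SimulatedDataset(
        config=config,
        gff3=gff3,
        cds_focal=cds_focal,
        cds_ortholog=cds_ortholog,
        protein_alignments=protein_alignments,
        calls=calls,
        covariates=covariates,
        truth_exons=pd.DataFrame(truth_rows),
        truth_cpgs=pd.DataFrame(truth_cpg_rows),
    )
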