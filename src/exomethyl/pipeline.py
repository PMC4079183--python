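"""End-to-end orchestration: inputs -> master per-exon table -> analyses.

The pipeline's spine is a single master table with one row per retained
coding exon, carrying classification labels, methylation/composition
metrics, evolutionary-rate estimates, and covariates.  Every analysis
is a view over this table, so every reported n is traceable to row
counts.

Two dataset tiers mirror the study design: the *background* tier holds
all rate-bearing exons regardless of methylome QC; the *methylome* tier
holds the QC-passing subset (coding length > 80 bp, >= 10 sampled CpGs).
Methylation analyses use the methylome tier; the length-vs-rate table
uses the background tier (optionally the methylome tier when mCG
density joins the control set).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import annotation, evolution, methylome, stats
from .simulate import SimulationConfig, SimulatedDataset, simulate_dataset

__version__ = "0.1.0"

FIGURE3_CONTROLS = ("cpg_density", "gc_content", "length", "is_ase")
TABLE2_CONTROLS = ("is_ase", "repeat_prop", "disorder_prop", "expression")
RATES = ("omega", "dn", "ds")
CLASSES = ("first", "last", "internal")


@dataclass
class PipelineConfig:
    """Inputs (paths or a simulation config), QC thresholds, and outputs."""

    simulation: SimulationConfig | None = None
    gff3: str | None = None
    cds_focal: str | None = None
    cds_ortholog: str | None = None
    protein_alignments: str | None = None
    methylation_calls: str | None = None
    covariates: str | None = None

    min_coverage: int = methylome.DEFAULT_MIN_COVERAGE
    meth_threshold: float = methylome.DEFAULT_METH_THRESHOLD
    min_sampled_cpg: int = methylome.DEFAULT_MIN_SAMPLED
    min_exon_length: int = methylome.DEFAULT_MIN_LENGTH
    drop_no_utr: bool = False

    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_coverage <= 0 or self.min_sampled_cpg <= 0:
            raise ValueError("thresholds must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg


@dataclass
class AnalysisReport:
    master: pd.DataFrame
    figure1: pd.DataFrame
    figure2: pd.DataFrame
    figure3: pd.DataFrame
    figure4: pd.DataFrame
    table2: pd.DataFrame
    metadata: dict

    def write(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("master", "figure1", "figure2", "figure3", "figure4", "table2"):
            path = outdir / f"{name}.tsv"
            getattr(self, name).to_csv(
                path, sep="\t", index=False, float_format="%.6g"
            )
            paths[name] = str(path)
        meta_path = outdir / "run_metadata.json"
        meta_path.write_text(json.dumps(self.metadata, indent=2, sort_keys=True))
        paths["metadata"] = str(meta_path)
        return paths


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# input assembly
# ---------------------------------------------------------------------------


def _read_fasta(path: str) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulation is not None:
        ds = simulate_dataset(cfg.simulation)
        genes = annotation.parse_annotations(ds.gff3, from_string=True)
        aln = ds.protein_alignments
        calls = ds.calls.assign(pos=ds.calls["pos"] - 1)  # emitted 1-based
        return genes, ds.cds_focal, ds.cds_ortholog, aln, calls, ds.covariates
    genes = annotation.parse_annotations(cfg.gff3)
    cds_focal = _read_fasta(cfg.cds_focal)
    cds_ortholog = _read_fasta(cfg.cds_ortholog)
    raw = _read_fasta(cfg.protein_alignments)
    aln: dict[str, list] = {}
    for key, seq in raw.items():
        gid, _, which = key.partition("|")
        aln.setdefault(gid, [None, None])
        aln[gid][0 if which == "focal" else 1] = seq
    aln = {g: tuple(v) for g, v in aln.items() if None not in v}
    calls = methylome.load_methylation_calls(cfg.methylation_calls)
    covariates = (
        pd.read_csv(cfg.covariates, sep="\t") if cfg.covariates else pd.DataFrame()
    )
    return genes, cds_focal, cds_ortholog, aln, calls, covariates


def _reference_transcript(gene: annotation.GeneModel) -> annotation.TranscriptModel:
    """The isoform with the longest CDS anchors exon-wise rate slicing."""
    return max(
        gene.transcripts,
        key=lambda t: (sum(iv.length for iv in t.cds), t.transcript_id),
    )


def build_master_table(
    genes: list,
    cds_focal: dict,
    cds_ortholog: dict,
    alignments: dict,
    calls: pd.DataFrame,
    covariates: pd.DataFrame,
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, dict]:
    """Classify, profile, and estimate rates for every retained gene."""
    retained, exclusion_log = annotation.filter_genes(genes)
    merged_calls = methylome.merge_strands(calls) if len(calls) else pd.DataFrame(
        columns=["chrom", "pos", "coverage", "meth_reads"]
    )
    call_index = methylome.calls_lookup(merged_calls)

    rows = []
    tallies = {
        "genes_in": len(genes),
        "genes_retained": len(retained),
        "genes_excluded": len(exclusion_log),
        "exons_frame_failed": 0,
        "genes_missing_sequence": 0,
    }
    for gene in retained:
        coding = annotation.classify_exon_positions(gene)
        if cfg.drop_no_utr:
            coding = [
                ce
                for ce in coding
                if not ({"no_5utr", "no_3utr"} & set(ce.flags))
            ]
        ref_tx = _reference_transcript(gene)
        ref_exons = ref_tx.coding_exons()
        exon_lengths = [iv.length for iv in ref_exons]
        gid = gene.gene_id

        rates_by_iv: dict = {}
        if gid in cds_focal and gid in cds_ortholog and gid in alignments:
            a1, a2 = alignments[gid]
            try:
                n1, n2 = evolution.backtranslate(
                    a1, a2, cds_focal[gid], cds_ortholog[gid]
                )
                per_exon = evolution.exon_rates(n1, n2, exon_lengths)
                for iv, triple in zip(ref_exons, per_exon):
                    rates_by_iv[iv] = triple
            except (evolution.BacktranslationError, ValueError):
                tallies["genes_missing_sequence"] += 1
        else:
            tallies["genes_missing_sequence"] += 1

        # sense sequence of each coding exon from the focal CDS
        offsets = np.concatenate([[0], np.cumsum(exon_lengths)]).astype(int)
        seq_by_iv = {}
        if gid in cds_focal:
            cds = cds_focal[gid]
            for iv, off, ln in zip(ref_exons, offsets[:-1], exon_lengths):
                seq_by_iv[iv] = cds[off : off + ln]

        for order_idx, ce in enumerate(coding):
            iv = ce.interval
            seq = seq_by_iv.get(iv, "")
            if seq:
                cpos = methylome.cpg_positions(seq)
                if iv.strand == "+":
                    gpos = [iv.start + i for i in cpos]
                else:
                    gpos = [iv.end - 2 - i for i in cpos]
                profile = methylome.exon_profile(
                    (gid, iv.chrom, iv.start, iv.end),
                    seq,
                    gpos,
                    call_index,
                    cfg.min_coverage,
                    cfg.meth_threshold,
                    cfg.min_exon_length,
                    cfg.min_sampled_cpg,
                )
            else:
                profile = None
            triple = rates_by_iv.get(iv)
            frame_status, counts, rates = (
                triple if triple is not None else ("no_alignment", None, None)
            )
            if frame_status != "pass":
                tallies["exons_frame_failed"] += int(triple is not None)
            row = {
                "gene_id": gid,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "strand": iv.strand,
                "position_class": ce.position_class,
                "splice_class": ce.splice_class,
                "is_ase": int(ce.splice_class == "ASE"),
                "length": ce.length,
                "flags": ",".join(ce.flags),
                "frame_status": frame_status,
                "codons_compared": counts.codons_compared if counts else 0,
                "N": counts.n_sites if counts else math.nan,
                "S": counts.s_sites if counts else math.nan,
                "Nd": counts.n_diffs if counts else math.nan,
                "Sd": counts.s_diffs if counts else math.nan,
                "dn": rates.dn if rates else math.nan,
                "ds": rates.ds if rates else math.nan,
                "omega": rates.omega if rates else math.nan,
                "rate_status": rates.status if rates else "no_data",
            }
            if profile is not None:
                row.update(
                    {
                        "n_cpg": profile.n_cpg,
                        "n_sampled": profile.n_sampled,
                        "n_mcg": profile.n_mcg,
                        "mcg_density": profile.mcg_density,
                        "mcg_density_bp": profile.mcg_density_bp,
                        "cpg_oe": profile.cpg_oe,
                        "gc_content": profile.gc_content,
                        "cpg_density": profile.cpg_density,
                        "qc_pass": profile.qc_pass,
                        "qc_reason": profile.qc_reason,
                    }
                )
            else:
                row.update(
                    {
                        "n_cpg": 0,
                        "n_sampled": 0,
                        "n_mcg": 0,
                        "mcg_density": math.nan,
                        "mcg_density_bp": math.nan,
                        "cpg_oe": math.nan,
                        "gc_content": math.nan,
                        "cpg_density": math.nan,
                        "qc_pass": False,
                        "qc_reason": "no_sequence",
                    }
                )
            rows.append(row)

    master = pd.DataFrame(rows)
    if len(master):
        master = master.sort_values(
            ["gene_id", "start", "end"], kind="stable"
        ).reset_index(drop=True)
        master["has_rates"] = master["rate_status"].isin(["ok"]) & np.isfinite(
            master["dn"]
        )
    else:
        master["has_rates"] = pd.Series(dtype=bool)

    if len(covariates):
        master = master.merge(
            covariates[
                ["gene_id", "chrom", "start", "end", "expression", "repeat_prop", "disorder_prop"]
            ],
            on=["gene_id", "chrom", "start", "end"],
            how="left",
        )
    else:
        for col in ("expression", "repeat_prop", "disorder_prop"):
            master[col] = math.nan

    tallies["exons_total"] = int(len(master))
    tallies["exons_qc_pass"] = int(master["qc_pass"].sum()) if len(master) else 0
    tallies["exclusion_log"] = [
        {"gene_id": g, "reason": r} for g, r in exclusion_log
    ]
    return master, tallies


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------


def _analyzable(master: pd.DataFrame) -> pd.DataFrame:
    return master[master["position_class"].isin(CLASSES)]


def figure1_analysis(master: pd.DataFrame) -> pd.DataFrame:
    """Pearson r(mCG density, CpG O/E), overall and per position class.

    Methylome tier (QC-passing exons).  The mutagenic-effect expectation
    is directional: stronger methylation-driven C->T loss makes r more
    negative.
    """
    tier = _analyzable(master)
    tier = tier[tier["qc_pass"]]
    rows = []
    for stratum, sub in [("overall", tier)] + [
        (cls, tier[tier["position_class"] == cls]) for cls in CLASSES
    ]:
        res = stats.pearson(sub["mcg_density"], sub["cpg_oe"])
        rows.append(
            {
                "stratum": stratum,
                "method": "pearson",
                "coefficient": res.coefficient,
                "p_value": res.p_value,
                "n": res.n,
                "stars": _stars(res.p_value),
            }
        )
    return pd.DataFrame(rows)


def figure2_analysis(master: pd.DataFrame) -> pd.DataFrame:
    """Per-class rate medians and pairwise Wilcoxon rank-sum tests.

    Computed on both tiers, labeled: the methylome tier mirrors the
    sperm-methylome datasets, the background tier uses every
    rate-bearing exon.
    """
    rows = []
    base = _analyzable(master)
    for tier_name, tier in [
        ("methylome", base[base["qc_pass"] & base["has_rates"]]),
        ("background", base[base["has_rates"]]),
    ]:
        for rate in RATES:
            groups = {
                cls: tier.loc[
                    tier["position_class"] == cls, rate
                ].dropna()
                for cls in CLASSES
            }
            for cls_a, cls_b in itertools.combinations(CLASSES, 2):
                a, b = groups[cls_a], groups[cls_b]
                if len(a) == 0 or len(b) == 0:
                    continue
                cmp = stats.wilcoxon_rank_sum(
                    a, b, labels=(cls_a, cls_b), exact=False
                )
                rows.append(
                    {
                        "tier": tier_name,
                        "rate": rate,
                        "group_a": cls_a,
                        "group_b": cls_b,
                        "median_a": cmp.medians[0],
                        "median_b": cmp.medians[1],
                        "n_a": len(a),
                        "n_b": len(b),
                        "statistic": cmp.statistic,
                        "p_value": cmp.p_value,
                        "stars": _stars(cmp.p_value),
                    }
                )
    return pd.DataFrame(rows)


def _correlation_rows(
    sub: pd.DataFrame,
    xcol: str,
    rate: str,
    controls: tuple[str, ...],
    stratum: str,
) -> list[dict]:
    rows = []
    plain = stats.spearman(sub[xcol], sub[rate])
    rows.append(
        {
            "stratum": stratum,
            "x": xcol,
            "y": rate,
            "method": "spearman",
            "controls": "",
            "coefficient": plain.coefficient,
            "p_value": plain.p_value,
            "n": plain.n,
            "stars": _stars(plain.p_value),
        }
    )
    ctrl = stats.partial_spearman(
        sub[xcol],
        sub[rate],
        sub[list(controls)].to_numpy() if controls else np.empty((len(sub), 0)),
        control_names=list(controls),
    )
    rows.append(
        {
            "stratum": stratum,
            "x": xcol,
            "y": rate,
            "method": "partial_spearman",
            "controls": ",".join(controls),
            "coefficient": ctrl.coefficient,
            "p_value": ctrl.p_value,
            "n": ctrl.n,
            "stars": _stars(ctrl.p_value),
        }
    )
    return rows


def figure3_analysis(
    master: pd.DataFrame, controls: tuple[str, ...] = FIGURE3_CONTROLS
) -> pd.DataFrame:
    """Spearman (plain + partial) of mCG density vs each rate per class."""
    tier = _analyzable(master)
    tier = tier[tier["qc_pass"] & tier["has_rates"]]
    rows = []
    for cls in CLASSES:
        sub = tier[tier["position_class"] == cls]
        for rate in RATES:
            rows.extend(
                _correlation_rows(sub, "mcg_density", rate, controls, cls)
            )
    return pd.DataFrame(rows)


def table2_analysis(
    master: pd.DataFrame,
    controls: tuple[str, ...] = TABLE2_CONTROLS,
    include_mcg_control: bool = False,
) -> pd.DataFrame:
    """Spearman (plain + partial) of exon length vs each rate per class.

    Background tier by default; adding mCG density as a fifth control
    switches to the methylome tier, where mCG density is defined.
    """
    tier = _analyzable(master)
    if include_mcg_control:
        tier = tier[tier["qc_pass"] & tier["has_rates"]]
        controls = tuple(controls) + ("mcg_density",)
    else:
        tier = tier[tier["has_rates"]]
    rows = []
    for cls in CLASSES:
        sub = tier[tier["position_class"] == cls]
        for rate in RATES:
            rows.extend(_correlation_rows(sub, "length", rate, controls, cls))
    return pd.DataFrame(rows)


def figure4_analysis(master: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Pearson r(mCG density, CpG O/E) per position class per length
    subgroup (subgroup 1 = shortest exons)."""
    tier = _analyzable(master)
    tier = tier[tier["qc_pass"]]
    rows = []
    for cls in CLASSES:
        sub = tier[tier["position_class"] == cls].reset_index(drop=True)
        if len(sub) < k:
            continue
        for stratum in stats.length_quintiles(sub["length"], k=k):
            block = sub.iloc[stratum.indices]
            res = stats.pearson(block["mcg_density"], block["cpg_oe"])
            rows.append(
                {
                    "position_class": cls,
                    "subgroup": stratum.subgroup,
                    "length_min": stratum.length_range[0],
                    "length_max": stratum.length_range[1],
                    "coefficient": res.coefficient,
                    "p_value": res.p_value,
                    "n": res.n,
                    "stars": _stars(res.p_value),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------


def _analysis_config_dict(cfg: PipelineConfig) -> dict:
    """Config as recorded in metadata: the output path is not part of
    the analysis and is excluded so identical runs hash identically."""
    d = cfg.to_dict()
    d.pop("outdir", None)
    return d


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(_analysis_config_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> AnalysisReport:
    """Execute all stages and assemble the report.

    Stage order: parse/simulate -> gene filters -> classification ->
    methylation profiles + QC -> exon-wise rates -> statistics.  Every
    exclusion is tallied in the metadata; a fixed seed and config yield
    a byte-identical report bundle.
    """
    genes, cds_f, cds_o, aln, calls, covariates = _load_inputs(cfg)
    master, tallies = build_master_table(
        genes, cds_f, cds_o, aln, calls, covariates, cfg
    )
    report = AnalysisReport(
        master=master,
        figure1=figure1_analysis(master),
        figure2=figure2_analysis(master),
        figure3=figure3_analysis(master),
        figure4=figure4_analysis(master),
        table2=table2_analysis(master),
        metadata={
            "package_version": __version__,
            "estimator": "NG86 counting with Jukes-Cantor correction",
            "seed": cfg.seed,
            "config": _analysis_config_dict(cfg),
            "config_hash": _config_hash(cfg),
            "tallies": tallies,
        },
    )
    if cfg.outdir:
        report.write(cfg.outdir)
    return report
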