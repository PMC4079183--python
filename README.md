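# exomethyl

Exon-resolved analysis of how gene-body CpG methylation, relative exon
position, and exon length relate to coding-sequence evolutionary rates.

## The scientific problem

In plants, CpG methylation inside gene bodies is both a mutagen and a
regulatory mark.  Methylated cytosines deaminate to thymine at an
elevated rate, so exons that are heavily methylated should, over
evolutionary time, lose CpG dinucleotides — their CpG observed/expected
ratio falls — and accumulate C→T substitutions that register in the
synonymous rate d<sub>S</sub>, the nonsynonymous rate d<sub>N</sub>, and
their ratio ω = d<sub>N</sub>/d<sub>S</sub>.  At the same time, first,
internal, and last coding exons play different biological roles and sit
under different selective constraints, and exon length correlates with
several confounders (splice type, repeat content, protein disorder,
expression level).

`exomethyl` implements this analysis as a tested pipeline for anyone
studying exon-scale molecular evolution in plant-like genomes:

* classify coding exons by relative position (**first / last /
  internal**, across collated isoforms, anchored on the most downstream
  5'UTR and most upstream 3'UTR) and splice type (**CSE / ASE**);
* summarize base-resolution bisulfite calls into per-exon **mCG
  density** (methylated CpGs per 100 sampled CpGs; a CpG is *sampled*
  at ≥5 reads and *methylated* at ≥80% supporting reads) and the
  **CpG O/E ratio** = n<sub>CpG</sub>·L / (n<sub>C</sub>·n<sub>G</sub>);
* estimate per-exon d<sub>N</sub>, d<sub>S</sub>, and ω from pairwise
  ortholog alignments by back-translation, exon-wise slicing with frame
  checks, and **Nei–Gojobori (1986) counting** with Jukes–Cantor
  correction;
* relate the three — Pearson r(mCG density, CpG O/E) per position class
  and length quintile; rank-sum comparisons of rate distributions
  across classes; Spearman and **partial Spearman** correlations of mCG
  density and exon length against each rate, controlling simultaneously
  for CpG density, G+C content, exon length, splice type, repeat and
  disorder proportions, and expression.

Because the real inputs (a reference genome and annotation, sperm
methylomes, ortholog alignments) are bulky external downloads, the
package ships a first-class **synthetic-data generator** that emits the
same file dialects (GFF3, FASTA, TSV call tables) from an explicit
generative model — beta-distributed methylation with class-specific
means, negative-binomial read coverage, two-lineage sequence divergence
with a λ-fold C→T boost at methylated CpGs, and per-class nonsynonymous
acceptance probabilities — with full ground truth for recovery testing.

## Worked example

Run the pipeline on a simulated dataset with a strong mutagenic effect
(λ = 10, selection disabled, methylome-tier exon lengths):

```python
from exomethyl import scenarios
from exomethyl.pipeline import PipelineConfig, run_pipeline

rep = run_pipeline(
    PipelineConfig(simulation=scenarios.mutagenesis(10.0, seed=7), seed=7)
)
print(rep.figure1.to_string(index=False))
```

```
 stratum  method  coefficient      p_value    n stars
 overall pearson    -0.364333 2.417832e-61 1920   ***
   first pearson    -0.204036 1.231598e-05  452   ***
    last pearson    -0.364685 2.710030e-16  472   ***
internal pearson    -0.400691 1.053735e-39  996   ***
```

mCG density is strongly negatively correlated with the CpG O/E ratio in
every position class: heavily methylated exons have lost CpGs to C→T
mutation, and the correlation is the analysis' readout of that
mutagenic effect (at λ = 1 the same analysis gives r ≈ 0).  With
per-class nonsynonymous acceptance ordered first > last > internal
(0.9/0.6/0.3), the rate comparison recovers the selection structure:

```python
rep = run_pipeline(
    PipelineConfig(simulation=scenarios.selection_ordering(seed=7), seed=7)
)
f2 = rep.figure2
print(f2[(f2.tier == "background") & (f2.rate == "omega")].to_string(index=False))
```

```
 rate group_a  group_b  median_a  median_b      p_value stars
omega   first     last  0.830841  0.516288 4.195802e-16   ***
omega   first internal  0.830841  0.263032 4.096287e-68   ***
omega    last internal  0.516288  0.263032 3.698479e-33   ***
```

Median ω is highest for first exons and lowest for internal exons, with
every pairwise Wilcoxon rank-sum test significant — first exons evolve
under the weakest constraint in this configuration.

The same analyses are available from the shell:

```bash
exomethyl simulate --seed 3 --outdir sim/           # write a GFF3/FASTA/TSV bundle
exomethyl run --seed 3 --outdir out/                # simulate + full analysis
exomethyl report --master out/master.tsv --outdir rep/
```

`out/` then contains `master.tsv` (the per-exon spine: labels,
methylation metrics, rates, covariates), the analysis views
(`figure1.tsv` … `figure4.tsv`, `table2.tsv`), and `run_metadata.json`
(seed, config hash, exclusion tallies) sufficient to re-run the
analysis bit-identically.

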