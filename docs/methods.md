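# Methods

This note documents the models, estimators, and design choices behind
`exomethyl`, and what the synthetic-data generator does and does not
emulate.

## Coding-exon classification

Gene models are read from GFF3 (gene → mRNA → exon/CDS/UTR).  All
internal coordinates are 0-based half-open, so `length = end - start`
with no off-by-one adjustments; conversion happens only at I/O.

Gene-level exclusions: genes overlapping annotated non-coding RNAs or
pseudogenes are removed, as are genes whose *every* isoform is
single-exon (a gene with one single-exon and one multi-exon isoform is
retained — excluding it would discard usable multi-exon structure).

Position classes are assigned over the union of a gene's isoforms.  A
*coding exon* is the coding part of an exon (exon ∩ CDS), deduplicated
by exact coordinates across isoforms.  The anchor for "first" is the
most downstream 5'UTR end across isoforms, for "last" the most upstream
3'UTR start, both in transcription direction; the coding exon nearest
each anchor takes the label and everything else is internal.  When a
stand-alone 5'UTR exon precedes a second 5'UTR juxtaposed to the
candidate first coding exon, that coding exon is not part of the most
upstream transcribed region and is labeled `excluded`
(`non_upstream_first`); symmetrically at the 3' end.  Genes lacking an
annotated 5'UTR (or 3'UTR) fall back to the most upstream (downstream)
coding exon, flagged `no_5utr`/`no_3utr`; a pipeline switch drops
flagged exons for users who prefer the strict reading.

Splice classes use exact coordinate identity: an exon is constitutive
(CSE) iff an identical-coordinate coding exon appears in every isoform;
otherwise alternative (ASE).  Boundary-shifted variants therefore count
as ASE — presence/absence is the only criterion the classification
needs, and coordinate identity is the strictest reproducible reading.

## Methylation metrics

Bisulfite calls arrive as per-strand rows (chrom, 1-based position,
strand, coverage, methylated reads).  The two strands of a palindromic
CpG are merged onto the plus-strand C by summing reads before any
thresholding, maximizing usable coverage.  A CpG is *sampled* at
coverage ≥ 5 and *methylated* (an mCG) at methylation frequency ≥ 0.80;
both bounds are inclusive.  Per exon:

* mCG density = mCGs × 100 / sampled CpGs (the primary form; a per-100-bp
  variant is also computed),
* CpG O/E = observed CpGs × length / (#C × #G) on the sense-strand
  coding sequence, with an overlapping CpG scan,
* G+C content and CpG density (CpGs/bp).

QC keeps exons with coding length strictly > 80 bp and ≥ 10 sampled
CpGs.  Undefined metrics (no sampled CpGs; zero C or G counts)
propagate as missing values and are removed pairwise from correlations,
never coerced to zero.

CpGs are scanned within each exon's sense sequence.  A dinucleotide
whose C is the last base of an exon is not a genomic CpG (an intron
follows), and concatenating CDS pieces would fabricate spurious CpGs at
junctions; both the pipeline and the generator therefore count CpGs
strictly within exons, so the two views agree by construction.

## Evolutionary rates

Rates are estimated per exon from a pairwise protein alignment of
one-to-one orthologs plus both coding sequences:

1. **Back-translation** replaces each aligned residue with its source
   codon after verifying that each CDS translates to its aligned
   protein (terminal stop codons are stripped); residue gaps become
   codon gaps.
2. **Exon-wise slicing** assigns each codon column to the exon holding
   at least two of its reference bases (a tie is impossible for three
   bases); reference-gap columns follow their predecessor.  Counts over
   the whole CDS equal the sum over slices by construction.
3. **Frame checking** rejects slices with internal stop codons or gap
   runs that are not whole codons.
4. **NG86 counting**: per codon, each position contributes the fraction
   of its non-stop single-base changes that are synonymous to S (and
   3 − S to N); mutations to stop codons are excluded from the
   denominator.  Differences between two codons are averaged over all
   minimal mutational pathways (1, 2, or 6 orderings), pathways through
   stops excluded, so Nd + Sd equals the number of differing positions
   whenever a valid pathway exists.  Site counts are averaged over the
   two sequences; gapped/ambiguous columns and fully stop-blocked pairs
   are dropped pairwise.
5. **Jukes–Cantor correction** d = −(3/4)·ln(1 − (4/3)p) for
   p = Nd/N and Sd/S; p ≥ 3/4 is reported as saturated, and
   ω = dN/dS only when dS > 0.

A counting estimator was chosen over maximum likelihood deliberately:
at the divergence this pipeline targets (pairwise dS on the order of
0.1), counting and ML estimates agree closely, and counting is exactly
testable — the test suite checks every sense-codon pair against an
independent brute-force path enumerator.  The known limitation is
transition/transversion bias: NG86 site counting assumes unbiased
mutation, so strong transition bias deflates ω below 1 even for neutral
sequences.  The simulator's default bias (κ = 1.5, see below) is mild
enough that neutral simulations recover median ω ≈ 0.9.

## Statistics

* Pearson and Spearman correlations use the standard t-transform
  p-values (n − 2 df); Spearman uses mid-ranks for ties.
* **Partial Spearman** rank-transforms x, y, and every control,
  residualizes ranked x and ranked y on the ranked controls by least
  squares with intercept, and correlates the residuals; p uses
  n − 2 − k df.  This equals the recursive partial-correlation formula
  on the rank scale and extends cleanly to 4–5 simultaneous controls.
  Collinear control columns are dropped greedily and recorded.  When the
  controls explain a variable completely (residual variance numerically
  nil), the partial correlation is reported as 0 with p = 1.  Complete
  cases only; the n used is always reported.
* The **Wilcoxon rank-sum test** uses the tie-corrected normal
  approximation with continuity correction (the large-sample convention
  of R's `wilcox.test`); an exact enumeration of the rank-sum
  distribution (dynamic programming over doubled mid-ranks, valid under
  ties) is the default at n ≤ 10 per group.  Identical pooled values
  give p = 1 by convention.
* **Length subgroups**: within a position class, exons are stably
  sorted by length and split into five contiguous blocks with sizes as
  equal as possible, remainder to the lowest-index (shortest)
  subgroups.  Any deterministic remainder rule would do; this one is
  fixed for reproducibility.
* No multiple-testing correction is applied; raw p-values carry star
  annotations at 0.05/0.01/0.001.
* Exons of the same gene enter correlations as independent
  observations; gene ids are retained in the master table so users can
  subsample one exon per gene if they prefer.

## The synthetic-data generator

The generator emits a complete input bundle (GFF3, focal and ortholog
CDS FASTA, gap-free protein alignments, per-strand bisulfite calls,
covariates) plus ground truth.  Default parameter values are scaled to
the magnitudes of the real datasets this pipeline is shaped for, not
claims about any particular genome; all are config-exposed.

* **Gene models**: coding-exon count 2 + Poisson(mean − 2); exon coding
  lengths log-normal with class-specific means (283 bp background
  default; the methylome-tier scenario uses 650 bp, matching the longer
  exons that survive methylome QC), σ = 0.45, floor 60 bp.  Terminal
  UTRs attach to the first/last coding exon; a configurable fraction of
  genes get a stand-alone 5'UTR exon (default 5%), exercising the
  first-exon exclusion; a configurable fraction (default 15%) gain a
  second isoform skipping one frame-preserving internal exon (the ASEs);
  30% of genes sit on the minus strand.
* **Ancestral CDS**: first-order Markov chain over bases tuned to hit
  G+C = 0.44 and CpG rate 0.035/bp; in-frame stops repaired.
* **Methylation** is hierarchical: each exon draws a latent methylation
  level from a beta with class-specific mean (first 0.25 < last 0.45 <
  internal 0.60, concentration 1.5 — strongly bimodal, as gene-body
  methylation is in practice), then each CpG draws its frequency from a
  beta around the exon level (concentration 8).  True methylation state
  mirrors the calling rule (frequency ≥ 0.8).  The exon-level layer is
  essential: with purely CpG-level draws, exon-to-exon variation in
  methylation would be binomially small and could not carry the
  methylation–divergence coupling the analysis measures.
* **Divergence**: two lineages evolve independently from the ancestor
  (no indels, so alignments stay exact and rate estimation is isolated
  from alignment error).  Per-site substitution probability
  μ = 0.04/lineage (pairwise divergence ~0.08, the closely-related-
  species regime); transition weight κ = 1.5; the C→T channel at truly
  methylated CpG cytosines (and the paired G→A channel) is multiplied
  by λ ≥ 1 (default 3).  Methylation is assigned on the ancestor and
  held fixed.  Nonsynonymous proposals are accepted with the exon's
  acceptance probability (class defaults 0.9/0.6/0.3 for
  first/last/internal, matching the observed constraint ordering);
  synonymous proposals are always accepted; stop-creating proposals are
  rejected.  Acceptance can additionally be moved on the logit scale by
  standardized log-length or disorder, to build confounded or mediated
  configurations.
* **Bisulfite calls**: per-strand coverage ~ negative binomial
  (merged mean 20, dispersion 5), methylated reads ~ binomial(coverage,
  frequency).  CpGs destroyed in the focal lineage disappear from the
  call table; CpGs created by mutation draw a fresh frequency around
  their exon's level.
* **Covariates**: expression log-normal; repeat and disorder
  proportions beta; each can be coupled to standardized log exon
  length.

What the generator does *not* emulate: indels and alignment error,
CHG/CHH methylation, polymorphism within species, read-level bisulfite
chemistry, expression-level mutation biases, and any dependence of
methylation on sequence composition beyond CpG presence.  Passing
recovery tests therefore demonstrates that the pipeline measures what
the generative model encodes — not that real genomes satisfy that
model.  Quantitative correlation strengths in real data depend on
biology the generator does not constrain, so recovery tests are
ordinal/threshold-based rather than value-matched.

## Problem sizes and numerical conventions

Recovery analyses run at ~2,000 exons for the mutagenesis sweep
(λ ∈ {1, 3, 10}; |r| < 0.05 at λ = 1, r < −0.3 at λ = 10, monotone in
λ), ~500 exons per class for the selection ordering (all pairwise
rank-sum p < 0.001), ~2,000 exons for the mediation contrast
(attenuation > 50% mediated; plain/partial agreement within 0.02 null),
and 2,000 replicates at n = 100 with 4 controls for type-I calibration
(α = 0.05 within [0.03, 0.07]).  These sizes give comfortable margins
on every threshold while keeping any single analysis under a few
seconds.

Determinism: every random draw flows through one `numpy` Generator
seeded from the config; report bundles from identical seed/config are
byte-identical (the output directory is excluded from the config hash).
Floating-point output uses `%.6g` formatting.

## Known limitations

* NG86's κ-blindness biases ω slightly below 1 under transition-biased
  mutation (see above); comparisons *across* exon classes, the
  pipeline's object of study, are unaffected.
* The stand-alone-UTR exclusion inspects isoform structure only; it
  does not model promoter evidence.
* Partial Spearman's t-approximate p-value is asymptotic; at very small
  n with many controls it can be mildly anti-conservative (the
  calibration test bounds this at the sizes used).
* The master table treats exons as independent observations; gene-level
  clustering is left to the user via the retained gene ids.
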