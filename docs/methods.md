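# Methods

This note documents the models, algorithms, defaults and design
decisions behind `baitforge`, in the order of the pipeline.

## Spliced transcript-to-genome matching

Transcripts are placed on genome contigs by exact 11-mer seeding,
per-diagonal run merging, ungapped extension (stopping after 4
consecutive mismatches, with the mismatch tail trimmed), and
dynamic-programming chaining of collinear blocks.  Chains may overlap by
less than half a block (extension can overshoot an exon boundary on
chance matches); overlaps are resolved by assigning the zone to the
neighbouring block that matches it better, ties to the earlier block.
Multiple gene copies on one contig are recovered by iteratively peeling
off the best chain.  Reverse-strand matches are computed on the
reverse complement and reported in forward-contig coordinates with
strand `-`.

The contract is the output — exon blocks and an identity — not
bit-parity with any particular spliced aligner.  **Identity is
query-centric**: matched bases over aligned transcript bases, because
the per-dataset thresholds are framed per transcriptome.  Placements
covering less than half the transcript are discarded as seed noise.
Consequences worth knowing:

- splice boundaries can shift by a few bases when the intron start
  happens to match the next exon (any local aligner shares this
  ambiguity); block counts and identities are unaffected;
- the matcher assumes substitution-only divergence inside exons.  It is
  not indel-robust; the synthetic generator simulates no indels by
  default, and real data would be matched upstream by a dedicated
  spliced aligner.

Copy-number screening counts chained placements above the identity
threshold after merging placements whose spans overlap by more than 50%
of the shorter span.

## Selection thresholds (RunConfig defaults)

| parameter | default | meaning |
|---|---|---|
| per_dataset_identity | 0.92 / 0.90 / 0.95 | min placement identity per transcriptome dataset |
| cluster_identity | 0.90 | greedy clustering / dedup identity |
| max_gene_length | 2040 bp | strict upper bound on exonic length |
| max_introns | 10 | strict upper bound on intron count |
| bait_length / tiling_density | 80 bp / 2× | emitted kit; 120 bp used for design arithmetic |
| column_missing_max | 0.75 | strict masking threshold |
| low_representation_min | 0.70 | min fraction of samples with the gene |
| paralog_specimen_threshold | 3 | exclude when flagged in **more than** 3 |
| paralog_long_contig_fraction | 0.85 | "long contig" for paralog warnings |
| collapse_support_threshold | 30 | collapse branches with support **below** 30 |
| saturation_slope_threshold | 0.7 | flag alignments with slope below |

Both selection filters are strict inequalities (a gene of exactly
2,040 bp or exactly 10 introns is rejected).  Filters are applied per
dataset model; a gene survives if any dataset's model passes.  The
0.85 long-contig fraction mirrors the documented behaviour of standard
capture assemblers' paralog warnings; it is exposed in the config
because it is a convention, not a derived quantity.

The probe-count arithmetic `ceil(L·k/bait)` gives 34 probes for a
2,040 bp target only with 120-mers at 2×, while kits are typically
synthesized as 80 bp 2×-tiled oligos; both are supported, with 120/2
used for the design check and 80/2 as the emission default.  Tiling
places a terminal probe flush with the target end rather than
truncating it, so all probes have the uniform length synthesis
requires.

## Clustering and panel handling

Cross-dataset intersection uses CD-HIT-EST's documented greedy
strategy: sequences sorted longest-first, each compared against cluster
representatives only, no reclustering pass.  Pair identity is
`1 − editDistance/max(len)` from a global (NW) alignment (edlib).  A
cluster is kept when its members span ≥ 2 datasets.  Exact recovery of
a planted shared-gene set is guaranteed only when copies diverge from
their ancestor by less than `(1 − identity)/2` per copy; the test and
acceptance fixtures use 0.025 per copy (pairwise 0.05) against the 0.90
threshold.

Panel references: family rows win over outgroup fallbacks; among family
rows the longest ungapped row is taken, ties broken by lexicographically
smaller id; references are degapped.  Cross-panel duplicates (clusters
at ≥ 0.90) keep the highest-priority panel's locus
(angio353 > functional > custom).

## Recovery and triage

Recovered fraction = `min(1, longest contig / reference length)`; the
cap prevents supercontigs (exon + flanking splash-zone) from inflating
recovery, which is defined over exon-only references.  Per-sample
recovery-length percent is reference-length weighted.  The "70% of
species" rule counts all samples in the run, not unique species.

Triage bookkeeping applies the low-representation filter first, then
paralog triage on the remainder, so the three exclusion sets are
disjoint and `retained = assembled − low_rep − triaged` holds by
construction.  The monophyly test for same-sample copies treats the
gene tree as unrooted: copies are monophyletic iff some edge separates
exactly those tips (or their complement) from the rest.  Flagged
samples with fewer than two tips in the tree are skipped with a
warning.

## Distances, informativeness, saturation

- **Masking** deletes columns whose missing fraction (gaps plus any
  non-ACGT code) strictly exceeds 0.75; a column at exactly 0.75 is
  kept.  Masking happens before any taxon subsetting, so scope-level
  PIS counts are computed on the same masked columns as the full set.
- **PIS**: a column is parsimony-informative iff ≥ 2 distinct
  unambiguous states each occur in ≥ 2 taxa; gaps and ambiguity codes
  never count as states.
- **K80**: pairwise deletion; transitions are A↔G and C↔T, every other
  differing unambiguous pair a transversion;
  `d = −½ ln((1−2P−Q)√(1−2Q))`, undefined (reported, not imputed) when
  either log argument is non-positive.  The implementation agrees with
  `ape::dist.dna(model="K80")` to 12 digits on a frozen fixture, and
  the delta-method standard error is provided for the simulation
  tests.  Distance tables are reported in percent at one decimal.
- **Saturation**: through-origin least squares of p-distance on K80
  distance over all defined pairs (slope = Σpd/Σd²); flagged when the
  slope is below 0.7.  The threshold is dimensionless (the slope of an
  unsaturated alignment is 1 in the small-distance limit).  At least 3
  defined pairs are required; an all-zero-distance alignment yields an
  undefined slope and no flag.

## Gene concordance factors

For each internal branch of a bifurcating reference tree the four
around-branch clade groups (A,B | C,D) define a quartet.  A gene tree
is decisive iff it contains ≥ 1 taxon from each group; its induced
resolution is concordant if some gene-tree split separates A∪B from
C∪D (restricted to the gene tree's taxa), else alternative 1 (A∪C),
else alternative 2 (A∪D), else paraphyly/polytomy.  Percentages are
over decisive trees, so gCF+gDF1+gDF2+gDFP = 100 per branch; branches
with no decisive trees report missing values.  Gene trees are treated
as unrooted and their supports ignored.  Branch collapsing contracts
internal branches with support strictly below the threshold; the
threshold semantics are "collapse *low*-support branches" (collapsing
high-support branches would defeat the stated accuracy purpose).
Neighbor joining (fixture building only) delegates to scikit-bio and is
deterministic in the input taxon order.

## Synthetic data generator

All generators are pure functions of `(spec, seed)`
(`numpy.random.default_rng`); identical runs are byte-identical.

- **Reference sets**: genes with uniform exon counts (1–6 by default)
  and lengths (120–360 bp exons, 150–350 bp introns) planted
  sequentially in 12 kb contigs; transcriptomes are spliced copies
  mutated under exact K80 site probabilities at per-taxon divergences
  (defaults 0.04/0.05/0.025 — inside the 0.92/0.90/0.95 identity
  thresholds).  κ defaults to 2.
- **Assemblies**: 38 samples; each gene recovered with probability
  0.98 at a fraction drawn uniformly from 0.85–1.0 and mutated at 0.02;
  ~10% of genes carry a planted duplication (second contig ≥ 0.9×
  reference at divergence 0.08); read totals 10⁵ with a binomial
  on-target draw at the planted 73%.
- **Gene trees**: around one focal branch, the four group subtrees are
  rearranged as AB|CD, AC|BD, AD|BC or a four-way polytomy at planted
  proportions (default 0.6/0.2/0.2/0), with optional taxon dropout.
  Discordance is drawn categorically, not from a coalescent.

What the generator does **not** emulate: sequencing error and
read-level artifacts, indels (off by default; a simple geometric indel
mode exists for masking tests), rate heterogeneity across sites,
base-composition bias, and alignment error.  Passing tests therefore
demonstrate algorithmic correctness under the stated models, not
robustness to every property of real capture data.

Problem sizes in the default test and acceptance runs (12 genes, 4–5
contigs × 12 kb, 38 samples, ≤ 1,000 gene trees, 10 kb distance
fixtures) were chosen so the statistical checks have useful power
(3-SE binomial/delta-method bands) while the whole suite runs in
seconds.

## Known limitations

- The matcher is substitution-only and seed-based; genes whose true
  divergence drifts above the identity threshold are (correctly)
  dropped, and an unlucky mutation draw near the threshold can drop a
  marginal gene.
- Greedy clustering is representative-only; a chain of pairwise-similar
  sequences can split across clusters near the threshold, exactly as in
  CD-HIT.
- gCF requires a bifurcating reference tree; polytomous reference
  branches are skipped with a warning.
- Copy-number counting reports chained placements, not a gene-family
  reconstruction; tandem copies overlapping > 50% merge into one locus.
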