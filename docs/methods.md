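# Methods

This note documents the models, procedures and numerical choices behind
`syngraft`, in the spirit of a package methods appendix: what each stage
assumes, which knobs matter, and what the synthetic validation does and
does not demonstrate.

## Reference-guided anchoring

The anchoring model assumes near-complete conservation of gene order
(synteny) between the target species and a chromosome-scale reference
relative, so that each scaffold's CDS content identifies one reference
chromosome and one position on it.

**Hit ingestion.** External hit tables are standard 12-column tabular
alignments. The E-value filter is *inclusive* (rows at exactly the
1.0E-3 cutoff are retained), matching common aligner semantics. Each
CDS is represented on the reference by the midpoint of its annotated
span — an orientation-neutral choice. Multi-hit CDSs are reduced to a
single best placement (minimum E-value, then maximum bitscore, then
lexicographic scaffold id, then smallest scaffold coordinate); the
reduction is idempotent and logged, since an all-hits variant would
up-weight repetitive CDSs in the majority vote.

**Majority-chromosome filter.** The modal reference chromosome of the
scaffold's CDSs wins; a strict tie leaves the scaffold unplaced rather
than arbitrarily assigned. Only scaffolds with more than 10 CDSs enter
(default `min_cds_per_scaffold = 11`): below that, a majority of a
handful of markers carries little evidence.

**Distant-region filter.** "Very distant" is operationalised as a
robust outlier rule: a CDS is dropped when its reference position lies
more than `max(distant_mad_multiplier × MAD, distant_min_bp)` from the
scaffold's median reference position (defaults 5 × MAD with a 2 Mb
floor; the raw, unscaled MAD is used). The absolute floor prevents the
rule from degenerating when a scaffold's CDSs are tightly clustered
(MAD → 0). With fewer than three CDSs the statistic is meaningless and
the filter is skipped with a warning. Both knobs are exposed because no
canonical threshold exists for this filter.

**Anchor point.** Hits are ordered by scaffold coordinate and the
anchor is the arithmetic mean reference position of the
`anchor_window = 5` consecutive hits starting at index
`floor((n − w)/2)`. Centrality is taken in *scaffold* order, so the
anchor represents the scaffold's physical middle rather than the middle
of its reference footprint; for a collinear scaffold the two coincide.

**Orientation.** The Kendall rank correlation between scaffold
coordinate order and reference position order is a purely ordinal
statement of "same gene order": +1 → forward, −1 → reverse. The sign
decides the orientation; τ = 0 (or undefined, e.g. all positions tied)
yields '+' with a degenerate flag. Kendall is preferred over Spearman
because the quantity of interest is pairwise order concordance, not
position magnitudes. Values are rounded at 1e−12 so perfectly ordered
scaffolds report exactly ±1.

## Pseudomolecule layout

Within a chromosome, scaffolds are sorted by anchor position (ties:
longer scaffold first, then lexicographic id — longer scaffolds carry
more anchoring evidence), minus-oriented scaffolds are
reverse-complemented, and neighbours are joined with a 100-N spacer
written as an AGP v2.1 gap row (`scaffold`, linkage `yes`, evidence
`align_genus`), the convention for joins inferred from cross-species
alignment with unknown true gap size. Unplaced scaffolds are emitted as
a separate multi-FASTA, never concatenated into an artificial "chrUn"
molecule. Internally all coordinates are 0-based half-open; AGP and
GFF3 are 1-based inclusive with a single conversion layer that is
exercised by byte-identical round-trip tests (AGP + component FASTA →
object FASTA).

The assembly report totals per-molecule sizes exactly (integer
arithmetic) and reports the overall gap percentage as the size-weighted
mean of per-molecule values. The anchored fraction is only computed
against a caller-supplied total assembly size, since the proper
denominator (with or without spacers, pre- or post-filtering) varies
between studies.

The synteny report flags translocation / assembly-error candidate
scaffolds as those carrying a substantial minority of CDSs from a
second chromosome (≥ 2 CDSs and ≥ 20 % of the scaffold's CDSs) — the
truth-free signature of a breakpoint available from hit tables alone.

## TE curation

**Similarity search.** Genome-scale DNA similarity uses an
exact-k-mer-anchored, ungapped seed-and-extend matcher (`k = 13`,
probes capped at ~64 per query strand). Anchors sharing a diagonal are
evaluated as one ungapped candidate; the reported interval is the
maximal-scoring segment on the diagonal (match +1, mismatch penalised
at the odds implied by the identity threshold, i.e. a Kadane-style
local alignment), so a query that matches only partially — the
deletion-derivative case — is still recovered without dilution by
flanking noise. The ungapped model is a deliberate restriction: it
keeps the matcher exactly verifiable against brute-force oracles and is
adequate for the substitution-only divergence regime the package
simulates; indel-rich real data should be ingested as external hit
tables instead.

**Homology harvesting.** Protein-seed hits are extended by a flank of
5000–9000 bp (values outside that range are a configuration error) so
that complete elements, including their termini, fall inside the
candidate region; overlapping candidates merge. Non-autonomous
deletion derivatives are genomic intervals DNA-similar to family
members (matches separated by ≤ 30 bp merge, since an internal deletion
leaves two adjacent matched blocks) that do not overlap any
protein-coding hit — which also prevents double-reporting of the
autonomous copies themselves.

**Consensus.** Families are summarised by a per-column majority over a
star alignment onto the longest member (pairwise global alignments,
insertions relative to the backbone dropped, majority-gap columns
removed, base ties written as IUPAC ambiguity codes). On copies with
≤ 5 % substitutions the consensus recovers the ancestral element at
≥ 95 % identity (property-tested).

**De-novo TIR discovery.** Candidate elements are spans `[i, j + k)`
whose termini are exact reverse-complement k-mers (`k = min_tir_bp`,
default 10), whose inverted terminal repeat extends to ≥ `min_tir_bp`
at ≥ 80 % identity (extension stops after three consecutive
mismatches), and which are flanked by an exact direct repeat with
length in 2–11 bp (TSD). Element size is bounded (100 bp – 20 kb) and
homopolymer "TSDs" are ignored. Pair enumeration is fully vectorised
(composite code·position keys + binary search), so a 5-Mb genome is
scanned in seconds.

Because spans nudged a few bases off a true insertion boundary pick up
guaranteed shorter direct repeats (sub-repeats of the real TSD) and
occasionally a longer coincidental one at a single locus, candidates
are ranked by **TSD consistency across loci**: the number of loci
showing the modal TSD length, then the modal TSD length, then span
length. A true boundary shows the same TSD length at every copy and
wins this ranking; on the planted benchmark this recovers member
intervals base-exactly. Candidates are deduplicated per genomic locus,
pre-filtered by a genome-wide exact 16-mer count (median of 5 probes;
single-copy candidates never reach the expensive search), then verified
by a full genome search; a family requires ≥ `min_copies = 3` members
at ≥ 80 % identity over ≥ 80 % of the element. The copy-number
threshold, TIR/TSD bounds and identity levels are configurable, as no
single convention exists across TE annotation pipelines. Families are
named by superfamily three-letter code plus ordinal (e.g. `DTX_1` for
unclassified TIR elements), following the common field convention.

**Accounting.** Repeat-space merging is exact interval arithmetic via
an endpoint sweep: per-source base pairs are unions (duplicate
intervals within a source never double-count), the combined space is
the union over sources, and the multi-source overlap is the bases at
coverage depth ≥ 2. All three are verified against a per-base bitmask
oracle over randomized trials. Percentages are relative to a
caller-supplied assembly size.

**Density / centromere candidates.** Per family and chromosome,
coverage is binned into 1-Mb windows. A family marks a candidate
centromeric region when ≥ 90 % of its covered bases fall inside at most
two runs of ≤ 3 consecutive enriched windows (a window is enriched when
it holds ≥ 5 % of the family's coverage on that chromosome); a
chromosome showing two such disjoint runs is flagged separately, since
a doubled centromere-like signal can indicate scaffold orientation
problems or redundant haplotype scaffolds rather than biology.

## Annotation metrics

Gene models are parsed from GFF3 (gene → mRNA → exon) via an in-memory
`gffutils` database; orphan or exon-less mRNAs are a hard error listing
the offending ids. Gene space is the union of gene spans (overlapping
genes counted once). Mean exon size averages over exons, mean intron
size over introns (gaps between consecutive exons within an mRNA), and
exons-per-gene averages exon counts over mRNAs; empty annotations
report absent means rather than zeros.

AED is computed at nucleotide granularity against the single evidence
item with the largest footprint overlap: sensitivity = overlap /
evidence bases, specificity = overlap / model bases,
AED = 1 − (sn + sp)/2, so identical footprints give 0 and no overlap
gives 1. This is a simplification of the full multi-evidence,
junction-aware metric used by large annotation pipelines, chosen
because the package consumes AED only through thresholds (< 0.2, < 0.5,
= 1) and cumulative curves, which the nucleotide-level form preserves.
The cumulative curve reports, for each threshold t, the fraction of
isoforms with AED ≤ t; it is non-decreasing and reaches exactly 1 at
t = 1.

## Synthetic data

The simulator is the package's ground-truth instrument, not a model of
any particular sequencing project. A chromosome is a list of typed
blocks (background, gene, TE, N-gap); every operator (translocation,
inversion, TE insertion, fragmentation) edits blocks, which makes the
conservation invariants — the scaffold partition reconstructs the
target byte-for-byte, gene content is conserved — true by construction.

Choices and their rationale:

- **Background** is uniform i.i.d. A/C/G/T: no repeat structure other
  than planted TEs, giving TE detection a clean null (a 1.5-Mb
  background genome yields zero families at default thresholds).
- **Genes** (default 100 per chromosome, ~400 bp ± 20 %) are
  non-overlapping and ordered, with intergenic spacers drawn
  multinomially so each chromosome hits its configured length exactly.
- **Translocations** move `round(fraction × n_genes)` genes to a
  uniformly chosen *different* chromosome (the count is exact, so a
  12 % setting plants exactly 12 % discordant genes); **inversions**
  reverse runs of 5 consecutive genes in order and strand.
- **Fragmentation** cuts only intergenic background. A configurable
  fraction of scaffolds is constructed gene-poor (≤ 10 genes, the
  anchoring exclusion class); remaining genes are spread over the other
  scaffolds with log-normal weights (σ = 1), mimicking the
  many-short/few-long scaffold size profile of real assemblies and
  guaranteeing some scaffolds rich enough to anchor. With the default
  gene/scaffold ratio other scaffolds can fall below 11 genes as well,
  so the small-scaffold fraction is a lower bound. One N-run (default
  100 bp) is inserted per scaffold; each scaffold is independently
  reverse-complemented with probability 0.5 to exercise the orientation
  stage symmetrically.
- **TE planting** inserts elements only into background, with exact
  TSDs (insertion-site bases duplicated on both sides) and, for TIR
  elements, exact reverse-complement termini; LTR-class elements carry
  direct terminal repeats of `min(200 bp, length/5)`. Clustered
  families are confined to one ≤ 2-Mb window to emulate centromeric
  distributions. Placement retries up to 200 draws and errors out if
  no background block can host a copy.
- **Determinism**: every stage derives its generator from
  `(seed, stage-tag)`, so a fixed seed yields byte-identical FASTA,
  GFF3 and truth-table outputs across runs, and stages remain
  individually reproducible.

**What passing on synthetic data shows — and does not.** Perfect
recovery on these genomes validates the *logic* of the pipeline
(filters, ordering, orientation, boundary calling, accounting) under
the stated assumptions: substitution-only divergence, exact CDS copies,
no segmental duplication, uniform background. It does not demonstrate
robustness to diverged orthologs, tandem arrays, nested or fragmented
TEs, or assembly base errors — real inputs for those regimes should
come through the external hit-table route with an appropriate aligner.

## Problem sizes used in the checks

The standard validation conditions are 11 chromosomes × 1 Mb with 100
genes and 20 scaffolds per chromosome for anchoring (with and without
12 % translocation), a 5-Mb two-chromosome genome with three planted
TIR families (5/4/3 copies) plus a single-copy decoy for de-novo
discovery, 100 randomized trials against the bitmask oracle for the
accounting, and the published 11-molecule size table and repeat-space
percentages for the report operations. These sizes were chosen so the
whole validation runs in well under a minute while every stage still
operates far from trivial regimes (hundreds of scaffolds, thousands of
CDS placements, megabase searches).

## Known limitations

- The built-in CDS matcher reports exact occurrences only; diverged
  CDSs require an external aligner's hit table.
- The TE similarity model is ungapped; indel-rich families will be
  fragmented into multiple matches (merged only across small gaps).
- Consensus building drops insertions relative to the backbone member,
  so consensus length never exceeds the longest member.
- AED ignores splice-junction agreement and multi-evidence weighting.
- Anchoring cannot split chimeric scaffolds; a scaffold spanning a true
  breakpoint is assigned wholesale to its majority chromosome and
  surfaced only as a candidate in the synteny report.
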