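# Methods

This note documents the models, conventions, default parameters, and
numerical choices behind `mitopcg`, and what the synthetic fixtures do
and do not demonstrate.

## Reference library

The library models 30 *Rhodiola* mitochondrial protein-coding genes.
Seven are multi-exon — *nad1*, *nad2*, *nad5*, *nad7* with five exons,
*nad4* with four, *cox2* with three, *ccmFc* with two — and the *nad5*
model carries a 22 bp micro-exon.  Codon genotypes are recorded per
gene: ACG starts of *nad1*/*nad4L* and the CAA stop of *atp6* carry
C-to-U editing sites (`start_gain`/`stop_gain`); *cob* declares a
non-canonical ATT start; *nad6* is flagged `missing_stop` and ships two
reference forms of different length for boundary resolution.  *rps4*,
*rps14* and *sdh4* are registered as pseudogene loci, disjoint from the
gene set.

The packaged exon sequences are **synthetic stand-ins**: in-frame
random sense-codon sequence generated once from a fixed seed, honouring
the curated exon counts, lengths, and codon genotypes.  They carry no
information from any real accession; real deployments substitute a
curated FASTA + sidecar via `load_library`.  Persistence uses a
canonical YAML sidecar (sorted keys) beside an exon FASTA with
`gene`/`gene.exonN` headers, so save→load→save is byte-stable and a
curator can edit it by hand.  Unknown sidecar keys, missing exon
ordinals, duplicate records, and count mismatches are hard errors.

Micro-exon flank augmentation appends 150 bp of flanking context (the
default, configurable) to each side of any exon shorter than 30 bp.
The 30 bp cutoff captures the 22 bp case with margin; the flanks are
recorded on the model and stripped exactly whenever a spliced CDS is
assembled or a placement is reported.

## Homology mapping

The internal aligner uses exact k-mer seeding (default k = 15) on both
strands followed by ungapped extension: every seeded diagonal is
reduced to its best-scoring segment (match +1, mismatch −3, Kadane's
rule), which cleanly clips chimeric overlaps such as reads spanning an
exon/intron junction.  N never seeds and always counts as a mismatch.
Hits below 90 % identity (default) or shorter than the seed are
discarded; the hit score is `aln_length × identity / 100`.  One hit per
diagonal is reported, so tandem repeats on the same diagonal collapse
to the strongest copy — adequate for reference-vs-genome comparisons at
≥ 90 % identity, and not intended as a general-purpose local aligner
(no gapped alignment, no e-value statistics).  Precomputed hits in the
12-column tabular dialect are accepted interchangeably.

Exon placement selects, per exon, the best passing hit by a total
order: greatest aligned length, then identity, then score, then
smallest start, then subject id — making the result invariant under
permutation of the hit list.  Additional passing hits that do not
overlap a retained placement (≥ 1 shared bp on the same sequence,
strand-blind) are kept as duplicate copies; duplicates are reported but
excluded from classification.  Acceptance thresholds (identity ≥ 90 %,
exon coverage ≥ 80 %) are configuration, not ground truth.

## Transcript splitting and classification

Grouping breaks at every strand switch *and* every chromosome switch
(exons of trans-spliced genes are observed on different chromosomes, so
a chromosome change necessarily separates transcripts).  The intron gap
between ordinal-adjacent placements is measured orientation-blind on
the forward genome axis as `max(starts) − min(ends) − 1`; overlapping
placements count as gap 0.  The default splitting threshold is
5000 bp with per-gene overrides — the threshold is configuration to be
recalibrated per lineage, not a biological constant.  Sub-transcripts
take `k-1, k-2, …` labels in ordinal order.  The exon-order check is
off by default; when enabled, a reversal of canonical order flags the
gene as a pseudogene.  For trans-spliced genes whose groups interleave
on the genome axis, output locations follow exon-ordinal (translation)
order, which is what downstream translation consumes; the genomic
interleaving is preserved in the per-segment coordinates.

## Codon rules

Translation uses the standard genetic code (table 1), conventional for
land-plant mitochondria; every deviation is expressed through
qualifiers rather than a custom table.  Editing sites never modify the
CDS nucleotides — annotation describes the pre-edited genome — and emit
`transl_except` qualifiers in the range form `pos:P..P+2` anchored at
genomic coordinates; on the minus strand the ascending range
`min..max` is emitted without a `complement()` wrapper.  Edited stops
use `aa:TERM` per the GenBank convention for stop gains and truncate
the protein at that codon.  Non-canonical starts still render position
1 as Met.  A declared codon that disagrees with the observed CDS
produces a warning qualifier and flag instead of silent acceptance.

Stop-less boundary resolution aligns every reference form (base CDS
plus variant forms) to the candidate region and takes the 3′ end of the
highest-scoring form, with two deterministic tie-breaks: longest
identifiable ORF (any frame, ATG to stop or sequence end), then label.
The minimum form score (50) merely rejects junk regions.

## Flat-file output

GenBank serialization goes through Biopython.  Minus-strand multi-exon
CDSs therefore serialize as `join(complement(a..b),complement(c..d))`
rather than the equivalent `complement(join(...))`; both parse to the
same location and the write→read round trip of every CDS is exact and
tested.  Trans-spliced genes on one sequence get a single CDS with
`/trans_splicing`; genes spanning several sequences cannot be expressed
as one flat-file location, so one CDS per sequence is emitted with
`/note=trans-splicing partner (part i of n)` markers from which the
reader reassembles the spliced CDS.  Pseudogenes get a `gene` feature
with `/pseudo` and no CDS.  GFF3 phases accumulate over CDS segments in
translation order.

## Short-read recovery

Read extraction uses the union rule — a pair is retained for a gene
when either mate matches — to avoid orphan mates; matching defaults to
exact 21-mers seeding ≥ 50 bp at ≥ 95 % identity.  De novo assembly is
a pluggable external step; tests and the acceptance run substitute
truth-derived contigs that tile the genome, optionally broken inside a
named exon, so the reconstruction logic is verified independently of
any assembler binary.  Reconstruction takes, per exon, the hit with the
greatest exon-aligned length (ties: identity, then contig name).  An
exon covered only partially by hits on two or more contigs is logged
as `EXON_SPLIT_ACROSS_CONTIGS` and never auto-merged: the best partial
is used and the remainder recorded as a gap, mirroring the policy that
ambiguous reconstructions belong in an error log for manual curation.
Missing exons are logged and leave gaps in reference coordinates.
Output trees are gene-wise (for SNP scans) and sample-wise (for tree
building), lexicographically ordered and byte-idempotent.

## Supermatrix

Per-gene alignments are produced externally (MUSCLE/MAFFT class tools);
the builder intersects gene sets across samples and outgroup,
optionally excludes genes (e.g. the four highly conserved ones —
*atp9*, *rpl10*, *nad3*, *nad4L* — whose removal sharpens resolution),
concatenates in a stated order, and records partitions that must tile
`1..L` (asserted after every construction).  Gap filling is
deliberately conservative: a missing region is filled from a
conspecific donor only when every non-missing cohort row (excluding the
recipient) is identical over those columns; anything else is a logged
refusal.  Species identity defaults to the taxon-name prefix before the
first underscore.  Taxa missing more than 20 % of columns after fills
are recommended for exclusion — the fraction is configurable since the
underlying policy is qualitative.  Missing data are `-`, ambiguity `N`.
The handoff writes relaxed PHYLIP, FASTA and a `DNA, gene = start-end`
partition file and renders an ML command with the model string passed
through verbatim (default `GTR+GAMMA+I`, 1000 bootstrap replicates);
tree inference and model selection are out of scope.

## Synthetic fixtures

The genome generator plants library genes on random ~45 % GC background
with introns of 200–800 bp (safely below the splitting threshold)
unless an over-threshold intron is requested, realising cis
arrangements, the `+,−,−,−,+` strand-flip pattern, two-chromosome
trans-splicing, duplicated/deleted exons, frameshifts, and codon
genotype overrides, all recorded in a truth manifest.  Reads are
error-free 2×150 bp pairs at 50× from 350 bp fragments by default
(an optional uniform substitution rate exists for robustness
experiments); names encode the true origin interval so recall can be
scored against the manifest.  The default test/acceptance genome is a
single ~60 kb mitogenome carrying all 30 genes — deliberately toy-scale
so the full suite runs in seconds.

Passing on these fixtures demonstrates the *logic*: transcript
splitting, classification, qualifier generation, reconstruction and
error-logging behave exactly as specified on sequence whose ground
truth is known.  It does not demonstrate robustness to sequencing
error, heteroplasmy, nuclear-mitochondrial insertions, repeat-induced
misassembly, or diverged references — on real data those stresses fall
on the external assembler/aligner and on threshold calibration, which
must be revisited per lineage.  Quantities reported from real samples
(transcriptome-derived editing-site counts, population SNP tallies,
annotation concordance against other tools) require external sequencing
data and are intentionally outside the test surface.
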