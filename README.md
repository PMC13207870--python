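# mitopcg

Reference-guided annotation and short-read recovery of plant
**mito**chondrial **p**rotein-**c**oding **g**enes, with supermatrix
construction for downstream maximum-likelihood phylogenetics.

## The problem

Plant mitochondrial genomes are large (200 kb–3 Mb in angiosperms),
multi-chromosomal, and structurally dynamic.  Their protein-coding
genes break most assumptions of generic annotators:

* **trans-splicing** — the exons of one mRNA (classically *nad1*,
  *nad2*, *nad5*) may sit on opposite strands or on different
  chromosomes, kilobases apart;
* **C-to-U RNA editing** — the genome may encode ACG where the
  transcript has a canonical AUG start (*nad1*, *nad4L*), or CAA where
  the transcript gains a UAA stop (*atp6*);
* **non-canonical codons** — genuine ATT (*cob*) or GTG starts and GGA
  stops, plus stop-less genes (*nad6*) whose 3′ boundary must be chosen
  by reference alignment;
* **pseudogenes** — loci such as *rps4*, *rps14* and *sdh4* that
  resemble genes but lack transcript support, and genes degraded by
  exon loss or internal stop codons (*rpl16*).

`mitopcg` implements, for the genus *Rhodiola* (Crassulaceae), a
curated 30-gene reference library and the algorithms that exploit it:
an exon-based annotator that resolves trans-splicing, a codon-rule
layer producing GenBank `transl_except`/`note` qualifiers, a
reference-guided pipeline that recovers complete CDSs from Illumina
paired-end data via contigs, and a partitioned supermatrix builder.

## The core algorithm

For a gene with reference exons *e₁ … eₙ*, homology search yields one
placement per exon (interval, strand, chromosome).  Transcripts are
derived in two passes:

1. **strand/chromosome pass** — maximal runs of consecutive ordinals
   sharing (strand, chromosome) become transcripts `1, 2, …`.  The
   arrangement `e₁(+), e₂(−), e₃(−), e₄(−), e₅(+)` yields transcripts
   {e₁}, {e₂–e₄}, {e₅}.
2. **intron-gap pass** — within a transcript, adjacent exons separated
   by more than the gene's intron-length threshold *T* (default
   5000 bp, per-gene configurable) are split apart into `k-1, k-2, …`;
   if gap(e₃,e₄) > *T*, transcript 2 becomes `2-1` = {e₂,e₃} and
   `2-2` = {e₄}.

A gene with ≥ 2 final transcripts is **trans-spliced**; a gene whose
placed exon count differs from the reference is a **pseudogene**
(`EXON_COUNT_MISMATCH`), with an optional exon-order check
(`EXON_ORDER_VIOLATION`).  Codon rules then annotate the *pre-edited*
genomic CDS: an edited start emits
`/transl_except=(pos:P..P+2,aa:Met)` and translates as M; an edited
stop emits `aa:TERM`; non-canonical codons emit explanatory `/note`
qualifiers; stop-less genes take the 3′ boundary of the
highest-scoring reference form, ties broken by longest ORF.

Short-read recovery inverts the process: read pairs are extracted per
gene by the union rule (a pair is kept when *either* mate matches),
assembled externally into contigs, and each CDS is rebuilt from the
best per-exon contig alignments — micro-exons (the 22 bp *nad5* exon)
via search sequences augmented with 150 bp conserved flanks.  Anything
unresolvable (an exon split across contigs, a missing exon, tied hits)
goes to a structured error log instead of being silently merged.

## Worked example

```sh
mitopcg db build --out db
cat > layout.yaml <<EOF
nad1: {mode: trans_strand_flip}
cox2: {}
nad4: {delete_exon: 2}
EOF
mitopcg simulate --db db --layout layout.yaml --seed 7 --out sim
mitopcg annotate --db db --genome sim/genome.fasta --out-genbank annotated.gb
```

The simulator prints `genome: 1 sequence(s), 8952 bp; 11 planted
exon(s)` and the annotator reports (abridged):

```json
"nad1": {"groups": [{"label": "1", "exons": [1], "strand": "+"},
                    {"label": "2", "exons": [2, 3, 4], "strand": "-"},
                    {"label": "3", "exons": [5], "strand": "+"}],
         "trans_spliced": true, "pseudogene": false},
"cox2": {"groups": [{"label": "1", "exons": [1, 2, 3], "strand": "+"}],
         "trans_spliced": false, "pseudogene": false},
"nad4": {"pseudogene": true, "reasons": ["EXON_COUNT_MISMATCH"],
         "placed_exons": 3}
```

*nad1*, planted with its interior exons strand-flipped, is recognised
as trans-spliced with the expected three transcripts; cis *cox2* is a
single transcript; *nad4*, planted with exon 2 deleted, is flagged as a
pseudogene because only 3 of its 4 reference exons were found.
`annotated.gb` contains the corresponding `join(...)` /
`complement(...)` CDS locations, `/trans_splicing`, `/pseudo`,
`/transl_except` and `/note` qualifiers.

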