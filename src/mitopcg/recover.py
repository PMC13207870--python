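"""Reference-guided recovery of protein-coding genes from short reads
and contigs.

The recovery pipeline works without a genome assembly: paired reads are
screened against the reference gene library (a pair is kept for a gene
when *either* mate matches — the union rule, which avoids orphan
mates), the extracted pairs are assembled externally into contigs, and
the contigs are then mined for each gene's CDS.  Single-exon genes take
the contig region of the longest alignment; multi-exon genes are
reconstructed exon by exon in ordinal order.  Situations the pipeline
cannot resolve automatically — an exon fragmented across contigs, a
missing exon, equally good hits on different contigs — are written to a
structured error log for manual curation rather than silently merged.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .homology_map import (
    AlignmentHit,
    reverse_complement,
    seeded_align,
)
from .reference_db import GeneModel, ReferenceLibrary

__all__ = [
    "ReadPairSet",
    "RecoveredCDS",
    "ErrorLogEntry",
    "EXON_SPLIT_ACROSS_CONTIGS",
    "MISSING_EXON",
    "AMBIGUOUS_HIT",
    "extract_read_pairs",
    "reconstruct_single_exon",
    "reconstruct_multi_exon",
    "recover_genes",
    "organize_outputs",
    "count_variable_sites",
    "write_error_log",
]

logger = logging.getLogger(__name__)

EXON_SPLIT_ACROSS_CONTIGS = "EXON_SPLIT_ACROSS_CONTIGS"
MISSING_EXON = "MISSING_EXON"
AMBIGUOUS_HIT = "AMBIGUOUS_HIT"
_REASONS = {EXON_SPLIT_ACROSS_CONTIGS, MISSING_EXON, AMBIGUOUS_HIT}

# Read-matching defaults: exact 21-mers seeding >= 50 bp of >= 95 %
# identity — strict enough to reject random sequence, lenient enough to
# keep reads spanning an exon boundary by their exonic half.
READ_MATCH_K = 21
READ_MATCH_MIN_IDENTITY = 95.0
READ_MATCH_MIN_LEN = 50


@dataclass
class ReadPairSet:
    """Paired reads assigned to one gene; mates kept one-to-one by name."""

    gene: str
    pairs: list[tuple[SeqRecord, SeqRecord]] = field(default_factory=list)

    @property
    def read_names(self) -> set[str]:
        return {r1.id for r1, _ in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class RecoveredCDS:
    """A CDS rebuilt from contigs with gap and contig provenance.

    ``gaps`` are 1-based inclusive intervals of the reference CDS that
    no contig covered; ``complete`` iff there are none.
    """

    gene: str
    sequence: str
    complete: bool
    gaps: list[tuple[int, int]] = field(default_factory=list)
    source_contigs: list[str] = field(default_factory=list)
    exon_provenance: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.complete != (not self.gaps):
            raise ValueError("complete flag must mirror empty gap list")


@dataclass(frozen=True)
class ErrorLogEntry:
    gene: str
    exon_ordinal: int
    reason: str
    detail: str

    def __post_init__(self) -> None:
        if self.reason not in _REASONS:
            raise ValueError(f"unknown reason code {self.reason!r}")


# ---------------------------------------------------------------------------
# Read-pair extraction (union rule)
# ---------------------------------------------------------------------------


def _gene_search_sequences(library: ReferenceLibrary) -> dict[str, list[str]]:
    return {
        name: [ex.sequence for ex in library[name].exons]
        for name in library.gene_names()
    }


def _default_matcher(library: ReferenceLibrary) -> Callable[[str], set[str]]:
    """Build a k-mer prescreen + alignment verifier over all gene models."""
    k = READ_MATCH_K
    kmer_to_genes: dict[str, set[str]] = {}
    searches = _gene_search_sequences(library)
    for gene, seqs in searches.items():
        for seq in seqs:
            for strand_seq in (seq, reverse_complement(seq)):
                for i in range(len(strand_seq) - k + 1):
                    kmer = strand_seq[i : i + k]
                    if "N" in kmer:
                        continue
                    kmer_to_genes.setdefault(kmer, set()).add(gene)

    def match(read_seq: str) -> set[str]:
        read_seq = read_seq.upper()
        candidates: set[str] = set()
        for i in range(len(read_seq) - k + 1):
            hit_genes = kmer_to_genes.get(read_seq[i : i + k])
            if hit_genes:
                candidates |= hit_genes
        confirmed: set[str] = set()
        for gene in candidates:
            for seq in searches[gene]:
                hits = seeded_align(
                    read_seq,
                    seq,
                    k=k,
                    min_identity=READ_MATCH_MIN_IDENTITY,
                    min_length=READ_MATCH_MIN_LEN,
                )
                if hits:
                    confirmed.add(gene)
                    break
        return confirmed

    return match


def _read_fastq(path: str | Path) -> list[SeqRecord]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return list(SeqIO.parse(fh, "fastq"))


def extract_read_pairs(
    reads: Sequence[tuple[SeqRecord, SeqRecord]] | tuple[str | Path, str | Path],
    library: ReferenceLibrary,
    matcher: Callable[[str], set[str]] | None = None,
) -> dict[str, ReadPairSet]:
    """Assign read pairs to genes by homology, with the union rule.

    ``reads`` is either a sequence of (mate1, mate2) records or a pair
    of FASTQ paths (optionally gzipped) with mates matched by name.  A
    pair is kept for a gene when either mate matches that gene's
    reference; both mates are always emitted together, and one pair may
    serve several genes.  Orphan mates are logged and dropped.  The
    result is independent of input read order (pairs are sorted by
    name).
    """
    if matcher is None:
        matcher = _default_matcher(library)
    if (
        isinstance(reads, tuple)
        and len(reads) == 2
        and isinstance(reads[0], (str, Path))
    ):
        r1 = {rec.id: rec for rec in _read_fastq(reads[0])}
        r2 = {rec.id: rec for rec in _read_fastq(reads[1])}
        orphans = set(r1) ^ set(r2)
        for name in sorted(orphans):
            logger.warning("orphan mate %s dropped", name)
        pairs = [(r1[name], r2[name]) for name in sorted(set(r1) & set(r2))]
    else:
        pairs = sorted(reads, key=lambda pr: pr[0].id)
    out: dict[str, ReadPairSet] = {}
    for rec1, rec2 in pairs:
        genes = matcher(str(rec1.seq)) | matcher(str(rec2.seq))
        for gene in genes:
            out.setdefault(gene, ReadPairSet(gene)).pairs.append((rec1, rec2))
    return out


def write_read_pairs(
    sets: Mapping[str, ReadPairSet], outdir: str | Path
) -> dict[str, tuple[Path, Path]]:
    """One FASTQ pair per gene, ready for an external assembler."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, tuple[Path, Path]] = {}
    for gene in sorted(sets):
        p1 = outdir / f"{gene}_1.fastq"
        p2 = outdir / f"{gene}_2.fastq"
        with open(p1, "w") as fh1, open(p2, "w") as fh2:
            for rec1, rec2 in sets[gene].pairs:
                SeqIO.write([rec1], fh1, "fastq")
                SeqIO.write([rec2], fh2, "fastq")
        written[gene] = (p1, p2)
    return written


# ---------------------------------------------------------------------------
# Contig-based CDS reconstruction
# ---------------------------------------------------------------------------


def _oriented_region(contig_seq: str, hit: AlignmentHit) -> str:
    lo, hi = hit.subject_lo, hit.subject_hi
    region = contig_seq[lo - 1 : hi].upper()
    if hit.strand == "-":
        region = reverse_complement(region)
    return region


def _hit_sort_key(hit: AlignmentHit):
    return (-hit.aln_length, -hit.pct_identity, hit.subject_id, hit.subject_lo)


def reconstruct_single_exon(
    model: GeneModel,
    hits: Sequence[AlignmentHit],
    contigs: Mapping[str, str],
) -> tuple[RecoveredCDS | None, list[ErrorLogEntry]]:
    """Rebuild a single-exon CDS from the optimal contig alignment.

    The best hit is chosen by alignment length, then identity, then
    contig name; its contig region is strand-resolved and trimmed to the
    reference-aligned span.  Reference positions no hit covered are
    recorded as gaps.
    """
    gene = model.name
    if not hits:
        return None, [ErrorLogEntry(gene, 1, MISSING_EXON, "no contig hit")]
    errors: list[ErrorLogEntry] = []
    ordered = sorted(hits, key=_hit_sort_key)
    best = ordered[0]
    if len(ordered) > 1:
        runner = ordered[1]
        if (
            runner.subject_id != best.subject_id
            and runner.aln_length == best.aln_length
            and runner.pct_identity == best.pct_identity
        ):
            errors.append(
                ErrorLogEntry(
                    gene, 1, AMBIGUOUS_HIT,
                    f"tied hits on {best.subject_id} and {runner.subject_id}",
                )
            )
    ref_len = len(model.spliced_cds())
    sequence = _oriented_region(contigs[best.subject_id], best)
    gaps: list[tuple[int, int]] = []
    if best.q_start > 1:
        gaps.append((1, best.q_start - 1))
    if best.q_end < ref_len:
        gaps.append((best.q_end + 1, ref_len))
    return (
        RecoveredCDS(
            gene=gene,
            sequence=sequence,
            complete=not gaps,
            gaps=gaps,
            source_contigs=[best.subject_id],
            exon_provenance={1: best.subject_id},
        ),
        errors,
    )


def _core_hit_span(hit: AlignmentHit, model: GeneModel, ordinal: int) -> tuple[int, int] | None:
    """Hit span in exon-core coordinates (1-based), flanks removed."""
    pad = model.flank_pad if ordinal in model.padded_ordinals else 0
    core_len = model.core_length(ordinal)
    lo = max(hit.q_start, pad + 1) - pad
    hi = min(hit.q_end, pad + core_len) - pad
    if lo > hi:
        return None
    return lo, hi


def _core_region(
    hit: AlignmentHit, model: GeneModel, ordinal: int, contig_seq: str
) -> str:
    """Contig sequence for the core part of a hit, reference-oriented."""
    span = _core_hit_span(hit, model, ordinal)
    assert span is not None
    lo, hi = span
    pad = model.flank_pad if ordinal in model.padded_ordinals else 0
    q_lo = lo + pad
    q_hi = hi + pad
    if hit.strand == "+":
        s_lo = hit.s_start + (q_lo - hit.q_start)
        s_hi = hit.s_start + (q_hi - hit.q_start)
        region = contig_seq[s_lo - 1 : s_hi].upper()
    else:
        s_hi = hit.s_start - (q_lo - hit.q_start)
        s_lo = hit.s_start - (q_hi - hit.q_start)
        region = reverse_complement(contig_seq[s_lo - 1 : s_hi].upper())
    return region


def reconstruct_multi_exon(
    model: GeneModel,
    hits_by_exon: Mapping[int, Sequence[AlignmentHit]],
    contigs: Mapping[str, str],
) -> tuple[RecoveredCDS | None, list[ErrorLogEntry]]:
    """Rebuild a multi-exon CDS exon by exon.

    Per exon the hit with the greatest exon-aligned length wins.  An
    exon represented only by partial hits on two or more different
    contigs is flagged ``EXON_SPLIT_ACROSS_CONTIGS`` and not auto-merged
    (the best partial is used, the remainder becomes a gap); an exon
    with no hit at all is ``MISSING_EXON``.  Flank-augmented search
    sequences are trimmed back to the exon core.
    """
    gene = model.name
    errors: list[ErrorLogEntry] = []
    pieces: list[str] = []
    gaps: list[tuple[int, int]] = []
    provenance: dict[int, str] = {}
    source_contigs: list[str] = []
    cds_offset = 0
    any_piece = False
    for ex in model.exons:
        ordinal = ex.ordinal
        core_len = model.core_length(ordinal)
        candidates = []
        for hit in hits_by_exon.get(ordinal, ()):  # core-restricted ranking
            span = _core_hit_span(hit, model, ordinal)
            if span is None:
                continue
            lo, hi = span
            candidates.append((hi - lo + 1, hit, lo, hi))
        if not candidates:
            errors.append(
                ErrorLogEntry(gene, ordinal, MISSING_EXON, "no contig hit for exon")
            )
            gaps.append((cds_offset + 1, cds_offset + core_len))
            cds_offset += core_len
            continue
        candidates.sort(
            key=lambda t: (-t[0], -t[1].pct_identity, t[1].subject_id, t[2])
        )
        best_len, best_hit, best_lo, best_hi = candidates[0]
        contigs_hit = {hit.subject_id for _, hit, _, _ in candidates}
        if best_len < core_len and len(contigs_hit) > 1:
            others = sorted(contigs_hit - {best_hit.subject_id})
            errors.append(
                ErrorLogEntry(
                    gene, ordinal, EXON_SPLIT_ACROSS_CONTIGS,
                    f"partial hits on {best_hit.subject_id} and {', '.join(others)}; "
                    "not auto-merged",
                )
            )
        elif len(contigs_hit) > 1:
            runner = candidates[1]
            if (
                runner[0] == best_len
                and runner[1].pct_identity == best_hit.pct_identity
                and runner[1].subject_id != best_hit.subject_id
            ):
                errors.append(
                    ErrorLogEntry(
                        gene, ordinal, AMBIGUOUS_HIT,
                        f"tied full-length hits on {best_hit.subject_id} "
                        f"and {runner[1].subject_id}",
                    )
                )
        pieces.append(_core_region(best_hit, model, ordinal, contigs[best_hit.subject_id]))
        any_piece = True
        provenance[ordinal] = best_hit.subject_id
        if best_hit.subject_id not in source_contigs:
            source_contigs.append(best_hit.subject_id)
        if best_lo > 1:
            gaps.append((cds_offset + 1, cds_offset + best_lo - 1))
        if best_hi < core_len:
            gaps.append((cds_offset + best_hi + 1, cds_offset + core_len))
        cds_offset += core_len
    if not any_piece:
        return None, errors
    return (
        RecoveredCDS(
            gene=gene,
            sequence="".join(pieces),
            complete=not gaps,
            gaps=gaps,
            source_contigs=source_contigs,
            exon_provenance=provenance,
        ),
        errors,
    )


def recover_genes(
    library: ReferenceLibrary,
    contigs: Mapping[str, str],
    k: int = 15,
    min_identity: float = 90.0,
    genes: Sequence[str] | None = None,
) -> tuple[dict[str, RecoveredCDS], list[ErrorLogEntry]]:
    """Reconstruct every gene (or ``genes``) from a contig set."""
    recovered: dict[str, RecoveredCDS] = {}
    errors: list[ErrorLogEntry] = []
    wanted = list(genes) if genes is not None else library.gene_names()
    for gene in wanted:
        model = library[gene]
        if model.is_multi_exon:
            hits_by_exon: dict[int, list[AlignmentHit]] = {}
            for ex in model.exons:
                for contig_id, seq in contigs.items():
                    hits_by_exon.setdefault(ex.ordinal, []).extend(
                        seeded_align(
                            ex.sequence, seq, k=k, min_identity=min_identity,
                            query_id=f"{gene}.exon{ex.ordinal}", subject_id=contig_id,
                        )
                    )
            cds, errs = reconstruct_multi_exon(model, hits_by_exon, contigs)
        else:
            hits: list[AlignmentHit] = []
            for contig_id, seq in contigs.items():
                hits.extend(
                    seeded_align(
                        model.exons[0].sequence, seq, k=k, min_identity=min_identity,
                        query_id=gene, subject_id=contig_id,
                    )
                )
            cds, errs = reconstruct_single_exon(model, hits, contigs)
        if cds is not None:
            recovered[gene] = cds
        errors.extend(errs)
    return recovered, errors


# ---------------------------------------------------------------------------
# Output organization and variation scanning
# ---------------------------------------------------------------------------


def organize_outputs(
    samples: Mapping[str, Mapping[str, RecoveredCDS]], outdir: str | Path
) -> tuple[Path, Path]:
    """Write gene-wise and sample-wise multi-FASTA trees.

    ``by_gene/<gene>.fasta`` holds one record per sample (SNP-oriented);
    ``by_sample/<sample>.fasta`` holds one record per gene (tree-
    oriented).  Ordering is lexicographic and re-running overwrites to
    identical bytes.
    """
    outdir = Path(outdir)
    gene_dir = outdir / "by_gene"
    sample_dir = outdir / "by_sample"
    gene_dir.mkdir(parents=True, exist_ok=True)
    sample_dir.mkdir(parents=True, exist_ok=True)

    genes = sorted({g for per_gene in samples.values() for g in per_gene})
    for gene in genes:
        records = []
        for sample in sorted(samples):
            cds = samples[sample].get(gene)
            if cds is None:
                logger.info("gene %s absent from sample %s", gene, sample)
                continue
            records.append(SeqRecord(Seq(cds.sequence), id=sample, description=""))
        SeqIO.write(records, str(gene_dir / f"{gene}.fasta"), "fasta")
    for sample in sorted(samples):
        records = [
            SeqRecord(Seq(samples[sample][gene].sequence), id=gene, description="")
            for gene in sorted(samples[sample])
        ]
        SeqIO.write(records, str(sample_dir / f"{sample}.fasta"), "fasta")
    return gene_dir, sample_dir


def count_variable_sites(rows: Sequence[str]) -> int:
    """Number of alignment columns with >= 2 distinct non-gap, non-N
    states.  Rows must be equal length."""
    if not rows:
        return 0
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("ragged alignment: rows differ in length")
    count = 0
    for col in range(length):
        states = {r[col].upper() for r in rows}
        states -= {"-", "N", "?"}
        if len(states) >= 2:
            count += 1
    return count


def write_error_log(entries: Iterable[ErrorLogEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\texon\treason\tdetail\n")
        for e in entries:
            fh.write(f"{e.gene}\t{e.exon_ordinal}\t{e.reason}\t{e.detail}\n")
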