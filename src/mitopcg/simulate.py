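"""Synthetic mitogenome, read, and contig generation with truth manifests.

The generators realise on random background sequence all the structural
situations the annotator and recovery pipeline must handle: cis
multi-exon genes with introns below the splitting threshold, strand-flip
and multi-chromosome trans-splicing, duplicated and deleted exons,
over-threshold introns, frameshifts, and edited / non-canonical codon
genotypes.  Every generator is a pure function of its inputs and a seed,
and every planted feature is recorded in a :class:`TruthManifest` that
fully determines the expected annotation and recovery outcome.

Background composition is ~45 % GC, typical of plant mitogenomes
(cosmetic only).  Simulated reads are error-free by default — recovery
correctness, not error correction, is what the fixtures probe — with an
optional uniform substitution rate for robustness experiments.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .homology_map import reverse_complement
from .reference_db import ReferenceLibrary

__all__ = [
    "PlantedExon",
    "TruthManifest",
    "LayoutError",
    "make_genome",
    "simulate_reads",
    "fragment_contigs",
    "write_fastq_pairs",
]

_LAYOUT_KEYS = {
    "mode", "duplicate_exon", "delete_exon", "long_intron_after",
    "frameshift_after", "edit_start_ACG", "stop_CAA", "start_ATT",
}
_MODES = {"cis", "trans_strand_flip", "trans_multichrom"}

# background base weights, ~45 % GC
_BASES = "ACGT"
_WEIGHTS = (0.275, 0.225, 0.225, 0.275)


class LayoutError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedExon:
    """Ground-truth location of one planted exon copy."""

    gene: str
    ordinal: int
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    is_duplicate: bool = False


@dataclass
class TruthManifest:
    """Everything needed to predict annotation and recovery outcomes."""

    seed: int
    exons: list[PlantedExon] = field(default_factory=list)
    genotypes: dict[str, str] = field(default_factory=dict)
    deleted_exons: dict[str, int] = field(default_factory=dict)
    frameshifts: dict[str, int] = field(default_factory=dict)

    def exons_for(self, gene: str, include_duplicates: bool = False) -> list[PlantedExon]:
        return [
            e for e in self.exons
            if e.gene == gene and (include_duplicates or not e.is_duplicate)
        ]

    def planted_cds(self, library: ReferenceLibrary, gene: str) -> str:
        """Spliced CDS the annotator should reconstruct for ``gene``
        (per-gene genotype edits applied, deleted exons absent)."""
        model = library[gene]
        parts = []
        for ex in model.exons:
            if self.deleted_exons.get(gene) == ex.ordinal:
                continue
            parts.append(model.core_sequence(ex.ordinal))
        cds = "".join(parts)
        return _apply_genotype(cds, self.genotypes.get(gene, ""), self.frameshifts.get(gene))


def _rand_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choices(_BASES, weights=_WEIGHTS, k=n))


def _apply_genotype(cds: str, genotype: str, frameshift_after: int | None) -> str:
    if "edit_start_ACG" in genotype:
        cds = "ACG" + cds[3:]
    if "start_ATT" in genotype:
        cds = "ATT" + cds[3:]
    if "stop_CAA" in genotype:
        cds = cds[:-3] + "CAA"
    if frameshift_after is not None:
        cds = cds[:frameshift_after] + cds[frameshift_after + 1 :]
    return cds


def _strand_pattern(n_exons: int) -> list[str]:
    """Default trans-splicing strand pattern: first and last exons on
    plus, interior exons flipped to minus (the classic +,-,-,-,+ shape
    for a five-exon gene)."""
    if n_exons == 1:
        return ["+"]
    if n_exons == 2:
        return ["+", "-"]
    return ["+"] + ["-"] * (n_exons - 2) + ["+"]


def make_genome(
    library: ReferenceLibrary,
    layout: Mapping[str, Mapping[str, object]],
    seed: int,
    intron_range: tuple[int, int] = (200, 800),
    spacer_range: tuple[int, int] = (300, 900),
    long_intron_factor: float = 1.5,
) -> tuple[dict[str, str], TruthManifest]:
    """Plant the genes named in ``layout`` on synthetic chromosomes.

    ``layout`` maps gene name to an options mapping: ``mode`` selects
    cis (default), strand-flip trans-splicing, or multi-chromosome
    trans-splicing; ``duplicate_exon``/``delete_exon`` take an exon
    ordinal; ``long_intron_after`` places an intron exceeding the
    gene's splitting threshold after the given ordinal;
    ``frameshift_after`` deletes one base that many bp into the CDS;
    ``edit_start_ACG``/``stop_CAA``/``start_ATT`` override the planted
    codon genotype.  Introns are otherwise drawn from ``intron_range``,
    well below the default threshold, so both splitting outcomes are
    exercised.  Deterministic under ``seed``.
    """
    rng = random.Random(seed)
    manifest = TruthManifest(seed=seed)
    chrom_parts: dict[str, list[str]] = {"chr1": []}
    chrom_len: dict[str, int] = {"chr1": 0}

    def append(chrom: str, seq: str) -> tuple[int, int]:
        chrom_parts.setdefault(chrom, [])
        chrom_len.setdefault(chrom, 0)
        start = chrom_len[chrom] + 1
        chrom_parts[chrom].append(seq)
        chrom_len[chrom] += len(seq)
        return start, chrom_len[chrom]

    def spacer(chrom: str) -> None:
        append(chrom, _rand_seq(rng, rng.randint(*spacer_range)))

    for gene in layout:
        if gene not in library:
            raise LayoutError(f"unknown gene {gene!r}")

    for gene, raw_opts in layout.items():
        opts = dict(raw_opts or {})
        unknown = set(opts) - _LAYOUT_KEYS
        if unknown:
            raise LayoutError(f"gene {gene}: unknown layout options {sorted(unknown)}")
        model = library[gene]
        mode = opts.get("mode", "cis")
        if mode not in _MODES:
            raise LayoutError(f"gene {gene}: unknown mode {mode!r}")
        if mode != "cis" and not model.is_multi_exon:
            raise LayoutError(f"gene {gene}: trans-splicing requires a multi-exon gene")
        delete = opts.get("delete_exon")
        duplicate = opts.get("duplicate_exon")
        if delete is not None and not model.is_multi_exon and delete != 1:
            raise LayoutError(f"gene {gene}: no exon {delete} to delete")
        if delete is not None and duplicate is not None and delete == duplicate:
            raise LayoutError(f"gene {gene}: cannot delete and duplicate exon {delete}")

        genotype_flags = [
            flag for flag in ("edit_start_ACG", "stop_CAA", "start_ATT") if opts.get(flag)
        ]
        if "edit_start_ACG" in genotype_flags and "start_ATT" in genotype_flags:
            raise LayoutError(f"gene {gene}: conflicting start-codon options")
        genotype = "+".join(genotype_flags)
        if genotype:
            manifest.genotypes[gene] = genotype
        frameshift = opts.get("frameshift_after")
        if frameshift is not None:
            manifest.frameshifts[gene] = int(frameshift)

        # per-exon planted sequence, genotype applied at the CDS level
        cds = _apply_genotype(model.spliced_cds(), genotype, None)
        exon_seqs: dict[int, str] = {}
        pos = 0
        for ex in model.exons:
            core_len = model.core_length(ex.ordinal)
            exon_seqs[ex.ordinal] = cds[pos : pos + core_len]
            pos += core_len
        if frameshift is not None:
            # drop one base 'frameshift' bp into the containing exon
            off = int(frameshift)
            for ex in model.exons:
                ln = len(exon_seqs[ex.ordinal])
                if off < ln:
                    s = exon_seqs[ex.ordinal]
                    exon_seqs[ex.ordinal] = s[:off] + s[off + 1 :]
                    break
                off -= ln

        strands = (
            _strand_pattern(model.expected_exon_count)
            if mode == "trans_strand_flip"
            else ["+"] * model.expected_exon_count
        )
        if mode == "trans_multichrom":
            cut = (model.expected_exon_count + 1) // 2
            chrom_of = ["chr1" if i < cut else "chr2" for i in range(model.expected_exon_count)]
        else:
            chrom_of = ["chr1"] * model.expected_exon_count

        threshold = library.intron_threshold(gene)
        long_after = opts.get("long_intron_after")
        prev_chrom: str | None = None
        for idx, ex in enumerate(model.exons):
            if delete is not None and ex.ordinal == delete:
                manifest.deleted_exons[gene] = delete
                continue
            chrom = chrom_of[idx]
            if chrom != prev_chrom:
                spacer(chrom)
            elif long_after is not None and ex.ordinal == int(long_after) + 1:
                append(chrom, _rand_seq(rng, int(threshold * long_intron_factor)))
            else:
                append(chrom, _rand_seq(rng, rng.randint(*intron_range)))
            seq = exon_seqs[ex.ordinal]
            planted = seq if strands[idx] == "+" else reverse_complement(seq)
            start, end = append(chrom, planted)
            manifest.exons.append(
                PlantedExon(gene, ex.ordinal, chrom, start, end, strands[idx])
            )
            prev_chrom = chrom
        if duplicate is not None:
            dup_seq = exon_seqs[int(duplicate)]
            spacer("chr1")
            start, end = append("chr1", dup_seq)
            manifest.exons.append(
                PlantedExon(gene, int(duplicate), "chr1", start, end, "+", is_duplicate=True)
            )
    for chrom in chrom_parts:
        spacer(chrom)
    genome = {c: "".join(parts) for c, parts in chrom_parts.items()}
    return genome, manifest


# ---------------------------------------------------------------------------
# Paired-read simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    genome: Mapping[str, str],
    read_len: int = 150,
    coverage: float = 50.0,
    insert: int = 350,
    seed: int = 0,
    error_rate: float = 0.0,
) -> list[tuple[SeqRecord, SeqRecord]]:
    """Uniform paired-end reads; names carry the origin coordinates.

    Pair count is ``total_length * coverage / (2 * read_len)``.  Mate 1
    is the fragment 5' end, mate 2 the reverse complement of its 3'
    end.  ``error_rate`` > 0 applies uniform random substitutions.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    if read_len > insert:
        raise ValueError(f"read_len {read_len} exceeds insert size {insert}")
    chroms = sorted(genome)
    eligible = [c for c in chroms if len(genome[c]) >= insert]
    if not eligible:
        raise ValueError(f"no genome sequence reaches the insert size {insert}")
    rng = random.Random(seed)
    total = sum(len(genome[c]) for c in eligible)
    n_pairs = round(total * coverage / (2 * read_len))
    weights = [len(genome[c]) for c in eligible]

    def mutate(seq: str) -> str:
        if error_rate <= 0:
            return seq
        out = list(seq)
        for i, base in enumerate(out):
            if rng.random() < error_rate:
                out[i] = rng.choice([b for b in "ACGT" if b != base])
        return "".join(out)

    pairs: list[tuple[SeqRecord, SeqRecord]] = []
    for i in range(n_pairs):
        chrom = rng.choices(eligible, weights=weights, k=1)[0]
        start0 = rng.randrange(0, len(genome[chrom]) - insert + 1)
        frag = genome[chrom][start0 : start0 + insert]
        name = f"sim{i}|{chrom}|{start0 + 1}|{start0 + insert}"
        seq1 = mutate(frag[:read_len])
        seq2 = mutate(reverse_complement(frag[-read_len:]))
        rec1 = SeqRecord(Seq(seq1), id=name, description="")
        rec2 = SeqRecord(Seq(seq2), id=name, description="")
        rec1.letter_annotations["phred_quality"] = [40] * read_len
        rec2.letter_annotations["phred_quality"] = [40] * read_len
        pairs.append((rec1, rec2))
    return pairs


def write_fastq_pairs(
    pairs: Sequence[tuple[SeqRecord, SeqRecord]], path1: str | Path, path2: str | Path
) -> None:
    SeqIO.write([p[0] for p in pairs], str(path1), "fastq")
    SeqIO.write([p[1] for p in pairs], str(path2), "fastq")


# ---------------------------------------------------------------------------
# Truth-derived contigs
# ---------------------------------------------------------------------------


def fragment_contigs(
    genome: Mapping[str, str],
    manifest: TruthManifest,
    break_spec: Sequence[tuple[str, int, int]] = (),
    seed: int = 0,
) -> dict[str, str]:
    """Cut the genome into contigs that tile it exactly.

    ``break_spec`` entries are (gene, exon_ordinal, offset_in_exon): a
    breakpoint ``offset`` bases into the named planted exon guarantees
    that the exon yields two partial alignments on different contigs.
    With no breaks, each chromosome becomes a single contig.
    Deterministic (the seed is accepted for API symmetry with the other
    generators).
    """
    del seed  # tiling is fully determined by genome + breaks
    cuts: dict[str, set[int]] = {c: set() for c in genome}
    for gene, ordinal, offset in break_spec:
        planted = [
            e for e in manifest.exons
            if e.gene == gene and e.ordinal == ordinal and not e.is_duplicate
        ]
        if not planted:
            raise LayoutError(f"no planted exon {gene}.exon{ordinal} in manifest")
        exon = planted[0]
        if not 0 < offset < (exon.end - exon.start + 1):
            raise LayoutError(
                f"breakpoint offset {offset} outside exon {gene}.exon{ordinal} "
                f"of length {exon.end - exon.start + 1}"
            )
        pos = exon.start + offset - 1  # cut after this 1-based position
        if not 1 <= pos < len(genome[exon.chrom]):
            raise LayoutError("breakpoint outside genome")
        cuts[exon.chrom].add(pos)
    contigs: dict[str, str] = {}
    for chrom in sorted(genome):
        seq = genome[chrom]
        bounds = [0] + sorted(cuts[chrom]) + [len(seq)]
        for i, (lo, hi) in enumerate(zip(bounds, bounds[1:]), start=1):
            contigs[f"{chrom}_ctg{i}"] = seq[lo:hi]
    return contigs
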