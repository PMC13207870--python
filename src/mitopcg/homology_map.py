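"""Strand-aware homology mapping of reference exons onto genome sequence.

Two sources of similarity evidence are supported interchangeably:

* :func:`parse_hits_tabular` reads precomputed hits in the standard
  12-column tabular report dialect (BLAST ``-outfmt 6``);
* :func:`seeded_align` is a self-contained exact-k-mer seed / ungapped
  extension aligner, adequate for the near-identical reference-vs-genome
  comparisons this pipeline performs and usable without any external
  binary.

:func:`place_exons` turns hits into per-exon genomic placements with a
deterministic best-hit rule and duplicate-copy detection, trimming any
conserved flanks that were appended to micro-exon search sequences.

Coordinates on all public types are 1-based inclusive on the forward
genome axis; a hit's ``s_start > s_end`` encodes a minus-strand match,
as in the tabular dialect.  Internally the aligner works 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence, TextIO

from .reference_db import GeneModel, ReferenceLibrary

__all__ = [
    "AlignmentHit",
    "ExonPlacement",
    "HitParseError",
    "parse_hits_tabular",
    "write_hits_tabular",
    "seeded_align",
    "place_exons",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class HitParseError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise local alignment in outfmt-6 field order."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.q_start > self.q_end:
            raise ValueError("q_start must be <= q_end")

    @property
    def strand(self) -> str:
        return "-" if self.s_start > self.s_end else "+"

    @property
    def subject_lo(self) -> int:
        return min(self.s_start, self.s_end)

    @property
    def subject_hi(self) -> int:
        return max(self.s_start, self.s_end)

    @property
    def score(self) -> float:
        """Length-weighted identity score used for hit ranking."""
        return self.aln_length * self.pct_identity / 100.0


def parse_hits_tabular(stream: TextIO | Iterable[str]) -> list[AlignmentHit]:
    """Parse 12-column tab-separated hits; ``#`` lines and blanks skipped."""
    hits: list[AlignmentHit] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) == 1:  # tolerate space-separated test fixtures
            cols = line.split()
        if len(cols) != 12:
            raise HitParseError(
                f"line {lineno}: expected 12 columns, got {len(cols)}"
            )
        try:
            hits.append(
                AlignmentHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pct_identity=float(cols[2]),
                    aln_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    s_start=int(cols[8]),
                    s_end=int(cols[9]),
                    e_value=float(cols[10]),
                    bit_score=float(cols[11]),
                )
            )
        except ValueError as exc:
            raise HitParseError(f"line {lineno}: {exc}") from exc
    return hits


def write_hits_tabular(hits: Iterable[AlignmentHit], stream: TextIO) -> None:
    for h in hits:
        stream.write(
            "\t".join(
                str(v)
                for v in (
                    h.query_id, h.subject_id, f"{h.pct_identity:.2f}",
                    h.aln_length, h.mismatches, h.gap_opens,
                    h.q_start, h.q_end, h.s_start, h.s_end,
                    f"{h.e_value:.2g}", f"{h.bit_score:.1f}",
                )
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# Seeded ungapped aligner
# ---------------------------------------------------------------------------


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue  # N never seeds
        index.setdefault(kmer, []).append(i)
    return index


def _best_segment(query: str, subject: str, diag: int) -> tuple[int, int, int] | None:
    """Best-scoring ungapped segment on one diagonal (Kadane, match +1,
    mismatch/N -3).  Returns (q_lo, q_hi_exclusive, matches) or None."""
    q_lo = max(0, -diag)
    q_hi = min(len(query), len(subject) - diag)
    if q_hi - q_lo <= 0:
        return None
    best = (0, q_lo, q_lo, 0)  # score, start, end, matches
    score = 0
    start = q_lo
    matches = 0
    for q in range(q_lo, q_hi):
        a = query[q]
        b = subject[q + diag]
        if a == b and a != "N":
            score += 1
            matches += 1
        else:
            score -= 3
        if score > best[0]:
            best = (score, start, q + 1, matches)
        if score <= 0:
            score = 0
            start = q + 1
            matches = 0
    if best[0] <= 0:
        return None
    _, seg_lo, seg_hi, _ = best
    # recount matches inside the winning window (running 'matches' resets
    # with 'start', so recompute exactly)
    m = sum(
        1
        for q in range(seg_lo, seg_hi)
        if query[q] == subject[q + diag] and query[q] != "N"
    )
    return seg_lo, seg_hi, m


def seeded_align(
    query: str,
    subject: str,
    k: int = 15,
    min_identity: float = 90.0,
    query_id: str = "query",
    subject_id: str = "subject",
    min_length: int | None = None,
) -> list[AlignmentHit]:
    """Exact-k-mer seeded, ungapped local alignment on both strands.

    Every diagonal receiving at least one exact k-mer seed is extended to
    its best-scoring ungapped segment; segments with percent identity
    below ``min_identity`` (N counts as mismatch) or shorter than
    ``min_length`` (default ``k``) are discarded.  Hit scores are
    ``aln_length * identity / 100``.
    """
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    query = query.upper()
    subject = subject.upper()
    if min_length is None:
        min_length = k
    if len(query) < k or len(subject) < k:
        return []
    subject_index = _kmer_index(subject, k)
    hits: list[AlignmentHit] = []
    for strand in ("+", "-"):
        q_eff = query if strand == "+" else reverse_complement(query)
        diags: set[int] = set()
        for qpos in range(len(q_eff) - k + 1):
            kmer = q_eff[qpos : qpos + k]
            if "N" in kmer:
                continue
            for spos in subject_index.get(kmer, ()):
                diags.add(spos - qpos)
        for diag in sorted(diags):
            seg = _best_segment(q_eff, subject, diag)
            if seg is None:
                continue
            q_lo, q_hi, matches = seg
            length = q_hi - q_lo
            if length < min_length:
                continue
            identity = 100.0 * matches / length
            if identity < min_identity:
                continue
            s_lo = q_lo + diag  # 0-based on subject, ascending
            s_hi = q_hi + diag
            if strand == "+":
                qs, qe = q_lo + 1, q_hi
                ss, se = s_lo + 1, s_hi
            else:
                # map back to original query coordinates (ascending)
                qs = len(query) - q_hi + 1
                qe = len(query) - q_lo
                ss, se = s_hi, s_lo + 1  # s_start > s_end encodes minus
            score = length * identity / 100.0
            hits.append(
                AlignmentHit(
                    query_id=query_id,
                    subject_id=subject_id,
                    pct_identity=round(identity, 2),
                    aln_length=length,
                    mismatches=length - matches,
                    gap_opens=0,
                    q_start=qs,
                    q_end=qe,
                    s_start=ss,
                    s_end=se,
                    e_value=0.0,
                    bit_score=round(score, 1),
                )
            )
    hits.sort(key=lambda h: (-h.score, h.subject_lo, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Exon placement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExonPlacement:
    """One exon located on a genome sequence (1-based inclusive coords)."""

    gene: str
    exon_ordinal: int
    subject_id: str
    start: int
    end: int
    strand: str
    identity: float
    aln_length: int
    score: float
    is_duplicate_copy: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("placement start must be <= end")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    def overlaps(self, other: "ExonPlacement") -> bool:
        """>= 1 shared bp on the same subject sequence, strand-blind."""
        return (
            self.subject_id == other.subject_id
            and self.start <= other.end
            and other.start <= self.end
        )


def _parse_query_label(label: str) -> tuple[str, int]:
    if ".exon" in label:
        gene, _, tail = label.partition(".exon")
        return gene, int(tail)
    return label, 1


def _trim_flanks(
    hit: AlignmentHit, model: GeneModel, ordinal: int
) -> tuple[int, int, int] | None:
    """Restrict a hit to the exon core, removing appended flanks.

    Returns (genome_lo, genome_hi, covered_core_bp) in 1-based inclusive
    forward-axis coordinates, or None when the hit misses the core.
    Extension is ungapped, so query->subject mapping is linear.
    """
    pad = model.flank_pad if ordinal in model.padded_ordinals else 0
    core_len = model.core_length(ordinal)
    core_q_lo = pad + 1
    core_q_hi = pad + core_len
    q_lo = max(hit.q_start, core_q_lo)
    q_hi = min(hit.q_end, core_q_hi)
    if q_lo > q_hi:
        return None
    if hit.strand == "+":
        # subject position of query base q: s_start + (q - q_start)
        g_lo = hit.s_start + (q_lo - hit.q_start)
        g_hi = hit.s_start + (q_hi - hit.q_start)
    else:
        # minus strand: query base q pairs with subject s_start - (q - q_start)
        g_hi = hit.s_start - (q_lo - hit.q_start)
        g_lo = hit.s_start - (q_hi - hit.q_start)
    return g_lo, g_hi, q_hi - q_lo + 1


def compute_hits(
    library: ReferenceLibrary,
    genome: Mapping[str, str],
    k: int = 15,
    min_identity: float = 90.0,
) -> list[AlignmentHit]:
    """Align every exon search sequence of every gene to every sequence."""
    hits: list[AlignmentHit] = []
    for name in library.gene_names():
        model = library[name]
        for ex in model.exons:
            label = f"{name}.exon{ex.ordinal}" if model.is_multi_exon else name
            for subject_id, seq in genome.items():
                hits.extend(
                    seeded_align(
                        ex.sequence,
                        seq,
                        k=k,
                        min_identity=min_identity,
                        query_id=label,
                        subject_id=subject_id,
                    )
                )
    return hits


def place_exons(
    library: ReferenceLibrary,
    genome: Mapping[str, str],
    hits: Sequence[AlignmentHit] | None = None,
    min_identity: float = 90.0,
    min_coverage: float = 0.8,
) -> list[ExonPlacement]:
    """Select per-exon placements from alignment hits.

    For each exon the best passing hit is chosen by (1) greatest aligned
    length, (2) greatest identity, (3) greatest score, (4) smallest
    start, (5) subject id — a total, permutation-invariant order.
    Additional passing hits that do not overlap an already retained
    placement (>= 1 shared bp on the same subject, strand-blind) are
    kept with ``is_duplicate_copy=True``.  Flank-augmented search
    sequences are trimmed back to the exon core before coverage is
    assessed and coordinates reported.
    """
    if hits is None:
        hits = compute_hits(library, genome, min_identity=min_identity)
    per_exon: dict[tuple[str, int], list[ExonPlacement]] = {}
    for hit in hits:
        gene, ordinal = _parse_query_label(hit.query_id)
        if gene not in library:
            continue
        model = library[gene]
        try:
            core_len = model.core_length(ordinal)
        except KeyError:
            continue
        if hit.pct_identity < min_identity:
            continue
        trimmed = _trim_flanks(hit, model, ordinal)
        if trimmed is None:
            continue
        g_lo, g_hi, covered = trimmed
        if covered < min_coverage * core_len:
            continue
        per_exon.setdefault((gene, ordinal), []).append(
            ExonPlacement(
                gene=gene,
                exon_ordinal=ordinal,
                subject_id=hit.subject_id,
                start=g_lo,
                end=g_hi,
                strand=hit.strand,
                identity=hit.pct_identity,
                aln_length=covered,
                score=covered * hit.pct_identity / 100.0,
                is_duplicate_copy=False,
            )
        )
    placements: list[ExonPlacement] = []
    for key in sorted(per_exon):
        candidates = sorted(
            per_exon[key],
            key=lambda p: (-p.aln_length, -p.identity, -p.score, p.start, p.subject_id),
        )
        retained: list[ExonPlacement] = []
        for cand in candidates:
            if any(cand.overlaps(r) for r in retained):
                continue
            if retained:
                cand = replace(cand, is_duplicate_copy=True)
            retained.append(cand)
        placements.extend(retained)
    placements.sort(
        key=lambda p: (p.gene, p.exon_ordinal, p.is_duplicate_copy, p.subject_id, p.start)
    )
    return placements
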