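"""Exon-based transcript splitting and gene classification (EBAnno).

Plant mitochondrial genes may be trans-spliced: the exons of one mature
mRNA can sit on opposite strands or on different chromosomes, kilobases
apart.  The algorithm therefore splits the placed exons of a gene into
transcript groups in two passes:

1. :func:`group_by_strand` — maximal runs of consecutive exon ordinals
   sharing strand *and* subject sequence become groups "1", "2", ...;
2. :func:`split_by_gap` — within a group, adjacent exons separated by
   more than the gene's intron-length threshold are split apart,
   yielding sublabels "k-1", "k-2", ...

A gene with two or more final groups is trans-spliced.  A gene whose
placed exon count deviates from the reference model is a pseudogene
(reason ``EXON_COUNT_MISMATCH``); an optional exon-order check can also
demote a gene (``EXON_ORDER_VIOLATION``); a gene with no placements at
all is ``MISSING_GENE``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .homology_map import ExonPlacement
from .reference_db import ReferenceLibrary

__all__ = [
    "TranscriptGroup",
    "GeneAnnotation",
    "group_by_strand",
    "split_by_gap",
    "split_groups",
    "validate_exon_order",
    "classify",
    "EXON_COUNT_MISMATCH",
    "EXON_ORDER_VIOLATION",
    "MISSING_GENE",
]

EXON_COUNT_MISMATCH = "EXON_COUNT_MISMATCH"
EXON_ORDER_VIOLATION = "EXON_ORDER_VIOLATION"
MISSING_GENE = "MISSING_GENE"


@dataclass(frozen=True)
class TranscriptGroup:
    """A maximal same-strand, gap-bounded run of exon placements."""

    label: str
    placements: tuple[ExonPlacement, ...]

    def __post_init__(self) -> None:
        if not self.placements:
            raise ValueError("transcript group must contain >= 1 placement")
        strands = {p.strand for p in self.placements}
        subjects = {p.subject_id for p in self.placements}
        if len(strands) > 1 or len(subjects) > 1:
            raise ValueError("group placements must share strand and subject")
        ordinals = [p.exon_ordinal for p in self.placements]
        if ordinals != sorted(ordinals):
            raise ValueError("group placements must be sorted by exon ordinal")

    @property
    def strand(self) -> str:
        return self.placements[0].strand

    @property
    def subject_id(self) -> str:
        return self.placements[0].subject_id

    @property
    def ordinals(self) -> tuple[int, ...]:
        return tuple(p.exon_ordinal for p in self.placements)


@dataclass
class GeneAnnotation:
    """Classification of one gene after both splitting passes."""

    gene: str
    groups: list[TranscriptGroup]
    trans_spliced: bool
    pseudogene: bool
    reasons: list[str]
    placed_exon_count: int
    order_violations: list[tuple[int, int]] = field(default_factory=list)
    duplicate_placements: list[ExonPlacement] = field(default_factory=list)


def group_by_strand(placements: Sequence[ExonPlacement]) -> list[TranscriptGroup]:
    """First splitting pass: break at every strand or chromosome switch.

    ``placements`` must be the primary (non-duplicate) copies, one per
    placed exon, ordered by exon ordinal.  Maximal runs of consecutive
    entries sharing (strand, subject_id) become groups labelled "1",
    "2", ... in ordinal order.
    """
    groups: list[TranscriptGroup] = []
    run: list[ExonPlacement] = []
    for p in placements:
        if run and (p.strand != run[-1].strand or p.subject_id != run[-1].subject_id):
            groups.append(TranscriptGroup(str(len(groups) + 1), tuple(run)))
            run = []
        run.append(p)
    if run:
        groups.append(TranscriptGroup(str(len(groups) + 1), tuple(run)))
    return groups


def _interval_gap(a: ExonPlacement, b: ExonPlacement) -> int:
    """Distance in bp between two placements on the forward genome axis.

    Orientation-blind: the separation of the two intervals regardless of
    which is the upstream exon.  Overlapping intervals yield a negative
    value (treated as gap 0 by the splitter).
    """
    return max(a.start, b.start) - min(a.end, b.end) - 1


def split_by_gap(group: TranscriptGroup, threshold: int) -> list[TranscriptGroup]:
    """Second splitting pass: break where the intron exceeds ``threshold``.

    Between each adjacent placement pair the forward-axis gap is
    measured; where it exceeds ``threshold`` the group is split, and the
    resulting subgroups take sublabels "<label>-1", "<label>-2", ... in
    ordinal order.  When no gap exceeds the threshold the group is
    returned unchanged, keeping its original label.
    """
    if threshold <= 0:
        raise ValueError("intron threshold must be > 0")
    if len(group.placements) < 2:
        return [group]
    pieces: list[list[ExonPlacement]] = [[group.placements[0]]]
    for prev, cur in zip(group.placements, group.placements[1:]):
        gap = _interval_gap(prev, cur)
        if gap < 0:
            gap = 0  # overlapping exon placements: flagged upstream, gap 0
        if gap > threshold:
            pieces.append([cur])
        else:
            pieces[-1].append(cur)
    if len(pieces) == 1:
        return [group]
    return [
        TranscriptGroup(f"{group.label}-{i}", tuple(piece))
        for i, piece in enumerate(pieces, start=1)
    ]


def split_groups(groups: Sequence[TranscriptGroup], threshold: int) -> list[TranscriptGroup]:
    """Apply :func:`split_by_gap` to every group, preserving order."""
    out: list[TranscriptGroup] = []
    for g in groups:
        out.extend(split_by_gap(g, threshold))
    return out


def validate_exon_order(
    group: TranscriptGroup, enabled: bool = False
) -> list[tuple[int, int]]:
    """Optional check that exon ordinals follow the canonical genomic order.

    On the plus strand consecutive ordinals i < j must satisfy
    start(i) < start(j); on the minus strand start(i) > start(j).
    Returns the violating ordinal pairs; always empty when disabled.
    """
    if not enabled:
        return []
    violations: list[tuple[int, int]] = []
    for prev, cur in zip(group.placements, group.placements[1:]):
        if group.strand == "+" and not prev.start < cur.start:
            violations.append((prev.exon_ordinal, cur.exon_ordinal))
        elif group.strand == "-" and not prev.start > cur.start:
            violations.append((prev.exon_ordinal, cur.exon_ordinal))
    return violations


def classify(
    gene_name: str,
    groups: Sequence[TranscriptGroup],
    library: ReferenceLibrary,
    order_check: bool = False,
) -> GeneAnnotation:
    """Classify a gene from its final transcript groups.

    ``pseudogene`` with ``EXON_COUNT_MISMATCH`` when the number of
    distinct placed ordinals differs from the reference exon count;
    ``EXON_ORDER_VIOLATION`` when the optional order check fails;
    ``MISSING_GENE`` when nothing was placed.  ``trans_spliced`` when
    two or more groups remain and the gene is not a pseudogene.
    """
    if gene_name not in library:
        raise KeyError(f"unknown gene {gene_name!r}")
    model = library[gene_name]
    placed = sorted({p.exon_ordinal for g in groups for p in g.placements})
    reasons: list[str] = []
    violations: list[tuple[int, int]] = []
    if not placed:
        reasons.append(MISSING_GENE)
    elif len(placed) != model.expected_exon_count:
        reasons.append(EXON_COUNT_MISMATCH)
    if order_check:
        for g in groups:
            violations.extend(validate_exon_order(g, enabled=True))
        if violations:
            reasons.append(EXON_ORDER_VIOLATION)
    pseudo = bool(reasons)
    return GeneAnnotation(
        gene=gene_name,
        groups=list(groups),
        trans_spliced=len(groups) >= 2 and not pseudo,
        pseudogene=pseudo,
        reasons=reasons,
        placed_exon_count=len(placed),
        order_violations=violations,
    )
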