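"""End-to-end genome annotation: homology mapping, transcript splitting,
codon-level qualifiers, and feature construction.

:func:`annotate_genome` is the programmatic equivalent of the
``mitopcg annotate`` command: given a reference library and a genome it
places exons, splits transcripts by strand/chromosome and intron gap,
classifies genes (trans-spliced / pseudogene / missing), assembles the
spliced CDS of every intact gene, applies RNA-editing and non-canonical
codon qualifiers, and returns annotation records plus serializable
features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import codon_rules, ebanno
from .annot_io import FeatureRecord
from .codon_rules import CodingAssembly
from .ebanno import GeneAnnotation
from .homology_map import AlignmentHit, ExonPlacement, place_exons, reverse_complement
from .reference_db import ReferenceLibrary

__all__ = ["AnnotationResult", "annotate_genome", "assemble_cds"]


@dataclass
class AnnotationResult:
    annotations: dict[str, GeneAnnotation] = field(default_factory=dict)
    assemblies: dict[str, CodingAssembly] = field(default_factory=dict)
    features: list[FeatureRecord] = field(default_factory=list)
    placements: list[ExonPlacement] = field(default_factory=list)


def assemble_cds(
    genome: Mapping[str, str], placements: Sequence[ExonPlacement]
) -> tuple[str, tuple[int, ...]]:
    """Splice placements (ordinal order) into a strand-resolved CDS.

    Returns the CDS string and, per CDS base, its 1-based genomic
    coordinate (descending within minus-strand exons).
    """
    parts: list[str] = []
    positions: list[int] = []
    for p in sorted(placements, key=lambda p: p.exon_ordinal):
        seq = genome[p.subject_id][p.start - 1 : p.end].upper()
        coords = list(range(p.start, p.end + 1))
        if p.strand == "-":
            seq = reverse_complement(seq)
            coords.reverse()
        parts.append(seq)
        positions.extend(coords)
    return "".join(parts), tuple(positions)


def annotate_genome(
    library: ReferenceLibrary,
    genome: Mapping[str, str],
    hits: Sequence[AlignmentHit] | None = None,
    order_check: bool = False,
    min_identity: float = 90.0,
    min_coverage: float = 0.8,
    genes: Sequence[str] | None = None,
) -> AnnotationResult:
    """Annotate every library gene (or ``genes``) on ``genome``."""
    all_placements = place_exons(
        library, genome, hits=hits, min_identity=min_identity, min_coverage=min_coverage
    )
    result = AnnotationResult(placements=all_placements)
    wanted = list(genes) if genes is not None else library.gene_names()
    by_gene: dict[str, list[ExonPlacement]] = {g: [] for g in wanted}
    for p in all_placements:
        if p.gene in by_gene:
            by_gene[p.gene].append(p)

    for gene in wanted:
        model = library[gene]
        primaries = sorted(
            (p for p in by_gene[gene] if not p.is_duplicate_copy),
            key=lambda p: p.exon_ordinal,
        )
        duplicates = [p for p in by_gene[gene] if p.is_duplicate_copy]
        groups = ebanno.group_by_strand(primaries)
        groups = ebanno.split_groups(groups, library.intron_threshold(gene))
        ann = ebanno.classify(gene, groups, library, order_check=order_check)
        ann.duplicate_placements = duplicates
        result.annotations[gene] = ann

        if not primaries:
            continue

        segments = tuple(
            (p.subject_id, p.start, p.end, p.strand)
            for p in sorted(primaries, key=lambda p: p.exon_ordinal)
        )
        gene_segments = _gene_extent_segments(primaries)
        if ann.pseudogene:
            result.features.append(
                FeatureRecord(
                    gene=gene, kind="gene", segments=gene_segments, pseudo=True
                )
            )
            continue

        cds, positions = assemble_cds(genome, primaries)
        assembly = CodingAssembly(
            gene=gene,
            cds=cds,
            protein=codon_rules.translate(cds),
            genomic_positions=positions,
            partial_codon=len(cds) % 3 != 0,
        )
        if model.editing_sites:
            assembly = codon_rules.apply_editing_exceptions(
                assembly, model.editing_sites, positions
            )
        assembly = codon_rules.annotate_noncanonical(assembly, model)
        result.assemblies[gene] = assembly

        result.features.append(
            FeatureRecord(gene=gene, kind="gene", segments=gene_segments)
        )
        result.features.append(
            FeatureRecord(
                gene=gene,
                kind="CDS",
                segments=segments,
                qualifiers=assembly.qualifiers,
                trans_spliced=ann.trans_spliced,
                translation=assembly.protein,
            )
        )
    return result


def _gene_extent_segments(
    placements: Sequence[ExonPlacement],
) -> tuple[tuple[str, int, int, str], ...]:
    """One spanning segment per subject sequence the gene touches."""
    extents: dict[str, list] = {}
    for p in placements:
        ext = extents.setdefault(p.subject_id, [p.start, p.end, p.strand])
        ext[0] = min(ext[0], p.start)
        ext[1] = max(ext[1], p.end)
    return tuple(
        (subject, lo, hi, strand) for subject, (lo, hi, strand) in extents.items()
    )
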