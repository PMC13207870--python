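"""Codon-level annotation: RNA-editing exceptions, non-canonical codons,
missing-stop boundary resolution, and CDS translation.

Plant mitochondrial transcripts undergo C-to-U RNA editing that can
restore canonical codons absent from the genome: an ACG genomic start
is edited to AUG, a CAA genomic stop to UAA.  Annotation works on the
*pre-edited* genomic sequence and records each such event as a GenBank
``transl_except`` qualifier while rendering the translation as if the
edit had occurred (REAnno).  Genes that genuinely initiate or terminate
at non-canonical codons (an ATT start of cob, species-specific GTG
starts or GGA stops) receive explanatory ``note`` qualifiers and are
still translated from position 1 as Met (NCAnno).  Stop-less genes such
as nad6 have their 3' boundary chosen by aligning reference forms of
varying length and keeping the highest-scoring one, ties broken by the
longest identifiable open reading frame.

Translation uses the standard genetic code (table 1), as conventional
for land-plant mitochondria; all deviations are expressed through
qualifiers rather than a custom code.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

from Bio.Data import CodonTable

from .reference_db import EditingSite, GeneModel, STOP_CODONS

__all__ = [
    "CodingAssembly",
    "BoundaryNote",
    "TranslationError",
    "MissingGeneError",
    "translate",
    "apply_editing_exceptions",
    "annotate_noncanonical",
    "resolve_missing_stop",
    "scan_internal_stops",
    "longest_orf",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"


class TranslationError(ValueError):
    pass


class MissingGeneError(ValueError):
    """No reference form aligned to the region above threshold."""


@dataclass(frozen=True)
class BoundaryNote:
    """Record of how a 3' boundary was chosen among reference forms."""

    chosen_label: str
    chosen_score: float
    scores: tuple[tuple[str, float], ...]


@dataclass(frozen=True)
class CodingAssembly:
    """A spliced, strand-resolved CDS with its qualifiers and protein.

    ``qualifiers`` are verbatim GenBank-style strings (``/key=value`` or
    bare ``/key``); ``genomic_positions``, when present, maps each CDS
    base (0-based index) to its 1-based genomic coordinate and is what
    anchors ``transl_except`` positions.
    """

    gene: str
    cds: str
    protein: str
    qualifiers: tuple[str, ...] = ()
    genomic_positions: tuple[int, ...] | None = None
    boundary_note: BoundaryNote | None = None
    partial_codon: bool = False
    warnings: tuple[str, ...] = ()


def translate(cds: str, exceptions: dict[int, str] | None = None) -> str:
    """Codon-wise translation under the standard code.

    ``exceptions`` maps 1-based codon indices to the amino acid to emit
    instead (``"M"`` for edited/non-canonical starts, ``"*"`` for edited
    stops).  A trailing incomplete codon is dropped.  N-containing
    codons translate to ``X``; any other non-ACGTN symbol is an error.
    """
    if len(cds) < 3:
        raise TranslationError(f"CDS too short to translate ({len(cds)} nt)")
    cds = cds.upper()
    bad = set(cds) - set("ACGTN")
    if bad:
        raise TranslationError(f"non-ACGTN symbols in CDS: {sorted(bad)}")
    exceptions = exceptions or {}
    out: list[str] = []
    for idx in range(len(cds) // 3):
        codon_no = idx + 1
        if codon_no in exceptions:
            out.append(exceptions[codon_no])
            continue
        codon = cds[idx * 3 : idx * 3 + 3]
        out.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def _transl_except_qualifier(positions: Sequence[int], aa: str) -> str:
    lo, hi = min(positions), max(positions)
    return f"/transl_except=(pos:{lo}..{hi},aa:{aa})"


def apply_editing_exceptions(
    assembly: CodingAssembly,
    editing_sites: Iterable[EditingSite],
    genomic_positions: Sequence[int] | None = None,
) -> CodingAssembly:
    """Apply C-to-U editing sites as qualifiers and translation overrides.

    The CDS nucleotides are never changed — annotation describes the
    pre-edited genome.  ``start_gain`` sites emit a
    ``/transl_except=(pos:..,aa:Met)`` qualifier anchored at the codon's
    genomic coordinates and render that codon as M; ``stop_gain`` sites
    emit ``aa:TERM`` and terminate the translation there.  Missense and
    synonymous sites are recorded in translation overrides only when
    they change the residue, and emit no qualifier.
    """
    positions = genomic_positions if genomic_positions is not None else assembly.genomic_positions
    cds = assembly.cds
    exceptions: dict[int, str] = {}
    new_quals: list[str] = []
    stop_at: int | None = None
    for site in sorted(editing_sites, key=lambda s: s.cds_position):
        pos = site.cds_position
        if not 1 <= pos <= len(cds) - 2:
            raise ValueError(
                f"{assembly.gene}: editing site position {pos} outside CDS "
                f"of length {len(cds)}"
            )
        codon_no = (pos - 1) // 3 + 1
        genomic_codon = cds[pos - 1 : pos + 2]
        warn = None
        if genomic_codon != site.genomic_codon:
            warn = (
                f"editing site at {pos}: CDS codon {genomic_codon} differs "
                f"from declared {site.genomic_codon}"
            )
        if positions is not None:
            codon_genomic = positions[pos - 1 : pos + 2]
        else:
            codon_genomic = list(range(pos, pos + 3))  # CDS-relative fallback
        if site.effect == "start_gain":
            exceptions[codon_no] = "M"
            new_quals.append(_transl_except_qualifier(codon_genomic, "Met"))
        elif site.effect == "stop_gain":
            exceptions[codon_no] = "*"
            stop_at = codon_no if stop_at is None else min(stop_at, codon_no)
            new_quals.append(_transl_except_qualifier(codon_genomic, "TERM"))
        elif site.effect == "missense":
            exceptions[codon_no] = site.amino_acid
        # synonymous: recorded structurally, nothing to change
        if warn is not None:
            new_quals.append(f"/note=WARNING: {warn}")
    protein = translate(cds, exceptions)
    if stop_at is not None:
        protein = protein[: stop_at - 1] + "*"
    return replace(
        assembly,
        protein=protein,
        qualifiers=assembly.qualifiers + tuple(new_quals),
    )


def annotate_noncanonical(assembly: CodingAssembly, model: GeneModel) -> CodingAssembly:
    """Emit notes for genuinely non-canonical start/stop codons.

    Codons already explained by a start_gain/stop_gain editing site are
    the province of :func:`apply_editing_exceptions` and are skipped
    here.  The start codon is still translated as M.  A declared codon
    that disagrees with the CDS sequence produces a warning qualifier
    and a warning flag instead of a silent mismatch.
    """
    quals: list[str] = []
    warnings: list[str] = []
    exceptions: dict[int, str] = {}
    edited_effects = {s.effect for s in model.editing_sites}
    start = model.start_codon.upper()
    if start != "ATG" and "start_gain" not in edited_effects:
        observed = assembly.cds[:3]
        if observed != start:
            msg = f"declared start codon {start} disagrees with CDS start {observed}"
            warnings.append(msg)
            quals.append(f"/note=WARNING: {msg}")
        else:
            quals.append(
                f"/note=Translation initiates from a non-canonical {start} start codon."
            )
            exceptions[1] = "M"
    stop = model.stop_codon.upper()
    if stop not in STOP_CODONS and stop != "NONE" and "stop_gain" not in edited_effects:
        observed = assembly.cds[-3:]
        if observed != stop:
            msg = f"declared stop codon {stop} disagrees with CDS end {observed}"
            warnings.append(msg)
            quals.append(f"/note=WARNING: {msg}")
        else:
            quals.append(
                f"/note=Translation terminates at a non-canonical {stop} stop codon."
            )
            exceptions[len(assembly.cds) // 3] = "*"
    if not quals and not exceptions:
        return assembly
    protein = translate(assembly.cds, exceptions) if exceptions else assembly.protein
    return replace(
        assembly,
        protein=protein,
        qualifiers=assembly.qualifiers + tuple(quals),
        warnings=assembly.warnings + tuple(warnings),
    )


def longest_orf(seq: str) -> int:
    """Length in nt of the longest identifiable ORF in ``seq`` (all 3
    forward frames; an ORF runs from an ATG to the first in-frame stop,
    or to the end of the sequence when no stop follows)."""
    seq = seq.upper()
    best = 0
    for frame in range(3):
        starts: list[int] = []
        i = frame
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if codon == "ATG":
                starts.append(i)
            if codon in STOP_CODONS and starts:
                best = max(best, i + 3 - starts[0])
                starts = []
            i += 3
        if starts:
            end = frame + ((len(seq) - frame) // 3) * 3
            best = max(best, end - starts[0])
    return best


def resolve_missing_stop(
    gene: str,
    genome_region: str,
    model: GeneModel,
    aligner: Callable | None = None,
    min_score: float = 50.0,
) -> tuple[int, BoundaryNote]:
    """Choose the 3' boundary of a stop-less gene within a genome region.

    Each reference form of the gene (the model's spliced CDS plus every
    variant form) is aligned to ``genome_region``; the boundary is the
    last aligned base (1-based within the region) of the highest-scoring
    form.  Score ties are broken by the longer identifiable ORF in the
    form, then by label for full determinism, making the result
    invariant under permutation of the variant list.
    """
    if not model.missing_stop and len(model.variant_forms) < 2:
        raise ValueError(
            f"{gene}: boundary resolution requires missing_stop or >= 2 variant forms"
        )
    if aligner is None:
        from .homology_map import seeded_align as aligner  # noqa: PLC0415
    forms: list[tuple[str, str]] = []
    if model.missing_stop or not model.variant_forms:
        forms.append(("reference", model.spliced_cds()))
    forms.extend(model.variant_forms)
    # dedupe by label keeping first occurrence
    seen: set[str] = set()
    forms = [(lbl, s) for lbl, s in forms if not (lbl in seen or seen.add(lbl))]

    scored: list[tuple[float, int, str, int]] = []  # score, orf, label, boundary
    for label, form_seq in forms:
        hits = aligner(form_seq, genome_region, query_id=label, subject_id="region")
        if not hits:
            continue
        best = max(hits, key=lambda h: h.score)
        if best.score < min_score:
            continue
        scored.append((best.score, longest_orf(form_seq), label, best.subject_hi))
    if not scored:
        raise MissingGeneError(f"{gene}: no reference form aligned above threshold")
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    score, _, label, boundary = scored[0]
    note = BoundaryNote(
        chosen_label=label,
        chosen_score=score,
        scores=tuple(sorted(((lbl, sc) for sc, _, lbl, _ in scored))),
    )
    return boundary, note


def scan_internal_stops(cds: str) -> list[tuple[int, str]]:
    """Report stop codons strictly before the final codon of an in-frame
    CDS as (1-based codon index, codon) pairs — the signature of ongoing
    pseudogenization (e.g. rpl16 in *Rhodiola*)."""
    cds = cds.upper()
    n_codons = len(cds) // 3
    found: list[tuple[int, str]] = []
    for idx in range(n_codons - 1):
        codon = cds[idx * 3 : idx * 3 + 3]
        if codon in STOP_CODONS:
            found.append((idx + 1, codon))
    return found
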