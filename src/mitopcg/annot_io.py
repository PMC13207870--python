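"""Serialization of annotations to GenBank flat files and GFF3, and
extraction of CDSs from outgroup GenBank records.

Conventions:

* coordinates in files are 1-based inclusive, minus-strand features are
  wrapped in ``complement``; a multi-exon cis gene becomes a ``join``;
* a trans-spliced gene on a single sequence becomes one CDS whose
  location joins all transcript groups' segments in exon-ordinal
  (translation) order, marked with ``/trans_splicing``;
* a trans-spliced gene spanning several sequences cannot be expressed
  as a single flat-file location, so one CDS feature is emitted per
  sequence, cross-referenced through a shared ``/gene`` and a
  ``/note=trans-splicing partner (part i of n)`` marker that the reader
  uses to reassemble the spliced CDS;
* pseudogenes get a ``gene`` feature with ``/pseudo`` and no CDS.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FeatureRecord",
    "AnnotationIOError",
    "write_genbank",
    "write_gff3",
    "read_genbank_cds",
]

logger = logging.getLogger(__name__)

_PART_RE = re.compile(r"trans-splicing partner \(part (\d+) of (\d+)\)")


class AnnotationIOError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureRecord:
    """A gene or CDS ready for serialization.

    ``segments`` are (subject_id, start, end, strand) tuples, 1-based
    inclusive, listed in exon-ordinal (translation) order.  ``qualifiers``
    are verbatim ``/key=value`` (or bare ``/key``) strings.
    """

    gene: str
    kind: str  # "gene" | "CDS"
    segments: tuple[tuple[str, int, int, str], ...]
    qualifiers: tuple[str, ...] = ()
    pseudo: bool = False
    trans_spliced: bool = False
    translation: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "CDS"):
            raise AnnotationIOError(f"unknown feature kind {self.kind!r}")
        if not self.segments:
            raise AnnotationIOError("feature must have >= 1 segment")
        for _, start, end, strand in self.segments:
            if start > end:
                raise AnnotationIOError("segment start must be <= end")
            if strand not in "+-":
                raise AnnotationIOError("segment strand must be + or -")

    def subjects(self) -> list[str]:
        seen: list[str] = []
        for subject, *_ in self.segments:
            if subject not in seen:
                seen.append(subject)
        return seen


def _parse_qualifier(raw: str) -> tuple[str, str | None]:
    if not raw.startswith("/"):
        raise AnnotationIOError(f"qualifier must start with '/': {raw!r}")
    body = raw[1:]
    if "=" not in body:
        return body, None
    key, _, value = body.partition("=")
    return key, value


def _location_for(
    segments: Iterable[tuple[str, int, int, str]], seq_len: int
) -> SimpleLocation | CompoundLocation:
    parts = []
    for subject, start, end, strand in segments:
        if end > seq_len:
            raise AnnotationIOError(
                f"segment {start}..{end} beyond sequence {subject} of length {seq_len}"
            )
        parts.append(SimpleLocation(start - 1, end, strand=1 if strand == "+" else -1))
    if len(parts) == 1:
        return parts[0]
    return CompoundLocation(parts)


def write_genbank(
    genome: Mapping[str, str],
    features: Iterable[FeatureRecord],
    path: str | Path,
    molecule: str = "DNA",
    organism: str = "synthetic construct",
) -> None:
    """Write genome sequences plus features as a multi-record flat file."""
    features = list(features)
    records: dict[str, SeqRecord] = {}
    for subject_id, seq in genome.items():
        rec = SeqRecord(
            Seq(seq),
            id=subject_id,
            name=subject_id[:16],
            description=f"{organism} mitochondrial sequence",
            annotations={"molecule_type": molecule, "topology": "linear"},
        )
        rec.features.append(
            SeqFeature(SimpleLocation(0, len(seq), strand=1), type="source",
                       qualifiers={"organism": [organism]})
        )
        records[subject_id] = rec

    for feat in features:
        subjects = feat.subjects()
        multi = len(subjects) > 1
        for i, subject in enumerate(subjects, start=1):
            if subject not in records:
                raise AnnotationIOError(f"feature references unknown sequence {subject!r}")
            rec = records[subject]
            segs = [s for s in feat.segments if s[0] == subject]
            location = _location_for(segs, len(rec.seq))
            qualifiers: dict[str, list] = {"gene": [feat.gene]}
            if feat.pseudo:
                qualifiers["pseudo"] = [None]
            if feat.trans_spliced and feat.kind == "CDS":
                qualifiers["trans_splicing"] = [None]
            for raw in feat.qualifiers:
                key, value = _parse_qualifier(raw)
                qualifiers.setdefault(key, []).append(value)
            if multi and feat.kind == "CDS":
                qualifiers.setdefault("note", []).append(
                    f"trans-splicing partner (part {i} of {len(subjects)})"
                )
            if feat.kind == "CDS" and feat.translation is not None:
                qualifiers["translation"] = [feat.translation.rstrip("*")]
            rec.features.append(SeqFeature(location, type=feat.kind, qualifiers=qualifiers))

    with open(path, "w") as fh:
        SeqIO.write(list(records.values()), fh, "genbank")


def write_gff3(features: Iterable[FeatureRecord], handle: TextIO,
               source: str = "mitopcg") -> None:
    """Write gene and CDS rows; phase accumulates over CDS segments in
    exon-ordinal order, and trans-spliced parts share one feature ID."""
    handle.write("##gff-version 3\n")
    for feat in features:
        fid = f"{feat.kind.lower()}-{feat.gene}"
        attrs = [f"ID={fid}", f"gene={feat.gene}"]
        if feat.pseudo:
            attrs.append("pseudo=true")
        if feat.trans_spliced:
            attrs.append("trans_splicing=true")
        if feat.kind == "gene":
            for subject, start, end, strand in feat.segments:
                handle.write(
                    "\t".join(
                        [subject, source, "gene", str(start), str(end), ".",
                         strand, ".", ";".join(attrs)]
                    )
                    + "\n"
                )
        else:
            cumulative = 0
            for subject, start, end, strand in feat.segments:
                phase = (3 - cumulative % 3) % 3
                handle.write(
                    "\t".join(
                        [subject, source, "CDS", str(start), str(end), ".",
                         strand, str(phase), ";".join(attrs)]
                    )
                    + "\n"
                )
                cumulative += end - start + 1


def read_genbank_cds(path: str | Path) -> dict[str, str]:
    """Extract spliced, strand-resolved CDS sequence per gene name.

    ``join``/``complement`` locations are resolved by Biopython's
    feature extraction.  CDS features without a ``gene`` qualifier are
    skipped with a logged warning.  Multi-record trans-spliced genes
    marked with partner notes are reassembled in part order.
    """
    singles: dict[str, str] = {}
    parts: dict[str, dict[int, str]] = {}
    feature_index = 0
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            feature_index += 1
            gene_vals = feat.qualifiers.get("gene")
            if not gene_vals:
                logger.warning(
                    "CDS feature #%d in %s has no gene qualifier; skipped",
                    feature_index, rec.id,
                )
                continue
            gene = gene_vals[0]
            try:
                seq = str(feat.extract(rec.seq))
            except Exception as exc:  # malformed location
                raise AnnotationIOError(
                    f"CDS feature #{feature_index} ({gene}): bad location: {exc}"
                ) from exc
            part_no = None
            total = None
            for note in feat.qualifiers.get("note", []):
                m = _PART_RE.search(note or "")
                if m:
                    part_no, total = int(m.group(1)), int(m.group(2))
            if part_no is None:
                if gene in singles:
                    logger.warning("gene %s seen in multiple CDS features; keeping first", gene)
                else:
                    singles[gene] = seq
            else:
                parts.setdefault(gene, {})[part_no] = seq
    for gene, pieces in parts.items():
        singles[gene] = "".join(pieces[i] for i in sorted(pieces))
    return singles
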