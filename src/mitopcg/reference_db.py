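"""Curated reference library of mitochondrial protein-coding genes.

The library is the single source of truth for both annotation and
short-read recovery: for every gene it records the ordered exon
sequences, the expected exon count, codon peculiarities (RNA-edited
start/stop codons, non-canonical starts, a missing stop codon), known
pseudogene loci, and the intron-length thresholds used when splitting
transcripts of multi-exon genes.

The packaged *Rhodiola* library ships 30 protein-coding genes, seven of
which are multi-exon (nad1/nad2/nad5/nad7 with five exons, nad4 with
four, cox2 with three, ccmFc with two).  Exon sequences are synthetic
stand-ins generated deterministically from a fixed seed; they honour the
curated structure (exon counts and lengths, including the 22 bp nad5
micro-exon, and the ACG/CAA/ATT codon genotypes) without reproducing any
real accession.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ExonModel",
    "EditingSite",
    "GeneModel",
    "ReferenceLibrary",
    "ReferenceLibraryError",
    "build_rhodiola_library",
    "save_library",
    "load_library",
    "augment_with_flanks",
    "add_variant_form",
    "DEFAULT_INTRON_THRESHOLD",
    "DEFAULT_FLANK_LEN",
    "SMALL_EXON_CUTOFF",
]

DEFAULT_INTRON_THRESHOLD = 5000
DEFAULT_FLANK_LEN = 150
SMALL_EXON_CUTOFF = 30

STOP_CODONS = ("TAA", "TAG", "TGA")

_VALID_EFFECTS = {"start_gain", "stop_gain", "missense", "synonymous"}


class ReferenceLibraryError(ValueError):
    """Raised on structurally invalid library content."""


@dataclass(frozen=True)
class ExonModel:
    """One exon of a gene model (1-based ordinal within the gene)."""

    ordinal: int
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if self.ordinal < 1:
            raise ReferenceLibraryError(f"exon ordinal must be >= 1, got {self.ordinal}")
        if not self.sequence:
            raise ReferenceLibraryError("exon sequence must be non-empty")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ReferenceLibraryError(f"exon sequence contains invalid symbols {sorted(bad)}")


@dataclass(frozen=True)
class EditingSite:
    """A C-to-U RNA-editing site affecting a codon of the spliced CDS.

    ``cds_position`` is the 1-based offset of the edited codon's first
    base within the spliced CDS.  ``effect`` is one of ``start_gain``
    (ACG edited to a canonical AUG start), ``stop_gain`` (e.g. CAA
    edited to UAA), ``missense`` or ``synonymous``.
    """

    cds_position: int
    genomic_codon: str
    edited_codon: str
    effect: str
    amino_acid: str

    def __post_init__(self) -> None:
        if len(self.genomic_codon) != 3 or len(self.edited_codon) != 3:
            raise ReferenceLibraryError("editing-site codons must be 3 nt")
        for g, e in zip(self.genomic_codon, self.edited_codon):
            if g != e and not (g == "C" and e == "T"):
                raise ReferenceLibraryError(
                    f"editing {self.genomic_codon}->{self.edited_codon} is not C-to-U type"
                )
        if self.effect not in _VALID_EFFECTS:
            raise ReferenceLibraryError(f"unknown editing effect {self.effect!r}")
        if self.effect == "start_gain" and self.edited_codon != "ATG":
            raise ReferenceLibraryError("start_gain must edit to ATG")
        if self.effect == "stop_gain" and self.edited_codon not in STOP_CODONS:
            raise ReferenceLibraryError("stop_gain must edit to a stop codon")


@dataclass(frozen=True)
class GeneModel:
    """Reference model of one protein-coding gene.

    ``flank_pad`` > 0 means the exons listed in ``padded_ordinals``
    carry ``flank_pad`` bp of conserved flanking sequence on each side
    of the true exon (used to rescue micro-exons during homology
    search); the flanks are stripped whenever the spliced CDS is
    assembled.
    """

    name: str
    exons: tuple[ExonModel, ...]
    start_codon: str = "ATG"
    stop_codon: str = "TAA"  # literal "NONE" for stop-less genes
    editing_sites: tuple[EditingSite, ...] = ()
    trans_splicing_allowed: bool = False
    missing_stop: bool = False
    variant_forms: tuple[tuple[str, str], ...] = ()
    flank_pad: int = 0
    padded_ordinals: tuple[int, ...] = ()

    @property
    def expected_exon_count(self) -> int:
        return len(self.exons)

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1

    def exon(self, ordinal: int) -> ExonModel:
        for ex in self.exons:
            if ex.ordinal == ordinal:
                return ex
        raise KeyError(f"{self.name} has no exon {ordinal}")

    def core_sequence(self, ordinal: int) -> str:
        """Exon sequence with any appended flanks stripped."""
        ex = self.exon(ordinal)
        if self.flank_pad and ordinal in self.padded_ordinals:
            return ex.sequence[self.flank_pad : len(ex.sequence) - self.flank_pad]
        return ex.sequence

    def core_length(self, ordinal: int) -> int:
        return len(self.core_sequence(ordinal))

    def spliced_cds(self) -> str:
        """Concatenate exon cores in ordinal order."""
        return "".join(self.core_sequence(ex.ordinal) for ex in self.exons)

    def validate(self) -> None:
        ordinals = [ex.ordinal for ex in self.exons]
        if ordinals != list(range(1, len(ordinals) + 1)):
            missing = sorted(set(range(1, max(ordinals, default=0) + 1)) - set(ordinals))
            raise ReferenceLibraryError(
                f"gene {self.name}: exon ordinals not contiguous from 1 "
                f"(got {ordinals}, missing {missing})"
            )
        cds = self.spliced_cds()
        if not self.missing_stop and len(cds) % 3 != 0:
            raise ReferenceLibraryError(
                f"gene {self.name}: spliced CDS length {len(cds)} not a multiple of 3"
            )
        for site in self.editing_sites:
            if not 1 <= site.cds_position <= len(cds) - 2:
                raise ReferenceLibraryError(
                    f"gene {self.name}: editing site position {site.cds_position} "
                    f"outside CDS of length {len(cds)}"
                )
        labels = [label for label, _ in self.variant_forms]
        if len(labels) != len(set(labels)):
            raise ReferenceLibraryError(f"gene {self.name}: duplicate variant labels")


@dataclass
class ReferenceLibrary:
    """Gene models plus pseudogene loci and intron-length configuration."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    pseudogene_loci: frozenset[str] = frozenset()
    intron_thresholds: dict[str, int] = field(default_factory=dict)
    default_intron_threshold: int = DEFAULT_INTRON_THRESHOLD

    def __getitem__(self, name: str) -> GeneModel:
        return self.genes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.genes

    def __iter__(self):
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def gene_names(self) -> list[str]:
        return sorted(self.genes)

    def multi_exon_genes(self) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.is_multi_exon]

    def intron_threshold(self, gene: str) -> int:
        return self.intron_thresholds.get(gene, self.default_intron_threshold)

    def validate(self) -> None:
        for name, model in self.genes.items():
            if name != model.name:
                raise ReferenceLibraryError(f"gene keyed {name!r} is named {model.name!r}")
            model.validate()
        overlap = self.pseudogene_loci & set(self.genes)
        if overlap:
            raise ReferenceLibraryError(
                f"pseudogene loci overlap gene set: {sorted(overlap)}"
            )


# ---------------------------------------------------------------------------
# Packaged Rhodiola library
# ---------------------------------------------------------------------------

# (gene, total CDS length, exon lengths, start codon, stop codon, flags)
# Exon counts follow the curated Rhodiola gene structures: five exons for
# nad1/nad2/nad5/nad7, four for nad4, three for cox2, two for ccmFc; the
# nad5 model carries the genus' 22 bp micro-exon.  Codon genotypes: ACG
# starts of nad1/nad4L and the CAA stop of atp6 are restored by C-to-U
# editing; cob initiates at a non-canonical ATT; nad6 lacks a genomic
# stop codon and its 3' boundary is resolved by reference alignment.
_GENE_TABLE: list[dict] = [
    {"name": "atp1", "exons": [1524]},
    {"name": "atp4", "exons": [594]},
    {"name": "atp6", "exons": [720], "stop": "CAA", "stop_gain": True},
    {"name": "atp8", "exons": [480]},
    {"name": "atp9", "exons": [225]},
    {"name": "ccmB", "exons": [621]},
    {"name": "ccmC", "exons": [753]},
    {"name": "ccmFc", "exons": [772, 548]},
    {"name": "ccmFn", "exons": [1728]},
    {"name": "cob", "exons": [1182], "start": "ATT"},
    {"name": "cox1", "exons": [1584]},
    {"name": "cox2", "exons": [391, 230, 159]},
    {"name": "cox3", "exons": [798]},
    {"name": "matR", "exons": [1965]},
    {"name": "mttB", "exons": [780]},
    {"name": "nad1", "exons": [387, 192, 59, 245, 95], "start": "ACG",
     "start_gain": True, "trans": True},
    {"name": "nad2", "exons": [156, 391, 161, 518, 241], "trans": True},
    {"name": "nad3", "exons": [357]},
    {"name": "nad4", "exons": [461, 515, 413, 99]},
    {"name": "nad4L", "exons": [303], "start": "ACG", "start_gain": True},
    {"name": "nad5", "exons": [230, 1222, 22, 300, 236], "trans": True},
    {"name": "nad6", "exons": [619], "stop": "NONE", "missing_stop": True},
    {"name": "nad7", "exons": [143, 69, 467, 244, 262]},
    {"name": "nad9", "exons": [573]},
    {"name": "rpl5", "exons": [555]},
    {"name": "rpl10", "exons": [480]},
    {"name": "rpl16", "exons": [540]},
    {"name": "rps7", "exons": [447]},
    {"name": "rps12", "exons": [378]},
    {"name": "rps13", "exons": [351]},
]

_PSEUDOGENE_LOCI = frozenset({"rps4", "rps14", "sdh4"})

_LIBRARY_SEED = 20240601

# Sense codons of the standard code (no stops), used to synthesise
# internal-stop-free coding sequence.
_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


def _synth_cds(rng: random.Random, length: int, start: str, stop: str,
               missing_stop: bool) -> str:
    """Random in-frame CDS: start codon, sense codons, declared stop.

    For stop-less genes the trailing bases (up to a full frame plus a
    partial codon) are sense codons with no terminator.
    """
    if missing_stop:
        n_full = (length - 3) // 3
        tail = (length - 3) % 3
        body = "".join(rng.choice(_SENSE_CODONS) for _ in range(n_full))
        extra = "".join(rng.choice("ACGT") for _ in range(tail))
        return start + body + extra
    if length % 3 != 0:
        raise ReferenceLibraryError(f"CDS length {length} not a multiple of 3")
    n_mid = length // 3 - 2
    body = "".join(rng.choice(_SENSE_CODONS) for _ in range(n_mid))
    return start + body + stop


def _split_exons(cds: str, lengths: Iterable[int]) -> tuple[ExonModel, ...]:
    exons = []
    pos = 0
    for i, ln in enumerate(lengths, start=1):
        exons.append(ExonModel(ordinal=i, sequence=cds[pos : pos + ln]))
        pos += ln
    assert pos == len(cds)
    return tuple(exons)


def build_rhodiola_library(seed: int = _LIBRARY_SEED) -> ReferenceLibrary:
    """Build the packaged 30-gene *Rhodiola* reference library.

    Deterministic: two calls with the same seed produce equal libraries.
    """
    rng = random.Random(seed)
    genes: dict[str, GeneModel] = {}
    for spec in _GENE_TABLE:
        name = spec["name"]
        lengths = spec["exons"]
        total = sum(lengths)
        start = spec.get("start", "ATG")
        stop = spec.get("stop", "TAA")
        missing_stop = spec.get("missing_stop", False)
        cds = _synth_cds(rng, total, start, "" if stop == "NONE" else stop, missing_stop)
        sites: list[EditingSite] = []
        if spec.get("start_gain"):
            sites.append(EditingSite(1, start, "ATG", "start_gain", "M"))
        if spec.get("stop_gain"):
            pos = total - 2
            sites.append(EditingSite(pos, stop, "T" + stop[1:], "stop_gain", "TERM"))
        variants: tuple[tuple[str, str], ...] = ()
        if missing_stop:
            # Alternate-length reference forms used to pin the 3' boundary
            # of the stop-less gene by alignment score.
            short = cds[:519]
            variants = (("long", cds), ("short", short))
        model = GeneModel(
            name=name,
            exons=_split_exons(cds, lengths),
            start_codon=start,
            stop_codon=stop,
            editing_sites=tuple(sites),
            trans_splicing_allowed=spec.get("trans", False),
            missing_stop=missing_stop,
            variant_forms=variants,
        )
        model.validate()
        genes[name] = model
    lib = ReferenceLibrary(
        genes=genes,
        pseudogene_loci=_PSEUDOGENE_LOCI,
        intron_thresholds={},
        default_intron_threshold=DEFAULT_INTRON_THRESHOLD,
    )
    lib.validate()
    return lib


# ---------------------------------------------------------------------------
# Persistence: FASTA of exon sequences + structured YAML sidecar
# ---------------------------------------------------------------------------

_SIDECAR_TOP_KEYS = {
    "format", "version", "default_intron_threshold", "pseudogene_loci",
    "intron_thresholds", "genes",
}
_SIDECAR_GENE_KEYS = {
    "expected_exon_count", "start_codon", "stop_codon", "editing_sites",
    "trans_splicing", "missing_stop", "variant_forms", "flank_pad",
    "padded_exons",
}
_SIDECAR_SITE_KEYS = {
    "cds_position", "genomic_codon", "edited_codon", "effect", "amino_acid",
}


def _fasta_records(lib: ReferenceLibrary) -> list[SeqRecord]:
    records = []
    for name in lib.gene_names():
        model = lib[name]
        if model.is_multi_exon:
            for ex in model.exons:
                records.append(
                    SeqRecord(Seq(ex.sequence), id=f"{name}.exon{ex.ordinal}", description="")
                )
        else:
            records.append(SeqRecord(Seq(model.exons[0].sequence), id=name, description=""))
    return records


def save_library(lib: ReferenceLibrary, fasta_path: str | Path, sidecar_path: str | Path) -> None:
    """Persist a library as exon FASTA plus a canonical YAML sidecar."""
    lib.validate()
    SeqIO.write(_fasta_records(lib), str(fasta_path), "fasta")
    doc: dict = {
        "format": "mitopcg-reference-db",
        "version": 1,
        "default_intron_threshold": lib.default_intron_threshold,
        "pseudogene_loci": sorted(lib.pseudogene_loci),
        "intron_thresholds": dict(sorted(lib.intron_thresholds.items())),
        "genes": {},
    }
    for name in lib.gene_names():
        model = lib[name]
        doc["genes"][name] = {
            "expected_exon_count": model.expected_exon_count,
            "start_codon": model.start_codon,
            "stop_codon": model.stop_codon,
            "trans_splicing": model.trans_splicing_allowed,
            "missing_stop": model.missing_stop,
            "flank_pad": model.flank_pad,
            "padded_exons": list(model.padded_ordinals),
            "editing_sites": [
                {
                    "cds_position": s.cds_position,
                    "genomic_codon": s.genomic_codon,
                    "edited_codon": s.edited_codon,
                    "effect": s.effect,
                    "amino_acid": s.amino_acid,
                }
                for s in model.editing_sites
            ],
            "variant_forms": [
                {"label": label, "cds": cds} for label, cds in model.variant_forms
            ],
        }
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True, default_flow_style=False)


def load_library(fasta_path: str | Path, sidecar_path: str | Path) -> ReferenceLibrary:
    """Load a library persisted by :func:`save_library`.

    Structural problems (missing exon ordinal, duplicate gene, exon-count
    mismatch, unknown sidecar keys) raise :class:`ReferenceLibraryError`.
    """
    with open(sidecar_path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ReferenceLibraryError("sidecar is not a mapping")
    unknown = set(doc) - _SIDECAR_TOP_KEYS
    if unknown:
        raise ReferenceLibraryError(f"unknown sidecar keys: {sorted(unknown)}")
    if doc.get("format") != "mitopcg-reference-db":
        raise ReferenceLibraryError("sidecar format tag missing or unrecognised")

    # Exon sequences from FASTA, keyed (gene, ordinal)
    seqs: dict[str, dict[int, str]] = {}
    seen_ids: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen_ids:
            raise ReferenceLibraryError(f"duplicate FASTA record {rec.id}")
        seen_ids.add(rec.id)
        if ".exon" in rec.id:
            gene, _, tail = rec.id.partition(".exon")
            try:
                ordinal = int(tail)
            except ValueError as exc:
                raise ReferenceLibraryError(f"bad exon header {rec.id!r}") from exc
        else:
            gene, ordinal = rec.id, 1
        bucket = seqs.setdefault(gene, {})
        if ordinal in bucket:
            raise ReferenceLibraryError(f"duplicate exon record for {gene} exon {ordinal}")
        bucket[ordinal] = str(rec.seq).upper()

    genes: dict[str, GeneModel] = {}
    for name, meta in (doc.get("genes") or {}).items():
        unknown = set(meta) - _SIDECAR_GENE_KEYS
        if unknown:
            raise ReferenceLibraryError(f"gene {name}: unknown sidecar keys {sorted(unknown)}")
        if name not in seqs:
            raise ReferenceLibraryError(f"gene {name}: no FASTA records")
        bucket = seqs[name]
        expected = int(meta["expected_exon_count"])
        ordinals = sorted(bucket)
        if ordinals != list(range(1, max(ordinals) + 1)):
            missing = sorted(set(range(1, max(ordinals) + 1)) - set(ordinals))
            raise ReferenceLibraryError(
                f"gene {name}: missing exon ordinal(s) {missing}"
            )
        if len(ordinals) != expected:
            raise ReferenceLibraryError(
                f"gene {name}: sidecar declares {expected} exon(s) "
                f"but FASTA has {len(ordinals)}"
            )
        sites = []
        for raw in meta.get("editing_sites", []):
            unknown = set(raw) - _SIDECAR_SITE_KEYS
            if unknown:
                raise ReferenceLibraryError(
                    f"gene {name}: unknown editing-site keys {sorted(unknown)}"
                )
            sites.append(
                EditingSite(
                    cds_position=int(raw["cds_position"]),
                    genomic_codon=raw["genomic_codon"],
                    edited_codon=raw["edited_codon"],
                    effect=raw["effect"],
                    amino_acid=raw["amino_acid"],
                )
            )
        model = GeneModel(
            name=name,
            exons=tuple(ExonModel(i, bucket[i]) for i in ordinals),
            start_codon=meta.get("start_codon", "ATG"),
            stop_codon=meta.get("stop_codon", "TAA"),
            editing_sites=tuple(sites),
            trans_splicing_allowed=bool(meta.get("trans_splicing", False)),
            missing_stop=bool(meta.get("missing_stop", False)),
            variant_forms=tuple(
                (v["label"], v["cds"]) for v in meta.get("variant_forms", [])
            ),
            flank_pad=int(meta.get("flank_pad", 0)),
            padded_ordinals=tuple(meta.get("padded_exons", [])),
        )
        model.validate()
        genes[name] = model
    extra = set(seqs) - set(genes)
    if extra:
        raise ReferenceLibraryError(f"FASTA genes absent from sidecar: {sorted(extra)}")
    lib = ReferenceLibrary(
        genes=genes,
        pseudogene_loci=frozenset(doc.get("pseudogene_loci", [])),
        intron_thresholds=dict(doc.get("intron_thresholds", {})),
        default_intron_threshold=int(
            doc.get("default_intron_threshold", DEFAULT_INTRON_THRESHOLD)
        ),
    )
    lib.validate()
    return lib


# ---------------------------------------------------------------------------
# Flank augmentation and variant forms
# ---------------------------------------------------------------------------


def augment_with_flanks(
    model: GeneModel,
    genome_context: str,
    flank_len: int = DEFAULT_FLANK_LEN,
    small_exon_cutoff: int = SMALL_EXON_CUTOFF,
) -> GeneModel:
    """Append conserved flanking sequence to micro-exons of a gene model.

    Every exon shorter than ``small_exon_cutoff`` bp is located verbatim
    inside ``genome_context`` and extended by ``flank_len`` bp on each
    side, producing a search sequence long enough for homology search to
    pick up; the flanks are recorded in ``flank_pad``/``padded_ordinals``
    and stripped whenever the spliced CDS is assembled.
    """
    if flank_len == 0:
        return model
    if flank_len < 0:
        raise ReferenceLibraryError("flank_len must be >= 0")
    context = genome_context.upper()
    new_exons: list[ExonModel] = []
    padded: list[int] = []
    for ex in model.exons:
        core = model.core_sequence(ex.ordinal)
        if len(core) >= small_exon_cutoff:
            new_exons.append(ex)
            continue
        at = context.find(core)
        if at < 0:
            raise ReferenceLibraryError(
                f"{model.name} exon {ex.ordinal}: core sequence not found in context"
            )
        upstream = at
        downstream = len(context) - (at + len(core))
        if upstream < flank_len or downstream < flank_len:
            raise ReferenceLibraryError(
                f"{model.name} exon {ex.ordinal}: context supplies only "
                f"{upstream} bp upstream / {downstream} bp downstream "
                f"(need {flank_len} each side)"
            )
        padded_seq = context[at - flank_len : at + len(core) + flank_len]
        new_exons.append(ExonModel(ex.ordinal, padded_seq))
        padded.append(ex.ordinal)
    if not padded:
        return model
    out = replace(
        model,
        exons=tuple(new_exons),
        flank_pad=flank_len,
        padded_ordinals=tuple(padded),
    )
    out.validate()
    return out


def add_variant_form(
    lib: ReferenceLibrary, gene: str, label: str, cds: str
) -> ReferenceLibrary:
    """Return a library with an alternate full-CDS form added to a gene.

    Variant forms capture atypical boundary genotypes curated by hand;
    boundary resolution can later select among them by alignment score.
    """
    if gene not in lib:
        raise ReferenceLibraryError(f"unknown gene {gene!r}")
    if not cds:
        raise ReferenceLibraryError("variant CDS must be non-empty")
    model = lib[gene]
    if any(existing == label for existing, _ in model.variant_forms):
        raise ReferenceLibraryError(f"gene {gene}: variant label {label!r} already present")
    new_model = replace(model, variant_forms=model.variant_forms + ((label, cds.upper()),))
    genes = dict(lib.genes)
    genes[gene] = new_model
    return ReferenceLibrary(
        genes=genes,
        pseudogene_loci=lib.pseudogene_loci,
        intron_thresholds=dict(lib.intron_thresholds),
        default_intron_threshold=lib.default_intron_threshold,
    )
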