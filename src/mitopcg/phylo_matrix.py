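"""Concatenated supermatrix construction for ML phylogenetics.

Per-gene multiple alignments (produced externally, e.g. with MUSCLE or
MAFFT — alignment heuristics are deliberately pluggable) are reduced to
the genes shared by all samples and the outgroup, optionally pruned of
uninformative genes, and concatenated into a single partitioned matrix.
Missing regions may be filled from a conspecific sample, but only where
the region is completely conserved across the cohort — a conservative
rule that repairs technical artifacts without inventing variation.
The matrix is handed off to an external ML program (RAxML-style) as
relaxed PHYLIP + FASTA + partition file plus a ready-to-run command;
tree inference itself is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Supermatrix",
    "SupermatrixError",
    "FillRecord",
    "shared_genes",
    "concatenate",
    "fill_missing",
    "exclude_genes",
    "recommend_exclusions",
    "emit_phylo_handoff",
    "write_phylip",
    "read_phylip",
    "DEFAULT_MODEL",
    "DEFAULT_BOOTSTRAPS",
]

DEFAULT_MODEL = "GTR+GAMMA+I"
DEFAULT_BOOTSTRAPS = 1000
MISSING_CHARS = frozenset("-?")


class SupermatrixError(ValueError):
    pass


@dataclass(frozen=True)
class FillRecord:
    """Outcome of one gap-fill attempt."""

    taxon: str
    gene: str
    region: tuple[int, int]
    filled: bool
    donor: str | None
    reason: str


@dataclass
class Supermatrix:
    """Concatenated per-gene alignments with a partition map.

    ``partitions`` are (gene, start, end), 1-based inclusive, tiling
    1..L in concatenation order.
    """

    taxa: list[str]
    matrix: dict[str, str]
    partitions: list[tuple[str, int, int]]
    fill_log: list[FillRecord] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.matrix[self.taxa[0]]) if self.taxa else 0

    def validate(self) -> None:
        lengths = {len(s) for s in self.matrix.values()}
        if len(lengths) > 1:
            raise SupermatrixError(f"rows differ in length: {sorted(lengths)}")
        expect = 1
        for gene, start, end in self.partitions:
            if start != expect or end < start:
                raise SupermatrixError(
                    f"partition {gene} = {start}-{end} does not tile (expected start {expect})"
                )
            expect = end + 1
        if self.partitions and expect != self.length + 1:
            raise SupermatrixError(
                f"partitions end at {expect - 1}, matrix length {self.length}"
            )


def shared_genes(
    sample_gene_sets: Iterable[Iterable[str]],
    outgroup_gene_set: Iterable[str],
) -> list[str]:
    """Genes present in every sample and the outgroup, sorted by name."""
    sets = [set(s) for s in sample_gene_sets]
    if not sets:
        raise SupermatrixError("no sample gene sets given")
    shared = set(outgroup_gene_set)
    for s in sets:
        shared &= s
    if not shared:
        raise SupermatrixError("no gene shared by all samples and the outgroup")
    return sorted(shared)


def concatenate(
    per_gene_alignments: Mapping[str, Mapping[str, str]],
    gene_order: Sequence[str],
) -> Supermatrix:
    """Concatenate aligned genes in ``gene_order`` into a supermatrix."""
    if not gene_order:
        raise SupermatrixError("empty gene order")
    taxa: list[str] | None = None
    for gene in gene_order:
        if gene not in per_gene_alignments:
            raise SupermatrixError(f"no alignment for gene {gene!r}")
        aln = per_gene_alignments[gene]
        row_lengths = {len(s) for s in aln.values()}
        if len(row_lengths) != 1:
            raise SupermatrixError(f"gene {gene}: ragged alignment rows")
        if taxa is None:
            taxa = sorted(aln)
        elif sorted(aln) != taxa:
            missing = set(taxa) ^ set(aln)
            raise SupermatrixError(
                f"gene {gene}: taxon set mismatch involving {sorted(missing)}"
            )
    assert taxa is not None
    rows = {t: [] for t in taxa}
    partitions: list[tuple[str, int, int]] = []
    cursor = 1
    for gene in gene_order:
        aln = per_gene_alignments[gene]
        glen = len(next(iter(aln.values())))
        for t in taxa:
            rows[t].append(aln[t].upper())
        partitions.append((gene, cursor, cursor + glen - 1))
        cursor += glen
    matrix = Supermatrix(
        taxa=taxa,
        matrix={t: "".join(parts) for t, parts in rows.items()},
        partitions=partitions,
    )
    matrix.validate()
    return matrix


def default_species_of(taxon: str) -> str:
    """Species label = prefix before the first underscore."""
    return taxon.split("_", 1)[0]


def fill_missing(
    taxon: str,
    gene: str,
    region: tuple[int, int],
    cohort_alignment: Mapping[str, str],
    species_of: Callable[[str], str] = default_species_of,
) -> tuple[str | None, FillRecord]:
    """Fill a missing region of one taxon's gene row from a conspecific.

    The fill is permitted only when (a) a conspecific donor with the
    region present exists, and (b) every other taxon's non-missing
    sequence is identical over the region's columns (complete
    conservation).  Otherwise a refusal record is returned and the row
    is left untouched.  ``region`` is 1-based inclusive in alignment
    columns.
    """
    lo, hi = region
    row = cohort_alignment[taxon]
    if not 1 <= lo <= hi <= len(row):
        raise SupermatrixError(f"region {region} outside alignment of length {len(row)}")
    sl = slice(lo - 1, hi)

    def missing(segment: str) -> bool:
        return all(c in MISSING_CHARS for c in segment)

    others = {t: s for t, s in cohort_alignment.items() if t != taxon}
    present = {t: s[sl] for t, s in others.items() if not missing(s[sl])}
    if not present:
        record = FillRecord(taxon, gene, region, False, None,
                            "no cohort sequence covers the region")
        return None, record
    distinct = set(present.values())
    if len(distinct) > 1:
        record = FillRecord(taxon, gene, region, False, None,
                            "region is not completely conserved in the cohort")
        return None, record
    species = species_of(taxon)
    donors = sorted(t for t in present if species_of(t) == species)
    if not donors:
        record = FillRecord(taxon, gene, region, False, None,
                            "no conspecific donor covers the region")
        return None, record
    donor = donors[0]
    filled = row[: lo - 1] + present[donor] + row[hi:]
    record = FillRecord(taxon, gene, region, True, donor, "filled from conspecific donor")
    return filled, record


def exclude_genes(
    per_gene_alignments: Mapping[str, Mapping[str, str]],
    gene_names: Iterable[str],
) -> dict[str, Mapping[str, str]]:
    """Drop named genes before concatenation (e.g. highly conserved,
    phylogenetically uninformative ones)."""
    drop = set(gene_names)
    unknown = drop - set(per_gene_alignments)
    if unknown:
        raise SupermatrixError(f"cannot exclude unknown gene(s): {sorted(unknown)}")
    remaining = {g: a for g, a in per_gene_alignments.items() if g not in drop}
    if not remaining:
        raise SupermatrixError("excluding all genes leaves an empty matrix")
    return remaining


def recommend_exclusions(
    matrix: Supermatrix, max_missing_frac: float = 0.2
) -> list[str]:
    """Taxa whose missing fraction (after fills) exceeds the cutoff —
    candidates for removal before tree building."""
    flagged = []
    for taxon in matrix.taxa:
        row = matrix.matrix[taxon]
        miss = sum(1 for c in row if c in MISSING_CHARS)
        if matrix.length and miss / matrix.length > max_missing_frac:
            flagged.append(taxon)
    return flagged


# ---------------------------------------------------------------------------
# File handoff
# ---------------------------------------------------------------------------


def write_phylip(matrix: Supermatrix, path: str | Path) -> None:
    aln = MultipleSeqAlignment(
        SeqRecord(Seq(matrix.matrix[t]), id=t, description="") for t in matrix.taxa
    )
    AlignIO.write(aln, str(path), "phylip-relaxed")


def read_phylip(path: str | Path) -> dict[str, str]:
    aln = AlignIO.read(str(path), "phylip-relaxed")
    return {rec.id: str(rec.seq) for rec in aln}


def emit_phylo_handoff(
    matrix: Supermatrix,
    outdir: str | Path,
    model: str = DEFAULT_MODEL,
    bootstraps: int = DEFAULT_BOOTSTRAPS,
    seed: int = 12345,
    run_name: str = "mitopcg",
) -> dict[str, object]:
    """Write PHYLIP/FASTA/partition files and render the external ML
    command (not executed)."""
    matrix.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phy = outdir / "supermatrix.phy"
    fasta = outdir / "supermatrix.fasta"
    parts = outdir / "partitions.txt"
    write_phylip(matrix, phy)
    SeqIO.write(
        (SeqRecord(Seq(matrix.matrix[t]), id=t, description="") for t in matrix.taxa),
        str(fasta),
        "fasta",
    )
    with open(parts, "w") as fh:
        for gene, start, end in matrix.partitions:
            fh.write(f"DNA, {gene} = {start}-{end}\n")
    command = (
        f"raxmlHPC -f a -s {phy.name} -q {parts.name} -m {model} "
        f"-p {seed} -x {seed} -# {bootstraps} -n {run_name}"
    )
    return {"phylip": phy, "fasta": fasta, "partitions": parts, "command": command}
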