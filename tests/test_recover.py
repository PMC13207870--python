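"""Read-pair extraction (union rule), contig-based CDS reconstruction,
error logging, output organization, and variable-site counting."""

import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mitopcg.homology_map import reverse_complement, seeded_align
from mitopcg.recover import (
    EXON_SPLIT_ACROSS_CONTIGS,
    MISSING_EXON,
    RecoveredCDS,
    count_variable_sites,
    extract_read_pairs,
    organize_outputs,
    reconstruct_multi_exon,
    reconstruct_single_exon,
    recover_genes,
)
from mitopcg.reference_db import augment_with_flanks
from mitopcg.simulate import fragment_contigs, make_genome, simulate_reads


def _pair(name, seq1, seq2):
    r1 = SeqRecord(Seq(seq1), id=name, description="")
    r2 = SeqRecord(Seq(seq2), id=name, description="")
    return r1, r2


def _rand(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestExtractReadPairs:
    def test_union_rule_keeps_pair_when_one_mate_matches(self, library, rng):
        nad4 = library["nad4"].exons[0].sequence
        matching = nad4[100:250]
        junk = _rand(rng, 150)
        sets = extract_read_pairs([_pair("p1", matching, junk)], library)
        assert "nad4" in sets
        assert sets["nad4"].read_names == {"p1"}
        (r1, r2) = sets["nad4"].pairs[0]
        assert (str(r1.seq), str(r2.seq)) == (matching, junk)  # both mates kept

    def test_unmatched_pair_assigned_nowhere(self, library, rng):
        sets = extract_read_pairs([_pair("p1", _rand(rng, 150), _rand(rng, 150))], library)
        assert sets == {}

    def test_order_independence(self, library, rng):
        pairs = [
            _pair("a", library["cox1"].exons[0].sequence[:150], _rand(rng, 150)),
            _pair("b", _rand(rng, 150), library["atp9"].exons[0].sequence[:150]),
            _pair("c", library["cox1"].exons[0].sequence[300:450], _rand(rng, 150)),
        ]
        fwd = extract_read_pairs(pairs, library)
        rev = extract_read_pairs(list(reversed(pairs)), library)
        assert {g: s.read_names for g, s in fwd.items()} == \
            {g: s.read_names for g, s in rev.items()}

    def test_full_recall_against_simulator_truth(self, library):
        """Every simulated pair whose fragment overlaps the planted cox1
        locus by at least the matcher's minimum span is captured."""
        genome, manifest = make_genome(library, {"cox1": {}}, seed=5)
        exon = manifest.exons_for("cox1")[0]
        pairs = simulate_reads(genome, coverage=30, seed=5)
        truth = set()
        for r1, _ in pairs:
            _, chrom, lo, hi = r1.id.split("|")
            lo, hi = int(lo), int(hi)
            frag_len = hi - lo + 1
            # overlap of either mate's interval with the exon
            m1 = (lo, lo + 149)
            m2 = (hi - 149, hi)
            for a, b in (m1, m2):
                if min(b, exon.end) - max(a, exon.start) + 1 >= 50:
                    truth.add(r1.id)
                    break
        sets = extract_read_pairs(pairs, library)
        captured = sets["cox1"].read_names
        assert truth <= captured  # recall 1.0 against the truth manifest


class TestSingleExonReconstruction:
    def test_full_hit_recovers_gene_byte_identically(self, library, rng):
        model = library["rpl5"]
        gene_seq = model.spliced_cds()
        contig = _rand(rng, 200) + gene_seq + _rand(rng, 200)
        hits = seeded_align(gene_seq, contig, query_id="rpl5", subject_id="c1")
        cds, errors = reconstruct_single_exon(model, hits, {"c1": contig})
        assert errors == []
        assert cds.complete and cds.sequence == gene_seq

    def test_minus_strand_contig_is_reoriented(self, library, rng):
        model = library["rpl5"]
        gene_seq = model.spliced_cds()
        contig = _rand(rng, 100) + reverse_complement(gene_seq) + _rand(rng, 100)
        hits = seeded_align(gene_seq, contig, query_id="rpl5", subject_id="c1")
        cds, _ = reconstruct_single_exon(model, hits, {"c1": contig})
        assert cds.sequence == gene_seq

    def test_longest_alignment_wins(self, library, rng):
        model = library["rpl5"]
        gene_seq = model.spliced_cds()
        contigs = {
            "short": _rand(rng, 50) + gene_seq[:480] + _rand(rng, 50),
            "long": _rand(rng, 50) + gene_seq[:500] + _rand(rng, 50),
        }
        hits = []
        for cid, seq in contigs.items():
            hits += seeded_align(gene_seq, seq, query_id="rpl5", subject_id=cid)
        cds, _ = reconstruct_single_exon(model, hits, contigs)
        assert cds.source_contigs == ["long"]

    def test_truncated_contig_records_gap(self, library, rng):
        model = library["nad3"]  # 357 bp
        gene_seq = model.spliced_cds()
        contig = _rand(rng, 80) + gene_seq[:290]  # contig ends mid-gene
        hits = seeded_align(gene_seq, contig, query_id="nad3", subject_id="c1")
        cds, _ = reconstruct_single_exon(model, hits, {"c1": contig})
        assert not cds.complete
        assert cds.gaps == [(291, 357)]
        assert cds.sequence == gene_seq[:290]

    def test_no_hit_logs_missing_exon(self, library):
        cds, errors = reconstruct_single_exon(library["nad3"], [], {})
        assert cds is None
        assert [(e.gene, e.reason) for e in errors] == [("nad3", MISSING_EXON)]


class TestMultiExonReconstruction:
    @staticmethod
    def _hits_for(model, contigs):
        hits_by_exon = {}
        for ex in model.exons:
            hits_by_exon[ex.ordinal] = []
            for cid, seq in contigs.items():
                hits_by_exon[ex.ordinal] += seeded_align(
                    ex.sequence, seq,
                    query_id=f"{model.name}.exon{ex.ordinal}", subject_id=cid,
                )
        return hits_by_exon

    def test_exons_on_separate_contigs_recovered(self, library, rng):
        model = library["nad4"]
        contigs = {
            f"c{ex.ordinal}": _rand(rng, 60) + ex.sequence + _rand(rng, 60)
            for ex in model.exons
        }
        cds, errors = reconstruct_multi_exon(model, self._hits_for(model, contigs), contigs)
        assert errors == []
        assert cds.complete and cds.sequence == model.spliced_cds()
        assert cds.exon_provenance == {1: "c1", 2: "c2", 3: "c3", 4: "c4"}

    def test_split_exon_flagged_once_not_merged(self, library, rng):
        model = library["cox2"]
        ex2 = model.exons[1].sequence  # 230 bp, split 60/170 between contigs
        contigs = {
            "a": _rand(rng, 60) + model.exons[0].sequence + ex2[:60],
            "b": ex2[60:] + model.exons[2].sequence + _rand(rng, 60),
        }
        cds, errors = reconstruct_multi_exon(model, self._hits_for(model, contigs), contigs)
        split = [e for e in errors if e.reason == EXON_SPLIT_ACROSS_CONTIGS]
        assert [(e.gene, e.exon_ordinal) for e in split] == [("cox2", 2)]
        assert not cds.complete

    def test_missing_exon_leaves_gap_in_cds_coords(self, library, rng):
        model = library["cox2"]
        contigs = {
            "a": _rand(rng, 40) + model.exons[0].sequence + _rand(rng, 40),
            "c": _rand(rng, 40) + model.exons[2].sequence + _rand(rng, 40),
        }
        cds, errors = reconstruct_multi_exon(model, self._hits_for(model, contigs), contigs)
        assert [(e.exon_ordinal, e.reason) for e in errors] == [(2, MISSING_EXON)]
        lengths = [model.core_length(i) for i in (1, 2, 3)]
        assert cds.gaps == [(lengths[0] + 1, lengths[0] + lengths[1])]

    def test_micro_exon_recovered_only_via_flanks(self, library, rng):
        """The 22 bp nad5 exon is invisible to a >= 50 bp matcher on its
        own, but the 150+22+150 flank-augmented search sequence finds it
        and stripping returns exactly the 22 bp core."""
        base = library["nad5"]
        # genome context around the micro-exon: flanks + core + flanks
        up, down = _rand(rng, 200), _rand(rng, 200)
        core = base.core_sequence(3)
        context = up + core + down
        contigs = {"c": _rand(rng, 80) + context + _rand(rng, 80)}

        plain_hits = seeded_align(core, contigs["c"], min_length=50)
        assert plain_hits == []  # unaugmented search cannot pass the span filter

        model = augment_with_flanks(base, context)
        hits = {
            3: seeded_align(model.exon(3).sequence, contigs["c"],
                            query_id="nad5.exon3", subject_id="c", min_length=50)
        }
        # other exons absent on purpose; we check exon 3's recovered piece
        cds, errors = reconstruct_multi_exon(model, hits, contigs)
        assert cds.exon_provenance == {3: "c"}
        start = model.core_length(1) + model.core_length(2)
        piece_gaps = [g for g in cds.gaps if g[0] <= start + 1 <= g[1]]
        assert piece_gaps == []  # exon 3 itself fully covered
        assert cds.sequence == core


class TestEndToEndRecovery:
    def test_truth_contigs_recover_all_thirty_genes(self, library, full_genome):
        genome, manifest = full_genome
        contigs = fragment_contigs(genome, manifest)
        recovered, errors = recover_genes(library, contigs)
        assert len(recovered) == 30
        assert all(c.complete for c in recovered.values())
        identical = [
            g for g in recovered
            if recovered[g].sequence == manifest.planted_cds(library, g)
        ]
        assert len(identical) == 30
        assert errors == []

    def test_deliberate_break_yields_exactly_one_split_entry(self, library, full_genome):
        genome, manifest = full_genome
        contigs = fragment_contigs(genome, manifest, break_spec=[("cox2", 2, 100)])
        _, errors = recover_genes(library, contigs)
        split = [e for e in errors if e.reason == EXON_SPLIT_ACROSS_CONTIGS]
        assert [(e.gene, e.exon_ordinal) for e in split] == [("cox2", 2)]


class TestOutputsAndVariation:
    def _cds(self, gene, seq):
        return RecoveredCDS(gene=gene, sequence=seq, complete=True)

    def test_gene_and_sample_trees(self, tmp_path):
        samples = {
            "s1": {"atp1": self._cds("atp1", "ATG"), "cox1": self._cds("cox1", "CCC"),
                   "nad3": self._cds("nad3", "GGG")},
            "s2": {"atp1": self._cds("atp1", "ATT"), "cox1": self._cds("cox1", "CCA"),
                   "nad3": self._cds("nad3", "GGT")},
        }
        gene_dir, sample_dir = organize_outputs(samples, tmp_path)
        assert sorted(p.name for p in gene_dir.iterdir()) == \
            ["atp1.fasta", "cox1.fasta", "nad3.fasta"]
        assert sorted(p.name for p in sample_dir.iterdir()) == ["s1.fasta", "s2.fasta"]
        atp1 = (gene_dir / "atp1.fasta").read_text()
        assert atp1.count(">") == 2 and ">s1" in atp1

    def test_absent_gene_shrinks_gene_file(self, tmp_path):
        samples = {
            "s1": {"atp1": self._cds("atp1", "ATG")},
            "s2": {},
        }
        gene_dir, _ = organize_outputs(samples, tmp_path)
        assert (gene_dir / "atp1.fasta").read_text().count(">") == 1

    def test_rerun_is_byte_idempotent(self, tmp_path):
        samples = {"s1": {"atp1": self._cds("atp1", "ATGATG")}}
        gene_dir, _ = organize_outputs(samples, tmp_path)
        first = (gene_dir / "atp1.fasta").read_bytes()
        organize_outputs(samples, tmp_path)
        assert (gene_dir / "atp1.fasta").read_bytes() == first

    def test_variable_sites_counts_columns(self):
        assert count_variable_sites(["ACGT", "ACGT"]) == 0
        assert count_variable_sites(["ACGTAA", "ATGTCC"]) == 3
        assert count_variable_sites(["A-N", "T-N"]) == 1

    def test_gap_and_n_states_ignored(self):
        assert count_variable_sites(["A-", "T-"]) == 1
        assert count_variable_sites(["AN", "AN", "A-"]) == 0

    def test_ragged_rows_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            count_variable_sites(["ACGT", "ACG"])

    def test_agrees_with_per_column_scan(self, rng):
        for _ in range(30):
            n_rows = rng.randrange(2, 6)
            length = rng.randrange(1, 60)
            rows = [
                "".join(rng.choice("ACGT-N") for _ in range(length))
                for _ in range(n_rows)
            ]
            oracle = sum(
                1 for col in zip(*rows)
                if len(set(col) - {"-", "N", "?"}) >= 2
            )
            assert count_variable_sites(rows) == oracle
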