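"""RNA-editing qualifiers, non-canonical codon notes, missing-stop
boundary choice, translation, and internal-stop scanning."""

import pytest
from Bio.Seq import Seq

from mitopcg.codon_rules import (
    CodingAssembly,
    MissingGeneError,
    TranslationError,
    annotate_noncanonical,
    apply_editing_exceptions,
    longest_orf,
    resolve_missing_stop,
    scan_internal_stops,
    translate,
)
from mitopcg.reference_db import EditingSite, GeneModel, ExonModel, STOP_CODONS


def _assembly(gene, cds, positions=None):
    return CodingAssembly(
        gene=gene, cds=cds, protein=translate(cds),
        genomic_positions=tuple(positions) if positions else None,
    )


class TestTranslate:
    def test_standard_code(self):
        assert translate("ATGGCTTAA") == "MA*"

    def test_start_gain_exception_renders_met(self):
        assert translate("ACGGCTTAA", {1: "M"}) == "MA*"

    def test_trailing_partial_codon_dropped(self):
        assert translate("ATGGCTTA") == "MA"

    def test_n_codon_translates_to_x(self):
        assert translate("ATGNNNTAA") == "MX*"

    def test_bad_symbol_rejected(self):
        with pytest.raises(TranslationError):
            translate("ATGGCUTAA")

    def test_agrees_with_independent_codon_table(self, rng):
        """10,000 random codons against Biopython's translator."""
        codons = ["".join(rng.choice("ACGT") for _ in range(3)) for _ in range(10_000)]
        cds = "".join(codons)
        assert translate(cds) == str(Seq(cds).translate())


class TestEditingExceptions:
    def test_acg_start_gain_emits_met_qualifier(self):
        cds = "ACG" + "GCT" * 10 + "TAA"
        positions = list(range(101, 101 + len(cds)))
        asm = apply_editing_exceptions(
            _assembly("nad4L", cds, positions),
            [EditingSite(1, "ACG", "ATG", "start_gain", "M")],
        )
        assert asm.protein.startswith("M")
        assert asm.qualifiers == ("/transl_except=(pos:101..103,aa:Met)",)
        assert asm.cds == cds  # nucleotides never edited

    def test_no_sites_is_identity(self):
        cds = "ATG" + "GCT" * 10 + "TAA"
        asm = apply_editing_exceptions(_assembly("cox1", cds), [])
        assert asm.qualifiers == ()
        assert asm.protein == translate(cds)

    def test_caa_stop_gain_terminates_translation(self):
        cds = "ATG" + "GCT" * 10 + "CAA"
        positions = list(range(1, len(cds) + 1))
        site = EditingSite(len(cds) - 2, "CAA", "TAA", "stop_gain", "TERM")
        asm = apply_editing_exceptions(_assembly("atp6", cds, positions), [site])
        assert asm.qualifiers[0].endswith("aa:TERM)")
        assert asm.protein.endswith("*")
        assert "Q" not in asm.protein[-1:]  # no 3' extension past the stop

    def test_minus_strand_positions_emit_ascending_range(self):
        cds = "ACG" + "GCT" * 3 + "TAA"
        positions = list(range(500, 500 - len(cds), -1))
        asm = apply_editing_exceptions(
            _assembly("nad1", cds, positions),
            [EditingSite(1, "ACG", "ATG", "start_gain", "M")],
        )
        assert asm.qualifiers == ("/transl_except=(pos:498..500,aa:Met)",)

    def test_out_of_range_site_rejected(self):
        with pytest.raises(ValueError, match="outside CDS"):
            apply_editing_exceptions(
                _assembly("x", "ATGTAA"),
                [EditingSite(7, "CAA", "TAA", "stop_gain", "TERM")],
            )


def _model(name, cds, **kw):
    return GeneModel(name=name, exons=(ExonModel(1, cds),), **kw)


class TestNonCanonical:
    def test_cob_att_note_byte_exact(self):
        cds = "ATT" + "GCT" * 8 + "TAA"
        model = _model("cob", cds, start_codon="ATT")
        asm = annotate_noncanonical(_assembly("cob", cds), model)
        assert asm.qualifiers == (
            "/note=Translation initiates from a non-canonical ATT start codon.",
        )
        assert asm.protein.startswith("M")

    def test_gtg_start_note(self):
        cds = "GTG" + "GCT" * 8 + "TAA"
        model = _model("atp8", cds, start_codon="GTG")
        asm = annotate_noncanonical(_assembly("atp8", cds), model)
        assert asm.qualifiers == (
            "/note=Translation initiates from a non-canonical GTG start codon.",
        )

    def test_gga_stop_note(self):
        cds = "ATG" + "GCT" * 8 + "GGA"
        model = _model("cox1", cds, stop_codon="GGA", missing_stop=False)
        asm = annotate_noncanonical(_assembly("cox1", cds), model)
        assert asm.qualifiers == (
            "/note=Translation terminates at a non-canonical GGA stop codon.",
        )
        assert asm.protein.endswith("*")

    def test_declared_codon_mismatch_warns(self):
        cds = "ATG" + "GCT" * 8 + "TAA"  # actually canonical
        model = _model("cob", cds, start_codon="ATT")
        asm = annotate_noncanonical(_assembly("cob", cds), model)
        assert asm.warnings
        assert any(q.startswith("/note=WARNING") for q in asm.qualifiers)

    def test_edited_start_left_to_editing_module(self):
        cds = "ACG" + "GCT" * 8 + "TAA"
        model = _model(
            "nad4L", cds, start_codon="ACG",
            editing_sites=(EditingSite(1, "ACG", "ATG", "start_gain", "M"),),
        )
        asm = annotate_noncanonical(_assembly("nad4L", cds), model)
        assert asm.qualifiers == ()


def brute_force_longest_orf(seq):
    best = 0
    for frame in range(3):
        codons = [seq[i:i + 3] for i in range(frame, len(seq) - 2, 3)]
        for i, c in enumerate(codons):
            if c != "ATG":
                continue
            length = 0
            for c2 in codons[i:]:
                length += 3
                if c2 in STOP_CODONS:
                    break
            best = max(best, length)
    return best


class TestMissingStopBoundary:
    def _region(self, rng, core):
        pad = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
        return pad(120) + core + pad(120)

    def test_highest_scoring_form_wins(self, library, rng):
        model = library["nad6"]
        full = model.spliced_cds()
        region = self._region(rng, full)
        boundary, note = resolve_missing_stop("nad6", region, model)
        assert note.chosen_label in ("reference", "long")
        assert boundary == 120 + len(full)

    def test_score_tie_broken_by_longest_orf(self, rng):
        base = "ATG" + "GCT" * 60              # shared 183 bp prefix
        a = base + "TAA" + "GCT" * 10          # ORF ends at the early stop
        b = base + "GCT" * 11                  # same length, stop-free ORF
        assert len(a) == len(b)
        assert longest_orf(b) > longest_orf(a)
        model = GeneModel(
            name="toy", exons=(ExonModel(1, a),), missing_stop=True,
            variant_forms=(("stops-early", a), ("runs-long", b)),
        )
        # region contains only the shared prefix: both variants align with
        # identical score, so the ORF tie-break must decide
        region = self._region(rng, base)
        _, note = resolve_missing_stop("toy", region, model)
        assert note.chosen_label == "runs-long"

    def test_planted_deletion_boundary_matches_orf_scan(self, library, rng):
        """A single-nucleotide deletion partway through the gene shifts the
        frame; the longest-ORF rule picks the form matching the exhaustive
        ORF scan."""
        model = library["nad6"]
        full = model.spliced_cds()
        mutated = full[:400] + full[401:]  # deletion after 400 bp
        region = self._region(rng, mutated)
        boundary, note = resolve_missing_stop("nad6", region, model)
        forms = dict((("reference", full),) + model.variant_forms)
        chosen = forms[note.chosen_label]
        assert longest_orf(chosen) == brute_force_longest_orf(chosen)
        assert boundary <= 120 + len(mutated)

    def test_permutation_invariant_in_variant_list(self, library, rng):
        model = library["nad6"]
        region = self._region(rng, model.spliced_cds())
        from dataclasses import replace

        flipped = replace(model, variant_forms=tuple(reversed(model.variant_forms)))
        assert resolve_missing_stop("nad6", region, model) == \
            resolve_missing_stop("nad6", region, flipped)

    def test_nothing_aligns_is_missing_gene(self, library, rng):
        model = library["nad6"]
        junk = "".join(rng.choice("ACGT") for _ in range(800))
        with pytest.raises(MissingGeneError):
            resolve_missing_stop("nad6", junk, model)


class TestInternalStops:
    def test_premature_taa_reported_with_codon_index(self):
        cds = "ATG" + "GCT" * 71 + "TAA" + "GCT" * 20 + "TAA"
        assert scan_internal_stops(cds) == [(73, "TAA")]

    def test_terminal_stop_only_is_clean(self):
        assert scan_internal_stops("ATGGCTGCTTAA") == []

    def test_agrees_with_naive_triplet_scan(self, rng):
        for _ in range(50):
            n = rng.randrange(2, 120)
            cds = "".join(rng.choice("ACGT") for _ in range(3 * n))
            naive = [
                (i + 1, cds[i * 3:i * 3 + 3])
                for i in range(n - 1)
                if cds[i * 3:i * 3 + 3] in STOP_CODONS
            ]
            assert scan_internal_stops(cds) == naive
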