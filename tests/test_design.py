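"""PAM scanning, stop-edit enumeration and knockout design tests."""

import pytest

from bestop.design import (
    EditingWindow,
    PamSpec,
    PAM_PRESETS,
    classify_hit,
    design_knockouts,
    scan_pam_sites,
    stop_edits_for_protospacer,
)
from bestop.genome import AnnotatedGenome, CdsRecord
from bestop.simulate import (
    SyntheticGenomeSpec,
    generate_annotated_genome,
    plant_stop_protospacer,
)

from _oracles import brute_design, brute_pam_sites, rc

NGG = PAM_PRESETS["NGG"]
NG = PAM_PRESETS["NG"]


class TestScanPamSites:
    def test_direct_pattern_match_linear(self):
        g = AnnotatedGenome("x", "AAAGGA")
        sites = scan_pam_sites(g, PamSpec("t", "NGG", spacer_length=2))
        plus = [s for s in sites if s.strand == "+"]
        assert len(plus) == 1
        assert plus[0].pam_seq(g) == "AGG"
        assert plus[0].protospacer_seq(g) == "AA"

    def test_pattern_subsumption(self, small_genome):
        ngg = {(s.proto_start0, s.strand) for s in scan_pam_sites(small_genome, NGG)}
        ng = {(s.proto_start0, s.strand) for s in scan_pam_sites(small_genome, NG)}
        assert ngg <= ng

    @pytest.mark.parametrize("pattern", ["NGG", "NG", "NAA", "NRG"])
    def test_oracle_equality(self, small_genome, pattern):
        pam = PamSpec(pattern, pattern)
        got = {(s.proto_start0, s.strand) for s in scan_pam_sites(small_genome, pam)}
        assert got == brute_pam_sites(small_genome, pattern)

    def test_oracle_equality_linear(self, linear_genome):
        got = {(s.proto_start0, s.strand) for s in scan_pam_sites(linear_genome, NGG)}
        assert got == brute_pam_sites(linear_genome, "NGG")

    def test_circular_origin_spanning_site(self):
        # PAM wraps the origin: ...AG | G at position 0
        g = AnnotatedGenome("x", "GGTTTTTTTTTTTTTTTTTTTTTTTTTA", circular=True)
        got = {(s.proto_start0, s.strand) for s in scan_pam_sites(g, NGG)}
        assert got == brute_pam_sites(g, "NGG")
        # the protospacer+PAM block extends past the origin
        assert any(start + 23 > len(g) for start, strand in got)

    def test_ambiguous_base_never_matches(self):
        g = AnnotatedGenome("x", "T" * 25 + "ANG" + "T" * 5)
        assert all(s.pam_seq(g) != "ANG" for s in scan_pam_sites(g, NGG))


class TestStopEdits:
    def test_sense_caa_to_taa_at_minus_17(self):
        # 20-nt guide with its CAA codon in frame: the single window C sits at
        # -17 and converts CAA -> TAA
        edits = stop_edits_for_protospacer("aaacaagcaattgttccgtt", "sense", 0)
        assert [(e.edited_offsets, e.wt_codon, e.mutant_codon) for e in edits] == \
            [((-17,), "CAA", "TAA")]

    def test_antisense_cca_three_stop_subsets(self):
        # antisense guide over a coding-strand TGG: editing either or both of
        # the CCA cytosines gives TGA, TAG or TAA
        edits = stop_edits_for_protospacer("ctccagtcaggtgttgtgca", "antisense", 0)
        got = {(e.edited_offsets, e.mutant_codon) for e in edits}
        assert got == {((-18,), "TGA"), ((-17,), "TAG"), ((-18, -17), "TAA")}
        assert all(e.wt_codon == "TGG" for e in edits)

    def test_no_window_c_empty(self):
        assert stop_edits_for_protospacer("G" * 20, "sense", 0) == []

    def test_deterministic_order(self):
        edits = stop_edits_for_protospacer("ctccagtcaggtgttgtgca", "antisense", 0)
        keys = [(e.codon_index, len(e.edited_offsets), e.edited_offsets) for e in edits]
        assert keys == sorted(keys)

    def test_invalid_frame_offset(self):
        with pytest.raises(ValueError):
            stop_edits_for_protospacer("A" * 20, "sense", 3)

    def test_selectable_wider_window(self):
        # a C at -20 only qualifies under the wider window
        proto = "CAAAAAAAAAAAAAAAAAAA"
        assert stop_edits_for_protospacer(proto, "sense", 0) == []
        edits = stop_edits_for_protospacer(proto, "sense", 0,
                                           window=EditingWindow(-20, -16))
        assert [(e.edited_offsets, e.mutant_codon) for e in edits] == [((-20,), "TAA")]


class TestDesignKnockouts:
    def test_planted_hit_recovered_exactly(self, at_genome):
        g, entry = plant_stop_protospacer(at_genome, "SYN_0002", "sense", -18, 7)
        hits = design_knockouts(g, NGG)
        assert len(hits) == 1
        h = hits[0]
        assert (h.genome_start, h.protospacer_strand, h.cds_id) == \
            (entry.genome_start, entry.strand, "SYN_0002")
        assert h.window_c_offsets == (-18,)
        assert h.quality == "clean"
        assert h.protospacer_seq == entry.protospacer_seq

    def test_threshold_boundary(self, at_genome):
        g, entry = plant_stop_protospacer(at_genome, "SYN_0003", "sense", -18, 9,
                                          allow_beyond=True)
        assert entry.cds_fraction > 0.75
        assert design_knockouts(g, NGG, first_fraction=0.75) == []
        late = design_knockouts(g, NGG, first_fraction=1.0)
        assert [h.cds_id for h in late] == ["SYN_0003"]

    @pytest.mark.parametrize("pattern", ["NGG", "NG"])
    def test_oracle_equality(self, small_genome, pattern):
        pam = PamSpec(pattern, pattern)
        got = {(h.genome_start, h.protospacer_strand, h.cds_id)
               for h in design_knockouts(small_genome, pam)}
        assert got == brute_design(small_genome, pattern)

    def test_oracle_equality_single_c_mode(self, small_genome):
        got = {(h.genome_start, h.protospacer_strand, h.cds_id)
               for h in design_knockouts(small_genome, NGG, single_only=True)}
        assert got == brute_design(small_genome, "NGG", single_only=True)

    def test_pattern_monotonicity(self, small_genome):
        ngg = {(h.genome_start, h.protospacer_strand, h.cds_id)
               for h in design_knockouts(small_genome, NGG)}
        ng = {(h.genome_start, h.protospacer_strand, h.cds_id)
              for h in design_knockouts(small_genome, NG)}
        assert ngg <= ng

    def test_stop_edit_substitution_validates(self, small_genome):
        """Applying any reported edit subset to the CDS yields the stop codon."""
        hits = design_knockouts(small_genome, NG)
        recs = {f.id: f for f in small_genome.features}
        assert hits
        for h in hits:
            rec = recs[h.cds_id]
            for e in h.stop_edits:
                assert rec.coding_sequence[3 * e.codon_index:3 * e.codon_index + 3] \
                    == e.wt_codon
                assert e.mutant_codon in ("TAA", "TAG", "TGA")

    def test_strand_mirror(self, small_genome):
        n = len(small_genome)
        mirrored = AnnotatedGenome(
            small_genome.id, rc(small_genome.sequence), small_genome.circular,
            [CdsRecord(f.id, n - f.end + 1, n - f.start + 1,
                       "-" if f.strand == "+" else "+", f.coding_sequence,
                       f.pseudo_flag)
             for f in small_genome.features],
        )
        fwd = design_knockouts(small_genome, NGG)
        mir = design_knockouts(mirrored, NGG)
        key_fwd = {((n - (h.genome_start - 1) - 20) % n + 1, h.cds_id,
                    "-" if h.protospacer_strand == "+" else "+") for h in fwd}
        key_mir = {(h.genome_start, h.cds_id, h.protospacer_strand) for h in mir}
        assert key_fwd == key_mir

    def test_no_cds_warns_and_returns_empty(self):
        g = AnnotatedGenome("x", "ACGT" * 30)
        with pytest.warns(UserWarning):
            assert design_knockouts(g, NGG) == []


class TestClassifyHit:
    @pytest.mark.parametrize("offsets,label", [
        ((-18,), "clean"),
        ((-19,), "clean"),
        ((-18, -17), "multi_C"),
        ((-19, -18, -16), "multi_C"),
        ((-16,), "window_edge"),
        ((-17,), "window_edge"),
    ])
    def test_quality_labels(self, offsets, label):
        from types import SimpleNamespace

        assert classify_hit(SimpleNamespace(window_c_offsets=offsets)) == label
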