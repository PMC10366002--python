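"""Bulge-aware off-target search, variant association and alignment fallback."""

import numpy as np
import pytest

from bestop.genome import AnnotatedGenome, CdsRecord
from bestop.offtarget import (
    OffTargetQuery,
    VariantRecord,
    associate_variants,
    generate_query_variants,
    genes_in_region,
    local_align_fallback,
    read_variants,
    search_offtargets,
    variant_context,
)
from bestop.simulate import (
    generate_variants,
    plant_offtarget_site,
    write_vcf,
)

from _oracles import (
    brute_offtargets,
    brute_rna_bulge_patterns,
    rc,
    smith_waterman_score,
)

SPACER = "GACTTAGCCGATTGTTCAAC"


class TestQueryVariants:
    def test_no_bulges_single_variant(self):
        q = OffTargetQuery("q", SPACER, max_dna_bulge=0, max_rna_bulge=0)
        vs = generate_query_variants(q)
        assert len(vs) == 1 and vs[0].pattern == SPACER

    @pytest.mark.parametrize("spacer", [SPACER, "AAAACCCCGGGGTTTTAAAA", "ATATATATATATATATATAT"])
    def test_rna_bulge_count_matches_dedup_enumeration(self, spacer):
        q = OffTargetQuery("q", spacer, max_dna_bulge=0, max_rna_bulge=1)
        got = {v.pattern for v in generate_query_variants(q) if v.bulge_type == "RNA"}
        want = brute_rna_bulge_patterns(spacer, 1) - {spacer}
        assert got == want

    def test_terminal_bulges_excluded(self):
        q = OffTargetQuery("q", SPACER, max_dna_bulge=2, max_rna_bulge=2)
        for v in generate_query_variants(q):
            if v.bulge_type == "RNA":
                assert 1 <= v.bulge_pos and v.bulge_pos + v.bulge_size <= len(SPACER) - 1
            elif v.bulge_type == "DNA":
                assert v.pattern[0] != "N" and v.pattern[-1] != "N"

    def test_deterministic(self):
        q = OffTargetQuery("q", SPACER)
        assert generate_query_variants(q) == generate_query_variants(q)


class TestSearchOfftargets:
    def test_exact_planted_site(self, at_genome):
        g, entry = plant_offtarget_site(at_genome, SPACER, 0, "none", 0, seed=1)
        q = OffTargetQuery("q", SPACER, "NGG", 0, 0, 0)
        sites = search_offtargets(g, q)
        assert [(s.genome_position, s.strand, s.mismatches) for s in sites] == \
            [(entry.genome_position, entry.strand, 0)]

    def test_two_mismatch_site_found_then_lost(self, at_genome):
        g, entry = plant_offtarget_site(at_genome, SPACER, 2, "none", 0, seed=2)
        hit2 = search_offtargets(g, OffTargetQuery("q", SPACER, "NGG", 2, 0, 0))
        assert any(s.genome_position == entry.genome_position
                   and s.mismatches == 2 for s in hit2)
        hit1 = search_offtargets(g, OffTargetQuery("q", SPACER, "NGG", 1, 0, 0))
        assert all(s.genome_position != entry.genome_position for s in hit1)

    def test_zero_limits_equal_naive_exact_scan(self, small_genome):
        # plant one exact occurrence so the comparison is not vacuous
        g, _ = plant_offtarget_site(small_genome, SPACER, 0, "none", 0, seed=3)
        q = OffTargetQuery("q", SPACER, "NGG", 0, 0, 0)
        got = {(s.genome_position, s.strand) for s in search_offtargets(g, q)}
        naive = set()
        n = len(g)
        for strand in "+-":
            s = g.sequence if strand == "+" else rc(g.sequence)
            s2 = s + s[: len(SPACER) + 3] if g.circular else s
            hi = n if g.circular else n - len(SPACER) - 2
            for p in range(max(hi, 0)):
                if s2[p:p + 20] == SPACER and s2[p + 21:p + 23] == "GG":
                    if strand == "+":
                        naive.add((p % n + 1, "+"))
                    else:
                        naive.add(((n - p - 20) % n + 1, "-"))
        assert got == naive and got

    @pytest.mark.parametrize("profile", [
        (1, "none", 0), (2, "RNA", 1), (1, "DNA", 1), (3, "RNA", 2), (2, "DNA", 2),
    ])
    def test_planted_profile_recovered(self, at_genome, profile):
        mm, btype, bsize = profile
        g, entry = plant_offtarget_site(at_genome, SPACER, mm, btype, bsize,
                                        seed=10 + mm + bsize)
        q = OffTargetQuery("q", SPACER, "NGG", mm,
                           bsize if btype == "DNA" else 0,
                           bsize if btype == "RNA" else 0)
        sites = [s for s in search_offtargets(g, q)
                 if s.genome_position == entry.genome_position
                 and s.strand == entry.strand]
        assert len(sites) == 1
        s = sites[0]
        assert (s.mismatches, s.bulge_type, s.bulge_size) == profile

    def test_monotone_in_limits(self, small_genome):
        keys = []
        for mm in (2, 4, 6):
            q = OffTargetQuery("q", SPACER, "NG", mm, 1, 1)
            keys.append({(s.genome_position, s.strand)
                         for s in search_offtargets(small_genome, q)})
        assert keys[0] <= keys[1] <= keys[2]

    def test_oracle_equality_with_bulges(self, small_genome):
        q = OffTargetQuery("q", SPACER, "NGG", 3, 1, 1)
        got = {(s.genome_position, s.strand): (s.mismatches, s.bulge_type, s.bulge_size)
               for s in search_offtargets(small_genome, q)}
        assert got == brute_offtargets(small_genome, SPACER, "NGG", 3, 1, 1)

    def test_oracle_equality_linear(self, linear_genome):
        q = OffTargetQuery("q", SPACER, "NG", 3, 1, 1)
        got = {(s.genome_position, s.strand): (s.mismatches, s.bulge_type, s.bulge_size)
               for s in search_offtargets(linear_genome, q)}
        assert got == brute_offtargets(linear_genome, SPACER, "NG", 3, 1, 1)

    def test_sites_revalidate_from_alignment(self, small_genome):
        q = OffTargetQuery("q", SPACER, "NG", 5, 2, 2)
        for s in search_offtargets(small_genome, q)[:200]:
            assert len(s.aligned_query) == len(s.aligned_target)
            recomputed = sum(
                a != b for a, b in zip(s.aligned_query, s.aligned_target)
                if a != "-" and b != "-"
            )
            assert recomputed == s.mismatches
            # degapped target is the genomic substring (strand-oriented)
            degapped = s.aligned_target.replace("-", "")
            start0 = s.genome_position - 1
            fwd = small_genome.fetch(start0, start0 + len(degapped))
            assert degapped == (fwd if s.strand == "+" else rc(fwd))

    def test_raw_counts_at_least_primary(self, small_genome):
        q = OffTargetQuery("q", SPACER, "NGG", 4, 1, 1)
        raw = search_offtargets(small_genome, q, mode="raw")
        primary = search_offtargets(small_genome, q, mode="primary")
        assert len(raw) >= len(primary)
        assert {(s.genome_position, s.strand) for s in raw} == \
            {(s.genome_position, s.strand) for s in primary}

    def test_bad_spacer_rejected(self):
        with pytest.raises(ValueError):
            OffTargetQuery("q", "ACGTACGTACGTACGTACGN")


@pytest.fixture(scope="module")
def planted(at_genome):
    g, entry = plant_offtarget_site(at_genome, SPACER, 1, "none", 0, seed=21)
    q = OffTargetQuery("q1", SPACER, "NGG", 1, 0, 0)
    sites = search_offtargets(g, q)
    return g, entry, sites


class TestAssociation:
    def test_boundary_inclusive_at_threshold(self, planted):
        g, entry, sites = planted
        variants, ledger = generate_variants(g, [entry], distances=(0, 50, 51),
                                             n_background=2, seed=5)
        assoc = associate_variants(sites, variants, max_distance=50)
        by_pos = {a.variant.pos: a.distance for a in assoc}
        for entry_v in ledger:
            if entry_v.distance in (0, 50):
                assert by_pos[entry_v.pos] == entry_v.distance
            else:  # 51 or background
                assert entry_v.pos not in by_pos

    def test_variant_inside_site_distance_zero(self, planted):
        g, entry, sites = planted
        v = VariantRecord(g.id, entry.genome_position, g.sequence[entry.genome_position - 1], "T")
        assoc = associate_variants(sites, [v])
        assert any(a.distance == 0 for a in assoc)

    def test_variant_may_associate_with_multiple_sites(self):
        site_args = dict(query_label="q", strand="+", mismatches=0,
                         bulge_type="none", bulge_size=0,
                         aligned_target="A" * 20, aligned_query="A" * 20)
        from bestop.offtarget import OffTargetSite

        s1 = OffTargetSite(genome_position=100, **site_args)
        s2 = OffTargetSite(genome_position=140, **site_args)
        v = VariantRecord("x", 130, "A", "T")
        assoc = associate_variants([s1, s2], [v], max_distance=50)
        assert len(assoc) == 2

    def test_vcf_roundtrip_and_ref_check(self, planted, tmp_path):
        g, entry, _ = planted
        variants, _ = generate_variants(g, [entry], distances=(10,), seed=9)
        path = str(tmp_path / "v.vcf")
        write_vcf(variants, g, path)
        back = read_variants(path, g)
        assert [(v.pos, v.ref, v.alt) for v in back] == \
            [(v.pos, v.ref, v.alt) for v in sorted(variants, key=lambda v: v.pos)]
        bad = [VariantRecord(g.id, v.pos, "N" if v.ref != "N" else "A", v.alt)
               for v in variants[:1]]
        write_vcf(bad, g, str(tmp_path / "bad.vcf"))
        with pytest.raises(ValueError, match="does not match"):
            read_variants(str(tmp_path / "bad.vcf"), g)


class TestLocalAlignFallback:
    def test_verbatim_spacer_full_length(self, at_genome):
        g, entry = plant_offtarget_site(at_genome, SPACER, 0, "none", 0, seed=31)
        v = VariantRecord(g.id, entry.genome_position + 5,
                          g.sequence[entry.genome_position + 4], "T")
        ctx = variant_context(g, v)
        assert len(ctx) == 41
        rep = local_align_fallback(SPACER, ctx)
        assert rep is not None
        assert rep.matches == 20 and rep.mismatches == 0 and rep.gaps == 0

    def test_reverse_orientation_found(self):
        ctx = "T" * 10 + rc(SPACER) + "T" * 11
        rep = local_align_fallback(SPACER, ctx)
        assert rep is not None and rep.strand == "-" and rep.matches == 20

    def test_score_matches_dp_oracle(self):
        rng = np.random.RandomState(17)
        bases = "ACGT"
        for _ in range(10):
            ctx = "".join(bases[i] for i in rng.randint(0, 4, size=41))
            rep = local_align_fallback(SPACER, ctx, min_matches=0)
            want = max(smith_waterman_score(ctx, SPACER),
                       smith_waterman_score(ctx, rc(SPACER)))
            assert rep is not None
            assert rep.score == pytest.approx(want)

    def test_threshold_suppresses_weak_matches(self):
        ctx = "T" * 41  # spacer shares only scattered T's with this context
        assert local_align_fallback(SPACER, ctx, min_matches=11) is None

    def test_short_context_rejected(self):
        with pytest.raises(ValueError):
            local_align_fallback(SPACER, "ACGT")


class TestGenesInRegion:
    def test_whole_containment_only(self):
        feats = [
            CdsRecord("inside", 120, 200, "+", "A" * 81),
            CdsRecord("straddles_left", 80, 150, "+", "A" * 71),
            CdsRecord("straddles_right", 900, 1060, "+", "A" * 161),
            CdsRecord("outside", 1200, 1300, "+", "A" * 101),
            CdsRecord("at_edges", 100, 1000, "+", "A" * 901),
        ]
        g = AnnotatedGenome("x", "A" * 1500, features=feats)
        got = [r.id for r in genes_in_region(g, start=100, size=901)]
        assert got == ["inside", "at_edges"]
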