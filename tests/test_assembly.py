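"""Umotif merging, CRE projection, CRM linkage, target assignment."""
import numpy as np
import pytest

from crmine.assembly import (
    AssemblyConfig,
    apply_umotifs_to_crmcs,
    assign_target_genes,
    link_cres_into_crms,
    merge_umotifs,
    project_cres,
    site_overlap_rate,
    CRM,
    Umotif,
)
from crmine.discovery import Motif, Site
from crmine.genome import Genome
from crmine.intervals import AnnotationSet, Gene, GenomicInterval
from crmine.mining import CRMC
from crmine.pswm import PSWM
from crmine.similarity import SimilarityConfig, motif_similarity


def pm(word):
    m = np.zeros((4, len(word)))
    for j, b in enumerate(word):
        m["ACGT".index(b), j] = 1.0
    return PSWM.from_freqs(m, name=word)


def motif_with_sites(motif_id, word, positions, genome, strand="+"):
    sites = [
        Site(f"peak{i}", GenomicInterval("chr1", p, p + len(word), strand), strand,
             genome.fetch(GenomicInterval("chr1", p, p + len(word), strand)))
        for i, p in enumerate(positions)
    ]
    return Motif(motif_id, "d1", pm(word), sites)


def plant(genome_seq, word, positions):
    s = list(genome_seq)
    for p in positions:
        s[p : p + len(word)] = list(word)
    return "".join(s)


@pytest.fixture
def planted_genome(rng):
    seq = "".join("ACGT"[c] for c in rng.integers(0, 4, 20_000))
    return seq


class TestSiteOverlapRate:
    def mk(self, spans):
        class C:
            sites = [
                Site("p", GenomicInterval("chr1", s, e), "+", "A" * (e - s))
                for s, e in spans
            ]
        return C()

    def test_identical(self):
        a = self.mk([(0, 8), (20, 28)])
        assert site_overlap_rate(a, a) == 1.0

    def test_disjoint(self):
        assert site_overlap_rate(self.mk([(0, 8)]), self.mk([(100, 108)])) == 0.0

    def test_smaller_set_normalization(self):
        small = self.mk([(0, 8), (20, 28), (40, 48), (60, 68)])
        big = self.mk([(4, 12), (22, 30), (44, 52), (100, 108), (200, 208)])
        # 3 of the 4 smaller-set sites overlap
        assert site_overlap_rate(small, big) == pytest.approx(0.75)

    def test_empty_undefined(self):
        assert site_overlap_rate(self.mk([]), self.mk([(0, 8)])) is None


class TestMergeUmotifs:
    def test_identical_motifs_merge(self, planted_genome):
        seq = plant(planted_genome, "ACGTAAGG", [100, 300, 500, 700])
        genome = Genome({"chr1": seq})
        m1 = motif_with_sites("m1", "ACGTAAGG", [100, 300, 500, 700], genome)
        m2 = motif_with_sites("m2", "ACGTAAGG", [100, 300, 500, 700], genome)
        umotifs, mapping = merge_umotifs([m1, m2], genome)
        assert len(umotifs) == 1
        assert umotifs[0].member_count == 2
        assert mapping == {"m1": umotifs[0].umotif_id, "m2": umotifs[0].umotif_id}

    def test_dissimilar_motifs_stay_separate(self, planted_genome):
        seq = plant(planted_genome, "ACGTAAGG", [100, 300])
        seq = plant(seq, "TTGCGCAA", [1000, 1300])
        genome = Genome({"chr1": seq})
        m1 = motif_with_sites("m1", "ACGTAAGG", [100, 300], genome)
        m2 = motif_with_sites("m2", "TTGCGCAA", [1000, 1300], genome)
        umotifs, _ = merge_umotifs([m1, m2], genome)
        assert len(umotifs) == 2

    def test_planted_variants_merge_to_one(self, planted_genome):
        # three variants of one consensus, one column perturbed each, on
        # overlapping site sets: recovered as a single Umotif
        word = "ACGTAAGGCC"
        positions = [1000 + 400 * i for i in range(8)]
        seq = plant(planted_genome, word, positions)
        genome = Genome({"chr1": seq})
        variants = []
        for k, w in enumerate([word, word[:4] + "C" + word[5:], word[:7] + "A" + word[8:]]):
            f = pm(w).freqs * 0.94 + 0.015
            m = Motif(f"v{k}", "d1", PSWM.from_freqs(f / f.sum(axis=0)), [
                Site(f"p{i}", GenomicInterval("chr1", p, p + len(word)), "+",
                     genome.fetch(GenomicInterval("chr1", p, p + len(word))))
                for i, p in enumerate(positions)
            ])
            variants.append(m)
        umotifs, _ = merge_umotifs(variants, genome)
        assert len(umotifs) == 1
        cons = umotifs[0].pswm.consensus()
        from crmine.genome import reverse_complement
        assert (sum(a != b for a, b in zip(cons, word)) <= 1
                or sum(a != b for a, b in zip(cons, reverse_complement(word))) <= 1
                or word in cons or reverse_complement(word) in cons)

    def test_terminal_contract(self, planted_genome, rng):
        # after merging, no pair violates (sim > 0.4 AND overlap > 0.5)
        genome = Genome({"chr1": planted_genome})
        motifs = []
        for k in range(6):
            word = "".join("ACGT"[c] for c in rng.integers(0, 4, 8))
            positions = sorted(rng.choice(19_000, size=5, replace=False))
            motifs.append(motif_with_sites(f"m{k}", word, positions, genome))
        cfg = AssemblyConfig()
        simcfg = SimilarityConfig()
        umotifs, _ = merge_umotifs(motifs, genome, simcfg, cfg)
        for i in range(len(umotifs)):
            for j in range(i + 1, len(umotifs)):
                s = motif_similarity(umotifs[i].pswm, umotifs[j].pswm, simcfg) or 0
                r = site_overlap_rate(umotifs[i], umotifs[j]) or 0
                assert not (s > cfg.stop_similarity and r > cfg.stop_overlap)


class TestApplyUmotifs:
    def test_identical_patterns_merged(self):
        crmcs = [
            CRMC("crmc1", ["c1"], ["m1", "m2"]),
            CRMC("crmc2", ["c2"], ["m3", "m4"]),
        ]
        mapping = {"m1": "U1", "m2": "U2", "m3": "U2", "m4": "U1"}
        out = apply_umotifs_to_crmcs(crmcs, mapping)
        assert len(out) == 1
        assert out[0].umotif_ids == ["U1", "U2"]
        assert out[0].cpc_ids == ["c1", "c2"]

    def test_distinct_patterns_identity(self):
        crmcs = [CRMC("crmc1", ["c1"], ["m1"]), CRMC("crmc2", ["c2"], ["m2"])]
        out = apply_umotifs_to_crmcs(crmcs, {"m1": "U1", "m2": "U2"})
        assert len(out) == 2

    def test_unmapped_motif_raises(self):
        with pytest.raises(KeyError):
            apply_umotifs_to_crmcs([CRMC("c", [], ["mX"])], {})


def umotif(uid, spans):
    return Umotif(uid, [uid], pm("ACGTACGT"),
                  [GenomicInterval("chr1", s, e) for s, e in spans])


class TestProjectCres:
    def test_overlap_merged(self):
        cres = project_cres([umotif("U1", [(100, 110)]), umotif("U2", [(105, 115)])])
        assert [(iv.start, iv.end) for iv, _ in cres] == [(100, 115)]
        assert cres[0][1] == frozenset({"U1", "U2"})

    def test_adjacent_not_merged(self):
        cres = project_cres([umotif("U1", [(100, 110), (110, 120)])])
        assert [(iv.start, iv.end) for iv, _ in cres] == [(100, 110), (110, 120)]

    def test_fuzz_union_oracle(self, rng):
        spans = [(int(s), int(s) + int(l)) for s, l in
                 zip(rng.integers(0, 100_000, 1000), rng.integers(1, 30, 1000))]
        cres = project_cres([umotif("U1", spans)])
        # pairwise non-overlapping and sorted
        for (a, _), (b, _) in zip(cres, cres[1:]):
            assert a.end <= b.start
        # total covered bp equals brute-force union length
        covered = set()
        for s, e in spans:
            covered.update(range(s, e))
        assert sum(iv.length for iv, _ in cres) == len(covered)


class TestLinkage:
    def cres(self, spans):
        return [(GenomicInterval("chr1", s, e), frozenset({"U1"})) for s, e in spans]

    def test_gap_below_delta_links(self, empty_exons):
        crms = link_cres_into_crms(self.cres([(100, 110), (200, 210)]), empty_exons, 150)
        assert len(crms) == 1
        assert (crms[0].span.start, crms[0].span.end) == (100, 210)

    def test_gap_exactly_delta_not_linked(self, empty_exons):
        crms = link_cres_into_crms(self.cres([(100, 110), (260, 270)]), empty_exons, 150)
        assert crms == []  # two singletons, no CRM

    def test_exon_blocks_unless_it_contains_a_cre(self):
        # exon fully inside the gap, no CRE inside -> blocked
        exons = AnnotationSet([GenomicInterval("chr1", 120, 190)], kind="exon")
        crms = link_cres_into_crms(self.cres([(100, 110), (200, 210)]), exons, 150)
        assert crms == []
        # same exon containing a CRE -> linked (three CREs, one inside exon)
        cres = self.cres([(100, 110), (150, 160), (200, 210)])
        crms = link_cres_into_crms(cres, exons, 150)
        assert len(crms) == 1
        assert len(crms[0].cres) == 3

    def test_singletons_are_not_crms(self, empty_exons):
        crms = link_cres_into_crms(self.cres([(100, 110)]), empty_exons, 150)
        assert crms == []

    def test_all_crms_have_two_plus_cres_sorted_nonoverlapping(self, empty_exons, rng):
        spans = sorted({int(s) for s in rng.integers(0, 50_000, 300)})
        cres = self.cres([(s, s + 8) for s in spans if True][:200])
        # deduplicate overlaps for a valid input
        dedup = []
        for iv, lab in cres:
            if not dedup or iv.start >= dedup[-1][0].end:
                dedup.append((iv, lab))
        for crm in link_cres_into_crms(dedup, empty_exons, 150):
            assert len(crm.cres) >= 2
            for (a, _), (b, _) in zip(crm.cres, crm.cres[1:]):
                assert a.end <= b.start
                assert b.start - a.end < 150


class TestAssignTargets:
    def test_tss_inside_distance_zero(self):
        crm = CRM("c1", GenomicInterval("chr1", 1000, 2000), [])
        genes = [Gene("gA", "chr1", 1500, "+"), Gene("gB", "chr1", 5000, "+")]
        out = assign_target_genes([crm], genes)
        assert out[0].target_gene == "gA"
        assert out[0].target_distance == 0

    def test_equidistant_lexicographic(self):
        crm = CRM("c1", GenomicInterval("chr1", 1000, 2000), [])
        genes = [Gene("gB", "chr1", 2498, "+"), Gene("gA", "chr1", 501, "+")]
        # distances: gB: 2498-1999=499; gA: 1000-501=499 -> tie -> gA
        out = assign_target_genes([crm], genes)
        assert out[0].target_gene == "gA"

    def test_single_gene_gets_all(self):
        crms = [CRM(f"c{i}", GenomicInterval("chr1", 1000 * i + 10, 1000 * i + 500), [])
                for i in range(1, 4)]
        out = assign_target_genes(crms, [Gene("only", "chr1", 0, "+")])
        assert all(c.target_gene == "only" for c in out)

    def test_brute_force_distances(self, rng):
        genes = [Gene(f"g{i}", "chr1", int(t), "+") for i, t in
                 enumerate(rng.integers(0, 100_000, 30))]
        for _ in range(20):
            s = int(rng.integers(0, 99_000))
            crm = CRM("c", GenomicInterval("chr1", s, s + 500), [])
            out = assign_target_genes([crm], genes)[0]
            def dist(g):
                if s <= g.tss < s + 500:
                    return 0
                return min(abs(g.tss - s), abs(g.tss - (s + 500 - 1)))
            best = min((dist(g), g.gene_id) for g in genes)
            assert (out.target_distance, out.target_gene) == best
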