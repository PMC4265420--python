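"""Co-occurrence mining: Sc, Ss, S_CPC, threshold selection, CPC/CRMC cuts."""
import itertools

import numpy as np
import pytest

from crmine.discovery import Motif, Site
from crmine.graphs import MclConfig
from crmine.intervals import GenomicInterval
from crmine.mining import (
    CP,
    CPC,
    MiningConfig,
    build_cp_graph,
    cooccurrence_score,
    cp_similarity,
    cpc_cooccurrence,
    find_cps,
    find_cpcs,
    find_crmcs,
    select_alpha,
    select_beta,
    select_gamma,
)
from crmine.pswm import PSWM
from crmine.similarity import SimilarityConfig


def pm(word, name=None):
    m = np.zeros((4, len(word)))
    for j, b in enumerate(word):
        m["ACGT".index(b), j] = 1.0
    return PSWM.from_freqs(m, name=name or word)


def mk_motif(motif_id, dataset_id, peaks, word="ACGTACGT"):
    """Motif whose supporting peaks are given explicitly."""
    sites = [
        Site(p, GenomicInterval("chr1", 100 * i, 100 * i + len(word)), "+", word)
        for i, p in enumerate(sorted(peaks))
    ]
    return Motif(motif_id, dataset_id, pm(word, motif_id), sites,
                 support_peak_ids=frozenset(peaks))


class TestCooccurrenceScore:
    def test_subset_gives_one(self):
        mi = mk_motif("m1", "d", {"p1", "p2"})
        mj = mk_motif("m2", "d", {"p1", "p2", "p3", "p4"})
        assert cooccurrence_score(mi, mj) == 1.0

    def test_disjoint_zero(self):
        assert cooccurrence_score(mk_motif("m1", "d", {"a"}), mk_motif("m2", "d", {"b"})) == 0.0

    def test_min_normalized(self):
        mi = mk_motif("m1", "d", {f"p{i}" for i in range(10)})
        mj = mk_motif("m2", "d", {"p0", "p1", "x1", "x2"})
        assert cooccurrence_score(mi, mj) == pytest.approx(0.5)

    def test_zero_support_undefined(self):
        empty = Motif("m0", "d", pm("ACGTACGT"), [], support_peak_ids=frozenset())
        assert cooccurrence_score(empty, mk_motif("m1", "d", {"a"})) is None

    def test_brute_force_oracle_random(self, rng):
        for _ in range(100):
            pa = {f"p{i}" for i in rng.choice(12, size=rng.integers(1, 10), replace=False)}
            pb = {f"p{i}" for i in rng.choice(12, size=rng.integers(1, 10), replace=False)}
            got = cooccurrence_score(mk_motif("a", "d", pa), mk_motif("b", "d", pb))
            assert got == len(pa & pb) / min(len(pa), len(pb))


class TestFindCps:
    def test_three_fully_cooccurring(self):
        peaks = {"p1", "p2", "p3"}
        motifs = {"d": [mk_motif(f"m{i}", "d", peaks, w) for i, w in
                        enumerate(["ACGTACGT", "AAAACCCC", "GGGGTTTT"])]}
        cps = find_cps(motifs, MiningConfig(alpha=0.7))
        assert len(cps) == 3

    def test_below_alpha_none(self):
        motifs = {"d": [mk_motif("m1", "d", {"a", "b", "c", "d"}),
                        mk_motif("m2", "d", {"a", "x", "y", "z"})]}
        assert find_cps(motifs, MiningConfig(alpha=0.7)) == []


class TestSelectAlpha:
    def test_fixed_mode(self):
        a, table = select_alpha([0.1, 0.9] * 60, MiningConfig(threshold_mode="fixed"))
        assert a == 0.7
        assert {"alpha", "retained_pairs", "retained_fraction"} <= set(table.columns)

    def test_auto_on_background_gaussian(self, rng):
        # pure background component: alpha lands in [0.5, 0.7] and excludes
        # nearly all of the background mass
        sc = np.clip(rng.normal(0.19, 0.067, size=5000), 0, 1)
        a, _ = select_alpha(sc, MiningConfig(threshold_mode="auto"))
        assert 0.5 <= a <= 0.7
        assert (sc < a).mean() >= 0.99

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_alpha([], MiningConfig())

    def test_mixture_separation_curve(self, rng):
        # background N(0.19, 0.067) + planted pairs at ~0.9: the retention
        # curve flattens between the components
        sc = np.concatenate([
            np.clip(rng.normal(0.19, 0.067, 2000), 0, 1),
            np.clip(rng.normal(0.9, 0.03, 100), 0, 1),
        ])
        _, table = select_alpha(sc, MiningConfig(threshold_mode="fixed"))
        at = lambda a: int(table.loc[np.isclose(table["alpha"], a), "retained_pairs"].iloc[0])
        assert at(0.5) < 2100 * 0.06  # background almost fully gone
        assert at(0.7) >= 95  # planted component retained
        assert at(0.95) <= 10


def cp_from(dataset, m1, m2, peaks, cp_id=None):
    return CP(cp_id or f"{dataset}:{m1.motif_id}+{m2.motif_id}", dataset,
              (m1.motif_id, m2.motif_id), 1.0, frozenset(peaks))


class TestCpSimilarity:
    def setup_method(self):
        self.simcfg = SimilarityConfig(metric="column-l1")

    def test_identical_pairs_two(self):
        a = mk_motif("a", "d1", {"p"}, "ACGTACGT")
        b = mk_motif("b", "d1", {"p"}, "AATTCCGG")
        c = mk_motif("c", "d2", {"p"}, "ACGTACGT")
        d = mk_motif("d", "d2", {"p"}, "AATTCCGG")
        idx = {m.motif_id: m for m in (a, b, c, d)}
        p = cp_from("d1", a, b, {"p"})
        q = cp_from("d2", c, d, {"p"})
        assert cp_similarity(p, q, idx, self.simcfg) == pytest.approx(2.0)

    def test_same_dataset_rejected(self):
        a = mk_motif("a", "d1", {"p"})
        b = mk_motif("b", "d1", {"p"}, "AATTCCGG")
        idx = {m.motif_id: m for m in (a, b)}
        p = cp_from("d1", a, b, {"p"}, "cp1")
        q = cp_from("d1", a, b, {"p"}, "cp2")
        with pytest.raises(ValueError):
            cp_similarity(p, q, idx, self.simcfg)

    def test_max_first_rule(self, monkeypatch):
        # Sim(A,C)=0.9, Sim(A,D)=0.2, Sim(B,C)=0.3, Sim(B,D)=0.8 -> 1.7
        import crmine.mining as mining

        a = mk_motif("A", "d1", {"p"})
        b = mk_motif("B", "d1", {"p"}, "AATTCCGG")
        c = mk_motif("C", "d2", {"p"}, "ACGTACGT")
        d = mk_motif("D", "d2", {"p"}, "AATTCCGG")
        idx = {m.motif_id: m for m in (a, b, c, d)}
        table = {("A", "C"): 0.9, ("A", "D"): 0.2, ("B", "C"): 0.3, ("B", "D"): 0.8}

        def fake_sim(x, y, cfg):
            return table[(x.name, y.name)]

        monkeypatch.setattr(mining, "motif_similarity", fake_sim)
        for m in (a, b, c, d):
            m.pswm.name = m.motif_id
        p = cp_from("d1", a, b, {"p"})
        q = cp_from("d2", c, d, {"p"})
        assert cp_similarity(p, q, idx, self.simcfg) == pytest.approx(1.7)

    def test_max_first_can_differ_from_best_pairing(self, monkeypatch):
        # anchoring on the single best similarity is not the same as
        # maximizing the pairing sum: 0.9+0.1 beats pairing sum 0.5+0.6
        import crmine.mining as mining

        a = mk_motif("A", "d1", {"p"})
        b = mk_motif("B", "d1", {"p"}, "AATTCCGG")
        c = mk_motif("C", "d2", {"p"}, "ACGTACGT")
        d = mk_motif("D", "d2", {"p"}, "AATTCCGG")
        idx = {m.motif_id: m for m in (a, b, c, d)}
        table = {("A", "C"): 0.9, ("A", "D"): 0.5, ("B", "C"): 0.6, ("B", "D"): 0.1}
        monkeypatch.setattr(mining, "motif_similarity",
                            lambda x, y, cfg: table[(x.name, y.name)])
        for m in (a, b, c, d):
            m.pswm.name = m.motif_id
        p = cp_from("d1", a, b, {"p"})
        q = cp_from("d2", c, d, {"p"})
        assert cp_similarity(p, q, idx, self.simcfg) == pytest.approx(1.0)


class TestCpGraphAndCpcs:
    def make_cps(self, n_datasets=3, words=("ACGTACGT", "AATTCCGG")):
        motifs = {}
        cps = []
        idx = {}
        for k in range(n_datasets):
            ds = f"d{k}"
            a = mk_motif(f"{ds}.a", ds, {"p1", "p2"}, words[0])
            b = mk_motif(f"{ds}.b", ds, {"p1", "p2"}, words[1])
            idx[a.motif_id] = a
            idx[b.motif_id] = b
            cps.append(cp_from(ds, a, b, {"p1", "p2"}))
        return cps, idx

    def test_beta_above_two_no_edges(self):
        cps, idx = self.make_cps()
        g = build_cp_graph(cps, idx, beta=2.0 + 1e-9)
        assert g.n_edges == 0

    def test_beta_zero_complete_multipartite(self):
        cps, idx = self.make_cps()
        g = build_cp_graph(cps, idx, beta=0.0)
        assert g.n_edges == 3  # all cross-dataset pairs

    def test_recurring_pair_forms_clique_and_cpc(self):
        cps, idx = self.make_cps(n_datasets=3)
        g = build_cp_graph(cps, idx, beta=1.5)
        assert g.n_edges == 3
        cpcs = find_cpcs(g, cps, MclConfig(), tau=2)
        assert len(cpcs) == 1
        assert len(cpcs[0].cp_ids) == 3
        assert len(cpcs[0].dataset_ids) == 3

    def test_singleton_cluster_discarded(self):
        cps, idx = self.make_cps(n_datasets=2)
        # isolate one CP by giving it dissimilar motifs
        lone_a = mk_motif("dz.a", "dz", {"p"}, "ATATATAT")
        lone_b = mk_motif("dz.b", "dz", {"p"}, "CGCGCGCG")
        idx.update({m.motif_id: m for m in (lone_a, lone_b)})
        cps.append(cp_from("dz", lone_a, lone_b, {"p"}))
        g = build_cp_graph(cps, idx, beta=1.5)
        cpcs = find_cpcs(g, cps, MclConfig(), tau=2)
        assert len(cpcs) == 1
        assert all("dz" not in c.dataset_ids for c in cpcs)


class TestSelectBeta:
    def test_fixed_mode(self):
        cps, idx = TestCpGraphAndCpcs().make_cps()
        beta, table = select_beta(cps, idx, MiningConfig(threshold_mode="fixed"))
        assert beta == 1.36
        assert {"beta", "n_nodes", "n_edges", "density"} <= set(table.columns)

    def test_auto_knee_between_modes_keeps_planted(self, rng):
        # a recurring identical pair in 4 datasets (Ss ~ 2) over a background
        # of dataset-specific random pairs: the knee lands between the modes
        idx = {}
        cps = []
        for k in range(4):
            ds = f"d{k}"
            a = mk_motif(f"{ds}.a", ds, {"p"}, "ACGTAAGG")
            b = mk_motif(f"{ds}.b", ds, {"p"}, "TTGCGCAA")
            idx.update({a.motif_id: a, b.motif_id: b})
            cps.append(cp_from(ds, a, b, {"p"}))
            for r in range(3):
                w1 = "".join("ACGT"[c] for c in rng.integers(0, 4, 8))
                w2 = "".join("ACGT"[c] for c in rng.integers(0, 4, 8))
                x = mk_motif(f"{ds}.x{r}", ds, {"p"}, w1)
                y = mk_motif(f"{ds}.y{r}", ds, {"p"}, w2)
                idx.update({x.motif_id: x, y.motif_id: y})
                cps.append(cp_from(ds, x, y, {"p"}))
        beta, _ = select_beta(cps, idx, MiningConfig(threshold_mode="auto"))
        assert 0.1 < beta < 1.9
        g = build_cp_graph(cps, idx, beta)
        planted_ids = {f"d{k}:d{k}.a+d{k}.b" for k in range(4)}
        # all planted CPs keep at least one edge at the selected beta
        degree = {n: 0 for n in g.nodes}
        for x, y, _w in g.to_edge_list():
            degree[x] += 1
            degree[y] += 1
        for cp in cps:
            if cp.cp_id in planted_ids:
                assert degree.get(cp.cp_id, 0) >= 1


class TestCpcCooccurrence:
    def build(self, shared_ratio):
        """Two CPCs with one shared dataset; one cross pair with the given
        overlap ratio."""
        peaks_s = {f"p{i}" for i in range(6)}
        peaks_t = {f"p{i}" for i in range(4, 8)}  # |s|=6, |t|=4, o=2
        ps = CP("d1.cp1", "d1", ("m1", "m2"), 1.0, frozenset(peaks_s))
        pt = CP("d1.cp2", "d1", ("m3", "m4"), 1.0, frozenset(peaks_t))
        ci = CPC("c1", ["d1.cp1"], ["m1", "m2"], ["d1"])
        cj = CPC("c2", ["d1.cp2"], ["m3", "m4"], ["d1"])
        return ci, cj, [ps, pt]

    def test_one_shared_dataset_ratio(self):
        ci, cj, cps = self.build(0.5)
        assert cpc_cooccurrence(ci, cj, cps) == pytest.approx(2 / 4)

    def test_identical_peak_sets_one(self):
        peaks = frozenset({"p1", "p2"})
        ps = CP("d1.cp1", "d1", ("m1", "m2"), 1.0, peaks)
        pt = CP("d1.cp2", "d1", ("m3", "m4"), 1.0, peaks)
        ci = CPC("c1", ["d1.cp1"], ["m1", "m2"], ["d1"])
        cj = CPC("c2", ["d1.cp2"], ["m3", "m4"], ["d1"])
        assert cpc_cooccurrence(ci, cj, [ps, pt]) == 1.0

    def test_no_shared_dataset_zero(self):
        ps = CP("d1.cp1", "d1", ("m1", "m2"), 1.0, frozenset({"p"}))
        pt = CP("d2.cp1", "d2", ("m3", "m4"), 1.0, frozenset({"q"}))
        ci = CPC("c1", ["d1.cp1"], ["m1", "m2"], ["d1"])
        cj = CPC("c2", ["d2.cp1"], ["m3", "m4"], ["d2"])
        assert cpc_cooccurrence(ci, cj, [ps, pt]) == 0.0

    def test_brute_force_oracle_random(self, rng):
        # multi-dataset, multi-CP instances against a direct reimplementation
        for _ in range(100):
            cps = []
            ci_ids, cj_ids = [], []
            for ds in ("d1", "d2", "d3"):
                for side, bucket in (("i", ci_ids), ("j", cj_ids)):
                    if rng.random() < 0.8:
                        peaks = frozenset(
                            f"{ds}:p{k}" for k in rng.choice(10, size=rng.integers(1, 8),
                                                             replace=False)
                        )
                        cid = f"{ds}.cp{side}{len(cps)}"
                        cps.append(CP(cid, ds, (f"m{side}1", f"m{side}2"), 1.0, peaks))
                        bucket.append(cid)
            if not ci_ids or not cj_ids:
                continue
            ci = CPC("ci", ci_ids, ["mi1", "mi2"], sorted({c.split(".")[0] for c in ci_ids}))
            cj = CPC("cj", cj_ids, ["mj1", "mj2"], sorted({c.split(".")[0] for c in cj_ids}))
            got = cpc_cooccurrence(ci, cj, cps)
            # oracle
            cp_map = {c.cp_id: c for c in cps}
            terms = []
            for ds in ("d1", "d2", "d3"):
                crossed = [
                    (cp_map[a], cp_map[b])
                    for a in ci_ids for b in cj_ids
                    if cp_map[a].dataset_id == ds and cp_map[b].dataset_id == ds
                ]
                ratios = [len(a.peak_ids & b.peak_ids) / min(len(a.peak_ids), len(b.peak_ids))
                          for a, b in crossed]
                if ratios:
                    terms.append(sum(ratios) / len(ratios))
            expect = sum(terms) / len(terms) if terms else 0.0
            assert got == pytest.approx(expect)


class TestSelectGamma:
    def test_fixed(self):
        assert select_gamma([0.1] * 200, MiningConfig(threshold_mode="fixed")) == 0.69

    def test_bimodal_valley(self, rng):
        scores = np.concatenate([
            rng.normal(0.2, 0.05, 400), rng.normal(0.9, 0.05, 400)
        ])
        g = select_gamma(scores, MiningConfig(threshold_mode="auto"))
        assert 0.45 <= g <= 0.65

    def test_degenerate_falls_back(self):
        g = select_gamma([0.5] * 500, MiningConfig(threshold_mode="auto"))
        assert g == 0.69


class TestFindCrmcs:
    def test_topology_three_plus_singleton(self):
        # C1,C2,C3 mutually co-occurring; C4 apart -> two CRMCs
        peaks = frozenset({"p1", "p2", "p3"})
        cps = [
            CP("d1.cp1", "d1", ("a", "b"), 1.0, peaks),
            CP("d1.cp2", "d1", ("c", "d"), 1.0, peaks),
            CP("d1.cp3", "d1", ("e", "f"), 1.0, peaks),
            CP("d2.cp4", "d2", ("g", "h"), 1.0, frozenset({"q1"})),
        ]
        cpcs = [
            CPC("c1", ["d1.cp1"], ["a", "b"], ["d1"]),
            CPC("c2", ["d1.cp2"], ["c", "d"], ["d1"]),
            CPC("c3", ["d1.cp3"], ["e", "f"], ["d1"]),
            CPC("c4", ["d2.cp4"], ["g", "h"], ["d2"]),
        ]
        crmcs = find_crmcs(cpcs, cps, gamma=0.69)
        patterns = sorted(tuple(c.cpc_ids) for c in crmcs)
        assert patterns == [("c1", "c2", "c3"), ("c4",)]

    def test_empty(self):
        assert find_crmcs([], [], 0.69) == []

    def test_funnel_monotonicity(self):
        # motifs(CRMCs) subset motifs(CPCs) subset motifs(CPs)
        peaks = frozenset({"p1", "p2"})
        cps = [CP("d1.cp1", "d1", ("a", "b"), 1.0, peaks),
               CP("d2.cp1", "d2", ("c", "d"), 1.0, frozenset({"x"}))]
        cpcs = [CPC("c1", ["d1.cp1"], ["a", "b"], ["d1"])]
        crmcs = find_crmcs(cpcs, cps, gamma=0.69)
        cp_motifs = {m for c in cps for m in c.motif_ids}
        cpc_motifs = {m for c in cpcs for m in c.motif_ids}
        crmc_motifs = {m for c in crmcs for m in c.motif_ids}
        assert crmc_motifs <= cpc_motifs <= cp_motifs
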