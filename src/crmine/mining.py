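"""Co-occurrence mining: CPs, CPCs and CRM components.

Stage logic: within each dataset, motif pairs whose supporting peak sets
overlap strongly (Sc >= alpha) become co-occurring pairs (CPs); CPs from
different datasets with highly similar motif content (Ss >= beta) are
clustered into CP clusters (CPCs); CPCs that co-occur on the same binding
peaks (S_CPC >= gamma) are clustered into CRM components (CRMCs), each a
recurring motif combination.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .discovery import Motif
from .graphs import MclConfig, WeightedGraph, mcl
from .similarity import SimilarityConfig, motif_similarity

log = logging.getLogger(__name__)


@dataclass
class CP:
    """A co-occurring motif pair within one dataset."""

    cp_id: str
    dataset_id: str
    motif_ids: tuple  # unordered pair, stored sorted
    sc: float
    peak_ids: frozenset  # peaks containing sites of both motifs

    def __post_init__(self) -> None:
        if self.motif_ids[0] == self.motif_ids[1]:
            raise ValueError("CP motifs must be distinct")
        self.motif_ids = tuple(sorted(self.motif_ids))
        if not (0 <= self.sc <= 1):
            raise ValueError("Sc out of [0, 1]")

    @property
    def size(self) -> int:
        """|P|: number of supporting peaks."""
        return len(self.peak_ids)


@dataclass
class CPC:
    """A cluster of mutually similar CPs from different datasets."""

    cpc_id: str
    cp_ids: list[str]
    motif_ids: list[str]
    dataset_ids: list[str]


@dataclass
class CRMC:
    """A cluster of co-occurring CPCs: a recurring motif combination."""

    crmc_id: str
    cpc_ids: list[str]
    motif_ids: list[str]
    umotif_ids: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class MiningConfig:
    alpha: float = 0.7
    beta: float = 1.36
    gamma: float = 0.69
    tau: int = 2
    threshold_mode: str = "fixed"  # or "auto"

    def __post_init__(self) -> None:
        if not (0 <= self.alpha <= 1 and 0 <= self.gamma <= 1):
            raise ValueError("alpha and gamma must lie in [0, 1]")
        if not (0 <= self.beta <= 2):
            raise ValueError("beta must lie in [0, 2]")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")


# ---------------------------------------------------------------------------
# Step 1: CPs
# ---------------------------------------------------------------------------
def cooccurrence_score(mi: Motif, mj: Motif) -> Optional[float]:
    """Sc = o / min(|Mi|, |Mj|) over supporting peak counts; None if a
    motif has zero support."""
    pi, pj = mi.peak_ids, mj.peak_ids
    if not pi or not pj:
        return None
    return len(pi & pj) / min(len(pi), len(pj))


def find_cps(
    motifs_per_dataset: dict[str, list[Motif]], cfg: MiningConfig = MiningConfig()
) -> list[CP]:
    """Score all unordered within-dataset motif pairs; keep Sc >= alpha."""
    cps: list[CP] = []
    for dataset_id in sorted(motifs_per_dataset):
        motifs = motifs_per_dataset[dataset_id]
        count = 0
        for mi, mj in itertools.combinations(motifs, 2):
            sc = cooccurrence_score(mi, mj)
            if sc is None or sc < cfg.alpha:
                continue
            count += 1
            cps.append(
                CP(
                    cp_id=f"{dataset_id}.cp{count}",
                    dataset_id=dataset_id,
                    motif_ids=(mi.motif_id, mj.motif_id),
                    sc=sc,
                    peak_ids=mi.peak_ids & mj.peak_ids,
                )
            )
        log.info("dataset %s: %d CPs at alpha=%.2f", dataset_id, count, cfg.alpha)
    return cps


def all_pair_scores(motifs_per_dataset: dict[str, list[Motif]]) -> list[float]:
    """Sc of every within-dataset motif pair (for threshold diagnostics)."""
    out = []
    for dataset_id in sorted(motifs_per_dataset):
        for mi, mj in itertools.combinations(motifs_per_dataset[dataset_id], 2):
            sc = cooccurrence_score(mi, mj)
            if sc is not None:
                out.append(sc)
    return out


def retention_curve(sc_values: Sequence[float], grid: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Fraction of motif pairs surviving each candidate alpha."""
    sc = np.asarray(sc_values, dtype=float)
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.05), 3)
    rows = [
        {"alpha": float(a), "retained_pairs": int((sc >= a).sum()),
         "retained_fraction": float((sc >= a).mean()) if len(sc) else float("nan")}
        for a in grid
    ]
    return pd.DataFrame(rows)


def select_alpha(
    sc_values: Sequence[float], cfg: MiningConfig = MiningConfig()
) -> tuple[float, pd.DataFrame]:
    """Choose alpha. Fixed mode returns the configured value; auto mode fits
    a Gaussian to the low-score background component (mode via histogram,
    sigma via left-half mirroring) and returns mu + 6 sigma capped to
    [0.5, 0.9]. Always returns the retention-curve table as well."""
    sc = np.asarray([s for s in sc_values if s is not None], dtype=float)
    if len(sc) == 0:
        raise ValueError("no co-occurrence scores")
    table = retention_curve(sc)
    if cfg.threshold_mode == "fixed":
        return cfg.alpha, table
    if len(sc) < 100:
        log.warning("auto alpha needs >= 100 scores (%d given); using fixed %.2f", len(sc), cfg.alpha)
        return cfg.alpha, table
    hist, edges = np.histogram(sc, bins=50)
    mode_bin = int(np.argmax(hist))
    mu = 0.5 * (edges[mode_bin] + edges[mode_bin + 1])
    left = sc[sc <= mu]
    sigma = float(np.sqrt(np.mean((left - mu) ** 2))) if len(left) else 0.0
    if sigma == 0:
        log.warning("degenerate score distribution; using fixed alpha %.2f", cfg.alpha)
        return cfg.alpha, table
    alpha = float(np.clip(mu + 6 * sigma, 0.5, 0.9))
    return alpha, table


# ---------------------------------------------------------------------------
# Step 2-3: CP similarity graph
# ---------------------------------------------------------------------------
class SimCache:
    """Memoized pairwise motif similarity over a motif index."""

    def __init__(self, motif_index: dict[str, Motif], simcfg: SimilarityConfig):
        self.index = motif_index
        self.cfg = simcfg
        self._d: dict[tuple, float] = {}

    def __call__(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in self._d:
            s = motif_similarity(self.index[key[0]].pswm, self.index[key[1]].pswm, self.cfg)
            self._d[key] = 0.0 if s is None else s
        return self._d[key]


def cp_similarity(
    p: CP,
    q: CP,
    motif_index: dict[str, Motif],
    simcfg: SimilarityConfig = SimilarityConfig(),
    cache: Optional[SimCache] = None,
) -> float:
    """Ss in [0, 2]: pick the maximal cross-dataset motif pairing, then add
    the similarity of the remaining pair."""
    if p.dataset_id == q.dataset_id:
        raise ValueError("CP similarity is defined across datasets only")
    a, b = p.motif_ids
    c, d = q.motif_ids
    sim = {}
    for x, y in ((a, c), (a, d), (b, c), (b, d)):
        if cache is not None:
            s = cache(x, y)
        else:
            s = motif_similarity(motif_index[x].pswm, motif_index[y].pswm, simcfg)
        sim[(x, y)] = 0.0 if s is None else s
    pairing1 = sim[(a, c)] + sim[(b, d)]
    pairing2 = sim[(a, d)] + sim[(b, c)]
    # max-first rule: anchor on the single highest cross similarity
    best_pair = max(sim, key=sim.get)
    if best_pair in ((a, c), (b, d)):
        return pairing1
    return pairing2


def build_cp_graph(
    cps: Sequence[CP],
    motif_index: dict[str, Motif],
    beta: float,
    simcfg: SimilarityConfig = SimilarityConfig(),
) -> WeightedGraph:
    """Multi-partite CP graph: edges where Ss >= beta, weighted by Ss."""
    g = WeightedGraph()
    cache = SimCache(motif_index, simcfg)
    for cp in cps:
        g.add_node(cp.cp_id, part=cp.dataset_id)
    for p, q in itertools.combinations(cps, 2):
        if p.dataset_id == q.dataset_id:
            continue
        ss = cp_similarity(p, q, motif_index, simcfg, cache)
        if ss >= beta and ss > 0:
            g.add_edge(p.cp_id, q.cp_id, ss)
    return g


def beta_curve(
    cps: Sequence[CP],
    motif_index: dict[str, Motif],
    grid: Sequence[float],
    simcfg: SimilarityConfig = SimilarityConfig(),
) -> pd.DataFrame:
    """Density and node count of the beta-thresholded CP graph on a grid."""
    ss_values = []
    cache = SimCache(motif_index, simcfg)
    for p, q in itertools.combinations(cps, 2):
        if p.dataset_id != q.dataset_id:
            ss_values.append(cp_similarity(p, q, motif_index, simcfg, cache))
    ss = np.asarray(ss_values)
    rows = []
    n_all = len(cps)
    for b in grid:
        edges = ss[ss >= b]
        # nodes with at least one surviving edge
        n_nodes = 0
        node_alive = set()
        k = 0
        for p, q in itertools.combinations(cps, 2):
            if p.dataset_id == q.dataset_id:
                continue
            if ss_values[k] >= b:
                node_alive.add(p.cp_id)
                node_alive.add(q.cp_id)
            k += 1
        n_nodes = len(node_alive)
        density = (2 * len(edges) / (n_nodes * (n_nodes - 1))) if n_nodes >= 2 else 0.0
        rows.append({"beta": float(b), "n_nodes": n_nodes, "n_edges": int(len(edges)),
                     "density": float(density)})
    return pd.DataFrame(rows)


def select_beta(
    cps: Sequence[CP],
    motif_index: dict[str, Motif],
    cfg: MiningConfig = MiningConfig(),
    grid: Optional[Sequence[float]] = None,
    simcfg: SimilarityConfig = SimilarityConfig(),
) -> tuple[float, pd.DataFrame]:
    """Fixed mode returns the configured beta; auto mode takes the knee of
    the node-count-versus-beta curve (maximal perpendicular distance from
    the endpoints' chord)."""
    if grid is None:
        grid = np.round(np.arange(0.0, 2.0001, 0.05), 3)
    table = beta_curve(cps, motif_index, grid, simcfg)
    if cfg.threshold_mode == "fixed":
        return cfg.beta, table
    y = table["n_nodes"].to_numpy(dtype=float)
    x = table["beta"].to_numpy(dtype=float)
    if len(x) < 3 or y.max() == y.min():
        log.warning("degenerate beta curve; using fixed beta %.2f", cfg.beta)
        return cfg.beta, table
    # knee: perpendicular distance from the chord between curve endpoints
    p0 = np.array([x[0], y[0] / y.max()])
    p1 = np.array([x[-1], y[-1] / y.max()])
    chord = p1 - p0
    chord = chord / np.linalg.norm(chord)
    pts = np.stack([x, y / y.max()], axis=1) - p0
    proj = pts @ chord
    dist = np.linalg.norm(pts - proj[:, None] * chord[None, :], axis=1)
    return float(x[int(np.argmax(dist))]), table


# ---------------------------------------------------------------------------
# Step 4: CPCs
# ---------------------------------------------------------------------------
def find_cpcs(
    graph: WeightedGraph,
    cps: Sequence[CP],
    mclcfg: MclConfig = MclConfig(),
    tau: int = 2,
) -> list[CPC]:
    """MCL clusters of the CP graph; clusters with < tau members discarded."""
    cp_index = {cp.cp_id: cp for cp in cps}
    result = mcl(graph, mclcfg)
    cpcs: list[CPC] = []
    n_discarded = 0
    for members in result.clusters:
        if len(members) < tau:
            n_discarded += 1
            continue
        member_cps = [cp_index[m] for m in members]
        motif_ids = sorted({mid for cp in member_cps for mid in cp.motif_ids})
        dataset_ids = sorted({cp.dataset_id for cp in member_cps})
        cpcs.append(
            CPC(
                cpc_id=f"cpc{len(cpcs) + 1}",
                cp_ids=sorted(m for m in members),
                motif_ids=motif_ids,
                dataset_ids=dataset_ids,
            )
        )
    if n_discarded:
        log.info("discarded %d CP clusters with < %d members", n_discarded, tau)
    return cpcs


# ---------------------------------------------------------------------------
# Step 5-7: CPC co-occurrence and CRMCs
# ---------------------------------------------------------------------------
def cpc_cooccurrence(ci: CPC, cj: CPC, cps: Sequence[CP]) -> float:
    """S_CPC: mean over shared datasets of the mean cross-CP overlap ratio.

    For each dataset contributing CPs to both clusters, every cross pair
    (Ps in ci, Pt in cj) is scored o / min(|Ps|, |Pt|) with o the number of
    peaks supporting both CPs; scores are averaged within the dataset and
    then across datasets. No shared dataset yields 0 (no edge).
    """
    if ci.cpc_id == cj.cpc_id:
        raise ValueError("S_CPC is defined between distinct CPCs")
    cp_index = {cp.cp_id: cp for cp in cps}
    ci_by_ds: dict[str, list[CP]] = {}
    cj_by_ds: dict[str, list[CP]] = {}
    for cid in ci.cp_ids:
        cp = cp_index[cid]
        ci_by_ds.setdefault(cp.dataset_id, []).append(cp)
    for cid in cj.cp_ids:
        cp = cp_index[cid]
        cj_by_ds.setdefault(cp.dataset_id, []).append(cp)
    shared = sorted(set(ci_by_ds) & set(cj_by_ds))
    if not shared:
        return 0.0
    terms = []
    for ds in shared:
        ratios = []
        for ps in ci_by_ds[ds]:
            for pt in cj_by_ds[ds]:
                if ps.cp_id == pt.cp_id:
                    continue
                denom = min(ps.size, pt.size)
                if denom == 0:
                    continue
                ratios.append(len(ps.peak_ids & pt.peak_ids) / denom)
        if ratios:
            terms.append(float(np.mean(ratios)))
    return float(np.mean(terms)) if terms else 0.0


def select_gamma(
    scores: Sequence[float], cfg: MiningConfig = MiningConfig()
) -> float:
    """Fixed mode returns the configured gamma; auto mode places gamma at
    the deepest KDE valley between the two highest local maxima."""
    if cfg.threshold_mode == "fixed":
        return cfg.gamma
    vals = np.asarray(scores, dtype=float)
    if len(vals) < 100 or np.ptp(vals) == 0:
        log.warning("auto gamma needs >= 100 varied scores; using fixed %.2f", cfg.gamma)
        return cfg.gamma
    kde = gaussian_kde(vals)  # Silverman-style bandwidth (scipy default: Scott)
    kde.set_bandwidth("silverman")
    xs = np.linspace(vals.min(), vals.max(), 512)
    ys = kde(xs)
    maxima = [i for i in range(1, 511) if ys[i] >= ys[i - 1] and ys[i] >= ys[i + 1]]
    if len(maxima) < 2:
        log.warning("unimodal S_CPC density; using fixed gamma %.2f", cfg.gamma)
        return cfg.gamma
    top2 = sorted(sorted(maxima, key=lambda i: -ys[i])[:2])
    lo, hi = top2
    valley = lo + int(np.argmin(ys[lo : hi + 1]))
    return float(xs[valley])


def build_cpc_graph(cpcs: Sequence[CPC], cps: Sequence[CP], gamma: float) -> tuple[WeightedGraph, list[float]]:
    g = WeightedGraph()
    scores = []
    for c in cpcs:
        g.add_node(c.cpc_id)
    for ci, cj in itertools.combinations(cpcs, 2):
        s = cpc_cooccurrence(ci, cj, cps)
        scores.append(s)
        if s >= gamma and s > 0:
            g.add_edge(ci.cpc_id, cj.cpc_id, s)
    return g, scores


def find_crmcs(
    cpcs: Sequence[CPC],
    cps: Sequence[CP],
    gamma: float,
    mclcfg: MclConfig = MclConfig(),
) -> list[CRMC]:
    """MCL on the gamma-thresholded CPC graph. Singleton clusters are kept:
    a lone CPC is still a motif combination."""
    if not cpcs:
        return []
    graph, _ = build_cpc_graph(cpcs, cps, gamma)
    result = mcl(graph, mclcfg)
    cpc_index = {c.cpc_id: c for c in cpcs}
    crmcs = []
    for members in result.clusters:
        motif_ids = sorted({m for cid in members for m in cpc_index[cid].motif_ids})
        crmcs.append(
            CRMC(
                crmc_id=f"crmc{len(crmcs) + 1}",
                cpc_ids=sorted(members),
                motif_ids=motif_ids,
            )
        )
    return crmcs
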