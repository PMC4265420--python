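"""Umotif merging and CRM assembly.

Highly similar per-dataset motifs presumed to belong to one TF are merged
iteratively into unique motifs (Umotifs); the Umotifs' CREs are projected
onto the genome, overlapping projections are collapsed, and nearby CREs are
linked into CRMs unless the link would span a CRE-free exon.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .discovery import DiscoveryConfig, Motif, Site, find_motifs
from .genome import Genome, reverse_complement
from .graphs import MclConfig, WeightedGraph, mcl
from .intervals import AnnotationSet, Gene, GenomicInterval, merge_labelled_intervals
from .mining import CRMC
from .pswm import PSWM
from .similarity import SimilarityConfig, motif_similarity

log = logging.getLogger(__name__)


@dataclass
class Umotif:
    """A non-redundant merged motif with the union of member sites."""

    umotif_id: str
    member_motif_ids: list[str]
    pswm: PSWM
    sites: list[GenomicInterval]  # merged, non-overlapping genome intervals

    @property
    def member_count(self) -> int:
        return len(self.member_motif_ids)


@dataclass
class CRM:
    """A predicted cis-regulatory module: linked projected CREs."""

    crm_id: str
    span: GenomicInterval
    cres: list[tuple[GenomicInterval, frozenset]]  # (interval, umotif ids)
    crmc_ids: list[str] = field(default_factory=list)
    target_gene: Optional[str] = None
    target_distance: Optional[int] = None
    mean_conservation: Optional[float] = None


@dataclass(frozen=True)
class AssemblyConfig:
    merge_edge_threshold: float = 0.7
    stop_similarity: float = 0.4
    stop_overlap: float = 0.5
    cre_pad: int = 5
    delta: int = 150
    max_merge_iterations: int = 20
    # Umotif site list: "member-union" keeps the union of the member motifs'
    # sites (projection retains every dataset's pattern variants);
    # "rediscovered" replaces them with the re-discovered common motif's sites
    umotif_site_policy: str = "member-union"

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be > 0")


# ---------------------------------------------------------------------------
# site overlap
# ---------------------------------------------------------------------------
def _site_intervals(x) -> list[GenomicInterval]:
    if isinstance(x, Umotif):
        return list(x.sites)
    return [s.interval for s in x.sites]


def site_overlap_rate(m, n) -> Optional[float]:
    """Fraction of the smaller site set overlapping (>= 1 bp) the other."""
    si, sj = _site_intervals(m), _site_intervals(n)
    if not si or not sj:
        return None
    small, big = (si, sj) if len(si) <= len(sj) else (sj, si)
    big_set = AnnotationSet(big, kind="sites")
    hit = sum(1 for iv in small if big_set.any_overlap(iv))
    return hit / len(small)


# ---------------------------------------------------------------------------
# Umotif merging (iterative)
# ---------------------------------------------------------------------------
def _merge_intervals(ivs: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    merged = merge_labelled_intervals([(iv, frozenset()) for iv in ivs])
    return [iv for iv, _ in merged]


def _rediscover(
    cluster: list[Motif],
    genome: Genome,
    cfg: AssemblyConfig,
    seed: int,
) -> tuple[PSWM, list[GenomicInterval]]:
    """Re-find the common motif on the 5 bp-padded member sites.

    Member CREs are padded, the internal finder is run on the padded site
    sequences against their Markov negatives, and the best motif's sites
    (mapped back to the genome) replace the old ones. When nothing clears
    the E-value threshold the member site union and a site-built PSWM are
    kept instead.
    """
    from .peaks import Dataset, Peak  # local import to avoid a cycle

    padded: list[tuple[GenomicInterval, Site]] = []
    for m in cluster:
        for s in m.sites:
            iv = s.interval
            start = max(0, iv.start - cfg.cre_pad)
            end = min(genome.chrom_length(iv.chrom), iv.end + cfg.cre_pad)
            padded.append((GenomicInterval(iv.chrom, start, end, s.strand), s))
    widths = sorted({m.pswm.width for m in cluster})
    peaks = [
        Peak(peak_id=f"site:{i}", dataset_id="merge", original=iv, extended=iv)
        for i, (iv, _) in enumerate(padded)
    ]
    ds = Dataset("merge", "merge", peaks)
    disc = DiscoveryConfig(
        widths=tuple(range(max(4, min(widths)), max(widths) + 1)),
        evalue_threshold=0.05,
        max_motifs=1,
        markov_order=1,
        seed=seed,
    )
    found = find_motifs(ds, genome, disc)
    if found:
        best = found[0]
        return best.pswm, _merge_intervals([s.interval for s in best.sites])
    # fallback: union of member sites, PSWM from member site sequences
    seqs = [s.seq for m in cluster for s in m.sites]
    pswm = PSWM.from_sites([q for q in seqs if len(q) == len(seqs[0])])
    return pswm, _merge_intervals([s.interval for m in cluster for s in m.sites])


def merge_umotifs(
    motifs: Sequence[Motif],
    genome: Genome,
    simcfg: SimilarityConfig = SimilarityConfig(),
    cfg: AssemblyConfig = AssemblyConfig(),
    mclcfg: MclConfig = MclConfig(),
    seed: int = 0,
) -> tuple[list[Umotif], dict[str, str]]:
    """Iteratively merge similar motifs into Umotifs.

    Returns the Umotif list and a map from every input motif id to its
    Umotif id. On termination no two Umotifs have similarity > 0.4 together
    with site-overlap rate > 0.5.
    """
    # working state: list of (member ids, Motif-like carrier)
    @dataclass
    class _Work:
        members: list[str]
        pswm: PSWM
        sites: list[Site]
        evidence: list[Site]

    work = [
        _Work([m.motif_id], m.pswm, list(m.sites),
              list(m.evidence_sites) if m.evidence_sites else list(m.sites))
        for m in motifs
    ]

    def sim(a: _Work, b: _Work) -> float:
        s = motif_similarity(a.pswm, b.pswm, simcfg)
        return 0.0 if s is None else s

    def orate(a: _Work, b: _Work) -> float:
        # the terminal invariant is on the carried site lists; the
        # substitution-tolerant evidence overlap additionally captures
        # variants of one motif whose exact-pattern sites are disjoint
        class _C:  # adapter for site_overlap_rate
            def __init__(self, sites):
                self.sites = sites
        r1 = site_overlap_rate(_C(a.sites), _C(b.sites)) or 0.0
        r2 = site_overlap_rate(_C(a.evidence), _C(b.evidence)) or 0.0
        return max(r1, r2)

    for iteration in range(cfg.max_merge_iterations):
        g = WeightedGraph()
        for i in range(len(work)):
            g.add_node(i)
        any_edge = False
        for i, j in itertools.combinations(range(len(work)), 2):
            s = sim(work[i], work[j])
            merge_now = s > cfg.merge_edge_threshold
            if not merge_now and iteration > 0:
                # progress guarantee: pairs violating the stop condition
                # are merged even below the primary edge threshold
                if s > cfg.stop_similarity and orate(work[i], work[j]) > cfg.stop_overlap:
                    merge_now = True
            if merge_now:
                g.add_edge(i, j, max(s, 1e-6))
                any_edge = True
        if not any_edge:
            break
        clusters = mcl(g, mclcfg).clusters
        new_work: list[_Work] = []
        for members in sorted(clusters, key=lambda c: sorted(c)[0] if c else 0):
            items = [work[i] for i in sorted(members)]
            if len(items) == 1:
                new_work.append(items[0])
                continue
            cluster_motifs = [
                Motif(motif_id=f"tmp{i}", dataset_id="merge", pswm=it.pswm, sites=it.sites)
                for i, it in enumerate(items)
            ]
            pswm, merged_sites = _rediscover(cluster_motifs, genome, cfg, seed + iteration)
            if cfg.umotif_site_policy == "member-union":
                merged_sites = _merge_intervals(
                    [s.interval for it in items for s in it.sites]
                )
            # carry sites as Site records for further rounds
            carrier_sites = [
                Site(peak_id=f"merged:{k}", interval=iv, strand=".",
                     seq=genome.fetch(iv))
                for k, iv in enumerate(merged_sites)
            ]
            merged_evidence = _merge_intervals(
                [s.interval for it in items for s in it.evidence]
            )
            carrier_evidence = [
                Site(peak_id=f"ev:{k}", interval=iv, strand=".", seq="")
                for k, iv in enumerate(merged_evidence)
            ]
            new_work.append(
                _Work(
                    members=sorted(mid for it in items for mid in it.members),
                    pswm=pswm,
                    sites=carrier_sites,
                    evidence=carrier_evidence,
                )
            )
        work = new_work
        # stop when no pair violates the terminal condition
        violating = False
        for i, j in itertools.combinations(range(len(work)), 2):
            if sim(work[i], work[j]) > cfg.stop_similarity and \
               orate(work[i], work[j]) > cfg.stop_overlap:
                violating = True
                break
        if not violating:
            break
    else:
        log.warning("Umotif merging hit max iterations (%d)", cfg.max_merge_iterations)

    work.sort(key=lambda wk: wk.members[0])
    umotifs: list[Umotif] = []
    mapping: dict[str, str] = {}
    for k, wk in enumerate(work):
        uid = f"U{k + 1}"
        umotifs.append(
            Umotif(
                umotif_id=uid,
                member_motif_ids=list(wk.members),
                pswm=wk.pswm,
                sites=_merge_intervals([s.interval for s in wk.sites]),
            )
        )
        for mid in wk.members:
            mapping[mid] = uid
    return umotifs, mapping


def apply_umotifs_to_crmcs(
    crmcs: Sequence[CRMC], umotif_map: dict[str, str]
) -> list[CRMC]:
    """Rewrite CRMC motif sets as Umotif sets; CRMCs with identical Umotif
    sets are merged (provenance unioned)."""
    by_pattern: dict[frozenset, list[CRMC]] = {}
    for c in crmcs:
        missing = [m for m in c.motif_ids if m not in umotif_map]
        if missing:
            raise KeyError(f"CRMC {c.crmc_id}: motifs without Umotif mapping: {missing}")
        pattern = frozenset(umotif_map[m] for m in c.motif_ids)
        by_pattern.setdefault(pattern, []).append(c)
    out = []
    for pattern in sorted(by_pattern, key=lambda p: sorted(p)):
        group = by_pattern[pattern]
        out.append(
            CRMC(
                crmc_id=f"crmc{len(out) + 1}",
                cpc_ids=sorted({cid for c in group for cid in c.cpc_ids}),
                motif_ids=sorted({m for c in group for m in c.motif_ids}),
                umotif_ids=sorted(pattern),
            )
        )
    return out


# ---------------------------------------------------------------------------
# projection and linkage
# ---------------------------------------------------------------------------
def project_cres(umotifs: Sequence[Umotif]) -> list[tuple[GenomicInterval, frozenset]]:
    """Project all Umotif sites onto the genome; overlapping projections are
    merged into non-overlapping intervals carrying all contributing Umotif
    ids. Half-open adjacency is not merged."""
    labelled = [
        (GenomicInterval(iv.chrom, iv.start, iv.end), frozenset([u.umotif_id]))
        for u in umotifs
        for iv in u.sites
    ]
    return merge_labelled_intervals(labelled)


def link_cres_into_crms(
    cres: Sequence[tuple[GenomicInterval, frozenset]],
    exons: AnnotationSet,
    delta: int = 150,
    umotif_to_crmcs: Optional[dict[str, list[str]]] = None,
) -> list[CRM]:
    """Link adjacent CREs closer than delta into CRMs.

    A link is blocked when the gap fully contains an exon, unless that exon
    itself contains a projected CRE. Maximal linked runs of >= 2 CREs become
    CRMs; singleton CREs do not.
    """
    cre_set = AnnotationSet([iv for iv, _ in cres], kind="cre")
    exon_has_cre = {iv: cre_set.any_overlap(iv) for iv in exons.intervals}

    def blocked(chrom: str, gap_start: int, gap_end: int) -> bool:
        if gap_end <= gap_start:
            return False
        for e in exons.overlapping(GenomicInterval(chrom, gap_start, gap_end)):
            if e.start >= gap_start and e.end <= gap_end and not exon_has_cre[e]:
                return True
        return False

    ordered = sorted(cres, key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    crms: list[CRM] = []
    run: list[tuple[GenomicInterval, frozenset]] = []

    def flush() -> None:
        if len(run) >= 2:
            span = GenomicInterval(run[0][0].chrom, run[0][0].start, run[-1][0].end)
            uids = sorted({u for _, lab in run for u in lab})
            crmc_ids = sorted({
                c for u in uids for c in (umotif_to_crmcs or {}).get(u, [])
            })
            crms.append(
                CRM(
                    crm_id=f"crm{len(crms) + 1}",
                    span=span,
                    cres=list(run),
                    crmc_ids=crmc_ids,
                )
            )
        run.clear()

    for iv, lab in ordered:
        if run:
            prev = run[-1][0]
            gap = iv.start - prev.end
            same = prev.chrom == iv.chrom
            if same and 0 <= gap < delta and not blocked(iv.chrom, prev.end, iv.start):
                run.append((iv, lab))
                continue
            flush()
        run.append((iv, lab))
    flush()
    return crms


def assign_target_genes(crms: Sequence[CRM], genes: Sequence[Gene]) -> list[CRM]:
    """Assign each CRM the gene whose TSS is nearest its span (distance 0
    when the TSS lies inside); ties break to the lexicographically smaller
    gene id. Returns new CRM records."""
    if not genes:
        raise ValueError("gene list is empty")
    out = []
    for crm in crms:
        best: Optional[tuple[int, str]] = None
        for gene in genes:
            if gene.chrom != crm.span.chrom:
                continue
            if crm.span.start <= gene.tss < crm.span.end:
                d = 0
            else:
                d = min(abs(gene.tss - crm.span.start), abs(gene.tss - (crm.span.end - 1)))
            cand = (d, gene.gene_id)
            if best is None or cand < best:
                best = cand
        if best is None:  # no gene on this chromosome: fall back to any gene
            best = min(
                (abs(g.tss - crm.span.start), g.gene_id) for g in genes
            )
        out.append(replace(crm, target_gene=best[1], target_distance=best[0]))
    return out
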