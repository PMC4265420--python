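"""End-to-end orchestration with checkpoints, funnel reporting and manifest.

Stage order: prep -> discovery (+QC, + CRE re-placement by scanning) ->
CPs -> CPCs -> CRMCs -> Umotifs -> CRM projection/linkage -> evaluation.
Each stage writes a JSON checkpoint; a run is resumable from any of them,
and the manifest lists every output with a content hash so identical seeds
can be verified to give byte-identical runs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .assembly import (
    CRM,
    AssemblyConfig,
    Umotif,
    apply_umotifs_to_crmcs,
    assign_target_genes,
    link_cres_into_crms,
    merge_umotifs,
    project_cres,
)
from .discovery import (
    DiscoveryConfig,
    Motif,
    Site,
    apply_dataset_qc,
    attach_scan_support,
    find_motifs,
)
from .evaluation import (
    ConservationReport,
    RecoveryReport,
    circular_random_baseline,
    conservation_compare,
    recovery_rate,
)
from .genome import Genome
from .graphs import MclConfig
from .intervals import AnnotationSet, ConservationTrack, GenomicInterval
from .mining import (
    CP,
    CPC,
    CRMC,
    MiningConfig,
    all_pair_scores,
    build_cp_graph,
    find_cps,
    find_cpcs,
    find_crmcs,
    select_alpha,
    select_beta,
    select_gamma,
)
from .peaks import Dataset, Peak, PrepConfig, PrepReport, dataset_overlap_score, extend_peaks, filter_hot
from .pswm import PSWM
from .similarity import SimilarityConfig

log = logging.getLogger(__name__)

STAGES = ["prep", "discovery", "cps", "cpcs", "crmcs", "umotifs", "crms", "evaluation"]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    prep: PrepConfig = field(default_factory=PrepConfig)
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    mcl: MclConfig = field(default_factory=MclConfig)
    mining: MiningConfig = field(default_factory=MiningConfig)
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    # CRE placement: accepted motifs are re-scanned over the peaks with a
    # smoothed log-odds matrix; 0.5 of the maximum score admits roughly one
    # substitution in a sharp width-8 motif.
    scan_fraction: float = 0.5
    scan_rel_pseudocount: float = 0.04
    # CRE projection source:
    #   "anchored-scan" (default): the union of the member motifs'
    #     discovered sites anchors the projection; substitution-tolerant
    #     scan hits are added only where an anchor of another Umotif lies
    #     within the CRM linkage distance (context-supported site rescue)
    #   "pattern-sites": anchors only (high precision, misses mutated sites)
    #   "scan-genome": every scan hit (high recall, high noise floor)
    projection: str = "anchored-scan"
    baseline_reps: int = 50
    seed: int = 0

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        sub = {
            "prep": PrepConfig, "discovery": DiscoveryConfig, "similarity": SimilarityConfig,
            "mcl": MclConfig, "mining": MiningConfig, "assembly": AssemblyConfig,
        }
        for k, v in d.items():
            if k in sub:
                if "widths" in v:
                    v = dict(v, widths=tuple(v["widths"]))
                kwargs[k] = sub[k](**v)
            else:
                kwargs[k] = v
        return cls(**kwargs)


@dataclass
class PipelineResult:
    config: PipelineConfig
    datasets: list[Dataset]
    motifs: dict[str, list[Motif]]          # QC-passed, refined sites
    raw_motif_counts: dict[str, int]
    cps: list[CP]
    cpcs: list[CPC]
    crmcs: list[CRMC]
    merged_crmcs: list[CRMC]
    umotifs: list[Umotif]
    cres: list[tuple[GenomicInterval, frozenset]]
    crms: list[CRM]
    funnel: dict
    thresholds: dict
    recovery: Optional[RecoveryReport] = None
    conservation: Optional[ConservationReport] = None
    manifest: Optional[dict] = None


# ---------------------------------------------------------------------------
# JSON (de)serialization of stage state
# ---------------------------------------------------------------------------
def _iv_to_d(iv: GenomicInterval) -> dict:
    return {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "strand": iv.strand}


def _iv_from_d(d: dict) -> GenomicInterval:
    return GenomicInterval(d["chrom"], d["start"], d["end"], d.get("strand", "."))


def _motif_to_d(m: Motif) -> dict:
    return {
        "motif_id": m.motif_id,
        "dataset_id": m.dataset_id,
        "consensus": m.consensus,
        "evalue": m.evalue,
        "counts": [[round(x, 6) for x in row] for row in m.pswm.counts.tolist()],
        "pseudocount": m.pswm.pseudocount,
        "sites": [
            {"peak_id": s.peak_id, "strand": s.strand, "seq": s.seq, **_iv_to_d(s.interval)}
            for s in m.sites
        ],
    }


def _motif_from_d(d: dict) -> Motif:
    return Motif(
        motif_id=d["motif_id"],
        dataset_id=d["dataset_id"],
        pswm=PSWM(np.array(d["counts"]), pseudocount=d["pseudocount"], name=d["motif_id"]),
        sites=[
            Site(s["peak_id"], _iv_from_d(s), s["strand"], s["seq"]) for s in d["sites"]
        ],
        consensus=d.get("consensus", ""),
        evalue=d.get("evalue", float("nan")),
    )


class _Checkpointer:
    def __init__(self, out_dir: Optional[Union[str, Path]]):
        self.dir = Path(out_dir) if out_dir is not None else None
        if self.dir is not None:
            (self.dir / "checkpoints").mkdir(parents=True, exist_ok=True)
        self.files: dict[str, str] = {}

    def path(self, name: str) -> Optional[Path]:
        return None if self.dir is None else self.dir / "checkpoints" / f"{name}.json"

    def write(self, name: str, payload) -> None:
        if self.dir is None:
            return
        p = self.path(name)
        with open(p, "w") as fh:
            json.dump({"schema": 1, "stage": name, "data": payload}, fh, sort_keys=True)
        self.files[str(p.relative_to(self.dir))] = _sha256(p)

    def read(self, name: str):
        p = self.path(name)
        if p is None or not p.exists():
            raise StageError(name, f"checkpoint {p} not found for resume")
        with open(p) as fh:
            return json.load(fh)["data"]

    def write_text(self, relname: str, text: str) -> None:
        if self.dir is None:
            return
        p = self.dir / relname
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(text)
        self.files[relname] = _sha256(p)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------
def covered_regions(datasets: Sequence[Dataset]) -> AnnotationSet:
    """Union of all extended peaks (the sequence space the pipeline sees)."""
    return AnnotationSet(
        [p.extended for ds in datasets for p in ds.peaks], kind="covered"
    ).merged()


def scan_umotif_sites(
    umotifs: Sequence[Umotif],
    covered: AnnotationSet,
    genome: Genome,
    score_fraction: float,
    rel_pseudocount: float,
) -> list[Umotif]:
    """Re-place each Umotif's CREs by scanning the covered genome regions
    with its smoothed matrix (same tolerance as support counting)."""
    from .discovery import scan_sites

    segs = covered.intervals
    seqs = [genome.fetch(iv) for iv in segs]
    out = []
    for u in umotifs:
        scan = u.pswm.smoothed(rel_pseudocount)
        hits = scan_sites(scan, seqs, score_fraction)
        w = u.pswm.width
        ivs = []
        for h in hits:
            seg = segs[h.seq_index]
            ivs.append(GenomicInterval(seg.chrom, seg.start + h.offset, seg.start + h.offset + w))
        merged: list[GenomicInterval] = []
        for iv in sorted(ivs, key=lambda x: (x.chrom, x.start)):
            if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
                if iv.end > merged[-1].end:
                    merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
            else:
                merged.append(iv)
        out.append(Umotif(u.umotif_id, u.member_motif_ids, u.pswm, merged))
    return out


def _anchor_rescue(
    anchors: Sequence[Umotif], scanned: Sequence[Umotif], delta: int
) -> list[Umotif]:
    """Two-tier CRE placement: exact-pattern sites anchor; a scan hit is
    kept only when a non-overlapping anchor of a *different* Umotif lies
    within the linkage distance. Mutated true sites sit next to their
    grammar partners' anchors and are rescued; isolated scan noise is not.
    """
    anchor_ivs: list[tuple[GenomicInterval, str]] = [
        (iv, u.umotif_id) for u in anchors for iv in u.sites
    ]
    tree = AnnotationSet([iv for iv, _ in anchor_ivs], kind="anchor")
    labels: dict[tuple, set] = {}
    for iv, uid in anchor_ivs:
        labels.setdefault((iv.chrom, iv.start, iv.end), set()).add(uid)
    anchor_by_u = {u.umotif_id: set((iv.chrom, iv.start, iv.end) for iv in u.sites) for u in anchors}
    out = []
    scanned_by_id = {u.umotif_id: u for u in scanned}
    for u in anchors:
        keep = {(iv.chrom, iv.start, iv.end) for iv in u.sites}
        for iv in scanned_by_id[u.umotif_id].sites:
            window = GenomicInterval(
                iv.chrom, max(0, iv.start - delta + 1), iv.end + delta - 1
            )
            for hit in tree.overlapping(window):
                if hit.overlaps(iv):
                    continue
                if labels[(hit.chrom, hit.start, hit.end)] - {u.umotif_id}:
                    keep.add((iv.chrom, iv.start, iv.end))
                    break
        sites = sorted(GenomicInterval(c, s, e) for c, s, e in keep)
        # collapse overlaps
        merged: list[GenomicInterval] = []
        for iv in sites:
            if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
                if iv.end > merged[-1].end:
                    merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
            else:
                merged.append(iv)
        out.append(Umotif(u.umotif_id, u.member_motif_ids, u.pswm, merged))
    return out


def run_pipeline(
    datasets: Sequence[Dataset],
    genome: Genome,
    cfg: PipelineConfig = PipelineConfig(),
    exons: Optional[AnnotationSet] = None,
    hot: Optional[AnnotationSet] = None,
    known_crms: Optional[AnnotationSet] = None,
    conservation: Optional[ConservationTrack] = None,
    genes: Optional[Sequence] = None,
    out_dir: Optional[Union[str, Path]] = None,
    resume_from: Optional[str] = None,
) -> PipelineResult:
    """Run the full pipeline. See module docstring for the stage order.

    ``resume_from`` names the first stage to *recompute*; all earlier stages
    are loaded from checkpoints in ``out_dir``.
    """
    if len(datasets) < 2:
        raise StageError("prep", "at least 2 datasets are required (pair mining needs cross-dataset evidence)")
    if resume_from is not None and resume_from not in STAGES:
        raise ValueError(f"unknown stage {resume_from!r}; stages are {STAGES}")
    exons = exons if exons is not None else AnnotationSet([], kind="exon")
    hot = hot if hot is not None else AnnotationSet([], kind="hot")
    ck = _Checkpointer(out_dir)
    resume_idx = STAGES.index(resume_from) if resume_from else 0
    ss = np.random.SeedSequence(cfg.seed)
    stage_seed = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGES, ss.spawn(len(STAGES)))
    }

    funnel: dict = {"n_datasets_input": len(datasets)}
    thresholds: dict = {}

    # -- prep ---------------------------------------------------------------
    if resume_idx > STAGES.index("prep"):
        data = ck.read("prep")
        prepped = [
            Dataset(
                d["dataset_id"], d["tf_name"],
                [
                    Peak(p["peak_id"], d["dataset_id"], _iv_from_d(p["original"]),
                         _iv_from_d(p["extended"]), p.get("is_signal"))
                    for p in d["peaks"]
                ],
            )
            for d in data
        ]
    else:
        prepped = []
        prep_reports: list[PrepReport] = []
        for ds in datasets:
            rep = PrepReport(ds.dataset_id, n_input=len(ds))
            ds2 = filter_hot(ds, hot, rep)
            ds2 = extend_peaks(ds2, genome, exons, cfg.prep, rep)
            prepped.append(ds2)
            prep_reports.append(rep)
        ck.write_text(
            "prep_report.tsv",
            "dataset\tn_input\tn_hot_removed\tn_too_long\tn_kept\n"
            + "".join(
                f"{r.dataset_id}\t{r.n_input}\t{r.n_hot_removed}\t{r.n_too_long}\t{r.n_kept}\n"
                for r in prep_reports
            ),
        )
        ck.write(
            "prep",
            [
                {
                    "dataset_id": d.dataset_id,
                    "tf_name": d.tf_name,
                    "peaks": [
                        {"peak_id": p.peak_id, "original": _iv_to_d(p.original),
                         "extended": _iv_to_d(p.extended), "is_signal": p.is_signal}
                        for p in d.peaks
                    ],
                }
                for d in prepped
            ],
        )
    funnel["n_peaks_prepped"] = sum(len(d) for d in prepped)

    # -- discovery + QC + CRE placement ------------------------------------
    if resume_idx > STAGES.index("discovery"):
        data = ck.read("discovery")
        motifs = {k: [_motif_from_d(m) for m in v] for k, v in data["motifs"].items()}
        raw_counts = data["raw_counts"]
        # scan-derived support and evidence are deterministic; recompute
        # rather than storing the bulky hit lists in the checkpoint
        ds_index = {d.dataset_id: d for d in prepped}
        motifs = {
            k: [
                attach_scan_support(m, ds_index[k], genome,
                                    cfg.scan_fraction, cfg.scan_rel_pseudocount)
                for m in v
            ]
            for k, v in motifs.items()
        }
    else:
        motifs = {}
        raw_counts = {}
        for i, ds in enumerate(prepped):
            dcfg = dataclasses.replace(
                cfg.discovery, seed=(stage_seed["discovery"] + i) % (2**31)
            )
            found = find_motifs(ds, genome, dcfg)
            raw_counts[ds.dataset_id] = len(found)
            motifs[ds.dataset_id] = found
            log.info("dataset %s: %d motifs", ds.dataset_id, len(found))
        motifs = apply_dataset_qc(motifs)
        if len(motifs) < 2:
            raise StageError(
                "discovery",
                "dataset QC left fewer than 2 datasets with >= 2 motifs; "
                "cross-dataset mining is impossible",
            )
        # supporting-peak evidence: substitution-tolerant re-scan of each
        # accepted motif against its dataset (original-peak overlap)
        ds_index = {d.dataset_id: d for d in prepped}
        motifs = {
            k: [
                attach_scan_support(m, ds_index[k], genome,
                                    cfg.scan_fraction, cfg.scan_rel_pseudocount)
                for m in v
            ]
            for k, v in motifs.items()
        }
        ck.write(
            "discovery",
            {
                "motifs": {k: [_motif_to_d(m) for m in v] for k, v in motifs.items()},
                "raw_counts": raw_counts,
            },
        )
    funnel["n_datasets_qc"] = len(motifs)
    funnel["n_motifs"] = sum(len(v) for v in motifs.values())

    # -- CPs ----------------------------------------------------------------
    motif_index = {m.motif_id: m for v in motifs.values() for m in v}
    if resume_idx > STAGES.index("cps"):
        data = ck.read("cps")
        cps = [
            CP(d["cp_id"], d["dataset_id"], tuple(d["motif_ids"]), d["sc"],
               frozenset(d["peak_ids"]))
            for d in data["cps"]
        ]
        alpha = data["alpha"]
    else:
        sc_values = all_pair_scores(motifs)
        alpha, _table = select_alpha(sc_values, cfg.mining)
        mining = dataclasses.replace(cfg.mining, alpha=alpha)
        cps = find_cps(motifs, mining)
        ck.write(
            "cps",
            {
                "alpha": alpha,
                "cps": [
                    {"cp_id": c.cp_id, "dataset_id": c.dataset_id,
                     "motif_ids": list(c.motif_ids), "sc": c.sc,
                     "peak_ids": sorted(c.peak_ids)}
                    for c in cps
                ],
            },
        )
    thresholds["alpha"] = alpha
    funnel["n_cps"] = len(cps)
    funnel["n_motifs_in_cps"] = len({m for c in cps for m in c.motif_ids})

    # -- CPCs ---------------------------------------------------------------
    if resume_idx > STAGES.index("cpcs"):
        data = ck.read("cpcs")
        cpcs = [CPC(d["cpc_id"], d["cp_ids"], d["motif_ids"], d["dataset_ids"]) for d in data["cpcs"]]
        beta = data["beta"]
    else:
        beta, _bt = select_beta(cps, motif_index, cfg.mining, simcfg=cfg.similarity) \
            if cfg.mining.threshold_mode == "auto" else (cfg.mining.beta, None)
        graph = build_cp_graph(cps, motif_index, beta, cfg.similarity)
        cpcs = find_cpcs(graph, cps, cfg.mcl, cfg.mining.tau)
        ck.write(
            "cpcs",
            {
                "beta": beta,
                "cpcs": [dataclasses.asdict(c) for c in cpcs],
            },
        )
    thresholds["beta"] = beta
    funnel["n_cpcs"] = len(cpcs)
    funnel["n_motifs_in_cpcs"] = len({m for c in cpcs for m in c.motif_ids})

    # -- CRMCs --------------------------------------------------------------
    if resume_idx > STAGES.index("crmcs"):
        data = ck.read("crmcs")
        crmcs = [CRMC(d["crmc_id"], d["cpc_ids"], d["motif_ids"], d.get("umotif_ids", [])) for d in data["crmcs"]]
        gamma = data["gamma"]
    else:
        if cfg.mining.threshold_mode == "auto":
            from .mining import build_cpc_graph

            _g, scores = build_cpc_graph(cpcs, cps, 0.0)
            gamma = select_gamma(scores, cfg.mining)
        else:
            gamma = cfg.mining.gamma
        crmcs = find_crmcs(cpcs, cps, gamma, cfg.mcl)
        ck.write(
            "crmcs",
            {"gamma": gamma, "crmcs": [dataclasses.asdict(c) for c in crmcs]},
        )
    thresholds["gamma"] = gamma
    funnel["n_crmcs"] = len(crmcs)
    funnel["n_motifs_in_crmcs"] = len({m for c in crmcs for m in c.motif_ids})

    # -- Umotifs ------------------------------------------------------------
    covered = covered_regions(prepped)
    if resume_idx > STAGES.index("umotifs"):
        data = ck.read("umotifs")
        umotifs = [
            Umotif(d["umotif_id"], d["member_motif_ids"],
                   PSWM(np.array(d["counts"]), pseudocount=d["pseudocount"], name=d["umotif_id"]),
                   [_iv_from_d(iv) for iv in d["sites"]])
            for d in data["umotifs"]
        ]
        umotif_map = data["map"]
        merged_crmcs = [
            CRMC(d["crmc_id"], d["cpc_ids"], d["motif_ids"], d["umotif_ids"])
            for d in data["merged_crmcs"]
        ]
    else:
        crmc_motifs = sorted({m for c in crmcs for m in c.motif_ids})
        umotifs, umotif_map = merge_umotifs(
            [motif_index[m] for m in crmc_motifs],
            genome,
            cfg.similarity,
            cfg.assembly,
            cfg.mcl,
            seed=stage_seed["umotifs"],
        )
        if cfg.projection == "scan-genome":
            umotifs = scan_umotif_sites(
                umotifs, covered, genome, cfg.scan_fraction, cfg.scan_rel_pseudocount
            )
        elif cfg.projection == "anchored-scan":
            scanned = scan_umotif_sites(
                umotifs, covered, genome, cfg.scan_fraction, cfg.scan_rel_pseudocount
            )
            umotifs = _anchor_rescue(umotifs, scanned, cfg.assembly.delta)
        merged_crmcs = apply_umotifs_to_crmcs(crmcs, umotif_map)
        ck.write(
            "umotifs",
            {
                "map": umotif_map,
                "umotifs": [
                    {
                        "umotif_id": u.umotif_id,
                        "member_motif_ids": u.member_motif_ids,
                        "counts": [[round(x, 6) for x in row] for row in u.pswm.counts.tolist()],
                        "pseudocount": u.pswm.pseudocount,
                        "sites": [_iv_to_d(iv) for iv in u.sites],
                    }
                    for u in umotifs
                ],
                "merged_crmcs": [dataclasses.asdict(c) for c in merged_crmcs],
            },
        )
    funnel["n_umotifs"] = len(umotifs)
    funnel["n_crmcs_merged"] = len(merged_crmcs)

    # -- CRMs ---------------------------------------------------------------
    if resume_idx > STAGES.index("crms"):
        data = ck.read("crms")
        cres = [(_iv_from_d(d), frozenset(d["umotifs"])) for d in data["cres"]]
        crms = [
            CRM(d["crm_id"], _iv_from_d(d["span"]),
                [(_iv_from_d(c), frozenset(c["umotifs"])) for c in d["cres"]],
                d["crmc_ids"], d.get("target_gene"), d.get("target_distance"),
                d.get("mean_conservation"))
            for d in data["crms"]
        ]
    else:
        cres = project_cres(umotifs)
        u2c: dict[str, list[str]] = {}
        for c in merged_crmcs:
            for u in c.umotif_ids:
                u2c.setdefault(u, []).append(c.crmc_id)
        crms = link_cres_into_crms(cres, exons, cfg.assembly.delta, u2c)
        if genes:
            crms = assign_target_genes(crms, genes)
        if conservation is not None:
            crms = [
                dataclasses.replace(c, mean_conservation=conservation.mean(c.span))
                for c in crms
            ]
        ck.write(
            "crms",
            {
                "cres": [dict(_iv_to_d(iv), umotifs=sorted(lab)) for iv, lab in cres],
                "crms": [
                    {
                        "crm_id": c.crm_id,
                        "span": _iv_to_d(c.span),
                        "cres": [dict(_iv_to_d(iv), umotifs=sorted(lab)) for iv, lab in c.cres],
                        "crmc_ids": c.crmc_ids,
                        "target_gene": c.target_gene,
                        "target_distance": c.target_distance,
                        "mean_conservation": c.mean_conservation,
                    }
                    for c in crms
                ],
            },
        )
    funnel["n_cres"] = len(cres)
    funnel["n_crms"] = len(crms)

    # -- evaluation ---------------------------------------------------------
    recovery = None
    cons_report = None
    if known_crms is not None and len(known_crms) and crms:
        recovery = recovery_rate(known_crms, crms)
        mean, sd, _rates = circular_random_baseline(
            crms, covered, known_crms, n_reps=cfg.baseline_reps,
            seed=stage_seed["evaluation"],
        )
        recovery.baseline_mean = mean
        recovery.baseline_sd = sd
        funnel["known_recovery_rate"] = recovery.rate
        funnel["baseline_recovery_mean"] = mean
        cre_set = AnnotationSet([iv for iv, _ in cres], kind="cre")
        funnel["known_with_cre"] = sum(1 for k in known_crms if cre_set.any_overlap(k))
    if conservation is not None and crms:
        cons_report = conservation_compare(
            [c.span for c in crms], conservation, covered,
            seed=stage_seed["evaluation"],
        )
        ck.write(
            "evaluation",
            {
                "ks_statistic": cons_report.ks_statistic,
                "ks_pvalue": cons_report.ks_pvalue,
                "n_highly_conserved": cons_report.n_highly_conserved,
                "n_non_conserved": cons_report.n_non_conserved,
            },
        )

    # -- reports and manifest ----------------------------------------------
    funnel_lines = ["metric\tvalue"] + [f"{k}\t{v}" for k, v in funnel.items()]
    ck.write_text("funnel.tsv", "\n".join(funnel_lines) + "\n")
    disc_lines = ["dataset\tn_motifs_discovered\tn_motifs_kept\tranks"]
    for ds_id in sorted(raw_counts):
        kept = motifs.get(ds_id, [])
        ranks = ",".join(m.motif_id.rsplit("m", 1)[-1] for m in kept)
        disc_lines.append(f"{ds_id}\t{raw_counts[ds_id]}\t{len(kept)}\t{ranks}")
    ck.write_text("discovery_report.tsv", "\n".join(disc_lines) + "\n")
    if ck.dir is not None:
        from .io import write_meme_motifs

        all_pswms = [m.pswm for v in motifs.values() for m in v]
        write_meme_motifs(ck.dir / "motifs.meme", all_pswms)
        ck.files["motifs.meme"] = _sha256(ck.dir / "motifs.meme")
        umotif_pswms = []
        for u in umotifs:
            p = PSWM(u.pswm.counts, pseudocount=u.pswm.pseudocount, name=u.umotif_id)
            umotif_pswms.append(p)
        write_meme_motifs(ck.dir / "umotifs.meme", umotif_pswms)
        ck.files["umotifs.meme"] = _sha256(ck.dir / "umotifs.meme")
    bed_lines = []
    for iv, lab in cres:
        bed_lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{','.join(sorted(lab))}\t0\t.")
    ck.write_text("cres.bed", "\n".join(bed_lines) + ("\n" if bed_lines else ""))
    bed_lines = []
    for c in crms:
        score = c.mean_conservation if c.mean_conservation is not None else 0
        bed_lines.append(
            f"{c.span.chrom}\t{c.span.start}\t{c.span.end}\t{c.crm_id}\t{score:g}\t."
        )
    ck.write_text("crms.bed", "\n".join(bed_lines) + ("\n" if bed_lines else ""))

    manifest = None
    if ck.dir is not None:
        manifest = {
            "schema": 1,
            "seed": cfg.seed,
            "config": cfg.to_dict(),
            "thresholds": thresholds,
            "funnel": funnel,
            "files": dict(sorted(ck.files.items())),
        }
        with open(ck.dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=1)

    return PipelineResult(
        config=cfg,
        datasets=list(prepped),
        motifs=motifs,
        raw_motif_counts=raw_counts,
        cps=cps,
        cpcs=cpcs,
        crmcs=crmcs,
        merged_crmcs=merged_crmcs,
        umotifs=umotifs,
        cres=cres,
        crms=crms,
        funnel=funnel,
        thresholds=thresholds,
        recovery=recovery,
        conservation=cons_report,
        manifest=manifest,
    )
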