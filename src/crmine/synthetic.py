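"""Fully ground-truthed synthetic inputs for the whole pipeline.

The generator emulates the situation the mining stages assume: a genome
carrying planted CRMs, each an instance of a recurring "grammar" (a fixed
combination of TF motifs written at random spacings with per-base
mutations), and per-TF peak datasets whose signal peaks pile up over the
planted sites of that TF while noise peaks fall uniformly. Every stage of
the pipeline can therefore be scored against exact truth records.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome import Genome, reverse_complement
from .intervals import AnnotationSet, GenomicInterval
from .peaks import Dataset, Peak

log = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class PlantedCre:
    interval: GenomicInterval
    motif_index: int
    strand: str
    seq: str  # as written into the genome, motif orientation


@dataclass
class PlantedCrm:
    interval: GenomicInterval
    grammar_index: int
    cres: list[PlantedCre]


@dataclass
class SyntheticTruth:
    """Everything needed to score pipeline output against the plant."""

    genome: Genome
    consensi: list[str]
    grammars: list[tuple]
    crms: list[PlantedCrm]
    datasets: list[Dataset] = field(default_factory=list)
    dataset_tf: dict = field(default_factory=dict)  # dataset id -> motif index
    params: dict = field(default_factory=dict)

    @property
    def planted_cres(self) -> list[PlantedCre]:
        return [c for crm in self.crms for c in crm.cres]

    def known_crm_set(self) -> AnnotationSet:
        return AnnotationSet([c.interval for c in self.crms], kind="known_crm")

    def sites_of_motif(self, motif_index: int) -> list[PlantedCre]:
        return [c for c in self.planted_cres if c.motif_index == motif_index]


def make_genome(
    length: int,
    gc: float = 0.45,
    seed: int = 0,
    chrom: str = "chr1",
) -> Genome:
    """An i.i.d. random genome at the stated GC fraction."""
    if length <= 0:
        raise ValueError("length must be > 0")
    if not (0 < gc < 1):
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode()
    return Genome({chrom: seq})


def random_motif_library(
    n_motifs: int,
    width: int = 8,
    seed: int = 0,
    min_hamming: int = 3,
) -> list[str]:
    """Random high-information consensus words, pairwise dissimilar in both
    orientations so planted motifs stay distinguishable."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    attempts = 0
    while len(out) < n_motifs:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("cannot place dissimilar motif consensi; lower min_hamming")
        cand = "".join(_BASES[c] for c in rng.integers(0, 4, size=width))
        ok = True
        for prev in out:
            for other in (prev, reverse_complement(prev)):
                if sum(a != b for a, b in zip(cand, other)) < min_hamming:
                    ok = False
        if ok:
            out.append(cand)
    return out


DEFAULT_GRAMMARS = ((0, 1), (2, 3), (4, 5, 6), (0, 2, 4, 7))


def plant_crms(
    genome: Genome,
    consensi: Sequence[str],
    grammars: Sequence[tuple] = DEFAULT_GRAMMARS,
    n_instances: int = 40,
    spacing: tuple[int, int] = (20, 120),
    mutation_rate: float = 0.05,
    seed: int = 0,
) -> SyntheticTruth:
    """Write grammar instances into the genome and record exact truth.

    Each instance lays its grammar's motif consensi left to right at
    spacings drawn uniformly from ``spacing``, each CRE on a random strand
    with i.i.d. per-base substitutions at ``mutation_rate``. Instances do
    not overlap; spacings below the CRM linkage distance keep planted CRMs
    linkable by construction.
    """
    rng = np.random.default_rng(seed)
    chrom = next(iter(genome.chroms))
    seq = np.frombuffer(genome.chroms[chrom].encode(), dtype=np.uint8).copy()
    glen = len(seq)
    occupied: list[tuple[int, int]] = []
    crms: list[PlantedCrm] = []

    for gi, grammar in enumerate(grammars):
        for _ in range(n_instances):
            widths = [len(consensi[m]) for m in grammar]
            gaps = [int(rng.integers(spacing[0], spacing[1] + 1)) for _ in range(len(grammar) - 1)]
            total = sum(widths) + sum(gaps)
            # rejection-sample a non-overlapping placement
            placed = None
            for _attempt in range(1000):
                start = int(rng.integers(0, glen - total))
                end = start + total
                if all(end + 10 <= s or e + 10 <= start for s, e in occupied):
                    placed = (start, end)
                    break
            if placed is None:
                raise RuntimeError("genome too crowded to place CRM instances")
            occupied.append(placed)
            pos = placed[0]
            cres: list[PlantedCre] = []
            for k, m in enumerate(grammar):
                cons = consensi[m]
                w = len(cons)
                bases = list(cons)
                muts = rng.random(w) < mutation_rate
                for j in np.nonzero(muts)[0]:
                    choices = [b for b in _BASES if b != bases[j]]
                    bases[j] = choices[int(rng.integers(0, 3))]
                site_seq = "".join(bases)
                strand = "+" if rng.random() < 0.5 else "-"
                written = site_seq if strand == "+" else reverse_complement(site_seq)
                seq[pos : pos + w] = np.frombuffer(written.encode(), dtype=np.uint8)
                cres.append(
                    PlantedCre(
                        interval=GenomicInterval(chrom, pos, pos + w, strand),
                        motif_index=m,
                        strand=strand,
                        seq=site_seq,
                    )
                )
                pos += w
                if k < len(gaps):
                    pos += gaps[k]
            crms.append(
                PlantedCrm(
                    interval=GenomicInterval(chrom, placed[0], placed[1]),
                    grammar_index=gi,
                    cres=cres,
                )
            )

    mutated_genome = Genome({chrom: seq.tobytes().decode()})
    return SyntheticTruth(
        genome=mutated_genome,
        consensi=list(consensi),
        grammars=[tuple(g) for g in grammars],
        crms=crms,
        params={
            "n_instances": n_instances,
            "spacing": list(spacing),
            "mutation_rate": mutation_rate,
            "seed": seed,
        },
    )


def simulate_peak_datasets(
    truth: SyntheticTruth,
    n_datasets: int = 12,
    peaks_per_dataset: int = 300,
    signal_fraction: float = 0.5,
    peak_len_mean: float = 1000.0,
    peak_len_sd: float = 200.0,
    peak_len_bounds: tuple[int, int] = (200, 4000),
    jitter: int = 100,
    seed: int = 0,
    n_noise_datasets: int = 0,
) -> SyntheticTruth:
    """Simulate per-TF peak datasets over the planted genome.

    Signal peaks are centered (with uniform jitter) on planted sites of the
    dataset's TF; noise peaks are uniform over the genome. Optional extra
    datasets contain noise peaks only (no TF assignment), emulating
    low-quality experiments.
    """
    rng = np.random.default_rng(seed)
    chrom = next(iter(truth.genome.chroms))
    glen = truth.genome.chrom_length(chrom)
    n_motifs = len(truth.consensi)
    used_motifs = sorted({m for g in truth.grammars for m in g})

    def draw_len() -> int:
        ln = rng.normal(peak_len_mean, peak_len_sd)
        return int(np.clip(ln, *peak_len_bounds))

    def make_peak(center: int, ln: int) -> tuple[int, int]:
        start = max(0, min(glen - ln, center - ln // 2))
        return start, start + ln

    datasets: list[Dataset] = []
    dataset_tf: dict = {}
    for di in range(n_datasets + n_noise_datasets):
        ds_id = f"d{di:02d}"
        is_noise_ds = di >= n_datasets
        if is_noise_ds:
            tf_index = None
            tf_name = f"noiseTF{di - n_datasets}"
        else:
            tf_index = used_motifs[di % len(used_motifs)]
            tf_name = f"TF{tf_index}"
        sites = [] if tf_index is None else truth.sites_of_motif(tf_index)
        n_signal = 0 if tf_index is None else int(round(peaks_per_dataset * signal_fraction))
        if sites and n_signal > len(sites):
            log.info(
                "dataset %s: %d signal peaks from %d planted sites (sampling with replacement)",
                ds_id, n_signal, len(sites),
            )
        intervals: list[GenomicInterval] = []
        labels: list[bool] = []
        for _ in range(n_signal):
            site = sites[int(rng.integers(0, len(sites)))]
            center = (site.interval.start + site.interval.end) // 2 + int(
                rng.integers(-jitter, jitter + 1)
            )
            s, e = make_peak(center, draw_len())
            intervals.append(GenomicInterval(chrom, s, e))
            labels.append(True)
        for _ in range(peaks_per_dataset - n_signal):
            ln = draw_len()
            s = int(rng.integers(0, glen - ln))
            intervals.append(GenomicInterval(chrom, s, s + ln))
            labels.append(False)
        datasets.append(Dataset.from_intervals(ds_id, tf_name, intervals, labels))
        dataset_tf[ds_id] = tf_index

    truth.datasets = datasets
    truth.dataset_tf = dataset_tf
    truth.params.update(
        {
            "n_datasets": n_datasets,
            "n_noise_datasets": n_noise_datasets,
            "peaks_per_dataset": peaks_per_dataset,
            "signal_fraction": signal_fraction,
            "peak_len_mean": peak_len_mean,
            "peak_len_sd": peak_len_sd,
            "peak_len_bounds": list(peak_len_bounds),
            "jitter": jitter,
        }
    )
    return truth


def canonical_scenario(
    seed: int = 0,
    scale: float = 1.0,
    n_noise_datasets: int = 0,
) -> SyntheticTruth:
    """The canonical test scenario: 2 Mb genome, 8 width-8 motifs, four
    grammars (two pairs, a triple, a quadruple) with 40 instances each, and
    12 datasets of 300 peaks at signal fraction 0.5.

    ``scale`` < 1 shrinks the genome, instance counts and dataset sizes
    proportionally for quick smoke runs; the default is the full scenario.
    """
    ss = np.random.SeedSequence(seed)
    s_genome, s_lib, s_plant, s_peaks = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)]
    glen = int(2_000_000 * scale)
    genome = make_genome(glen, gc=0.45, seed=s_genome)
    consensi = random_motif_library(8, width=8, seed=s_lib)
    truth = plant_crms(
        genome,
        consensi,
        grammars=DEFAULT_GRAMMARS,
        n_instances=max(8, int(40 * scale)),
        spacing=(20, 120),
        mutation_rate=0.05,
        seed=s_plant,
    )
    return simulate_peak_datasets(
        truth,
        n_datasets=12,
        peaks_per_dataset=max(60, int(300 * scale)),
        signal_fraction=0.5,
        seed=s_peaks,
        n_noise_datasets=n_noise_datasets,
    )


def write_truth_json(truth: SyntheticTruth, path) -> None:
    """Serialize the truth records (not the genome sequence) as JSON."""
    payload = {
        "consensi": truth.consensi,
        "grammars": [list(g) for g in truth.grammars],
        "params": truth.params,
        "dataset_tf": {k: (None if v is None else int(v)) for k, v in truth.dataset_tf.items()},
        "crms": [
            {
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "grammar": c.grammar_index,
                "cres": [
                    {
                        "start": cre.interval.start,
                        "end": cre.interval.end,
                        "motif": cre.motif_index,
                        "strand": cre.strand,
                        "seq": cre.seq,
                    }
                    for cre in c.cres
                ],
            }
            for c in truth.crms
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
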