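"""Readers and writers for BED, GFF3, bedGraph/wiggle and MEME minimal."""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np


from .intervals import AnnotationSet, ConservationTrack, Gene, GenomicInterval
from .pswm import PSWM

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------
def read_bed(path: PathLike, kind: str = "region") -> AnnotationSet:
    """Read BED3+ into an :class:`AnnotationSet`.

    BED start/end are taken verbatim as 0-based half-open. Lines with
    start >= end are rejected with a warning (count kept on the returned
    set as ``n_rejected``); non-numeric coordinates raise.
    """
    intervals: list[GenomicInterval] = []
    names: list[str] = []
    scores: list[float] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric coordinates"
                ) from exc
            if start >= end or start < 0:
                log.warning("%s: line %d: rejected interval %s:%d-%d",
                            path, lineno, parts[0], start, end)
                n_rejected += 1
                continue
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-." else "."
            intervals.append(GenomicInterval(parts[0], start, end, strand))
            names.append(parts[3] if len(parts) > 3 else f"{kind}_{lineno}")
            try:
                scores.append(float(parts[4]) if len(parts) > 4 else 0.0)
            except ValueError:
                scores.append(0.0)
    out = AnnotationSet(intervals, kind=kind, names=names, scores=scores)
    out.n_rejected = n_rejected  # type: ignore[attr-defined]
    return out


def write_bed(
    path: PathLike,
    intervals: Sequence[GenomicInterval],
    names: Optional[Sequence[str]] = None,
    scores: Optional[Sequence[float]] = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region_{i}"
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# GFF3 (features "exon" and "gene"; TSS from gene start respecting strand)
# ---------------------------------------------------------------------------
def read_gff3(path: PathLike) -> AnnotationSet:
    exons: list[GenomicInterval] = []
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}: line {lineno}: fewer than 9 GFF3 fields")
            chrom, _, feature, start, end, _, strand, _, attrs = parts[:9]
            start_i, end_i = int(start) - 1, int(end)  # GFF3 is 1-based inclusive
            if feature == "exon":
                exons.append(GenomicInterval(chrom, start_i, end_i, strand if strand in "+-" else "."))
            elif feature == "gene":
                gene_id = None
                for kv in attrs.split(";"):
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                        if k.strip() in ("ID", "gene_id", "Name"):
                            gene_id = v.strip()
                            break
                if gene_id is None:
                    gene_id = f"gene_{lineno}"
                tss = start_i if strand != "-" else end_i - 1
                genes.append(Gene(gene_id, chrom, tss, strand if strand in "+-" else "+"))
    return AnnotationSet(exons, kind="exon", genes=genes)


# ---------------------------------------------------------------------------
# Conservation tracks: bedGraph and fixed-step wiggle
# ---------------------------------------------------------------------------
def read_conservation(path: PathLike) -> ConservationTrack:
    """Read a bedGraph or fixed-step wiggle track of per-base scores in [0,1].

    Overlapping bedGraph records are resolved last-wins with a warning.
    """
    track = ConservationTrack()
    fixed: Optional[dict] = None
    seen = ConservationTrack()  # coverage bookkeeping for overlap warning
    warned = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=", 1) for kv in line.split()[1:])
                fixed = {
                    "chrom": fields["chrom"],
                    "pos": int(fields["start"]) - 1,  # wiggle is 1-based
                    "step": int(fields.get("step", 1)),
                    "span": int(fields.get("span", 1)),
                }
                continue
            if line.startswith("variableStep"):
                raise ValueError(f"{path}: line {lineno}: variableStep wiggle not supported")
            parts = line.split()
            if fixed is not None and len(parts) == 1:
                value = float(parts[0])
                if not (0.0 <= value <= 1.0):
                    raise ValueError(f"{path}: line {lineno}: score {value} outside [0, 1]")
                track.set_scores(fixed["chrom"], fixed["pos"], np.full(fixed["span"], value))
                fixed["pos"] += fixed["step"]
                continue
            if len(parts) != 4:
                raise ValueError(f"{path}: line {lineno}: expected bedGraph 'chrom start end value'")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{path}: line {lineno}: score {value} outside [0, 1]")
            if not warned:
                prior = seen.values(GenomicInterval(chrom, start, end))
                if np.any(~np.isnan(prior)):
                    log.warning("%s: line %d: overlapping bedGraph records; last wins", path, lineno)
                    warned = True
            seen.set_scores(chrom, start, np.zeros(end - start))
            track.set_scores(chrom, start, np.full(end - start, value))
    return track


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------
def read_meme_motifs(path: PathLike) -> list[PSWM]:
    """Read MEME minimal format motifs as PSWMs (alphabet must be ACGT).

    Each letter-probability column must sum to 1 within 1e-3 and is
    renormalized exactly. (Parsed directly so probabilities are preserved
    bit-exactly; count-quantizing round trips are avoided.)
    """
    out: list[PSWM] = []
    name: Optional[str] = None
    rows: list[list[float]] = []
    width: Optional[int] = None
    alphabet: Optional[str] = None

    def finish() -> None:
        nonlocal name, rows, width
        if name is None:
            return
        if width == 0 or not rows:
            raise ValueError(f"{path}: motif {name!r} has width 0")
        freqs = np.array(rows).T  # rows are per-position A C G T
        if freqs.shape[0] != 4:
            raise ValueError(f"{path}: motif {name!r}: expected 4 letter frequencies per row")
        sums = freqs.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            raise ValueError(f"{path}: motif {name!r}: columns do not sum to 1 within 1e-3")
        out.append(PSWM.from_freqs(freqs, name=name))
        name, rows, width = None, [], None

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("ALPHABET"):
                alphabet = line.split("=", 1)[-1].strip() if "=" in line else line.split()[-1]
            elif line.startswith("MOTIF"):
                finish()
                parts = line.split()
                name = parts[1] if len(parts) > 1 else f"motif_{len(out) + 1}"
                rows = []
            elif line.startswith("letter-probability matrix"):
                if "w=" in line:
                    width = int(line.split("w=")[1].split()[0])
            elif name is not None and line and line[0] in "0123456789.":
                rows.append([float(x) for x in line.split()])
    finish()
    if alphabet is not None and "".join(sorted(alphabet)) != "ACGT":
        raise ValueError(f"{path}: unsupported alphabet {alphabet!r}; need ACGT")
    return out


def write_meme_motifs(
    path: PathLike, pswms: Sequence[PSWM], background: Optional[np.ndarray] = None
) -> None:
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for i, p in enumerate(pswms):
            name = p.name or f"motif_{i + 1}"
            fh.write(f"MOTIF {name}\n")
            nsites = max(int(round(p.n_sites)), 1)
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} "
                f"nsites= {nsites} E= 0\n"
            )
            for j in range(p.width):
                fh.write(" ".join(f"{p.freqs[b, j]:.6f}" for b in range(4)) + "\n")
            fh.write("\n")
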