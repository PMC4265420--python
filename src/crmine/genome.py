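"""In-memory genome over the {A,C,G,T,N} alphabet."""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from .intervals import GenomicInterval

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID = set("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """Per-chromosome nucleotide sequences; sequences are stored uppercased."""

    def __init__(self, chroms: Mapping[str, str]):
        self.chroms: dict[str, str] = {}
        for name, seq in chroms.items():
            seq = seq.upper()
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(f"chromosome {name!r} contains invalid characters {sorted(bad)}")
            self.chroms[name] = seq

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chroms.values())

    def chrom_length(self, chrom: str) -> int:
        return len(self.chroms[chrom])

    def fetch(self, iv: GenomicInterval) -> str:
        seq = self.chroms.get(iv.chrom)
        if seq is None:
            raise KeyError(f"chromosome {iv.chrom!r} not in genome")
        if iv.end > len(seq):
            raise ValueError(f"interval {iv.pretty()} exceeds chromosome length {len(seq)}")
        sub = seq[iv.start : iv.end]
        return reverse_complement(sub) if iv.strand == "-" else sub

    def to_fasta(self, path: Union[str, Path], width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chroms.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def read_fasta(path: Union[str, Path]) -> Genome:
    """Read a (possibly multi-record) FASTA file into a :class:`Genome`.

    Raises a ``ValueError`` naming the offending line for malformed input
    and rejects duplicate chromosome names.
    """
    chroms: dict[str, list[str]] = {}
    current: Optional[str] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ValueError(f"{path}: line {lineno}: empty FASTA header")
                if name in chroms:
                    raise ValueError(f"{path}: line {lineno}: duplicate chromosome {name!r}")
                chroms[name] = []
                current = name
            else:
                if current is None:
                    raise ValueError(
                        f"{path}: line {lineno}: sequence before any FASTA header"
                    )
                chroms[current].append(line)
    return Genome({name: "".join(parts) for name, parts in chroms.items()})
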