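"""Reference genome container.

A :class:`GenomeModel` holds named contigs with their sequence and a coarse
class label (nuclear / mito / other).  It is the coordinate frame for every
downstream interval: all coordinates in this package are 0-based, half-open
(BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pyfaidx

VALID_CLASSES = ("nuclear", "mito", "other")

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_RC)[::-1]


@dataclass
class Contig:
    name: str
    sequence: str
    contig_class: str = "nuclear"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.name!r}: empty sequence")
        if self.contig_class not in VALID_CLASSES:
            raise ValueError(
                f"contig {self.name!r}: class {self.contig_class!r} not in {VALID_CLASSES}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeModel:
    contigs: list[Contig] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("contig names must be unique")
        self._by_name = {c.name: c for c in self.contigs}

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.contigs]

    @property
    def lengths(self) -> dict[str, int]:
        return {c.name: len(c) for c in self.contigs}

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def contig(self, name: str) -> Contig:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown contig {name!r}") from None

    def sequence(self, name: str) -> str:
        return self.contig(name).sequence

    def fetch(self, name: str, start: int, end: int) -> str:
        """Sequence of [start, end) on the top strand, clipped to the contig."""
        seq = self.sequence(name)
        return seq[max(start, 0) : min(end, len(seq))]

    # ------------------------------------------------------------------ IO
    @classmethod
    def from_fasta(cls, path: str | Path, classes: dict[str, str] | None = None) -> "GenomeModel":
        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        contigs = [
            Contig(name, str(fa[name][:]), (classes or {}).get(name, "nuclear"))
            for name in fa.keys()
        ]
        fa.close()
        return cls(contigs)

    def to_fasta(self, path: str | Path, width: int = 80) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for c in self.contigs:
                fh.write(f">{c.name}\n")
                for i in range(0, len(c.sequence), width):
                    fh.write(c.sequence[i : i + width] + "\n")
        return path
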