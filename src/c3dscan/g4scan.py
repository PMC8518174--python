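"""Putative G-quadruplex (G4) motif detection.

The scanner implements the classic quadparser grammar: a motif is >= 4 tracts
of >= 3 consecutive guanines separated by loops of 1-7 arbitrary bases.
Tracts are *maximal* G-runs — a run longer than ``min_tract`` is absorbed
into a single tract, never split into several motifs, so an uninterrupted
poly-G stretch counts as one tract.  Matches are reported maximal,
non-overlapping, left to right.

Motifs are reported on the G-tract-bearing strand; the complementary (C-rich)
strand of a motif — the candidate i-motif strand — is obtained with
:func:`antisense_of`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .genome import GenomeModel, revcomp

_VALID = re.compile(r"^[ACGTN]*$")


@dataclass(frozen=True)
class G4Motif:
    contig: str
    start: int
    end: int
    strand: str  # strand carrying the G tracts
    n_tracts: int
    loop_lengths: tuple[int, ...] = ()

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("motif end must exceed start")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def scan_g4(
    sequence: str,
    min_tract: int = 3,
    loop_min: int = 1,
    loop_max: int = 7,
    min_tracts: int = 4,
) -> list[tuple[int, int, tuple[int, ...]]]:
    """Find G4 motifs in ``sequence``; returns (start, end, loop_lengths) tuples.

    N is never part of a match (it breaks a G tract and the grammar's loops
    are drawn from unambiguous bases here because tracts are maximal runs).
    """
    seq = sequence.upper()
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains invalid characters: {bad}")
    if min_tract < 1 or min_tracts < 2 or loop_min < 1 or loop_max < loop_min:
        raise ValueError("invalid grammar parameters")

    runs = [m.span() for m in re.finditer(f"G{{{min_tract},}}", seq)]
    out: list[tuple[int, int, tuple[int, ...]]] = []
    i = 0
    while i < len(runs):
        # extend a chain of consecutive maximal runs while gaps are legal loops
        j = i
        loops: list[int] = []
        while j + 1 < len(runs):
            gap = runs[j + 1][0] - runs[j][1]
            # a loop must be a legal length and contain no N (N never matches)
            if loop_min <= gap <= loop_max and "N" not in seq[runs[j][1] : runs[j + 1][0]]:
                loops.append(gap)
                j += 1
            else:
                break
        n = j - i + 1
        if n >= min_tracts:
            out.append((runs[i][0], runs[j][1], tuple(loops)))
        i = j + 1
    return out


def scan_genome_g4(
    genome: GenomeModel,
    min_tract: int = 3,
    loop_min: int = 1,
    loop_max: int = 7,
    min_tracts: int = 4,
) -> list[G4Motif]:
    """Scan both strands of every contig; coordinates are on the top strand."""
    motifs: list[G4Motif] = []
    for contig in genome.contigs:
        seq = contig.sequence.upper()
        L = len(seq)
        for s, e, loops in scan_g4(seq, min_tract, loop_min, loop_max, min_tracts):
            motifs.append(G4Motif(contig.name, s, e, "+", len(loops) + 1, loops))
        for s, e, loops in scan_g4(revcomp(seq), min_tract, loop_min, loop_max, min_tracts):
            motifs.append(G4Motif(contig.name, L - e, L - s, "-", len(loops) + 1, loops))
    motifs.sort(key=lambda m: (m.contig, m.start, m.strand))
    return motifs


def antisense_of(motifs: list[G4Motif]) -> list[G4Motif]:
    """Same intervals with strands flipped — the C-rich comparator set."""
    flipped = []
    for m in motifs:
        if m.strand not in "+-":
            raise ValueError("antisense_of requires stranded motifs")
        flipped.append(replace(m, strand="-" if m.strand == "+" else "+"))
    return flipped


def motif_position_in_peak(peak, motif) -> float:
    """Relative position of the motif midpoint along the peak, 5' -> 3'.

    0 is the peak's 5' terminus, 1 its 3' terminus; for minus-strand peaks the
    genomic right end is the 5' terminus.  ``peak`` needs ``start``, ``end``
    and ``strand`` attributes (or mapping keys); ``motif`` needs coordinates.
    """
    p_start, p_end, p_strand = _ivl(peak)
    m_start, m_end, _ = _ivl(motif, need_strand=False)
    if m_start >= p_end or m_end <= p_start:
        raise ValueError("motif does not overlap peak")
    if p_strand not in "+-":
        raise ValueError("peak must be stranded")
    mid = (m_start + m_end) / 2.0
    width = p_end - p_start
    if p_strand == "+":
        rel = (mid - p_start) / width
    else:
        rel = (p_end - mid) / width
    return min(max(rel, 0.0), 1.0)


def _ivl(obj, need_strand: bool = True):
    if hasattr(obj, "start"):
        return obj.start, obj.end, getattr(obj, "strand", ".")
    return obj["start"], obj["end"], obj.get("strand", ".") if need_strand else "."
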