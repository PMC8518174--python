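"""Base-composition statistics and per-peak strand bias.

C-content and GC-skew characterise the strand asymmetry of peak sequences:
a C-rich top strand gives a negative GC-skew = (#G - #C) / (#G + #C).
Random k-mers drawn from the genome serve as the background distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel, revcomp


@dataclass
class CompositionStats:
    length: int
    a_frac: float
    c_frac: float
    g_frac: float
    t_frac: float
    n_count: int
    c_content: float          # #C / length
    gc_skew: float | None     # None when #G + #C == 0 (flagged, not coerced)

    @property
    def gc_skew_defined(self) -> bool:
        return self.gc_skew is not None


def base_composition(sequence: str) -> CompositionStats:
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)}")
    n = len(seq)
    counts = {b: seq.count(b) for b in "ACGTN"}
    g, c = counts["G"], counts["C"]
    skew = (g - c) / (g + c) if g + c else None
    return CompositionStats(
        length=n,
        a_frac=counts["A"] / n,
        c_frac=c / n,
        g_frac=g / n,
        t_frac=counts["T"] / n,
        n_count=counts["N"],
        c_content=c / n,
        gc_skew=skew,
    )


def gc_skew(sequence: str) -> float | None:
    """(#G - #C)/(#G + #C) on the given strand; None when undefined."""
    return base_composition(sequence).gc_skew


def composition_table(sequences: list[str], names: list[str] | None = None) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(sequences):
        st = base_composition(s)
        rows.append(
            {
                "name": names[i] if names else f"seq{i}",
                "length": st.length,
                "a_frac": st.a_frac,
                "c_frac": st.c_frac,
                "g_frac": st.g_frac,
                "t_frac": st.t_frac,
                "n_count": st.n_count,
                "c_content": st.c_content,
                "gc_skew": math.nan if st.gc_skew is None else st.gc_skew,
                "gc_skew_defined": st.gc_skew_defined,
            }
        )
    return pd.DataFrame(rows)


def sample_background_kmers(
    genome: GenomeModel, k: int = 50, n: int = 10000, seed: int = 0
) -> list[str]:
    """n random k-mers from the genome, uniform over eligible start positions,
    strand chosen uniformly; contigs shorter than k are skipped."""
    if n < 1:
        raise ValueError("n must be >= 1")
    eligible = [(c.name, len(c) - k + 1) for c in genome.contigs if len(c) >= k]
    if not eligible:
        raise ValueError(f"no contig of length >= k={k}")
    rng = np.random.default_rng(seed)
    weights = np.array([e[1] for e in eligible], dtype=float)
    choice = rng.choice(len(eligible), size=n, p=weights / weights.sum())
    out = []
    for ci in choice:
        name, span = eligible[ci]
        s = int(rng.integers(0, span))
        kmer = genome.fetch(name, s, s + k)
        if rng.integers(0, 2):
            kmer = revcomp(kmer)
        out.append(kmer)
    return out


def peak_strand_bias(peak, fragments, genome: GenomeModel):
    """Signed fragment-strand bias of a peak toward its C-rich strand.

    The C-rich strand is decided from the peak's reference sequence: negative
    top-strand GC-skew means the top strand is C-rich.  Ties (skew 0 or
    undefined) default to the top strand and are flagged.  Returns a dict with
    the bias in [-1, 1] (NaN when no fragment overlaps, flagged undefined).
    """
    start, end, contig = int(peak["start"]), int(peak["end"]), peak["contig"]
    seq = genome.fetch(contig, start, end)
    skew = gc_skew(seq) if seq else None
    tie = skew is None or skew == 0
    c_rich = "+" if (tie or skew < 0) else "-"

    df = fragments.df
    mask = (
        (df["contig"].to_numpy() == contig)
        & (df["start"].to_numpy() < end)
        & (df["end"].to_numpy() > start)
    )
    strands = df["strand"].to_numpy()[mask]
    n_crich = int((strands == c_rich).sum())
    n_other = int((strands != c_rich).sum())
    total = n_crich + n_other
    bias = (n_crich - n_other) / total if total else float("nan")
    return {
        "c_rich_strand": c_rich,
        "n_crich": n_crich,
        "n_other": n_other,
        "bias": bias,
        "defined": total > 0,
        "tie": tie,
    }


def strand_bias_table(peaks_df: pd.DataFrame, fragments, genome: GenomeModel) -> pd.DataFrame:
    rows = []
    for _, peak in peaks_df.iterrows():
        r = peak_strand_bias(peak, fragments, genome)
        r.update(contig=peak["contig"], start=int(peak["start"]), end=int(peak["end"]))
        rows.append(r)
    cols = ["contig", "start", "end", "c_rich_strand", "n_crich", "n_other", "bias", "defined", "tie"]
    return pd.DataFrame(rows, columns=cols)
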