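"""Fragment ingestion, size classification and coverage tracks.

Each record is one sequenced cfDNA molecule: an interval on the reference
plus the strand of the *original single-stranded molecule* (the library
chemistry preserves strand of origin).  Size gates split fragments into the
short single-stranded class (C3D, 35-75 nt) and the nucleosome-protected
class (NPD, 147-190 nt); everything else is OTHER.

All coordinates are 0-based half-open.  BAM input (1-based internally in the
format) is converted by pysam on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genome import GenomeModel

log = logging.getLogger(__name__)

C3D = "C3D"
NPD = "NPD"
OTHER = "OTHER"

FRAGMENT_COLUMNS = ["contig", "start", "end", "strand", "donor"]


@dataclass
class SizeGateConfig:
    """Inclusive fragment-length gates (nt) for the two size classes."""

    c3d_min: int = 35
    c3d_max: int = 75
    npd_min: int = 147
    npd_max: int = 190

    def __post_init__(self):
        if not (0 < self.c3d_min <= self.c3d_max < self.npd_min <= self.npd_max):
            raise ValueError("size gates must satisfy 0 < c3d_min <= c3d_max < npd_min <= npd_max")


@dataclass
class FragmentSet:
    """Thin wrapper over a DataFrame with columns contig/start/end/strand/donor."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in FRAGMENT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"fragment table missing columns {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def subset(self, mask) -> "FragmentSet":
        return FragmentSet(self.df[np.asarray(mask)].reset_index(drop=True))

    def for_strand(self, strand: str) -> "FragmentSet":
        return self.subset(self.df["strand"].to_numpy() == strand)

    def for_donor(self, donor: str) -> "FragmentSet":
        return self.subset(self.df["donor"].to_numpy() == donor)

    @property
    def donors(self) -> list[str]:
        return sorted(self.df["donor"].unique())

    def sorted(self) -> "FragmentSet":
        return FragmentSet(
            self.df.sort_values(["contig", "start", "end", "strand"], kind="mergesort")
        )

    def concat(self, other: "FragmentSet") -> "FragmentSet":
        return FragmentSet(pd.concat([self.df, other.df], ignore_index=True))

    def to_bed(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.df[["contig", "start", "end", "donor"]].copy()
        out["score"] = 0
        out["strand"] = self.df["strand"]
        out.to_csv(path, sep="\t", header=False, index=False)
        return path


def empty_fragment_set() -> FragmentSet:
    return FragmentSet(pd.DataFrame({c: [] for c in FRAGMENT_COLUMNS}).astype(
        {"start": int, "end": int}))


# --------------------------------------------------------------------- input

def read_fragments(
    path: str | Path,
    format: str = "BED6",
    strand_rule: str = "mate1-opposite",
    donor: str | None = None,
    genome: GenomeModel | None = None,
    trim5: int = 0,
    trim3: int = 0,
) -> FragmentSet:
    """Read fragment records from BED6 or a coordinate-sorted paired-end BAM.

    BED6: columns contig/start/end/name/score/strand; the name column is the
    donor label unless ``donor`` overrides it, and the strand column is taken
    verbatim as the original-ssDNA strand.

    BAM: one fragment per properly paired template, spanning the outer
    coordinates.  ``strand_rule`` maps mate-1 orientation to the original
    ssDNA strand: "mate1-opposite" (default; library amplification starts
    from the complementary strand) or "mate1-same".  Templates with unmapped
    mates are dropped and counted in the log.

    ``trim5``/``trim3`` shave fixed lengths off the fragment's 5'/3' ends
    (tail bases added by the library chemistry are normally trimmed upstream;
    this is a convenience for untrimmed input).
    """
    fmt = format.upper()
    if fmt == "BED6":
        fs = _read_bed6(Path(path), donor)
    elif fmt == "BAM":
        fs = _read_bam(Path(path), strand_rule, donor or Path(path).stem)
    else:
        raise ValueError(f"unknown fragment format {format!r}")

    if trim5 or trim3:
        df = fs.df.copy()
        plus = df["strand"].to_numpy() == "+"
        df.loc[plus, "start"] += trim5
        df.loc[plus, "end"] -= trim3
        df.loc[~plus, "start"] += trim3
        df.loc[~plus, "end"] -= trim5
        keep = df["start"] < df["end"]
        fs = FragmentSet(df[keep])

    if genome is not None:
        unknown = set(fs.df["contig"].unique()) - set(genome.names)
        if unknown:
            raise ValueError(f"fragments reference unknown contigs: {sorted(unknown)}")
    return fs


def _read_bed6(path: Path, donor: str | None) -> FragmentSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BED columns, got {len(f)}")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if f[5] not in "+-":
                raise ValueError(f"{path}:{lineno}: strand must be + or -, got {f[5]!r}")
            rows.append((f[0], start, end, f[5], donor or f[3]))
    if not rows:
        return empty_fragment_set()
    return FragmentSet(pd.DataFrame(rows, columns=FRAGMENT_COLUMNS))


def _read_bam(path: Path, strand_rule: str, donor: str) -> FragmentSet:
    if strand_rule not in ("mate1-opposite", "mate1-same"):
        raise ValueError(f"unknown strand_rule {strand_rule!r}")
    rows, dropped = [], 0
    with pysam.AlignmentFile(str(path)) as bam:
        for read in bam:
            if not read.is_read1 or read.is_secondary or read.is_supplementary:
                continue
            if read.is_unmapped or read.mate_is_unmapped or not read.is_proper_pair:
                dropped += 1
                continue
            tlen = abs(read.template_length)
            if tlen == 0:
                dropped += 1
                continue
            start = min(read.reference_start, read.next_reference_start)
            mate1_fwd = not read.is_reverse
            if strand_rule == "mate1-opposite":
                strand = "-" if mate1_fwd else "+"
            else:
                strand = "+" if mate1_fwd else "-"
            rows.append((read.reference_name, start, start + tlen, strand, donor))
    if dropped:
        log.info("read_fragments: dropped %d templates (unmapped mate / improper pair)", dropped)
    if not rows:
        return empty_fragment_set()
    return FragmentSet(pd.DataFrame(rows, columns=FRAGMENT_COLUMNS))


# ------------------------------------------------------------ classification

def classify_by_size(length: int, gates: SizeGateConfig | None = None) -> str:
    """C3D / NPD / OTHER for a fragment length (gates inclusive at both ends)."""
    gates = gates or SizeGateConfig()
    if length < 1:
        raise ValueError("fragment length must be >= 1")
    if gates.c3d_min <= length <= gates.c3d_max:
        return C3D
    if gates.npd_min <= length <= gates.npd_max:
        return NPD
    return OTHER


def classify_set(fs: FragmentSet, gates: SizeGateConfig | None = None) -> pd.Series:
    """Vectorised size classification; returns a Series aligned to fs.df."""
    gates = gates or SizeGateConfig()
    ln = fs.lengths
    labels = np.full(len(ln), OTHER, dtype=object)
    labels[(ln >= gates.c3d_min) & (ln <= gates.c3d_max)] = C3D
    labels[(ln >= gates.npd_min) & (ln <= gates.npd_max)] = NPD
    return pd.Series(labels, index=fs.df.index, name="size_class")


def split_by_class(fs: FragmentSet, gates: SizeGateConfig | None = None) -> dict[str, FragmentSet]:
    labels = classify_set(fs, gates)
    return {cls: fs.subset((labels == cls).to_numpy()) for cls in (C3D, NPD, OTHER)}


def split_by_strand(fs: FragmentSet) -> tuple[FragmentSet, FragmentSet]:
    """Partition into (top '+', bottom '-') fragment sets."""
    strands = fs.df["strand"].to_numpy()
    return fs.subset(strands == "+"), fs.subset(strands == "-")


# ----------------------------------------------------------------- coverage

@dataclass
class CoverageTrack:
    """Per-contig binned depth vectors."""

    values: dict[str, np.ndarray]
    bin_size: int
    normalization: str  # raw | CPM
    strand: str  # + | - | both
    n_fragments: int = 0

    def to_bedgraph(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for contig, vals in self.values.items():
                for i, v in enumerate(vals):
                    if v != 0:
                        s = i * self.bin_size
                        fh.write(f"{contig}\t{s}\t{s + self.bin_size}\t{v:g}\n")
        return path


def base_coverage(fs: FragmentSet, genome: GenomeModel, strand: str = "both") -> dict[str, np.ndarray]:
    """Per-base raw depth per contig from fragment spans."""
    use = fs if strand == "both" else fs.for_strand(strand)
    cov = {name: np.zeros(L, dtype=np.float64) for name, L in genome.lengths.items()}
    for contig, sub in use.df.groupby("contig", sort=False):
        arr = cov[contig]
        diff = np.zeros(len(arr) + 1)
        np.add.at(diff, np.clip(sub["start"].to_numpy(), 0, len(arr)), 1.0)
        np.add.at(diff, np.clip(sub["end"].to_numpy(), 0, len(arr)), -1.0)
        arr += np.cumsum(diff[:-1])
    return cov


def coverage_track(
    fs: FragmentSet,
    genome: GenomeModel,
    bin_size: int = 1,
    normalization: str = "raw",
    strand: str = "both",
) -> CoverageTrack:
    """Binned coverage (mean base depth per bin); CPM scales by 1e6 / |set|.

    The CPM denominator is the full input set, before strand filtering, so
    plus- and minus-strand tracks from one set are directly comparable.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if normalization not in ("raw", "CPM"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if normalization == "CPM" and len(fs) == 0:
        raise ValueError("CPM normalization of an empty fragment set")
    cov = base_coverage(fs, genome, strand)
    scale = 1.0 if normalization == "raw" else 1e6 / len(fs)
    out = {}
    for contig, arr in cov.items():
        if bin_size == 1:
            out[contig] = arr * scale
            continue
        n_bins = int(np.ceil(len(arr) / bin_size))
        padded = np.zeros(n_bins * bin_size)
        padded[: len(arr)] = arr
        binned = padded.reshape(n_bins, bin_size).mean(axis=1)
        # trailing partial bin: average over real bases only
        rem = len(arr) % bin_size
        if rem:
            binned[-1] = arr[len(arr) - rem :].mean()
        out[contig] = binned * scale
    return CoverageTrack(out, bin_size, normalization, strand, len(fs))
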