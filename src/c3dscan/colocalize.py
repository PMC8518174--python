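"""Interval colocalization: overlap counts, permutation tests, enrichment
folds, genomic-feature annotation and aggregation (metaplot) profiles.

The permutation null re-places each query interval uniformly at random within
its own contig, preserving length and strand (overlaps between placed
intervals are not forbidden).  p = (1 + #{null >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .fragments import FragmentSet, base_coverage
from .genome import GenomeModel


@dataclass
class FeatureSet:
    name: str
    df: pd.DataFrame  # contig, start, end [, strand, name]
    stranded: bool = False

    def __post_init__(self):
        for c in ("contig", "start", "end"):
            if c not in self.df.columns:
                raise ValueError(f"feature set {self.name!r} missing column {c}")
        if self.stranded and "strand" not in self.df.columns:
            raise ValueError(f"feature set {self.name!r} declared stranded but has no strand")
        self.df = self.df.sort_values(["contig", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    def total_bp(self) -> int:
        """Union basepairs (overlaps within the set counted once)."""
        total = 0
        for _, g in self.df.groupby("contig", sort=False):
            s = g["start"].to_numpy()
            e = g["end"].to_numpy()
            cur_s, cur_e = s[0], e[0]
            for k in range(1, len(s)):
                if s[k] <= cur_e:
                    cur_e = max(cur_e, e[k])
                else:
                    total += cur_e - cur_s
                    cur_s, cur_e = s[k], e[k]
            total += cur_e - cur_s
        return int(total)


def read_bed(path: str | Path, name: str | None = None) -> FeatureSet:
    """BED3/BED6 reader; 6+ columns with +/- in column 6 makes the set stranded."""
    path = Path(path)
    rows = []
    stranded = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                s, e = int(f[1]), int(f[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if s >= e:
                raise ValueError(f"{path}:{lineno}: start >= end")
            strand = f[5] if len(f) >= 6 else "."
            if strand not in "+-":
                stranded = False
            rows.append((f[0], s, e, f[3] if len(f) >= 4 else f"f{lineno}", strand))
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "name", "strand"])
    return FeatureSet(name or path.stem, df, stranded=stranded and len(df) > 0)


def write_bed(fs: FeatureSet, path: str | Path) -> Path:
    path = Path(path)
    df = fs.df
    with open(path, "w") as fh:
        for i, r in df.iterrows():
            nm = r.get("name", f"f{i}")
            st = r.get("strand", ".") if fs.stranded else "."
            fh.write(f"{r['contig']}\t{int(r['start'])}\t{int(r['end'])}\t{nm}\t0\t{st}\n")
    return path


def _as_df(x) -> tuple[pd.DataFrame, bool]:
    """Coerce PeakSet / FeatureSet / DataFrame to (df, stranded)."""
    if isinstance(x, FeatureSet):
        return x.df, x.stranded
    df = getattr(x, "df", x)
    stranded = "strand" in df.columns and df["strand"].isin(["+", "-"]).all() and len(df) > 0
    return df, stranded


def _hit_mask(a_df, b_df, strand_mode, min_overlap, a_stranded, b_stranded) -> np.ndarray:
    """Per-A boolean: overlapped by some B >= min_overlap bp under strand_mode."""
    if strand_mode not in ("ignore", "same", "opposite"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    if strand_mode != "ignore" and not (a_stranded and b_stranded):
        raise ValueError("strand-aware overlap requires stranded inputs on both sides")
    hits = np.zeros(len(a_df), dtype=bool)
    if len(a_df) == 0 or len(b_df) == 0:
        return hits

    groups: list[tuple[pd.DataFrame, pd.DataFrame]] = []
    if strand_mode == "ignore":
        groups.append((a_df, b_df))
    else:
        flip = {"+": "-", "-": "+"}
        for s in "+-":
            a_sub = a_df[a_df["strand"] == s]
            want = s if strand_mode == "same" else flip[s]
            b_sub = b_df[b_df["strand"] == want]
            groups.append((a_sub, b_sub))

    for a_sub, b_sub in groups:
        if len(a_sub) == 0 or len(b_sub) == 0:
            continue
        b_by = {c: g for c, g in b_sub.groupby("contig", sort=False)}
        for contig, g in a_sub.groupby("contig", sort=False):
            b = b_by.get(contig)
            if b is None:
                continue
            bs = b["start"].to_numpy()
            be = b["end"].to_numpy()
            order = np.argsort(bs, kind="mergesort")
            bs, be = bs[order], be[order]
            qs = g["start"].to_numpy()
            qe = g["end"].to_numpy()
            if min_overlap == 1:
                pme = np.maximum.accumulate(be)
                idx = np.searchsorted(bs, qe, side="left")
                ok = idx > 0
                h = np.zeros(len(g), dtype=bool)
                h[ok] = pme[idx[ok] - 1] > qs[ok]
            else:
                h = np.array(
                    [bool(np.any(np.minimum(be, e) - np.maximum(bs, s) >= min_overlap))
                     for s, e in zip(qs, qe)]
                )
            hits[g.index.to_numpy()] = h
    return hits


@dataclass
class OverlapCounts:
    n_A_hit: int
    n_B_hit: int
    n_A_only: int
    n_B_only: int
    a_hits: np.ndarray = field(repr=False, default=None)
    b_hits: np.ndarray = field(repr=False, default=None)


def overlap_counts(A, B, strand_mode: str = "ignore", min_overlap: int = 1) -> OverlapCounts:
    """Element-wise overlap counts between two interval sets (Venn numbers)."""
    a_df, a_str = _as_df(A)
    b_df, b_str = _as_df(B)
    a_df = a_df.reset_index(drop=True)
    b_df = b_df.reset_index(drop=True)
    a_hits = _hit_mask(a_df, b_df, strand_mode, min_overlap, a_str, b_str)
    # symmetric: for B, "opposite" is symmetric, "same" is symmetric
    b_hits = _hit_mask(b_df, a_df, strand_mode, min_overlap, b_str, a_str)
    return OverlapCounts(
        int(a_hits.sum()), int(b_hits.sum()),
        int((~a_hits).sum()), int((~b_hits).sum()),
        a_hits, b_hits,
    )


@dataclass
class PermutationResult:
    observed: int
    null_mean: float
    null_sd: float
    z: float
    p: float
    n_perm: int
    seed: int


def permutation_test(
    A,
    B,
    genome: GenomeModel,
    n_perm: int = 1000,
    seed: int = 0,
    strategy: str = "uniform",
    strand_mode: str = "ignore",
    min_overlap: int = 1,
) -> PermutationResult:
    """Colocalization significance of A with B by random re-placement of A.

    strategy "uniform": each A interval is re-placed uniformly within its
    contig, length and strand preserved.  strategy "circular": all intervals
    on a contig are rotated by one shared random offset (modular), which
    preserves the internal spacing of A.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    a_df, a_str = _as_df(A)
    b_df, b_str = _as_df(B)
    if len(a_df) == 0:
        raise ValueError("A must be non-empty")
    a_df = a_df.reset_index(drop=True)
    b_df = b_df.reset_index(drop=True)
    lengths = (a_df["end"] - a_df["start"]).to_numpy()
    contigs = a_df["contig"].to_numpy()
    for c in np.unique(contigs):
        L = genome.lengths.get(c)
        if L is None:
            raise ValueError(f"unknown contig {c!r}")
        if lengths[contigs == c].max() > L:
            raise ValueError(f"interval longer than contig {c!r}")

    if strategy not in ("uniform", "circular"):
        raise ValueError(f"unknown strategy {strategy!r}")

    observed = int(_hit_mask(a_df, b_df, strand_mode, min_overlap, a_str, b_str).sum())

    rng = np.random.default_rng(seed)
    if min_overlap == 1:
        null = _null_counts_fast(a_df, b_df, genome, n_perm, rng, strategy, strand_mode)
    else:
        null = np.zeros(n_perm, dtype=int)
        base = a_df.copy()
        for k in range(n_perm):
            perm = base.copy()
            new_starts = np.empty(len(perm), dtype=int)
            for c in np.unique(contigs):
                m = contigs == c
                L = genome.lengths[c]
                if strategy == "uniform":
                    new_starts[m] = rng.integers(0, L - lengths[m] + 1)
                else:
                    shift = int(rng.integers(0, L))
                    ns = (a_df.loc[m, "start"].to_numpy() + shift) % L
                    new_starts[m] = np.minimum(ns, L - lengths[m])
            perm["start"] = new_starts
            perm["end"] = new_starts + lengths
            null[k] = int(_hit_mask(perm, b_df, strand_mode, min_overlap, a_str, b_str).sum())

    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    z = (observed - mean) / sd if sd > 0 else float("nan")
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return PermutationResult(observed, mean, sd, z, p, n_perm, seed)


def _null_counts_fast(a_df, b_df, genome, n_perm, rng, strategy, strand_mode):
    """Vectorized null hit counts for min_overlap = 1.

    All permutations are drawn as one (n_perm x nA) start matrix per contig
    group; the hit test uses sorted B starts with prefix-max ends.
    """
    flip = {"+": "-", "-": "+"}
    nA = len(a_df)
    contigs = a_df["contig"].to_numpy()
    lengths = (a_df["end"] - a_df["start"]).to_numpy()
    if strand_mode == "ignore":
        want = np.full(nA, ".", dtype=object)
        b_groups = {
            (c, "."): g for c, g in b_df.groupby("contig", sort=False)
        }
    else:
        strands = a_df["strand"].to_numpy()
        want = np.array(
            [s if strand_mode == "same" else flip[s] for s in strands], dtype=object
        )
        b_groups = {
            (c, s): g
            for (c, s), g in b_df.groupby(["contig", "strand"], sort=False)
        }

    b_sorted = {}
    for key, g in b_groups.items():
        bs = g["start"].to_numpy()
        be = g["end"].to_numpy()
        order = np.argsort(bs, kind="mergesort")
        b_sorted[key] = (bs[order], np.maximum.accumulate(be[order]))

    null = np.zeros(n_perm, dtype=int)
    # draw per-contig so RNG consumption is independent of B; circular shares
    # one shift per contig per permutation
    for c in np.unique(contigs):
        m = contigs == c
        L = genome.lengths[c]
        lens_m = lengths[m]
        if strategy == "uniform":
            starts = rng.integers(0, L - lens_m + 1, size=(n_perm, int(m.sum())))
        else:
            shifts = rng.integers(0, L, size=(n_perm, 1))
            base = a_df.loc[m, "start"].to_numpy()
            starts = np.minimum((base + shifts) % L, L - lens_m)
        ends = starts + lens_m
        hits = np.zeros(starts.shape, dtype=bool)
        for w in np.unique(want[m]):
            key = (c, w)
            if key not in b_sorted:
                continue
            cols = np.flatnonzero(want[m] == w)
            bs, pme = b_sorted[key]
            idx = np.searchsorted(bs, ends[:, cols], side="left")
            ok = idx > 0
            h = np.zeros(idx.shape, dtype=bool)
            h[ok] = pme[idx[ok] - 1] > starts[:, cols][ok]
            hits[:, cols] = h
        null += hits.sum(axis=1)
    return null


@dataclass
class EnrichmentResult:
    feature: str
    observed_fraction: float
    expected_fraction: float
    fold: float
    n_peaks: int


def enrichment_fold(peaks, feature: FeatureSet, genome: GenomeModel) -> EnrichmentResult:
    """Observed / expected fraction of peak midpoints inside the feature.

    Expected is the feature's union bp divided by genome bp (bp-fraction
    convention).
    """
    p_df, _ = _as_df(peaks)
    if len(p_df) == 0:
        raise ValueError("empty peak set")
    fbp = feature.total_bp()
    gbp = genome.total_length
    if fbp == 0 or gbp == 0:
        raise ValueError("zero-length feature or genome")
    mids = ((p_df["start"].to_numpy() + p_df["end"].to_numpy()) // 2)
    mid_df = pd.DataFrame(
        {"contig": p_df["contig"].to_numpy(), "start": mids, "end": mids + 1}
    )
    inside = _hit_mask(mid_df, feature.df, "ignore", 1, False, False)
    observed = inside.mean()
    expected = fbp / gbp
    return EnrichmentResult(feature.name, float(observed), float(expected),
                            float(observed / expected), len(p_df))


def colocalization_report(
    peaks,
    features: list[FeatureSet],
    genome: GenomeModel,
    n_perm: int = 200,
    seed: int = 0,
    strand_mode: str = "ignore",
) -> pd.DataFrame:
    """Per-feature enrichment fold + permutation p/z, BH-adjusted across features."""
    rows = []
    for i, feat in enumerate(features):
        enr = enrichment_fold(peaks, feat, genome)
        perm = permutation_test(peaks, feat, genome, n_perm=n_perm, seed=seed + i,
                                strand_mode=strand_mode)
        rows.append(
            dict(feature=feat.name, observed_fraction=enr.observed_fraction,
                 expected_fraction=enr.expected_fraction, fold=enr.fold,
                 observed_hits=perm.observed, null_mean=perm.null_mean,
                 null_sd=perm.null_sd, z=perm.z, p=perm.p, n_perm=perm.n_perm)
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


# ----------------------------------------------------------------- annotation

@dataclass
class GeneModel:
    name: str
    contig: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: list[tuple[int, int]]


def read_gene_models(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Gene models from BED12 or GFF3 (format inferred from the extension)."""
    path = Path(path)
    if fmt is None:
        fmt = "GFF3" if path.suffix.lower() in (".gff", ".gff3") else "BED12"
    if fmt.upper() == "BED12":
        return _read_bed12(path)
    if fmt.upper() == "GFF3":
        return _read_gff3(path)
    raise ValueError(f"unknown gene model format {fmt!r}")


def _read_bed12(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns")
            if f[5] not in "+-":
                raise ValueError(f"{path}:{lineno}: gene records must be stranded")
            start = int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + sz) for o, sz in zip(offs, sizes)]
            genes.append(
                GeneModel(f[3], f[0], f[5], start, int(f[2]), int(f[6]), int(f[7]), exons)
            )
    return genes


def _read_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes = []
    for tx in db.features_of_type(("mRNA", "transcript")):
        if tx.strand not in "+-":
            raise ValueError(f"transcript {tx.id}: missing strand")
        exons = sorted((f.start - 1, f.end) for f in db.children(tx, featuretype="exon"))
        cds = sorted((f.start - 1, f.end) for f in db.children(tx, featuretype="CDS"))
        if cds:
            cds_start, cds_end = cds[0][0], cds[-1][1]
        else:
            cds_start = cds_end = tx.start - 1  # non-coding: empty CDS at tx start
        genes.append(
            GeneModel(tx.id, tx.seqid, tx.strand, tx.start - 1, tx.end,
                      cds_start, cds_end, exons or [(tx.start - 1, tx.end)])
        )
    return genes


ANNOTATION_PRIORITY = ["promoter", "5utr", "exon", "intron", "3utr", "tts", "intergenic"]


def annotate_peaks(
    peaks,
    genes: list[GeneModel],
    cpg: FeatureSet | None = None,
    promoter_window: tuple[int, int] = (1000, 100),
    tts_window: tuple[int, int] = (100, 1000),
    shore_bp: int = 2000,
) -> tuple[pd.DataFrame, pd.Series]:
    """Label each peak midpoint with its genomic context.

    Priority: promoter > 5'UTR > exon > intron > 3'UTR > TTS > intergenic.
    Promoter = [TSS - promoter_window[0], TSS + promoter_window[1]) and
    TTS window = [TES - tts_window[0], TES + tts_window[1]), both strand-aware.
    CpG islands and their 2-kb shores are reported in separate columns since
    they are orthogonal to the gene-model labels.
    """
    from intervaltree import IntervalTree

    trees: dict[str, dict[str, IntervalTree]] = {lab: {} for lab in ANNOTATION_PRIORITY[:-1]}

    def add(label: str, contig: str, s: int, e: int) -> None:
        if e <= s:
            return
        trees[label].setdefault(contig, IntervalTree()).addi(s, e)

    up_p, down_p = promoter_window
    up_t, down_t = tts_window
    for g in genes:
        coding = g.cds_end > g.cds_start
        if g.strand == "+":
            tss, tes = g.tx_start, g.tx_end
            add("promoter", g.contig, tss - up_p, tss + down_p)
            add("tts", g.contig, tes - up_t, tes + down_t)
            utr5 = [(max(s, g.tx_start), min(e, g.cds_start)) for s, e in g.exons] if coding else []
            utr3 = [(max(s, g.cds_end), min(e, g.tx_end)) for s, e in g.exons] if coding else []
        else:
            tss, tes = g.tx_end, g.tx_start
            add("promoter", g.contig, tss - down_p, tss + up_p)
            add("tts", g.contig, tes - down_t, tes + up_t)
            utr5 = [(max(s, g.cds_end), min(e, g.tx_end)) for s, e in g.exons] if coding else []
            utr3 = [(max(s, g.tx_start), min(e, g.cds_start)) for s, e in g.exons] if coding else []
        for s, e in utr5:
            add("5utr", g.contig, s, e)
        for s, e in utr3:
            add("3utr", g.contig, s, e)
        # "exon" means the coding part; otherwise UTR labels would be unreachable
        for s, e in g.exons:
            if coding:
                add("exon", g.contig, max(s, g.cds_start), min(e, g.cds_end))
            else:
                add("exon", g.contig, s, e)
        exons_sorted = sorted(g.exons)
        for (s1, e1), (s2, e2) in zip(exons_sorted, exons_sorted[1:]):
            add("intron", g.contig, e1, s2)

    cpg_trees: dict[str, IntervalTree] = {}
    shore_trees: dict[str, IntervalTree] = {}
    if cpg is not None:
        for r in cpg.df.itertuples(index=False):
            cpg_trees.setdefault(r.contig, IntervalTree()).addi(r.start, r.end)
            shore_trees.setdefault(r.contig, IntervalTree()).addi(max(r.start - shore_bp, 0), r.start)
            shore_trees.setdefault(r.contig, IntervalTree()).addi(r.end, r.end + shore_bp)

    p_df, _ = _as_df(peaks)
    labels, cpg_lab = [], []
    for r in p_df.itertuples(index=False):
        mid = (r.start + r.end) // 2
        label = "intergenic"
        for lab in ANNOTATION_PRIORITY[:-1]:
            t = trees[lab].get(r.contig)
            if t is not None and t.overlaps(mid, mid + 1):
                label = lab
                break
        labels.append(label)
        in_cpg = r.contig in cpg_trees and cpg_trees[r.contig].overlaps(mid, mid + 1)
        in_shore = (not in_cpg) and r.contig in shore_trees and shore_trees[r.contig].overlaps(mid, mid + 1)
        cpg_lab.append("island" if in_cpg else ("shore" if in_shore else "none"))

    out = p_df[["contig", "start", "end"]].copy()
    out["label"] = labels
    out["cpg"] = cpg_lab
    proportions = out["label"].value_counts(normalize=True).reindex(
        ANNOTATION_PRIORITY, fill_value=0.0
    )
    return out, proportions


# ---------------------------------------------------------------- aggregation

@dataclass
class AggregationMatrix:
    matrix: np.ndarray  # regions x bins
    mode: str
    flank: int
    bins: int
    region_strands: np.ndarray | None = None

    @property
    def mean_profile(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(self.matrix).to_csv(path, sep="\t", index=False,
                                         header=[f"bin{i}" for i in range(self.matrix.shape[1])])
        return path


def aggregate_profile(
    fragments: FragmentSet,
    regions: FeatureSet,
    genome: GenomeModel,
    mode: str = "reference-point",
    anchor: str = "midpoint",
    flank: int = 2000,
    bins: int = 100,
    flank_bins: int = 25,
    strand_aware: bool = True,
    strand: str = "both",
    normalization: str = "CPM",
) -> AggregationMatrix:
    """Normalized coverage matrix around (or across) a region set.

    reference-point: a fixed window of +-flank bp around the anchor
    (region midpoint or strand-aware 5' end), averaged into ``bins`` bins and
    oriented so the 5' direction is on the left for minus-strand regions.

    scale-regions: region bodies rescaled to ``bins`` bins with ``flank_bins``
    fixed-width flank bins on each side (flank bp total per side).

    ``strand`` restricts which fragments contribute ('+', '-', 'both'); the
    CPM denominator is always the full input set so sense/antisense profiles
    from the same set are comparable.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    cov = base_coverage(fragments, genome, strand=strand)
    scale = 1.0 if normalization == "raw" else 1e6 / max(len(fragments), 1)

    rdf = regions.df
    strands = (
        rdf["strand"].to_numpy()
        if (strand_aware and regions.stranded)
        else np.full(len(rdf), "+")
    )

    def window_vec(contig: str, lo: int, hi: int) -> np.ndarray:
        arr = cov[contig]
        out = np.zeros(hi - lo)
        a, b = max(lo, 0), min(hi, len(arr))
        if b > a:
            out[a - lo : b - lo] = arr[a:b]
        return out

    def rebin(vec: np.ndarray, n: int) -> np.ndarray:
        edges = np.linspace(0, len(vec), n + 1)
        csum = np.concatenate([[0.0], np.cumsum(vec)])
        lo = edges[:-1]
        hi = edges[1:]
        # mean over (possibly fractional) base spans
        L = len(vec)

        def frac_sum(x0, x1):
            i0, i1 = int(np.floor(x0)), int(np.floor(x1))
            if i0 == i1:
                return vec[i0] * (x1 - x0) if i0 < L else 0.0
            s = csum[min(i1, L)] - csum[i0 + 1]
            s += vec[i0] * (i0 + 1 - x0)
            if i1 < L:
                s += vec[i1] * (x1 - i1)
            return s
        return np.array([frac_sum(a, b) / (b - a) for a, b in zip(lo, hi)])

    rows = []
    for i, r in enumerate(rdf.itertuples(index=False)):
        if mode == "reference-point":
            if anchor == "midpoint":
                a = (r.start + r.end) // 2
            elif anchor == "five_prime":
                a = r.start if strands[i] == "+" else r.end - 1
            else:
                raise ValueError(f"unknown anchor {anchor!r}")
            vec = window_vec(r.contig, a - flank, a + flank)
            if strands[i] == "-":
                vec = vec[::-1]
            rows.append(rebin(vec, bins))
        elif mode == "scale-regions":
            body = window_vec(r.contig, r.start, r.end)
            left = window_vec(r.contig, r.start - flank, r.start)
            right = window_vec(r.contig, r.end, r.end + flank)
            if strands[i] == "-":
                body = body[::-1]
                left, right = right[::-1], left[::-1]
            rows.append(
                np.concatenate([rebin(left, flank_bins), rebin(body, bins), rebin(right, flank_bins)])
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
    mat = np.vstack(rows) * scale
    return AggregationMatrix(mat, mode, flank, mat.shape[1], strands)
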