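"""Strand-specific peak calling and cross-donor peak statistics.

The caller scans each strand with a sliding window over fragment 5'-start
counts, tests each window against a local Poisson rate (the maximum of the
genome-wide background rate and several centred local rates, MACS-style),
adjusts with Benjamini-Hochberg across all tested windows, and merges
significant windows into peaks.  Peak significance is assessed per strand
independently; merging across strands/donors is a reporting step and never
re-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fragments import FragmentSet, base_coverage
from .genome import GenomeModel

log = logging.getLogger(__name__)

PEAK_COLUMNS = ["contig", "start", "end", "strand", "summit", "p_value", "q_value"]


@dataclass
class PeakCallConfig:
    window: int = 50
    step: int = 10
    local_lambda_windows: tuple[int, ...] = (1000, 5000, 10000)
    q_cutoff: float = 0.05
    merge_gap: int = 50
    min_width: int = 35

    def __post_init__(self):
        if self.step > self.window:
            raise ValueError("step must be <= window")
        if not (0 < self.q_cutoff < 1):
            raise ValueError("q_cutoff must be in (0, 1)")


@dataclass
class PeakSet:
    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in ("contig", "start", "end", "strand") if c not in self.df.columns]
        if missing:
            raise ValueError(f"peak table missing columns {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def sorted(self) -> "PeakSet":
        return PeakSet(self.df.sort_values(["contig", "start", "end"], kind="mergesort"))

    def to_narrowpeak(self, path: str | Path) -> Path:
        """narrowPeak-style BED: score = int(-10 log10 q), summit as offset."""
        path = Path(path)
        df = self.df
        with open(path, "w") as fh:
            for i, r in df.iterrows():
                q = r.get("q_value", np.nan)
                p = r.get("p_value", np.nan)
                score = int(min(-10 * np.log10(max(q, 1e-300)), 1000)) if np.isfinite(q) else 0
                summit_off = int(r["summit"] - r["start"]) if "summit" in df.columns and np.isfinite(r.get("summit", np.nan)) else -1
                fh.write(
                    f"{r['contig']}\t{int(r['start'])}\t{int(r['end'])}\t"
                    f"peak_{i}\t{score}\t{r['strand']}\t"
                    f"{r.get('signal', 0):.4g}\t{p:.4g}\t{q:.4g}\t{summit_off}\n"
                )
        return path


def empty_peak_set() -> PeakSet:
    df = pd.DataFrame({c: [] for c in PEAK_COLUMNS})
    return PeakSet(df.astype({"start": int, "end": int, "summit": int}, errors="ignore"))


# ------------------------------------------------------------------- calling

def call_peaks_stranded(
    fragments: FragmentSet,
    genome: GenomeModel,
    config: PeakCallConfig | None = None,
) -> PeakSet:
    """Call peaks on each strand of a single-donor, single-size-class set."""
    if genome is None:
        raise ValueError("genome required for peak calling")
    cfg = config or PeakCallConfig()
    if len(fragments) == 0:
        log.info("call_peaks_stranded: empty fragment set, no peaks")
        return empty_peak_set()

    records = []  # (strand, contig, win_start, count, lam)
    for strand in "+-":
        sub = fragments.for_strand(strand)
        n_strand = len(sub)
        if n_strand == 0:
            continue
        lam_bg = n_strand * cfg.window / genome.total_length
        for contig, cdf in sub.df.groupby("contig", sort=True):
            L = genome.lengths[contig]
            if L < cfg.window:
                continue
            starts = np.sort(cdf["start"].to_numpy())
            w0 = np.arange(0, L - cfg.window + 1, cfg.step)
            cnt = np.searchsorted(starts, w0 + cfg.window) - np.searchsorted(starts, w0)
            centers = w0 + cfg.window / 2.0
            lam = np.full(len(w0), lam_bg)
            for span in cfg.local_lambda_windows:
                lo = np.maximum(centers - span / 2.0, 0)
                hi = np.minimum(centers + span / 2.0, L)
                c_loc = np.searchsorted(starts, hi) - np.searchsorted(starts, lo)
                np.maximum(lam, c_loc * cfg.window / span, out=lam)
            records.append((strand, contig, w0, cnt, lam))

    if not records:
        return empty_peak_set()

    all_p = np.concatenate(
        [stats.poisson.sf(cnt - 1, lam) for _, _, _, cnt, lam in records]
    )
    # BH across every tested window (both strands, all contigs)
    _, all_q, _, _ = multipletests(all_p, method="fdr_bh")

    peaks = []
    off = 0
    for strand, contig, w0, cnt, lam in records:
        n = len(w0)
        p = all_p[off : off + n]
        q = all_q[off : off + n]
        off += n
        sig = np.flatnonzero(q < cfg.q_cutoff)
        if sig.size == 0:
            continue
        # merge significant windows into intervals, allowing merge_gap
        ivl_s = w0[sig]
        ivl_e = w0[sig] + cfg.window
        cur_s, cur_e = ivl_s[0], ivl_e[0]
        cur_p, cur_q = p[sig[0]], q[sig[0]]
        merged = []
        for k in range(1, sig.size):
            if ivl_s[k] - cur_e <= cfg.merge_gap:
                cur_e = max(cur_e, ivl_e[k])
                cur_p = min(cur_p, p[sig[k]])
                cur_q = min(cur_q, q[sig[k]])
            else:
                merged.append((cur_s, cur_e, cur_p, cur_q))
                cur_s, cur_e, cur_p, cur_q = ivl_s[k], ivl_e[k], p[sig[k]], q[sig[k]]
        merged.append((cur_s, cur_e, cur_p, cur_q))
        sub = fragments.for_strand(strand)
        max_len = int(sub.lengths.max()) if len(sub) else 0
        cov = None
        L = genome.lengths[contig]
        for s, e, pp, qq in merged:
            if cov is None:
                cov = base_coverage(sub, genome)[contig]
            # refine boundaries to the coverage support around the summit:
            # window quantization otherwise leaves start-side margins and, on
            # the plus strand, truncates the fragment bodies
            lo = max(int(s) - max_len, 0)
            hi = min(int(e) + max_len, L)
            region = cov[lo:hi]
            if region.size == 0 or region.max() <= 0:
                continue
            summit_rel = int(np.argmax(region))
            thr = max(1.0, 0.1 * region[summit_rel])
            left = summit_rel
            while left > 0 and region[left - 1] >= thr:
                left -= 1
            right = summit_rel + 1
            while right < region.size and region[right] >= thr:
                right += 1
            ps, pe = lo + left, lo + right
            if pe - ps < cfg.min_width:
                continue
            peaks.append(
                dict(contig=contig, start=int(ps), end=int(pe), strand=strand,
                     summit=int(lo + summit_rel), p_value=float(pp), q_value=float(qq),
                     signal=float(region[summit_rel]))
            )

    if not peaks:
        return empty_peak_set()
    return PeakSet(pd.DataFrame(peaks)).sorted()


# ------------------------------------------------------------------- merging

def merge_peak_sets(peak_sets: list[PeakSet], labels: list[str] | None = None) -> PeakSet:
    """Interval union across strands/donors; records contributors and best q.

    Merging is purely positional (overlapping or bookended intervals join);
    the contributing strand set and source labels are kept per merged peak.
    """
    labels = labels or [f"set{i}" for i in range(len(peak_sets))]
    frames = []
    for lab, ps in zip(labels, peak_sets):
        if len(ps) == 0:
            continue
        df = ps.df.copy()
        df["source"] = lab
        frames.append(df)
    if not frames:
        return empty_peak_set()
    allp = pd.concat(frames, ignore_index=True).sort_values(
        ["contig", "start", "end"], kind="mergesort"
    )
    rows = []
    for contig, cdf in allp.groupby("contig", sort=True):
        cur = None
        for r in cdf.itertuples(index=False):
            if cur is None or r.start > cur["end"]:
                if cur is not None:
                    rows.append(cur)
                cur = dict(
                    contig=contig, start=int(r.start), end=int(r.end),
                    strands={r.strand}, sources=[r.source],
                    p_value=float(getattr(r, "p_value", np.nan)),
                    q_value=float(getattr(r, "q_value", np.nan)),
                    summit=int(getattr(r, "summit", r.start)),
                )
            else:
                cur["end"] = max(cur["end"], int(r.end))
                cur["strands"].add(r.strand)
                cur["sources"].append(r.source)
                q = float(getattr(r, "q_value", np.nan))
                if np.isnan(cur["q_value"]) or (not np.isnan(q) and q < cur["q_value"]):
                    cur["q_value"] = q
                    cur["p_value"] = float(getattr(r, "p_value", np.nan))
                    cur["summit"] = int(getattr(r, "summit", r.start))
        if cur is not None:
            rows.append(cur)
    out = pd.DataFrame(rows)
    out["strand"] = out["strands"].map(lambda s: ",".join(sorted(s)))
    out["n_sources"] = out["sources"].map(len)
    out["sources"] = out["sources"].map(lambda s: ",".join(s))
    out = out.drop(columns=["strands"])
    return PeakSet(out)


# ------------------------------------------------------------- donor sharing

def _hit_any(a_df: pd.DataFrame, b_df: pd.DataFrame, min_overlap: int = 1) -> np.ndarray:
    """Boolean per a row: does any b interval overlap it by >= min_overlap bp?

    Exact for min_overlap == 1 via sorted starts + prefix-max ends; falls back
    to a quadratic-per-contig scan otherwise.
    """
    hits = np.zeros(len(a_df), dtype=bool)
    b_by = {c: g for c, g in b_df.groupby("contig", sort=False)}
    for contig, g in a_df.groupby("contig", sort=False):
        b = b_by.get(contig)
        if b is None:
            continue
        bs = b["start"].to_numpy()
        be = b["end"].to_numpy()
        order = np.argsort(bs, kind="mergesort")
        bs, be = bs[order], be[order]
        if min_overlap == 1:
            pme = np.maximum.accumulate(be)
            idx = np.searchsorted(bs, g["end"].to_numpy(), side="left")
            ok = idx > 0
            h = np.zeros(len(g), dtype=bool)
            h[ok] = pme[idx[ok] - 1] > g["start"].to_numpy()[ok]
        else:
            h = np.array(
                [
                    bool(np.any(np.minimum(be, e) - np.maximum(bs, s) >= min_overlap))
                    for s, e in zip(g["start"].to_numpy(), g["end"].to_numpy())
                ]
            )
        hits[g.index.to_numpy()] = h
    return hits


def donor_sharing(
    peaks_by_donor: dict[str, PeakSet],
    min_donors: int = 2,
    min_overlap: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label every donor's peaks shared/specific and count per donor.

    A peak is "shared" iff it overlaps (>= min_overlap bp) a peak in at least
    ``min_donors - 1`` *other* donors.
    """
    if len(peaks_by_donor) < 2:
        raise ValueError("donor_sharing requires >= 2 donors")
    donors = sorted(peaks_by_donor)
    labelled = []
    for d in donors:
        ps = peaks_by_donor[d]
        if len(ps) == 0:
            continue
        a = ps.df.reset_index(drop=True)
        n_others = np.zeros(len(a), dtype=int)
        for other in donors:
            if other == d or len(peaks_by_donor[other]) == 0:
                continue
            n_others += _hit_any(a, peaks_by_donor[other].df, min_overlap).astype(int)
        lab = a[["contig", "start", "end", "strand"]].copy()
        lab["donor"] = d
        lab["n_other_donors"] = n_others
        lab["label"] = np.where(n_others >= min_donors - 1, "shared", "specific")
        labelled.append(lab)
    table = pd.concat(labelled, ignore_index=True) if labelled else pd.DataFrame(
        columns=["contig", "start", "end", "strand", "donor", "n_other_donors", "label"]
    )
    counts = (
        table.groupby(["donor", "label"]).size().unstack(fill_value=0)
        .reindex(columns=["shared", "specific"], fill_value=0).reset_index()
        if len(table)
        else pd.DataFrame(columns=["donor", "shared", "specific"])
    )
    return table, counts


# -------------------------------------------------------- coverage / correlation

def normalized_peak_coverage(
    peaks: PeakSet, fragments_by_donor: dict[str, FragmentSet]
) -> pd.DataFrame:
    """CPM matrix (peaks x donors): overlapping fragments x 1e6 / donor total."""
    donors = sorted(fragments_by_donor)
    pdf = peaks.df
    mat = pd.DataFrame(index=pdf.index, columns=donors, dtype=float)
    for d in donors:
        fs = fragments_by_donor[d]
        total = len(fs)
        if total == 0:
            raise ValueError(f"donor {d!r} has zero fragments")
        col = np.zeros(len(pdf))
        fby = {c: g for c, g in fs.df.groupby("contig", sort=False)}
        for contig, g in pdf.groupby("contig", sort=False):
            f = fby.get(contig)
            if f is None:
                continue
            fstarts = np.sort(f["start"].to_numpy())
            fends = np.sort(f["end"].to_numpy())
            n_ov = (
                np.searchsorted(fstarts, g["end"].to_numpy(), side="left")
                - np.searchsorted(fends, g["start"].to_numpy(), side="right")
            )
            col[g.index.to_numpy()] = n_ov
        mat[d] = col * 1e6 / total
    return mat


@dataclass
class DonorCorrelation:
    r: pd.DataFrame
    pseudocount: float
    undefined: list[str] = field(default_factory=list)  # constant columns

    @property
    def pairwise_values(self) -> np.ndarray:
        m = self.r.to_numpy()
        iu = np.triu_indices(m.shape[0], k=1)
        return m[iu]


def donor_correlation(matrix: pd.DataFrame, pseudocount: float = 0.5) -> DonorCorrelation:
    """Pairwise Pearson r between donors on log10(CPM + pseudocount)."""
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 donors")
    if matrix.shape[0] < 3:
        raise ValueError("need >= 3 peaks")
    logm = np.log10(matrix.to_numpy(dtype=float) + pseudocount)
    undefined = [
        matrix.columns[j] for j in range(logm.shape[1]) if np.ptp(logm[:, j]) == 0
    ]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(logm, rowvar=False)
    rdf = pd.DataFrame(r, index=matrix.columns, columns=matrix.columns)
    return DonorCorrelation(rdf, pseudocount, undefined)


def donor_location_test(matrix: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum p-values on log10 normalized coverage."""
    cols = list(matrix.columns)
    out = pd.DataFrame(np.ones((len(cols), len(cols))), index=cols, columns=cols)
    logm = np.log10(matrix.to_numpy(dtype=float) + pseudocount)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            p = stats.ranksums(logm[:, i], logm[:, j]).pvalue
            out.iloc[i, j] = out.iloc[j, i] = p
    return out


# ------------------------------------------------------------------ on / off

def split_reads_on_off(
    fragments: FragmentSet, peaks: PeakSet, min_overlap: int = 1
) -> tuple[FragmentSet, FragmentSet, float]:
    """Partition fragments into on-peak / off-peak; returns (on, off, on_fraction)."""
    if len(fragments) == 0:
        return fragments, fragments, float("nan")
    if len(peaks) == 0:
        return fragments.subset(np.zeros(len(fragments), bool)), fragments, 0.0
    hits = _hit_any(fragments.df, peaks.df, min_overlap)
    on = fragments.subset(hits)
    off = fragments.subset(~hits)
    return on, off, len(on) / len(fragments)
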