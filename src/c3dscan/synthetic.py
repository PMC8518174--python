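"""Synthetic study generator with planted ground truth.

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* a toy genome of i.i.d. bases at a chosen GC fraction, with G4 motifs
  (quadparser grammar) planted at known coordinates and strands;
* strand-specific "peaks" placed antisense to planted motifs — the short
  single-stranded fragment class (C3D) piles up on the C-rich strand with the
  motif at the fragment's 5' side;
* two fragment-length populations: C3D (truncated normal, mean 50, sd 8,
  gates 35-75 nt) and NPD (mean 167, sd 10, gates 147-190 nt);
* roughly one-fifth of C3D fragments assigned to peaks, the rest (and all
  NPD) placed uniformly;
* several donors whose per-peak read intensities share a latent log-normal
  signal (default latent correlation 0.9) with independent donor noise.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import FRAGMENT_COLUMNS, FragmentSet
from .g4scan import G4Motif
from .genome import Contig, GenomeModel, revcomp


# ------------------------------------------------------------------- configs

@dataclass
class LengthLaw:
    """Truncated-normal integer fragment length; bounds inclusive."""

    mean: float
    sd: float
    lo: int
    hi: int

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.lo - 0.5 - self.mean) / self.sd
        b = (self.hi + 0.5 - self.mean) / self.sd
        x = stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)
        return np.clip(np.rint(x).astype(int), self.lo, self.hi)


@dataclass
class SimConfig:
    n_fragments_per_donor: int = 200_000
    n_donors: int = 5
    c3d_length: LengthLaw = field(default_factory=lambda: LengthLaw(50, 8, 35, 75))
    npd_length: LengthLaw = field(default_factory=lambda: LengthLaw(167, 10, 147, 190))
    c3d_npd_ratio: float = 0.5          # fraction of fragments that are C3D
    c_rich_bias: float = 0.7            # per-base C probability on the peak strand
    max_motif_offset: int = 10          # 5' offset of the motif within a fragment, bp
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.c3d_npd_ratio <= 1 and 0 <= self.c_rich_bias <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_fragments_per_donor < 1 or self.n_donors < 1:
            raise ValueError("need at least one fragment and one donor")


@dataclass
class PlantedPeak:
    contig: str
    start: int
    end: int
    strand: str          # strand of the C-rich fragment pile (antisense to the G4)
    enrichment: float    # expected fold over the uniform background
    motif_index: int     # index into SimTruth.planted_g4
    antisense_g4: bool = True


@dataclass
class SimTruth:
    planted_g4: list[G4Motif]
    planted_peaks: list[PlantedPeak]
    on_peak_fraction: float
    donor_signal: np.ndarray    # peaks x donors latent intensity
    donor_names: list[str]
    seed: int

    def peaks_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(contig=p.contig, start=p.start, end=p.end, strand=p.strand,
                     enrichment=p.enrichment, motif_index=p.motif_index)
                for p in self.planted_peaks
            ]
        )

    def motifs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(contig=m.contig, start=m.start, end=m.end, strand=m.strand,
                     n_tracts=m.n_tracts)
                for m in self.planted_g4
            ]
        )


# -------------------------------------------------------------------- genome

_MOTIF_BUFFER = 8  # AT-only flank so planted motifs cannot chain into background


def _make_motif_sequence(rng: np.random.Generator, min_tract: int = 3,
                         loop_min: int = 1, loop_max: int = 3) -> tuple[str, tuple[int, ...]]:
    """One quadparser-conformant motif: 4 tracts of 3-4 G, loops of 1-3 nt
    drawn from {A, C, T} without CCC runs (so the complement plants no
    accidental extra tract).

    Planted motifs are kept <= 25 bp so that a motif plus its 5' placement
    offset always fits inside the shortest C3D fragment (35 nt): the on-peak
    fragments must carry the whole motif at their 5' side.
    """
    n_tracts = 4
    parts = []
    loops = []
    g_left = 25 - n_tracts * min_tract - (n_tracts - 1) * loop_min  # slack bp
    for t in range(n_tracts):
        extra_g = int(rng.integers(0, 2)) if g_left > 0 else 0
        g_left -= extra_g
        parts.append("G" * (min_tract + extra_g))
        if t < n_tracts - 1:
            hi = min(loop_max, 1 + g_left)
            while True:
                L = int(rng.integers(loop_min, hi + 1))
                loop = "".join(rng.choice(list("ACT"), size=L))
                if "CCC" not in loop:
                    break
            g_left -= L - 1
            loops.append(L)
            parts.append(loop)
    return "".join(parts), tuple(loops)


def generate_genome(
    length_per_contig: int = 2_000_000,
    n_contigs: int = 1,
    gc_fraction: float = 0.4,
    n_g4_motifs: int = 100,
    seed: int = 0,
    contig_class: str = "nuclear",
) -> tuple[GenomeModel, list[G4Motif]]:
    """Toy genome with planted, re-detectable G4 motifs.

    Background bases are i.i.d. at ``gc_fraction``; each planted motif is
    flanked by an 8-bp A/T buffer so the scanner recovers it at exactly the
    planted interval and strand.
    """
    if length_per_contig < 1000:
        raise ValueError("contig length must be >= 1 kb")
    if not (0 <= gc_fraction < 1):
        raise ValueError("gc_fraction must be in [0, 1)")
    total = length_per_contig * n_contigs
    if n_g4_motifs * 30 >= total:
        raise ValueError("infeasible motif packing: n_g4_motifs * 30 must be < total length")

    rng = np.random.default_rng(seed)
    pg = gc_fraction / 2.0
    pa = (1.0 - gc_fraction) / 2.0
    probs = np.array([pa, pg, pg, pa])
    bases = np.array(list("ACGT"))

    # spread motifs across contigs proportionally to length (equal here)
    per_contig = np.full(n_contigs, n_g4_motifs // n_contigs)
    per_contig[: n_g4_motifs % n_contigs] += 1

    contigs: list[Contig] = []
    motifs: list[G4Motif] = []
    for ci in range(n_contigs):
        name = f"chr{ci + 1}"
        seq = rng.choice(bases, size=length_per_contig, p=probs)
        occupied: list[tuple[int, int]] = []
        for _ in range(int(per_contig[ci])):
            motif_seq, loops = _make_motif_sequence(rng)
            strand = "+" if rng.integers(0, 2) else "-"
            span = len(motif_seq) + 2 * _MOTIF_BUFFER
            placed = False
            for _attempt in range(1000):
                s = int(rng.integers(_MOTIF_BUFFER + 100,
                                     length_per_contig - span - 100))
                lo, hi = s - 50, s + span + 50
                if all(hi <= o_lo or lo >= o_hi for o_lo, o_hi in occupied):
                    placed = True
                    break
            if not placed:
                raise ValueError("infeasible motif packing: could not place motif")
            occupied.append((lo, hi))
            insert = motif_seq if strand == "+" else revcomp(motif_seq)
            buf_left = rng.choice(list("AT"), size=_MOTIF_BUFFER)
            buf_right = rng.choice(list("AT"), size=_MOTIF_BUFFER)
            seq[s - _MOTIF_BUFFER : s] = buf_left
            seq[s : s + len(insert)] = list(insert)
            seq[s + len(insert) : s + len(insert) + _MOTIF_BUFFER] = buf_right
            motifs.append(
                G4Motif(name, s, s + len(insert), strand,
                        n_tracts=len(loops) + 1, loop_lengths=loops)
            )
        contigs.append(Contig(name, "".join(seq), contig_class))

    motifs.sort(key=lambda m: (m.contig, m.start))
    return GenomeModel(contigs), motifs


# --------------------------------------------------------------------- truth

def plant_truth(
    genome: GenomeModel,
    motifs: list[G4Motif],
    n_donors: int = 5,
    on_peak_fraction: float = 0.2,
    n_peaks: int | None = None,
    config: SimConfig | None = None,
    latent_log10_sd: float = 0.36,
    donor_log10_sd: float = 0.12,
    seed: int = 0,
) -> SimTruth:
    """Define peaks antisense to planted motifs and per-donor latent intensities.

    When ``config.c_rich_bias`` exceeds the genome C fraction, the non-motif
    part of each peak region is rewritten on the peak strand with that C
    probability (the motif itself and its A/T buffer stay untouched), giving
    on-peak fragments the C-rich composition the pipeline measures.

    The latent model gives log10 per-peak donor intensity = shared effect
    (sd ``latent_log10_sd``) + donor noise (sd ``donor_log10_sd``); the
    defaults set the latent pairwise correlation to 0.36^2/(0.36^2+0.12^2)=0.9.
    """
    if not motifs:
        raise ValueError("need at least one planted motif")
    if not (0 <= on_peak_fraction <= 1):
        raise ValueError("on_peak_fraction must lie in [0, 1]")
    cfg = config or SimConfig(n_donors=n_donors, seed=seed)
    rng = np.random.default_rng(seed)

    chosen = list(range(len(motifs)))
    if n_peaks is not None and n_peaks < len(motifs):
        chosen = sorted(rng.choice(len(motifs), size=n_peaks, replace=False))

    lmax = cfg.c3d_length.hi
    peaks: list[PlantedPeak] = []
    new_seqs = {c.name: None for c in genome.contigs}
    for mi in chosen:
        m = motifs[mi]
        p_strand = "-" if m.strand == "+" else "+"
        L = genome.lengths[m.contig]
        if p_strand == "-":
            # fragment 5' end (genomic right) sits at motif end + offset
            s, e = max(m.end - lmax, 0), min(m.end + cfg.max_motif_offset, L)
        else:
            s, e = max(m.start - cfg.max_motif_offset, 0), min(m.start + lmax, L)
        peaks.append(PlantedPeak(m.contig, int(s), int(e), p_strand, 1.0, mi))

    # rewrite non-motif peak bases with the C-rich bias on the peak strand
    genome_c = _genome_c_fraction(genome)
    if cfg.c_rich_bias > genome_c:
        for p in peaks:
            m = motifs[p.motif_index]
            if new_seqs[p.contig] is None:
                new_seqs[p.contig] = np.array(list(genome.sequence(p.contig)))
            arr = new_seqs[p.contig]
            protect_lo = m.start - _MOTIF_BUFFER
            protect_hi = m.end + _MOTIF_BUFFER
            pos = np.arange(p.start, p.end)
            pos = pos[(pos < protect_lo) | (pos >= protect_hi)]
            if pos.size == 0:
                continue
            # C-rich on the peak strand: on '+', write C on top; on '-', write G
            rich = "C" if p.strand == "+" else "G"
            other = list("AT")
            draw = rng.random(pos.size)
            fill = np.where(draw < cfg.c_rich_bias, rich,
                            np.array(other)[rng.integers(0, 2, size=pos.size)])
            arr[pos] = fill
        for c in genome.contigs:
            if new_seqs[c.name] is not None:
                c.sequence = "".join(new_seqs[c.name])

    # latent per-peak signal shared across donors + donor-specific noise
    donors = [f"donor{i + 1}" for i in range(cfg.n_donors)]
    shared = rng.normal(0.0, latent_log10_sd, size=(len(peaks), 1))
    noise = rng.normal(0.0, donor_log10_sd, size=(len(peaks), cfg.n_donors))
    signal = 10.0 ** (shared + noise)

    # expected fold enrichment of window counts at the planted peaks
    n_c3d = cfg.n_fragments_per_donor * cfg.c3d_npd_ratio
    mean_width = float(np.mean([p.end - p.start for p in peaks])) if peaks else 1.0
    bg_rate = n_c3d * (1 - on_peak_fraction) / 2 / genome.total_length
    pk_rate = n_c3d * on_peak_fraction / max(len(peaks), 1) / mean_width
    fold = pk_rate / bg_rate if bg_rate > 0 else float("inf")
    for p in peaks:
        p.enrichment = float(fold)

    return SimTruth(motifs, peaks, on_peak_fraction, signal, donors, seed)


def _genome_c_fraction(genome: GenomeModel) -> float:
    c = sum(ctg.sequence.count("C") for ctg in genome.contigs)
    return c / genome.total_length


# ------------------------------------------------------------------ fragments

def simulate_fragments(
    genome: GenomeModel,
    truth: SimTruth,
    config: SimConfig | None = None,
) -> dict[str, FragmentSet]:
    """Per-donor fragment sets with the planted on-peak structure.

    C3D fragments are assigned to peaks with probability ``on_peak_fraction``;
    the peak for each on-peak fragment is drawn proportionally to that donor's
    latent intensity, the fragment lies on the peak strand and carries the
    motif at its 5' side.  Off-peak C3D and all NPD fragments are uniform on
    the genome with uniform strand.
    """
    cfg = config or SimConfig(n_donors=len(truth.donor_names), seed=truth.seed)
    if genome.total_length == 0:
        raise ValueError("empty genome")
    if cfg.n_fragments_per_donor < 1:
        raise ValueError("zero fragments requested")

    contig_names = genome.names
    contig_lens = np.array([genome.lengths[n] for n in contig_names])
    contig_p = contig_lens / contig_lens.sum()

    peaks = truth.planted_peaks
    motifs = truth.planted_g4
    if peaks:
        p_contig = np.array([p.contig for p in peaks])
        p_minus = np.array([p.strand == "-" for p in peaks])
        p_mstart = np.array([motifs[p.motif_index].start for p in peaks])
        p_mend = np.array([motifs[p.motif_index].end for p in peaks])
        p_clen = np.array([genome.lengths[p.contig] for p in peaks])

    seeds = np.random.SeedSequence(cfg.seed).spawn(len(truth.donor_names))
    out: dict[str, FragmentSet] = {}
    for di, donor in enumerate(truth.donor_names):
        rng = np.random.default_rng(seeds[di])
        n = cfg.n_fragments_per_donor
        n_c3d = int(round(n * cfg.c3d_npd_ratio))
        n_npd = n - n_c3d
        n_on = int(round(n_c3d * truth.on_peak_fraction)) if peaks else 0
        n_off = n_c3d - n_on

        parts: list[pd.DataFrame] = []

        if n_on:
            w = truth.donor_signal[:, di]
            pk = rng.choice(len(peaks), size=n_on, p=w / w.sum())
            lens = cfg.c3d_length.sample(n_on, rng)
            offs = rng.integers(0, cfg.max_motif_offset + 1, size=n_on)
            minus = p_minus[pk]
            Lp = p_clen[pk]
            e_minus = np.minimum(p_mend[pk] + offs, Lp)
            s_minus = np.maximum(e_minus - lens, 0)
            s_plus = np.maximum(p_mstart[pk] - offs, 0)
            e_plus = np.minimum(s_plus + lens, Lp)
            parts.append(
                pd.DataFrame(
                    {
                        "contig": p_contig[pk],
                        "start": np.where(minus, s_minus, s_plus).astype(int),
                        "end": np.where(minus, e_minus, e_plus).astype(int),
                        "strand": np.where(minus, "-", "+"),
                        "donor": donor,
                    }
                )
            )

        for count, law in ((n_off, cfg.c3d_length), (n_npd, cfg.npd_length)):
            if count == 0:
                continue
            lens = law.sample(count, rng)
            cis = rng.choice(len(contig_names), size=count, p=contig_p)
            Ls = contig_lens[cis]
            lns = np.minimum(lens, Ls)
            starts = (rng.random(count) * (Ls - lns + 1)).astype(int)
            parts.append(
                pd.DataFrame(
                    {
                        "contig": np.array(contig_names)[cis],
                        "start": starts,
                        "end": starts + lns,
                        "strand": np.where(rng.integers(0, 2, size=count) == 1, "+", "-"),
                        "donor": donor,
                    }
                )
            )

        df = pd.concat(parts, ignore_index=True)[FRAGMENT_COLUMNS]
        out[donor] = FragmentSet(df).sorted()
    return out


def simulate_donor_intensities(
    n_peaks: int,
    n_donors: int,
    latent_corr: float = 0.9,
    total_log10_sd: float = 0.38,
    base_cpm: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """CPM-like intensity matrix with a chosen latent log-scale correlation.

    log10 intensity = log10(base_cpm) + shared peak effect + donor noise with
    variances split so the pairwise correlation of the log intensities equals
    ``latent_corr``.
    """
    if not (0 < latent_corr < 1):
        raise ValueError("latent_corr must be in (0, 1)")
    rng = np.random.default_rng(seed)
    sd_s = total_log10_sd * np.sqrt(latent_corr)
    sd_e = total_log10_sd * np.sqrt(1.0 - latent_corr)
    shared = rng.normal(0.0, sd_s, size=(n_peaks, 1))
    noise = rng.normal(0.0, sd_e, size=(n_peaks, n_donors))
    mat = 10.0 ** (np.log10(base_cpm) + shared + noise)
    return pd.DataFrame(mat, columns=[f"donor{i + 1}" for i in range(n_donors)])


# ------------------------------------------------------------------------ IO

def write_truth(truth: SimTruth, genome: GenomeModel, out_dir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, planted peak/motif BED6, donor manifest and config.

    The BED files round-trip through :func:`c3dscan.colocalize.read_bed`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["genome"] = genome.to_fasta(out / "genome.fa")

    pk = out / "planted_peaks.bed"
    with open(pk, "w") as fh:
        for i, p in enumerate(truth.planted_peaks):
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\tpeak{i}\t{int(round(p.enrichment))}\t{p.strand}\n")
    files["peaks"] = pk

    mo = out / "planted_g4.bed"
    with open(mo, "w") as fh:
        for i, m in enumerate(truth.planted_g4):
            fh.write(f"{m.contig}\t{m.start}\t{m.end}\tg4_{i}\t{m.n_tracts}\t{m.strand}\n")
    files["motifs"] = mo

    dn = out / "donors.tsv"
    sig = pd.DataFrame(truth.donor_signal, columns=truth.donor_names)
    sig.to_csv(out / "donor_signal.tsv", sep="\t", index=False)
    files["donor_signal"] = out / "donor_signal.tsv"
    pd.DataFrame({"donor": truth.donor_names}).to_csv(dn, sep="\t", index=False)
    files["donors"] = dn

    cfgp = out / "truth.json"
    with open(cfgp, "w") as fh:
        json.dump(
            {
                "on_peak_fraction": truth.on_peak_fraction,
                "seed": truth.seed,
                "n_peaks": len(truth.planted_peaks),
                "n_motifs": len(truth.planted_g4),
            },
            fh,
            indent=2,
        )
    files["truth"] = cfgp
    return files
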