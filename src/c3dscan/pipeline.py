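"""End-to-end pipeline orchestration.

Wires the stages in their natural order — ingest fragments, size-gate,
strand-specific peak calling per donor, cross-donor merge and sharing, G4
scanning, composition and strand bias, colocalization / annotation /
aggregation — and writes plain-text outputs plus a manifest with checksums.
Outputs are byte-identical across reruns with the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .colocalize import (
    FeatureSet,
    aggregate_profile,
    annotate_peaks,
    colocalization_report,
    overlap_counts,
    permutation_test,
    read_bed,
    read_gene_models,
)
from .composition import composition_table, sample_background_kmers, strand_bias_table
from .fragments import C3D, FragmentSet, SizeGateConfig, read_fragments, split_by_class
from .g4scan import G4Motif, antisense_of, motif_position_in_peak, scan_genome_g4
from .genome import GenomeModel
from .peaks import (
    PeakCallConfig,
    call_peaks_stranded,
    donor_correlation,
    donor_sharing,
    merge_peak_sets,
    normalized_peak_coverage,
    split_reads_on_off,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome: Path
    fragments: dict[str, Path]          # donor -> BED6/BAM path
    out_dir: Path
    seed: int
    fragment_format: str = "BED6"
    features: dict[str, Path] = field(default_factory=dict)
    annotation: Path | None = None      # BED12 / GFF3 gene models
    cpg: Path | None = None
    size_gates: SizeGateConfig = field(default_factory=SizeGateConfig)
    peak_config: PeakCallConfig = field(default_factory=PeakCallConfig)
    g4_min_tract: int = 3
    g4_loop_min: int = 1
    g4_loop_max: int = 7
    g4_min_tracts: int = 4
    n_perm: int = 200
    background_kmers: int = 5000
    size_class: str = C3D

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        base = Path(path).parent
        rp = lambda p: (base / p) if not Path(p).is_absolute() else Path(p)
        cfg = cls(
            genome=rp(raw["genome"]),
            fragments={d: rp(p) for d, p in raw["fragments"].items()},
            out_dir=rp(raw["out_dir"]),
            seed=int(raw["seed"]),
            fragment_format=raw.get("fragment_format", "BED6"),
            features={n: rp(p) for n, p in raw.get("features", {}).items()},
            annotation=rp(raw["annotation"]) if raw.get("annotation") else None,
            cpg=rp(raw["cpg"]) if raw.get("cpg") else None,
            n_perm=int(raw.get("n_perm", 200)),
            background_kmers=int(raw.get("background_kmers", 5000)),
        )
        if "size_gates" in raw:
            cfg.size_gates = SizeGateConfig(**raw["size_gates"])
        if "peak_config" in raw:
            cfg.peak_config = PeakCallConfig(**{
                k: (tuple(v) if isinstance(v, list) else v) for k, v in raw["peak_config"].items()
            })
        for k in ("g4_min_tract", "g4_loop_min", "g4_loop_max", "g4_min_tracts", "size_class"):
            if k in raw:
                setattr(cfg, k, raw[k])
        return cfg

    def validate(self) -> None:
        missing = [str(p) for p in
                   [self.genome, *self.fragments.values(), *self.features.values()]
                   + ([self.annotation] if self.annotation else [])
                   + ([self.cpg] if self.cpg else [])
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage_log: list[str] = []

    def note(msg: str) -> None:
        log.info(msg)
        stage_log.append(msg)

    genome = GenomeModel.from_fasta(config.genome)
    note(f"genome: {len(genome.contigs)} contigs, {genome.total_length} bp")

    # ---- ingest + size gate
    frags_by_donor: dict[str, FragmentSet] = {}
    class_by_donor: dict[str, FragmentSet] = {}
    summary_rows = []
    for donor, path in sorted(config.fragments.items()):
        fs = read_fragments(path, format=config.fragment_format, donor=donor, genome=genome)
        classes = split_by_class(fs, config.size_gates)
        frags_by_donor[donor] = fs
        class_by_donor[donor] = classes[config.size_class]
        summary_rows.append(
            dict(donor=donor, total=len(fs),
                 c3d=len(classes["C3D"]), npd=len(classes["NPD"]), other=len(classes["OTHER"]),
                 plus=int((fs.df["strand"] == "+").sum()),
                 minus=int((fs.df["strand"] == "-").sum()))
        )
        note(f"{donor}: {len(fs)} fragments, {len(classes['C3D'])} C3D / "
             f"{len(classes['NPD'])} NPD / {len(classes['OTHER'])} other")
    fsum = out / "fragments_summary.tsv"
    pd.DataFrame(summary_rows).to_csv(fsum, sep="\t", index=False)
    written.append(fsum)

    # ---- peak calling per donor (caller splits strands internally)
    peaks_by_donor = {}
    for donor in sorted(class_by_donor):
        ps = call_peaks_stranded(class_by_donor[donor], genome, config.peak_config)
        peaks_by_donor[donor] = ps
        p = out / f"peaks_{donor}.narrowPeak"
        ps.to_narrowpeak(p)
        written.append(p)
        note(f"{donor}: {len(ps)} {config.size_class} peaks")

    merged = merge_peak_sets(list(peaks_by_donor.values()), labels=sorted(peaks_by_donor))
    mp = out / "peaks_merged.bed"
    with open(mp, "w") as fh:
        for i, r in merged.df.iterrows():
            fh.write(f"{r['contig']}\t{r['start']}\t{r['end']}\tmerged_{i}\t{r['n_sources']}\t"
                     f"{r['strand'] if r['strand'] in '+-' else '.'}\n")
    written.append(mp)
    note(f"merged: {len(merged)} peaks")

    # ---- donor sharing, coverage matrix, correlation
    if len(peaks_by_donor) >= 2 and all(len(p) for p in peaks_by_donor.values()):
        table, counts = donor_sharing(peaks_by_donor)
        t1, t2 = out / "donor_sharing.tsv", out / "donor_sharing_counts.tsv"
        table.to_csv(t1, sep="\t", index=False)
        counts.to_csv(t2, sep="\t", index=False)
        written += [t1, t2]

        cov = normalized_peak_coverage(merged, class_by_donor)
        cv = out / "peak_coverage_matrix.tsv"
        cov.to_csv(cv, sep="\t", index=False)
        written.append(cv)
        if len(cov) >= 3:
            corr = donor_correlation(cov)
            cr = out / "donor_correlation.tsv"
            corr.r.to_csv(cr, sep="\t")
            written.append(cr)
            note(f"mean pairwise donor r = {np.nanmean(corr.pairwise_values):.3f}")

    # ---- on/off-peak split
    all_class = None
    for donor in sorted(class_by_donor):
        all_class = class_by_donor[donor] if all_class is None else all_class.concat(class_by_donor[donor])
    on, off, on_frac = split_reads_on_off(all_class, merged)
    note(f"on-peak fraction: {on_frac:.4f}")

    # ---- G4 scan + antisense colocalization
    motifs = scan_genome_g4(genome, config.g4_min_tract, config.g4_loop_min,
                            config.g4_loop_max, config.g4_min_tracts)
    g4p = out / "g4_motifs.bed"
    with open(g4p, "w") as fh:
        for i, m in enumerate(motifs):
            fh.write(f"{m.contig}\t{m.start}\t{m.end}\tg4_{i}\t{m.n_tracts}\t{m.strand}\n")
    written.append(g4p)
    note(f"g4 motifs: {len(motifs)}")

    coloc_rows = []
    stranded_peaks = merged.df[merged.df["strand"].isin(["+", "-"])]
    if len(motifs) and len(stranded_peaks):
        anti = antisense_of(motifs)
        anti_fs = FeatureSet(
            "antisense_g4",
            pd.DataFrame([dict(contig=m.contig, start=m.start, end=m.end, strand=m.strand)
                          for m in anti]),
            stranded=True,
        )
        from .peaks import PeakSet
        sp = PeakSet(stranded_peaks.reset_index(drop=True))
        oc = overlap_counts(sp, anti_fs, strand_mode="same")
        perm = permutation_test(sp, anti_fs, genome, n_perm=config.n_perm,
                                seed=config.seed, strand_mode="same")
        coloc_rows.append(
            dict(comparison="peaks_vs_antisense_g4", n_A=len(sp), n_A_hit=oc.n_A_hit,
                 pct_A_hit=100.0 * oc.n_A_hit / len(sp), n_B_hit=oc.n_B_hit,
                 p=perm.p, z=perm.z, null_mean=perm.null_mean)
        )
        # motif position along overlapping peaks (5' -> 3')
        positions = []
        for _, pr in sp.df.iterrows():
            for m in motifs:
                if m.contig == pr["contig"] and m.start < pr["end"] and m.end > pr["start"]:
                    positions.append(motif_position_in_peak(pr, m))
        if positions:
            note(f"median motif position in peak (5'->3'): {float(np.median(positions)):.3f}")
            posp = out / "motif_positions.tsv"
            pd.DataFrame({"relative_position": positions}).to_csv(posp, sep="\t", index=False)
            written.append(posp)
    if coloc_rows:
        clp = out / "antisense_colocalization.tsv"
        pd.DataFrame(coloc_rows).to_csv(clp, sep="\t", index=False)
        written.append(clp)

    # ---- composition of peak sequences vs random background
    if len(merged):
        seqs = [genome.fetch(r["contig"], int(r["start"]), int(r["end"]))
                for _, r in merged.df.iterrows()]
        comp = composition_table(seqs, [f"peak_{i}" for i in range(len(seqs))])
        cp = out / "composition_peaks.tsv"
        comp.to_csv(cp, sep="\t", index=False)
        written.append(cp)
        bg = sample_background_kmers(genome, k=50, n=config.background_kmers, seed=config.seed)
        bgt = composition_table(bg)
        bp = out / "composition_background.tsv"
        bgt.to_csv(bp, sep="\t", index=False)
        written.append(bp)
        note(f"peak C-content mean {comp['c_content'].mean():.3f} vs background "
             f"{bgt['c_content'].mean():.3f}")

        sb = strand_bias_table(merged.df, all_class, genome)
        sbp = out / "strand_bias.tsv"
        sb.to_csv(sbp, sep="\t", index=False)
        written.append(sbp)

    # ---- feature colocalization / enrichment
    if config.features and len(merged):
        feats = [read_bed(p, name=n) for n, p in sorted(config.features.items())]
        rep = colocalization_report(merged, feats, genome, n_perm=config.n_perm,
                                    seed=config.seed)
        ep = out / "feature_enrichment.tsv"
        rep.to_csv(ep, sep="\t", index=False)
        written.append(ep)

    # ---- annotation
    if config.annotation and len(merged):
        genes = read_gene_models(config.annotation)
        cpg = read_bed(config.cpg, name="cpg") if config.cpg else None
        ann, props = annotate_peaks(merged, genes, cpg)
        ap = out / "annotation.tsv"
        ann.to_csv(ap, sep="\t", index=False)
        pp = out / "annotation_proportions.tsv"
        props.rename("proportion").to_frame().to_csv(pp, sep="\t")
        written += [ap, pp]

    # ---- aggregation over G4 motifs, sense vs antisense fragment strand
    if len(motifs) and all_class is not None and len(all_class):
        mot_fs = FeatureSet(
            "g4_motifs",
            pd.DataFrame([dict(contig=m.contig, start=m.start, end=m.end, strand=m.strand)
                          for m in motifs]),
            stranded=True,
        )
        profiles = {}
        for lab, frag_strand in (("sense", "same"), ("antisense", "opposite")):
            rows = []
            for rs in "+-":
                fstr = rs if frag_strand == "same" else ("-" if rs == "+" else "+")
                sub_regions = FeatureSet(lab, mot_fs.df[mot_fs.df["strand"] == rs], stranded=True)
                if len(sub_regions) == 0:
                    continue
                agg = aggregate_profile(all_class, sub_regions, genome, flank=500, bins=50,
                                        strand=fstr)
                rows.append(agg.matrix)
            profiles[lab] = np.vstack(rows).mean(axis=0)
        prof = pd.DataFrame(profiles)
        prp = out / "g4_aggregation_profiles.tsv"
        prof.to_csv(prp, sep="\t", index=False)
        written.append(prp)

    # ---- manifest
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "size_class": config.size_class,
            "size_gates": vars(config.size_gates),
            "peak_config": {k: list(v) if isinstance(v, tuple) else v
                            for k, v in vars(config.peak_config).items()},
            "g4": dict(min_tract=config.g4_min_tract, loop_min=config.g4_loop_min,
                       loop_max=config.g4_loop_max, min_tracts=config.g4_min_tracts),
            "n_perm": config.n_perm,
        },
        "inputs": {"genome": str(config.genome),
                   "fragments": {d: str(p) for d, p in config.fragments.items()}},
        "outputs": {p.name: _sha256(p) for p in written},
        "log": stage_log,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
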