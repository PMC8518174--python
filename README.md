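# c3dscan

Plasma cell-free DNA (cfDNA) is dominated by ~160 nt nucleosome-protected
double-stranded fragments, but a second population of short (~50 nt)
**single-stranded** fragments exists whose strand of origin, genomic sources
and sequence composition carry their own signal. `c3dscan` is a pipeline for
characterising that short single-stranded class (here "C3D", size-gated
35–75 nt) against the nucleosome-protected class ("NPD", 147–190 nt) from
strand-resolved fragment data:

* **fragments** — BED6/BAM ingestion with explicit original-ssDNA strand
  semantics, inclusive size gating, strand splitting, CPM coverage tracks;
* **peaks** — a strand-specific peak caller (sliding window over fragment
  5'-start counts, Poisson tail against a MACS-style max of genome-wide and
  local rates λ = max(λ_bg, λ_1k, λ_5k, λ_10k), Benjamini–Hochberg across all
  tested windows, coverage-support boundary refinement), cross-donor merging,
  shared/specific donor labels, CPM peak-coverage matrices and Pearson-on-log10
  donor correlations;
* **g4scan** — quadparser G-quadruplex motifs (≥4 maximal G-runs of ≥3 G,
  loops 1–7 nt) on both strands, antisense interval sets, and the motif's
  strand-aware relative position inside a peak;
* **composition** — C-content, GC-skew = (#G−#C)/(#G+#C), random 50-mer
  genome backgrounds, per-peak strand bias toward the C-rich strand;
* **colocalize** — Venn-style overlap counts under strand modes, permutation
  colocalization tests with p = (1+#{null ≥ obs})/(n_perm+1), midpoint
  enrichment folds over bp-expected frequencies, gene-model/CpG annotation,
  and metaplot aggregation matrices;
* **synthetic** — a generator that plants ground truth (toy genome, G4 motifs,
  antisense C-rich peaks, multi-donor fragment populations with a latent
  correlated intensity model) so every stage above is verifiable at desk scale.

## Worked example

```python
import numpy as np, pandas as pd
from c3dscan import *
from c3dscan.synthetic import SimConfig
from c3dscan.colocalize import FeatureSet

# a 500 kb toy genome with 40 planted G4 motifs, and 3 donors whose short
# fragments pile up antisense to those motifs (~20% of C3D reads on peaks)
genome, motifs = generate_genome(length_per_contig=500_000, n_contigs=1,
                                 gc_fraction=0.4, n_g4_motifs=40, seed=7)
cfg = SimConfig(n_fragments_per_donor=50_000, n_donors=3, seed=11)
truth = plant_truth(genome, motifs, n_donors=3, config=cfg, seed=5)
frags = simulate_fragments(genome, truth, cfg)

calls = {d: call_peaks_stranded(split_by_class(fs)["C3D"], genome)
         for d, fs in frags.items()}
merged = merge_peak_sets(list(calls.values()), labels=sorted(calls))
table, counts = donor_sharing(calls)
print(f"{len(merged)} merged peaks, "
      f"{(table['label'] == 'shared').mean():.1%} shared by >=2 donors")

c3d = {d: split_by_class(fs)["C3D"] for d, fs in frags.items()}
r = donor_correlation(normalized_peak_coverage(merged, c3d))
print(f"mean pairwise donor r = {np.mean(r.pairwise_values):.3f}")

found = scan_genome_g4(genome)
anti = FeatureSet("antisense_g4", pd.DataFrame(
    [dict(contig=m.contig, start=m.start, end=m.end, strand=m.strand)
     for m in antisense_of(found)]), stranded=True)
stranded = PeakSet(merged.df[merged.df["strand"].isin(["+", "-"])].reset_index(drop=True))
oc = overlap_counts(stranded, anti, strand_mode="same")
perm = permutation_test(stranded, anti, genome, n_perm=199, seed=1, strand_mode="same")
print(f"{oc.n_A_hit}/{len(stranded)} peaks overlap an antisense G4 motif "
      f"(permutation p = {perm.p:.3g}, z = {perm.z:.1f})")
```

Output:

```
40 merged peaks, 100.0% shared by >=2 donors
mean pairwise donor r = 0.886
40/40 peaks overlap an antisense G4 motif (permutation p = 0.005, z = 74.5)
```

All 40 planted peaks are recovered on the planted strand and shared by every
donor; per-peak normalized coverage correlates across donors close to the
latent model's r = 0.9 (small study, so sampling noise shows); and every peak
sits on the strand **antisense** to a G4 motif — the colocalization a
permutation null rejects at its smallest attainable p, (1+0)/(199+1) = 0.005.

## Command line

```bash
c3dscan simulate --out study/ --seed 123 --length 500000 --motifs 40 --donors 3 --fragments 50000
c3dscan all --config study/pipeline_config.json
c3dscan g4scan study/genome.fa --out g4.bed
c3dscan callpeaks study/fragments_donor1.bed --genome study/genome.fa --out d1.narrowPeak
c3dscan colocalize d1.narrowPeak g4.bed --genome study/genome.fa --strand-mode opposite --seed 1
```

`c3dscan all` runs ingest → size gate → per-donor strand-specific peak
calling → merge → donor sharing/correlation → G4 scan → antisense
colocalization → composition/strand bias → annotation → aggregation, and
writes TSV/BED outputs plus a `manifest.json` with SHA-256 checksums; reruns
with the same config and seed are byte-identical.

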