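# Methods

`c3dscan` analyses strand-resolved plasma cfDNA fragment data to characterise
a short (~50 nt) single-stranded fragment class (here called C3D) against the
familiar nucleosome-protected ~160 nt class (NPD). This note documents the
models, the parameters that matter, the synthetic data the package is
validated on, and the numerical choices that were genuinely open.

## Coordinates and strand semantics

All intervals are 0-based, half-open (BED convention); BAM input is converted
on read. `FragmentRecord.strand` is the strand of the **original
single-stranded molecule**, not the mate-1 mapping strand. For BAM input the
default rule is `mate1-opposite` — the ssDNA template is taken to be the
complement of the strand mate 1 maps to, because second-strand synthesis in
an ssDNA-ligation library proceeds from the complementary strand. The rule is
configurable (`mate1-same`) because library chemistries differ; BED6 input
uses its strand column verbatim.

## Size gates

C3D: 35–75 nt; NPD: 147–190 nt; everything else OTHER. Both bounds are
treated as inclusive; the boundaries are exposed in `SizeGateConfig` because
inclusivity at the edges is a convention, not a law.

## Strand-specific peak caller

Each strand of each donor's size-gated fragment set is scanned independently
with a sliding window (default 50 bp, step 10 bp) over **fragment 5'-start
counts**. The null rate for a window is

    lambda = max(lambda_genome, lambda_1kb, lambda_5kb, lambda_10kb)

i.e. the genome-wide background rate and centred local rates rescaled to the
window size — the max-of-lambdas device that makes the test robust to local
coverage structure. Window significance is the Poisson upper tail
P(X ≥ k | lambda); Benjamini–Hochberg adjustment runs across **all** tested
windows on both strands. Windows with q below the cutoff (default 0.05) are
merged when separated by at most `merge_gap` (50 bp).

Merged window spans are then **refined to the coverage support**: the
reported peak is the contiguous region around the summit where the strand's
base coverage stays at or above max(1, 10% of the summit height). Without
this step the peak interval inherits window-grid margins on the start side
and, on the plus strand, truncates the fragment bodies entirely — peak
geometry would depend on strand, which is wrong for a strand-symmetric
protocol. Peaks narrower than `min_width` (35 bp, one minimal C3D fragment)
are dropped.

Significance is per strand and per donor; cross-strand/donor merging
(`merge_peak_sets`) is a pure reporting union that keeps contributing strands,
donors and the best q, and never re-tests.

The caller is calibrated, not just powered: on pure-background simulations
(uniform fragments, no planted structure) it returns essentially zero peaks
(see `test_caller_null_calibration`), because BH across ~2×10^5 windows at
q<0.05 leaves no budget for isolated Poisson fluctuations.

## G4 motif scanner

The quadparser grammar: ≥ 4 tracts of ≥ 3 consecutive G separated by loops of
1–7 bases. Two deliberate interpretations:

* **Tracts are maximal G-runs.** A run longer than `min_tract` is one tract,
  never split, so an uninterrupted poly-G stretch is a single tract and e.g.
  `"G"*20` contains no motif. (A naive regex `G{3,}(N{1,7}G{3,}){3,}` would
  match it by spending G's as loop bases.)
* **N never matches**, neither in a tract nor inside a loop.

Under this reading a match is exactly a group of consecutive maximal G-runs
whose inter-run gaps are all legal loops; the scanner finds these by run
grouping, and the test suite checks it **exactly** against an independent
brute-force oracle (substring enumeration + leftmost-longest greedy
selection) on 1,000 seeded random 200-mers. Minus-strand motifs come from
scanning the reverse complement with coordinates mapped back to the top
strand; motifs are always reported on the G-tract-bearing strand, and
`antisense_of` flips strands to produce the C-rich comparator set.

`motif_position_in_peak` reports the motif midpoint's relative position along
the peak measured from the peak's 5' terminus (genomic right end for minus
peaks), in [0, 1].

## Composition and strand bias

GC-skew is (#G − #C)/(#G + #C) computed on the reference top strand; a C-rich
top strand is negative-skewed. When #G + #C = 0 the skew is undefined and
flagged, never silently 0. The C-rich strand of a peak is decided from the
peak's reference sequence (not from fragment sequences, so the score exists
at any depth); ties default to the top strand and carry a flag. Strand bias
is (n_Crich − n_other)/(n_Crich + n_other) over overlapping fragments.

## Colocalization statistics

* `overlap_counts` — element-wise Venn counts under `ignore`/`same`/
  `opposite` strand modes, exact for any `min_overlap` (a vectorised sorted-
  array path handles the 1 bp default; an explicit scan handles larger
  overlap demands).
* `permutation_test` — every query interval is re-placed uniformly at random
  within its own contig, preserving length and strand; overlaps among placed
  intervals are not forbidden. p = (1 + #{null ≥ obs})/(n_perm + 1),
  z = (obs − mean)/sd. A circular-rotation strategy is available when the
  internal spacing of the query set should be preserved. Because the
  statistic is a discrete hit count, ties make the p-value conservative when
  the query set is small; calibration experiments should use enough intervals
  (hundreds) that the count has resolution.
* `enrichment_fold` — observed fraction of peak **midpoints** inside the
  feature over the feature's union-bp fraction of the genome (bp-fraction
  convention, chosen over feature-count fraction and documented here because
  external annotation tools leave it implicit).
* `annotate_peaks` — midpoint label with priority promoter > 5'UTR > exon >
  intron > 3'UTR > TTS > intergenic; promoter = [TSS−1000, TSS+100), TTS
  window = [TES−100, TES+1000), both strand-aware; "exon" means the coding
  part of exons (otherwise the UTR labels below it in priority would be
  unreachable). CpG islands and their 2 kb shores are reported separately
  since they are orthogonal to gene-model labels.
* `aggregate_profile` — reference-point (±flank around midpoint or 5' end)
  or scale-regions matrices of CPM coverage, strand-oriented so the 5'
  direction is always on the left; the CPM denominator is the full fragment
  set before any strand filtering, so sense and antisense profiles from the
  same set are directly comparable.

## Synthetic data: what it emulates

`generate_genome` draws i.i.d. bases at a chosen GC fraction and plants
quadparser-conformant motifs (4 tracts of 3–4 G, loops 1–3 nt, total ≤ 25 bp)
at known positions and strands, each flanked by an 8 bp A/T buffer so the
scanner provably recovers the planted interval exactly. Planted motifs are
kept ≤ 25 bp because an on-peak fragment must carry the whole motif plus its
5' offset (≤ 10 bp) inside the shortest C3D fragment (35 nt).

`plant_truth` places one peak antisense to each motif: for a plus-strand
motif the fragment pile lies on the minus strand with fragment 5' ends
(genomic right) at motif end + offset, and symmetrically for minus-strand
motifs — the motif therefore sits at the 5' side of every on-peak fragment.
The non-motif part of each peak is rewritten with per-base C probability
`c_rich_bias` (default 0.7) on the peak strand, giving on-peak fragments the
C-rich composition the pipeline measures.

`simulate_fragments` draws, per donor, truncated-normal fragment lengths
(C3D: mean 50, sd 8, bounds 35–75; NPD: mean 167, sd 10, bounds 147–190 —
the truncation bounds equal the classifier gates so truth and classification
agree), assigns a fraction `on_peak_fraction` (default 0.2, roughly one
fragment in five) of C3D fragments to peaks, and places everything else
uniformly with uniform strand. Defaults: 5 donors, 2×10^5 fragments per
donor, C3D:NPD ratio 0.5 — depths chosen for desk-scale runtimes while
keeping per-peak counts in the hundreds.

Per-peak donor intensities follow a latent log-normal model: log10 intensity
= shared peak effect (sd 0.36) + donor noise (sd 0.12), so the latent
pairwise correlation is 0.36²/(0.36²+0.12²) = 0.90. The fragment-count chain
(fragments → peaks → CPM → Pearson on log10(CPM+0.5)) recovers r ≈ 0.91–0.93
at the default depth.

**What the generator does not emulate:** sequencing errors, quality scores,
adapters, PCR duplicates, mappability structure, microbial reads, and any
*variation* in peak C-richness — every peak is planted at the same
`c_rich_bias`, so the real-data correlation between a peak's strand bias and
its C-content is degenerate here and is not asserted by the tests. Passing
tests therefore demonstrate that the pipeline recovers planted structure of
this statistical shape, not that real plasma libraries look like this.

## Numerical choices

* Poisson tails via `scipy.stats.poisson.sf`; BH via
  `statsmodels.stats.multitest`.
* Log-scale correlation pseudocount: 0.5 CPM.
* Truncated-normal lengths sampled on half-integer-widened bounds and
  rounded, so integer lengths include both gate boundaries.
* Seeds: every stochastic function takes an explicit seed; multi-donor
  simulation spawns per-donor child streams from one `SeedSequence`, so
  per-donor output is independent of donor order.
* Degenerate inputs fail loudly: empty sequences, CPM of an empty set,
  zero-fragment donors, unstranded input to strand-aware operations, and
  intervals longer than their contig all raise with context; empty fragment
  sets entering the peak caller return an empty peak set (logged) because an
  empty library is data, not a programming error.

## Problem sizes used in validation

The standard benchmark is a 2 Mb single-contig genome with 100 planted
motif/peak pairs and 5 donors × 2×10^5 fragments; null calibration uses 20
pure-background replicates (1 Mb, 5×10^4 fragments) and 500 random-vs-random
permutation trials (n_perm = 199). The full test suite runs in well under a
minute on one CPU; `scripts/acceptance.py` re-runs everything from scratch in
under a minute.

## Known limitations

* The caller tests fragment 5'-start clustering; protocols whose information
  is in fragment midpoints would need a different statistic.
* Local-lambda windows are not clipped at contig edges (rates there are
  slightly deflated, which is conservative).
* `min_overlap > 1` falls back to a slower exact path in the permutation
  machinery.
* Merged peaks spanning both strands are excluded from strand-aware
  colocalization (they are reported with the compound strand label).
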