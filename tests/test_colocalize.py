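"""Overlap counting vs brute force, permutation test, enrichment, annotation,
aggregation profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from c3dscan import (
    FeatureSet,
    FragmentSet,
    GenomeModel,
    aggregate_profile,
    annotate_peaks,
    enrichment_fold,
    overlap_counts,
    permutation_test,
    read_bed,
    read_gene_models,
)
from c3dscan.colocalize import GeneModel, colocalization_report
from c3dscan.genome import Contig

from oracles import brute_overlap_hits


def fset(rows, stranded=True, name="x"):
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "strand"])
    return FeatureSet(name, df, stranded=stranded)


@pytest.fixture(scope="module")
def genome():
    return GenomeModel([Contig("chr1", "ACGT" * 25_000), Contig("chr2", "ACGT" * 12_500)])


# ------------------------------------------------------------------- overlap

def test_overlap_identity_and_disjoint():
    a = fset([("chr1", 100, 200, "+"), ("chr1", 400, 500, "-")])
    oc = overlap_counts(a, a, strand_mode="same")
    assert (oc.n_A_hit, oc.n_B_hit, oc.n_A_only, oc.n_B_only) == (2, 2, 0, 0)
    b = fset([("chr1", 1000, 1100, "+")])
    oc = overlap_counts(a, b)
    assert oc.n_A_hit == 0 and oc.n_B_hit == 0


def test_strand_modes():
    a = fset([("chr1", 100, 200, "+")])
    b = fset([("chr1", 100, 200, "-")])
    assert overlap_counts(a, b, strand_mode="opposite").n_A_hit == 1
    assert overlap_counts(a, b, strand_mode="same").n_A_hit == 0
    assert overlap_counts(a, b, strand_mode="ignore").n_A_hit == 1


def test_strand_mode_requires_strands():
    a = fset([("chr1", 100, 200, "+")])
    b = FeatureSet("u", pd.DataFrame([("chr1", 0, 300)], columns=["contig", "start", "end"]))
    with pytest.raises(ValueError):
        overlap_counts(a, b, strand_mode="same")


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.data())
def test_overlap_matches_brute_force(data):
    def rand_rows(n):
        return [
            (
                data.draw(st.sampled_from(["chr1", "chr2"])),
                s := data.draw(st.integers(0, 900)),
                s + data.draw(st.integers(1, 150)),
                data.draw(st.sampled_from("+-")),
            )
            for _ in range(n)
        ]

    # FeatureSet sorts its rows, so sort the oracle's inputs the same way
    a_rows = sorted(rand_rows(data.draw(st.integers(1, 12))))
    b_rows = sorted(rand_rows(data.draw(st.integers(0, 12))))
    mode = data.draw(st.sampled_from(["ignore", "same", "opposite"]))
    ov = data.draw(st.sampled_from([1, 5, 30]))
    a, b = fset(a_rows), fset(b_rows)
    oc = overlap_counts(a, b, strand_mode=mode, min_overlap=ov)
    assert list(oc.a_hits) == brute_overlap_hits(a_rows, b_rows, mode, ov)
    assert list(oc.b_hits) == brute_overlap_hits(b_rows, a_rows, mode, ov)


# --------------------------------------------------------------- permutation

def test_permutation_b_covers_genome(genome):
    a = fset([("chr1", 100, 200, "+"), ("chr2", 100, 200, "-")])
    b = FeatureSet("all", pd.DataFrame(
        [("chr1", 0, 100_000), ("chr2", 0, 50_000)], columns=["contig", "start", "end"]))
    res = permutation_test(a, b, genome, n_perm=99, seed=1)
    assert res.observed == 2 and res.p == 1.0


def test_permutation_empty_b(genome):
    a = fset([("chr1", 100, 200, "+")])
    b = FeatureSet("none", pd.DataFrame(columns=["contig", "start", "end"]))
    res = permutation_test(a, b, genome, n_perm=99, seed=1)
    assert res.observed == 0 and res.p == 1.0 and np.isnan(res.z)


def test_permutation_detects_real_colocalization(genome):
    rng = np.random.default_rng(8)
    pos = rng.integers(0, 99_000, size=30)
    a = fset([("chr1", int(p), int(p) + 100, "+") for p in pos])
    b = fset([("chr1", int(p) - 20, int(p) + 120, "+") for p in pos])
    res = permutation_test(a, b, genome, n_perm=199, seed=3)
    assert res.p <= 0.01 and res.z > 3


def test_permutation_deterministic_and_contig_relabel_invariant(genome):
    a = fset([("chr1", 100, 200, "+")] * 5)
    b = fset([("chr1", 5000, 6000, "+")] * 3)
    r1 = permutation_test(a, b, genome, n_perm=99, seed=7)
    r2 = permutation_test(a, b, genome, n_perm=99, seed=7)
    assert (r1.p, r1.z, list((r1.observed,))) == (r2.p, r2.z, [r2.observed])
    # relabel the contig everywhere: p must be identical (same RNG consumption)
    g2 = GenomeModel([Contig("X", genome.sequence("chr1")), Contig("chr2", genome.sequence("chr2"))])
    a2 = fset([("X", 100, 200, "+")] * 5)
    b2 = fset([("X", 5000, 6000, "+")] * 3)
    r3 = permutation_test(a2, b2, g2, n_perm=99, seed=7)
    assert r3.p == r1.p


def test_permutation_interval_longer_than_contig_rejected(genome):
    a = fset([("chr2", 0, 60_000, "+")])
    with pytest.raises(ValueError):
        permutation_test(a, a, genome, n_perm=19, seed=0)


# ---------------------------------------------------------------- enrichment

def test_enrichment_constructed_case(genome):
    """Feature spanning 10% of the genome, 36 of 100 midpoints inside -> fold 3.6."""
    gbp = genome.total_length
    feat = FeatureSet("f", pd.DataFrame(
        [("chr1", 0, gbp // 10)], columns=["contig", "start", "end"]))
    inside = [("chr1", 100 + i * 10, 120 + i * 10, "+") for i in range(36)]
    outside = [("chr1", 50_000 + i * 100, 50_020 + i * 100, "+") for i in range(64)]
    peaks = fset(inside + outside)
    res = enrichment_fold(peaks, feat, genome)
    assert res.observed_fraction == pytest.approx(0.36)
    assert res.expected_fraction == pytest.approx(0.10)
    assert res.fold == pytest.approx(3.6)


def test_enrichment_uniform_placement_near_one(genome):
    rng = np.random.default_rng(12)
    rows = []
    for _ in range(10_000):
        contig = "chr1" if rng.random() < 2 / 3 else "chr2"  # proportional to length
        L = genome.lengths[contig]
        s = int(rng.integers(0, L - 20))
        rows.append((contig, s, s + 20, "+"))
    peaks = fset(rows)
    feat = FeatureSet("f", pd.DataFrame(
        [("chr1", 20_000, 30_000)], columns=["contig", "start", "end"]))
    res = enrichment_fold(peaks, feat, genome)
    assert res.fold == pytest.approx(1.0, abs=0.1)


def test_enrichment_fold_zero_and_genome_feature(genome):
    peaks = fset([("chr1", 50_000, 50_100, "+")] * 10)
    whole = FeatureSet("g", pd.DataFrame(
        [("chr1", 0, 100_000), ("chr2", 0, 50_000)], columns=["contig", "start", "end"]))
    assert enrichment_fold(peaks, whole, genome).fold == pytest.approx(1.0)
    feat = FeatureSet("f", pd.DataFrame([("chr2", 0, 1000)], columns=["contig", "start", "end"]))
    assert enrichment_fold(peaks, feat, genome).fold == 0.0


def test_colocalization_report_bh(genome):
    peaks = fset([("chr1", i * 1000, i * 1000 + 100, "+") for i in range(20)])
    feats = [
        FeatureSet("hit", pd.DataFrame([("chr1", 0, 25_000)], columns=["contig", "start", "end"])),
        FeatureSet("miss", pd.DataFrame([("chr2", 0, 1000)], columns=["contig", "start", "end"])),
    ]
    rep = colocalization_report(peaks, feats, genome, n_perm=49, seed=5)
    assert set(rep["feature"]) == {"hit", "miss"}
    assert "q" in rep.columns and (rep["q"] >= rep["p"] - 1e-12).all()


# ---------------------------------------------------------------- annotation

@pytest.fixture()
def gene_models():
    # one + gene: tx [2000,5000), CDS [2500,4500), exons [2000,3000)+[4000,5000)
    plus = GeneModel("gA", "chr1", "+", 2000, 5000, 2500, 4500, [(2000, 3000), (4000, 5000)])
    minus = GeneModel("gB", "chr1", "-", 20_000, 24_000, 20_500, 23_500,
                      [(20_000, 21_000), (23_000, 24_000)])
    return [plus, minus]


def peaks_at(midpoints):
    return fset([("chr1", m - 10, m + 10, "+") for m in midpoints])


def test_annotation_priority_labels(gene_models):
    ann, props = annotate_peaks(peaks_at([1700, 2200, 2700, 3500, 4700, 5500, 60_000]),
                                gene_models)
    assert list(ann["label"]) == [
        "promoter",    # 300 bp upstream of + TSS
        "5utr",        # exonic, before CDS start
        "exon",        # CDS exon
        "intron",      # between exons
        "3utr",        # exonic, after CDS end
        "tts",         # within [TES-100, TES+1000)
        "intergenic",
    ]
    assert props.sum() == pytest.approx(1.0)


def test_annotation_minus_strand_promoter(gene_models):
    # promoter of the minus-strand gene sits right of its genomic end
    # (rows come back sorted by coordinate: 19,950 first, then 24,500)
    ann, _ = annotate_peaks(peaks_at([24_500, 19_950]), gene_models)
    assert list(ann["label"]) == ["tts", "promoter"]


def test_cpg_islands_and_shores(gene_models):
    cpg = FeatureSet("cpg", pd.DataFrame(
        [("chr1", 40_000, 41_000)], columns=["contig", "start", "end"]))
    # sorted row order: 39,500 / 40,500 / 41,500 / 44,000
    ann, _ = annotate_peaks(peaks_at([40_500, 39_500, 41_500, 44_000]), gene_models, cpg=cpg)
    assert list(ann["cpg"]) == ["shore", "island", "shore", "none"]


def test_gene_model_readers(tmp_path):
    bed12 = tmp_path / "genes.bed"
    bed12.write_text(
        "chr1\t2000\t5000\tgA\t0\t+\t2500\t4500\t0\t2\t1000,1000\t0,2000\n"
    )
    genes = read_gene_models(bed12)
    g = genes[0]
    assert (g.tx_start, g.tx_end, g.cds_start, g.cds_end) == (2000, 5000, 2500, 4500)
    assert g.exons == [(2000, 3000), (4000, 5000)]

    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t2001\t5000\t.\t+\t.\tID=geneA\n"
        "chr1\tsrc\tmRNA\t2001\t5000\t.\t+\t.\tID=txA;Parent=geneA\n"
        "chr1\tsrc\texon\t2001\t3000\t.\t+\t.\tID=e1;Parent=txA\n"
        "chr1\tsrc\texon\t4001\t5000\t.\t+\t.\tID=e2;Parent=txA\n"
        "chr1\tsrc\tCDS\t2501\t3000\t.\t+\t0\tID=c1;Parent=txA\n"
        "chr1\tsrc\tCDS\t4001\t4500\t.\t+\t0\tID=c2;Parent=txA\n"
    )
    g2 = read_gene_models(gff)[0]
    assert (g2.tx_start, g2.tx_end, g2.cds_start, g2.cds_end) == (2000, 5000, 2500, 4500)
    assert g2.exons == [(2000, 3000), (4000, 5000)]


def test_missing_strand_gene_rejected(tmp_path):
    bed12 = tmp_path / "genes.bed"
    bed12.write_text("chr1\t2000\t5000\tgA\t0\t.\t2500\t4500\t0\t1\t3000\t0\n")
    with pytest.raises(ValueError, match="strand"):
        read_gene_models(bed12)


# ---------------------------------------------------------------- aggregation

def _frag_df(rows):
    return FragmentSet(pd.DataFrame(rows, columns=["contig", "start", "end", "strand", "donor"]))


def test_aggregate_uniform_coverage_flat(genome):
    # tile chr1 completely at 1x
    rows = [("chr1", s, s + 100, "+", "d") for s in range(0, 100_000, 100)]
    fs = _frag_df(rows)
    regions = fset([("chr1", 50_000, 50_100, "+"), ("chr1", 20_000, 20_100, "-")])
    agg = aggregate_profile(fs, regions, genome, flank=1000, bins=20, normalization="raw")
    np.testing.assert_allclose(agg.matrix, 1.0)


def test_aggregate_delta_peaks_central_bin(genome):
    anchors = [10_000, 30_000, 70_000]
    rows = [("chr1", a, a + 1, "+", "d") for a in anchors for _ in range(5)]
    fs = _frag_df(rows)
    regions = fset([("chr1", a - 50, a + 50, "+") for a in anchors])
    agg = aggregate_profile(fs, regions, genome, flank=500, bins=100, normalization="raw")
    prof = agg.mean_profile
    assert np.argmax(prof) == 50  # anchor (midpoint) falls in the central bin
    assert prof.sum() * (1000 / 100) == pytest.approx(5.0 * 1, rel=1e-6)  # mass conserved


def test_aggregate_strand_mirror(genome):
    rows = [("chr1", 10_000, 10_200, "+", "d")] * 3
    fs = _frag_df(rows)
    plus = fset([("chr1", 9_900, 10_100, "+")])
    minus = fset([("chr1", 9_900, 10_100, "-")])
    a = aggregate_profile(fs, plus, genome, flank=300, bins=30, normalization="raw")
    b = aggregate_profile(fs, minus, genome, flank=300, bins=30, normalization="raw")
    np.testing.assert_allclose(a.matrix[0], b.matrix[0][::-1])


def test_aggregate_scale_regions_shape(genome):
    rows = [("chr1", 10_000, 10_500, "+", "d")] * 2
    fs = _frag_df(rows)
    regions = fset([("chr1", 10_000, 10_500, "+"), ("chr1", 40_000, 40_250, "-")])
    agg = aggregate_profile(fs, regions, genome, mode="scale-regions",
                            flank=200, bins=40, flank_bins=10, normalization="raw")
    assert agg.matrix.shape == (2, 60)
    # first region is fully covered across its body
    np.testing.assert_allclose(agg.matrix[0][10:50], 2.0)


def test_aggregate_empty_regions_rejected(genome):
    fs = _frag_df([("chr1", 0, 50, "+", "d")])
    empty = FeatureSet("e", pd.DataFrame(columns=["contig", "start", "end"]))
    with pytest.raises(ValueError):
        aggregate_profile(fs, empty, genome)
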