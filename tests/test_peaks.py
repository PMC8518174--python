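"""Peak caller recovery/calibration, merging, donor sharing, correlations."""

import numpy as np
import pandas as pd
import pytest

from c3dscan import (
    FragmentSet,
    GenomeModel,
    PeakCallConfig,
    PeakSet,
    call_peaks_stranded,
    donor_correlation,
    donor_location_test,
    donor_sharing,
    merge_peak_sets,
    normalized_peak_coverage,
    simulate_donor_intensities,
    split_by_class,
    split_reads_on_off,
)
from c3dscan.colocalize import FeatureSet, overlap_counts
from c3dscan.genome import Contig
from c3dscan.peaks import empty_peak_set


def _fs(rows):
    return FragmentSet(pd.DataFrame(rows, columns=["contig", "start", "end", "strand", "donor"]))


def _peaks(rows):
    return PeakSet(pd.DataFrame(rows, columns=["contig", "start", "end", "strand"]))


def _uniform_fragments(rng, n, L, contig="chr1", donor="d"):
    starts = rng.integers(0, L - 50, size=n)
    strands = np.where(rng.integers(0, 2, size=n) == 1, "+", "-")
    return FragmentSet(pd.DataFrame({
        "contig": contig, "start": starts, "end": starts + 50,
        "strand": strands, "donor": donor,
    }))


def test_empty_input_empty_peaks():
    genome = GenomeModel([Contig("chr1", "A" * 2000)])
    ps = call_peaks_stranded(_fs([]), genome)
    assert len(ps) == 0


def test_single_fragment_not_significant():
    genome = GenomeModel([Contig("chr1", "ACGT" * 500_000)])  # 2 Mb
    ps = call_peaks_stranded(_fs([("chr1", 1000, 1050, "+", "d")]), genome)
    assert len(ps) == 0


def test_planted_pile_recovered_on_correct_strand():
    """A 20x pile over uniform background yields exactly one peak, at the pile."""
    rng = np.random.default_rng(17)
    L = 2_000_000
    genome = GenomeModel([Contig("chr1", "ACGT" * (L // 4))])
    bg = _uniform_fragments(rng, 20_000, L)
    pile_starts = rng.integers(500_000, 500_060, size=200)
    pile = FragmentSet(pd.DataFrame({
        "contig": "chr1", "start": pile_starts, "end": pile_starts + 50,
        "strand": "-", "donor": "d",
    }))
    ps = call_peaks_stranded(bg.concat(pile), genome)
    assert len(ps) == 1
    r = ps.df.iloc[0]
    assert r["strand"] == "-"
    # the peak covers the dense core of the pile (starts 500,000-500,060 + 50 nt)
    assert r["start"] <= 500_020 and r["end"] >= 500_090
    assert 499_900 <= r["start"] and r["end"] <= 500_200
    assert r["start"] <= r["summit"] < r["end"]
    assert r["q_value"] <= 1


def test_no_peaks_on_pure_background():
    rng = np.random.default_rng(99)
    genome = GenomeModel([Contig("chr1", "ACGT" * 250_000)])  # 1 Mb
    ps = call_peaks_stranded(_uniform_fragments(rng, 50_000, 1_000_000), genome)
    assert len(ps) <= 1


def test_strand_fidelity_never_crosses():
    """A pile entirely on '-' fragments never produces a '+' peak."""
    rng = np.random.default_rng(4)
    L = 500_000
    genome = GenomeModel([Contig("chr1", "ACGT" * (L // 4))])
    starts = rng.integers(100_000, 100_050, size=300)
    pile = FragmentSet(pd.DataFrame({
        "contig": "chr1", "start": starts, "end": starts + 50,
        "strand": "-", "donor": "d",
    }))
    ps = call_peaks_stranded(pile, genome)
    assert len(ps) >= 1
    assert set(ps.df["strand"]) == {"-"}


# ------------------------------------------------------------------- merging

def test_merge_union_and_multiplicity():
    a = _peaks([("chr1", 100, 200, "+")])
    b = _peaks([("chr1", 150, 250, "-")])
    merged = merge_peak_sets([a, b], labels=["d1", "d2"])
    assert len(merged) == 1
    r = merged.df.iloc[0]
    assert (r["start"], r["end"]) == (100, 250)
    assert r["strand"] == "+,-"
    assert r["n_sources"] == 2

    same = merge_peak_sets([a, a], labels=["x", "y"])
    assert len(same) == 1 and same.df.iloc[0]["n_sources"] == 2
    assert len(merge_peak_sets([])) == 0


def test_merge_idempotent_and_order_invariant():
    a = _peaks([("chr1", 100, 200, "+"), ("chr1", 500, 600, "-"), ("chr2", 10, 80, "+")])
    b = _peaks([("chr1", 180, 260, "+")])
    m1 = merge_peak_sets([a, b]).df[["contig", "start", "end"]]
    m2 = merge_peak_sets([b, a]).df[["contig", "start", "end"]]
    pd.testing.assert_frame_equal(m1, m2)
    again = merge_peak_sets([PeakSet(merge_peak_sets([a, b]).df)]).df[["contig", "start", "end"]]
    pd.testing.assert_frame_equal(m1, again)


# -------------------------------------------------------------- donor sharing

def test_donor_sharing_labels():
    d1 = _peaks([("chr1", 100, 200, "+"), ("chr1", 900, 950, "+")])
    d2 = _peaks([("chr1", 150, 250, "+")])
    d3 = _peaks([("chr1", 5000, 5100, "-")])
    table, counts = donor_sharing({"d1": d1, "d2": d2, "d3": d3})
    lab = table.set_index(["donor", "start"])["label"]
    assert lab[("d1", 100)] == "shared"      # overlaps d2
    assert lab[("d2", 150)] == "shared"
    assert lab[("d1", 900)] == "specific"
    assert lab[("d3", 5000)] == "specific"   # only donor 3
    assert counts.set_index("donor").loc["d1", "shared"] == 1


def test_identical_donors_fully_shared():
    p = _peaks([("chr1", 0, 100, "+"), ("chr1", 500, 600, "-")])
    table, _ = donor_sharing({f"d{i}": p for i in range(5)})
    assert (table["label"] == "shared").all()


def test_single_donor_rejected():
    with pytest.raises(ValueError):
        donor_sharing({"d1": _peaks([("chr1", 0, 10, "+")])})


# -------------------------------------------------- coverage matrix / correlation

def test_normalized_peak_coverage_cpm():
    peaks = _peaks([("chr1", 100, 200, "+")])
    frags = {"d1": _fs([("chr1", 150, 190, "+", "d1")] * 10
                       + [("chr1", 5000, 5050, "+", "d1")] * 10)}
    # pad library to a known total
    pad = _fs([("chr1", 9000, 9050, "+", "d1")] * 80)
    frags["d1"] = FragmentSet(pd.concat([frags["d1"].df, pad.df], ignore_index=True))
    mat = normalized_peak_coverage(peaks, frags)
    assert mat.iloc[0, 0] == pytest.approx(10 * 1e6 / 100)
    doubled = {"d1": FragmentSet(pd.concat([frags["d1"].df] * 2, ignore_index=True))}
    mat2 = normalized_peak_coverage(peaks, doubled)
    assert mat2.iloc[0, 0] == pytest.approx(mat.iloc[0, 0])


def test_zero_fragment_donor_rejected():
    with pytest.raises(ValueError):
        normalized_peak_coverage(_peaks([("chr1", 0, 10, "+")]), {"d": _fs([])})


def test_donor_correlation_closed_cases():
    m = pd.DataFrame({"a": [1.0, 10.0, 100.0], "b": [1.0, 10.0, 100.0]})
    assert donor_correlation(m).r.loc["a", "b"] == pytest.approx(1.0)
    m2 = pd.DataFrame({"a": [1.0, 10.0, 100.0], "b": [2.0, 20.0, 200.0]})
    # scaling is additive in log space => still perfectly correlated
    assert donor_correlation(m2, pseudocount=0).r.loc["a", "b"] == pytest.approx(1.0)
    const = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
    dc = donor_correlation(const)
    assert dc.undefined == ["a"]


def test_latent_correlation_recovered():
    mat = simulate_donor_intensities(2000, 5, latent_corr=0.9, seed=21)
    dc = donor_correlation(mat, pseudocount=0.0)
    assert np.mean(dc.pairwise_values) == pytest.approx(0.90, abs=0.05)


def test_rank_sum_location_test_symmetric():
    mat = simulate_donor_intensities(500, 3, latent_corr=0.9, seed=2)
    p = donor_location_test(mat)
    assert np.allclose(p.to_numpy(), p.to_numpy().T)
    assert (p.to_numpy() > 0).all()


# ---------------------------------------------------------------- on/off split

def test_split_on_off_partitions():
    peaks = _peaks([("chr1", 100, 200, "+")])
    inside = _fs([("chr1", 120, 170, "+", "d")] * 3)
    outside = _fs([("chr1", 5000, 5050, "+", "d")] * 7)
    both = inside.concat(outside)
    on, off, frac = split_reads_on_off(both, peaks)
    assert len(on) == 3 and len(off) == 7 and frac == pytest.approx(0.3)
    on2, off2, f2 = split_reads_on_off(inside, peaks)
    assert len(off2) == 0 and f2 == 1.0
    on3, off3, f3 = split_reads_on_off(outside, peaks)
    assert len(on3) == 0 and f3 == 0.0
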