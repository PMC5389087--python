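"""Landmark construction, random placement, permutation enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from sdscape import (build_landmarks, empirical_enrichment,
                     gene_family_enrichment, overlap_statistic,
                     random_placement)
from sdscape.enrich_perm import empirical_p_value
from sdscape.errors import (InvalidSpecError, PlacementError,
                            UndefinedResultError)
from sdscape import intervals as iv

from _oracles import bitmap_overlap


def test_landmark_arithmetic_2mb_flanks():
    sub, peri = build_landmarks({"chr1": 50_000_000},
                                {"chr1": 20_000_000})
    assert sub.intervals.values.tolist() == [
        ["chr1", 0, 2_000_000], ["chr1", 48_000_000, 50_000_000]]
    assert peri.intervals.values.tolist() == [
        ["chr1", 18_000_000, 22_000_000]]


def test_landmark_short_chromosome_flank():
    sub, peri = build_landmarks(
        {"mic1": 1_000_000}, {"mic1": 500_000}, short_chroms=["mic1"])
    assert sub.intervals.values.tolist() == [
        ["mic1", 0, 300_000], ["mic1", 700_000, 1_000_000]]
    assert peri.intervals.values.tolist() == [
        ["mic1", 200_000, 800_000]]


def test_landmark_clipping_covers_small_chromosome():
    sub, peri = build_landmarks({"chr1": 3_000_000}, {"chr1": 1_500_000})
    # 2 Mb flanks swallow the whole 3 Mb chromosome after clipping/merging
    assert sub.intervals.values.tolist() == [["chr1", 0, 3_000_000]]
    assert peri.intervals.values.tolist() == [["chr1", 0, 3_000_000]]


def test_landmark_missing_centromere_warns():
    with pytest.warns(UserWarning):
        sub, peri = build_landmarks({"chr1": 10_000_000}, {})
    assert len(peri.intervals) == 0 and len(sub.intervals) == 2
    with pytest.raises(InvalidSpecError):
        build_landmarks({"chr1": 10_000_000}, {"chr1": 5_000_000}, flank=0)


def test_random_placement_contract(rng):
    regions = iv.to_frame([("chrA", 0, 1000)])
    lengths = {"chr1": 1_000_000}
    p1 = random_placement(regions, lengths, np.random.default_rng(42))
    p2 = random_placement(regions, lengths, np.random.default_rng(42))
    pd.testing.assert_frame_equal(p1, p2)
    assert p1.iloc[0]["end"] - p1.iloc[0]["start"] == 1000
    assert 0 <= p1.iloc[0]["start"] <= 999_000


def test_random_placement_pigeonhole_failure(rng):
    regions = iv.to_frame([("q", 0, 99_900)] )
    with pytest.raises(PlacementError):
        random_placement(iv.to_frame([("q", 0, 40_000), ("q", 0, 40_000),
                                      ("q", 0, 40_000)]),
                         {"chr1": 100_000}, rng, max_tries=50)


def test_random_placement_uniform_starts():
    rng = np.random.default_rng(7)
    lengths = {"chr1": 1_000_000}
    region = iv.to_frame([("q", 0, 10_000)])
    starts = [int(random_placement(region, lengths, rng).iloc[0]["start"])
              for _ in range(1000)]
    counts, _ = np.histogram(starts, bins=10, range=(0, 990_001))
    chi2 = ((counts - 100.0) ** 2 / 100.0).sum()
    assert chi2 < sstats.chi2.ppf(0.99, df=9)


def test_overlap_statistic_hand_example():
    landmarks = iv.to_frame([("chr1", 0, 100), ("chr1", 200, 300)])
    regions = iv.to_frame([("chr1", 50, 250)])
    assert overlap_statistic(regions, landmarks, "count") == 2
    assert overlap_statistic(regions, landmarks, "length") == 100
    empty = iv.to_frame([("chr1", 400, 500)])
    assert overlap_statistic(empty, landmarks, "count") == 0
    assert overlap_statistic(empty, landmarks, "length") == 0


def test_overlap_statistic_matches_bitmap_oracle(rng):
    lengths = {"chr1": 300_000, "chr2": 200_000}
    def rand_ivs(n):
        rows = []
        for _ in range(n):
            c = "chr1" if rng.random() < 0.6 else "chr2"
            s = int(rng.integers(0, lengths[c] - 2000))
            rows.append((c, s, s + int(rng.integers(50, 2000))))
        return iv.to_frame(rows)
    regions = rand_ivs(500)
    landmarks = rand_ivs(500)
    lm_merged = iv.merge(landmarks)
    assert overlap_statistic(regions, lm_merged, "length") == \
        bitmap_overlap(regions, lm_merged, lengths, "length")
    assert overlap_statistic(regions, lm_merged, "count") == \
        bitmap_overlap(regions, lm_merged, lengths, "count")


def test_empirical_p_value_monotone():
    null = np.array([1.0, 5.0, 5.0, 9.0, 12.0])
    ps = [empirical_p_value(null, o) for o in (0, 1, 5, 9, 12, 13)]
    assert ps == sorted(ps, reverse=True)
    assert ps[0] == 1.0 and ps[-1] == 1 / 6
    assert all(p > 0 for p in ps)


def test_replicates_preserve_lengths_and_disjointness():
    lengths = {"chr1": 500_000}
    regions = iv.to_frame([("chr1", 0, 5000), ("chr1", 10_000, 18_000),
                           ("chr1", 30_000, 31_000)])
    # check_replicates=True asserts disjointness/lengths per replicate
    res = empirical_enrichment(regions,
                               iv.to_frame([("chr1", 100_000, 150_000)]),
                               mode="length", n_replicates=100, seed=3,
                               chrom_lengths=lengths, check_replicates=True)
    assert res.n_replicates == 100


def test_fold_near_one_under_independence():
    # a single draw of few regions is noisy (a region hits a landmark or
    # not); the unbiasedness shows in the mean fold over independent draws
    rng = np.random.default_rng(11)
    lengths = {"chr1": 2_000_000}
    landmarks = iv.to_frame([("chr1", s, s + 20_000)
                             for s in range(0, 2_000_000, 200_000)])
    folds = []
    for t in range(20):
        regions = random_placement(
            iv.to_frame([("q", 0, 5000)] * 15), lengths, rng)
        res = empirical_enrichment(regions, landmarks, mode="length",
                                   n_replicates=200, seed=100 + t,
                                   chrom_lengths=lengths,
                                   check_replicates=False)
        folds.append(res.fold)
    assert 0.8 <= float(np.mean(folds)) <= 1.2


def test_planted_inside_landmarks_is_extreme():
    lengths = {"chr1": 2_000_000}
    landmarks = iv.to_frame([("chr1", s, s + 20_000)
                             for s in range(0, 2_000_000, 200_000)])
    # regions constructed fully inside the landmarks (10% of the genome)
    regions = iv.to_frame([("chr1", s + 2000, s + 4000)
                           for s in range(0, 2_000_000, 200_000)])
    res = empirical_enrichment(regions, landmarks, mode="length",
                               n_replicates=500, seed=9,
                               chrom_lengths=lengths,
                               check_replicates=False)
    assert res.fold >= 5.0
    assert res.empirical_p == pytest.approx(1 / 501)
    assert res.depletion_p > 0.99


def test_gene_family_enrichment_power_and_symmetry():
    rng = np.random.default_rng(23)
    lengths = {"chr1": 2_000_000}
    sd_map = iv.to_frame([("chr1", s, s + 20_000)
                          for s in range(0, 2_000_000, 200_000)])
    # family genes planted inside SDs far above the 10% background rate
    fam = iv.to_frame([("chr1", s + 1000, s + 3000)
                       for s in range(0, 2_000_000, 200_000)])
    res = gene_family_enrichment(sd_map, fam, mode="number",
                                 n_replicates=1000, seed=2,
                                 chrom_lengths=lengths)
    assert res.fold > 2.0
    assert res.empirical_p <= 0.01
    # family and non-family genes placed identically -> mean fold near 1
    # and identical for the two labels (symmetry)
    folds, contrast = [], []
    for t in range(10):
        uni = random_placement(iv.to_frame([("q", 0, 2000)] * 20),
                               lengths, rng)
        res2 = gene_family_enrichment(sd_map, uni, nonfamily_genes=uni,
                                      mode="length", n_replicates=200,
                                      seed=40 + t, chrom_lengths=lengths)
        folds.append(res2.fold)
        contrast.append(res2.extra["nonfamily_fold"])
    assert 0.7 <= float(np.mean(folds)) <= 1.3
    with pytest.raises(UndefinedResultError):
        gene_family_enrichment(sd_map, iv.to_frame([]),
                               chrom_lengths=lengths)


def test_minimum_replicates_enforced():
    with pytest.raises(InvalidSpecError):
        empirical_enrichment(iv.to_frame([("chr1", 0, 100)]),
                             iv.to_frame([("chr1", 0, 100)]),
                             n_replicates=10, seed=1,
                             chrom_lengths={"chr1": 10_000})
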