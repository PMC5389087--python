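"""Self-alignment detection, repeat excision, and high-copy cleaning."""

import numpy as np
import pytest

from sdscape import (AlignmentSet, DuplicationEvent, GenomeSpec,
                     PairwiseAlignment, filter_high_copy, generate_reference,
                     identity_histogram, mask_and_excise,
                     plant_duplications, self_align)
from sdscape.errors import InvalidSpecError, LiftoverError
from sdscape import intervals as iv
from sdscape.seqio import revcomp


def _mk_genome(length=60_000, seed=5, chroms=1):
    spec = GenomeSpec({f"chr{i+1}": length for i in range(chroms)},
                      seed=seed)
    return generate_reference(spec)


# ---------------------------------------------------------------------------
# mask_and_excise


def test_excision_coordinates_round_trip():
    g = {"chr1": np.zeros(1000, dtype=np.uint8)}
    rep = iv.to_frame([("chr1", 100, 200)])
    condensed, cmap = mask_and_excise(g, rep)
    assert len(condensed["chr1"]) == 900
    assert cmap.to_original("chr1", 250) == 350
    assert cmap.to_condensed("chr1", 350) == 250
    # non-repeat positions round-trip to themselves
    for pos in (0, 99, 500):
        assert cmap.to_original("chr1", cmap.to_condensed("chr1", pos)) == pos
    with pytest.raises(LiftoverError):
        cmap.to_condensed("chr1", 150)


def test_excision_empty_and_overlapping_bed():
    g = _mk_genome(20_000)
    condensed, _ = mask_and_excise(g, iv.to_frame([]))
    assert np.array_equal(condensed["chr1"], g["chr1"])
    with pytest.warns(UserWarning):
        condensed, _ = mask_and_excise(
            g, iv.to_frame([("chr1", 10, 100), ("chr1", 50, 150)]))
    assert len(condensed["chr1"]) == 20_000 - 140


# ---------------------------------------------------------------------------
# self_align


def test_exact_pair_detected_with_full_length():
    g = _mk_genome(60_000, seed=5)
    ev = DuplicationEvent(("chr1", 5000, 6200), [("chr1", 40_000, 41_200)],
                          0.0)
    ref, _, _ = plant_duplications(g, [ev], seed=1)
    aln = self_align(ref)
    assert len(aln) == 1
    a = aln.alignments[0]
    assert a.identity >= 0.998
    assert a.aligned_length >= 0.95 * 1200
    assert abs(a.locus_a[1] - 5000) <= 50 and abs(a.locus_b[1] - 40_000) <= 50


def test_below_length_floor_not_reported():
    g = _mk_genome(60_000, seed=6)
    ev = DuplicationEvent(("chr1", 5000, 5800), [("chr1", 30_000, 30_800)],
                          0.0)
    ref, _, _ = plant_duplications(g, [ev], seed=1)
    assert len(self_align(ref)) == 0


def test_diverged_pair_identity_matches_mutation_log():
    g = _mk_genome(80_000, seed=7)
    ev = DuplicationEvent(("chr1", 5000, 15_000),
                          [("chr1", 50_000, 60_000)], 0.03)
    ref, _, truth = plant_duplications(g, [ev], seed=2)
    aln = self_align(ref)
    assert len(aln) == 1
    realized = truth.copy_records[0][0].realized_identity
    assert abs(aln.alignments[0].identity - realized) <= 0.01


def test_reverse_complement_symmetry():
    g = _mk_genome(40_000, seed=8, chroms=2)
    ev = DuplicationEvent(("chr1", 3000, 6000), [("chr2", 10_000, 13_000)],
                          0.02)
    ref, _, _ = plant_duplications(g, [ev], seed=3)
    fwd = self_align(ref)
    flipped = {c: revcomp(a) for c, a in ref.items()}
    rev = self_align(flipped)
    assert len(fwd) == len(rev) == 1

    def as_flipped(locus, lengths):
        c, s, e = locus
        return (c, lengths[c] - e, lengths[c] - s)

    lengths = {c: len(a) for c, a in ref.items()}
    f = fwd.alignments[0]
    r = rev.alignments[0]
    exp = sorted([as_flipped(f.locus_a, lengths),
                  as_flipped(f.locus_b, lengths)])
    got = sorted([r.locus_a, r.locus_b])
    for (ec, es, ee), (gc, gs, ge) in zip(exp, got):
        assert ec == gc and abs(es - gs) <= 50 and abs(ee - ge) <= 50
    assert f.strand == r.strand == "+"


def test_inverted_duplication_reported_on_minus_strand():
    g = _mk_genome(50_000, seed=12)
    src = g["chr1"][4000:7000].copy()
    ref = {"chr1": g["chr1"].copy()}
    ref["chr1"][30_000:33_000] = revcomp(src)
    aln = self_align(ref)
    assert len(aln) == 1
    assert aln.alignments[0].strand == "-"
    a = aln.alignments[0]
    assert abs(a.locus_a[1] - 4000) <= 50
    assert abs(a.locus_b[1] - 30_000) <= 50


def test_min_identity_monotonicity():
    g = _mk_genome(80_000, seed=9)
    evs = [
        DuplicationEvent(("chr1", 2000, 6000), [("chr1", 40_000, 44_000)],
                         0.02),
        DuplicationEvent(("chr1", 10_000, 14_000),
                         [("chr1", 60_000, 64_000)], 0.07),
    ]
    ref, _, _ = plant_duplications(g, evs, seed=4)
    n_90 = len(self_align(ref, min_identity=0.90))
    n_95 = len(self_align(ref, min_identity=0.95))
    n_99 = len(self_align(ref, min_identity=0.99))
    assert n_90 >= n_95 >= n_99
    assert n_90 == 2 and n_95 == 1


def test_short_genome_rejected():
    with pytest.raises(InvalidSpecError):
        self_align({"chr1": np.zeros(10, dtype=np.uint8)})
    g = _mk_genome(20_000)
    with pytest.raises(InvalidSpecError):
        self_align(g, k=25)


# ---------------------------------------------------------------------------
# filter_high_copy


def _family(chrom_positions, length=1500, ident=0.97):
    """Alignments linking the first locus to every other (star family)."""
    loci = [(c, p, p + length) for c, p in chrom_positions]
    return [
        PairwiseAlignment(loci[0], loc, "+", ident, length).canonical()
        for loc in loci[1:]
    ]


def test_high_copy_family_removed_entirely():
    fam = _family([("chr1", 10_000 * i) for i in range(60)])
    control = _family([("chr2", 900_000), ("chr2", 950_000)])
    aln = AlignmentSet(fam + control, stage="initial")
    cleaned = filter_high_copy(aln)
    assert len(cleaned) == 1
    assert cleaned.alignments[0].locus_a[0] == "chr2"
    assert cleaned.stage == "cleaned"


def test_three_chromosome_family_removed():
    fam = _family([("chr1", 1000), ("chr2", 1000), ("chr3", 1000)])
    aln = AlignmentSet(fam, stage="initial")
    assert len(filter_high_copy(aln)) == 0


def test_forty_nine_copies_on_one_chromosome_retained():
    fam = _family([("chr1", 10_000 * i) for i in range(49)])
    aln = AlignmentSet(fam, stage="initial")
    assert len(filter_high_copy(aln)) == len(fam)


def test_filter_idempotent_and_empty():
    fam = _family([("chr1", 1000), ("chr1", 50_000), ("chr2", 1000)])
    aln = AlignmentSet(fam, stage="initial")
    once = filter_high_copy(aln)
    twice = filter_high_copy(once)
    assert [a for a in once.alignments] == [a for a in twice.alignments]
    assert len(filter_high_copy(AlignmentSet([], stage="initial"))) == 0


def test_overlap_linkage_merges_copies():
    # two alignments share an overlapping locus -> one family of 3 copies
    a1 = PairwiseAlignment(("chr1", 0, 2000), ("chr1", 10_000, 12_000),
                          "+", 0.95, 2000)
    a2 = PairwiseAlignment(("chr1", 11_000, 13_000),
                           ("chr1", 30_000, 32_000), "+", 0.95, 2000)
    cleaned = filter_high_copy(AlignmentSet([a1, a2], stage="initial"),
                               max_copies=3)
    assert len(cleaned) == 0   # merged family has 3 distinct copies


# ---------------------------------------------------------------------------
# identity_histogram


def test_identity_histogram_binning():
    alns = [
        PairwiseAlignment(("chr1", 0, 1000), ("chr1", 5000, 6000), "+",
                          idt, 1000)
        for idt in (0.905, 0.915, 0.915, 1.0)
    ]
    h = identity_histogram(AlignmentSet(alns, stage="cleaned"))
    assert h[90] == 1 and h[91] == 2 and h[100] == 1
    assert h.sum() == 4
    assert identity_histogram(AlignmentSet([], stage="cleaned")).sum() == 0


def test_identity_histogram_modes_from_planted_cohort():
    g = _mk_genome(900_000, seed=10)
    evs = []
    pos = 2000
    for j in range(10):
        evs.append(DuplicationEvent(
            ("chr1", pos, pos + 3000), [("chr1", pos + 5000, pos + 8000)],
            0.02))
        pos += 12_000
    for j in range(10):
        evs.append(DuplicationEvent(
            ("chr1", pos, pos + 3000), [("chr1", pos + 5000, pos + 8000)],
            0.06))
        pos += 12_000
    ref, _, _ = plant_duplications(g, evs, seed=6)
    h = identity_histogram(filter_high_copy(self_align(ref)))
    assert h.sum() == 20
    # binomial jitter at n=3000 straddles adjacent 1-point bins
    assert h[97] + h[98] == 10
    assert h[93] + h[94] == 10
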