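"""Read placement, depth profiling, interval calling, copy number."""

import numpy as np
import pandas as pd
import pytest

from sdscape import (DuplicationEvent, GenomeSpec, ReadSet,
                     call_wssd_intervals, estimate_copy_number,
                     generate_reference, place_reads, plant_duplications,
                     profile_depth, simulate_reads)
from sdscape.errors import CalibrationError
from sdscape.wssd_depth import DepthProfile
from sdscape import intervals as iv


def _readset(genome, rows):
    """Build a ReadSet from explicit (chrom, start[, seq]) rows."""
    names = list(genome)
    chrom_idx, starts, seqs = [], [], []
    for row in rows:
        chrom, start = row[0], row[1]
        seq = row[2] if len(row) > 2 else genome[chrom][start:start + 36]
        chrom_idx.append(names.index(chrom))
        starts.append(start)
        seqs.append(seq)
    return ReadSet(36, float("nan"), names,
                   np.array(chrom_idx, np.int32),
                   np.array(starts, np.int64),
                   np.array(seqs, np.uint8))


@pytest.fixture(scope="module")
def unique_genome():
    return generate_reference(GenomeSpec({"chr1": 40_000, "chr2": 30_000},
                                         seed=17))


def test_unique_read_places_at_origin(unique_genome):
    rs = _readset(unique_genome, [("chr1", 1234), ("chr2", 8000)])
    pl = place_reads(rs, unique_genome)
    assert pl.n_unmapped == 0
    assert len(pl.pos) == 2
    got = sorted(zip(pl.chrom_idx.tolist(), pl.pos.tolist()))
    assert got == [(0, 1234), (1, 8000)]
    assert np.allclose(pl.weight, 1.0)


def test_read_from_donor_only_copy_maps_to_source():
    g = generate_reference(GenomeSpec({"chr1": 40_000}, seed=3))
    ev = DuplicationEvent(("chr1", 2000, 4000), [("chr1", 0, 2000)],
                          [0.0], in_reference=[False])
    ref, donor, truth = plant_duplications(g, [ev], seed=1)
    c, s, e = truth.copy_records[0][0].interval
    rs = _readset(donor, [("chr1", s + 100)])
    pl = place_reads(rs, ref)
    assert len(pl.pos) == 1
    assert pl.pos[0] == 2100   # the reference source locus


def test_read_with_three_mismatches_everywhere_dropped(unique_genome):
    seq = unique_genome["chr1"][500:536].copy()
    for p in (3, 17, 30):
        seq[p] = (seq[p] + 1) % 4
    pl = place_reads(_readset(unique_genome, [("chr1", 500, seq)]),
                     unique_genome)
    assert pl.n_unmapped == 1 and len(pl.pos) == 0


def test_multimapper_weight_split():
    g = generate_reference(GenomeSpec({"chr1": 40_000}, seed=4))
    ev = DuplicationEvent(("chr1", 2000, 4000), [("chr1", 20_000, 22_000)],
                          0.0)
    ref, _, _ = plant_duplications(g, [ev], seed=1)
    pl = place_reads(_readset(ref, [("chr1", 2500)]), ref)
    assert len(pl.pos) == 2
    assert np.allclose(pl.weight, 0.5)
    assert sorted(pl.pos.tolist()) == [2500, 20_500]


def test_depth_conservation_error_free(unique_genome):
    rs = simulate_reads(unique_genome, depth=5.0, error_rate=0.0, seed=9)
    pl = place_reads(rs, unique_genome)
    assert pl.n_unmapped == 0
    assert pl.weight.sum() == pytest.approx(rs.n_reads, rel=1e-6)
    assert pl.placed_bases <= rs.n_reads * 36 + 1e-6


def test_background_calibration_near_truth(unique_genome):
    rs = simulate_reads(unique_genome, depth=20.0, error_rate=0.005, seed=5)
    pl = place_reads(rs, unique_genome)
    prof = profile_depth(pl, unique_genome)
    assert abs(prof.background_mean - 20.0) <= 1.0
    assert prof.background_sd > 0
    assert len(call_wssd_intervals(prof)) == 0   # no flagged windows


def test_repeat_window_uncallable():
    g = generate_reference(GenomeSpec({"chr1": 40_000}, seed=6))
    rep = iv.to_frame([("chr1", 10_000, 16_000)])
    rs = simulate_reads(g, depth=8.0, error_rate=0.0, seed=2)
    prof = profile_depth(place_reads(rs, g), g, repeats=rep)
    # the window fully inside the masked repeat is flagged uncallable
    starts = prof.win_start["chr1"]
    inside = (starts >= 10_000) & (starts + 5000 <= 16_000)
    assert inside.any()
    assert not prof.win_callable["chr1"][inside].any()


def test_all_windows_uncallable_raises():
    g = generate_reference(GenomeSpec({"chr1": 12_000}, seed=6))
    rep = iv.to_frame([("chr1", 0, 12_000)])
    rs = simulate_reads(g, depth=2.0, error_rate=0.0, seed=2)
    with pytest.raises(CalibrationError):
        profile_depth(place_reads(rs, g), g, repeats=rep)


def test_calibration_robust_to_duplicated_fraction():
    # trimmed background moves <2% when ~5% of the genome is duplicated
    g = generate_reference(GenomeSpec({"chr1": 400_000}, seed=7))
    ev = DuplicationEvent(("chr1", 100_000, 120_000),
                          [("chr1", 0, 20_000)], [0.0],
                          in_reference=[False])
    ref, donor, _ = plant_duplications(g, [ev], seed=1)
    rs_u = simulate_reads(g, depth=15.0, error_rate=0.0, seed=3)
    rs_d = simulate_reads(donor, depth=15.0, error_rate=0.0, seed=3)
    bg_u = profile_depth(place_reads(rs_u, g), g).background_mean
    bg_d = profile_depth(place_reads(rs_d, ref), ref).background_mean
    assert abs(bg_d - bg_u) / bg_u < 0.02


def _synthetic_profile(depths, bg_mean, bg_sd, window=5000, slide=1000):
    n = len(depths)
    return DepthProfile(
        window=window, slide=slide, chrom_names=["chr1"],
        win_start={"chr1": np.arange(n) * slide},
        win_end={"chr1": np.arange(n) * slide + window},
        win_depth={"chr1": np.asarray(depths, float)},
        win_callable={"chr1": np.ones(n, bool)},
        base_depth={"chr1": np.repeat(np.asarray(depths, np.float32),
                                      slide)[: (n - 1) * slide + window]},
        base_callable={"chr1": np.ones((n - 1) * slide + window, bool)},
        background_mean=bg_mean, background_sd=bg_sd)


def test_copy_number_arithmetic():
    prof = _synthetic_profile([75.0] * 20, bg_mean=30.0, bg_sd=1.0)
    assert estimate_copy_number(("chr1", 0, 20_000), prof) == 5.0
    prof2 = _synthetic_profile([30.0] * 20, bg_mean=30.0, bg_sd=1.0)
    assert estimate_copy_number(("chr1", 0, 20_000), prof2) == 2.0
    prof2.background_mean = None
    with pytest.raises(CalibrationError):
        estimate_copy_number(("chr1", 0, 20_000), prof2)


def test_z_monotonicity_on_called_length(small_products):
    prof = small_products["profile"]
    lengths = []
    for z in (2.0, 3.0, 4.0, 6.0):
        calls = call_wssd_intervals(prof, z=z)
        lengths.append(int((calls["end"] - calls["start"]).sum())
                       if len(calls) else 0)
    assert all(a >= b for a, b in zip(lengths, lengths[1:]))


def test_six_kb_excess_region_not_called():
    g = generate_reference(GenomeSpec({"chr1": 200_000}, seed=8))
    ev = DuplicationEvent(("chr1", 60_000, 66_000),
                          [("chr1", 0, 6000)] * 3, [0.0] * 3,
                          in_reference=[False] * 3)
    ref, donor, _ = plant_duplications(g, [ev], seed=1)
    rs = simulate_reads(donor, depth=20.0, error_rate=0.005, seed=4)
    prof = profile_depth(place_reads(rs, ref), ref,
                         exclude=iv.to_frame([("chr1", 60_000, 66_000)]))
    calls = call_wssd_intervals(prof, min_len=10_000)
    assert len(calls) == 0
    # the excess itself is real: a relaxed floor recovers it
    relaxed = call_wssd_intervals(prof, min_len=5000)
    assert len(relaxed) == 1
    assert relaxed.iloc[0]["start"] < 66_000 and relaxed.iloc[0]["end"] > 60_000


def test_fifteen_kb_triplicated_region_called(small_products):
    g = generate_reference(GenomeSpec({"chr1": 300_000}, seed=9))
    ev = DuplicationEvent(("chr1", 100_000, 115_000),
                          [("chr1", 0, 15_000)] * 2, [0.003] * 2,
                          in_reference=[False] * 2)
    ref, donor, _ = plant_duplications(g, [ev], seed=2)
    rs = simulate_reads(donor, depth=20.0, error_rate=0.005, seed=5)
    prof = profile_depth(place_reads(rs, ref), ref,
                         exclude=iv.to_frame([("chr1", 100_000, 115_000)]))
    calls = call_wssd_intervals(prof)
    assert len(calls) == 1
    c = calls.iloc[0]
    span = min(c["end"], 115_000) - max(c["start"], 100_000)
    assert c["end"] - c["start"] >= 10_000
    assert span >= 0.8 * 15_000
    # depth 3x background -> absolute copy number near 6
    assert abs(c["copy_number"] - 6.0) <= 1.0


def test_empty_reads_warns(unique_genome):
    rs = ReadSet(36, 0.0, list(unique_genome), np.empty(0, np.int32),
                 np.empty(0, np.int64), np.empty((0, 36), np.uint8))
    with pytest.warns(UserWarning):
        pl = place_reads(rs, unique_genome)
    assert len(pl.pos) == 0
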