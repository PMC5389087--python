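"""Read-depth detection of duplications and absolute copy-number (WSSD stage).

Short reads are placed at every locus within a mismatch budget; the depth
contribution of a multi-mapping read is split equally among its equal-best
loci, so a locus collapsed in the assembly but present in extra copies in
the sequenced individual accumulates excess depth.  Depth is profiled in
sliding windows over non-repeat bases, a background mean/SD is calibrated
from trimmed control windows, and runs of high-depth windows >= 10 kb are
reported with absolute copy number 2 x depth / background (diploid scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import CalibrationError, InvalidSpecError
from .seqio import ConcatGenome, Genome, kmer_codes
from .sim_genome import ReadSet
from . import intervals as iv


@dataclass
class PlacementTable:
    """Equal-best read placements in concatenated genome coordinates."""

    chrom_names: List[str]
    read_length: int
    read_idx: np.ndarray   # int64, index of the read
    chrom_idx: np.ndarray  # int32, chromosome of the placement
    pos: np.ndarray        # int64, 0-based start within the chromosome
    weight: np.ndarray     # float32, 1 / number of equal-best loci
    n_reads: int = 0
    n_unmapped: int = 0

    @property
    def placed_bases(self) -> float:
        return float(self.weight.sum()) * self.read_length


@dataclass
class DepthProfile:
    """Sliding-window depth track plus calibrated background."""

    window: int
    slide: int
    chrom_names: List[str]
    win_start: Dict[str, np.ndarray]
    win_end: Dict[str, np.ndarray]
    win_depth: Dict[str, np.ndarray]     # NaN where uncallable
    win_callable: Dict[str, np.ndarray]
    base_depth: Dict[str, np.ndarray]    # per-base weighted depth
    base_callable: Dict[str, np.ndarray]  # per-base non-repeat mask
    background_mean: Optional[float] = None
    background_sd: Optional[float] = None

    def require_calibrated(self) -> None:
        if self.background_mean is None or self.background_sd is None:
            raise CalibrationError("depth profile is not calibrated")

    def to_bedgraph_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.chrom_names:
            for s, e, d in zip(self.win_start[c], self.win_end[c],
                               self.win_depth[c]):
                rows.append((c, int(s), int(e),
                             round(float(d), 4) if np.isfinite(d) else -1))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"])


# ---------------------------------------------------------------------------
# read placement


def place_reads(reads: ReadSet, genome: Genome,
                max_mismatches: int = 2,
                chunk_reads: int = 400_000) -> PlacementTable:
    """Place each read at all equal-best loci within the mismatch budget.

    Candidate loci are found by the pigeonhole principle: a read with at
    most ``max_mismatches`` substitutions carries at least one exact
    ``L // (max_mismatches + 1)``-mer segment, which is looked up in a
    sorted k-mer index of the genome.  Reads with no locus within budget
    are dropped and counted.
    """
    names = list(genome)
    L = reads.read_length
    if L > min(len(a) for a in genome.values()):
        raise InvalidSpecError("read length exceeds the shortest chromosome")
    nseg = max_mismatches + 1
    seg = L // nseg
    if seg < 10:
        raise InvalidSpecError(
            f"read length {L} too short for {max_mismatches} mismatches")
    if reads.n_reads == 0:
        warnings.warn("empty read set: no placements")
        return PlacementTable(names, L, *(np.empty(0, t) for t in
                                          (np.int64, np.int32, np.int64,
                                           np.float32)),
                              n_reads=0, n_unmapped=0)

    cat = ConcatGenome(genome)
    S = cat.seq
    N = len(S)
    codes, valid = kmer_codes(S, seg)
    vpos = np.flatnonzero(valid)
    kv = codes[valid]
    order = np.argsort(kv, kind="stable")
    sk = kv[order]
    sp = vpos[order]
    win_off = np.arange(L)

    out_read, out_pos, out_w = [], [], []
    n_unmapped = 0
    for lo_read in range(0, reads.n_reads, chunk_reads):
        hi_read = min(lo_read + chunk_reads, reads.n_reads)
        seqs = reads.seqs[lo_read:hi_read]
        nr = hi_read - lo_read
        cand_r, cand_p = [], []
        s64 = seqs.astype(np.int64)
        for si in range(nseg):
            o = si * seg
            rk = np.zeros(nr, dtype=np.int64)
            for j in range(seg):
                rk = rk * 5 + s64[:, o + j]
            lo = np.searchsorted(sk, rk, side="left")
            hi = np.searchsorted(sk, rk, side="right")
            cnt = hi - lo
            total = int(cnt.sum())
            if total == 0:
                continue
            ridx = np.repeat(np.arange(nr), cnt)
            base = np.repeat(lo, cnt)
            within = np.arange(total) - np.repeat(
                np.concatenate([[0], np.cumsum(cnt)[:-1]]), cnt)
            gpos = sp[base + within] - o
            ok = (gpos >= 0) & (gpos + L <= N)
            cand_r.append(ridx[ok])
            cand_p.append(gpos[ok])
        if not cand_r:
            n_unmapped += nr
            continue
        ridx = np.concatenate(cand_r)
        gpos = np.concatenate(cand_p)
        # one chromosome only
        ci = cat.chrom_index_of(gpos)
        ci_end = cat.chrom_index_of(gpos + L - 1)
        ok = (ci >= 0) & (ci == ci_end)
        ridx, gpos = ridx[ok], gpos[ok]
        # deduplicate (read, locus) pairs found via several segments
        key = ridx * np.int64(N) + gpos
        _, uidx = np.unique(key, return_index=True)
        ridx, gpos = ridx[uidx], gpos[uidx]
        # verify mismatch counts in sub-batches
        mm = np.empty(len(ridx), dtype=np.int32)
        B = 2_000_000
        for b in range(0, len(ridx), B):
            sl = slice(b, min(b + B, len(ridx)))
            wins = S[gpos[sl][:, None] + win_off]
            mm[sl] = (wins != seqs[ridx[sl]]).sum(axis=1)
        ok = mm <= max_mismatches
        ridx, gpos, mm = ridx[ok], gpos[ok], mm[ok]
        if len(ridx) == 0:
            n_unmapped += nr
            continue
        # equal-best selection per read
        best = np.full(nr, np.iinfo(np.int32).max, dtype=np.int32)
        np.minimum.at(best, ridx, mm)
        keep = mm == best[ridx]
        ridx, gpos = ridx[keep], gpos[keep]
        n_best = np.bincount(ridx, minlength=nr)
        mapped = n_best > 0
        n_unmapped += int(nr - mapped.sum())
        w = (1.0 / n_best[ridx]).astype(np.float32)
        out_read.append(ridx.astype(np.int64) + lo_read)
        out_pos.append(gpos)
        out_w.append(w)

    if out_read:
        read_idx = np.concatenate(out_read)
        gpos = np.concatenate(out_pos)
        weight = np.concatenate(out_w)
    else:
        read_idx = np.empty(0, np.int64)
        gpos = np.empty(0, np.int64)
        weight = np.empty(0, np.float32)
    ci = cat.chrom_index_of(gpos).astype(np.int32)
    pos = gpos - cat.offsets[np.clip(ci, 0, None)]
    return PlacementTable(names, L, read_idx, ci, pos, weight,
                          n_reads=reads.n_reads, n_unmapped=n_unmapped)


# ---------------------------------------------------------------------------
# depth profiling


def profile_depth(
    placements: PlacementTable,
    genome: Genome,
    repeats: Optional[pd.DataFrame] = None,
    window: int = 5000,
    slide: int = 1000,
    exclude: Optional[pd.DataFrame] = None,
    trim: float = 0.05,
) -> DepthProfile:
    """Windowed weighted depth over non-repeat bases, with background.

    ``exclude`` intervals (typically WGAC duplication loci) are kept out of
    the background calibration; the background mean/SD is the per-tail
    ``trim``-trimmed mean/SD of the remaining callable windows.
    """
    if slide > window:
        raise InvalidSpecError("slide must be <= window")
    names = list(genome)
    L = placements.read_length
    rep = iv.by_chrom(repeats, merged=True) if repeats is not None else {}
    exc = iv.by_chrom(exclude, merged=True) if exclude is not None else {}

    base_depth, base_callable = {}, {}
    win_start, win_end, win_depth, win_call = {}, {}, {}, {}
    calib_values = []
    for ci, name in enumerate(names):
        clen = len(genome[name])
        sel = placements.chrom_idx == ci
        p = placements.pos[sel]
        w = placements.weight[sel].astype(np.float64)
        diff = (np.bincount(p, weights=w, minlength=clen + L)
                - np.bincount(p + L, weights=w, minlength=clen + L + 1)[:-1])
        depth = np.cumsum(diff)[:clen]
        callable_mask = np.ones(clen, dtype=bool)
        if name in rep:
            s, e = rep[name]
            for a, b in zip(s, e):
                callable_mask[a:b] = False
        base_depth[name] = depth.astype(np.float32)
        base_callable[name] = callable_mask

        starts = np.arange(0, max(clen - window, 0) + 1, slide, dtype=np.int64)
        if len(starts) == 0:
            starts = np.array([0], dtype=np.int64)
        ends = np.minimum(starts + window, clen)
        cs_d = np.concatenate([[0.0], np.cumsum(depth * callable_mask)])
        cs_c = np.concatenate([[0], np.cumsum(callable_mask.astype(np.int64))])
        num = cs_d[ends] - cs_d[starts]
        den = cs_c[ends] - cs_c[starts]
        wlen = ends - starts
        callable_w = den >= 0.5 * wlen
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(callable_w, num / np.maximum(den, 1), np.nan)
        win_start[name] = starts
        win_end[name] = ends
        win_depth[name] = d
        win_call[name] = callable_w
        # calibration candidates: callable and outside excluded loci
        use = callable_w.copy()
        if name in exc:
            es, ee = exc[name]
            # mark windows overlapping an excluded interval
            i0 = np.searchsorted(ee, starts, side="right")
            i1 = np.searchsorted(es, ends, side="left")
            use &= ~(i1 > i0)
        calib_values.append(d[use & np.isfinite(d)])

    calib = np.concatenate(calib_values) if calib_values else np.empty(0)
    calib = calib[np.isfinite(calib)]
    if len(calib) == 0:
        raise CalibrationError("no callable control windows for calibration")
    calib.sort()
    t = int(np.floor(trim * len(calib)))
    core = calib[t:len(calib) - t] if len(calib) > 2 * t else calib
    mean = float(np.mean(core))
    sd = float(np.std(core, ddof=1)) if len(core) > 1 else 0.0
    if sd <= 0:
        raise CalibrationError("degenerate background (sd == 0)")
    return DepthProfile(window, slide, names, win_start, win_end, win_depth,
                        win_call, base_depth, base_callable,
                        background_mean=mean, background_sd=sd)


# ---------------------------------------------------------------------------
# interval calling


def call_wssd_intervals(profile: DepthProfile, z: float = 3.0,
                        min_len: int = 10_000,
                        refine_window: int = 1000) -> pd.DataFrame:
    """Merge runs of excess-depth windows into intervals >= ``min_len``.

    Runs of flagged sliding windows give candidate spans; each candidate is
    then trimmed to the bases where a ``refine_window`` rolling mean of the
    per-base depth still exceeds the threshold, so reported boundaries
    track the duplicated segment rather than the coarse window grid.
    Returns a BED-style frame with ``mean_depth`` and ``copy_number``
    columns (absolute diploid-scaled copies, 1 decimal).
    """
    profile.require_calibrated()
    thr = profile.background_mean + z * profile.background_sd
    rows = []
    for name in profile.chrom_names:
        d = profile.win_depth[name]
        flag = np.isfinite(d) & (d > thr)
        if not flag.any():
            continue
        s = profile.win_start[name][flag]
        e = profile.win_end[name][flag]
        # merge overlapping/adjacent flagged windows
        ms, me = [], []
        for a, b in zip(s, e):
            if ms and a <= me[-1]:
                me[-1] = max(me[-1], b)
            else:
                ms.append(int(a))
                me.append(int(b))
        for a, b in zip(ms, me):
            a, b = _refine_span(profile, name, a, b, thr, refine_window)
            if b - a < min_len:
                continue
            md = _interval_mean_depth(profile, name, int(a), int(b))
            cn = round(2.0 * md / profile.background_mean, 1)
            rows.append((name, int(a), int(b), round(md, 3), cn))
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "mean_depth", "copy_number"])


def _refine_span(profile: DepthProfile, chrom: str, start: int, end: int,
                 thr: float, refine_window: int) -> Tuple[int, int]:
    """Trim a candidate span to the duplicated core by half-height descent.

    A rolling-mean depth track over the span is thresholded at the midpoint
    between the background mean and the span's (robust) peak depth; the
    longest contiguous run above that level is the refined interval.  The
    half-height level sits many background SDs above the noise, so ordinary
    depth fluctuations in the flanks cannot drag the boundaries outward the
    way the raw calling threshold would.
    """
    if refine_window <= 0:
        return start, end
    clen = len(profile.base_depth[chrom])
    start = max(start, 0)
    end = min(end, clen)
    d = profile.base_depth[chrom][start:end].astype(np.float64)
    c = profile.base_callable[chrom][start:end].astype(np.float64)
    cs_d = np.concatenate([[0.0], np.cumsum(d * c)])
    cs_c = np.concatenate([[0.0], np.cumsum(c)])
    n = end - start
    half = refine_window // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half, 0, n)
    num = cs_d[hi] - cs_d[lo]
    den = cs_c[hi] - cs_c[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        roll = np.where(den > 0.25 * (hi - lo), num / np.maximum(den, 1e-9),
                        np.nan)
    finite = roll[np.isfinite(roll)]
    if len(finite) == 0:
        return start, start
    peak = float(np.percentile(finite, 95))
    level = max(thr, (profile.background_mean + peak) / 2.0)
    above = np.isfinite(roll) & (roll > level)
    if not above.any():
        return start, start
    # longest contiguous run above the half-height level
    padded = np.concatenate([[False], above, [False]]).astype(np.int8)
    diff = np.diff(padded)
    run_s = np.flatnonzero(diff == 1)
    run_e = np.flatnonzero(diff == -1)
    best = int(np.argmax(run_e - run_s))
    return start + int(run_s[best]), start + int(run_e[best])


def _interval_mean_depth(profile: DepthProfile, chrom: str,
                         start: int, end: int) -> float:
    d = profile.base_depth[chrom][start:end]
    c = profile.base_callable[chrom][start:end]
    n = int(c.sum())
    if n == 0:
        return float("nan")
    return float(d[c].sum() / n)


def estimate_copy_number(interval: Tuple[str, int, int],
                         profile: DepthProfile) -> float:
    """Absolute copy number 2 x mean depth / background, to 1 decimal."""
    profile.require_calibrated()
    chrom, start, end = interval
    md = _interval_mean_depth(profile, chrom, start, end)
    return round(2.0 * md / profile.background_mean, 1)
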