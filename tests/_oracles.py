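"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately avoid the code paths (seeding, chaining, sorted-array
sweeps) of the implementations they check: alignment detection scans every
diagonal of the full self-comparison matrix, interval statistics use
per-base bitmaps, and cross-species combination counts enumerate subsets
exhaustively.
"""

from __future__ import annotations

from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd

from sdscape.seqio import ConcatGenome, SENTINEL, revcomp


def _max_width_window(prefix: np.ndarray) -> Tuple[int, int]:
    """Longest (i, j), i < j, with prefix[j] >= prefix[i] (max-width ramp).

    Exact: walk indices in increasing prefix value (stable), tracking the
    smallest index seen so far, which is the best left end for each j.
    """
    order = np.argsort(prefix, kind="stable")
    best = (0, 0)
    min_idx = len(prefix)
    for j in order:
        if j < min_idx:
            min_idx = int(j)
        elif j - min_idx > best[1] - best[0]:
            best = (min_idx, int(j))
    return best


def _max_score_segments(match: np.ndarray) -> List[Tuple[int, int]]:
    """Disjoint maximal-scoring segments (match +1 / mismatch -2).

    Recursive Kadane: take the best-scoring subarray, then recurse on what
    remains to its left and right.  These are the endpoints a gap-free DP
    local alignment would report.
    """
    score = np.where(match, 1, -2).astype(np.int64)
    prefix = np.concatenate([[0], np.cumsum(score)])
    out: List[Tuple[int, int]] = []

    def rec(lo: int, hi: int) -> None:
        if hi - lo < 100:
            return
        p = prefix[lo:hi + 1]
        # best subarray = max over j of p[j] - min(p[:j])
        run_min = np.minimum.accumulate(p)
        gain = p - run_min
        j = int(np.argmax(gain))
        if gain[j] < 50:    # nothing alignment-like here
            return
        i = int(np.argmin(p[:j + 1]))
        out.append((lo + i, lo + j))
        rec(lo, lo + i)
        rec(lo + j, hi)

    rec(0, len(match))
    return sorted(out)


def _qualifying_windows(match: np.ndarray, min_len: int,
                        min_identity: float) -> List[Tuple[int, int]]:
    """Score-maximal segments trimmed to the identity floor and filtered."""
    thr = round(min_identity * 100_000)
    out: List[Tuple[int, int]] = []
    for s, e in _max_score_segments(match):
        sub = match[s:e]
        val = np.where(sub, 100_000 - thr, -thr).astype(np.int64)
        prefix = np.concatenate([[0], np.cumsum(val)])
        i, j = _max_width_window(prefix)
        if j - i >= min_len:
            out.append((s + i, s + j))
    return sorted(out)


def brute_force_self_align(genome: Dict[str, np.ndarray],
                           min_len: int = 1000,
                           min_identity: float = 0.90):
    """Scan every diagonal of the self-comparison for qualifying windows.

    Returns a list of (locus_a, locus_b, strand) with canonical ordering,
    loci as (chrom, start, end).
    """
    cat = ConcatGenome(genome)
    S = cat.seq.astype(np.int16)
    n = len(S)
    results = []
    # any >=1 kb window at >=90% identity must contain a 100 bp window
    # with >=90 matches (averaging), so a dense-100-mer screen is lossless
    screen_w, screen_hits = 100, int(np.ceil(100 * min_identity))

    def scan(T: np.ndarray, strand: str) -> None:
        for d in range(1 if strand == "+" else -(n - min_len),
                       n - min_len + 1):
            if d >= 0:
                a = S[: n - d]
                b = T[d:]
                off_a, off_b = 0, d
            else:
                a = S[-d:]
                b = T[: n + d]
                off_a, off_b = -d, 0
            m = (a == b) & (a != SENTINEL) & (b != SENTINEL)
            if len(m) < screen_w:
                continue
            cs = np.concatenate([[0], np.cumsum(m)])
            if int((cs[screen_w:] - cs[:-screen_w]).max()) < screen_hits:
                continue
            for i, j in _qualifying_windows(m, min_len, min_identity):
                a0, a1 = off_a + i, off_a + j
                b0, b1 = off_b + i, off_b + j
                if strand == "-":
                    b0, b1 = n - b1, n - b0
                try:
                    la = cat.to_chrom(a0, a1)
                    lb = cat.to_chrom(b0, b1)
                except ValueError:
                    continue
                if la == lb:
                    continue
                if la > lb:
                    la, lb = lb, la
                results.append((la, lb, strand))

    scan(S, "+")
    scan(np.where(cat.seq == SENTINEL, SENTINEL,
                  3 - cat.seq.astype(np.int16))[::-1], "-")
    # deduplicate (reverse-strand hits are found twice by symmetry)
    seen = set()
    out = []
    for la, lb, st in results:
        key = (la, lb, st)
        if key not in seen:
            seen.add(key)
            out.append((la, lb, st))
    return out


def bitmap_overlap(regions: pd.DataFrame, landmarks: pd.DataFrame,
                   chrom_lengths: Dict[str, int], mode: str) -> float:
    """Per-base bitmap computation of the overlap statistic."""
    masks = {c: np.zeros(l, dtype=bool) for c, l in chrom_lengths.items()}
    for r in regions.itertuples():
        masks[r.chrom][r.start:r.end] = True
    if mode == "length":
        lmask = {c: np.zeros(l, dtype=bool) for c, l in chrom_lengths.items()}
        for r in landmarks.itertuples():
            lmask[r.chrom][r.start:r.end] = True
        return float(sum((masks[c] & lmask[c]).sum() for c in masks))
    # count merged landmark intervals hit
    merged = _bitmap_merge(landmarks, chrom_lengths)
    return float(sum(1 for c, s, e in merged if masks[c][s:e].any()))


def _bitmap_merge(df: pd.DataFrame, chrom_lengths: Dict[str, int]):
    out = []
    for chrom, length in chrom_lengths.items():
        mask = np.zeros(length + 1, dtype=bool)
        for r in df[df["chrom"] == chrom].itertuples():
            mask[r.start:r.end] = True
        diff = np.diff(mask.astype(np.int8))
        starts = list(np.flatnonzero(diff == 1) + 1)
        ends = list(np.flatnonzero(diff == -1) + 1)
        if mask[0]:
            starts = [0] + starts
        for s, e in zip(starts, ends):
            out.append((chrom, int(s), int(e)))
    return out


def bitmap_genes_in_sd(genes: pd.DataFrame, sd_map: pd.DataFrame,
                       chrom_lengths: Dict[str, int],
                       min_overlap: int = 1) -> Set[str]:
    mask = {c: np.zeros(l, dtype=bool) for c, l in chrom_lengths.items()}
    for r in sd_map.itertuples():
        mask[r.chrom][r.start:r.end] = True
    hits = set()
    for r in genes.itertuples():
        if int(mask[r.chrom][r.start:r.end].sum()) >= min_overlap:
            hits.add(r.gene_id)
    return hits


def enumerate_combinations(mapped_sets: Dict[str, Set[str]]):
    """Exhaustive subset enumeration of gene membership combinations."""
    from itertools import combinations

    species = sorted(mapped_sets)
    universe = set().union(*mapped_sets.values())
    counts = {}
    for r in range(1, len(species) + 1):
        for combo in combinations(species, r):
            inset = set(universe)
            for sp in combo:
                inset &= mapped_sets[sp]
            for sp in set(species) - set(combo):
                inset -= mapped_sets[sp]
            if inset:
                counts[frozenset(combo)] = len(inset)
    return counts
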