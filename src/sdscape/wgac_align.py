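"""Whole-genome self-alignment detection of duplication pairs (WGAC stage).

The detector follows the classic assembly-self-comparison recipe: excise
known common repeats so they cannot seed alignments, find exact k-mer seeds
shared by two loci, chain co-linear seeds on the same diagonal, extend each
chain by gap-free X-drop extension, and finally trim each candidate to the
longest stretch whose identity stays at or above the reporting floor
(length >= 1 kb, identity >= 90% by default).  Coordinates are lifted back
to the original assembly space before reporting.

High-copy artifact cleanup (`filter_high_copy`) clusters duplicated loci
into duplicon families by single-linkage interval overlap plus the
alignment links themselves, and removes whole families with >= 50 copies
or members on >= 3 distinct chromosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import InvalidSpecError, LiftoverError
from .seqio import ConcatGenome, Genome, SENTINEL, kmer_codes, revcomp
from . import intervals as iv

Interval = Tuple[str, int, int]

MATCH_SCORE = 1
MISMATCH_SCORE = -2
MAX_SEED_GROUP = 100      # k-mers occurring more often than this are skipped
CHAIN_GAP = 250           # max bp between chained seeds on one diagonal
MIN_CLUSTER_SPAN = 100    # seed chains shorter than this are not extended
MAX_EXTEND = 60_000       # cap on single-sided X-drop extension


@dataclass(frozen=True)
class PairwiseAlignment:
    """One local duplication alignment between two genomic loci."""

    locus_a: Interval
    locus_b: Interval
    strand: str            # '+' or '-'
    identity: float        # matched columns / aligned columns, 4 decimals
    aligned_length: int

    def canonical(self) -> "PairwiseAlignment":
        if self.locus_a <= self.locus_b:
            return self
        return replace(self, locus_a=self.locus_b, locus_b=self.locus_a)


@dataclass
class AlignmentSet:
    alignments: List[PairwiseAlignment]
    genome_id: str = "genome"
    stage: str = "initial"   # initial | cleaned

    def __len__(self) -> int:
        return len(self.alignments)

    def loci(self) -> pd.DataFrame:
        rows = []
        for a in self.alignments:
            rows.append(a.locus_a)
            rows.append(a.locus_b)
        return iv.to_frame(rows)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (a.locus_a[0], a.locus_a[1], a.locus_a[2],
             a.locus_b[0], a.locus_b[1], a.locus_b[2],
             a.strand, a.aligned_length, a.identity, self.stage)
            for a in self.alignments
        ]
        return pd.DataFrame(rows, columns=[
            "chromA", "startA", "endA", "chromB", "startB", "endB",
            "strand", "aligned_length", "identity", "stage"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   genome_id: str = "genome") -> "AlignmentSet":
        alns = [
            PairwiseAlignment(
                (r.chromA, int(r.startA), int(r.endA)),
                (r.chromB, int(r.startB), int(r.endB)),
                r.strand, float(r.identity), int(r.aligned_length))
            for r in df.itertuples()
        ]
        stage = str(df["stage"].iloc[0]) if len(df) else "initial"
        return cls(alns, genome_id=genome_id, stage=stage)


# ---------------------------------------------------------------------------
# repeat excision


class CoordinateMap:
    """Maps condensed (repeat-excised) coordinates back to original space."""

    def __init__(self, kept: Dict[str, np.ndarray]):
        self._kept = kept   # chrom -> sorted original positions retained

    def to_original(self, chrom: str, pos: int) -> int:
        return int(self._kept[chrom][pos])

    def interval_to_original(self, chrom: str, start: int,
                             end: int) -> Tuple[int, int]:
        kept = self._kept[chrom]
        return int(kept[start]), int(kept[end - 1]) + 1

    def to_condensed(self, chrom: str, pos: int) -> int:
        kept = self._kept[chrom]
        i = int(np.searchsorted(kept, pos))
        if i >= len(kept) or kept[i] != pos:
            raise LiftoverError(
                f"position {chrom}:{pos} lies inside an excised repeat")
        return i


def mask_and_excise(genome: Genome,
                    repeats: Optional[pd.DataFrame]) -> Tuple[Genome,
                                                              CoordinateMap]:
    """Remove known-repeat bases; returns (condensed genome, coordinate map).

    Overlapping repeat records are merged (with a warning) rather than
    rejected.
    """
    kept: Dict[str, np.ndarray] = {}
    condensed: Genome = {}
    per_chrom = {}
    if repeats is not None and len(repeats):
        if len(iv.merge(repeats)) < len(repeats):
            warnings.warn("overlapping repeat records merged")
        per_chrom = iv.by_chrom(repeats, merged=True)
    for name, arr in genome.items():
        mask = np.zeros(len(arr), dtype=bool)
        if name in per_chrom:
            s, e = per_chrom[name]
            if (s < 0).any() or (e > len(arr)).any():
                raise InvalidSpecError(
                    f"repeat interval outside chromosome {name}")
            for a, b in zip(s, e):
                mask[a:b] = True
        keep_idx = np.flatnonzero(~mask)
        kept[name] = keep_idx
        condensed[name] = arr[keep_idx]
    return condensed, CoordinateMap(kept)


# ---------------------------------------------------------------------------
# seed pairing


def _self_seed_pairs(codes: np.ndarray, valid: np.ndarray,
                     positions_offset: int = 0):
    """All position pairs (p < q) sharing an exact k-mer within one sequence."""
    vpos = np.flatnonzero(valid) + positions_offset
    kv = codes[valid]
    order = np.lexsort((vpos, kv))
    sk = kv[order]
    sp = vpos[order]
    if len(sk) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    same = np.concatenate([[False], sk[1:] == sk[:-1]])
    group = np.cumsum(~same) - 1
    sizes = np.bincount(group)
    # drop hyper-abundant k-mers (unmasked satellite-like sequence)
    bad_groups = np.flatnonzero(sizes > MAX_SEED_GROUP)
    if len(bad_groups):
        keep = ~np.isin(group, bad_groups)
        sp, group = sp[keep], group[keep]
        sizes = np.bincount(group) if len(group) else sizes[:0]
    max_size = int(sizes.max()) if len(sizes) else 0
    pa_parts, pb_parts = [], []
    for off in range(1, max_size):
        m = group[off:] == group[:-off]
        if m.any():
            pa_parts.append(sp[:-off][m])
            pb_parts.append(sp[off:][m])
    if not pa_parts:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    return np.concatenate(pa_parts), np.concatenate(pb_parts)


def _cross_seed_pairs(codes_a, valid_a, codes_b, valid_b):
    """All (i in A, j in B) position pairs sharing an exact k-mer."""
    apos = np.flatnonzero(valid_a)
    akv = codes_a[valid_a]
    bpos = np.flatnonzero(valid_b)
    bkv = codes_b[valid_b]
    bo = np.lexsort((bpos, bkv))
    bsk, bsp = bkv[bo], bpos[bo]
    lo = np.searchsorted(bsk, akv, side="left")
    hi = np.searchsorted(bsk, akv, side="right")
    cnt = np.clip(hi - lo, 0, MAX_SEED_GROUP)
    total = int(cnt.sum())
    if total == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    ai = np.repeat(np.arange(len(akv)), cnt)
    base = np.repeat(lo, cnt)
    within = np.arange(total) - np.repeat(
        np.concatenate([[0], np.cumsum(cnt)[:-1]]), cnt)
    return apos[ai], bsp[base + within]


# ---------------------------------------------------------------------------
# chaining, extension, trimming


def _cluster_diagonal_hits(pa: np.ndarray, pb: np.ndarray, k: int):
    """Chain seed hits sharing a diagonal into (a_start, a_end, diag) spans."""
    if len(pa) == 0:
        return []
    d = pb - pa
    order = np.lexsort((pa, d))
    d, pa = d[order], pa[order]
    new = np.empty(len(pa), dtype=bool)
    new[0] = True
    new[1:] = (d[1:] != d[:-1]) | (pa[1:] - pa[:-1] > CHAIN_GAP)
    starts = np.flatnonzero(new)
    ends = np.append(starts[1:], len(pa))
    clusters = []
    for s, e in zip(starts, ends):
        a0 = int(pa[s])
        a1 = int(pa[e - 1]) + k
        if a1 - a0 >= MIN_CLUSTER_SPAN:
            clusters.append((a0, a1, int(d[s])))
    return clusters


def _xdrop_extend(sa: np.ndarray, sb: np.ndarray, xdrop: int) -> int:
    """Gap-free extension length along paired arrays (already oriented)."""
    if len(sa) == 0:
        return 0
    m = (sa == sb) & (sa != SENTINEL)
    scores = np.where(m, MATCH_SCORE, MISMATCH_SCORE).astype(np.int64)
    cs = np.cumsum(scores)
    run_max = np.maximum.accumulate(cs)
    dropped = np.flatnonzero(run_max - cs > xdrop)
    limit = int(dropped[0]) if len(dropped) else len(cs)
    if limit == 0:
        return 0
    return int(np.argmax(cs[:limit])) + 1


def _longest_window_at_identity(match: np.ndarray,
                                min_identity: float) -> Tuple[int, int]:
    """Longest contiguous window with mean(match) >= min_identity.

    Uses integer prefix scores and a monotone-stack scan; returns (i, j)
    half-open, or (0, 0) when no non-empty window qualifies.  Leftmost
    window wins ties.
    """
    thr = round(min_identity * 100_000)
    val = np.where(match, 100_000 - thr, -thr).astype(np.int64)
    prefix = np.concatenate([[0], np.cumsum(val)])
    n = len(prefix)
    stack = [0]
    for i in range(1, n):
        if prefix[i] < prefix[stack[-1]]:
            stack.append(i)
    best_len, best = 0, (0, 0)
    for j in range(n - 1, 0, -1):
        while stack and prefix[j] >= prefix[stack[-1]]:
            i = stack.pop()
            if j - i > best_len:
                best_len = j - i
                best = (i, j)
    return best


@dataclass
class _Segment:
    a0: int
    a1: int
    diag: int
    strand: str


def _extend_and_collect(S: np.ndarray, T: np.ndarray, clusters, strand: str,
                        xdrop: int) -> List[_Segment]:
    """X-drop extend each cluster; T is the second sequence (S itself for +)."""
    n = len(S)
    segments = []
    for a0, a1, d in clusters:
        # left extension
        lim = min(a0, a0 + d, MAX_EXTEND)
        if lim > 0:
            la = S[a0 - lim:a0][::-1]
            lb = T[a0 + d - lim:a0 + d][::-1]
            a0 -= _xdrop_extend(la, lb, xdrop)
        # right extension
        lim = min(n - a1, n - (a1 + d), MAX_EXTEND)
        if lim > 0:
            ra = S[a1:a1 + lim]
            rb = T[a1 + d:a1 + d + lim]
            a1 += _xdrop_extend(ra, rb, xdrop)
        segments.append(_Segment(a0, a1, d, strand))
    return segments


def _merge_segments(segments: List[_Segment]) -> List[_Segment]:
    """Union overlapping extended spans that share a diagonal and strand."""
    out: List[_Segment] = []
    key = lambda s: (s.strand, s.diag, s.a0, s.a1)
    for seg in sorted(segments, key=key):
        if (out and out[-1].strand == seg.strand and out[-1].diag == seg.diag
                and seg.a0 <= out[-1].a1):
            out[-1].a1 = max(out[-1].a1, seg.a1)
        else:
            out.append(_Segment(seg.a0, seg.a1, seg.diag, seg.strand))
    return out


def _trim_segment(S: np.ndarray, T: np.ndarray, seg: _Segment,
                  min_len: int, min_identity: float):
    """Trim to the longest window holding the identity floor; may reject."""
    a, b, d = seg.a0, seg.a1, seg.diag
    sa = S[a:b]
    sb = T[a + d:b + d]
    # clip columns where either locus touches a chromosome-separating
    # sentinel (extension can poke a few bases into the run)
    ok = (sa != SENTINEL) & (sb != SENTINEL)
    if not ok.any():
        return None
    valid = np.flatnonzero(ok)
    a += int(valid[0])
    b = a + int(valid[-1]) - int(valid[0]) + 1
    sa = S[a:b]
    sb = T[a + d:b + d]
    match = sa == sb
    i, j = _longest_window_at_identity(match, min_identity)
    if j - i < min_len:
        return None
    ident = float(match[i:j].mean())
    return a + i, a + j, round(ident, 4)


# ---------------------------------------------------------------------------


def self_align(
    genome: Genome,
    k: int = 14,
    min_len: int = 1000,
    min_identity: float = 0.90,
    xdrop: int = 20,
    coord_map: Optional[CoordinateMap] = None,
    genome_id: str = "genome",
) -> AlignmentSet:
    """Detect duplication alignments by comparing the genome to itself.

    ``genome`` is typically the repeat-condensed genome from
    :func:`mask_and_excise`; pass the accompanying ``coord_map`` to report
    alignments in original assembly coordinates.
    """
    if not 12 <= k <= 20:
        raise InvalidSpecError("seed length k must lie in [12, 20]")
    if min(len(a) for a in genome.values()) < k:
        raise InvalidSpecError("genome shorter than seed length k")
    cat = ConcatGenome(genome)
    S = cat.seq
    codes, valid = kmer_codes(S, k)

    # forward strand: self-join of the k-mer table
    pa, pb = _self_seed_pairs(codes, valid)
    keep = pb > pa   # exclude the trivial self-diagonal
    fw_clusters = _cluster_diagonal_hits(pa[keep], pb[keep], k)
    segments = _extend_and_collect(S, S, fw_clusters, "+", xdrop)

    # reverse strand: compare against the reverse complement
    T = revcomp(S)
    tcodes, tvalid = kmer_codes(T, k)
    ra, rb = _cross_seed_pairs(codes, valid, tcodes, tvalid)
    rv_clusters = _cluster_diagonal_hits(ra, rb, k)
    segments += _extend_and_collect(S, T, rv_clusters, "-", xdrop)

    segments = _merge_segments(segments)

    n = len(S)
    seen = set()
    alignments: List[PairwiseAlignment] = []
    for seg in segments:
        trimmed = _trim_segment(S, S if seg.strand == "+" else T, seg,
                                min_len, min_identity)
        if trimmed is None:
            continue
        a0, a1, ident = trimmed
        b0, b1 = a0 + seg.diag, a1 + seg.diag
        if seg.strand == "-":
            b0, b1 = n - b1, n - b0
        try:
            locus_a = cat.to_chrom(a0, a1)
            locus_b = cat.to_chrom(b0, b1)
        except ValueError:
            continue  # spans a sentinel boundary; cannot happen post-trim
        if coord_map is not None:
            ca, (s0, s1) = locus_a[0], coord_map.interval_to_original(
                locus_a[0], locus_a[1], locus_a[2])
            cb, (t0, t1) = locus_b[0], coord_map.interval_to_original(
                locus_b[0], locus_b[1], locus_b[2])
            locus_a, locus_b = (ca, s0, s1), (cb, t0, t1)
        if locus_a == locus_b:
            continue
        aln = PairwiseAlignment(locus_a, locus_b, seg.strand, ident,
                                a1 - a0).canonical()
        key = (aln.locus_a, aln.locus_b, aln.strand)
        if key in seen:
            continue
        seen.add(key)
        alignments.append(aln)
    alignments = _dedupe_redundant(alignments)
    alignments.sort(key=lambda a: (a.locus_a, a.locus_b, a.strand))
    return AlignmentSet(alignments, genome_id=genome_id, stage="initial")


def _dedupe_redundant(alignments: List[PairwiseAlignment],
                      frac: float = 0.5) -> List[PairwiseAlignment]:
    """Drop alignments whose both loci are mostly contained in a longer one."""
    kept: List[PairwiseAlignment] = []
    order = sorted(alignments, key=lambda a: -a.aligned_length)

    def _contained(inner: Interval, outer: Interval) -> bool:
        if inner[0] != outer[0]:
            return False
        ov = min(inner[2], outer[2]) - max(inner[1], outer[1])
        return ov > frac * (inner[2] - inner[1])

    for a in order:
        redundant = any(
            a.strand == b.strand
            and _contained(a.locus_a, b.locus_a)
            and _contained(a.locus_b, b.locus_b)
            for b in kept)
        if not redundant:
            kept.append(a)
    return kept


# ---------------------------------------------------------------------------
# high-copy artifact filter


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def filter_high_copy(aln_set: AlignmentSet, max_copies: int = 50,
                     max_chroms: int = 3) -> AlignmentSet:
    """Remove whole duplicon families with too many copies or chromosomes.

    Families are connected components over duplicated loci, linking the two
    loci of every alignment and any loci that overlap on the genome
    (single-linkage).  A family is removed when its merged-copy count is
    >= ``max_copies`` or it touches >= ``max_chroms`` distinct chromosomes.
    Idempotent.
    """
    alns = aln_set.alignments
    if not alns:
        return AlignmentSet([], aln_set.genome_id, "cleaned")
    loci: List[Interval] = []
    for a in alns:
        loci.append(a.locus_a)
        loci.append(a.locus_b)
    uf = _UnionFind(len(loci))
    for i in range(0, len(loci), 2):
        uf.union(i, i + 1)
    # single-linkage by interval overlap, per chromosome sweep
    idx_by_chrom: Dict[str, List[int]] = {}
    for i, (chrom, s, e) in enumerate(loci):
        idx_by_chrom.setdefault(chrom, []).append(i)
    for chrom, idxs in idx_by_chrom.items():
        idxs.sort(key=lambda i: (loci[i][1], loci[i][2]))
        cur_end = -1
        cur_rep = -1
        for i in idxs:
            _, s, e = loci[i]
            if s < cur_end:
                uf.union(cur_rep, i)
                cur_end = max(cur_end, e)
            else:
                cur_rep, cur_end = i, e
    # evaluate each family
    comp_members: Dict[int, List[int]] = {}
    for i in range(len(loci)):
        comp_members.setdefault(uf.find(i), []).append(i)
    removed_comps = set()
    for root, members in comp_members.items():
        ivs = iv.to_frame([loci[i] for i in members])
        merged = iv.merge(ivs)
        n_copies = len(merged)
        n_chroms = merged["chrom"].nunique()
        if n_copies >= max_copies or n_chroms >= max_chroms:
            removed_comps.add(root)
    survivors = [
        a for j, a in enumerate(alns)
        if uf.find(2 * j) not in removed_comps
    ]
    return AlignmentSet(survivors, aln_set.genome_id, "cleaned")


def identity_histogram(aln_set: AlignmentSet) -> pd.Series:
    """Counts of alignments per 1-percentage-point identity bin (90..100).

    Bins 90..99 are half-open [i%, i+1%); bin 100 holds exact-identity
    alignments.  Counts sum to the alignment count.
    """
    counts = pd.Series(0, index=range(90, 101), dtype=int)
    for a in aln_set.alignments:
        b = min(int(np.floor(a.identity * 100 + 1e-9)), 100)
        b = max(b, 90)
        counts[b] += 1
    return counts
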