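"""Base-level interval arithmetic on BED-style DataFrames.

All functions treat intervals as 0-based half-open.  Inputs need not be
sorted; functions that require merged (disjoint, sorted) sets merge
internally.  The implementations are plain sorted-array sweeps, which keeps
the base-level semantics explicit and easy to verify against per-base
bitmap oracles.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

ChromArrays = Dict[str, Tuple[np.ndarray, np.ndarray]]


def to_frame(rows, columns=("chrom", "start", "end")) -> pd.DataFrame:
    df = pd.DataFrame(list(rows), columns=list(columns))
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def empty() -> pd.DataFrame:
    return to_frame([])


def _merge_arrays(starts: np.ndarray, ends: np.ndarray):
    """Merge possibly-overlapping intervals; returns sorted disjoint arrays."""
    if len(starts) == 0:
        return starts.astype(np.int64), ends.astype(np.int64)
    order = np.lexsort((ends, starts))
    s = np.asarray(starts, np.int64)[order]
    e = np.asarray(ends, np.int64)[order]
    run_max = np.maximum.accumulate(e)
    # a new merged block starts where start > max end seen so far
    new_block = np.empty(len(s), dtype=bool)
    new_block[0] = True
    new_block[1:] = s[1:] > run_max[:-1]
    block = np.cumsum(new_block) - 1
    out_s = s[new_block]
    out_e = np.maximum.reduceat(e, np.flatnonzero(new_block))
    del block
    return out_s, out_e


def by_chrom(df: pd.DataFrame, merged: bool = False) -> ChromArrays:
    out: ChromArrays = {}
    if len(df) == 0:
        return out
    for chrom, g in df.groupby("chrom", sort=True):
        s = g["start"].to_numpy(np.int64)
        e = g["end"].to_numpy(np.int64)
        if merged:
            s, e = _merge_arrays(s, e)
        else:
            order = np.lexsort((e, s))
            s, e = s[order], e[order]
        out[str(chrom)] = (s, e)
    return out


def merge(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping intervals per chromosome."""
    rows = []
    for chrom, (s, e) in by_chrom(df, merged=True).items():
        for a, b in zip(s, e):
            rows.append((chrom, int(a), int(b)))
    return to_frame(rows)


def total_length(df: pd.DataFrame, pre_merged: bool = False) -> int:
    """Total bases covered (after merging unless ``pre_merged``)."""
    if len(df) == 0:
        return 0
    if pre_merged:
        return int((df["end"] - df["start"]).sum())
    tot = 0
    for _, (s, e) in by_chrom(df, merged=True).items():
        tot += int((e - s).sum())
    return tot


def _overlap_with_merged(q_s: np.ndarray, q_e: np.ndarray,
                         b_s: np.ndarray, b_e: np.ndarray) -> np.ndarray:
    """Overlap bases of each query interval with a merged set (vectorised)."""
    if len(b_s) == 0 or len(q_s) == 0:
        return np.zeros(len(q_s), dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(b_e - b_s)])
    i0 = np.searchsorted(b_e, q_s, side="right")
    i1 = np.searchsorted(b_s, q_e, side="left")
    full = cum[i1] - cum[i0]
    has = i1 > i0
    left = np.zeros(len(q_s), np.int64)
    right = np.zeros(len(q_s), np.int64)
    idx0 = np.clip(i0, 0, len(b_s) - 1)
    idx1 = np.clip(i1 - 1, 0, len(b_s) - 1)
    left[has] = np.clip(q_s[has] - b_s[idx0[has]], 0, None)
    right[has] = np.clip(b_e[idx1[has]] - q_e[has], 0, None)
    return full - left - right


def overlap_per_row(query: pd.DataFrame, cover: pd.DataFrame) -> np.ndarray:
    """Per-row overlap bases of `query` with the merged `cover` set."""
    cov = by_chrom(cover, merged=True)
    out = np.zeros(len(query), dtype=np.int64)
    if len(query) == 0:
        return out
    q = query.reset_index(drop=True)
    qs = q["start"].to_numpy(np.int64)
    qe = q["end"].to_numpy(np.int64)
    for chrom, g in q.groupby("chrom", sort=False):
        pos = g.index.to_numpy()
        if str(chrom) not in cov:
            continue
        b_s, b_e = cov[str(chrom)]
        out[pos] = _overlap_with_merged(qs[pos], qe[pos], b_s, b_e)
    return out


def overlap_bases(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Total intersection bases between the merged a and merged b sets."""
    am = merge(a)
    return int(overlap_per_row(am, b).sum())


def count_overlapping(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Number of rows of `a` with at least 1 bp overlap with merged `b`."""
    return int((overlap_per_row(a, b) > 0).sum())


def coverage_fraction(query: pd.DataFrame, cover: pd.DataFrame) -> np.ndarray:
    """Fraction of each query interval covered by the merged cover set."""
    ov = overlap_per_row(query, cover)
    lengths = (query["end"] - query["start"]).to_numpy(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(lengths > 0, ov / lengths, 0.0)
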