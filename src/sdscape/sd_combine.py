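"""Combine self-alignment and read-depth evidence into the final SD map.

The combination rule: alignments below 94% identity enter the map directly;
alignments at or above 94% — the identity range where assembly artifacts
concentrate — are kept only when read-depth (WSSD) intervals support at
least one of their loci.  Read-depth-only intervals with no alignment
support are reported as a separate track, not counted in the map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .wgac_align import AlignmentSet, PairwiseAlignment
from . import intervals as iv

IDENTITY_CUT = 0.94


@dataclass
class SDSummary:
    total_sd_length: int
    genome_length: int
    sd_content: float
    per_chromosome: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total_sd_length": self.total_sd_length,
            "genome_length": self.genome_length,
            "sd_content": self.sd_content,
            "per_chromosome": self.per_chromosome,
        }


def split_by_identity(aln_set: AlignmentSet,
                      cut: float = IDENTITY_CUT
                      ) -> Tuple[AlignmentSet, AlignmentSet]:
    """Partition cleaned alignments at the identity cut (>= goes high)."""
    low = [a for a in aln_set.alignments if a.identity < cut]
    high = [a for a in aln_set.alignments if a.identity >= cut]
    return (AlignmentSet(low, aln_set.genome_id, aln_set.stage),
            AlignmentSet(high, aln_set.genome_id, aln_set.stage))


def validate_high_identity(
    high: AlignmentSet,
    wssd: pd.DataFrame,
    min_support: float = 0.5,
) -> Tuple[AlignmentSet, AlignmentSet]:
    """Keep high-identity alignments with read-depth support.

    A locus is supported when at least ``min_support`` of its length is
    covered by WSSD intervals; an alignment survives when either locus is
    supported.  Returns (validated, artifactual).
    """
    if not len(high.alignments):
        return (AlignmentSet([], high.genome_id, high.stage),
                AlignmentSet([], high.genome_id, high.stage))
    loci = high.loci()
    frac = iv.coverage_fraction(loci, wssd)
    validated, dropped = [], []
    for j, a in enumerate(high.alignments):
        if frac[2 * j] >= min_support or frac[2 * j + 1] >= min_support:
            validated.append(a)
        else:
            dropped.append(a)
    return (AlignmentSet(validated, high.genome_id, high.stage),
            AlignmentSet(dropped, high.genome_id, high.stage))


def build_final_map(
    low: AlignmentSet,
    validated: AlignmentSet,
    wssd: pd.DataFrame,
    chrom_lengths: Dict[str, int],
) -> Tuple[pd.DataFrame, SDSummary, pd.DataFrame]:
    """Merge duplicated loci into the final SD map.

    Returns ``(sd_map, summary, wssd_only)``.  The map is the base-level
    union of loci from low-identity and validated high-identity alignments,
    annotated with support class, the highest identity among contributing
    alignments, and the copy number of the largest-overlap WSSD interval.
    WSSD intervals with no overlap with the map form the separate
    ``wssd_only`` track.
    """
    low_loci = low.loci()
    val_loci = validated.loci()
    all_loci = pd.concat([low_loci, val_loci], ignore_index=True)
    merged = iv.merge(all_loci)
    rows = []
    for r in merged.itertuples():
        region = (r.chrom, int(r.start), int(r.end))
        support_low = _any_overlap(region, low)
        support_high = _any_overlap(region, validated)
        if support_low and support_high:
            support = "wgac_low+wgac_high_validated"
        elif support_high:
            support = "wgac_high_validated"
        else:
            support = "wgac_low"
        max_ident = max(
            (a.identity for a in low.alignments + validated.alignments
             if _locus_overlaps(region, a)), default=np.nan)
        cn = _best_overlap_cn(region, wssd)
        rows.append(region + (support, max_ident, cn))
    sd_map = pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "support", "max_identity", "copy_number"])
    genome_length = int(sum(chrom_lengths.values()))
    per_chrom = {
        c: int((g["end"] - g["start"]).sum())
        for c, g in sd_map.groupby("chrom")
    }
    total = int(sum(per_chrom.values()))
    summary = SDSummary(
        total_sd_length=total,
        genome_length=genome_length,
        sd_content=(total / genome_length) if genome_length else 0.0,
        per_chromosome=per_chrom,
    )
    if len(wssd):
        ov = iv.overlap_per_row(wssd, sd_map)
        wssd_only = wssd[ov == 0].reset_index(drop=True)
    else:
        wssd_only = wssd.copy()
    return sd_map, summary, wssd_only


def _locus_overlaps(region: Tuple[str, int, int],
                    a: PairwiseAlignment) -> bool:
    for chrom, s, e in (a.locus_a, a.locus_b):
        if chrom == region[0] and s < region[2] and e > region[1]:
            return True
    return False


def _any_overlap(region: Tuple[str, int, int], aln_set: AlignmentSet) -> bool:
    return any(_locus_overlaps(region, a) for a in aln_set.alignments)


def _best_overlap_cn(region: Tuple[str, int, int],
                     wssd: pd.DataFrame) -> float:
    if not len(wssd):
        return float("nan")
    sel = wssd[(wssd["chrom"] == region[0])
               & (wssd["start"] < region[2])
               & (wssd["end"] > region[1])]
    if not len(sel):
        return float("nan")
    ov = np.minimum(sel["end"], region[2]) - np.maximum(sel["start"],
                                                        region[1])
    return float(sel["copy_number"].iloc[int(np.argmax(ov.to_numpy()))])


def verification_proportion(
    cleaned: AlignmentSet,
    wssd: pd.DataFrame,
    min_len: int = 10_000,
    cut: float = IDENTITY_CUT,
    min_support: float = 0.5,
) -> float:
    """Length proportion of long high-identity loci verified by read depth.

    Considers every locus of a cleaned alignment with identity >= ``cut``
    whose own length is strictly greater than ``min_len``; a locus is
    verified when >= ``min_support`` of its length is covered by WSSD
    intervals.  Returns merged verified length / merged total length, or
    NaN (with a warning) when no qualifying locus exists.
    """
    qual: List[Tuple[str, int, int]] = []
    for a in cleaned.alignments:
        if a.identity < cut:
            continue
        for locus in (a.locus_a, a.locus_b):
            if locus[2] - locus[1] > min_len:
                qual.append(locus)
    if not qual:
        warnings.warn("no long high-identity loci: proportion undefined")
        return float("nan")
    qdf = iv.to_frame(qual)
    frac = iv.coverage_fraction(qdf, wssd)
    verified = qdf[frac >= min_support]
    denom = iv.total_length(qdf)
    if denom == 0:
        return float("nan")
    return iv.total_length(verified) / denom
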