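"""Gene content of segmental duplications.

Intersects gene annotations with the SD map, assigns per-gene absolute
copy numbers from the read-depth intervals, bins them in the conventional
copy-number table (right-closed edges at 1.5, 2.5, 10.5, 20.5, ... 100.5
plus a Null row for genes with no callable depth interval), and computes
cross-species common-gene sets through an ortholog map into a reference
gene namespace.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, List, Set, Tuple

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from . import intervals as iv

CN_EDGES = [1.5, 2.5] + [10.5 + 10 * i for i in range(10)]  # ... 100.5
CN_LABELS = (["<=1.5", "1.5-2.5", "2.5-10.5"]
             + [f"{10.5 + 10 * i}-{20.5 + 10 * i}" for i in range(9)]
             + [">100.5"])


def read_genes(path) -> Tuple[pd.DataFrame, int]:
    """Read a gene annotation (BED with name column, or GFF3).

    Returns (frame with gene_id/chrom/start/end/strand, n_malformed_rows).
    """
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        return _read_genes_gff3(path)
    rows = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                if end <= start:
                    raise ValueError
                name = parts[3] if len(parts) > 3 else f"gene{len(rows)}"
                strand = parts[5] if len(parts) > 5 else "."
            except (ValueError, IndexError):
                skipped += 1
                continue
            rows.append((name, chrom, start, end, strand))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                     "strand"])
    return df, skipped


def _read_genes_gff3(path) -> Tuple[pd.DataFrame, int]:
    import gffutils

    db = gffutils.create_db(path, dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        # GFF3 is 1-based closed; convert to 0-based half-open
        rows.append((gid, feat.seqid, feat.start - 1, feat.end, feat.strand))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                     "strand"])
    return df, 0


def genes_in_sd(genes: pd.DataFrame, sd_map: pd.DataFrame,
                min_overlap: int = 1) -> pd.DataFrame:
    """Genes overlapping the merged SD map by at least ``min_overlap`` bp.

    The result carries ``overlap_bp`` and ``overlap_fraction`` columns and
    is invariant to the ordering or pre-merging of the SD intervals.
    """
    if min_overlap < 1:
        raise InvalidSpecError("min_overlap must be >= 1 bp")
    g = genes.reset_index(drop=True)
    ov = iv.overlap_per_row(g, sd_map)
    lengths = (g["end"] - g["start"]).to_numpy(np.int64)
    out = g[ov >= min_overlap].copy()
    out["overlap_bp"] = ov[ov >= min_overlap]
    out["overlap_fraction"] = out["overlap_bp"] / lengths[ov >= min_overlap]
    return out.reset_index(drop=True)


def assign_gene_cn(genes: pd.DataFrame, wssd: pd.DataFrame) -> pd.Series:
    """Copy number of the WSSD interval with the largest overlap per gene.

    Genes overlapping no WSSD interval get NaN (the "Null" class).
    """
    cns = np.full(len(genes), np.nan)
    if len(wssd) == 0 or len(genes) == 0:
        return pd.Series(cns, index=genes.index, name="copy_number")
    g = genes.reset_index(drop=True)
    for i, r in enumerate(g.itertuples()):
        sel = wssd[(wssd["chrom"] == r.chrom)
                   & (wssd["start"] < r.end) & (wssd["end"] > r.start)]
        if not len(sel):
            continue
        ov = (np.minimum(sel["end"], r.end)
              - np.maximum(sel["start"], r.start)).to_numpy()
        cns[i] = float(sel["copy_number"].iloc[int(np.argmax(ov))])
    return pd.Series(cns, index=genes.index, name="copy_number")


def bin_gene_cn(copy_numbers: pd.Series) -> pd.DataFrame:
    """Bin gene copy numbers into the conventional right-closed table.

    Returns a frame with one row per bin (plus "Null" and "Ave.CN"); the
    average is over non-null genes, to one decimal.  Counts always sum to
    the number of genes.
    """
    cn = pd.Series(copy_numbers, dtype=float)
    non_null = cn.dropna()
    edges = [-np.inf] + CN_EDGES + [np.inf]
    if len(non_null):
        binned = pd.cut(non_null, bins=edges, labels=CN_LABELS, right=True)
        counts = binned.value_counts().reindex(CN_LABELS, fill_value=0)
    else:
        counts = pd.Series(0, index=CN_LABELS)
    rows = [(lab, int(counts[lab])) for lab in CN_LABELS]
    rows.append(("Null", int(cn.isna().sum())))
    ave = round(float(non_null.mean()), 1) if len(non_null) else float("nan")
    table = pd.DataFrame(rows, columns=["bin", "count"])
    table.attrs["ave_cn"] = ave
    table.attrs["total"] = int(len(cn))
    return table


def common_genes(
    species_gene_sets: Dict[str, Set[str]],
    ortholog_maps: Dict[str, Dict[str, str]],
    min_species: int = 5,
) -> Tuple[List[str], Dict[FrozenSet[str], int], Dict[str, int]]:
    """Cross-species common genes in a shared reference namespace.

    ``species_gene_sets`` maps species -> set of species-native gene ids in
    SD regions; ``ortholog_maps`` maps species -> {native id: reference id}.
    Returns (sorted common gene list present in >= min_species species,
    Venn-style combination counts keyed by frozenset of species, and the
    per-species count of unmapped ids).
    """
    if len(species_gene_sets) < min_species:
        raise InvalidSpecError(
            f"need >= {min_species} species, got {len(species_gene_sets)}")
    mapped: Dict[str, Set[str]] = {}
    unmapped: Dict[str, int] = {}
    for sp, genes in species_gene_sets.items():
        omap = ortholog_maps.get(sp, {})
        refs = set()
        miss = 0
        for g in genes:
            if g in omap:
                refs.add(omap[g])
            else:
                miss += 1
        mapped[sp] = refs
        unmapped[sp] = miss
    universe = set().union(*mapped.values()) if mapped else set()
    membership: Dict[str, FrozenSet[str]] = {}
    for gene in universe:
        membership[gene] = frozenset(
            sp for sp, refs in mapped.items() if gene in refs)
    combo_counts: Dict[FrozenSet[str], int] = {}
    for gene, combo in membership.items():
        combo_counts[combo] = combo_counts.get(combo, 0) + 1
    common = sorted(g for g, combo in membership.items()
                    if len(combo) >= min_species)
    return common, combo_counts, unmapped
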