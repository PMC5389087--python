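"""End-to-end orchestration, canonical fixtures, and run manifests.

A run proceeds simulate? -> wgac -> wssd -> combine -> enrich -> genes.
Every stage's randomness is derived from the single config seed via
``stage_seed(seed, name)`` so stages are individually reproducible, and a
manifest capturing the config, record counts and output checksums is
written for every run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidSpecError
from . import intervals as iv
from . import seqio
from .sim_genome import (DuplicationEvent, GenomeSpec, PlantedTruth, ReadSet,
                         generate_reference, place_interval,
                         plant_duplications, plant_repeats, simulate_reads)
from . import wgac_align, wssd_depth, sd_combine, enrich_perm, gene_annot


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16) % (2 ** 31)


@dataclass
class RunConfig:
    """All stage parameters with their documented defaults."""

    outdir: str = "sdscape_run"
    seed: int = 1
    # input paths (None -> produced by the simulate stage)
    genome: Optional[str] = None
    reads: Optional[str] = None
    repeats: Optional[str] = None
    genes: Optional[str] = None
    centromeres: Optional[str] = None
    simulate_scale: Optional[str] = None   # small | standard
    # wgac
    k: int = 14
    min_len: int = 1000
    min_identity: float = 0.90
    xdrop: int = 20
    max_copies: int = 50
    max_chroms: int = 3
    # wssd
    max_mismatches: int = 2
    window: int = 5000
    slide: int = 1000
    z: float = 3.0
    wssd_min_len: int = 10_000
    # combine
    cut: float = 0.94
    min_support: float = 0.5
    # enrich
    flank: int = 2_000_000
    short_chrom_flank: int = 300_000
    n_replicates: int = 10_000
    enrich_mode: str = "length"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidSpecError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# canonical fixtures


@dataclass
class Fixture:
    """In-memory canonical synthetic dataset with full ground truth."""

    spec: GenomeSpec
    reference: Dict[str, np.ndarray]
    donor: Dict[str, np.ndarray]
    truth: PlantedTruth
    repeats: pd.DataFrame
    reads: ReadSet
    genes: pd.DataFrame
    centromeres: Dict[str, int]

    def scored_truth_intervals(self) -> pd.DataFrame:
        """Reference intervals of genuine (non-artifact) planted SDs."""
        return self.truth.duplicated_intervals(labels=["scored"])


FIXTURE_SCALES = {
    # scale: (n chroms, chrom length, n scored events, depth)
    "small": (3, 350_000, 8, 20.0),
    "standard": (5, 1_000_000, 30, 20.0),
}


def build_fixture(scale: str = "standard", seed: int = 1) -> Fixture:
    """Construct the canonical synthetic dataset for the given scale.

    The standard fixture is a 5 Mb, 5-chromosome genome with 30 scored
    duplication events (lengths 1-50 kb, target identities 0.90-1.00, each
    confined to at most 2 chromosomes and carrying one donor-only extra
    copy that supplies read-depth support), one 60-copy family and one
    3-chromosome family planted as designed artifacts, a 200-copy masked
    repeat family, and 20x 36 bp reads from the donor.
    """
    if scale not in FIXTURE_SCALES:
        raise InvalidSpecError(
            f"unknown fixture scale {scale!r}; choose from "
            f"{sorted(FIXTURE_SCALES)}")
    n_chrom, clen, n_events, depth = FIXTURE_SCALES[scale]
    chrom_lengths = {f"chr{i + 1}": clen for i in range(n_chrom)}
    spec = GenomeSpec(chrom_lengths, gc_fraction=0.42,
                      seed=stage_seed(seed, "genome"))
    base = generate_reference(spec)
    rng = np.random.default_rng(stage_seed(seed, "events"))
    names = list(chrom_lengths)

    # masked common-repeat family first, so both the reference and the
    # donor inherit the same repeat landscape and events avoid it
    n_rep = 200 if scale == "standard" else 60
    base, repeats = plant_repeats(base, 300, n_rep, divergence=0.05,
                                  seed=stage_seed(seed, "repeats"))
    occupied: List[Tuple[str, int, int]] = [
        (r.chrom, int(r.start), int(r.end)) for r in repeats.itertuples()]
    events: List[DuplicationEvent] = []
    # scored duplication events
    min_l, max_l = (1000, 50_000) if scale == "standard" else (1000, 20_000)
    # longest events first so rejection placement stays feasible
    event_lengths = np.sort(rng.uniform(min_l, max_l,
                                        size=n_events).astype(int))[::-1]
    for i in range(n_events):
        length = int(event_lengths[i])
        identity = rng.uniform(0.90, 1.00)
        mode = ["tandem", "intrachromosomal", "interchromosomal"][i % 3]
        source = place_interval(rng, chrom_lengths, length, occupied,
                                gap=1500)
        copies, divs, in_ref = [], [], []
        if mode == "tandem":
            # directly downstream of the source when space allows
            c, s, e = source
            tstart = e + 20
            if tstart + length <= chrom_lengths[c] and not any(
                    c == oc and tstart - 1500 < oe and
                    tstart + length + 1500 > os_
                    for oc, os_, oe in occupied):
                cand = (c, tstart, tstart + length)
                occupied.append(cand)
                copies.append(cand)
            else:
                copies.append(place_interval(rng, chrom_lengths, length,
                                             occupied, chrom=c, gap=1500))
        elif mode == "intrachromosomal":
            copies.append(place_interval(rng, chrom_lengths, length,
                                         occupied, chrom=source[0],
                                         gap=1500))
        else:
            other = names[(names.index(source[0]) + 1 + i) % n_chrom]
            copies.append(place_interval(rng, chrom_lengths, length,
                                         occupied, chrom=other, gap=1500))
        divs.append(round(1.0 - identity, 4))
        in_ref.append(True)
        # a donor-only extra copy supplies the read-depth (CNV) support;
        # it is inserted into the donor genome, so the placeholder start
        # is immaterial
        copies.append((source[0], 0, length))
        divs.append(0.005)
        in_ref.append(False)
        events.append(DuplicationEvent(source, copies, divs, mode, in_ref,
                                       label="scored"))
    # designed artifacts: a 60-copy family (copy-count rule) ...
    fam_len = 1500
    fam_src = place_interval(rng, chrom_lengths, fam_len, occupied,
                             chrom=names[0], gap=500)
    fam_copies, fam_divs, fam_in_ref = [], [], []
    for j in range(59):
        c = names[j % 2]   # spread over exactly 2 chromosomes
        fam_copies.append(place_interval(rng, chrom_lengths, fam_len,
                                         occupied, chrom=c, gap=500))
        fam_divs.append(0.02)
        fam_in_ref.append(True)
    events.append(DuplicationEvent(fam_src, fam_copies, fam_divs,
                                   "intrachromosomal", fam_in_ref,
                                   label="artifact_high_copy"))
    # ... and a 3-chromosome family (chromosome-count rule)
    tri_len = 2000
    tri_src = place_interval(rng, chrom_lengths, tri_len, occupied,
                             chrom=names[0], gap=500)
    tri_copies = [
        place_interval(rng, chrom_lengths, tri_len, occupied,
                       chrom=names[1], gap=500),
        place_interval(rng, chrom_lengths, tri_len, occupied,
                       chrom=names[2 % n_chrom], gap=500),
    ]
    events.append(DuplicationEvent(tri_src, tri_copies, [0.03, 0.03],
                                   "interchromosomal", [True, True],
                                   label="artifact_multi_chrom"))

    reference, donor, truth = plant_duplications(
        base, events, seed=stage_seed(seed, "plant"))
    truth.repeat_elements = repeats

    reads = simulate_reads(donor, read_length=36, depth=depth,
                           error_rate=0.005,
                           seed=stage_seed(seed, "reads"))
    genes = _synthetic_genes(rng, chrom_lengths, truth)
    centromeres = {c: chrom_lengths[c] // 2 for c in chrom_lengths}
    return Fixture(spec, reference, donor, truth, repeats, reads, genes,
                   centromeres)


def _synthetic_genes(rng: np.random.Generator,
                     chrom_lengths: Dict[str, int],
                     truth: PlantedTruth) -> pd.DataFrame:
    """Random gene annotation, half inside planted SDs, half background."""
    dup = truth.duplicated_intervals(labels=["scored"])
    rows = []
    gid = 0
    for r in dup.itertuples():
        if r.end - r.start < 3000 or rng.random() < 0.5:
            continue
        glen = int(rng.integers(1000, min(5000, r.end - r.start)))
        s = int(rng.integers(r.start, r.end - glen + 1))
        rows.append((f"G{gid:04d}", r.chrom, s, s + glen,
                     "+" if rng.random() < 0.5 else "-"))
        gid += 1
    names = list(chrom_lengths)
    for _ in range(120):
        c = names[int(rng.integers(len(names)))]
        glen = int(rng.integers(1000, 5000))
        if chrom_lengths[c] <= glen:
            continue
        s = int(rng.integers(0, chrom_lengths[c] - glen))
        rows.append((f"G{gid:04d}", c, s, s + glen,
                     "+" if rng.random() < 0.5 else "-"))
        gid += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand"])


def make_fixture(outdir, scale: str = "standard", seed: int = 1) -> Fixture:
    """Write the canonical synthetic dataset to ``outdir``."""
    fx = build_fixture(scale, seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seqio.write_fasta(out / "reference.fa", fx.reference)
    seqio.write_fasta(out / "donor.fa", fx.donor)
    seqio.write_fastq(out / "reads.fastq", fx.reads.names(), fx.reads.seqs)
    seqio.write_bed(out / "repeats.bed", fx.repeats)
    fx.truth.to_json(out / "truth.json")
    seqio.write_bed(out / "truth_sd.bed", fx.scored_truth_intervals())
    fx.genes[["chrom", "start", "end", "gene_id", "strand"]].assign(
        score=0)[["chrom", "start", "end", "gene_id", "score", "strand"]
                 ].to_csv(out / "genes.bed", sep="\t", header=False,
                          index=False)
    pd.DataFrame(
        [(c, p) for c, p in fx.centromeres.items()],
        columns=["chrom", "centromere"],
    ).to_csv(out / "centromeres.tsv", sep="\t", index=False)
    return fx


# ---------------------------------------------------------------------------
# the full pipeline


def run_all(config: RunConfig,
            fixture: Optional[Fixture] = None) -> dict:
    """Execute every stage in order and return the run manifest.

    When ``fixture`` is given (or ``config.simulate_scale`` is set) the
    inputs come from the simulator; otherwise the configured input paths
    are read.  Outputs and the manifest land in ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    counts: Dict[str, int] = {}
    timings: Dict[str, float] = {}

    def _tick(stage, start):
        timings[stage] = round(time.time() - start, 2)

    # --- inputs / simulate
    t = time.time()
    if fixture is None and config.simulate_scale:
        fixture = make_fixture(out / "fixture", config.simulate_scale,
                               stage_seed(config.seed, "fixture"))
    if fixture is not None:
        reference = fixture.reference
        reads = fixture.reads
        repeats = fixture.repeats
        genes = fixture.genes
        centromeres = fixture.centromeres
    else:
        if not config.genome or not config.reads:
            raise InvalidSpecError("genome and reads paths are required "
                                   "when not simulating")
        reference = seqio.read_fasta(config.genome)
        names, mat = seqio.read_fastq(config.reads)
        chrom_names = list(reference)
        reads = ReadSet(read_length=mat.shape[1] if mat.size else 36,
                        depth=float("nan"), chrom_names=chrom_names,
                        chrom_idx=np.zeros(len(names), np.int32),
                        starts=np.zeros(len(names), np.int64), seqs=mat)
        if config.repeats:
            repeats = seqio.read_bed(config.repeats)
        else:
            import warnings
            warnings.warn("no repeat annotation: self-alignment runs "
                          "unmasked")
            repeats = iv.to_frame([])
        genes = None
        centromeres = {}
        if config.genes:
            genes, _ = gene_annot.read_genes(config.genes)
        if config.centromeres:
            cdf = pd.read_csv(config.centromeres, sep="\t")
            centromeres = dict(zip(cdf["chrom"], cdf["centromere"]))
    chrom_lengths = {c: len(a) for c, a in reference.items()}
    _tick("inputs", t)

    # --- wgac
    t = time.time()
    condensed, cmap = wgac_align.mask_and_excise(reference, repeats)
    initial = wgac_align.self_align(
        condensed, k=config.k, min_len=config.min_len,
        min_identity=config.min_identity, xdrop=config.xdrop,
        coord_map=cmap)
    cleaned = wgac_align.filter_high_copy(
        initial, max_copies=config.max_copies, max_chroms=config.max_chroms)
    counts["wgac_initial"] = len(initial)
    counts["wgac_cleaned"] = len(cleaned)
    initial.to_frame().to_csv(out / "wgac_initial.tsv", sep="\t",
                              index=False)
    cleaned.to_frame().to_csv(out / "wgac_alignments.tsv", sep="\t",
                              index=False)
    seqio.write_bed(out / "wgac_loci.bed", iv.merge(cleaned.loci()))
    _tick("wgac", t)

    # --- wssd
    t = time.time()
    placements = wssd_depth.place_reads(reads, reference,
                                        max_mismatches=config.max_mismatches)
    profile = wssd_depth.profile_depth(
        placements, reference, repeats, window=config.window,
        slide=config.slide, exclude=cleaned.loci())
    wssd = wssd_depth.call_wssd_intervals(profile, z=config.z,
                                          min_len=config.wssd_min_len)
    counts["reads_unmapped"] = placements.n_unmapped
    counts["wssd_intervals"] = len(wssd)
    profile.to_bedgraph_frame().to_csv(out / "depth.bedgraph", sep="\t",
                                       header=False, index=False)
    wssd.to_csv(out / "wssd.bed", sep="\t", header=False, index=False)
    _tick("wssd", t)

    # --- combine
    t = time.time()
    low, high = sd_combine.split_by_identity(cleaned, cut=config.cut)
    validated, artifactual = sd_combine.validate_high_identity(
        high, wssd, min_support=config.min_support)
    sd_map, summary, wssd_only = sd_combine.build_final_map(
        low, validated, wssd, chrom_lengths)
    counts["wgac_low"] = len(low)
    counts["wgac_high"] = len(high)
    counts["wgac_high_validated"] = len(validated)
    counts["sd_regions"] = len(sd_map)
    sd_map.to_csv(out / "sd_map.bed", sep="\t", header=False, index=False)
    wssd_only.to_csv(out / "wssd_only.bed", sep="\t", header=False,
                     index=False)
    with open(out / "sd_summary.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=1)
    _tick("combine", t)

    # --- enrich
    t = time.time()
    enrich_out = {}
    if len(sd_map) and centromeres:
        sub, peri = enrich_perm.build_landmarks(
            chrom_lengths, centromeres, flank=config.flank,
            short_chrom_flank=config.short_chrom_flank)
        for lm in (sub, peri):
            res = enrich_perm.empirical_enrichment(
                sd_map[["chrom", "start", "end"]], lm.intervals,
                mode=config.enrich_mode, n_replicates=config.n_replicates,
                seed=stage_seed(config.seed, f"enrich:{lm.name}"),
                chrom_lengths=chrom_lengths, check_replicates=False)
            enrich_out[lm.name] = res.to_dict()
    with open(out / "enrichment.json", "w") as fh:
        json.dump(enrich_out, fh, indent=1)
    counts["enrichment_tests"] = len(enrich_out)
    _tick("enrich", t)

    # --- genes
    t = time.time()
    if genes is not None and len(genes):
        in_sd = gene_annot.genes_in_sd(genes, sd_map)
        in_sd = in_sd.assign(
            copy_number=gene_annot.assign_gene_cn(in_sd, wssd))
        table = gene_annot.bin_gene_cn(in_sd["copy_number"])
        in_sd.to_csv(out / "genes_in_sd.tsv", sep="\t", index=False)
        table.to_csv(out / "cn_bins.tsv", sep="\t", index=False)
        counts["genes_in_sd"] = len(in_sd)
    _tick("genes", t)

    # --- manifest
    outputs = sorted(p for p in out.glob("**/*") if p.is_file()
                     and p.name != "manifest.json")
    checksums = {str(p.relative_to(out)): _sha256(p) for p in outputs}
    config_snapshot = config.to_dict()
    config_snapshot.pop("outdir")   # location metadata, not run content
    manifest = {
        "determinism": {
            "config": config_snapshot,
            "counts": counts,
            "output_checksums": checksums,
        },
        "timing": {"stages": timings,
                   "wall_time": round(time.time() - t0, 2)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
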