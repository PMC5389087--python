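"""Synthetic genomes with planted segmental duplications and reads.

The simulator emulates the study conditions every downstream stage is
validated against: a reference assembly containing dispersed and tandem
duplications of controlled length, identity and copy number, interspersed
high-copy repeat elements, and uniform-coverage short reads drawn from a
*donor* genome that may carry extra duplication copies absent from the
reference.  Donor-only copies are what create excess mapped read depth at
their reference source locus, the signal the read-depth (WSSD) detector
keys on.

Substitutions are the only mutation type, so per-copy divergence maps 1:1
to percent identity; every applied substitution is logged and the realized
identity of each copy is recorded in the ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InvalidSpecError, PlacementError
from .seqio import Genome
from . import intervals as iv

Interval = Tuple[str, int, int]

MIN_CHROM_LEN = 10_000
MIN_SOURCE_LEN = 200
MAX_DIVERGENCE = 0.12


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome lengths, GC fraction and the seed that fixes the genome."""

    chrom_lengths: Dict[str, int]
    gc_fraction: float = 0.42
    seed: int = 0

    def __post_init__(self):
        if not self.chrom_lengths:
            raise InvalidSpecError("at least one chromosome required")
        for name, length in self.chrom_lengths.items():
            if length < MIN_CHROM_LEN:
                raise InvalidSpecError(
                    f"chromosome {name!r} length {length} < {MIN_CHROM_LEN}")
        if not 0.0 < self.gc_fraction < 1.0:
            raise InvalidSpecError("gc_fraction must lie in (0, 1)")


@dataclass
class DuplicationEvent:
    """A source locus and the copies derived from it.

    ``divergence`` is the per-copy substitution proportion; ``in_reference``
    flags which copies are written into the reference assembly (the rest
    exist only in the donor genome and therefore only in the reads).
    """

    source: Interval
    copies: List[Interval]
    divergence: List[float]
    mode: str = "intrachromosomal"  # tandem | intrachromosomal | interchromosomal
    in_reference: List[bool] = field(default_factory=list)
    label: str = ""

    def __post_init__(self):
        n = len(self.copies)
        if isinstance(self.divergence, (int, float)):
            self.divergence = [float(self.divergence)] * n
        if not self.in_reference:
            self.in_reference = [True] * n
        if len(self.divergence) != n or len(self.in_reference) != n:
            raise InvalidSpecError("per-copy fields must match copy count")
        _, s, e = self.source
        if e - s < MIN_SOURCE_LEN:
            raise InvalidSpecError(
                f"source length {e - s} < minimum {MIN_SOURCE_LEN}")
        for d in self.divergence:
            if not 0.0 <= d <= MAX_DIVERGENCE:
                raise InvalidSpecError(
                    f"divergence {d} outside [0, {MAX_DIVERGENCE}]")
        for c, (_, cs, ce) in enumerate(self.copies):
            if ce - cs != e - s:
                raise InvalidSpecError(
                    f"copy {c} length {ce - cs} != source length {e - s}")


@dataclass
class CopyRecord:
    """Realized state of one planted copy (from the mutation log)."""

    interval: Interval
    in_reference: bool
    expected_identity: float
    realized_identity: float
    n_substitutions: int


@dataclass
class PlantedTruth:
    """Ground truth for a simulated genome."""

    events: List[DuplicationEvent]
    copy_records: List[List[CopyRecord]]
    repeat_elements: pd.DataFrame  # chrom, start, end, name

    def duplicated_intervals(self, labels: Optional[Sequence[str]] = None,
                             include_sources: bool = True,
                             reference_only: bool = True) -> pd.DataFrame:
        """All duplicated intervals (sources + copies) as a BED frame."""
        rows = []
        for ev, recs in zip(self.events, self.copy_records):
            if labels is not None and ev.label not in labels:
                continue
            if include_sources:
                rows.append(ev.source)
            for rec in recs:
                if reference_only and not rec.in_reference:
                    continue
                rows.append(rec.interval)
        return iv.to_frame(rows)

    def to_json(self, path) -> None:
        payload = {
            "events": [
                {
                    "source": list(ev.source),
                    "copies": [list(c) for c in ev.copies],
                    "divergence": ev.divergence,
                    "mode": ev.mode,
                    "in_reference": ev.in_reference,
                    "label": ev.label,
                    "copy_records": [
                        {
                            "interval": list(r.interval),
                            "in_reference": r.in_reference,
                            "expected_identity": r.expected_identity,
                            "realized_identity": r.realized_identity,
                            "n_substitutions": r.n_substitutions,
                        }
                        for r in recs
                    ],
                }
                for ev, recs in zip(self.events, self.copy_records)
            ],
            "repeat_elements": self.repeat_elements.to_dict("records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            payload = json.load(fh)
        events, records = [], []
        for e in payload["events"]:
            events.append(DuplicationEvent(
                source=tuple(e["source"]),
                copies=[tuple(c) for c in e["copies"]],
                divergence=list(e["divergence"]),
                mode=e["mode"],
                in_reference=list(e["in_reference"]),
                label=e.get("label", ""),
            ))
            records.append([
                CopyRecord(tuple(r["interval"]), r["in_reference"],
                           r["expected_identity"], r["realized_identity"],
                           r["n_substitutions"])
                for r in e["copy_records"]
            ])
        rep = payload["repeat_elements"]
        rep_df = (pd.DataFrame(rep) if rep
                  else iv.to_frame([], ("chrom", "start", "end")))
        return cls(events, records, rep_df)


@dataclass
class ReadSet:
    """Simulated single-end reads with their origin coordinates retained."""

    read_length: int
    depth: float
    chrom_names: List[str]
    chrom_idx: np.ndarray  # per read, index into chrom_names
    starts: np.ndarray     # per read, 0-based origin start
    seqs: np.ndarray       # n_reads x read_length uint8 codes

    @property
    def n_reads(self) -> int:
        return len(self.starts)

    def names(self) -> List[str]:
        return [
            f"r{i}|{self.chrom_names[self.chrom_idx[i]]}|{self.starts[i]}"
            for i in range(self.n_reads)
        ]


# ---------------------------------------------------------------------------


def event_true_copy_number(event: DuplicationEvent) -> float:
    """Absolute diploid-scaled copy number of an event's reference loci.

    With D loci in the donor (source + all copies) collapsing onto R loci
    in the reference (source + in-reference copies), each reference locus
    attracts D/R haploid read depth, i.e. absolute copy number 2 D / R.
    """
    d = 1 + len(event.copies)
    r = 1 + sum(event.in_reference)
    return 2.0 * d / r


def generate_reference(spec: GenomeSpec) -> Genome:
    """I.i.d. nucleotide sequence per chromosome at the requested GC."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome: Genome = {}
    for name, length in spec.chrom_lengths.items():
        genome[name] = rng.choice(4, size=length, p=p).astype(np.uint8)
    return genome


def _check_disjoint(intervals: List[Interval]) -> None:
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise PlacementError(
                    f"intervals collide on {chrom}: "
                    f"[{s1},{e1}) overlaps [{s2},{e2})")


def _mutate(seq: np.ndarray, divergence: float,
            rng: np.random.Generator) -> Tuple[np.ndarray, int]:
    """Apply i.i.d. substitutions at the given rate; returns (seq, count)."""
    out = seq.copy()
    if divergence <= 0:
        return out, 0
    hit = rng.random(len(seq)) < divergence
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n)) % 4
    return out, n


def plant_duplications(
    genome: Genome,
    events: List[DuplicationEvent],
    seed: int = 0,
) -> Tuple[Genome, Genome, PlantedTruth]:
    """Write duplication events into reference and donor genomes.

    Returns ``(reference, donor, truth)``.  Copies flagged ``in_reference``
    appear in both genomes at their stated intervals; donor-only copies are
    *inserted* into the donor (appended to their chromosome — the sequenced
    individual carries extra sequence), so reads drawn from the donor carry
    excess depth at the reference source locus.  The realized donor-space
    interval of every copy is recorded in the truth's copy records.  The
    input ``genome`` is not modified.
    """
    all_ivs: List[Interval] = []
    for ev in events:
        all_ivs.append(ev.source)
        for (chrom, s, e), in_ref in zip(ev.copies, ev.in_reference):
            if chrom not in genome:
                raise PlacementError(f"unknown chromosome {chrom!r}")
            if not in_ref:
                continue  # donor-only copies are insertions, checked below
            if not (0 <= s < e <= len(genome[chrom])):
                raise PlacementError(
                    f"copy [{s},{e}) outside chromosome {chrom}")
            all_ivs.append((chrom, s, e))
    _check_disjoint(all_ivs)

    reference = {name: arr.copy() for name, arr in genome.items()}
    # donor chromosomes grow: donor-only copies are appended as inserted
    # sequence (an individual carrying an extra copy has MORE sequence, it
    # does not lose the unique locus the placeholder coordinates point at)
    donor_parts: Dict[str, List[np.ndarray]] = {
        name: [arr.copy()] for name, arr in genome.items()}
    donor_len: Dict[str, int] = {n: len(a) for n, a in genome.items()}
    rng = np.random.default_rng(seed)
    copy_records: List[List[CopyRecord]] = []
    for ev in events:
        chrom, s, e = ev.source
        src = genome[chrom][s:e]
        recs = []
        for (cchrom, cs, ce), div, in_ref in zip(
                ev.copies, ev.divergence, ev.in_reference):
            mutated, n_sub = _mutate(src, div, rng)
            if in_ref:
                reference[cchrom][cs:ce] = mutated
                donor_parts[cchrom][0][cs:ce] = mutated
                realized_iv = (cchrom, cs, ce)
            else:
                start = donor_len[cchrom]
                donor_parts[cchrom].append(mutated)
                donor_len[cchrom] += len(mutated)
                realized_iv = (cchrom, start, start + len(mutated))
            recs.append(CopyRecord(
                interval=realized_iv,
                in_reference=bool(in_ref),
                expected_identity=1.0 - div,
                realized_identity=1.0 - n_sub / (ce - cs),
                n_substitutions=n_sub,
            ))
        copy_records.append(recs)
    donor = {name: np.concatenate(parts)
             for name, parts in donor_parts.items()}
    truth = PlantedTruth(events=list(events), copy_records=copy_records,
                         repeat_elements=iv.to_frame([]))
    return reference, donor, truth


def place_interval(rng: np.random.Generator, chrom_lengths: Dict[str, int],
                   length: int, occupied: List[Interval],
                   chrom: Optional[str] = None, gap: int = 0,
                   max_tries: int = 200) -> Interval:
    """Draw a random interval not overlapping ``occupied`` (± gap padding)."""
    names = list(chrom_lengths)
    weights = np.array([chrom_lengths[n] for n in names], dtype=float)
    weights /= weights.sum()
    for _ in range(max_tries):
        c = chrom if chrom is not None else names[rng.choice(len(names),
                                                             p=weights)]
        L = chrom_lengths[c]
        if L < length:
            continue
        s = int(rng.integers(0, L - length + 1))
        cand = (c, s, s + length)
        clash = any(c == oc and s - gap < oe and s + length + gap > os_
                    for oc, os_, oe in occupied)
        if not clash:
            occupied.append(cand)
            return cand
    raise PlacementError(
        f"could not place a {length} bp interval after {max_tries} tries")


def plant_repeats(
    genome: Genome,
    family_length: int,
    n_copies: int,
    divergence: float = 0.05,
    seed: int = 0,
    avoid: Optional[List[Interval]] = None,
    family_name: str = "REP1",
) -> Tuple[Genome, pd.DataFrame]:
    """Plant a dispersed high-copy repeat family; returns (genome, BED).

    The returned BED is the known-repeat mask consumed by the self-alignment
    stage.  Copies are dispersed over at least 3 chromosomes whenever the
    genome has that many.
    """
    if not 100 <= family_length <= 1000:
        raise InvalidSpecError("family_length must lie in [100, 1000]")
    if n_copies < 50:
        raise InvalidSpecError("a high-copy family needs n_copies >= 50")
    chrom_lengths = {n: len(a) for n, a in genome.items()}
    if sum(chrom_lengths.values()) < 3 * n_copies * family_length:
        raise PlacementError("genome too small to place all repeat copies")
    rng = np.random.default_rng(seed)
    consensus = rng.integers(0, 4, size=family_length).astype(np.uint8)
    out = {n: a.copy() for n, a in genome.items()}
    occupied: List[Interval] = list(avoid) if avoid else []
    rows = []
    for i in range(n_copies):
        chrom, s, e = place_interval(rng, chrom_lengths, family_length,
                                     occupied)
        mutated, _ = _mutate(consensus, divergence, rng)
        out[chrom][s:e] = mutated
        rows.append((chrom, s, e, family_name))
    bed = iv.to_frame(rows, ("chrom", "start", "end", "name"))
    n_chroms_hit = bed["chrom"].nunique()
    if len(genome) >= 3 and n_chroms_hit < 3:
        raise PlacementError(
            "repeat copies landed on fewer than 3 chromosomes; "
            "use a different seed or more copies")
    return out, bed


def simulate_reads(
    donor: Genome,
    read_length: int = 36,
    depth: float = 20.0,
    error_rate: float = 0.005,
    seed: int = 0,
) -> ReadSet:
    """Uniform-coverage error-bearing reads from the donor genome."""
    if depth <= 0:
        raise InvalidSpecError("depth must be positive")
    if not 0.0 <= error_rate <= 0.02:
        raise InvalidSpecError("error_rate must lie in [0, 0.02]")
    names = list(donor)
    lengths = np.array([len(donor[n]) for n in names], dtype=np.int64)
    if read_length > lengths.min():
        raise InvalidSpecError(
            "read_length exceeds the shortest chromosome")
    total = int(lengths.sum())
    n_reads = int(round(depth * total / read_length))
    rng = np.random.default_rng(seed)
    feasible = lengths - read_length + 1
    p = feasible / feasible.sum()
    chrom_idx = rng.choice(len(names), size=n_reads, p=p).astype(np.int32)
    starts = np.empty(n_reads, dtype=np.int64)
    seqs = np.empty((n_reads, read_length), dtype=np.uint8)
    offsets = np.arange(read_length)
    for ci, name in enumerate(names):
        sel = np.flatnonzero(chrom_idx == ci)
        if len(sel) == 0:
            continue
        st = rng.integers(0, feasible[ci], size=len(sel))
        starts[sel] = st
        seqs[sel] = donor[name][st[:, None] + offsets]
    if error_rate > 0:
        hit = rng.random(seqs.shape) < error_rate
        n = int(hit.sum())
        seqs[hit] = (seqs[hit] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return ReadSet(read_length=read_length, depth=depth, chrom_names=names,
                   chrom_idx=chrom_idx, starts=starts, seqs=seqs)
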