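"""Sequence and interval file I/O.

Genomes are held in memory as ``dict[str, numpy.ndarray]`` with one uint8
array per chromosome, bases encoded A=0, C=1, G=2, T=3.  All interval tables
are pandas DataFrames with 0-based half-open ``chrom``, ``start``, ``end``
columns (BED convention on disk and in memory).
"""

from __future__ import annotations

import io
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO as _BioSeqIO

Genome = Dict[str, np.ndarray]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

#: numeric code used for inter-chromosome sentinels in concatenated space
SENTINEL = 4
#: sentinel run length separating chromosomes (long enough that no local
#: alignment or read placement can bridge two chromosomes)
SENTINEL_RUN = 50


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string to a uint8 code array."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an ACGT string."""
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement a code array (sentinels map to themselves)."""
    out = np.where(codes == SENTINEL, SENTINEL, 3 - codes.astype(np.int16))
    return out[::-1].astype(np.uint8)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> Genome:
    genome: Genome = {}
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        genome[rec.id] = encode(str(rec.seq))
    return genome


def write_fasta(path, genome: Genome, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, codes in genome.items():
            fh.write(f">{name}\n")
            s = decode(codes)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width])
                fh.write("\n")


def write_fastq(path, names: Sequence[str], seqs: np.ndarray,
                qual_char: str = "I") -> None:
    """Write reads (n x L code matrix) as FASTQ with constant quality."""
    n, L = seqs.shape
    qual = qual_char * L
    with open(path, "w") as fh:
        buf = io.StringIO()
        for i in range(n):
            buf.write(f"@{names[i]}\n{decode(seqs[i])}\n+\n{qual}\n")
            if buf.tell() > 8 << 20:
                fh.write(buf.getvalue())
                buf = io.StringIO()
        fh.write(buf.getvalue())


def read_fastq(path) -> Tuple[List[str], np.ndarray]:
    """Read a constant-length FASTQ; returns (names, n x L code matrix)."""
    import pysam

    names: List[str] = []
    chunks: List[np.ndarray] = []
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            names.append(entry.name)
            chunks.append(entry.sequence.encode("ascii"))
    if not names:
        return [], np.empty((0, 0), dtype=np.uint8)
    raw = np.frombuffer(b"".join(chunks), dtype=np.uint8)
    L = len(chunks[0])
    mat = _CODE[raw].reshape(len(names), L)
    return names, mat


# ---------------------------------------------------------------------------
# BED / TSV

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = _BED_COLS[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(path, df: pd.DataFrame) -> None:
    cols = [c for c in _BED_COLS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# concatenated genome coordinate space


class ConcatGenome:
    """A genome concatenated into one array with sentinel separators.

    Used by the self-aligner and the read mapper so k-mer indexing and
    window extraction work on a single flat coordinate space.
    """

    def __init__(self, genome: Genome, sentinel_run: int = SENTINEL_RUN):
        self.names: List[str] = list(genome)
        parts = []
        offsets = []
        pos = 0
        sent = np.full(sentinel_run, SENTINEL, dtype=np.uint8)
        for name in self.names:
            offsets.append(pos)
            parts.append(genome[name])
            pos += len(genome[name])
            parts.append(sent)
            pos += sentinel_run
        self.seq = np.concatenate(parts) if parts else np.empty(0, np.uint8)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.lengths = np.asarray([len(genome[n]) for n in self.names],
                                  dtype=np.int64)
        self.ends = self.offsets + self.lengths

    def __len__(self) -> int:
        return len(self.seq)

    def chrom_index_of(self, pos: np.ndarray) -> np.ndarray:
        """Chromosome index for each flat position (-1 inside sentinels)."""
        pos = np.asarray(pos)
        idx = np.searchsorted(self.offsets, pos, side="right") - 1
        idx = np.clip(idx, 0, len(self.names) - 1)
        inside = (pos >= self.offsets[idx]) & (pos < self.ends[idx])
        return np.where(inside, idx, -1)

    def to_chrom(self, start: int, end: int) -> Tuple[str, int, int]:
        """Map a flat interval (within one chromosome) to (chrom, start, end)."""
        idx = int(np.searchsorted(self.offsets, start, side="right") - 1)
        if not (self.offsets[idx] <= start and end <= self.ends[idx]):
            raise ValueError(f"interval [{start},{end}) crosses chromosomes")
        off = int(self.offsets[idx])
        return self.names[idx], start - off, end - off


def kmer_codes(seq: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Base-5 k-mer codes of `seq` and a validity mask (no sentinel inside).

    Returns (codes[int64] of length n-k+1, valid[bool] same length).
    """
    n = len(seq)
    if n < k:
        return np.empty(0, np.int64), np.empty(0, bool)
    s = seq.astype(np.int64)
    codes = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        codes = codes * 5 + s[j : n - k + 1 + j]
    is_sent = (seq == SENTINEL).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(is_sent)])
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid
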