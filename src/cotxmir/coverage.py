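"""Strand-specific per-base read-end and whole-read coverage tracks.

NET-seq style analyses work on single-nucleotide resolution tracks: the 5'
end of a nascent read marks where sequencing started, its 3' end marks the
RNAPII position or — for processing by-products — the nucleotide right
before a DCL1 cut.  This module converts aligned reads (BED6 or BAM) into
sparse per-base tracks in ``five_prime``, ``three_prime`` or ``whole`` mode,
merges replicates by position-wise summation (bigWigMerge semantics), and
round-trips tracks through bedGraph text files.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ReadInterval",
    "CoverageTrack",
    "end_coverage",
    "merge_replicates",
    "read_bedgraph",
    "write_bedgraph",
    "load_reads_bed6",
    "write_reads_bed6",
    "load_reads_bam",
]

MODES = ("five_prime", "three_prime", "whole")

#: Sanity bounds on read length (configurable per call).
MIN_READ_LEN = 15
MAX_READ_LEN = 500


@dataclass(frozen=True)
class ReadInterval:
    """One aligned read as a genomic half-open interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"read interval must be non-empty: [{self.start}, {self.end})")


@dataclass
class CoverageTrack:
    """Sparse strand-specific per-base track.

    ``data`` maps chrom -> Counter(position -> value).  Counts are integers
    for single samples in end modes; ``whole`` mode and DRIP coverage may be
    float-valued.
    """

    mode: str
    strand: str
    data: dict[str, Counter] = field(default_factory=dict)
    n_rejected: int = 0

    def add(self, chrom: str, pos: int, value: float = 1) -> None:
        self.data.setdefault(chrom, Counter())[pos] += value

    def get(self, chrom: str, pos: int) -> float:
        return self.data.get(chrom, {}).get(pos, 0)

    def total(self) -> float:
        return sum(sum(c.values()) for c in self.data.values())

    def values_over(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base values over genomic [start, end); gaps are 0."""
        out = np.zeros(end - start, dtype=float)
        counter = self.data.get(chrom)
        if counter:
            if end - start < len(counter):
                for i, pos in enumerate(range(start, end)):
                    out[i] = counter.get(pos, 0)
            else:
                for pos, v in counter.items():
                    if start <= pos < end:
                        out[pos - start] = v
        return out

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            self.mode, self.strand, {c: Counter(cnt) for c, cnt in self.data.items()}, self.n_rejected
        )


def end_coverage(
    reads: Iterable[ReadInterval],
    mode: str,
    strand_select: str,
    min_len: int = MIN_READ_LEN,
    max_len: int = MAX_READ_LEN,
) -> CoverageTrack:
    """Per-base coverage of read 5' ends, 3' ends, or whole-read occupancy.

    For a plus-strand read [s, e) the 5' end is ``s`` and the 3' end is
    ``e - 1``; polarity is reversed on the minus strand.  Reads failing the
    length sanity bounds are rejected and counted in ``track.n_rejected``;
    reads on the non-selected strand are simply not part of this track.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    track = CoverageTrack(mode=mode, strand=strand_select)
    for r in reads:
        if r.strand != strand_select:
            continue
        length = r.end - r.start
        if length < min_len or length > max_len:
            track.n_rejected += 1
            continue
        if mode == "whole":
            for pos in range(r.start, r.end):
                track.add(r.chrom, pos)
        elif mode == "five_prime":
            track.add(r.chrom, r.start if r.strand == "+" else r.end - 1)
        else:  # three_prime
            track.add(r.chrom, r.end - 1 if r.strand == "+" else r.start)
    return track


def merge_replicates(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Position-wise sum of replicate tracks (bigWigMerge semantics)."""
    if len(tracks) < 1:
        raise ValueError("need at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        if t.mode != first.mode or t.strand != first.strand:
            raise ValueError("cannot merge tracks with different mode or strand")
    merged = first.copy()
    for t in tracks[1:]:
        for chrom, counter in t.data.items():
            dest = merged.data.setdefault(chrom, Counter())
            dest.update(counter)
        merged.n_rejected += t.n_rejected
    return merged


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------


def write_bedgraph(track: CoverageTrack, path: str | os.PathLike) -> None:
    """Write a track as bedGraph; intervals are maximal runs of equal value."""
    with open(path, "w") as fh:
        fh.write("track type=bedGraph\n")
        for chrom in sorted(track.data):
            counter = track.data[chrom]
            positions = sorted(p for p, v in counter.items() if v != 0)
            run_start = None
            run_val = None
            prev = None
            for pos in positions:
                val = counter[pos]
                if run_start is not None and pos == prev + 1 and val == run_val:
                    prev = pos
                    continue
                if run_start is not None:
                    fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{_fmt(run_val)}\n")
                run_start, run_val, prev = pos, val, pos
            if run_start is not None:
                fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{_fmt(run_val)}\n")


def _fmt(v) -> str:
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def read_bedgraph(path: str | os.PathLike, mode: str, strand: str) -> CoverageTrack:
    """Load a bedGraph into a sparse track; overlapping intervals are an error."""
    track = CoverageTrack(mode=mode, strand=strand)
    last_end: dict[str, int] = {}
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{ln}: malformed bedGraph line")
            chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            intervals.setdefault(chrom, []).append((s, e))
            if v == 0:
                continue
            counter = track.data.setdefault(chrom, Counter())
            value = int(v) if v.is_integer() else v
            for pos in range(s, e):
                counter[pos] += value
    for chrom, ivs in intervals.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"{path}: overlapping bedGraph intervals on {chrom}: "
                                 f"[{s1},{e1}) and [{s2},{e2})")
    _ = last_end
    return track


# ---------------------------------------------------------------------------
# read ingestion
# ---------------------------------------------------------------------------


def load_reads_bed6(path: str | os.PathLike) -> list[ReadInterval]:
    reads = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{ln}: BED6 requires 6 columns")
            reads.append(ReadInterval(f[0], int(f[1]), int(f[2]), f[5]))
    return reads


def write_reads_bed6(
    reads: Iterable[ReadInterval], path: str | os.PathLike, names: Iterable[str] | None = None
) -> None:
    names = iter(names) if names is not None else None
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            name = next(names) if names is not None else f"read{i}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")


def load_reads_bam(path: str | os.PathLike, min_mapq: int = 10) -> list[ReadInterval]:
    """Primary alignments from an indexed BAM; MAPQ-filtered.

    Paired-end data contribute the read-1 interval only (single-end interval
    model; documented limitation).
    """
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            if aln.is_paired and not aln.is_read1:
                continue
            strand = "-" if aln.is_reverse else "+"
            reads.append(ReadInterval(aln.reference_name, aln.reference_start, aln.reference_end, strand))
    return reads
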