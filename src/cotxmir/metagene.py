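"""Scale-regions metagene aggregation over MIRNA loci.

Loci differ in length, so per-locus signal windows are rescaled to a fixed
number of bins (deepTools ``computeMatrix --scale-regions`` behaviour: the
window is partitioned into contiguous near-equal segments and each bin takes
the mean per-base signal of its segment).  Flanks are unscaled at 1 bp/bin.
Rows are always oriented 5'→3' in transcript space, so minus-strand loci are
reversed before any aggregation, and profiles can be stratified by
processing direction or R-loop class.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import MirnaLocus, ScalingWindows, scaling_windows
from .coverage import CoverageTrack

__all__ = [
    "bin_values",
    "transcript_values",
    "scale_region",
    "profile_matrix",
    "aggregate_profile",
    "unscaled_anchor_profile",
    "filter_low_signal",
    "mean_signal",
]


def bin_values(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Partition per-base values into ``n_bins`` contiguous segments; bin = mean.

    Largest-remainder partition: segment lengths differ by at most one base
    and the longer segments come first, so a length-7 window at 3 bins uses
    the partition {3, 2, 2}.  Scaling to ``n_bins == len(values)`` is exact.
    """
    values = np.asarray(values, dtype=float)
    L = len(values)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if L < 1:
        raise ValueError("window must be non-empty")
    base, rem = divmod(L, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:rem] += 1
    if base == 0:
        # more bins than bases: empty segments inherit the nearest base value
        edges = np.minimum(np.cumsum(sizes) - sizes, L - 1)
        return values[edges]
    starts = np.cumsum(sizes) - sizes
    return np.add.reduceat(values, starts) / sizes


def transcript_values(
    track: CoverageTrack, locus: MirnaLocus, t_start: int, t_end: int
) -> np.ndarray:
    """Dense per-base signal over transcript window [t_start, t_end), 5'→3'.

    Transcript coordinates may extend beyond the annotated locus (flanks);
    they are mapped through the locus to genomic positions, and genomic
    positions without signal contribute 0.
    """
    if t_end <= t_start:
        raise ValueError("empty transcript window")
    if locus.strand == "+":
        g0 = locus.tss + t_start
        vals = track.values_over(locus.chrom, g0, g0 + (t_end - t_start))
        return vals
    g_hi = locus.tss - t_start + 1  # exclusive
    g_lo = locus.tss - t_end + 1
    vals = track.values_over(locus.chrom, g_lo, g_hi)
    return vals[::-1]


def scale_region(
    track: CoverageTrack, locus: MirnaLocus, window: tuple[int, int], n_bins: int
) -> np.ndarray:
    """Mean-binned signal over one transcript-space window."""
    return bin_values(transcript_values(track, locus, window[0], window[1]), n_bins)


def profile_matrix(
    track: CoverageTrack,
    loci: Sequence[MirnaLocus],
    windows: Mapping[str, ScalingWindows] | None = None,
    n_bins: int = 100,
    flank: int = 300,
    body: str = "hairpin",
) -> pd.DataFrame:
    """Scaled profile matrix: one row per locus, flank + body + flank columns.

    ``body`` selects the scaled window (``"hairpin"`` or ``"tss"``); flanks
    are unscaled 1-bp bins.  All rows are transcript-oriented, so column 0 is
    the most 5' flank base for every locus regardless of genomic strand.
    """
    rows = {}
    for locus in loci:
        sw = windows[locus.locus_id] if windows is not None else scaling_windows(locus, flank)
        win = sw.hairpin_window if body == "hairpin" else sw.tss_window
        up = transcript_values(track, locus, win[0] - flank, win[0]) if flank else np.empty(0)
        mid = scale_region(track, locus, win, n_bins)
        down = transcript_values(track, locus, win[1], win[1] + flank) if flank else np.empty(0)
        rows[locus.locus_id] = np.concatenate([up, mid, down])
    cols = (
        [f"u{i}" for i in range(flank)]
        + [f"b{i}" for i in range(n_bins)]
        + [f"d{i}" for i in range(flank)]
    )
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    mat.attrs.update({"mode": track.mode, "statistic": "mean", "n_bins": n_bins, "flank": flank, "body": body})
    return mat


def aggregate_profile(
    matrix: pd.DataFrame, groups: Mapping[str, str] | pd.Series | None = None
) -> dict[str, tuple[np.ndarray | None, int]]:
    """Column-wise mean profile per locus group.

    Returns ``{group: (mean_vector, n_loci)}``; an empty group yields
    ``(None, 0)`` explicitly rather than a vector of zeros.
    """
    if groups is None:
        groups = pd.Series("all", index=matrix.index)
    groups = pd.Series(groups)
    out: dict[str, tuple[np.ndarray | None, int]] = {}
    for g in sorted(set(groups.values)):
        ids = [i for i in matrix.index if groups.get(i) == g]
        if not ids:
            out[g] = (None, 0)
        else:
            out[g] = (matrix.loc[ids].to_numpy(dtype=float).mean(axis=0), len(ids))
    return out


def unscaled_anchor_profile(
    track: CoverageTrack, locus: MirnaLocus, anchor: str = "mir3p", flank: int = 50
) -> np.ndarray:
    """Fixed-width (no scaling) profile around a mature-miRNA interval.

    With ``anchor="mir3p"`` and a 3'-end track, a co-transcriptionally
    retained pre-miRNA or mature miR-3p shows a peak at the last nucleotide
    of miR-3p (index ``flank + len(mir3p) - 1`` in the returned vector).
    """
    iv = locus.mir3p_t if anchor == "mir3p" else locus.mir5p_t
    return transcript_values(track, locus, iv[0] - flank, iv[1] + flank)


def mean_signal(track: CoverageTrack, locus: MirnaLocus, window: tuple[int, int]) -> float:
    """Mean per-base signal over a transcript-space window."""
    return float(transcript_values(track, locus, window[0], window[1]).mean())


def filter_low_signal(
    loci: Iterable[MirnaLocus],
    whole_track: CoverageTrack,
    threshold: float = 10.0,
    windows: Mapping[str, ScalingWindows] | None = None,
) -> tuple[list[MirnaLocus], list[MirnaLocus]]:
    """Keep loci whose mean whole-read signal over the hairpin window exceeds
    ``threshold`` (strictly); returns (kept, dropped)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    kept, dropped = [], []
    for locus in loci:
        sw = windows[locus.locus_id] if windows is not None else scaling_windows(locus)
        if mean_signal(whole_track, locus, sw.hairpin_window) > threshold:
            kept.append(locus)
        else:
            dropped.append(locus)
    return kept, dropped
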