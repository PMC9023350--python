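"""Co-/post-transcriptional processing ratio and direction inference.

The central statistic: at the anchor junction "a" of each locus (the basal
DCL1 cut for base-to-loop loci, the first loop-proximal cut for loop-to-base
loci), nascent reads whose 3' end coincides with the cut are
co-transcriptional processing by-products, while reads spanning the junction
are unprocessed pri-miRNA.  Their ratio estimates how prone each locus is to
co-transcriptional processing — a relative, not absolute, measure, since
by-product stability and chromatin retention also shape the counts.

All counting runs in transcript coordinates on half-open read intervals
``[ts, te)``: a read "ends at" junction ``j`` when its 3'-most base is
``j - 1`` (``te == j``); it "spans" ``j`` when it covers both
junction-adjacent bases (``ts <= j - 1`` and ``te >= j + 1`` at the default
span margin of 1).  For loop-to-base loci, reads ending at any annotated
junction are excluded from the spanning denominator only, because internal
processing intermediates would otherwise inflate the unprocessed count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import CleavageMap, MirnaLocus
from .coverage import CoverageTrack, ReadInterval
from .metagene import transcript_values

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptReads",
    "reads_to_transcript",
    "count_ends_at",
    "count_spanning",
    "processing_ratio",
    "ProcessingRatioRecord",
    "ConditionDelta",
    "compare_conditions",
    "score_matrix",
    "infer_direction",
    "DirectionCall",
]

PREFERENCES = ("co", "equal", "post", "undetermined")


@dataclass
class TranscriptReads:
    """Reads of one locus in transcript coordinates (numpy arrays)."""

    ts: np.ndarray
    te: np.ndarray

    def __len__(self):
        return len(self.ts)


def _as_arrays(reads) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(reads, TranscriptReads):
        return reads.ts, reads.te
    if isinstance(reads, tuple) and len(reads) == 2 and isinstance(reads[0], np.ndarray):
        return reads
    arr = np.asarray([(a, b) for a, b in reads], dtype=int).reshape(-1, 2)
    return arr[:, 0], arr[:, 1]


def reads_to_transcript(reads: Iterable[ReadInterval], locus: MirnaLocus) -> TranscriptReads:
    """Strand- and chrom-matched reads converted to transcript intervals."""
    ts, te = [], []
    for r in reads:
        if r.chrom != locus.chrom or r.strand != locus.strand:
            continue
        a, b = locus.g2t_interval((r.start, r.end))
        ts.append(a)
        te.append(b)
    return TranscriptReads(np.asarray(ts, dtype=int), np.asarray(te, dtype=int))


def count_ends_at(reads, junction: int) -> int:
    """Number of reads whose 3'-most base is ``junction - 1``."""
    _, te = _as_arrays(reads)
    return int(np.count_nonzero(te == junction))


def count_spanning(
    reads,
    junction: int,
    span_margin: int = 1,
    exclude_ends_at: Iterable[int] | None = None,
) -> int:
    """Number of reads covering both sides of ``junction``.

    A read spans when it reaches at least ``span_margin`` bases on each side
    of the bond.  ``exclude_ends_at`` removes reads whose 3' end falls at any
    of the given junctions (used for L-type loci, where such reads are
    processing intermediates rather than unprocessed transcripts).
    """
    ts, te = _as_arrays(reads)
    mask = (ts <= junction - span_margin) & (te >= junction + span_margin)
    if exclude_ends_at:
        mask &= ~np.isin(te, np.fromiter(exclude_ends_at, dtype=int))
    return int(np.count_nonzero(mask))


@dataclass
class ProcessingRatioRecord:
    locus_id: str
    site_a: int
    n_end_at_a: int
    n_span_a: int
    ratio: float  # nan when undefined, inf when n_span_a == 0 with signal
    preference: str
    condition: str = ""
    direction: str = ""

    def as_dict(self) -> dict:
        return {
            "locus_id": self.locus_id,
            "direction": self.direction,
            "condition": self.condition,
            "site_a": self.site_a,
            "n_end_at_a": self.n_end_at_a,
            "n_span_a": self.n_span_a,
            "ratio": self.ratio,
            "preference": self.preference,
        }


def processing_ratio(
    reads,
    cmap: CleavageMap,
    min_reads: int = 10,
    delta_eq: float = 0.1,
    span_margin: int = 1,
    condition: str = "",
) -> ProcessingRatioRecord:
    """Co-/post-transcriptional processing ratio at the anchor site "a".

    ``ratio = n_end_at_a / n_span_a``.  Preference is ``co`` when ratio >
    ``1 + delta_eq``, ``post`` when ratio < ``1 - delta_eq`` and ``equal``
    in the band between; loci with fewer than ``min_reads`` informative
    reads at the site are ``undetermined``.  A locus with by-products but no
    spanning reads gets an infinite ratio and ``co`` preference (logged).
    """
    exclude = cmap.all_junctions if cmap.is_loop_first else None
    n_end = count_ends_at(reads, cmap.site_a)
    n_span = count_spanning(reads, cmap.site_a, span_margin=span_margin, exclude_ends_at=exclude)
    if n_end + n_span < max(min_reads, 1):
        ratio, pref = math.nan, "undetermined"
    elif n_span == 0:
        ratio, pref = math.inf, "co"
        logger.warning(
            "locus %s: %d reads end at site a but none span it; ratio is infinite",
            cmap.locus_id, n_end,
        )
    else:
        ratio = n_end / n_span
        pref = "co" if ratio > 1 + delta_eq else ("post" if ratio < 1 - delta_eq else "equal")
    return ProcessingRatioRecord(
        locus_id=cmap.locus_id,
        site_a=cmap.site_a,
        n_end_at_a=n_end,
        n_span_a=n_span,
        ratio=ratio,
        preference=pref,
        condition=condition,
        direction=cmap.direction,
    )


@dataclass
class ConditionDelta:
    locus_id: str
    ratio_ctrl: float
    ratio_treat: float
    relative_change: float
    changed: str  # up | down | unchanged | undetermined


def compare_conditions(
    records_ctrl: Sequence[ProcessingRatioRecord],
    records_treat: Sequence[ProcessingRatioRecord],
    threshold: float = 0.5,
) -> list[ConditionDelta]:
    """Per-locus ratio change between two conditions at a ±50% threshold.

    ``changed`` is ``up``/``down`` when |ratio_treat/ratio_ctrl - 1| >=
    ``threshold``; loci with undefined or infinite ratios in either
    condition are reported as ``undetermined``.
    """
    ctrl = {r.locus_id: r for r in records_ctrl}
    treat = {r.locus_id: r for r in records_treat}
    out = []
    for locus_id in sorted(set(ctrl) & set(treat)):
        rc, rt = ctrl[locus_id].ratio, treat[locus_id].ratio
        if not (math.isfinite(rc) and math.isfinite(rt)) or rc == 0:
            out.append(ConditionDelta(locus_id, rc, rt, math.nan, "undetermined"))
            continue
        rel = rt / rc - 1.0
        if rel >= threshold:
            changed = "up"
        elif rel <= -threshold:
            changed = "down"
        else:
            changed = "unchanged"
        out.append(ConditionDelta(locus_id, rc, rt, rel, changed))
    return out


def score_matrix(
    tracks: Mapping[str, CoverageTrack],
    regions: Sequence[tuple[MirnaLocus, tuple[int, int]]],
) -> pd.DataFrame:
    """Per-region mean signal for each track (multiBigwigSummary-style).

    ``regions`` are (locus, transcript-window) pairs; the result has one row
    per locus and one column per track name.
    """
    rows = {}
    for locus, window in regions:
        rows[locus.locus_id] = {
            name: float(transcript_values(tr, locus, window[0], window[1]).mean())
            for name, tr in tracks.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(tracks))


# ---------------------------------------------------------------------------
# direction inference
# ---------------------------------------------------------------------------


@dataclass
class DirectionCall:
    locus_id: str
    direction: str
    retention: bool
    evidence: dict = field(default_factory=dict)


def _peak_at(arr: np.ndarray, p: int, tau_abs: float, tau_fold: float, w: int) -> tuple[bool, float, float]:
    """Peak test at position p: count >= tau_abs and >= tau_fold * local
    background (mean over ±w excluding p).  Returns (is_peak, count, fold)."""
    if p < 0 or p >= len(arr):
        return False, 0.0, 0.0
    lo, hi = max(0, p - w), min(len(arr), p + w + 1)
    neigh = np.concatenate([arr[lo:p], arr[p + 1:hi]])
    bg = float(neigh.mean()) if len(neigh) else 0.0
    count = float(arr[p])
    fold = count / bg if bg > 0 else math.inf if count > 0 else 0.0
    return (count >= tau_abs and (bg == 0 or count >= tau_fold * bg)), count, fold


def _best_near(arr, p, tol, tau_abs, tau_fold, w):
    """Strongest passing peak within ±tol of the expected position p."""
    best = (False, 0.0, 0.0, p)
    for q in range(p - tol, p + tol + 1):
        ok, c, f = _peak_at(arr, q, tau_abs, tau_fold, w)
        if ok and c > best[1]:
            best = (ok, c, f, q)
    return best


def infer_direction(
    track_or_values,
    locus: MirnaLocus,
    tau_abs: float = 5.0,
    tau_fold: float = 4.0,
    w: int = 10,
    spacing: int = 21,
    spacing_tol: int = 2,
    max_seq_cuts: int = 3,
) -> DirectionCall:
    """Infer the processing direction from a 3'-end coverage track.

    Candidate peaks are evaluated one base 5' of each candidate junction:
    the basal cut (miR-5p start), the loop cut (miR-5p end), evenly spaced
    (21 ± 2 nt) sequential positions below the base or beyond the loop cut,
    and the mature miR-3p end (retention evidence only, never direction
    evidence).  A loop-cut peak calls an L-type locus (LTBs when sequential
    loop peaks are present), a basal-only peak calls BTL, a sub-basal peak
    on the 21-nt grid calls BTLs (B-type loci show only their first cut);
    conflicting loop-side and sub-basal evidence yields UNDEFINED with both
    scores reported.
    """
    if isinstance(track_or_values, CoverageTrack):
        arr = transcript_values(track_or_values, locus, 0, locus.transcript_length)
    else:
        arr = np.asarray(track_or_values, dtype=float)
    m5s, m5e = locus.mir5p_t
    m3s, m3e = locus.mir3p_t
    basal_p, loop_p, mature_p = m5s - 1, m5e - 1, m3e - 1

    basal = _peak_at(arr, basal_p, tau_abs, tau_fold, w)
    loop = _peak_at(arr, loop_p, tau_abs, tau_fold, w)
    mature = _peak_at(arr, mature_p, tau_abs, tau_fold, w)

    seq_basal = []
    for k in range(1, max_seq_cuts + 1):
        cand = basal_p - spacing * k
        if cand < 0:
            break
        ok, c, f, q = _best_near(arr, cand, spacing_tol, tau_abs, tau_fold, w)
        if ok:
            seq_basal.append((q, c, f))
    seq_loop = []
    for k in range(1, max_seq_cuts + 1):
        cand = loop_p + spacing * k
        if cand >= m3s - 1 or abs(cand - mature_p) <= spacing_tol:
            break
        ok, c, f, q = _best_near(arr, cand, spacing_tol, tau_abs, tau_fold, w)
        if ok:
            seq_loop.append((q, c, f))

    evidence = {
        "basal": {"pos": basal_p, "peak": basal[0], "count": basal[1], "fold": basal[2]},
        "loop": {"pos": loop_p, "peak": loop[0], "count": loop[1], "fold": loop[2]},
        "mature_3p": {"pos": mature_p, "peak": mature[0], "count": mature[1], "fold": mature[2]},
        "sequential_basal": seq_basal,
        "sequential_loop": seq_loop,
    }

    # Signatures: L-type loci are processed fully co-transcriptionally, so
    # the loop cut (and for LTBs the sequential loop-region cuts) leaves
    # peaks; B-type loci show only their first cut — the basal cut for BTL,
    # a sub-basal cut on the ~21-nt grid for BTLs.
    if loop[0] and seq_basal:
        direction = "UNDEFINED"  # conflicting loop-side and sub-basal evidence
    elif loop[0]:
        direction = "LTBs" if seq_loop else "LTB"
    elif seq_basal:
        direction = "BTLs"
    elif basal[0]:
        direction = "BTL"
    else:
        direction = "UNDEFINED"
    return DirectionCall(locus.locus_id, direction, retention=mature[0], evidence=evidence)
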