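"""Strand-specific R-loop (ssDRIP-seq) profiling over MIRNA loci.

R-loops are three-stranded DNA:RNA hybrids; in plants they are frequent
near transcription start sites, often driven by antisense transcription.
Strand-specific DRIP coverage is profiled over three transcript-space
windows per locus — the TSS→miR-5p arm, the hairpin body, and the 3' tail
(hairpin end → transcript end) — on the sense and antisense strand relative
to the locus, normalized to the genome-wide median per-base signal of each
DRIP strand.  Loci are then sorted into five archetypes:

* ``alpha``   — no R-loops;
* ``beta``    — R-loops confined to the 5' ssRNA arm near the TSS;
* ``gamma``   — bipartite signal at the beginning and the end of the locus;
* ``delta``   — R-loops extending uniformly over the entire locus;
* ``epsilon`` — colliding R-loops: sense signal weighted to the 3' half
  against antisense signal weighted to the 5' half.

The published taxonomy is a visual sort; the thresholds here
(``kappa_present`` fold-over-background, ``uniform_frac`` body coverage,
half-split centroids for collisions) are this module's deterministic
operationalization and are fully configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import CleavageMap, MirnaLocus, ScalingWindows, scaling_windows
from .coverage import CoverageTrack
from .metagene import transcript_values
from .processing import ProcessingRatioRecord, _peak_at

__all__ = [
    "RCLASSES",
    "RloopProfileRecord",
    "strand_split_drip",
    "track_background",
    "window_means",
    "classify_rloop",
    "ratio_by_class",
    "locus_report",
]

RCLASSES = ("alpha", "beta", "gamma", "delta", "epsilon")
WINDOW_NAMES = ("tss", "body", "tail")


def strand_split_drip(
    fwd: CoverageTrack, rev: CoverageTrack, locus: MirnaLocus
) -> tuple[CoverageTrack, CoverageTrack]:
    """(sense, antisense) DRIP tracks relative to the locus strand.

    Pure relabeling: the forward-strand track is sense for a plus-strand
    locus and antisense for a minus-strand locus.
    """
    return (fwd, rev) if locus.strand == "+" else (rev, fwd)


def track_background(track: CoverageTrack) -> float:
    """Genome-wide median per-base signal of a DRIP strand.

    The median is taken over all covered bases (bases with recorded
    signal); enriched regions are a small minority of the covered genome,
    so the median is robust to R-loop peaks.
    """
    vals = [v for counter in track.data.values() for v in counter.values()]
    if not vals:
        return math.nan
    return float(np.median(np.asarray(vals, dtype=float)))


@dataclass
class RloopProfileRecord:
    """Windowed background-normalized DRIP means and the assigned class."""

    locus_id: str
    means: dict  # (window, strand_label) -> fold over background
    body_profile: dict  # strand_label -> per-base fold-over-background array
    centroid: dict  # strand_label -> centroid of full profile in [0, 1]
    background: tuple[float, float]  # (sense, antisense) background
    rclass: str | None = None
    margins: dict = field(default_factory=dict)


def _windows3(locus: MirnaLocus, sw: ScalingWindows) -> dict[str, tuple[int, int]]:
    T = locus.transcript_length
    m3e = sw.hairpin_window[1]
    tail = (m3e, T) if T > m3e else (m3e, m3e + 1)
    return {"tss": sw.tss_window, "body": sw.hairpin_window, "tail": tail}


def window_means(
    sense: CoverageTrack,
    antisense: CoverageTrack,
    locus: MirnaLocus,
    windows: ScalingWindows | None = None,
    background: tuple[float, float] | None = None,
    flank: int = 300,
) -> RloopProfileRecord:
    """Per-window, per-strand mean DRIP signal in fold-over-background units."""
    sw = windows or scaling_windows(locus, flank)
    w3 = _windows3(locus, sw)
    if background is None:
        background = (track_background(sense), track_background(antisense))
    bg_s, bg_a = background
    if not (bg_s > 0) or not (bg_a > 0):
        raise ValueError(f"locus {locus.locus_id}: non-positive DRIP background {background}")
    means: dict = {}
    body_profile: dict = {}
    centroid: dict = {}
    T = locus.transcript_length
    for label, track, bg in (("sense", sense, bg_s), ("antisense", antisense, bg_a)):
        for wname, (a, b) in w3.items():
            means[(wname, label)] = float(transcript_values(track, locus, a, b).mean()) / bg
        body = transcript_values(track, locus, *sw.hairpin_window) / bg
        body_profile[label] = body
        full = transcript_values(track, locus, -flank, T + flank) / bg
        total = full.sum()
        centroid[label] = float((np.arange(len(full)) * full).sum() / total / len(full)) if total > 0 else 0.5
    return RloopProfileRecord(
        locus_id=locus.locus_id,
        means=means,
        body_profile=body_profile,
        centroid=centroid,
        background=background,
    )


def classify_rloop(
    record: RloopProfileRecord,
    kappa_present: float = 2.0,
    uniform_frac: float = 0.8,
) -> str:
    """Assign one of the five R-loop archetypes by a deterministic rule order.

    A window is "present" on a strand when its background-normalized mean is
    at least ``kappa_present``.  Rules are tried in order ε → δ → γ → β → α,
    so every record receives exactly one class.  Classification is
    scale-invariant because all means are fold-over-background.
    """
    m = record.means

    def present(w, s):
        return m[(w, s)] >= kappa_present

    sense_any = any(present(w, "sense") for w in WINDOW_NAMES)
    anti_any = any(present(w, "antisense") for w in WINDOW_NAMES)

    # colliding R-loops must actually meet over the locus body: opposing
    # strands on opposite halves with at least one strand present mid-locus
    # (distinguishes a collision from disjoint 5'/3' bumps, i.e. gamma)
    if (
        sense_any
        and anti_any
        and (present("body", "sense") or present("body", "antisense"))
        and record.centroid["sense"] > 0.5
        and record.centroid["antisense"] < 0.5
    ):
        rclass = "epsilon"
    elif any(
        present("tss", s) and present("body", s) and present("tail", s)
        and float(np.mean(record.body_profile[s] >= kappa_present)) >= uniform_frac
        for s in ("sense", "antisense")
    ):
        rclass = "delta"
    elif (
        (present("tss", "sense") or present("tss", "antisense"))
        and (present("tail", "sense") or present("tail", "antisense"))
        and not present("body", "sense")
        and not present("body", "antisense")
    ):
        rclass = "gamma"
    elif (present("tss", "sense") or present("tss", "antisense")) and not any(
        present(w, s) for w in ("body", "tail") for s in ("sense", "antisense")
    ):
        rclass = "beta"
    else:
        rclass = "alpha"
    record.rclass = rclass
    record.margins = {
        f"{w}_{s}": m[(w, s)] - kappa_present for w in WINDOW_NAMES for s in ("sense", "antisense")
    }
    return rclass


def ratio_by_class(
    records: Sequence[RloopProfileRecord],
    ratios: Sequence[ProcessingRatioRecord],
    grouping: Mapping[str, tuple[str, ...]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Processing ratios grouped by R-loop class, with Welch t-tests.

    Default groups follow the published comparison: ``alpha`` vs
    ``beta+gamma`` vs ``delta+epsilon``.  Tests are two-tailed unpaired
    Welch t-tests on log-ratios (loci with undefined, infinite or zero
    ratios are excluded from testing and counted in the summary).  Groups
    with fewer than two usable loci get an undefined p-value (NaN).
    """
    if grouping is None:
        grouping = {
            "alpha": ("alpha",),
            "beta+gamma": ("beta", "gamma"),
            "delta+epsilon": ("delta", "epsilon"),
        }
    cls = {r.locus_id: r.rclass for r in records}
    values: dict[str, list[float]] = {g: [] for g in grouping}
    n_total: dict[str, int] = {g: 0 for g in grouping}
    for rec in ratios:
        rc = cls.get(rec.locus_id)
        for g, members in grouping.items():
            if rc in members:
                n_total[g] += 1
                if math.isfinite(rec.ratio) and rec.ratio > 0:
                    values[g].append(rec.ratio)
    summary_rows = []
    for g in grouping:
        v = np.asarray(values[g], dtype=float)
        summary_rows.append(
            {
                "group": g,
                "n_loci": n_total[g],
                "n_used": len(v),
                "median": float(np.median(v)) if len(v) else math.nan,
                "q1": float(np.percentile(v, 25)) if len(v) else math.nan,
                "q3": float(np.percentile(v, 75)) if len(v) else math.nan,
                "mean": float(v.mean()) if len(v) else math.nan,
            }
        )
    summary = pd.DataFrame(summary_rows).set_index("group")
    test_rows = []
    names = list(grouping)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.log(values[names[i]]) if values[names[i]] else np.empty(0)
            b = np.log(values[names[j]]) if values[names[j]] else np.empty(0)
            if len(a) >= 2 and len(b) >= 2:
                t, p = stats.ttest_ind(a, b, equal_var=False)
            else:
                t, p = math.nan, math.nan
            test_rows.append(
                {"group_a": names[i], "group_b": names[j], "t": float(t), "p_value": float(p)}
            )
    tests = pd.DataFrame(test_rows)
    return summary, tests


def locus_report(
    locus: MirnaLocus,
    cmap: CleavageMap,
    net_3p: CoverageTrack,
    drip_fwd: CoverageTrack,
    drip_rev: CoverageTrack,
    flank: int = 300,
    tau_abs: float = 5.0,
    tau_fold: float = 4.0,
    w: int = 10,
) -> pd.DataFrame:
    """Joint per-base NET-seq 3'-end and strand-specific DRIP table for one
    locus, with junction annotations and co-processing evidence.

    Works for independent, intronic and polycistron-member loci alike (the
    coordinate frame is the locus transcript; host context is carried in the
    table attrs).  Returns an empty frame (with columns) for empty tracks.
    """
    T = locus.transcript_length
    sense, antisense = strand_split_drip(drip_fwd, drip_rev, locus)
    net = transcript_values(net_3p, locus, -flank, T + flank)
    ds = transcript_values(sense, locus, -flank, T + flank)
    da = transcript_values(antisense, locus, -flank, T + flank)
    t_pos = np.arange(-flank, T + flank)
    g_pos = np.array([locus.t2g(t) for t in t_pos])
    junctions = {j: idx for idx, j in enumerate(cmap.junctions_5arm + cmap.junctions_3arm)}
    cut_index = np.full(len(t_pos), -1, dtype=int)
    for j, idx in junctions.items():
        # a junction annotates the base just 5' of the bond
        k = (j - 1) + flank
        if 0 <= k < len(cut_index):
            cut_index[k] = idx
    df = pd.DataFrame(
        {
            "t_pos": t_pos,
            "g_pos": g_pos,
            "net_3p_ends": net,
            "drip_sense": ds,
            "drip_antisense": da,
            "cut_index": cut_index,
        }
    )
    if net.sum() == 0 and ds.sum() == 0 and da.sum() == 0:
        df = df.iloc[0:0]
    arr = transcript_values(net_3p, locus, 0, T) if net.sum() > 0 else np.zeros(T)
    site_peak = _peak_at(arr, cmap.site_a - 1, tau_abs, tau_fold, w)
    df.attrs.update(
        {
            "locus_id": cmap.locus_id,
            "host_context": locus.host_context,
            "direction": cmap.direction,
            "site_a": cmap.site_a,
            "co_processing_evidence": bool(site_peak[0]),
            "site_a_count": site_peak[1],
        }
    )
    return df
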