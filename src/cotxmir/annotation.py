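"""MIRNA locus annotations, DCL1 cleavage junctions and metagene scaling windows.

A plant *MIRNA* gene is transcribed by RNAPII as a pri-miRNA: a capped,
polyadenylated transcript carrying a hairpin from which DICER-LIKE 1 (DCL1)
excises the mature miRNA-5p/miRNA-3p duplex.  Depending on the locus, DCL1
starts cutting at the base of the hairpin and proceeds toward the loop
(base-to-loop, ``BTL``; sequential multi-cut variant ``BTLs``) or starts near
the terminal loop and proceeds toward the base (loop-to-base, ``LTB`` /
``LTBs``).  Each cut leaves a diagnostic junction whose flanking nucleotides
are directly observable as read ends in nascent-transcript (NET-seq) data.

This module loads miRBase-dialect GFF3 annotations plus a TSV sidecar (TSS,
processing direction, optional extra junctions, host context), validates
them, and derives per-locus :class:`CleavageMap` and :class:`ScalingWindows`
objects that downstream counting and metagene code consumes.

Coordinate conventions
----------------------
Genomic coordinates are 0-based half-open throughout (GFF3's 1-based closed
intervals are converted at the parsing boundary).  Every analysis runs in
*transcript* coordinates: position 0 is the TSS and positions increase 5'→3'
along the transcript regardless of genomic strand.  A junction index ``j``
names the phosphodiester bond between transcript positions ``j-1`` and ``j``.
DCL1's 2-nt 3' overhangs are ignored: junctions sit exactly at annotated
mature-miRNA boundaries, which is where the observed read-end peaks anchor.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DIRECTIONS",
    "MirnaLocus",
    "CleavageMap",
    "ScalingWindows",
    "ValidationFailure",
    "AnnotationSet",
    "load_annotations",
    "derive_cleavage_map",
    "derive_cleavage_maps",
    "scaling_windows",
    "write_gff3",
    "write_sidecar",
    "write_annotation_tsv",
    "write_junction_bed",
]

#: Recognized processing-direction labels.
DIRECTIONS = ("BTL", "BTLs", "LTB", "LTBs", "DUAL", "UNDEFINED")

HOST_CONTEXTS = ("independent", "intronic", "polycistron-member")

#: Default spacing between sequential DCL1 cuts (nt) used when a BTLs/LTBs
#: locus has no explicit extra junctions in the sidecar; one extra cut is
#: assumed.  21 nt is the DCL1 step size.
DEFAULT_CUT_SPACING = 21
DEFAULT_EXTRA_CUTS = 1

#: Default unscaled flank added around scaling windows (bp).
DEFAULT_FLANK = 300


class AnnotationError(ValueError):
    """Hard error while loading annotations (e.g. a locus without a TSS)."""


@dataclass(frozen=True)
class MirnaLocus:
    """Genomic model of one MIRNA gene.

    ``tss`` is the genomic position of the first transcribed base.  On the
    minus strand the transcript runs genomically downhill, so ``tss`` is the
    *largest* coordinate of the locus and ``locus_end`` is one below the
    genomically smallest transcribed base (i.e. exclusive in the transcript
    direction).  ``mir5p``/``mir3p`` are genomic half-open intervals with
    ``start < end`` regardless of strand.
    """

    locus_id: str
    chrom: str
    strand: str
    tss: int
    locus_end: int
    mir5p: tuple[int, int]
    mir3p: tuple[int, int]
    direction: str
    extra_junctions: tuple[int, ...] | None = None
    host_context: str = "independent"

    # -- coordinate transforms ------------------------------------------------

    @property
    def transcript_length(self) -> int:
        return (self.locus_end - self.tss) if self.strand == "+" else (self.tss - self.locus_end)

    def g2t(self, pos: int) -> int:
        """Genomic base position -> transcript base position."""
        return pos - self.tss if self.strand == "+" else self.tss - pos

    def t2g(self, t: int) -> int:
        """Transcript base position -> genomic base position."""
        return self.tss + t if self.strand == "+" else self.tss - t

    def g2t_interval(self, iv: tuple[int, int]) -> tuple[int, int]:
        """Genomic half-open interval -> transcript half-open interval."""
        s, e = iv
        if self.strand == "+":
            return s - self.tss, e - self.tss
        return self.tss - e + 1, self.tss - s + 1

    def t2g_interval(self, iv: tuple[int, int]) -> tuple[int, int]:
        ts, te = iv
        if self.strand == "+":
            return self.tss + ts, self.tss + te
        return self.tss - te + 1, self.tss - ts + 1

    # -- convenience transcript-space anchors ---------------------------------

    @property
    def mir5p_t(self) -> tuple[int, int]:
        return self.g2t_interval(self.mir5p)

    @property
    def mir3p_t(self) -> tuple[int, int]:
        return self.g2t_interval(self.mir3p)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if self.strand not in ("+", "-"):
            problems.append(f"invalid strand {self.strand!r}")
            return problems
        if self.direction not in DIRECTIONS:
            problems.append(f"unknown direction label {self.direction!r}")
        if self.host_context not in HOST_CONTEXTS:
            problems.append(f"unknown host_context {self.host_context!r}")
        if self.transcript_length <= 0:
            problems.append("locus_end does not lie downstream of tss")
            return problems
        m5s, m5e = self.mir5p_t
        m3s, m3e = self.mir3p_t
        if not (0 < m5s < m5e <= m3s < m3e <= self.transcript_length):
            if m5e > m3s:
                problems.append("mir5p and mir3p overlap or are mis-ordered")
            else:
                problems.append(
                    "tss < mir5p <= mir3p <= locus_end ordering violated in transcript space"
                )
        for name, (a, b) in (("mir5p", (m5s, m5e)), ("mir3p", (m3s, m3e))):
            if not (19 <= b - a <= 25):
                problems.append(f"{name} length {b - a} outside 19-25 nt")
        if self.extra_junctions is not None and len(self.extra_junctions) > 0:
            tj = sorted(self.g2t(p) for p in self.extra_junctions)
            if len(set(tj)) != len(tj):
                problems.append("extra_junctions are not strictly ordered along the transcript")
            if self.direction == "BTLs" and not all(t < m5s for t in tj):
                problems.append("BTLs extra_junctions must lie below the hairpin base (before miR-5p)")
            if self.direction == "LTBs" and not all(m5e < t < m3s for t in tj):
                problems.append("LTBs extra_junctions must lie in the loop-proximal region")
        return problems


@dataclass(frozen=True)
class CleavageMap:
    """Ordered DCL1 cut junctions for one locus, in transcript coordinates.

    ``junctions_5arm`` lists the 5'-arm junctions in processing order (the
    first DCL1 cut first); ``site_a`` is the ratio anchor: the basal cut for
    B-type loci, the loop-proximal first cut for L-type loci.  ``pre_mirna``
    is the hairpin interval released by the basal cut and ``mature_3p_end``
    the bond just past the last nucleotide of miR-3p (where retained
    pre-miRNAs and retained mature miR-3p species leave a 3'-end peak).
    """

    locus_id: str
    direction: str
    junctions_5arm: tuple[int, ...]
    junctions_3arm: tuple[int, ...]
    site_a: int
    pre_mirna: tuple[int, int]
    mature_3p_end: int

    @property
    def all_junctions(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.junctions_5arm) | set(self.junctions_3arm)))

    @property
    def is_loop_first(self) -> bool:
        """True for loop-to-base (L-type) processing."""
        return self.direction in ("LTB", "LTBs")


@dataclass(frozen=True)
class ScalingWindows:
    """Transcript-space windows used by scale-regions metagene analysis.

    ``tss_window`` runs from the TSS to the nucleotide before miR-5p;
    ``hairpin_window`` from miR-5p start (or the first DCL1 cut, for BTLs)
    to the end of miR-3p.  ``flank`` is the unscaled padding in bp.
    """

    locus_id: str
    tss_window: tuple[int, int]
    hairpin_window: tuple[int, int]
    flank: int = DEFAULT_FLANK


@dataclass(frozen=True)
class ValidationFailure:
    locus_id: str
    reasons: tuple[str, ...]


@dataclass
class AnnotationSet:
    """Validated loci plus explicitly reported validation failures."""

    loci: list[MirnaLocus] = field(default_factory=list)
    failures: list[ValidationFailure] = field(default_factory=list)

    def __iter__(self):
        return iter(self.loci)

    def __len__(self):
        return len(self.loci)

    def by_id(self) -> dict[str, MirnaLocus]:
        return {loc.locus_id: loc for loc in self.loci}


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _read_sidecar(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str})
    required = {"locus_id", "tss", "direction"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"sidecar {path} missing required columns: {sorted(missing)}")
    if "extra_junctions" not in df.columns:
        df["extra_junctions"] = None
    if "host_context" not in df.columns:
        df["host_context"] = "independent"
    return df.set_index("locus_id")


def _parse_extra(value) -> tuple[int, ...] | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "" or pd.isna(value):
        return None
    return tuple(int(x) for x in str(value).split(","))


def load_annotations(gff3_path: str | os.PathLike, sidecar_path: str | os.PathLike) -> AnnotationSet:
    """Load and validate MIRNA loci from GFF3 (miRBase dialect) + TSV sidecar.

    The GFF3 must contain ``miRNA_primary_transcript`` features with child
    ``miRNA`` features (linked by ``Derives_from``).  The sidecar supplies
    the TSS, the processing direction, optional extra cleavage junctions
    (comma-separated genomic positions) and the host context.

    Loci that fail validation are returned in ``AnnotationSet.failures``
    with their reasons, never silently dropped.  A locus missing from the
    sidecar (no TSS) is a hard error.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    sidecar = _read_sidecar(sidecar_path)

    # miRBase links mature miRNAs to their precursor with Derives_from
    matures_by_parent: dict[str, list] = {}
    for m in db.features_of_type("miRNA"):
        for parent in m.attributes.get("Derives_from", []):
            matures_by_parent.setdefault(parent, []).append(m)

    out = AnnotationSet()
    for pt in db.features_of_type("miRNA_primary_transcript"):
        locus_id = pt.attributes.get("Name", [pt.id])[0]
        if locus_id not in sidecar.index:
            raise AnnotationError(f"locus {locus_id!r}: no sidecar entry (missing TSS)")
        row = sidecar.loc[locus_id]
        tss = row["tss"]
        if pd.isna(tss):
            raise AnnotationError(f"locus {locus_id!r}: TSS is missing in sidecar")
        tss = int(tss)
        strand = pt.strand
        # GFF3 1-based closed -> 0-based half-open
        fs, fe = pt.start - 1, pt.end
        matures = matures_by_parent.get(pt.id, []) or matures_by_parent.get(locus_id, [])
        if len(matures) != 2:
            out.failures.append(ValidationFailure(locus_id, (f"expected 2 mature miRNAs, found {len(matures)}",)))
            continue
        ivs = sorted((m.start - 1, m.end) for m in matures)
        if strand == "+":
            mir5p, mir3p = ivs[0], ivs[1]
            locus_end = max(fe, mir3p[1])
        else:
            mir5p, mir3p = ivs[1], ivs[0]  # 5p is nearer the (high-coordinate) TSS
            locus_end = min(fs, mir3p[0]) - 1
        locus = MirnaLocus(
            locus_id=locus_id,
            chrom=pt.seqid,
            strand=strand,
            tss=tss,
            locus_end=locus_end,
            mir5p=tuple(mir5p),
            mir3p=tuple(mir3p),
            direction=str(row["direction"]),
            extra_junctions=_parse_extra(row["extra_junctions"]),
            host_context=str(row["host_context"]) if not pd.isna(row["host_context"]) else "independent",
        )
        problems = locus.validate()
        if problems:
            out.failures.append(ValidationFailure(locus_id, tuple(problems)))
        else:
            out.loci.append(locus)
    return out


# ---------------------------------------------------------------------------
# cleavage maps
# ---------------------------------------------------------------------------


def derive_cleavage_map(
    locus: MirnaLocus,
    direction: str | None = None,
    allow_default_spacing: bool = True,
    locus_id: str | None = None,
) -> CleavageMap:
    """Place DCL1 cut junctions for one locus in transcript coordinates.

    Junction placement follows the processing direction:

    * ``BTL`` — one basal cut at the miR-5p start; ``site_a`` is that cut.
    * ``LTB`` — loop cut at the miR-5p end first, then the basal cut;
      ``site_a`` is the loop cut (the first cut toward the loop region).
    * ``BTLs`` — sequential cuts below the hairpin base preceding the basal
      cut; ``site_a`` is the most 5'-distal (first) cut.
    * ``LTBs`` — sequential cuts inside the loop preceding the plain loop
      cut; ``site_a`` is the loop-most (first) cut.

    For sequential variants without explicit ``extra_junctions`` a default
    of one extra cut at 21-nt spacing is assumed (``allow_default_spacing``).
    ``direction`` overrides the locus label (used for DUAL loci).
    """
    d = direction or locus.direction
    if d in ("UNDEFINED", "DUAL"):
        raise ValueError(
            f"locus {locus.locus_id}: direction {d} has no single cleavage map"
            + (" (use derive_cleavage_maps for DUAL)" if d == "DUAL" else "")
        )
    if d not in ("BTL", "BTLs", "LTB", "LTBs"):
        raise ValueError(f"unknown direction {d!r}")

    m5s, m5e = locus.mir5p_t
    m3s, m3e = locus.mir3p_t
    lid = locus_id or locus.locus_id
    extra_t: list[int] = sorted(locus.g2t(p) for p in (locus.extra_junctions or ()))

    if d == "BTL":
        j5 = (m5s,)
        j3 = (m3e,)
    elif d == "BTLs":
        if not extra_t:
            if not allow_default_spacing:
                raise ValueError(f"locus {lid}: BTLs without extra_junctions")
            extra_t = [m5s - DEFAULT_CUT_SPACING * k for k in range(DEFAULT_EXTRA_CUTS, 0, -1)]
        j5 = tuple(extra_t) + (m5s,)  # ascending = processing order (most distal first)
        j3 = (m3e,)
    elif d == "LTB":
        j5 = (m5e, m5s)  # loop cut first
        j3 = (m3s, m3e)
    else:  # LTBs
        if not extra_t:
            if not allow_default_spacing:
                raise ValueError(f"locus {lid}: LTBs without extra_junctions")
            extra_t = [m5e + DEFAULT_CUT_SPACING * k for k in range(1, DEFAULT_EXTRA_CUTS + 1)]
        j5 = tuple(sorted(extra_t, reverse=True)) + (m5e, m5s)  # loop-most first
        j3 = (m3s, m3e)

    site_a = j5[0]
    T = locus.transcript_length
    for j in j5 + j3:
        if not (0 < j < T):
            raise ValueError(f"locus {lid}: junction {j} outside transcript (0, {T})")
    return CleavageMap(
        locus_id=lid,
        direction=d,
        junctions_5arm=j5,
        junctions_3arm=j3,
        site_a=site_a,
        pre_mirna=(m5s, m3e),
        mature_3p_end=m3e,
    )


def derive_cleavage_maps(locus: MirnaLocus, **kw) -> list[CleavageMap]:
    """Cleavage maps for a locus; DUAL loci yield two (.1 = LTB, .2 = BTL)."""
    if locus.direction == "DUAL":
        return [
            derive_cleavage_map(locus, "LTB", locus_id=f"{locus.locus_id}.1", **kw),
            derive_cleavage_map(locus, "BTL", locus_id=f"{locus.locus_id}.2", **kw),
        ]
    return [derive_cleavage_map(locus, **kw)]


def scaling_windows(
    locus: MirnaLocus, flank: int = DEFAULT_FLANK, cmap: CleavageMap | None = None
) -> ScalingWindows:
    """Metagene windows: TSS->miR-5p and hairpin (first cut->miR-3p for BTLs)."""
    m5s, _ = locus.mir5p_t
    _, m3e = locus.mir3p_t
    direction = cmap.direction if cmap is not None else locus.direction
    if direction == "BTLs":
        cm = cmap or derive_cleavage_map(locus, "BTLs")
        hairpin = (cm.site_a, m3e)
    else:
        hairpin = (m5s, m3e)
    tss_window = (0, m5s)
    for name, (a, b) in (("tss_window", tss_window), ("hairpin_window", hairpin)):
        if b - a < 1:
            raise ValueError(f"locus {locus.locus_id}: {name} is empty ({a}, {b})")
    return ScalingWindows(locus.locus_id, tss_window, hairpin, flank)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_gff3(loci: Iterable[MirnaLocus], path: str | os.PathLike) -> None:
    """Write loci back to miRBase-dialect GFF3 (1-based closed at boundary)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            if loc.strand == "+":
                fs, fe = loc.tss, loc.locus_end
            else:
                fs, fe = loc.locus_end + 1, loc.tss + 1
            # primary transcript spans hairpin region; TSS lives in the sidecar,
            # so emit the hairpin-bearing span exactly as loaded: use the full
            # transcript span (round-trips with load_annotations).
            fh.write(
                f"{loc.chrom}\tcotxmir\tmiRNA_primary_transcript\t{fs + 1}\t{fe}\t.\t{loc.strand}\t.\t"
                f"ID={loc.locus_id};Name={loc.locus_id}\n"
            )
            for arm, (s, e) in (("5p", loc.mir5p), ("3p", loc.mir3p)):
                fh.write(
                    f"{loc.chrom}\tcotxmir\tmiRNA\t{s + 1}\t{e}\t.\t{loc.strand}\t.\t"
                    f"ID={loc.locus_id}-{arm};Name={loc.locus_id}-{arm};Derives_from={loc.locus_id}\n"
                )


def write_sidecar(loci: Iterable[MirnaLocus], path: str | os.PathLike) -> None:
    rows = []
    for loc in loci:
        rows.append(
            {
                "locus_id": loc.locus_id,
                "tss": loc.tss,
                "direction": loc.direction,
                "extra_junctions": ",".join(str(p) for p in loc.extra_junctions)
                if loc.extra_junctions
                else "",
                "host_context": loc.host_context,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_annotation_tsv(annset: AnnotationSet, path: str | os.PathLike) -> None:
    """Validated annotation table (one row per locus, transcript-space anchors)."""
    rows = []
    for loc in annset.loci:
        m5s, m5e = loc.mir5p_t
        m3s, m3e = loc.mir3p_t
        rows.append(
            {
                "locus_id": loc.locus_id,
                "chrom": loc.chrom,
                "strand": loc.strand,
                "tss": loc.tss,
                "locus_end": loc.locus_end,
                "transcript_length": loc.transcript_length,
                "mir5p_t_start": m5s,
                "mir5p_t_end": m5e,
                "mir3p_t_start": m3s,
                "mir3p_t_end": m3e,
                "direction": loc.direction,
                "host_context": loc.host_context,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_junction_bed(
    loci_cmaps: Sequence[tuple[MirnaLocus, CleavageMap]], path: str | os.PathLike
) -> None:
    """BED6 of DCL1 junctions; name = ``locus_id|cut_index``.

    Each junction ``j`` (a bond) is emitted as the 1-bp interval of the base
    just 5' of the bond (transcript position ``j-1``), where the 3'-end peak
    of reads ending at the cut is observed.
    """
    records = []
    for loc, cm in loci_cmaps:
        for idx, j in enumerate(cm.junctions_5arm + cm.junctions_3arm):
            g = loc.t2g(j - 1)
            records.append((loc.chrom, g, g + 1, f"{cm.locus_id}|{idx}", 0, loc.strand))
    records.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for r in records:
            fh.write("\t".join(str(x) for x in r) + "\n")
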