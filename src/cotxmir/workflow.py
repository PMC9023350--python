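"""End-to-end pipeline run: annotation → coverage → ratios/metagene/R-loops.

A run is configured by a flat TOML file, is deterministic given inputs and
seed, and writes versioned TSV tables into a run directory.  Every output
table carries the configuration hash in a leading comment line so results
can be traced back to the exact thresholds that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tomllib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "StageError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Flat run configuration; unknown keys in the TOML file are rejected."""

    annotations_gff3: str = ""
    annotations_sidecar: str = ""
    reads_bed: str = ""
    reads_bam: str = ""
    drip_fwd: str = ""
    drip_rev: str = ""
    smallrna_input: str = ""
    smallrna_ip: str = ""
    out_dir: str = "run"
    condition: str = "control"
    seed: int = 1
    min_reads: int = 10
    delta_eq: float = 0.1
    span_margin: int = 1
    kappa_present: float = 2.0
    uniform_frac: float = 0.8
    flank: int = 300
    bins: int = 100
    low_signal: float = 10.0
    min_mapq: int = 10
    ago_min_count: int = 5

    @classmethod
    def from_toml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.annotations_gff3 or not self.annotations_sidecar:
            raise ConfigError("annotations_gff3 and annotations_sidecar are required")
        for key in ("annotations_gff3", "annotations_sidecar", "reads_bed", "reads_bam",
                    "drip_fwd", "drip_rev", "smallrna_input", "smallrna_ip"):
            val = getattr(self, key)
            if val and not Path(val).exists():
                raise ConfigError(f"{key}: file not found: {val}")
        if not self.reads_bed and not self.reads_bam:
            raise ConfigError("one of reads_bed or reads_bam is required")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cotxmir config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full analysis and return the run directory."""
    from . import ago as ago_mod
    from .annotation import (
        derive_cleavage_maps,
        scaling_windows,
        write_annotation_tsv,
        write_junction_bed,
        load_annotations,
    )
    from .coverage import end_coverage, load_reads_bam, load_reads_bed6, read_bedgraph
    from .metagene import aggregate_profile, filter_low_signal, profile_matrix
    from .processing import infer_direction, processing_ratio, reads_to_transcript
    from .rloop import classify_rloop, ratio_by_class, strand_split_drip, track_background, window_means

    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cotxmir")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(cfg, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, out: Path) -> Path:
    from .annotation import (
        derive_cleavage_maps,
        load_annotations,
        scaling_windows,
        write_annotation_tsv,
        write_junction_bed,
    )
    from .coverage import end_coverage, load_reads_bam, load_reads_bed6, read_bedgraph
    from .metagene import aggregate_profile, filter_low_signal, profile_matrix
    from .processing import infer_direction, processing_ratio, reads_to_transcript
    from .rloop import classify_rloop, ratio_by_class, strand_split_drip, track_background, window_means
    from . import ago as ago_mod

    log = logging.getLogger("cotxmir.run")

    # stage 1: annotations -----------------------------------------------------
    try:
        annset = load_annotations(cfg.annotations_gff3, cfg.annotations_sidecar)
    except Exception as exc:
        raise StageError("annotations", str(exc)) from exc
    if not annset.loci:
        raise StageError("annotations", "no valid locus after validation")
    for failure in annset.failures:
        log.warning("locus %s failed validation: %s", failure.locus_id, "; ".join(failure.reasons))
    write_annotation_tsv(annset, out / "annotations_validated.tsv")
    pd.DataFrame(
        [{"locus_id": f.locus_id, "reasons": "; ".join(f.reasons)} for f in annset.failures]
    ).to_csv(out / "annotation_failures.tsv", sep="\t", index=False)

    cmaps = []
    for locus in annset.loci:
        for cm in derive_cleavage_maps(locus):
            cmaps.append((locus, cm))
    write_junction_bed(cmaps, out / "junctions.bed")
    windows = {loc.locus_id: scaling_windows(loc, cfg.flank) for loc in annset.loci}

    # stage 2: reads and coverage ---------------------------------------------
    try:
        if cfg.reads_bed:
            reads = load_reads_bed6(cfg.reads_bed)
        else:
            reads = load_reads_bam(cfg.reads_bam, min_mapq=cfg.min_mapq)
        tracks3p = {s: end_coverage(reads, "three_prime", s) for s in "+-"}
        tracks_whole = {s: end_coverage(reads, "whole", s) for s in "+-"}
    except StageError:
        raise
    except Exception as exc:
        raise StageError("coverage", str(exc)) from exc
    log.info("loaded %d reads", len(reads))

    # stage 3: low-signal filter ----------------------------------------------
    kept_by_strand = {}
    dropped_ids = []
    for s in "+-":
        loci_s = [l for l in annset.loci if l.strand == s]
        kept, dropped = filter_low_signal(loci_s, tracks_whole[s], cfg.low_signal, windows)
        kept_by_strand[s] = kept
        dropped_ids += [l.locus_id for l in dropped]
    kept_loci = kept_by_strand["+"] + kept_by_strand["-"]
    log.info("low-signal filter: kept %d loci, dropped %d", len(kept_loci), len(dropped_ids))
    kept_ids = {l.locus_id for l in kept_loci}

    # stage 4: processing ratios and direction inference -----------------------
    try:
        ratio_rows, dir_rows = [], []
        ratio_records = []
        for locus, cm in cmaps:
            if locus.locus_id not in kept_ids:
                continue
            treads = reads_to_transcript(reads, locus)
            rec = processing_ratio(
                treads, cm, min_reads=cfg.min_reads, delta_eq=cfg.delta_eq,
                span_margin=cfg.span_margin, condition=cfg.condition,
            )
            ratio_records.append(rec)
            ratio_rows.append(rec.as_dict())
            call = infer_direction(tracks3p[locus.strand], locus)
            dir_rows.append(
                {
                    "locus_id": cm.locus_id,
                    "annotated_direction": cm.direction,
                    "inferred_direction": call.direction,
                    "retention": int(call.retention),
                }
            )
    except Exception as exc:
        raise StageError("ratios", str(exc)) from exc
    _write_table(pd.DataFrame(ratio_rows), out / "ratios.tsv", cfg)
    _write_table(pd.DataFrame(dir_rows), out / "directions.tsv", cfg)

    # stage 5: metagene profiles by direction ----------------------------------
    try:
        for s in "+-":
            if not kept_by_strand[s]:
                continue
            mat = profile_matrix(
                tracks3p[s], kept_by_strand[s], windows, n_bins=cfg.bins, flank=cfg.flank
            )
            _write_table(mat, out / f"profile_matrix.{ 'fwd' if s == '+' else 'rev'}.tsv", cfg, index=True)
        groups = {l.locus_id: l.direction for l in kept_loci}
        mats = []
        for s in "+-":
            if kept_by_strand[s]:
                mats.append(
                    profile_matrix(tracks3p[s], kept_by_strand[s], windows, n_bins=cfg.bins, flank=cfg.flank)
                )
        if mats:
            full = pd.concat(mats)
            agg = aggregate_profile(full, groups)
            rows = {g: v for g, (v, n) in agg.items() if v is not None}
            agg_df = pd.DataFrame.from_dict(rows, orient="index", columns=full.columns)
            agg_df.insert(0, "n_loci", [agg[g][1] for g in agg_df.index])
            _write_table(agg_df, out / "metagene_by_direction.tsv", cfg, index=True)
    except Exception as exc:
        raise StageError("metagene", str(exc)) from exc

    # stage 6: R-loop classification -------------------------------------------
    if cfg.drip_fwd and cfg.drip_rev:
        try:
            fwd = read_bedgraph(cfg.drip_fwd, "whole", "+")
            rev = read_bedgraph(cfg.drip_rev, "whole", "-")
            bg = {"+": track_background(fwd), "-": track_background(rev)}
            rows = []
            rrecords = []
            for locus in kept_loci:
                sense, antisense = strand_split_drip(fwd, rev, locus)
                bg_pair = (bg[locus.strand], bg["-" if locus.strand == "+" else "+"])
                rec = window_means(sense, antisense, locus, windows[locus.locus_id], bg_pair, cfg.flank)
                classify_rloop(rec, cfg.kappa_present, cfg.uniform_frac)
                rrecords.append(rec)
                row = {"locus_id": rec.locus_id, "rclass": rec.rclass}
                row.update({f"mean_{w}_{s}": rec.means[(w, s)] for (w, s) in rec.means})
                rows.append(row)
            _write_table(pd.DataFrame(rows), out / "rloop_classes.tsv", cfg)
            summary, tests = ratio_by_class(rrecords, ratio_records)
            _write_table(summary, out / "rloop_ratio_groups.tsv", cfg, index=True)
            _write_table(tests, out / "rloop_ratio_tests.tsv", cfg)
        except Exception as exc:
            raise StageError("rloop", str(exc)) from exc

    # stage 7: AGO1 loading -----------------------------------------------------
    if cfg.smallrna_input and cfg.smallrna_ip:
        try:
            inp = ago_mod.read_count_table(cfg.smallrna_input)
            ip = ago_mod.read_count_table(cfg.smallrna_ip)
            records = ago_mod.loading_ratios(inp, ip, min_count=cfg.ago_min_count)
            _write_table(records, out / "ago_loading.tsv", cfg, index=True)
        except Exception as exc:
            raise StageError("ago", str(exc)) from exc

    with open(out / "config.json", "w") as fh:
        json.dump({"config": asdict(cfg), "config_hash": cfg.config_hash()}, fh, indent=2, sort_keys=True)
    return out
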