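"""Synthetic nascent-read and DRIP-coverage generator with known truth.

The generator emulates the statistical anatomy of NET-seq signal at MIRNA
loci so that every pipeline stage is testable without sequencing data:

* an RNAPII molecule sits at transcript position ``X`` (uniform or
  5'-biased truncated-geometric law);
* once the hairpin plus a short lag has been transcribed the molecule is
  eligible for co-transcriptional processing, which happens with
  probability ``p_co``;
* an unprocessed molecule contributes one read whose 3' end is the RNAPII
  position; a processed molecule contributes the retained 5'-arm by-product
  (3' end exactly at the first DCL1 cut), plus — depending on direction —
  retained pre-miRNA reads (B-type) or sequential-cut by-products and a
  retained mature miR-3p read (L-type);
* uniform background fragmentation adds noise reads.

``expected_counts`` computes the exact expectations of the end/span counts
at site "a" by enumerating the discrete joint law of (position, processed?,
read length) — an oracle that is independent of both the simulator's
sampling path and the counting pipeline.  Strand-specific DRIP coverage is
generated from the five R-loop archetypes with multiplicative noise.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    CleavageMap,
    MirnaLocus,
    derive_cleavage_map,
    derive_cleavage_maps,
    write_gff3,
    write_sidecar,
)
from .coverage import CoverageTrack, ReadInterval

__all__ = [
    "SimConfig",
    "SimReads",
    "SimTruth",
    "simulate_netseq",
    "ExpectedCounts",
    "expected_counts",
    "simulate_drip",
    "make_fixture",
    "PROVENANCES",
]

PROVENANCES = ("unprocessed", "byproduct_5arm", "pre_mirna", "mature_3p", "noise")


@dataclass(frozen=True)
class SimConfig:
    """Generative conditions for one locus.

    Defaults encode the qualitative signal anatomy seen in nascent data:
    near-complete retention of the 5'-arm by-product (``r5 = 1.0``), partial
    retention of the released pre-miRNA for B-type loci and of the mature
    miR-3p for L-type loci (0.3 each), read lengths uniform on 20–80 nt,
    and a low uniform background fragmentation rate.
    """

    seed: int = 1
    n_molecules: int = 10_000
    p_co: float = 0.5
    position_law: str = "uniform"  # uniform | truncated_geometric
    geom_scale: float = 500.0  # mean of the (untruncated) geometric, in nt
    position_min: int = 1  # smallest RNAPII position (force eligibility by raising)
    lag: int = 10
    r5: float = 1.0
    r_pre: float = 0.3
    r_mat: float = 0.3
    read_len_min: int = 20
    read_len_max: int = 80
    background_rate: float = 0.02

    def __post_init__(self):
        for name in ("p_co", "r5", "r_pre", "r_mat", "background_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_len_min < 15:
            raise ValueError("read_len_min must be >= 15")
        if self.read_len_max < self.read_len_min:
            raise ValueError("read_len_max < read_len_min")


@dataclass
class SimReads:
    """Simulated reads in transcript coordinates, with genomic conversion."""

    ts: np.ndarray
    te: np.ndarray
    provenance: np.ndarray  # int codes into PROVENANCES
    locus: MirnaLocus

    def __len__(self):
        return len(self.ts)

    def to_read_intervals(self) -> list[ReadInterval]:
        out = []
        for a, b in zip(self.ts, self.te):
            gs, ge = self.locus.t2g_interval((int(a), int(b)))
            out.append(ReadInterval(self.locus.chrom, gs, ge, self.locus.strand))
        return out

    def three_prime_values(self, T: int | None = None) -> np.ndarray:
        """Dense transcript-space 3'-end counts (index = 3'-most base)."""
        T = T or self.locus.transcript_length
        return np.bincount(np.clip(self.te - 1, 0, T - 1), minlength=T).astype(float)


@dataclass
class SimTruth:
    locus_id: str
    direction: str
    p_co: float
    counts: dict
    labels: np.ndarray


def _position_pmf(T: int, cfg: SimConfig) -> np.ndarray:
    """pmf of the RNAPII 3'-end position X over 1..T."""
    if cfg.position_law == "uniform":
        pmf = np.full(T, 1.0)
    elif cfg.position_law == "truncated_geometric":
        q = 1.0 / cfg.geom_scale
        pmf = (1 - q) ** np.arange(T)
    else:
        raise ValueError(f"unknown position law {cfg.position_law!r}")
    if cfg.position_min > 1:
        if cfg.position_min > T:
            raise ValueError("position_min beyond transcript length")
        pmf[: cfg.position_min - 1] = 0.0
    return pmf / pmf.sum()


def simulate_netseq(
    locus: MirnaLocus,
    cmap: CleavageMap,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SimReads, SimTruth]:
    """Draw one locus worth of nascent reads with per-read provenance.

    Identical seeds give byte-identical output.  Provenance labels
    partition the read set; their counts are returned in ``SimTruth``.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    T = locus.transcript_length
    m3e = cmap.mature_3p_end
    eligible_from = m3e + cfg.lag
    if cfg.p_co > 0 and eligible_from > T:
        import warnings

        warnings.warn(
            f"locus {locus.locus_id}: processing lag reaches past the transcript; "
            "no molecule is eligible for co-transcriptional processing"
        )
    n = cfg.n_molecules
    pmf = _position_pmf(T, cfg)
    X = rng.choice(np.arange(1, T + 1), size=n, p=pmf)
    eligible = X >= eligible_from
    processed = eligible & (rng.random(n) < cfg.p_co)

    def draw_len(k):
        return rng.integers(cfg.read_len_min, cfg.read_len_max + 1, size=k)

    blocks: list[tuple[np.ndarray, np.ndarray, int]] = []

    # unprocessed molecules: one read ending at the RNAPII position
    up = ~processed
    L = draw_len(int(up.sum()))
    te = X[up]
    blocks.append((np.maximum(0, te - L), te, 0))

    npro = int(processed.sum())
    if cmap.is_loop_first:
        # every cut is co-transcriptional for L-type loci: by-products end
        # at each 5'-arm junction, each retained with probability r5
        for j in cmap.junctions_5arm:
            keep = rng.random(npro) < cfg.r5
            k = int(keep.sum())
            L = draw_len(k)
            te = np.full(k, j)
            blocks.append((np.maximum(0, te - L), te, 1))
        # retained mature miR-3p (its own 19-25 nt interval)
        m3s_t, m3e_t = locus.mir3p_t
        keep = rng.random(npro) < cfg.r_mat
        k = int(keep.sum())
        blocks.append((np.full(k, m3s_t), np.full(k, m3e_t), 3))
    else:
        # only the first cut is co-transcriptional for B-type loci: one
        # by-product ending at site a, retained with probability r5
        keep = rng.random(npro) < cfg.r5
        k = int(keep.sum())
        L = draw_len(k)
        te = np.full(k, cmap.site_a)
        blocks.append((np.maximum(0, te - L), te, 1))
        # retained pre-miRNA hairpin: reads ending at the hairpin 3' end
        keep = rng.random(npro) < cfg.r_pre
        k = int(keep.sum())
        L = draw_len(k)
        te = np.full(k, m3e)
        blocks.append((np.maximum(cmap.pre_mirna[0], te - L), te, 2))

    # uniform background fragmentation
    bg = rng.random(n) < cfg.background_rate
    k = int(bg.sum())
    Xb = rng.choice(np.arange(1, T + 1), size=k)
    L = draw_len(k)
    blocks.append((np.maximum(0, Xb - L), Xb, 4))

    ts = np.concatenate([b[0] for b in blocks]).astype(int)
    te = np.concatenate([b[1] for b in blocks]).astype(int)
    prov = np.concatenate([np.full(len(b[0]), b[2]) for b in blocks]).astype(int)
    counts = {PROVENANCES[i]: int((prov == i).sum()) for i in range(len(PROVENANCES))}
    reads = SimReads(ts, te, prov, locus)
    truth = SimTruth(cmap.locus_id, cmap.direction, cfg.p_co, counts, prov)
    return reads, truth


@dataclass
class ExpectedCounts:
    """Exact expectations of site-"a" counts under the generative law."""

    e_end_at_a: float
    e_span_a: float
    ratio: float
    sd_end: float
    sd_span: float
    p_eligible: float
    components: dict = field(default_factory=dict)


def expected_counts(
    locus: MirnaLocus, cmap: CleavageMap, cfg: SimConfig, span_margin: int = 1
) -> ExpectedCounts:
    """Enumerate the joint law of (X, processed?, L) — no simulation.

    The per-molecule probability of producing a read that ends at site "a"
    is ``P(X = a)`` (such a molecule is never eligible, the hairpin not yet
    transcribed) plus ``P(eligible) * p_co * r5`` for the retained
    by-product.  Spanning reads can only come from unprocessed molecules or
    background; for loop-first loci, reads ending at any annotated junction
    are excluded from the spanning count, mirroring the pipeline's
    denominator rule.
    """
    T = locus.transcript_length
    a = cmap.site_a
    m = span_margin
    pmf = _position_pmf(T, cfg)  # index i -> X = i + 1
    x = np.arange(1, T + 1)
    eligible = x >= cmap.mature_3p_end + cfg.lag
    p_elig = float(pmf[eligible].sum())

    n_len = cfg.read_len_max - cfg.read_len_min + 1
    lengths = np.arange(cfg.read_len_min, cfg.read_len_max + 1)

    def p_len_ge(d: np.ndarray) -> np.ndarray:
        # P(L >= d) for the uniform length law
        return np.clip((cfg.read_len_max - np.maximum(d, cfg.read_len_min) + 1), 0, n_len) / n_len

    # --- reads ending exactly at site a --------------------------------------
    p_end_unproc = float(pmf[a - 1]) if 1 <= a <= T else 0.0
    if a <= T and eligible[a - 1]:
        p_end_unproc *= 1.0 - cfg.p_co  # unreachable for valid maps (a < hairpin end)
    p_end_proc = p_elig * cfg.p_co * cfg.r5
    p_end_bg = cfg.background_rate / T
    e_end = cfg.n_molecules * (p_end_unproc + p_end_proc + p_end_bg)

    # --- reads spanning site a -----------------------------------------------
    # geometry: te = X >= a + m and max(0, X - L) <= a - m  <=>  L >= X - a + m
    geom = np.where(x >= a + m, p_len_ge(x - a + m), 0.0)
    if cmap.is_loop_first:
        excl = np.isin(x, np.asarray(cmap.all_junctions))
        geom = np.where(excl, 0.0, geom)
    u = np.where(eligible, 1.0 - cfg.p_co, 1.0)  # P(molecule at X stays unprocessed)
    p_span_unproc = float((pmf * u * geom).sum())
    p_span_bg = cfg.background_rate * float(geom.sum()) / T
    e_span = cfg.n_molecules * (p_span_unproc + p_span_bg)

    p_end_mol = p_end_unproc + p_end_proc  # mutually exclusive per molecule
    var_end = cfg.n_molecules * (
        p_end_mol * (1 - p_end_mol) + p_end_bg * (1 - p_end_bg)
    )
    var_span = cfg.n_molecules * (
        p_span_unproc * (1 - p_span_unproc) + p_span_bg * (1 - p_span_bg)
    )
    _ = lengths
    return ExpectedCounts(
        e_end_at_a=e_end,
        e_span_a=e_span,
        ratio=e_end / e_span if e_span > 0 else math.inf if e_end > 0 else math.nan,
        sd_end=math.sqrt(var_end),
        sd_span=math.sqrt(var_span),
        p_eligible=p_elig,
        components={
            "p_end_unprocessed": p_end_unproc,
            "p_end_byproduct": p_end_proc,
            "p_end_background": p_end_bg,
            "p_span_unprocessed": p_span_unproc,
            "p_span_background": p_span_bg,
        },
    )


# ---------------------------------------------------------------------------
# DRIP archetypes
# ---------------------------------------------------------------------------


def simulate_drip(
    locus: MirnaLocus,
    rclass: str,
    snr: float | None = 5.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    flank: int = 300,
    amplitude: float = 5.0,
    baseline: float = 1.0,
    pad: int = 2000,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Strand-specific DRIP coverage for one R-loop archetype.

    Returns genomic (forward, reverse) tracks covering the locus ± flank,
    plus ``pad`` bp of baseline-only coverage on each side standing in for
    the genome-wide background against which the strand median is taken.
    ``snr`` is the ratio of the R-loop amplitude to the multiplicative noise
    s.d.; ``snr=None`` (or ``inf``) gives the noiseless archetype.
    """
    from .annotation import scaling_windows as _sw

    rng = rng or np.random.default_rng(seed if seed is not None else 0)
    T = locus.transcript_length
    sw = _sw(locus, flank)
    m5s = sw.tss_window[1]
    body = sw.hairpin_window
    flank = flank + pad
    L = T + 2 * flank  # transcript coords -(flank+pad) .. T+flank+pad
    sense = np.zeros(L)
    anti = np.zeros(L)

    def seg(a, b):  # transcript window -> array slice
        return slice(a + flank, b + flank)

    half = T // 2
    if rclass == "alpha":
        pass
    elif rclass == "beta":
        anti[seg(0, m5s)] += amplitude
    elif rclass == "gamma":
        anti[seg(0, m5s)] += amplitude
        sense[seg(body[1], T)] += amplitude
    elif rclass == "delta":
        sense[seg(0, T)] += amplitude
    elif rclass == "epsilon":
        sense[seg(half, T)] += amplitude
        anti[seg(0, half)] += amplitude
    else:
        raise ValueError(f"unknown R-loop class {rclass!r}")

    sense += baseline
    anti += baseline
    if snr is not None and math.isfinite(snr):
        sigma = math.sqrt(math.log1p(1.0 / snr**2))
        sense = sense * rng.lognormal(0.0, sigma, L)
        anti = anti * rng.lognormal(0.0, sigma, L)

    fwd = CoverageTrack(mode="whole", strand="+")
    rev = CoverageTrack(mode="whole", strand="-")
    sense_track, anti_track = (fwd, rev) if locus.strand == "+" else (rev, fwd)
    for i in range(L):
        t = i - flank
        g = locus.t2g(t)
        sense_track.add(locus.chrom, g, float(sense[i]))
        anti_track.add(locus.chrom, g, float(anti[i]))
    return fwd, rev


# ---------------------------------------------------------------------------
# packaged miniature dataset
# ---------------------------------------------------------------------------

#: (suffix, direction, p_co, rclass, host_context, hairpin offset from TSS)
_FIXTURE_PLAN = [
    ("001", "BTL", 0.8, "beta", "independent", 220),
    ("002", "BTL", 0.2, "alpha", "independent", 260),
    ("003", "LTB", 0.8, "gamma", "independent", 240),
    ("004", "LTB", 0.2, "delta", "independent", 300),
    ("005", "BTLs", 0.7, "beta", "independent", 280),
    ("006", "BTLs", 0.3, "epsilon", "independent", 320),
    ("007", "LTBs", 0.7, "gamma", "independent", 260),
    ("008", "LTBs", 0.3, "alpha", "independent", 300),
    ("009", "DUAL", 0.6, "beta", "independent", 240),
    # polycistron duet on one transcript: a beta R-loop at the 5' hairpin
    # only; the 3' hairpin has no R-loop of its own and low p_co
    ("010", "BTL", 0.8, "beta", "polycistron-member", 220),
    ("011", "BTL", 0.2, "alpha", "polycistron-member", 1200),
    ("012", "LTB", 0.7, "beta", "intronic", 400),
]


def _fixture_locus(suffix: str, direction: str, host: str, hp_off: int, chrom: str, origin: int, strand: str) -> MirnaLocus:
    """Deterministic locus geometry; 21-nt mature arms, 60-nt loop."""
    mir_len = 21
    loop = 60
    tail = 160
    if strand == "+":
        tss = origin
        m5s = tss + hp_off
        m5 = (m5s, m5s + mir_len)
        m3 = (m5[1] + loop, m5[1] + loop + mir_len)
        locus_end = m3[1] + tail
    else:
        tss = origin
        m5s_t = hp_off  # transcript coords
        m5 = (tss - (m5s_t + mir_len) + 1, tss - m5s_t + 1)
        m3s_t = m5s_t + mir_len + loop
        m3 = (tss - (m3s_t + mir_len) + 1, tss - m3s_t + 1)
        locus_end = m3[0] - tail - 1
    return MirnaLocus(
        locus_id=f"mir-sim-{suffix}",
        chrom=chrom,
        strand=strand,
        tss=tss,
        locus_end=locus_end,
        mir5p=m5,
        mir3p=m3,
        direction=direction,
        host_context=host,
    )


def make_fixture(out_dir: str | os.PathLike, seed: int = 1, n_molecules: int = 3000) -> dict:
    """Write a deterministic miniature dataset covering all directions.

    12 loci (all four directions, one DUAL locus, a polycistron duet and an
    intronic member), nascent reads as BED6, strand-specific DRIP bedGraph
    pair, small-RNA count tables with a planted 2x IP enrichment, and a
    truth table with per-locus direction, p_co, R-loop class and the
    oracle-expected ratio/preference.  Byte-identical for identical seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    loci: list[MirnaLocus] = []
    for i, (suffix, direction, p_co, rclass, host, hp_off) in enumerate(_FIXTURE_PLAN):
        chrom = f"chr{i % 3 + 1}"
        strand = "+" if i % 4 != 3 else "-"
        origin = 50_000 + (i // 3) * 20_000
        if strand == "-":
            origin += 8000
        if suffix == "011":
            # second hairpin of the polycistron duet: same transcript as 010
            prev = loci[-1]
            chrom, origin, strand = prev.chrom, prev.tss, prev.strand
        loci.append(_fixture_locus(suffix, direction, host, hp_off, chrom, origin, strand))

    write_gff3(loci, out / "annotations.gff3")
    write_sidecar(loci, out / "annotations.tsv")

    all_reads: list[ReadInterval] = []
    names: list[str] = []
    truth_rows = []
    fwd_all = CoverageTrack(mode="whole", strand="+")
    rev_all = CoverageTrack(mode="whole", strand="-")
    for (suffix, direction, p_co, rclass, host, _), locus in zip(_FIXTURE_PLAN, loci):
        cfg = SimConfig(seed=seed, n_molecules=n_molecules, p_co=p_co)
        cmaps = derive_cleavage_maps(locus)
        per_map = n_molecules // len(cmaps)
        for cm in cmaps:
            reads, truth = simulate_netseq(locus, cm, replace(cfg, n_molecules=per_map), rng=rng)
            ivs = reads.to_read_intervals()
            all_reads.extend(ivs)
            names.extend(
                f"{cm.locus_id}|{PROVENANCES[p]}|{k}" for k, p in enumerate(reads.provenance)
            )
            exp = expected_counts(locus, cm, replace(cfg, n_molecules=per_map))
            pref = "co" if exp.ratio > 1.1 else ("post" if exp.ratio < 0.9 else "equal")
            truth_rows.append(
                {
                    "locus_id": cm.locus_id,
                    "direction": cm.direction,
                    "p_co": p_co,
                    "rclass": rclass,
                    "host_context": host,
                    "n_molecules": per_map,
                    "expected_ratio": exp.ratio,
                    "expected_preference": pref,
                    # loci whose transcript is shared (DUAL maps, polycistron
                    # members) see each other's reads; the per-map oracle
                    # expectation is exact only for isolated loci
                    "isolated": int(host == "independent" and direction != "DUAL"),
                }
            )
        if suffix == "011":
            # shares the polycistron transcript with 010, whose padded DRIP
            # coverage already provides this member's (R-loop-free) baseline
            continue
        fwd, rev = simulate_drip(locus, rclass, snr=5.0, rng=rng)
        for chrom, cnt in fwd.data.items():
            fwd_all.data.setdefault(chrom, cnt.__class__()).update(cnt)
        for chrom, cnt in rev.data.items():
            rev_all.data.setdefault(chrom, cnt.__class__()).update(cnt)

    from .coverage import write_bedgraph, write_reads_bed6

    write_reads_bed6(all_reads, out / "reads.bed", names=names)
    write_bedgraph(fwd_all, out / "drip.fwd.bedGraph")
    write_bedgraph(rev_all, out / "drip.rev.bedGraph")
    pd.DataFrame(truth_rows).to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.6g")

    # small-RNA tables: 100 miRNAs, a planted 2x IP-enriched subset
    n_mir = 100
    ids = [f"mir-sim-sRNA-{i:03d}" for i in range(n_mir)]
    base = rng.integers(50, 2000, size=n_mir).astype(float)
    enriched = np.zeros(n_mir, dtype=bool)
    enriched[rng.choice(n_mir, size=20, replace=False)] = True
    ip = base * np.where(enriched, 2.0, 1.0)
    inp_counts = rng.poisson(base)
    ip_counts = rng.poisson(ip)
    pd.DataFrame({"mirna_id": ids, "count": inp_counts}).to_csv(
        out / "smallrna_input.tsv", sep="\t", index=False
    )
    pd.DataFrame({"mirna_id": ids, "count": ip_counts}).to_csv(
        out / "smallrna_ip.tsv", sep="\t", index=False
    )
    pd.DataFrame({"mirna_id": ids, "enriched": enriched.astype(int)}).to_csv(
        out / "smallrna_truth.tsv", sep="\t", index=False
    )

    manifest = {
        "gff3": str(out / "annotations.gff3"),
        "sidecar": str(out / "annotations.tsv"),
        "reads_bed": str(out / "reads.bed"),
        "drip_fwd": str(out / "drip.fwd.bedGraph"),
        "drip_rev": str(out / "drip.rev.bedGraph"),
        "truth": str(out / "truth.tsv"),
        "smallrna_input": str(out / "smallrna_input.tsv"),
        "smallrna_ip": str(out / "smallrna_ip.tsv"),
        "smallrna_truth": str(out / "smallrna_truth.tsv"),
        "seed": seed,
        "n_molecules": n_molecules,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
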