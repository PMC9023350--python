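import numpy as np
import pytest

from cotxmir.annotation import MirnaLocus


def make_locus(
    direction: str = "BTL",
    strand: str = "+",
    locus_id: str | None = None,
    tss: int = 1000,
    hp_off: int = 250,
    mir_len: int = 21,
    loop: int = 60,
    tail: int = 160,
    chrom: str = "chr1",
    extra_junctions_t: tuple[int, ...] | None = None,
) -> MirnaLocus:
    """Deterministic test locus; geometry given in transcript terms."""
    m5s_t = hp_off
    m5e_t = m5s_t + mir_len
    m3s_t = m5e_t + loop
    m3e_t = m3s_t + mir_len
    T = m3e_t + tail

    def t2g_iv(a, b):
        if strand == "+":
            return (tss + a, tss + b)
        return (tss - b + 1, tss - a + 1)

    extra = None
    if extra_junctions_t is not None:
        extra = tuple((tss + t) if strand == "+" else (tss - t) for t in extra_junctions_t)
    return MirnaLocus(
        locus_id=locus_id or f"toy-{direction}-{strand}",
        chrom=chrom,
        strand=strand,
        tss=tss,
        locus_end=tss + T if strand == "+" else tss - T,
        mir5p=t2g_iv(m5s_t, m5e_t),
        mir3p=t2g_iv(m3s_t, m3e_t),
        direction=direction,
        extra_junctions=extra,
        host_context="independent",
    )


@pytest.fixture
def btl_locus():
    return make_locus("BTL")


@pytest.fixture
def ltb_locus():
    return make_locus("LTB")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The packaged miniature dataset, generated once per session."""
    from cotxmir.simulate import make_fixture

    out = tmp_path_factory.mktemp("fixture")
    make_fixture(out, seed=1, n_molecules=3000)
    return out


def write_toy_gff3(path, sidecar_path, direction="BTL", tss=900):
    """One plus-strand hairpin at chr1:1000-1200 with matures at
    1050-1071 / 1120-1141 (0-based half-open) and a TSV sidecar."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            "chr1\ttest\tmiRNA_primary_transcript\t1001\t1200\t.\t+\t.\t"
            "ID=mirT;Name=mirT\n"
        )
        fh.write("chr1\ttest\tmiRNA\t1051\t1071\t.\t+\t.\tID=mirT-5p;Derives_from=mirT\n")
        fh.write("chr1\ttest\tmiRNA\t1121\t1141\t.\t+\t.\tID=mirT-3p;Derives_from=mirT\n")
    with open(sidecar_path, "w") as fh:
        fh.write("locus_id\ttss\tdirection\textra_junctions\thost_context\n")
        fh.write(f"mirT\t{tss}\t{direction}\t\tindependent\n")
    return path, sidecar_path


def brute_force_counts(reads_ts, reads_te, j, margin=1, exclude=()):
    """Independent O(n) per-read scan for end/span counts at junction j."""
    n_end = 0
    n_span = 0
    for ts, te in zip(reads_ts, reads_te):
        if te == j:
            n_end += 1
        if ts <= j - margin and te >= j + margin and te not in exclude:
            n_span += 1
    return n_end, n_span


def seeded_rng(seed=0):
    return np.random.default_rng(seed)
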