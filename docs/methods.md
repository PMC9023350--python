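# Methods

## Coordinate model

All genomic intervals are 0-based half-open; GFF3's 1-based closed
convention is converted at the parsing boundary.  Analysis runs in
*transcript coordinates*: position 0 is the TSS, positions increase 5′→3′
along the transcript, and minus-strand loci are mirrored once at load time
so every downstream operation is strand-agnostic.  A cleavage junction `j`
names the bond between transcript bases `j−1` and `j`; the read-end peak
diagnostic of a cut therefore sits at base `j−1` in 3′-end coverage.

DCL1 leaves 2-nt 3′ overhangs, but junctions are placed exactly at the
annotated mature-miRNA boundaries: the observable end-nucleotide peaks
anchor at those boundaries, and per-locus offsets can be supplied through
the sidecar's `extra_junctions` column when a different register is known.

## Cleavage maps per processing direction

* `BTL`: one basal cut at the miR-5p start; it is the ratio anchor
  (site "a").  The released hairpin (pre-miRNA) spans miR-5p start →
  miR-3p end.
* `LTB`: the loop cut (miR-5p end) comes first and is site "a"; the basal
  cut follows.  Anchoring on the loop cut avoids counting internal
  processing intermediates as unprocessed transcripts, which is also why
  reads ending at *any* annotated junction are excluded from the spanning
  denominator for L-type loci only.
* `BTLs` / `LTBs`: sequential variants with extra cuts below the base /
  inside the loop.  When the sidecar gives no positions, one extra cut at
  21-nt spacing (the DCL1 step) is assumed; site "a" is the most 5′-distal
  cut for `BTLs` and the loop-most cut for `LTBs`.
* `DUAL` loci emit two maps suffixed `.1` (loop-to-base) and `.2`
  (base-to-loop); the suffix order is a package convention.

## The processing ratio

`ratio = n_end_at_a / n_span_a`, where a read "ends at" the junction when
its 3′-most base is `a−1` and "spans" it when it covers both adjacent
bases (`--span-margin`, default 1, widens the required overlap).
Preference is `co` above `1 + δ_eq`, `post` below `1 − δ_eq`, `equal`
inside the band; `δ_eq = 0.1` is a package choice — the class exists
qualitatively in the source analyses without a printed band — and its
effect is continuous, so sensitivity can be assessed by re-running with a
different `--delta-eq`.  Loci with fewer than `min_reads` (default 10)
informative reads at the site are `undetermined`, mirroring the exclusion
of low-signal loci (whole-read hairpin mean ≤ 10) from profiling.
Condition comparisons call a locus changed when the ratio moves by at
least ±50% (`|ratio_treat/ratio_ctrl − 1| ≥ 0.5`).

The ratio is deliberately non-quantitative: by-product stability,
chromatin retention time and library depth all scale the two counts
differently between loci.  Within a locus and condition it orders
co- versus post-transcriptional preference; across loci it should be read
comparatively.

## Direction inference

A candidate position `p` is a peak when `count(p) ≥ τ_abs` (default 5) and
`count(p) ≥ τ_fold ×` local background (mean over ±`w` bases excluding
`p`; defaults τ_fold = 4, w = 10).  Candidates are the basal cut, the
loop cut, 21±2-nt grids below the base and beyond the loop cut, and the
miR-3p end.  L-type loci are processed entirely co-transcriptionally and
show every cut, so a loop-cut peak calls `LTB` (`LTBs` with sequential
loop peaks); B-type loci show only their first cut, so a basal-only peak
calls `BTL` and a sub-basal grid peak calls `BTLs`.  A peak at the miR-3p
end is recorded as retention evidence (retained pre-miRNA for B-type,
retained mature miR-3p for L-type), never as direction evidence.
Conflicting loop-side and sub-basal evidence returns `UNDEFINED` with both
scores reported.

## Metagene scaling

Scale-regions binning uses a largest-remainder partition: a window of
length L into n bins gives contiguous segments differing by at most one
base, longer segments first, each bin the mean per-base signal of its
segment.  Binning is exactly the identity when n equals the window length
and is linear in the signal.  Flanks (default 300 bp) are unscaled at
1 bp/bin.  The body bin count defaults to 100 and is configurable; the
source analyses do not print one.

## R-loop classification

Windows are TSS→miR-5p (`tss`), the hairpin (`body`), and the 3′ arm from
hairpin end to transcript end (`tail`); means are computed per strand
relative to the locus and divided by the genome-wide median per-base DRIP
signal of that strand (median over covered bases — robust to enrichment
peaks).  A window is *present* at ≥ `κ_present` fold over background
(default 2.0).  The published taxonomy is a visual sort; the deterministic
rule order used here is:

1. `ε` (colliding): sense and antisense both present somewhere, at least
   one of them present over the body, sense profile centroid in the 3′
   half and antisense centroid in the 5′ half;
2. `δ` (full-locus): one strand present in all three windows with at
   least `uniform_frac` (default 0.8) of body bases above threshold —
   `uniform_frac` is the explicit stand-in for the unstated visual
   criterion separating γ from δ at intermediate body signal;
3. `γ` (bipartite): tss and tail present, body below threshold on both
   strands;
4. `β`: tss present only;
5. `α`: otherwise.

Using fold-over-background units makes classification exactly
scale-invariant.  Group comparisons of processing ratios use the
α vs β+γ vs δ+ε grouping with two-tailed unpaired Welch t-tests on
log-ratios; non-positive and non-finite ratios are excluded from testing
and counted in the summary, and groups of fewer than two usable loci get
an undefined p-value.

## Synthetic-data generator

The generator emulates the signal anatomy the analysis assumes, not
sequence: per molecule an RNAPII position X is drawn (uniform by default —
the simplest law keeping the spanning denominator exactly enumerable; a
truncated-geometric law is available to emulate 5′-biased occupancy).
Once the hairpin plus a 10-nt lag is transcribed the molecule is eligible
and processed with probability `p_co`.  Unprocessed molecules yield one
read ending at X; processed B-type molecules yield the 5′-arm by-product
ending at site "a" (retention probability `r5 = 1.0`) and a pre-miRNA
read ending at the hairpin 3′ end (`r_pre = 0.3`); processed L-type
molecules yield by-products at every 5′-arm junction (`r5` each) plus the
mature miR-3p read (`r_mat = 0.3`).  Retention defaults encode the
qualitative observations — strong 5′ by-product retention, partial
pre-miRNA/mature retention — without asserting unprinted magnitudes.
Read lengths are uniform on 20–80 nt and uniform background fragmentation
adds reads at rate 0.02 per molecule, a level that leaves junction peaks
unambiguous while exercising the background-rejection logic.  All draws
come from one seeded generator; identical seeds give byte-identical
output.

`expected_counts` computes exact expectations (and per-molecule binomial
variances) of the site-"a" end and span counts by enumerating the joint
law of (X, processed?, read length) — an oracle independent of the
sampling path and of the counting implementation.  Under it the expected
ratio is strictly increasing in `p_co` at fixed geometry.

DRIP profiles are generated from the five archetypes as boxcar/plateau
shapes at 5× background amplitude with multiplicative lognormal noise
(σ = √log(1+1/snr²)), padded with 2 kb of baseline-only coverage per side
standing in for the genome-wide background against which the strand
median is taken.

What the simulator does **not** model: sequence and folding, alignment
artefacts, splicing, 5′-biased fragment recovery, locus-specific
by-product stability differences, or DRIP resolution limits.  Passing
tests therefore demonstrate the correctness and calibration of the
counting, inference and classification machinery under the stated
generative assumptions, not the biological accuracy of any specific
published number.

## Packaged fixture

`make_fixture` writes a 12-locus miniature dataset (3,000 molecules per
locus by default): two to three loci per direction, one DUAL locus, a
polycistron duet sharing one transcript (β R-loop at the 5′ hairpin only,
high `p_co` there, low at the 3′ hairpin) and one intronic member; all
four R-loop-bearing archetypes appear alongside α loci.  The truth table
stores each locus's direction, `p_co`, R-loop class, oracle-expected
ratio and preference, plus an `isolated` flag: DUAL maps and polycistron
members share reads on one transcript, so the per-map oracle expectation
is exact only for isolated loci, and truth-recovery checks restrict to
isolated loci whose expected ratio lies clearly outside the equal band
(below 0.8 or above 1.25).

## Pipeline and I/O choices

The `run` workflow is deterministic given inputs and seed; every table
carries a configuration hash.  bedGraph is the coverage interchange
format throughout (text, lossless for integer tracks); BAM ingestion uses
primary alignments at MAPQ ≥ 10 with read-1 intervals for paired data — a
documented single-end simplification.  Replicate merging is a positional
sum, not a mean.  Problem sizes in the test-suite and verification runs
(10⁴ molecules per simulated locus for ratio recovery, 200 loci for
direction inference, 500 profiles per class for the classifier, 2,000
replicates for test calibration) were chosen so that sampling error is
small against the tested tolerances while each check completes in
seconds.

## Known limitations

* TSS positions are required inputs; no de-novo TSS calling.
* The spanning-read definition covers the junction with a 1-nt margin by
  default; deeply-degraded libraries may need a larger `--span-margin`.
* Direction inference assumes the 21-nt DCL1 step for sequential
  variants; non-canonical spacings need explicit `extra_junctions`.
* The α–ε thresholds are a deterministic operationalization of a visual
  taxonomy; borderline loci (means near κ_present) are sensitive to the
  background estimate, which is why per-locus margins are reported.
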