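# Methods

This note describes the models and conventions behind `tgarray`, the
parameters that matter, the design choices that were genuinely open, and
what the simulator does and does not emulate.

## Problem setting

A transgenic allele produced by pronuclear injection is modeled as a host
contig into which a tandem array of `C` construct copies (each a ~17 kb
unit at full scale; 3 kb in desk-scale simulations) has integrated at a
single position, replacing `D ≥ 0` bp of host sequence.  Individual copies
may be inverted, and a segment of cloning-host (bacterial) DNA may sit
between copies.  A screened marker subsequence of the unit (an EGFP-like
reporter CDS, ~720 bp) is the counting unit for copy number.  Long reads
that cross a host/array junction — chimeric reads — carry both flanking
host sequence and array sequence in a single molecule, and are the primary
evidence for everything the package infers.

## Coordinate and boundary conventions

Alignment segments are 0-based half-open, with read coordinates always on
the read's forward orientation.  Reported integration boundaries are
1-based retained host bases: `left_boundary` is the last host base kept on
the left of the array, `right_boundary` the first kept on the right, so
the deleted length is `right − left − 1`.  This is the only convention
under which the triple (left, right, deletion) is self-consistent for the
published worked example this package checks itself against (boundaries
124,115,870 / 124,116,557, deletion 686 bp).  Conversion to 1-based
happens only at reporting; everything internal is 0-based half-open.

When the first (or last) base of the array happens to equal the host base
it replaced, the exact breakpoint is genuinely ambiguous (junction
micro-homology) — no caller can recover it uniquely.  The simulator
therefore adjusts at most one terminal array base so that simulated
junctions are identifiable and "exact recovery" is well defined.  Real
junctions with micro-homology will be reported at the maximal-host-match
position.

## Alignment (align)

The internal aligner is a canonical k-mer seed-and-chain design:

- `k = 15` by default (range 8–21); k-mers containing N are skipped;
  k-mers occurring more than 64 times are treated as repetitive and
  ignored.
- Seeds are grouped by (target, strand, diagonal band); the band split
  (300 bp on the sorted diagonals) separates tandem copies (one diagonal
  per copy, 3 kb apart) while tolerating indel drift within one segment.
- Within a band the longest strictly co-linear seed subset (patience LIS,
  deterministic tie-breaks) becomes a chain; chains need ≥3 seeds.
- Chain ends are extended by an ungapped X-drop (match +1, mismatch −2,
  drop 6, cut back to the running maximum) — cheap, and pins ends to
  within a few bases of junctions on clean reads.
- `n_match` is computed as `block_len − edit_distance` (edlib), with
  `block_len = max(read span, target span)`; segments shorter than 200 bp
  or below 60% identity are dropped.  These defaults target the ~10–15%
  error regime of nanopore reads.
- Within one target, a segment overlapping a better-scoring kept segment
  by ≥50% of the shorter read interval is dropped; overlaps across
  different targets are expected (the marker lies inside the transgene
  unit) and kept.

Against a Smith–Waterman oracle (Biopython's local `PairwiseAligner`) on
noisy 150–300 bp fragments, segment ends agree within ±10 bp; exact
substrings are recovered exactly.  `read_paf` / `write_paf` interchange
segments with any minimap2-style mapper, so the internal aligner is
swappable for external PAF.

A shared utility, `extend_gapped`, performs banded gapped extension from a
fixed anchor and returns how far along the second sequence the maximal
score reaches.  It backs two refinements where end-placement accuracy
matters more than speed (both are O(window × band) per call and applied
sparingly):

- **Junction boundaries**: the fast ungapped extension stops at the first
  read indel near a junction and occasionally steps a few bases past it on
  chance matches.  `call_junctions` re-anchors 30 bp inside each
  junction-facing host segment end and re-extends with conservative
  scoring (match +1, mismatch −6, gap −6).  Conservative scoring means
  only near-exact host continuation extends the flank: a chance run needs
  7 straight matches (probability 4⁻⁷) to move the boundary, while the
  positive expected score per base keeps extension moving through ~10%
  read error.
- **Marker spans**: the counting rule below compares a segment's target
  span to a threshold; spans near the threshold are re-measured by gapped
  extension so that end erosion on noisy reads does not bias match counts
  (and hence the depth estimate) low.

## Screening and depth copy number (screen)

N50 is the largest length L such that reads of length ≥ L contain at least
half of all bases.  Fold-coverage is total bases over a caller-supplied
genome size, reported to one decimal.

A read scores one marker match per distinct marker segment covering at
least `min_marker_cov = 0.5` of the marker; two marker segments on one
read are distinct when their read intervals overlap by <50% of the shorter
one.  The 0.5 threshold makes the per-copy expected match count equal to
the fold-coverage (a read overlapping a marker by ≥ half counts; summing
over uniform read placements gives exactly coverage × copies), so

    copies_per_allele = total_marker_matches / coverage

is unbiased, with Poisson dispersion `sqrt(matches)/coverage`.  No
zygosity correction is applied: dividing by whole-genome coverage treats
the transgene allele as present once per haploid genome equivalent.  For a
heterozygote sequenced diploid this is the convention the published
arithmetic uses; a homozygote would need the marker matches halved.  This
caveat is reported, not silently corrected.

The rounded estimate has standard error ≈ `sqrt(C/c)` copies at coverage
`c` (slightly more when reads span several copies).  Consequently,
expecting the *integer mode* across seeds to equal the truth requires
`c ≳ 2C`; the recovery studies in the test suite simulate coverage `2C`
(12/36/52-fold for 6/18/26 copies), a power choice made analytically up
front.  At ~2-fold real-world coverage the estimate is "approximately C",
not an integer determination — the same caveat applies to the published
estimate the method reproduces.

## Structure calls (structure)

**Junctions.**  A read witnesses a boundary wherever a host segment abuts
a transgene segment within `max_junction_gap = 100` bp on the read
(unaligned junction scars occur).  The host segment's array-facing end —
its read-forward end if the transgene follows, accounting for strand —
gives the boundary; the transgene orientation is reported relative to the
host genome.  Boundaries on one side within `cluster_radius = 50` bp merge
by median; clusters pair left↔right in descending support order (so a
handful of reads whose junction neighborhoods are error-dense cannot steal
the main cluster's partner), giving `deletion = right − left − 1`.  On
simulated loci, boundaries are exact on error-free reads and within a few
bp at 10% read error.

**Inversions.**  One event per adjacent pair of transgene segments with
opposite strands on one read, positioned at the midpoint of the
inter-segment gap.  Evidence is kept per read; deduplication across reads
is a reporting decision.  Flips shorter than `min_segment_len` are
invisible by design.

**Contaminant.**  Contaminant-role segments on one read merge into a call;
the merged target span is exact only when host/transgene segments flank
the run on both sides (`bounded_by_reads`), otherwise it is a lower bound
— mirroring the fact that read-terminated foreign DNA can only be sized by
other means (e.g. PCR).

**Minimal tiling path.**  Inside a perfect tandem array, read-vs-read
overlaps are ambiguous up to the unit period, and (with an inverted copy)
up to an orientation mirror around the flip — a naive overlap chain can
silently collapse or extend the array.  Three gates keep the copy lower
bound sound:

1. *Dovetail*: an overlap qualifies only if its alignment reaches the two
   facing read ends (within 150 bp); wrong-period overlaps leave a
   dangling end.  Containments are excluded.
2. *Landmark*: when landmark positions are supplied (role transitions such
   as host→transgene or transgene→contaminant, and strand flips), the
   overlap must span one — the array is not periodic across a landmark, so
   the relative placement is pinned.
3. *Witness voting*: a candidate read's placement must agree (offset
   within 300 bp, same orientation) with the majority of placed reads that
   overlap it, which rejects the rare spurious dovetail (e.g. palindromic
   overlaps centered on a flip).

Greedy furthest-reach selection from a junction-anchored read then yields
a minimal chain (ties prefer longer reads); the bound counts distinct
projected full-marker positions (clusters > 500 bp apart).  The bound is
conservative by construction: reads that cannot be placed unambiguously
contribute nothing.  Arrays whose landmarks are farther apart than the
read length cannot be tiled end-to-end, and the bound will sit well below
the true copy number — as a lower bound should.

## Dot plots (dotplot)

A match at (x, y) means the `window`-length subsequence of X at x equals
the window of Y at y (forward) or its reverse complement (reverse).
Defaults window 15, step 1, zero mismatches; exact windows are hashed
(linear expected time), fuzzy windows fall back to an all-pairs scan.
Diagonal runs (constant orientation, advancing (step, ±step)) segment the
plot; inversions appear as orientation changes between adjacent runs.

## Gene integrity (integrity)

Two deliberately different criteria are both reported: a gene is
*encompassed* when a single read's merged host span contains its whole CDS
span (gaps ≤1 kb within a read's host segments are bridged, since noisy
alignments fragment); *uncovered intervals* are the CDS span minus the
union of all reads' spans.  A gene whose CDS span intersects the called
integration interval (deleted bases, or the insertion point itself) is
flagged disrupted.  Uncovered intervals extended by a 300 bp flank and
merged become the windows a follow-up PCR assay must span.  UTRs are not
required — CDS only.

## qPCR (qpcr)

Comparative Ct with fixed efficiency `E = 2.0` (exposed as a parameter; no
efficiency correction is fitted):

    ΔCt_s  = mean Ct_marker(s) − mean Ct_housekeeping(s)
    ΔΔCt   = ΔCt_test − ΔCt_calibrator
    RQ     = E^(−ΔΔCt)
    copies_per_allele = RQ × calibrator_copies_per_genome / test_alleles

The SD comes from jackknifing the test sample's marker replicates.  The
calibrator is treated as carrying one marker copy per (diploid) genome by
default; both that and the test sample's allele count (1 heterozygous, 2
homozygous) are explicit parameters, because "copies per allele" is only
defined relative to those conventions.

The synthetic batch generator draws every well's Ct with i.i.d. Gaussian
noise (default SD 0.1 cycles, 6 replicates — typical intra-assay SYBR
precision; the SD of ΔΔCt is then `2σ/√n ≈ 0.08` cycles, i.e. ~6% on RQ,
consistent with the ~9% relative SD real batches of this kind show).
Recovery tests at these defaults find copies within 15% in ≥95% of
batches; that statement is about technical replication noise only, not
pipetting bias or inhibitors.

## Read simulator (simulate)

Reads are sampled from weighted haplotypes with log-normal lengths
(`exp(μ + σ²)` is the expected N50 — the length-biased median; defaults
give N50 ≈ 3 kb for desk-scale tests, and `lognormal_params_for_n50`
retargets e.g. 28 kb for full scale), uniform start positions *allowing
overhang* at the molecule ends (clipped; this makes expected coverage
exactly `total_bases / length` at every position, which the depth
estimator relies on), equiprobable strands, and i.i.d. per-base errors
(defaults 5% substitution, 2.5% insertion, 3.5% deletion — nanopore-like;
11% total).  The last read is length-clamped so total bases land within 5%
of the coverage target.  All randomness flows from one integer seed; a
fixed seed reproduces byte-identical FASTQ.

Not emulated: signal-level behavior, basecaller error structure
(homopolymer compression, strand bias, quality correlation), chimeric
adapter artifacts, coverage bias (GC, mappability).  Passing tests
therefore demonstrate correctness of the inference logic under a clean
error model, not robustness to every artifact of a real flow cell; the
PAF ingestion path exists precisely so real-data alignments from a
production mapper can be substituted.

## Degenerate inputs and determinism

Empty read sets classify to all-false; absent chimeric reads yield an
empty (not erroneous) call list; a registry without a contaminant target
rejects contaminant detection; tiling with no marker-bearing reads is an
error (empty evidence).  Every operation is deterministic given its inputs
and seed: ties in chaining break leftmost, cluster medians use the lower
median, and the pipeline report is byte-stable for a fixed config.

## Known limitations

- Copy-number estimates at low coverage are approximate by nature; the
  integer mode is only meaningful at coverage ≳ twice the copy number.
- The tiling bound depends on landmark density; a perfectly uniform array
  longer than the read length cannot be bounded above its junction-visible
  copies.
- Micro-inversions below the minimum segment length are invisible.
- The depth estimator's zygosity convention (above) must match how
  coverage was computed on real data.
- Gene integrity is positional (coverage), not sequence-level: SNP/indel
  integrity within covered CDS is out of scope.
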