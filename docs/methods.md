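# Methods

## Coordinate and counting conventions

All intervals are 0-based half-open (BED). An interval's center is
`floor((start + end) / 2)`; the floor makes even-width windows
deterministic and is below the resolution of every downstream bin.
Overlap means ≥1 shared bp on the same chromosome; adjacency
(`end == start`) is not overlap. Fragments are counted in windows by
their midpoint, one shared convention for both accessibility counting
and dyad mapping; an any-overlap counter is provided for comparison
but is not used by default.

## Fragment processing

Read pairs are collapsed to a single fragment spanning
`min(mate starts)..max(mate ends)`; inter-chromosomal pairs are
dropped and counted. Mono-nucleosomal selection keeps
120 ≤ length ≤ 170 bp — the bounds are read as a closed interval and
are configurable. Deduplication keys on `(chrom, start, end)` only,
which is all a post-alignment fragment file carries; it is applied for
ATAC and ChIP libraries and skipped for capture MNase, where targeted
deep coverage makes identical fragments expected rather than
PCR artifacts. The dyad estimate is the fragment midpoint with floor
rounding for odd spans (a ≤0.5 bp bias, below any bin size used).

## Depth normalization and signal matrices

"Normalized reads" are counts scaled by `target / library_size` with
target 10 million fragments. The target is a configuration knob;
10 M was chosen because it is a typical ATAC library scale, at which
the classifier's 30-reads-per-2-kb flank threshold separates open from
closed chromatin (a 10 M-fragment library on a ~3 Gb genome puts
~7 background reads in a 2 kb window, well under 30, while open
chromatin sits several-fold above it).

A signal matrix is anchors × bins of (scaled) midpoint counts in
`[center − flank + j·bin, center − flank + (j+1)·bin)`; the default
metaplot resolution is 10 bp bins over ±1 kb (±2 kb recommended for
dyad heatmaps, exposed as flags). Metaplots are column means
("reads/peak"). Timepoint normalization is entry-wise
`log2((a + 1)/(r + 1))`; the pseudocount guards empty bins, and the
matrix records its units (`raw_count`, `normalized_count`,
`log2_ratio`) so exported heatmaps are labeled honestly. bedGraph
export writes sorted, run-length-merged per-position counts × scale.

## Peak accessibility classification

The classifier consumes normalized midpoint counts in ±200 bp (center)
and ±1 kb (flank) windows of each peak for a pre- and a
post-induction library. Rules, evaluated in order:

1. `newly_accessible` iff
   `(center_post + 1)/(center_pre + 1) > 2` **and** `flank_post > 30`;
2. else `constitutively_accessible` iff `flank_pre > 30`;
3. else `constitutively_inaccessible`.

This order is the only precedence under which the three written
definitions are mutually exclusive; every peak gets exactly one label.
All inequalities are strict, so boundary values (fold change exactly
2, flank exactly 30) fall through to the next rule. The constitutive
split uses the **pre**-induction flank by default — "constitutive"
refers to the chromatin state before the factor acts — with a
`constitutive_on="post"` switch since the alternative reading is
defensible. The pseudocount of 1 in the fold change keeps fully
closed peaks finite. Thresholds (2-fold, 30 reads), window half-widths
(200/1000 bp) and the scale target are all parameters.

The count-matrix builder emits raw (unscaled) per-peak, per-sample
counts, the input format external differential tools expect;
differential testing itself is out of scope here.

## Consensus motif scanning and sampling enrichment

Patterns are IUPAC consensus strings matched exactly per position;
an `N` in the genome matches nothing, so assembly gaps never produce
sites. Both strands are scanned (reverse-complement pattern against
the forward sequence); a position matching on both strands is reported
once, on `+`, by default — without collapsing, every occurrence of a
self-reverse-complementary consensus like TGASTCA would be counted
twice. Consensus scanning is used rather than position-weight-matrix
scoring: the motifs analyzed here (WGATAR, TGASTCA) are defined as
consensus strings, and exact matching is parameter-free and exactly
reproducible.

Sampling loci are built by extending each site to 200 bp around its
center, then removing every window that overlaps an observed ChIP
peak — and every window that overlaps another window. Dropping *both*
members of a mutually overlapping pair is the conservative reading
(no signal is counted twice); keeping one member is available through
the underlying `remove_overlapping(..., also_remove_mutual=False)`
flag. Background regions are sampled with chromosome probability
proportional to length and uniform starts, without GC matching or
blacklist exclusion; equal count and width to the loci by default.
These are simplifications relative to real-genome practice and are
the documented assumptions behind the enrichment comparison.

Enrichment compares normalized per-locus counts with a two-sided
Mann–Whitney test: exact permutation null when `n1*n2 ≤ 10 000` with
no ties, otherwise the normal approximation with midrank tie handling
and continuity correction (group sizes in real scans are thousands).
A comparison in which every count is identical is degenerate and
reported as p = 1 with a flag.

The analytic expectation `expected_motif_spacing` computes the
per-position match probability as
`P(forward) + P(reverse-complement) − P(both)` under an i.i.d. base
composition; subtracting the both-strand overlap matches the
scanner's palindrome collapsing. Under uniform bases this gives
512 bp for WGATAR (8 of 4096 hexamers match either strand) and
8192 bp for TGASTCA (self-reverse-complementary: 2 of 16384
heptamers, each counted once).

## Synthetic data

The generator emulates the fragment-level structure of a
pioneer-factor induction experiment with and without a nucleosome
remodeler, at a scale a laptop can verify. What it models:

* **Genome and sites.** A uniform random chromosome (default 5 Mb)
  with `n_sites_per_class` (default 300) planted motif instances per
  accessibility class, random strand, minimum separation twice the
  phased-array span so neighboring arrays never interleave. Spurious
  motif occurrences are rewritten by single-base substitutions, so a
  consensus scan returns exactly the planted truth (an off switch
  exists for realism testing).
* **Nucleosomes (MNase).** Per site, dyads are drawn from a mixture:
  a motif-covering component with weight `occupancy_over_motif`
  (control defaults 0.2/0.3/0.5 for newly accessible / constitutively
  accessible / constitutively inaccessible) and a phased array at
  ±k·190 bp, k ≤ 3, jitter SD 20 bp, with total flanking weight
  `eviction_shift` (control 1.0). Remodeler depletion ("kd") raises
  the flanking amplitude (1.5) and halves motif occupancy at closed
  sites (0.5 → 0.25) — more alleles with a productively bound factor
  phase the array while dyads move off the motif. Fragment lengths are
  truncated normal (150 ± 12, clipped to 100–200 bp), 30% uniform
  background.
* **Accessibility (ATAC).** Poisson background at 0.005 events/bp —
  the per-bp rate of a 15 M-fragment library on a 3 Gb genome — plus
  class/condition rates in ±200 bp of each site: newly accessible
  0 → 0.15 events/bp upon induction (>4-fold center increase with
  flank support), constitutively accessible 0.15 in both conditions,
  constitutively inaccessible 0 in both. Fragment lengths uniform
  60–120 bp.
* **ChIP.** Fragment centers normal (SD 60 bp) around motifs with
  per-site weight ∝ occupancy (per-class map or per-site vector; weak
  uniform occupancy models sub-peak motif sampling), sonication-like
  lengths (200 ± 40, 100–300 bp), 50% uniform background.

Because the simulated chromosome is a window of a notionally larger
genome, `SimConfig.library_size` (default 15 M, consistent with the
background rate) declares the full-library total that depth
normalization should divide by; `SimConfig.scale_factor()` returns the
matching factor. Effect magnitudes are free parameters with the
defaults above — the underlying biology fixes directions, not
generative rates — and each emitted file uses an RNG stream derived
from `(seed, crc32(file tag))`, so regenerating one assay never
perturbs another and every file is byte-reproducible.

What the simulation does **not** model: sequence composition (GC
tracts, mappability), capture-probe pull-down bias, PCR duplicate
structure, inter-replicate variability, or sub-/di-nucleosomal MNase
classes. Passing recovery tests therefore demonstrates correctness of
the computations under the stated generative model, not robustness to
every artifact of real libraries.

## Validation design

The test suite checks implementations against independent oracles:
per-position naive scanning for the motif scanner, per-event recounts
for signal matrices, exhaustive pair enumeration for the Mann–Whitney
U, quadratic filters for interval algebra, and exhaustive k-mer
enumeration for the analytic motif density. End-to-end recovery runs
use the default simulation (900 sites, fixed seed): ≥95% planted-class
recovery; dyad-metaplot autocorrelation within ±10 bp of the planted
190 bp spacing at 10⁵ fragments; kd/control log2 dyad ratios positive
at flanking-array bins and negative at motif-central bins (3σ across
sites) at constitutively inaccessible sites; Mann–Whitney p-values
uniform under a uniform-events null (200 replicates, KS test). Problem
sizes (5 Mb genome, 10⁵-fragment assays, 200 null replicates) were
chosen so the full suite completes in a few minutes while leaving the
statistical checks well-powered.

## Numerical notes and edge cases

Empty peak or anchor lists error in library calls that cannot return a
sensible value (metaplot) and exit cleanly with empty outputs in the
CLI. Anchors on chromosomes absent from an event set produce zero
rows with a warning, mirroring a peak list against a library missing a
contig. Degenerate mixtures (all occupancies zero) yield
background-only or empty fragment sets rather than errors. Random
region sampling, simulation and the acceptance script derive every
random draw from explicit integer seeds; nothing uses global RNG
state.
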