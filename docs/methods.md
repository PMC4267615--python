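# Methods

This note documents the models, defaults and design decisions behind
`cas9rvl`, and what the synthetic data can and cannot establish.

## Coordinate system and library model

The analyzed molecule is the 35 nt variable insert of a plasmid target
library, indexed −5..29 left to right. The layout is fixed: 6 nt 5′ flank
(−5..0), 20 nt protospacer (1..20, position 1 PAM-distal), PAM (21..23,
NGG — the N at 21 is unconstrained), 6 nt 3′ flank (24..29). Every public
interface uses these position labels; 0-based indexing exists only inside
`library.py`.

Doped synthesis is modelled per position, independently: the 22 doped
positions (protospacer + the two PAM guanines) carry the canonical base with
probability 1 − r and each of the three alternatives with r/3; the 13 fully
random positions (flanks + PAM N) are uniform over the four bases. The
default doping rate r = 0.10 reproduces the standard "10% variant rate,
~3.3% per alternative base" synthesis recipe for such libraries; per-position
overrides allow emulating pools where synthesis over- or under-doped
individual positions. Species identity is the exact 35-mer; two molecules
with the same insert are one species, and the mismatch count deliberately
ignores the flank context and the PAM N (a variant signature covers doped
positions only). Whether highly-mutated classes such as "4–7 mismatches"
should count the PAM N is genuinely ambiguous; we count doped positions
only, consistent with treating position 21 as part of the random context.

Reads are assigned to species by exact match after optional constant-adapter
trimming. There is no error-tolerant clustering: a species is defined by its
full 35-mer and any collapsing rule would blur the variant signatures the
analysis keys on. Reads with indels, partial adapters, wrong length or
non-ACGT characters are tallied as unassigned (a >50% unassigned fraction
logs a warning but never aborts). Reverse-complement reads are not
auto-detected; the `count --rc-retry` flag retries unassigned reads as
reverse complements.

## Retention scoring

For species X, `Representation_X = count_X / count_reference` within a
sample, and `Retention[X]` is the log2 ratio of cleaved to uncleaved
representation. Two interchangeable reference populations are supported:

* `mismatch_class` (default): the aggregate of all retained species with
  4–7 doped-position mismatches, computed per library from the signatures;
* `spike_in`: a configured set of unrelated-target control species.

The minimum-representation filter retains species with ≥ `min_count`
(default 50) reads in the uncleaved sample; when several uncleaved
replicates exist their sum is used. The filter is applied before reference
construction, so the reference aggregate is itself well covered; a reference
aggregate under 500 reads in any sample triggers a warning (not an error).
Library complexity is reported as the number of species passing this filter.

A species with zero cleaved reads has *undefined* retention: we emit NA
rather than −∞ or an imputed floor, exclude such cells from medians, and
count them in the output metadata. A +0.5 pseudocount mode exists behind a
flag for users who prefer finite scores, but it fabricates magnitudes for
exactly the most-cleaved species and is off by default.

## Variant aggregation

Single-variant cells use two rules. Target-region cells (doped positions,
non-canonical base) take the median over species whose doped-region
signature is *exactly* that one variant — flanks free, no additional
mismatches. Flank and PAM-N cells take the median over species with a
perfect target+PAM region and the indicated base at the position. The WT
summary is the median over all perfect-target species. Cell dispersion is
the sample SD (ddof = 1) across the aggregated species' retentions; cells
with no qualifying species are reported empty, never as errors.

The heat map divides each cell median by the WT median, so ≈1 is WT-like,
≈0 uncleaved and >1 faster-than-WT depletion. No clamping of positive
retentions is applied before the ratio. A WT median of exactly 0 (or
undefined) makes the ratio meaningless and is refused at the operation
level; the pipeline then reports an all-NA heat map rather than aborting.

The double-variant matrix spans positions 1–23 × 4 bases (92 elements).
Off-diagonal cells are medians over species with exactly that signature
pair; pairs involving position 21 condition single-mismatch species on their
PAM-N base. Cells whose element is the canonical base of a doped position
are WT-flagged and carry no number; cells with fewer than `n_min` (default
1) qualifying species are masked. The diagonal repeats the single-variant
medians so the matrix is self-contained.

Synergy is `(LR_M12/LR_WT) / [(LR_M1/LR_WT)·(LR_M2/LR_WT)]`, computed only
where both singles are covered and — when counts are integers — both pass a
detectable-cleavage test: a two-sided Fisher exact test on the 2×2 table
(species vs reference aggregate × cleaved vs uncleaved) at α = 0.05,
combined with a depletion sign requirement so that enrichment is never
called cleavage. The exact-conditional choice fits the raw data (small
integer counts) and needs no variance model; the sign guard matters because
a two-sided test alone would flag significantly *enriched* species. With a
WT that is not detectably cleaved (LR_WT ≥ 0) synergy is refused, not
clamped.

## Cleavage simulator

Each species' cleavage weight w multiplies per-mismatch penalty factors
(and optional flank modifiers near 1); a perfect match has w = 1. Survival
follows a two-population mixture of exponentials,

    s(w, t) = f·exp(−k_fast·w·t) + (1 − f)·exp(−k_slow·w·t),

the simplest form that reproduces burst-then-slow cleavage and lets variants
lag early and catch up later. The weight scales both rates; whether enhanced
cleavage acts through rate or burst fraction is unknown, so both knobs
exist, with rate scaling the default. Defaults f = 0.3, k_fast = 0.5/min,
k_slow = 0.01/min give a perfect target ≈ 12% survival at 180 min — a
strongly but incompletely cleaved WT, the regime in which retention assays
are informative. Default timepoints 15/60/180 min span the fast and slow
phases.

The default penalty profile is a set of synthetic fixture constants, not
measurements: PAM transversions 0.01 (transitions 0.3/0.15 at positions
22/23), seed and PAM-distal (3–5) transversions 0.05 with transitions 0.5,
intermediate positions 6–8 at 0.3/0.7, mild positions 1–2/19–20 at 0.6/0.9,
and a 1.3× enhancement at positions 9–11 (capped at 2). These values encode
the qualitative specificity landscape (transversions worse than transitions,
seed and PAM critical, central enhancement) so that recovery tests have
non-trivial structure; every entry is configurable.

Sequencing is a multinomial draw of `depth` reads over species proportions
per sample, with optional static per-species PCR bias (identical across
samples, hence cancelling in retention — sample-specific bias can be
configured to study protocol artefacts qualitatively), optional per-base
substitution error when writing FASTQ, and an `expected` mode that emits
noise-free expectations for closed-form checks. Spike-in species have w = 0
by construction. Under f = 1 (single-exponential) kinetics and exact
expectations, log retentions are exactly −k·w·t·log2(e) relative to an
uncleaved reference, so multiplicative weights make every double-variant
synergy exactly 1 — the identity the test suite verifies to 1e−9.

### What the simulator does not emulate

Real amplicon data have position- and context-dependent sequencing error,
indels, chimeric PCR products, cycle-dependent amplification bias, and
cleavage kinetics that need not be two-exponential or weight-separable.
Passing tests therefore demonstrate that the *analysis* is correct under a
known generating model and calibrated sampling noise — not that the default
penalty constants describe any particular enzyme preparation. Fitting
kinetic or penalty parameters to real data is explicitly out of scope.

## Numerical and design choices

* Median/SD aggregation ignores NA retentions; SD needs n ≥ 2, else NA.
  The "SD of the median retentions" error bar is computed across the
  retentions of the species aggregated into that median at that timepoint.
* The demo guide (`demo_target_spec`) is synthetic; its canonical bases at
  positions 4, 11, 16, 20 (C, C, G, T) were chosen so that classic named
  variants (C4T, C11T, G16C/T, T20A) exist. Position 0 carries a G,
  mirroring the guanine that gRNA expression vectors prepend; analytically
  it is an ordinary flank position.
* Reads are counted order-independently; output rows sort by
  (mismatch_count, sequence); floats serialize with `%.10g`; JSON keys are
  sorted — together this makes every artifact byte-reproducible for a fixed
  config + seed.
* Configuration is validated as a whole before any stage runs; unknown keys
  are rejected with field paths.
* Scale of shipped experiments: the test suite simulates libraries of
  150–2,150 species at depths of 10⁵–10⁶ reads (10⁸ expected-count units
  for the noise-free identity checks), sizes at which binomial standard
  errors on retention are ≪ the 0.05–0.1 tolerances asserted.

## Known limitations

* Exact-match counting means sequencing errors leak species into neighbors'
  signatures; the simulator can generate such errors, but the counter will
  not correct them.
* The detectability test is skipped in expected-count mode (no integer
  counts to condition on); synergy is then gated only on coverage.
* Double-variant cells default to n_min = 1 (a single species defines a
  cell median); raise `analysis.n_min` for noisier data.
* No triple-or-higher variant analysis, genome-wide off-target scanning, or
  absolute cleavage-fraction estimation.
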