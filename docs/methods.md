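# Methods

## Detection model

The unit of data is a biallelic site with ref/alt read counts in two
pools (`PooledSiteCount`). Pool 1 is the heterogametic sex by convention;
`DetectorParams.heterogametic_pool` swaps the roles for WZ systems, so
"male pool" below means "heterogametic pool".

A site is **sex-patterned** when

1. the major allele of the homogametic pool has frequency
   ≥ 1 − `homog_fixed_max` (default 0.1, so ≥ 0.9),
2. the *other* allele has frequency within [`het_low`, `het_high`]
   (default [0.3, 0.7], closed on both ends) in the heterogametic pool, and
3. that candidate sex-linked allele has ≥ `min_allele_count` (default 2)
   reads in the heterogametic pool.

Sites with depth < `min_depth` (default 10) in either pool are marked
unevaluated and never classified. The inclusive 0.3/0.7 boundaries and the
0.1 "nearly fixed" cutoff are deliberate interpretations of the verbal
criteria; all three are parameters, and the near-fixed cutoff in
particular is this package's default rather than a community constant.
The minimum-allele-count filter is applied to the candidate Y (or W)
allele because that is the allele whose reality the filter protects; it
also absorbs sequencing error, which is why the simulator ships with
error off by default.

## Per-site statistics

With alt frequencies `p_x` (heterogametic) and `p_y` (homogametic) and
pool depths `n_x`, `n_y`:

- `π_pool = n/(n−1) · 2p(1−p)`; `π_S = (π_x + π_y)/2`; `π_T` computed by
  the same formula from the summed counts; `F_ST = (π_T − π_S)/π_T`.
  Because the finite-sample correction is `n/(n−1)` within a pool but
  `2n/(2n−1)` for the total, the raw estimator is slightly negative for
  identical pools; estimates are truncated to [0, 1] so that identical
  pools report exactly 0. `F_ST` is *undefined* — written `NA`, never
  0 — when either depth < 2 or `π_T = 0` (monomorphic combined data).
  This matters downstream: region-level "mean F_ST across polymorphic
  sites" averages only sites where the statistic is defined.
- `d_xy = p_x(1−p_y) + p_y(1−p_x)`; `d_a = d_xy − π_S` with the same
  corrected `π`. These are the standard single-site Nei definitions;
  `d_a ≤ d_xy` always, with equality iff both pools are monomorphic.
- Nei's `D = −ln I`, `I = Σx_i y_i / √(Σx_i²·Σy_i²)` over the two allele
  frequency vectors. `I = 0` only at alternatively fixed sites; exactly
  there, frequencies 0 and 1 are first replaced by `1/max_coverage` and
  `1 − 1/max_coverage` (`max_coverage` default 100), making the maximum
  attainable D a known function of the user's coverage ceiling. Partial
  fixation is never clamped.
- `C_P = Σ ½|x_i − y_i|`, which for biallelic sites reduces to
  `|p_x − p_y|`; the general form is kept (and tested against the
  reduction) because the identity is a useful internal check.

## Windows, regions, tests

Windows tile each chromosome from coordinate 0, non-overlapping, default
10 kb; the trailing partial window keeps its true span. A 1-based site
position `pos` belongs to window `⌊(pos−1)/size⌋`. Assembly gaps (BED,
merged on ingest) are subtracted from each window's effective length;
windows entirely inside gaps are excluded from density statistics. A
window is *enriched* at ≥ 10 sex-patterned SNPs (inclusive).

Regions are named interval sets; "rest of genome" is constructed as the
complement of the named regions. A window belongs to a region when its
midpoint falls inside it — an unambiguous rule for windows straddling
region boundaries. Densities are reported per Mb with half-up rounding to
2 decimals.

Region comparisons use a two-sided Mann–Whitney U on per-window
sex-patterned SNP counts: the exact null distribution when
`n_a + n_b ≤ 16` with no ties, otherwise the normal approximation with
tie and continuity corrections (scipy's implementation behind this
module's surface). The significance threshold is `α/m` rounded half-up to
6 decimals; the family size `m` (default 12) is an explicit parameter
because the comparison family is study-specific.

## Shared SNPs across species

Both species must be mapped to one reference; positions are compared
directly (no liftover). At a site sex-patterned in both species, X is the
allele fixed/near-fixed in the homogametic pool and Y the intermediate
one. Classes are checked in order: CONSERVED (`X_a=X_b ∧ Y_a=Y_b`),
SWITCHED (`X_a=Y_b ∧ Y_a=X_b`), SAME_X_DIFF_Y (`X_a=X_b ∧ Y_a≠Y_b`),
OTHER. OTHER is reported even though it is typically empty, so the
classes always partition the intersection. The null expectation for the
shared count in a region of length L is `n_a·n_b/L` — independent uniform
placement of each species' sex-patterned SNPs — reported both unrounded
and at 2 decimals; no significance test is attached, only the ratio of
observed to expected.

## Conserved CNVs

Input is VarScan-copynumber-style segments (1-based inclusive in the
file, converted to half-open internally). Direction thresholds are
inclusive: AMP at `log2 ≥ 0.2`, DEL at `log2 ≤ −0.2`. A conserved CNV is
a maximal interval covered by a same-direction call in **all** n
comparisons (`min_support` relaxes this); the implementation sweeps
elementary intervals and is tested for equality with a literal per-base
vote. Window densities count each conserved CNV once, at its midpoint.

## TFBS scanning

PFM → PWM per the common JASPAR-tool convention:
`cell = log2(((count + pc·bg_b)/(col_total + pc))/bg_b)` with
pseudocount `pc = 0.8` distributed by a uniform background; both are
parameters. A hit is reported when the relative score
`(raw − min)/(max − min)` reaches 0.80; both strands are scanned (reverse
strand via the reverse-complemented matrix), windows containing non-ACGT
characters are skipped with a warning. For an X/Y variant, each allele is
substituted into the flank and only windows overlapping the variant base
(within `flank_radius`, default 20 bp — comfortably above vertebrate
motif lengths) are compared, so a status of LOST_ON_Y / GAINED_ON_Y is
attributable to the SNP itself; distal hits cannot drive the call.

## Synthetic data

The generator emulates the study design: a single XY family sequenced as
a 21-male and a 22-female pool at mean 35× per pool. At sex-patterned
sites the chromosome-level Y frequency in the male pool is exactly
`n_males/(2·n_males) = 0.5` and 0 in the female pool; all variance in the
read counts comes from Poisson depth and binomial allele sampling.
Background polymorphism draws a shared population frequency from the
uniform folded spectrum {0.1, …, 0.9} and snaps it per pool to the
`k/(2n)` chromosome-count grid — the simplest adversarial background,
since shared-frequency sites can satisfy the fixed-homogametic and
intermediate-heterogametic criteria only through sampling noise.
Sequencing error is an optional per-read allele flip, off by default.
Default densities (sex-patterned 6×10⁻⁴/bp in the SD region over a
2×10⁻³/bp background) follow the per-Mb densities the emulated design
reports; the analysis drivers use a denser SD region (2×10⁻³) so that a
1 Mb desk-scale genome yields a few hundred truth sites.

Species pairs: ancestral sex-patterned positions are drawn in the overlap
of the two SD regions and apportioned to conserved / switched /
Y-replaced fates by largest-remainder rounding (deterministic: requested
fractions of 100 sites give exactly those counts); the remainder is
private to species A and species B receives an equal number of fresh
private sites. The reference base is the ancestral X allele, so a
switched site in species B is near-fixed for the *alternate* allele in
females — deliberately exercising that detector path.

CNV tracks tile each true event into 100 bp–1 kb segments (VarScan's
window bounds) with |log2| drawn from [0.2, 1.5] and the event's sign in
every track; noise segments are placed in single tracks only, rejected
against overlap with any other placed interval.

What the simulator does *not* model: mapping bias, reference bias,
indels, linked selection, inversion breakpoints, GC-dependent depth, and
read-level error profiles. Passing recovery tests therefore shows the
statistical machinery is correct under the declared generative model, not
that real pooled libraries will achieve the same recall/precision.

## Numerical conventions

- Coordinates: native conventions at file boundaries (VCF/VarScan
  1-based, BED 0-based half-open); internally intervals are 0-based
  half-open and SNP positions 1-based; converters live only in the I/O
  layer.
- Undefined statistics are `NA` in TSVs, never 0.
- Result writers use fixed 6-decimal float formatting and deterministic
  column order; identical inputs produce identical bytes.
- Densities: half-up rounding, 2 decimals; Bonferroni α: 6 decimals.
- All randomness flows through `numpy.random.default_rng(seed)`; a fixed
  seed reproduces outputs byte-for-byte.

## Problem sizes

Tests and the analysis drivers run on 0.2–1.2 Mb simulated chromosomes
with ~1,000–7,000 sites and coverages of 10–10,000×: large enough that
binomial expectations hold to the tested tolerances (e.g. ~2,000 truth
sites at 35× give recall ≥ 0.90 and precision ≥ 0.99 with margin), small
enough to iterate quickly. The exhaustive PWM oracle covers all 4⁸
8-mers for motif lengths 2 and 4; the conserved-CNV per-base oracle runs
100 random 3-track instances on a 10 kb toy region.

## Known limitations

- The F_ST estimator is this package's normative definition (π-based,
  per-site, corrected as above); other pool-seq tools differ in masking
  and correction details, so absolute values are comparable only within
  this pipeline.
- Pool allele counts taken from VCF `AD` fields inherit the upstream
  caller's filters; no pileup recount is attempted.
- Only biallelic SNPs are analyzed; multiallelic records and indels are
  dropped at ingest with a logged count.
- The shared-SNP null assumes uniform, independent SNP placement within
  the region; clustering of polymorphism inflates the false-sharing rate
  relative to this null.
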