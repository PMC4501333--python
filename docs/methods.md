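# Methods

## The coverage signal (USHP)

All analyses run on the *unique stack height profile* (USHP): the per-base
pileup depth of uniquely aligned, deduplicated reads (one stack per
(chromosome, start, strand)), summarized per 20 bp bin. The per-bin summary
is the **mean** per-base depth within the bin (a `max` option exists); the
mean preserves tag-count arithmetic used by the downstream filters. Tracks
are RPM-normalized (`value × 10^6 / unique reads`) so thresholds compare
across libraries of different depth.

Track processing order is **mask → interpolate → smooth → blacklist**:

1. *Mappability masking.* Bins with uniqueness score < 0.5 **and** no
   coverage are flagged masked. Genuine signal over a low-uniqueness bin is
   left alone — the mask targets coverage holes created by unalignable
   sequence, not enrichment.
2. *Interpolation.* A maximal run of masked bins is assigned the mean of
   the nearest valid bins up- and downstream, provided both exist within a
   3-bin scan distance of the run edges and at least one of them carries
   signal ≥ 2× the genome-wide valid-bin mean ("flanked by enriched
   signal"). Isolated masked deserts stay masked. The relative order of
   interpolation and smoothing is not dictated by the signal model; fixing
   interpolation first avoids smearing masked zeros into real peaks.
3. *Smoothing.* 60 bp (3-bin) moving average centered on each bin. At
   chromosome ends the average runs over the available neighbors rather
   than zero-padding, which would manufacture artificial edge slopes.
4. *Input blacklisting.* Bins where the input (no-ChIP) track exceeds 10×
   its genome-wide mean are excluded from detection. "Subtraction" of input
   regions is implemented as removal, since the purpose of the step is to
   kill false-positive peaks over sequencing artifacts, not to estimate a
   background level.

The slope at bin *i* is `(USHP[i+3] − USHP[i−3]) / 100` (the bins 60 bp
down- and upstream; the printed divisor 100 is used even though the bin
centers are 120 bp apart). Slopes are undefined within 3 bins of a
chromosome end and wherever the ±3-bin support window touches a masked or
blacklisted bin.

## Feature detection

Features are intervals spanning a maximal run of above-threshold positive
slopes joined to the nearest downstream run of below-threshold negative
slopes, with at most 400 bp between the end of the rise and the start of
the fall; each fall is consumed at most once (upstream rise first).

* **Slope threshold.** No published value exists. The default is the
  scale-free rule `genome-mean USHP / 100` — one genome-mean of signal
  change across the slope divisor — calibrated once on the synthetic study
  (where it sits ≈ 2σ above the background slope noise at the default
  coverage) and left fixed. It is a free `DetectionConfig` parameter.
* **Multiplet merging.** Adjacent features merge when
  `min(max_left, max_right) / trough < 2.5`, the trough being the minimum
  smoothed USHP between the two summits. The ratio definition (the paper
  leaves the numerator unstated) uses the *weaker* peak: conservative, it
  merges only when the smaller peak is poorly separated. A zero trough
  never merges. Passes repeat left-to-right to a fixpoint.
* **Local background.** Features with centers within 2 kb are chained into
  a domain, the domain expanded ±1 kb; the background is the mean smoothed
  USHP over valid/interpolated domain bins not covered by any feature. A
  feature is kept iff `max USHP ≥ 3.5 × background` (inclusive). A domain
  with no non-peak bins keeps its features and logs a warning.
* **Signal threshold.** ≥ 20 unique tags per feature **or** tag density
  ≥ 14.5 tags/bp, on raw (unnormalized) unique-read counts. The 14.5
  tags/bp figure is implausibly dense for a per-bp unit and is most likely
  a per-bin or per-100 bp figure in origin; it is implemented as printed
  and exposed as configuration. In practice the ≥ 20-tag branch decides.

The union across condition tracks coordinate-merges accepted features and
records which conditions contributed each one.

## Condition response, attributes and clustering

Per-feature tag counts across the four conditions (LD, LD+DMI, HD, HD+DMI)
are scaled to a common library size. For each of the 6 pairwise comparisons
(a, b), the attribute is **up** if `(b+1)/(a+1) ≥ 2`, **down** if ≤ 1/2,
else **nc** (pseudocount 1 normalized tag; the standard guard for folds of
zeros). Stage groups apply a two-level, editable rule table in order:

| rule (LD vs HD, HD vs HD+DMI) | group |
|---|---|
| (·, up) | DMI-induced |
| (up, ·) | HD-primed |
| (down, ·) | uncommitted |
| otherwise | ambiguous |

This preserves the two-level logic — density response vs cocktail
response — without inventing the original's exact 3^6 → 19-cluster mapping,
which is not recoverable from what is published; the ambiguous group
absorbs what that mapping left unclassified. k-means (scikit-learn,
k-means++ init, fixed seed, 300-iteration cap, tol 10^-6; k defaults to 19
to echo the published cluster count) orders features within groups for heat
maps. Heat-map entries are `log2((count+pc) / (row mean+pc))`.

## Motif windows and screening

Motif windows cover the bins at or above the within-feature 75th percentile
of USHP (nearest-rank), expanded symmetrically to ≥ 400 bp (clipped at
chromosome ends) and excluded if the top-quartile span exceeds 600 bp;
overlapping windows merge. Screening is consensus-string based (no PWM):
the hybrid C/EBP|ATF4 8-mer TTKCATCA, the canonical palindromic C/EBP motif
TTGCNNAA, and the heterodimer family pattern TTRSATCA are matched as IUPAC
classes on both strands (reverse-complement hits reported on "−" at the
same left coordinate). A hit whose + and − spans coincide (palindromes) is
reported once. A sequence `N` (unknown base) matches nothing. Group
frequencies are fractions of windows with ≥ 1 hit, with Clopper–Pearson
95% intervals; windows containing both motifs count toward both fractions.

## Co-occupancy and titration statistics

Co-localization is summit-to-summit distance ≤ 200 bp by default (the 4 kb
figure used for density heat-map windows is display geometry, not overlap
calling; both are parameters — the original's calling distance is
unpublished). Per-cluster enrichment is the upper-tail hypergeometric
probability P(X ≥ k) for k co-occupied of n cluster features given K
co-occupied of N genome-wide, computed via `scipy.stats.hypergeom` (log
space internally); raw p-values by default, Benjamini–Hochberg on request.
Density matrices sample a track in fixed bins across summit ± 2 kb without
re-sorting rows, with an optional display saturation cap.

Titration series are classified per site: **detected** at ≥ 1 RPM,
**co-bound** at ≥ 0.5 RPM in every cistrome of the series, **gained** when
below 1 RPM at all lower concentrations and at/above it at the top. "Gained"
is used narratively in the source; this formalization (detected only at the
top of the titration) is the package's. `rank_extremes` returns the
strongest-/weakest-n sites by RPM with coordinate tie-breaks.

## The synthetic study

The generator emulates a four-condition RNAPII experiment with full ground
truth; every output is a pure function of (spec, seed) through numpy's
PCG64 generator, so runs are byte-identical.

* **Genome**: i.i.d. bases at GC 0.41 (human-like), with concrete motif
  instances written verbatim at recorded positions/strands (overlaps
  rejected).
* **Reads**: background read starts uniform at 0.1 reads/bp (Poisson
  counts; negative-binomial with dispersion 0.3 available), 36 bp reads.
  Each planted feature adds `multiplier × 0.1 reads/bp × width` reads with
  a triangular positional density (unimodal peaks — the shape the
  rise/fall detector assumes; rectangular and bimodal shapes exist to
  stress the merge rule). Stage patterns are multiplier vectors over
  (LD, LD+DMI, HD, HD+DMI): uncommitted (8,8,1,1), HD-primed (1,1,8,8),
  DMI-induced (1,1,1,8), ambiguous (8,8,8,8). With 8× enrichment over a
  ~3.6× background pileup, coverage inside peaks is ~30×. Note that a
  "silent" multiplier of 1 still adds one background-equivalent of reads,
  so weak residual peaks in inactive conditions are real features of the
  simulation, as in real RNAPII data.
* **Truth closure**: the truth table records *expected* counts
  `background × width × (1 + multiplier)`, so the attribute logic can be
  verified without sampling noise.
* **Mappability**: uniqueness 1.0 except planted zero-score gaps; reads
  whose start falls in a gap are removed (unmappable positions yield no
  uniquely aligned reads), half the gaps are planted inside peaks to
  exercise interpolation.
* **Input**: uniform background at half rate plus planted 50× artifact
  regions kept ≥ 5 kb from features.
* **IVC**: expected site strength `depth × c/(c + Kd)` with Poisson count
  noise. The saturation law is generator machinery for testing the
  classification logic, not a fitted binding model.

The packaged "mini" study is 2 × 500 kb chromosomes with 60 features
(15 per stage pattern) — small enough that the full pipeline runs in
seconds on one CPU, large enough for per-group frequency statistics.

## Null behavior envelope

On pure background, an accepted feature needs a smoothed bin ≥ 3.5× the
local background mean. Bounding the stacks contributing to a 60 bp
smoothing window by the Poisson count of read starts in its 95 bp support
window (60 + readlength − 1), the expected number of false features is at
most `n_bins × P(Poisson(95·rate) ≥ 3.5 × 0.9 × 60·rate)`, the 0.9 giving
10% slack for local-background sampling error. Deduplication only lightens
this tail (stack counts are sub-Poisson). At 30× coverage the envelope is
≪ 1 per megabase; observed false discoveries in the suite are zero.

## What the synthetic tests do not show

The generator has no sequence-composition bias, no fragment-length model,
no duplicate or error model, and mappability is binary. Passing recovery
tests therefore demonstrates the algorithmic correctness and calibration of
the pipeline under its own assumptions (unimodal peaks, uniform background),
not performance on real ChIP-seq, where peak shapes, background structure
and the unpublished HOMER-era thresholds of the original analysis all
differ. The published genome-scale numbers (peak counts, pie-chart motif
percentages, co-occupancy rates) derive from the deposited accession data
and are approachable only with that data and a genome build.

## Numerical and degenerate-input choices

* Percentiles are nearest-rank; ties at the cut keep all tied bins.
* "Nearest downstream" ties in run pairing go to the earlier-starting fall.
* Equal-strength peaks in `rank_extremes` split by coordinate order.
* Zero-trough doublets never merge (ratio treated as +∞).
* A background domain with no usable bins accepts its features, loudly.
* k = 1 clustering and empty window groups are legal and return the
  obvious degenerate answers; empty groups report "not applicable".
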