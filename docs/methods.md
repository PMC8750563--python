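# Methods

## Coordinate and data model

All intervals are 0-based, half-open (BED convention), sorted by
(chromosome, start). A `GenomeModel` pairs chromosome sizes with an excluded
mask — blacklist-style artifact regions, assembly gaps, centromeres — which
is removed from desert statistics and from the sampling space of every
shuffle and simulation. Peak scores are accessibility intensities from the
upstream peak caller; all matrix work happens on the log₂(score + 1) scale.

## Peak merging

Merging follows center-distance semantics: two peaks unify when their centers
are within `merge_distance` (default 300 bp), and the relation is closed
transitively, so chains of nearby peaks collapse into one region spanning the
union of members. Because centers on one chromosome are totally ordered,
linking consecutive center-sorted peaks is an exact implementation of the
transitive closure (verified against a union-find all-pairs oracle in the
test suite). Each merged region records which input conditions contributed,
which drives condition-sharing (Venn) counts. When a condition contributes
several peaks to one merged region, its raw score for that region is the
maximum of the contributors.

## Gaps and peak deserts

Gaps are defined only between consecutive peaks of a merged set on the same
chromosome (`next.start − prev.end`); distances to chromosome ends are not
counted, so telomeric stretches never register as deserts. A desert is a gap
whose *effective* length — raw gap minus the base pairs it shares with the
excluded mask — exceeds `desert_min_gap` (default 1 Mb). Subtracting masked
bp from the gap (rather than splitting the gap at masked blocks) is the
simpler of the two defensible readings; with large contiguous masks the two
coincide in practice.

## Score matrix, quantile normalization, correlation

Cross-condition merged peaks are recentred to fixed `bin_size` windows
(default 300 bp; windows near a chromosome start are clamped at 0, keeping
their width). A condition that called no peak in a bin scores 0, not NA —
the absence of a called peak is informative, and it keeps quantile
normalization well defined. Quantile normalization maps the value at rank r
in each column to the mean of the rank-r values across the original columns;
ties are resolved by original row order (stable argsort), which makes the
operation exactly idempotent and leaves every column with the identical
sorted multiset. Condition similarity is the Pearson correlation of the
normalized columns over all bins (bins scored in only one condition
included; restricting to doubly-scored bins is possible by filtering rows
first, but all-bins is the default because absence is part of the signal).

## MPS / DPS classification

For a condition pair (a, b) on the log scale: MPS = (a + b)/2 and
DPS = a − b. MPS < 3 is "low accessibility", MPS > 5 "high", otherwise
moderate; |DPS| > 2 (a ≥ 4-fold change in the linear domain) is a major
accessibility change, signed by the direction of DPS. Thresholds are
surfaced in `PipelineConfig` (`mps_low`, `mps_high`, `dps_major`).

## Poisson differential peaks

Tag counts are compared depth-independently: the background count is scaled
by `depth_target / depth_background` to give the null rate λ, and a peak is
differential when `tags_target / λ ≥ 4` and the cumulative Poisson tail
P(X ≥ tags_target | λ) < 10⁻⁴. A zero background receives a 0.5 pseudocount
before scaling so fold and p remain finite. Flagged peaks are annotated to
the nearest TSS and joined to per-gene expression fold change
`(xₐ + ε)/(x_b + ε)` (ε = 1), the classic ratio-with-pseudocount.

## TSS annotation

Distance is peak center minus TSS position, sign flipped for minus-strand
genes so positive always means downstream. Nearest is by absolute distance
among same-chromosome TSSs; exact ties break to the lexicographically
smallest gene id (a deterministic convention, asserted in tests).

## Permutation overlap enrichment

The observed statistic is the total base-pair overlap between query and
reference (internal overlaps in each set collapsed first). The null shuffles
a length-matched copy of the query: each region is re-placed independently
and uniformly over *every* start position at which it fits entirely within
an unmasked span, genome-wide. Sampling is exact — spans are weighted by the
number of starts they admit for the region's length — rather than
rejection-based, so placements are provably uniform and a region that fits
nowhere raises immediately. Shuffled regions may overlap one another; the
null preserves chromosome structure only through the mask. The empirical
p-value is `max(1, #{null ≥ observed}) / n_permutations` — one-sided
(enrichment), with floor 1/N, so 1,000 permutations bottom out at exactly
0.001. Fold enrichment is observed over null mean (infinite, with a warning,
if the null mean is zero). Bonferroni adjustment (`min(1, m·p)`) is applied
across multiple tests.

## Motif scanning and enrichment

PWMs are 4 × L base-probability matrices with a 0.001 pseudocount
(renormalized) and a uniform background by default. A window scores the
maximum over all offsets and both strands of Σ log₂(p_base/bg_base); N and
repeat-masked (lowercase) positions contribute 0 (background odds). The
detection threshold defaults to 80% of the PWM's maximum achievable score —
high enough that an 8-bp consensus rarely fires in uniform DNA, low enough
that every planted consensus is detected. Windows are fixed-width (default
50 bp) and centered on peak centers, shifting left one base when parity
forces a choice; windows crossing a chromosome end or the excluded mask are
dropped (and counted). Enrichment of target vs background window hit counts
is the cumulative hypergeometric tail P(X ≥ target_hits) with population =
all windows, successes = all hit windows, draws = target windows; motifs
with p > 10⁻¹² are excluded from the reported set. Condition dynamics are
expressed as percentage-point differences of the target percentage versus
the untreated control. The enrichment table is emitted sorted by p; a
ranking by percentage change is a column away, since which criterion defines
"top differentially enriched" is a presentation choice.

## 76GS EMT scoring

The weight of signature gene *i* is its Pearson correlation with the anchor
gene (CDH1) across samples; the anchor's own weight is 1 and zero-variance
non-anchor genes get weight 0. The per-sample raw score is the weighted sum
over signature genes present in the matrix (missing genes trigger a warning
and a coverage fraction; scoring proceeds on the intersection). Final scores
subtract the cross-sample mean, so they always average to zero; positive
reads as epithelial, negative as mesenchymal. Signed correlations are used
as stated — no absolute-value variant. Expression input is assumed already
normalized (TPM-like); quantification is out of scope. Because Pearson
weights are invariant to positive affine transforms of any one gene, the
score is robust to per-gene scale conventions (asserted as a property test).

## Synthetic data: what it emulates, and what it does not

The generators produce every pipeline input with planted ground truth:

- **Genome/mask** — non-overlapping ~50 kb mask blocks placed at random to an
  exact target fraction (default 5%).
- **Peak sets** — truncated-normal lengths (mean 500 bp, SD 120, floor 50 bp
  so every peak hosts a 50-bp motif window), placed by rejection against the
  mask and each other; multi-condition sets share a configurable core (default
  250 shared + 60 unique per condition) with lognormal scores.
- **Tag counts** — Poisson, rates proportional to region length, background
  summing to the configured depth (default 2 × 10⁴ over 400 regions, i.e.
  ~50 tags per region); target rates multiply in the planted fold effect
  (default: 5% of regions at 8-fold), consistent with the cumulative-Poisson
  differential test the counts feed.
- **Motif windows** — exactly `round(rate · n)` windows carry the consensus
  at a random offset/strand in otherwise uniform DNA; per-condition plant
  rates default to 17.1 / 18.9 / 18.8 / 17.1%, the AP-1 dynamic shape across
  untreated, short-term, long-term and withdrawn conditions.
- **Nested queries** — `round(inside_fraction · n)` query regions wholly
  inside reference regions, the rest uniform over the unmasked genome.
- **Expression** — signature genes vary linearly along a per-sample EMT axis
  in [0, 1] (epithelial-direction genes, including the CDH1 anchor, high at
  0), baseline 10 ± amplitude 5 on a positive linear scale, additive Gaussian
  noise (default SD 0.5), floored at 0.01. Pearson-based 76GS weights are
  scale-free, so the linear scale is sufficient.

One master seed fans out to stable per-generator child seeds, so each input
can be regenerated independently and byte-identically.

What the simulation does **not** emulate: real ATAC fragment-length and Tn5
insertion bias, GC- and mappability-structured backgrounds, correlated peak
score structure along the genome, realistic motif information content beyond
a near-deterministic consensus, or the mRNA count distributions of real
RNA-seq. Passing tests therefore demonstrate the correctness of the
statistics and their recovery of planted effects under the stated sampling
models — not performance on the signal structure of real chromatin data.

## Problem sizes and numerical choices

Default fixtures use a 15 Mb two-chromosome genome, ~500 peaks per
condition, 400 tag-count regions, 200 motif windows per condition and 1,000
permutations; a full `run-all` completes in well under a minute on one CPU,
and the whole test suite in a few seconds. Degenerate inputs are handled
explicitly: empty BED files parse to empty sets; zero-variance columns are
rejected in correlation; constant genes contribute z = 0 in signature
summaries and weight 0 in 76GS; p-values outside (0, 1] are rejected by the
Bonferroni routine; a merged set is required (and checked) wherever gaps are
defined.

## Known limitations

- The center-distance merge is this package's reading of the referenced
  tool's documented semantics; other tools merge by bp-overlap and will give
  different Venn counts on the same inputs.
- Genome-wide published numbers (e.g. 113,680 vs 175,103 peaks, 185 → 99
  deserts, pairwise R² 0.81–0.94) arise from real deep-sequencing data
  processed through external aligners and peak callers and are
  integration-scale observations, not desk-scale test targets.
- The shuffle null is genome-wide uniform; it does not preserve
  per-chromosome region counts, local clustering, or GC composition
  (regioneR-style circular permutation and GC-matched nulls are out of
  scope).
- The published 76-gene list is configuration data; a synthetic stand-in
  signature (CDH1 anchor + placeholder genes) ships for testing and is
  labelled as such.
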