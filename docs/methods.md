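# Methods

This note documents the statistical and algorithmic choices behind
`interset`: what exactly is computed, which conventions were fixed where
the field leaves them open, and what the synthetic test data do and do not
establish about behaviour on real data.

## Interval model and normalization

All coordinates are 0-based half-open `[start, end)`, the BED convention.
GFF/GTF features `[s, e]` (1-based closed) become `[s−1, e)`; a VCF record
at POS with reference allele REF becomes `[POS−1, POS−1+len(REF))`. Only
CHROM/POS/REF of VCF records are consumed.

Every statistic operates on *merged* sets: intervals sorted by
(chromosome, start) with overlapping **and book-ended** neighbours
unioned, so consecutive intervals are separated by ≥ 1 base. Book-end
merging matches the default semantics of the standard interval toolkits;
it means two abutting peaks count as one region. Merging is idempotent
and preserves covered bases.

Zero- or negative-length records are skipped at parse time with a counted
warning rather than a fatal error, because real-world BED exports contain
them; the per-file tally is available in the parse report and logged by
the CLI. Strand is parsed and preserved but ignored by all intersection
statistics — a documented limitation; none of the computed quantities are
strand-aware.

## Membership decomposition

For *n* sets the union is cut into *fragments*: maximal intervals over
which the membership bitmask (bit *i* set ⇔ inside set *i*) is constant.
The sweep collects all merged-interval endpoints per chromosome, ORs each
set's bit into the segments it covers, and coalesces adjacent segments
with equal nonzero mask. Fragments are disjoint, sorted, cover exactly
the union, and are independent of input order up to bit relabeling.

Two counting modes are derived from the fragments:

- **base-pair mode**: count(mask) = Σ lengths of fragments with that mask.
  Sums to the union's covered bases by construction.
- **region mode**: count(mask) = number of maximal constant-mask
  fragments.

Region-mode counting is a deliberate design decision. "Number of
overlapping peaks" is ambiguous for interval Venn categories: when one
peak of A spans two peaks of B, peak-wise counts depend on which set is
treated as the reference. Counting maximal constant-membership blocks is
symmetric in the inputs, order-independent, and has an exact per-base
oracle (assign each base its bitmask; count maximal runs), which the test
suite exploits on hundreds of random fixtures. The cost is that a
region-mode count is a property of the *union geometry*, not of any one
input set's peak list; users comparing against reference-set conventions
should expect different numbers.

The decomposition is capped at n = 16 sets (bitmask width, and 2¹⁶
categories is already far beyond visualization); Venn rendering is capped
at 6.

## Pairwise statistics

With A, B merged:

- `overlap_count(A,B)`: A intervals overlapping ≥ 1 B interval by ≥ 1
  base. Computed with a binary search on B's starts; since B is merged,
  its ends are increasing, so only one candidate needs checking.
- `overlap_fraction(A,B) = overlap_count(A,B)/|A|` — interval-wise, not
  base-pair-wise (the choice is documented, not canonical), asymmetric,
  with the matrix row as the query set. An empty query set is an error.
- `jaccard(A,B)` — base-pair intersection over union. Both sets empty is
  defined as 0 with a warning.
- `fisher(A,B,genome)` — the 2×2 table is a genome-slot heuristic (the
  test itself is named in the literature but its table construction for
  intervals is not): n11 = overlap_count(A,B); n12 = |A| − n11;
  n21 = |B| − overlap_count(B,A); n22 fills the remainder of
  S = ⌊2G/(meanLenA + meanLenB)⌋ background "slots", G the total genome
  length and meanLen the covered bases per interval. On that table the
  left, right, and two-sided p-values are the exact hypergeometric ones
  (two-sided = total probability of tables no more likely than observed,
  at fixed margins), and the odds ratio is the sample odds ratio
  n11·n22/(n12·n21) (∞ when only the denominator vanishes). The table
  heuristic affects the *table*, never the exactness of the p-value given
  the table; treat absolute p-values as indicative, not calibrated.
- `reldist(A,B)` — for each A midpoint m with flanking B midpoints
  l ≤ m ≤ r on the same chromosome: min(m−l, r−m)/(r−l) ∈ [0, 0.5].
  Midpoints are ⌊(start+end)/2⌋. A midpoints outside B's midpoint range
  are skipped; duplicate B midpoints (r = l) score 0 by convention.
  Under a uniform null the mean is 0.25; values concentrated below 0.25
  indicate spatial attraction, above 0.25 repulsion.

### Matrix assembly

`pairwise_matrix` fills all n×n cells. Scalar summaries where a cell
needs one: the `reldist` cell is the distribution **median** (NaN when no
midpoint is scorable); the `fisher` cell is −log₁₀(p_two_sided) capped at
320 to stay finite in text outputs and color scales. Diagonal cells are
the identity values of each metric (1 for frac/jaccard, |A| for count, 0
median for reldist, the cap for fisher). Merged interval counts per set
are recorded for the marginal bar plot.

### Correlation and clustering

`correlate_matrix` correlates **columns** of the metric matrix
(pearson/spearman/kendall via pandas, average ranks for ties). With the
row-as-query convention, column j is "how set j is hit by every query",
so the correlation measures whether two targets are hit similarly by all
data sets — the right structure for clustering data sets, as in
co-binding analyses. Zero-variance columns give NaN cells plus a warning;
clustering refuses matrices with NaN and asks the user to impute or
switch metrics.

`hierarchical_order` clusters the **row** vectors with scipy. The eight
linkage methods are single, complete, average, mcquitty (scipy
"weighted"), centroid, median, ward, and ward2. The two Ward variants
follow the R convention: `ward2` squares the input dissimilarities
(scipy's `ward`), while `ward` applies the Lance–Williams Ward update to
the raw dissimilarities — implemented exactly via the identity
ward(d) = ward2(√d) with merge heights squared afterwards. Distances:
euclidean, manhattan, maximum (Chebyshev), canberra. Leaf order is
scipy's deterministic order (ties resolved by input order).

## Figures

- **Venn (2–6 sets)**: circles for 2–3; the classical four- and
  five-ellipse templates for 4–5; six triangles for 6 — six ellipses
  cannot form a Venn diagram, since two ellipses intersect in at most
  four points, too few to realize all 63 regions. Rather than hard-coding
  label positions, every membership region is constructed with shapely at
  plot time and its `representative_point` (guaranteed interior) anchors
  the count; the test suite asserts every region of every template has
  positive area. Zero counts are printed as 0. Area-proportional layouts
  are out of scope.
- **UpSet**: intersection-size bars (annotated with counts), membership
  dot matrix, and per-set size bars. Ranking is by descending count with
  deterministic tie-breaks (ascending degree, then combination string),
  or by degree. Empty categories are hidden by default and can be kept
  with `--show-empty`.
- **Heat map**: full square (optionally reordered by clustering, with a
  dendrogram), or lower-triangular with a marginal region-count bar plot
  for symmetric matrices; asymmetric matrices are rejected in triangular
  style with a pointer to the square style. Correlation matrices use a
  diverging scale fixed to [−1, 1]; other metrics a sequential scale
  normalized to the data range.
- Determinism: SVG output uses a fixed hash salt, a stripped date stamp,
  and text kept as text elements (not paths), so identical inputs give
  byte-identical SVG and text labels survive extraction. Default palette
  is a fixed colorblind-safe six-color list, overridable with `--colors`.

## Synthetic data

The generator produces uniform random interval sets (chromosome chosen
proportional to length, uniform starts, uniform lengths, clipped at
chromosome ends, deliberately unmerged so normalization is exercised),
thinned/jittered *derived* sets, and name lists sampled without
replacement. One `numpy` generator per call, seeded explicitly; no global
state.

The key analytic link to the statistics engine: a derived set built by
Bernoulli(p) retention from N equal-length disjoint base intervals with
no jitter is a subset of its base, so jaccard(base, derived) = K/N
exactly for the realized K, with expectation p. The tests recover p
within 3 standard errors at p ∈ {0.2, 0.5, 0.8} across seeds.

The bundled demo fixtures (six histone-mark-like sets, 2 × 50 kb genome,
~100–150 intervals per set, 150–400 bp lengths, pairwise overlap induced
by deriving sets from a shared base at retention 0.25–0.65) were generated
once by this module at a fixed seed and committed as BED text, so demo
outputs stay stable even if the generator evolves; `data/manifest.json`
records the parameters.

What the synthetic data do *not* emulate: realistic peak-length and
inter-peak spacing distributions, chromosome-scale domain structure,
GC/mappability biases, and genome sizes beyond toy scale. Passing tests
establish algorithmic correctness (agreement with brute force, exactness,
conservation, determinism) — not that any biological conclusion drawn
from a particular metric is appropriate for a given experiment.

## Problem sizes and numerics

Randomized validation uses 200 seeded fixtures (≤ 100 kb genomes, 2–5
sets, ≤ 200 intervals per set) — small enough for exact per-base oracles,
large enough to hit edge cases (book-ends, containment, duplicate
intervals, chromosome boundaries). Counts must agree exactly; ratios to
1e-12 relative; Fisher p-values to 1e-9 against enumeration. All interval
arithmetic is integer; the only floating-point quantities are the final
ratios, p-values, correlations, and merge heights.
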