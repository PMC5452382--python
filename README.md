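# interset

Intersection and visualization of multiple genomic region sets and
gene/name lists: classical **Venn diagrams** (2–6 sets), **UpSet plots**,
and **clustered pairwise heat maps**, from one library and one
command-line tool.

Comparing peak calls, variant sets, annotated features, or gene lists
across samples, conditions, or marks is one of the most common tasks in
regulatory genomics. With *n* sets there are 2ⁿ − 1 exclusive membership
categories to account for, and for genomic intervals even the notion of
"shared" needs care: overlaps are partial, many-to-many, and measured
either in regions or in base pairs. `interset` computes these
decompositions with a native sweep-line interval engine, derives the five
standard pairwise statistics, and renders publication-quality figures,
alongside plain-text matrices that interactive viewers and spreadsheets
can consume.

## What it computes

**Membership decomposition.** All input sets are normalized to sorted,
merged intervals (book-ended intervals are unioned, as in `bedtools merge`).
A sweep-line over the endpoints cuts the union into maximal *fragments* of
constant membership bitmask. Category counts are either summed fragment
lengths (base-pair mode) or numbers of maximal constant-membership
fragments (region mode). For name lists, each name in the union is
assigned its exact membership pattern.

**Pairwise statistics**, for every ordered pair of region sets (A, B):

- `count` — number of merged A intervals overlapping B by ≥ 1 bp;
- `frac` — that count divided by |A| (row = query set, so the matrix is
  asymmetric);
- `jaccard` — J(A,B) = |A ∩ B| / |A ∪ B| in base pairs, in [0, 1];
- `fisher` — Fisher's exact test of the 2×2 overlap table against a
  genome background (cells hold −log₁₀ of the two-sided p);
- `reldist` — the relative-distance statistic: for each A midpoint, its
  distance to the nearest B midpoint scaled by the spacing of the two
  flanking B midpoints, in [0, 0.5] with uniform-null mean 0.25.

Any metric matrix can be correlated column-wise (Pearson, Spearman,
Kendall) and ordered by agglomerative clustering (eight linkage methods ×
four distance measures), e.g. to reproduce the classic fraction-of-overlap
→ Spearman → clustered heat-map workflow for discovering co-binding
transcription factors.

**Inputs**: BED3+ (0-based half-open), GFF/GTF (1-based closed), VCF
(CHROM/POS/REF), plain-text name lists, and a `chrom<TAB>length` genome
file for the Fisher test. All coordinates are converted to 0-based
half-open internally.

## Worked example

The package bundles six small synthetic histone-mark-like peak sets on a
toy two-chromosome genome. Run the demo:

```sh
interset venn --test -o demo_venn
```

This writes the Venn figure (PDF/SVG/PNG/TIFF) plus the text outputs.
`demo_venn/venn_region.tsv` contains the seven exclusive categories,
ranked by count:

```
combination	degree	count
H3K27ac	1	65
H3K4me3	1	60
H3K27me3	1	55
H3K27ac&H3K4me3	2	48
H3K27ac&H3K27me3	2	31
H3K4me3&H3K27me3	2	26
H3K27ac&H3K4me3&H3K27me3	3	25
```

Read: 65 maximal fragments of the union are covered by H3K27ac alone,
48 by exactly H3K27ac and H3K4me3, and 25 by all three marks. The binary
membership matrix (`venn_region_binary_matrix.tsv`) lists each fragment
with its 0/1 membership per set, and `venn_region_sets.csv` lists each
set's merged intervals column-wise.

The pairwise demo

```sh
interset pairwise --test -o demo_pairwise
```

renders a lower-triangular Jaccard heat map with a marginal bar plot of
per-set region counts and writes the full-precision matrix; its first
cells are

```
	H3K27ac	H3K4me3	H3K27me3	...
H3K27ac	1.0	0.3965685711	0.2143978349	...
H3K4me3	0.3965685711	1.0	0.1624730409	...
```

i.e. the H3K27ac and H3K4me3 demo sets share ≈ 40% of their union's base
pairs, as expected for sets generated from a common base set. A clustered
Spearman analysis of fraction-of-overlap:

```sh
interset pairwise --test -o demo_corr --compute frac --corr spearman \
    --linkage average --htype square
```

## Library use

```python
from interset import read_bed, combination_counts, pairwise_matrix

sets = [read_bed(p) for p in ("a.bed", "b.bed", "c.bed")]
table = combination_counts(sets, mode="basepair")
jac = pairwise_matrix(sets, "jaccard")
```

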