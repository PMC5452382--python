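"""Pairwise overlap statistics between region sets, and the matrix machinery
for clustered heat maps.

Five per-pair metrics are provided: overlap counts, fraction of overlap,
the Jaccard statistic on base pairs, Fisher's exact test against a genome
background, and the relative-distance statistic.  An n x n
:class:`PairwiseMatrix` of any metric can then be correlated column-wise
(Pearson/Spearman/Kendall) and ordered by agglomerative clustering with the
eight standard linkage methods and four distance measures.

Conventions fixed here (the underlying statistics literature leaves them
open):

* ``frac`` is interval-wise and asymmetric: cell (i, j) is the fraction of
  set i's merged intervals that overlap set j by >= 1 base (row = query).
* the relative-distance cell is the MEDIAN of the per-interval distribution
  (uniform-null expectation of the mean is 0.25); the full distribution is
  available from :func:`reldist`.
* the Fisher cell is ``-log10(p_two_sided)`` capped at 320.
* the Fisher 2x2 table is a genome-slot heuristic: n11 = A-intervals
  hitting B, n12 = A-only, n21 = B-only, and n22 fills the remainder of
  S = floor(2G / (meanLenA + meanLenB)) background slots, G the genome
  length.  The hypergeometric p-values on that table are exact.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist

from .regionio import Genome, RegionSet, merge, total_bases

__all__ = [
    "PairwiseMatrix",
    "FisherResult",
    "METRICS",
    "overlap_count",
    "overlap_fraction",
    "intersect_bases",
    "jaccard",
    "fisher_test",
    "fisher_from_table",
    "reldist",
    "pairwise_matrix",
    "correlate_matrix",
    "hierarchical_order",
    "write_matrix_tsv",
    "LINKAGE_METHODS",
    "DISTANCE_MEASURES",
    "FISHER_LOG10_CAP",
]

METRICS = ("count", "frac", "jaccard", "fisher", "reldist")
FISHER_LOG10_CAP = 320.0

LINKAGE_METHODS = (
    "single",
    "complete",
    "average",
    "mcquitty",
    "ward",
    "centroid",
    "median",
    "ward2",
)
DISTANCE_MEASURES = ("euclidean", "manhattan", "maximum", "canberra")

_SCIPY_LINKAGE = {
    "single": "single",
    "complete": "complete",
    "average": "average",
    "mcquitty": "weighted",
    "centroid": "centroid",
    "median": "median",
    "ward2": "ward",
}
_SCIPY_DISTANCE = {
    "euclidean": "euclidean",
    "manhattan": "cityblock",
    "maximum": "chebyshev",
    "canberra": "canberra",
}


@dataclass
class PairwiseMatrix:
    """n x n matrix of one pairwise statistic, with labels and set sizes."""

    metric: str
    labels: tuple[str, ...]
    values: np.ndarray
    symmetric: bool
    set_sizes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class FisherResult:
    """2x2 contingency table and its exact hypergeometric test."""

    table: tuple[tuple[int, int], tuple[int, int]]
    p_two_sided: float
    p_left: float
    p_right: float
    odds_ratio: float


def _chrom_arrays(rs: RegionSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merged per-chromosome (starts, ends) arrays, both sorted ascending."""
    m = merge(rs)
    out: dict[str, tuple[list[int], list[int]]] = {}
    for iv in m.intervals:
        out.setdefault(iv.chrom, ([], []))
        out[iv.chrom][0].append(iv.start)
        out[iv.chrom][1].append(iv.end)
    return {
        c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
        for c, (s, e) in out.items()
    }


def overlap_count(a: RegionSet, b: RegionSet) -> int:
    """Number of merged ``a`` intervals overlapping >= 1 merged ``b`` interval
    by at least one base."""
    A, B = _chrom_arrays(a), _chrom_arrays(b)
    n = 0
    for chrom, (a_starts, a_ends) in A.items():
        if chrom not in B:
            continue
        b_starts, b_ends = B[chrom]
        # candidates: b intervals starting before a.end; with merged sorted b,
        # ends are increasing, so only the last candidate's end matters
        idx = np.searchsorted(b_starts, a_ends, side="left")
        hit = (idx > 0) & (b_ends[np.maximum(idx - 1, 0)] > a_starts)
        n += int(hit.sum())
    return n


def overlap_fraction(a: RegionSet, b: RegionSet) -> float:
    """overlap_count(a, b) / |merged a|; errors on empty query set."""
    n_a = len(merge(a))
    if n_a == 0:
        raise ValueError(f"overlap_fraction: query set {a.label!r} is empty")
    return overlap_count(a, b) / n_a


def intersect_bases(a: RegionSet, b: RegionSet) -> int:
    """Total bases covered by both merged sets."""
    A, B = _chrom_arrays(a), _chrom_arrays(b)
    total = 0
    for chrom, (a_starts, a_ends) in A.items():
        if chrom not in B:
            continue
        b_starts, b_ends = B[chrom]
        i = j = 0
        while i < len(a_starts) and j < len(b_starts):
            lo = max(a_starts[i], b_starts[j])
            hi = min(a_ends[i], b_ends[j])
            if hi > lo:
                total += int(hi - lo)
            if a_ends[i] < b_ends[j]:
                i += 1
            else:
                j += 1
    return total


def jaccard(a: RegionSet, b: RegionSet) -> float:
    """Intersection bases / union bases of the merged sets; in [0, 1]
    (0 = no overlap, 1 = full overlap).  Both sets empty -> 0 with warning."""
    inter = intersect_bases(a, b)
    union = total_bases(a) + total_bases(b) - inter
    if union == 0:
        warnings.warn("jaccard of two empty region sets defined as 0")
        return 0.0
    return inter / union


def fisher_from_table(table) -> FisherResult:
    """Exact hypergeometric test of a 2x2 table.

    ``p_two_sided`` is the total probability, at fixed margins, of all
    tables no more likely than the observed one; the odds ratio is the
    sample odds ratio n11*n22 / (n12*n21) (inf when only the denominator
    vanishes, NaN for 0/0).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative integers")
    (n11, n12), (n21, n22) = t
    p_two = float(sps.fisher_exact(t, alternative="two-sided")[1])
    p_left = float(sps.fisher_exact(t, alternative="less")[1])
    p_right = float(sps.fisher_exact(t, alternative="greater")[1])
    if n12 * n21 > 0:
        odds = (n11 * n22) / (n12 * n21)
    elif n11 * n22 > 0:
        odds = math.inf
    else:
        odds = math.nan
    return FisherResult(
        table=((int(n11), int(n12)), (int(n21), int(n22))),
        p_two_sided=min(1.0, p_two),
        p_left=min(1.0, p_left),
        p_right=min(1.0, p_right),
        odds_ratio=odds,
    )


def fisher_test(a: RegionSet, b: RegionSet, genome: Genome) -> FisherResult:
    """Fisher's exact test of overlap between two region sets.

    The 2x2 table is built with the genome-slot heuristic described in the
    module docstring; the left, right, and two-sided p-values on that table
    are the exact hypergeometric ones (two-sided = total probability of all
    tables, at fixed margins, no more likely than the observed one).
    """
    ma, mb = merge(a), merge(b)
    for rs in (ma, mb):
        for chrom in {iv.chrom for iv in rs.intervals}:
            if chrom not in genome:
                raise ValueError(
                    f"chromosome {chrom!r} (set {rs.label!r}) missing from genome file"
                )
    n_a, n_b = len(ma), len(mb)
    n11 = overlap_count(ma, mb)
    n12 = n_a - n11
    n21 = n_b - overlap_count(mb, ma)
    mean_a = total_bases(ma) / n_a if n_a else 0.0
    mean_b = total_bases(mb) / n_b if n_b else 0.0
    denom = mean_a + mean_b
    slots = int(2 * genome.total_length // denom) if denom > 0 else 0
    n22 = max(0, slots - n11 - n12 - n21)
    return fisher_from_table([[n11, n12], [n21, n22]])


def _midpoints(rs: RegionSet) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for iv in merge(rs).intervals:
        out.setdefault(iv.chrom, []).append((iv.start + iv.end) // 2)
    return {c: np.asarray(sorted(v), dtype=np.int64) for c, v in out.items()}


def reldist(a: RegionSet, b: RegionSet) -> np.ndarray:
    """Relative-distance distribution of ``a`` midpoints against ``b``.

    For each merged-``a`` midpoint m with flanking ``b`` midpoints
    l <= m <= r on the same chromosome, the statistic is
    min(m - l, r - m) / (r - l), in [0, 0.5]; midpoints without both
    flanking neighbours are skipped; r == l (duplicate reference
    midpoints) scores 0 by convention.  Under a uniform null the mean is
    0.25.
    """
    A, B = _midpoints(a), _midpoints(b)
    values: list[float] = []
    for chrom, a_mids in A.items():
        b_mids = B.get(chrom)
        if b_mids is None or len(b_mids) < 2:
            continue
        for m in a_mids:
            if m < b_mids[0] or m > b_mids[-1]:
                continue
            j = int(np.searchsorted(b_mids, m, side="left"))
            if b_mids[j] == m:
                values.append(0.0)
                continue
            left, right = b_mids[j - 1], b_mids[j]
            span = right - left
            values.append(float(min(m - left, right - m) / span) if span else 0.0)
    if not values:
        warnings.warn(
            f"reldist({a.label!r}, {b.label!r}): no scorable midpoints"
        )
    return np.asarray(values, dtype=float)


def pairwise_matrix(
    sets: list[RegionSet], metric: str, genome: Genome | None = None
) -> PairwiseMatrix:
    """Fill the n x n matrix of one metric over all ordered set pairs.

    ``reldist`` cells hold the median of the distribution (NaN when no
    midpoint is scorable); ``fisher`` cells hold -log10(p_two_sided) capped
    at ``FISHER_LOG10_CAP``.  Set sizes (merged interval counts) are
    recorded for the marginal bar plot.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if len(sets) < 2:
        raise ValueError("need at least 2 region sets")
    if metric == "fisher" and genome is None:
        raise ValueError("metric 'fisher' requires a genome")
    merged = [merge(s) for s in sets]
    n = len(merged)
    values = np.zeros((n, n), dtype=float)
    for i, a in enumerate(merged):
        for j, b in enumerate(merged):
            if metric == "count":
                values[i, j] = overlap_count(a, b)
            elif metric == "frac":
                values[i, j] = overlap_fraction(a, b)
            elif metric == "jaccard":
                values[i, j] = jaccard(a, b) if i != j else 1.0
            elif metric == "fisher":
                if i == j:
                    values[i, j] = FISHER_LOG10_CAP
                else:
                    p = fisher_test(a, b, genome).p_two_sided
                    values[i, j] = min(FISHER_LOG10_CAP, -math.log10(p)) if p > 0 else FISHER_LOG10_CAP
            elif metric == "reldist":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    d = reldist(a, b)
                values[i, j] = float(np.median(d)) if len(d) else math.nan
    symmetric = bool(np.allclose(values, values.T, equal_nan=True))
    return PairwiseMatrix(
        metric=metric,
        labels=tuple(s.label for s in sets),
        values=values,
        symmetric=symmetric,
        set_sizes=tuple(len(m) for m in merged),
    )


def correlate_matrix(m: PairwiseMatrix, method: str = "pearson") -> PairwiseMatrix:
    """Correlation between COLUMNS of ``m`` (column j = how set j is hit by
    every query), giving a symmetric matrix with unit diagonal.

    Zero-variance columns yield NaN cells with a warning.  Spearman uses
    average ranks for ties.
    """
    if method not in ("pearson", "spearman", "kendall"):
        raise ValueError(f"unknown correlation method {method!r}")
    df = m.to_dataframe()
    corr = df.corr(method=method, min_periods=2)
    values = corr.to_numpy(dtype=float)
    np.fill_diagonal(values, 1.0)
    if np.isnan(values).any():
        warnings.warn("zero-variance column(s): correlation cells set to NA")
    return PairwiseMatrix(
        metric="correlation",
        labels=m.labels,
        values=values,
        symmetric=True,
        set_sizes=m.set_sizes,
    )


def hierarchical_order(
    m: PairwiseMatrix,
    linkage: str = "average",
    distance: str = "euclidean",
) -> tuple[list[str], np.ndarray]:
    """Agglomerative clustering of the ROW vectors of ``m``.

    Returns the deterministic leaf label order (scipy's tie handling: input
    order) and the (n-1) x 4 merge tree.  ``ward`` is the classic
    Lance-Williams update on raw distances (R's ward.D); ``ward2`` squares
    the distances first (R's ward.D2, scipy's ``ward``).
    """
    if linkage not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGE_METHODS}")
    if distance not in DISTANCE_MEASURES:
        raise ValueError(
            f"unknown distance {distance!r}; choose from {DISTANCE_MEASURES}"
        )
    if np.isnan(m.values).any():
        raise ValueError(
            "matrix contains missing values; impute them or choose another metric "
            "before clustering"
        )
    if m.n < 2:
        raise ValueError("need at least 2 rows to cluster")
    d = pdist(m.values, metric=_SCIPY_DISTANCE[distance])
    if linkage == "ward":
        # ward.D on d == ward.D2 on sqrt(d) with merge heights squared
        Z = sch.linkage(np.sqrt(d), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
    else:
        Z = sch.linkage(d, method=_SCIPY_LINKAGE[linkage])
    leaves = sch.leaves_list(Z)
    return [m.labels[i] for i in leaves], Z


def write_matrix_tsv(m: PairwiseMatrix, path: str | os.PathLike) -> str:
    """Write the matrix as TSV: first cell empty, header = labels, one
    labeled row per set; counts as integers, everything else full precision;
    NaN written as ``NA``."""
    path = os.fspath(path)
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("\t" + "\t".join(m.labels) + "\n")
        for i, lab in enumerate(m.labels):
            cells = []
            for v in m.values[i]:
                if math.isnan(v):
                    cells.append("NA")
                elif m.metric == "count":
                    cells.append(str(int(round(v))))
                else:
                    cells.append(repr(float(v)))
            fh.write(lab + "\t" + "\t".join(cells) + "\n")
    return path
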