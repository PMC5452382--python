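"""Decomposition of n sets into their 2^n - 1 exclusive membership categories.

For interval inputs the decomposition is realized by *atomization*: a
sweep-line over all interval endpoints cuts the union of the n merged sets
into maximal fragments of constant membership bitmask (bit i set <=> the
fragment lies inside set i).  Category counts are then either summed
fragment lengths (base-pair mode) or numbers of maximal constant-membership
fragments (region mode).

Region-mode counting on the fragment space is a deliberate, symmetric
definition: "number of overlapping peaks" is ambiguous whenever one peak of
a set spans two peaks of another, whereas maximal constant-membership
blocks are order-independent and have an exact per-base oracle.
"""

from __future__ import annotations

import csv
import os
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .regionio import NameSet, RegionSet, merge

__all__ = [
    "Fragment",
    "CombinationTable",
    "MAX_SETS",
    "atomize",
    "combination_counts",
    "list_combination_counts",
    "combination_string",
    "sort_key",
    "write_combination_outputs",
    "write_sets_csv",
    "elements_from_fragments",
    "elements_from_namesets",
]

MAX_SETS = 16  # bitmask width cap for the decomposition


@dataclass(frozen=True)
class Fragment:
    """Maximal genomic interval with constant membership across all input sets."""

    chrom: str
    start: int
    end: int
    bitmask: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def id_string(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class CombinationTable:
    """Counts of the 2^n - 1 exclusive membership categories of n sets.

    ``counts`` maps a membership bitmask (1 .. 2^n - 1, bit i <=> set i in
    input order) to a nonnegative count; mask 0 (outside every set) never
    appears.  ``mode`` records what is being counted: atomized fragments
    (``region``), covered bases (``basepair``), or names (``list``).
    """

    labels: tuple[str, ...]
    mode: str
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not 2 <= n <= MAX_SETS:
            raise ValueError(f"need between 2 and {MAX_SETS} sets, got {n}")
        if len(set(self.labels)) != n:
            raise ValueError("set labels must be unique")
        if self.mode not in ("region", "basepair", "list"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for mask in self.counts:
            if not 1 <= mask <= (1 << n) - 1:
                raise ValueError(f"bitmask {mask} out of range for {n} sets")

    @property
    def n_sets(self) -> int:
        return len(self.labels)

    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, mask: int) -> int:
        return self.counts.get(mask, 0)

    def all_masks(self) -> list[int]:
        return list(range(1, (1 << self.n_sets)))


def combination_string(mask: int, labels: Sequence[str]) -> str:
    """Human-readable category name: member labels joined by '&' in input order."""
    return "&".join(lab for i, lab in enumerate(labels) if mask >> i & 1)


def sort_key(mask: int, count: int, labels: Sequence[str], by: str = "frequency"):
    """Deterministic ordering of categories.

    ``frequency``: descending count, then ascending degree, then combination
    string.  ``degree``: ascending degree, then descending count, then string.
    """
    degree = bin(mask).count("1")
    name = combination_string(mask, labels)
    if by == "frequency":
        return (-count, degree, name)
    if by == "degree":
        return (degree, -count, name)
    raise ValueError(f"unknown sort key {by!r}")


def _check_n(n: int) -> None:
    if n < 2:
        raise ValueError("need at least 2 sets")
    if n > MAX_SETS:
        raise ValueError(f"at most {MAX_SETS} sets supported, got {n}")


def atomize(sets: Sequence[RegionSet]) -> list[Fragment]:
    """Sweep-line decomposition of the union of the sets into maximal
    constant-bitmask fragments (bitmask-0 gaps omitted)."""
    _check_n(len(sets))
    merged = [merge(s) for s in sets]
    chroms = sorted({iv.chrom for s in merged for iv in s.intervals})
    fragments: list[Fragment] = []
    for chrom in chroms:
        per_set: list[list[tuple[int, int]]] = [
            [(iv.start, iv.end) for iv in s.intervals if iv.chrom == chrom]
            for s in merged
        ]
        points = sorted({p for ivs in per_set for se in ivs for p in se})
        if len(points) < 2:
            continue
        nseg = len(points) - 1
        masks = [0] * nseg
        for i, ivs in enumerate(per_set):
            bit = 1 << i
            for start, end in ivs:
                lo = bisect_left(points, start)
                hi = bisect_left(points, end)
                for k in range(lo, hi):
                    masks[k] |= bit
        # segments are contiguous, so maximal runs break only where the mask changes
        run_start = 0
        run_mask = 0
        for k in range(nseg):
            m = masks[k]
            if m == run_mask:
                continue
            if run_mask:
                fragments.append(Fragment(chrom, run_start, points[k], run_mask))
            run_start = points[k]
            run_mask = m
        if run_mask:
            fragments.append(Fragment(chrom, run_start, points[-1], run_mask))
    return fragments


def combination_counts(sets: Sequence[RegionSet], mode: str = "region") -> CombinationTable:
    """Category counts over region sets.

    ``basepair``: count[mask] = total bases whose membership pattern is mask.
    ``region``:   count[mask] = number of maximal constant-mask fragments.
    """
    if mode not in ("region", "basepair"):
        raise ValueError(f"mode must be 'region' or 'basepair', got {mode!r}")
    fragments = atomize(sets)
    counts: dict[int, int] = {}
    for fr in fragments:
        inc = fr.length if mode == "basepair" else 1
        counts[fr.bitmask] = counts.get(fr.bitmask, 0) + inc
    return CombinationTable(tuple(s.label for s in sets), mode, counts)


def list_combination_counts(sets: Sequence[NameSet]) -> CombinationTable:
    """Category counts over name sets: each name in the union is assigned its
    exact membership bitmask."""
    _check_n(len(sets))
    counts: dict[int, int] = {}
    universe = set().union(*(s.names for s in sets))
    for name in universe:
        mask = 0
        for i, s in enumerate(sets):
            if name in s.names:
                mask |= 1 << i
        counts[mask] = counts.get(mask, 0) + 1
    return CombinationTable(tuple(s.label for s in sets), "list", counts)


def elements_from_fragments(fragments: Iterable[Fragment]) -> list[tuple[str, int]]:
    """(element id, bitmask) pairs for the binary membership matrix."""
    return [(fr.id_string(), fr.bitmask) for fr in fragments]


def elements_from_namesets(sets: Sequence[NameSet]) -> list[tuple[str, int]]:
    universe = sorted(set().union(*(s.names for s in sets)))
    out = []
    for name in universe:
        mask = 0
        for i, s in enumerate(sets):
            if name in s.names:
                mask |= 1 << i
        out.append((name, mask))
    return out


def write_combination_outputs(
    table: CombinationTable,
    outdir: str | os.PathLike,
    elements: Sequence[tuple[str, int]] | None = None,
    prefix: str = "combinations",
    show_empty: bool = False,
) -> dict[str, str]:
    """Write the text outputs of a decomposition.

    Always writes the combinations TSV (``combination<TAB>degree<TAB>count``,
    count-sorted with deterministic tie-breaks; empty categories omitted
    unless ``show_empty``).  When ``elements`` is given, also writes the
    binary membership matrix (first column ``element``, one 0/1 column per
    set).  Returns the written paths keyed by kind.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    rows = [(mask, table.get(mask)) for mask in table.all_masks()]
    if not show_empty:
        rows = [(m, c) for m, c in rows if c > 0]
    rows.sort(key=lambda mc: sort_key(mc[0], mc[1], table.labels))
    combo_path = os.path.join(outdir, f"{prefix}.tsv")
    with open(combo_path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("combination\tdegree\tcount\n")
        for mask, count in rows:
            fh.write(
                f"{combination_string(mask, table.labels)}\t{bin(mask).count('1')}\t{count}\n"
            )
    paths["combinations"] = combo_path

    if elements is not None:
        matrix_path = os.path.join(outdir, f"{prefix}_binary_matrix.tsv")
        with open(matrix_path, "wt", encoding="utf-8", newline="\n") as fh:
            fh.write("element\t" + "\t".join(table.labels) + "\n")
            for elem, mask in elements:
                bits = "\t".join(str(mask >> i & 1) for i in range(table.n_sets))
                fh.write(f"{elem}\t{bits}\n")
        paths["binary_matrix"] = matrix_path
    return paths


def write_sets_csv(
    sets: Sequence[NameSet] | Sequence[RegionSet], path: str | os.PathLike
) -> str:
    """Write the one-column-per-set CSV: elements listed downward, short
    columns padded with empty fields.

    For region sets the elements are the merged intervals as
    ``chrom:start-end`` strings.
    """
    columns: list[list[str]] = []
    labels: list[str] = []
    for s in sets:
        labels.append(s.label)
        if isinstance(s, NameSet):
            columns.append(sorted(s.names))
        else:
            m = merge(s)
            columns.append([f"{iv.chrom}:{iv.start}-{iv.end}" for iv in m.intervals])
    height = max((len(c) for c in columns), default=0)
    path = os.fspath(path)
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(labels)
        for i in range(height):
            writer.writerow([c[i] if i < len(c) else "" for c in columns])
    return path
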