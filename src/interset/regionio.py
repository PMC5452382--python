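"""Region-set and name-list I/O and the interval data model.

All coordinates are held internally as 0-based half-open ``[start, end)``
intervals, the BED convention.  GFF/GTF (1-based closed) and VCF (1-based
POS with a REF allele span) are converted at parse time, so every statistic
downstream works in a single coordinate system.

Zero- or negative-length records are skipped with a counted warning rather
than aborting the run: real-world BED exports routinely contain them.  The
per-file tally is kept in a :class:`ParseReport` attached to the returned
:class:`RegionSet`.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "NameSet",
    "Genome",
    "ParseReport",
    "ParseError",
    "read_bed",
    "read_gff",
    "read_vcf",
    "read_list",
    "read_genome",
    "read_regions",
    "merge",
    "total_bases",
    "write_bed",
    "write_genome",
    "unique_labels",
]

_VALID_STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """Unrecoverable problem in an input file; message names file and line."""


@dataclass(frozen=True)
class GenomicInterval:
    """One region on a chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand is not None and self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ParseReport:
    """Per-file parsing tally: lines seen, records kept, records skipped."""

    path: str = ""
    n_records: int = 0
    n_skipped: int = 0
    messages: list[str] = field(default_factory=list)


@dataclass
class RegionSet:
    """A labeled collection of genomic intervals.

    ``is_merged`` certifies sorted order and that no two intervals on a
    chromosome overlap or book-end (gap >= 1 base between neighbours).
    """

    label: str
    intervals: tuple[GenomicInterval, ...] = ()
    is_merged: bool = False
    parse_report: ParseReport | None = None

    def __post_init__(self) -> None:
        self.intervals = tuple(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def chromosomes(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})


@dataclass
class NameSet:
    """A labeled set of names (gene symbols, ids, ...); exact string identity."""

    label: str
    names: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.names = frozenset(self.names)

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class Genome:
    """Chromosome name -> length in bases; the background space for overlap tests."""

    sizes: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, size in self.sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {size}")

    @property
    def total_length(self) -> int:
        return sum(self.sizes.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes


def _default_label(path: str | os.PathLike) -> str:
    return os.path.splitext(os.path.basename(os.fspath(path)))[0]


def _data_lines(path: str | os.PathLike, skip_prefixes: tuple[str, ...]) -> Iterator[tuple[int, str]]:
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if any(line.startswith(p) for p in skip_prefixes):
                continue
            yield lineno, line


def _parse_int(token: str, path: str, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(
            f"{path}, line {lineno}: cannot parse {what} field {token!r} as integer"
        ) from None


def read_bed(path: str | os.PathLike, label: str | None = None) -> RegionSet:
    """Read a BED3+ file (tab-separated, 0-based half-open).

    Lines starting with ``track``, ``browser`` or ``#`` are skipped.
    Records with ``start >= end`` are skipped and counted in the parse report.
    """
    path = os.fspath(path)
    report = ParseReport(path=path)
    intervals: list[GenomicInterval] = []
    for lineno, line in _data_lines(path, ("track", "browser", "#")):
        fields = line.split("\t")
        if len(fields) < 3:
            fields = line.split()  # tolerate space-separated BED
        if len(fields) < 3:
            raise ParseError(f"{path}, line {lineno}: fewer than 3 columns")
        start = _parse_int(fields[1], path, lineno, "start")
        end = _parse_int(fields[2], path, lineno, "end")
        if start < 0 or start >= end:
            report.n_skipped += 1
            report.messages.append(
                f"line {lineno}: skipped zero/negative-length record "
                f"({fields[0]}:{start}-{end})"
            )
            continue
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        strand = fields[5] if len(fields) > 5 and fields[5] in _VALID_STRANDS else None
        intervals.append(GenomicInterval(fields[0], start, end, name, strand))
        report.n_records += 1
    if report.n_skipped:
        warnings.warn(f"{path}: skipped {report.n_skipped} invalid record(s)")
    return RegionSet(label or _default_label(path), tuple(intervals), parse_report=report)


def read_gff(path: str | os.PathLike, label: str | None = None) -> RegionSet:
    """Read GFF/GTF features; 1-based closed [s, e] becomes 0-based half-open [s-1, e)."""
    path = os.fspath(path)
    report = ParseReport(path=path)
    intervals: list[GenomicInterval] = []
    for lineno, line in _data_lines(path, ("#",)):
        fields = line.split("\t")
        if len(fields) < 8:
            raise ParseError(f"{path}, line {lineno}: fewer than 8 GFF columns")
        s1 = _parse_int(fields[3], path, lineno, "start")
        e1 = _parse_int(fields[4], path, lineno, "end")
        start, end = s1 - 1, e1
        if start < 0 or start >= end:
            report.n_skipped += 1
            report.messages.append(f"line {lineno}: skipped invalid span {s1}..{e1}")
            continue
        strand = fields[6] if fields[6] in _VALID_STRANDS else None
        intervals.append(GenomicInterval(fields[0], start, end, fields[2] or None, strand))
        report.n_records += 1
    if report.n_skipped:
        warnings.warn(f"{path}: skipped {report.n_skipped} invalid record(s)")
    return RegionSet(label or _default_label(path), tuple(intervals), parse_report=report)


def read_vcf(path: str | os.PathLike, label: str | None = None) -> RegionSet:
    """Read VCF records as intervals [POS-1, POS-1+len(REF)).

    Only CHROM, POS and REF are consumed; genotypes and INFO are ignored.
    """
    path = os.fspath(path)
    report = ParseReport(path=path)
    intervals: list[GenomicInterval] = []
    for lineno, line in _data_lines(path, ("#",)):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}, line {lineno}: fewer than 4 VCF columns")
        pos = _parse_int(fields[1], path, lineno, "POS")
        ref = fields[3]
        start = pos - 1
        end = start + max(len(ref), 0)
        if start < 0 or start >= end:
            report.n_skipped += 1
            report.messages.append(f"line {lineno}: skipped record with empty span")
            continue
        intervals.append(GenomicInterval(fields[0], start, end, fields[2] if len(fields) > 2 and fields[2] != "." else None))
        report.n_records += 1
    if not intervals and report.n_skipped == 0:
        warnings.warn(f"{path}: no records found (header-only VCF?)")
    if report.n_skipped:
        warnings.warn(f"{path}: skipped {report.n_skipped} invalid record(s)")
    return RegionSet(label or _default_label(path), tuple(intervals), parse_report=report)


def read_list(path: str | os.PathLike, label: str | None = None) -> NameSet:
    """Read a plain-text name list, one token per line, deduplicated and stripped."""
    path = os.fspath(path)
    names: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for raw in fh:
            name = raw.strip()
            if name:
                names.add(name)
    if not names:
        warnings.warn(f"{path}: empty name list")
    return NameSet(label or _default_label(path), frozenset(names))


def read_genome(path: str | os.PathLike) -> Genome:
    """Read a genome file: ``chrom<TAB>length`` per line."""
    path = os.fspath(path)
    sizes: dict[str, int] = {}
    for lineno, line in _data_lines(path, ("#",)):
        fields = line.split("\t")
        if len(fields) < 2:
            fields = line.split()
        if len(fields) < 2:
            raise ParseError(f"{path}, line {lineno}: expected 'chrom<TAB>length'")
        chrom = fields[0]
        length = _parse_int(fields[1], path, lineno, "length")
        if length <= 0:
            raise ParseError(f"{path}, line {lineno}: non-positive length {length}")
        if chrom in sizes:
            raise ParseError(f"{path}, line {lineno}: duplicate chromosome {chrom!r}")
        sizes[chrom] = length
    return Genome(sizes)


_GENOMIC_EXTENSIONS = {
    ".bed": read_bed,
    ".gff": read_gff,
    ".gff3": read_gff,
    ".gtf": read_gff,
    ".vcf": read_vcf,
}


def read_regions(path: str | os.PathLike, label: str | None = None) -> RegionSet:
    """Dispatch on file extension (.bed/.gff/.gff3/.gtf/.vcf; default BED)."""
    ext = os.path.splitext(os.fspath(path))[1].lower()
    reader = _GENOMIC_EXTENSIONS.get(ext, read_bed)
    return reader(path, label)


def merge(rs: RegionSet) -> RegionSet:
    """Normalize to sorted, merged form (bedtools-merge default semantics).

    Overlapping and book-ended intervals are unioned; per-interval name and
    strand are dropped.  Idempotent.
    """
    if rs.is_merged:
        return rs
    ivs = sorted(rs.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return RegionSet(rs.label, tuple(merged), is_merged=True, parse_report=rs.parse_report)


def total_bases(rs: RegionSet) -> int:
    """Number of distinct bases covered (merges internally if needed)."""
    m = merge(rs)
    return sum(iv.length for iv in m.intervals)


def write_bed(rs: RegionSet, path: str | os.PathLike) -> str:
    """Write a BED file (BED3, or BED6 when name/strand are present)."""
    path = os.fspath(path)
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for iv in rs.intervals:
            if iv.name is None and iv.strand is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand or '.'}\n"
                )
    return path


def write_genome(genome: Genome, path: str | os.PathLike) -> str:
    path = os.fspath(path)
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for chrom, size in genome.sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    return path


def unique_labels(labels: Sequence[str]) -> list[str]:
    """Disambiguate duplicate labels with numeric suffixes (a, a_2, a_3, ...)."""
    seen: dict[str, int] = {}
    out: list[str] = []
    for lab in labels:
        if lab not in seen:
            seen[lab] = 1
            out.append(lab)
        else:
            seen[lab] += 1
            candidate = f"{lab}_{seen[lab]}"
            while candidate in seen:
                seen[lab] += 1
                candidate = f"{lab}_{seen[lab]}"
            seen[candidate] = 1
            out.append(candidate)
    return out
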