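"""Seeded generators of synthetic region sets, name lists and genomes.

These stand in for real peak calls so that every statistic and plot is
testable without downloads.  The central design point is `derived_regions`:
a set built from a base set by Bernoulli retention (probability ``p``) and
optional positional jitter has an analytically known expected Jaccard
against its base — with ``jitter=0`` the derived set is a subset of the
merged base, so for K of N equal-length disjoint base intervals kept,
jaccard(base, derived) = K / N exactly (expectation p) — which links the
generator to the statistics engine as a parameter-recovery check.

Each call consumes a single ``numpy.random.default_rng(seed)`` stream; no
global state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regionio import Genome, GenomicInterval, NameSet, RegionSet, merge

__all__ = [
    "GeneratorParams",
    "random_regions",
    "derived_regions",
    "random_name_lists",
    "toy_genome",
]


def toy_genome(n_chroms: int = 2, length: int = 50_000) -> Genome:
    """Small genome for tests and bundled fixtures."""
    return Genome({f"chr{i + 1}": length for i in range(n_chroms)})


@dataclass
class GeneratorParams:
    """Parameters for `random_regions`.

    length_range is inclusive on both ends; intervals are clipped to the
    chromosome end and never merged, so duplicates/overlaps can occur and
    exercise normalization downstream.
    """

    genome: Genome
    n_intervals: int
    length_range: tuple[int, int] = (100, 500)
    seed: int = 0
    label: str = "random"

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid length_range {self.length_range}")
        if self.n_intervals < 0:
            raise ValueError("n_intervals must be nonnegative")


def random_regions(params: GeneratorParams) -> RegionSet:
    """Uniform random intervals: chromosome chosen proportional to its
    length, start uniform, length uniform in ``length_range``."""
    genome = params.genome
    if not genome.sizes:
        raise ValueError("genome is empty")
    lo, hi = params.length_range
    smallest = min(genome.sizes.values())
    if lo > smallest:
        raise ValueError(
            f"minimum interval length {lo} exceeds smallest chromosome ({smallest})"
        )
    rng = np.random.default_rng(params.seed)
    chroms = list(genome.sizes)
    sizes = np.array([genome.sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    intervals: list[GenomicInterval] = []
    for _ in range(params.n_intervals):
        ci = int(rng.choice(len(chroms), p=probs))
        chrom, csize = chroms[ci], genome.sizes[chroms[ci]]
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, max(1, csize - 1)))
        end = min(start + length, csize)
        if end <= start:
            continue  # start landed on the last base of the chromosome
        intervals.append(GenomicInterval(chrom, start, end))
    return RegionSet(params.label, tuple(intervals))


def derived_regions(
    base: RegionSet,
    p: float,
    jitter: int = 0,
    seed: int = 0,
    genome: Genome | None = None,
    label: str | None = None,
) -> RegionSet:
    """Bernoulli-thin and jitter a base set.

    Each merged base interval is kept with probability ``p``; kept intervals
    are shifted by a uniform integer in [-jitter, +jitter], clipped to the
    chromosome (when a genome is given) or to position 0 otherwise.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"retention probability p={p} outside [0, 1]")
    if jitter < 0:
        raise ValueError("jitter must be nonnegative")
    rng = np.random.default_rng(seed)
    intervals: list[GenomicInterval] = []
    for iv in merge(base).intervals:
        if rng.random() >= p:
            continue
        shift = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        start, end = iv.start + shift, iv.end + shift
        limit = genome.sizes.get(iv.chrom) if genome is not None else None
        start = max(0, start)
        if limit is not None:
            end = min(end, limit)
        if end > start:
            intervals.append(GenomicInterval(iv.chrom, start, end))
    return RegionSet(label or f"{base.label}_derived", tuple(intervals))


def random_name_lists(
    n_sets: int,
    universe_size: int,
    set_size: int,
    seed: int = 0,
    labels: list[str] | None = None,
) -> list[NameSet]:
    """Sample ``n_sets`` name sets without replacement from a synthetic
    universe of ``universe_size`` gene-like names."""
    if set_size > universe_size:
        raise ValueError("set_size cannot exceed universe_size")
    rng = np.random.default_rng(seed)
    universe = np.array([f"gene{i:05d}" for i in range(universe_size)])
    out: list[NameSet] = []
    for k in range(n_sets):
        picked = rng.choice(universe_size, size=set_size, replace=False)
        lab = labels[k] if labels else f"list{k + 1}"
        out.append(NameSet(lab, frozenset(universe[picked].tolist())))
    return out
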