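"""Independent brute-force oracles used by the test suite.

Everything here works per base on explicit numpy arrays (or by exhaustive
enumeration), deliberately ignoring the sweep-line/searchsorted machinery of
the package so that agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np

from interset.regionio import RegionSet, merge
from interset.synthgen import GeneratorParams, derived_regions, random_regions, toy_genome


def per_base_masks(sets: list[RegionSet]) -> dict[str, np.ndarray]:
    """Chromosome -> per-base membership bitmask array (length = max end)."""
    chroms: dict[str, int] = {}
    for s in sets:
        for iv in s.intervals:
            chroms[iv.chrom] = max(chroms.get(iv.chrom, 0), iv.end)
    arrays = {c: np.zeros(L, dtype=np.uint32) for c, L in chroms.items()}
    for i, s in enumerate(sets):
        bit = np.uint32(1 << i)
        for iv in s.intervals:
            arrays[iv.chrom][iv.start : iv.end] |= bit
    return arrays


def bruteforce_combination_counts(sets: list[RegionSet]) -> tuple[dict[int, int], dict[int, int]]:
    """(basepair counts, maximal-run counts) per membership bitmask."""
    bp: dict[int, int] = {}
    runs: dict[int, int] = {}
    for arr in per_base_masks(sets).values():
        vals, counts = np.unique(arr, return_counts=True)
        for v, c in zip(vals.tolist(), counts.tolist()):
            if v:
                bp[v] = bp.get(v, 0) + c
        # maximal runs of constant nonzero value
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], change))
        for s in starts:
            v = int(arr[s])
            if v:
                runs[v] = runs.get(v, 0) + 1
    return bp, runs


def naive_overlap_count(a: RegionSet, b: RegionSet) -> int:
    ma, mb = merge(a), merge(b)
    n = 0
    for ia in ma.intervals:
        for ib in mb.intervals:
            if ia.chrom == ib.chrom and ia.start < ib.end and ib.start < ia.end:
                n += 1
                break
    return n


def naive_jaccard(a: RegionSet, b: RegionSet) -> float:
    masks = per_base_masks([a, b])
    inter = sum(int(((arr & 1) & (arr >> 1)).sum()) for arr in masks.values())
    union = sum(int((arr != 0).sum()) for arr in masks.values())
    return inter / union if union else 0.0


def fisher_enumeration(table) -> tuple[float, float, float]:
    """(p_left, p_right, p_two_sided) by enumerating all integer tables with
    the observed margins; probabilities from log-factorials."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d

    def logp(x: int) -> float:
        y = c1 - x
        if y < 0 or x > r1 or y > r2:
            return -math.inf
        return (
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1) - math.lgamma(y + 1) - math.lgamma(r2 - y + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: math.exp(logp(x)) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    p_left = sum(p for x, p in probs.items() if x <= a)
    p_right = sum(p for x, p in probs.items() if x >= a)
    p_two = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))
    return min(1.0, p_left), min(1.0, p_right), min(1.0, p_two)


def random_fixture(seed: int) -> list[RegionSet]:
    """2-5 partially overlapping region sets on a small genome (<= 100 kb),
    <= 200 intervals each, mixing independent and derived sets."""
    rng = np.random.default_rng(seed)
    genome = toy_genome(n_chroms=int(rng.integers(1, 3)), length=int(rng.integers(5_000, 25_000)))
    n_sets = int(rng.integers(2, 6))
    base = random_regions(
        GeneratorParams(
            genome,
            int(rng.integers(5, 200)),
            (1, int(rng.integers(50, 400))),
            seed=seed * 31 + 1,
            label="set1",
        )
    )
    sets = [base]
    for k in range(1, n_sets):
        if rng.random() < 0.5:
            sets.append(
                derived_regions(
                    base,
                    float(rng.uniform(0.2, 0.9)),
                    int(rng.integers(0, 300)),
                    seed=seed * 31 + 2 * k,
                    genome=genome,
                    label=f"set{k + 1}",
                )
            )
        else:
            sets.append(
                random_regions(
                    GeneratorParams(
                        genome,
                        int(rng.integers(1, 200)),
                        (1, int(rng.integers(50, 400))),
                        seed=seed * 31 + 2 * k + 1,
                        label=f"set{k + 1}",
                    )
                )
            )
    # guard against an (unlikely) empty derived set: counts need >= 1 interval
    return [s if len(s) else RegionSet(s.label, base.intervals) for s in sets]
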