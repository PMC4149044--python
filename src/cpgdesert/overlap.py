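"""Multi-set interval overlap: Venn partition across exposure lineages.

Two DMRs from different exposures are 'the same' when their intervals
share >= 1 bp (optionally a reciprocal overlap fraction). Chained
overlaps are resolved by connected components of the overlap graph, so a
component touching sets A, B and C lands in the {A,B,C} cell even when
the A and C members never overlap each other directly.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .intervals import GenomicInterval, intervals_overlap, overlap_length


@dataclass(frozen=True)
class NamedIntervalSet:
    """A labelled DMR set, e.g. one environmental-exposure lineage."""

    label: str
    intervals: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("label must be non-empty")


@dataclass(frozen=True)
class VennPartition:
    """Disjoint cells keyed by label subset; counts sum to universe_size."""

    labels: tuple[str, ...]
    cells: dict  # frozenset[str] -> list of (chrom, start, end) merged spans
    universe_size: int

    def counts(self) -> dict:
        return {key: len(members) for key, members in self.cells.items()}


def _merge_within(intervals) -> list[GenomicInterval]:
    """Merge overlapping intervals of one set into maximal spans."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged.pop()
            merged.append(
                GenomicInterval(last.chrom, last.start, max(last.end, iv.end))
            )
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _linked(a: GenomicInterval, b: GenomicInterval, reciprocal_fraction: float) -> bool:
    if not intervals_overlap(a, b):
        return False
    if reciprocal_fraction <= 0:
        return True
    ov = overlap_length(a, b)
    return (
        ov / a.length() >= reciprocal_fraction
        and ov / b.length() >= reciprocal_fraction
    )


def venn_partition(
    sets: list[NamedIntervalSet], reciprocal_fraction: float = 0.0
) -> VennPartition:
    """Partition the union of 2-7 labelled interval sets into Venn cells.

    Within-set duplicates are merged first; distinct elements are the
    connected components of the cross-set overlap graph. Every non-empty
    subset of labels appears as a cell (possibly with count 0).
    """
    if not (2 <= len(sets) <= 7):
        raise ValueError("need between 2 and 7 sets")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate labels: {labels}")

    items: list[tuple[str, GenomicInterval]] = []
    for s in sets:
        for iv in _merge_within(s.intervals):
            items.append((s.label, iv))

    uf = _UnionFind(len(items))
    order = sorted(range(len(items)), key=lambda i: items[i][1])
    # sweep per chromosome: an interval can only link to actives that
    # haven't ended before its start
    active: list[int] = []
    for i in order:
        iv = items[i][1]
        active = [
            j
            for j in active
            if items[j][1].chrom == iv.chrom and items[j][1].end > iv.start
        ]
        for j in active:
            if _linked(items[j][1], iv, reciprocal_fraction):
                uf.union(i, j)
        active.append(i)

    components: dict[int, list[int]] = {}
    for i in range(len(items)):
        components.setdefault(uf.find(i), []).append(i)

    cells: dict = {
        frozenset(c): []
        for r in range(1, len(labels) + 1)
        for c in combinations(labels, r)
    }
    for members in components.values():
        touched = frozenset(items[i][0] for i in members)
        lo = min(items[i][1].start for i in members)
        hi = max(items[i][1].end for i in members)
        chrom = items[members[0]][1].chrom
        cells[touched].append((chrom, lo, hi))

    part = VennPartition(tuple(labels), cells, len(components))
    assert sum(len(v) for v in part.cells.values()) == part.universe_size
    return part


def uniqueness_report(part: VennPartition) -> dict:
    """Exposure-specificity summary of a Venn partition."""
    counts = part.counts()
    specific_per_label = {
        lab: counts.get(frozenset([lab]), 0) for lab in part.labels
    }
    n_specific = sum(specific_per_label.values())
    all_labels = frozenset(part.labels)
    return {
        "universe_size": part.universe_size,
        "specific_per_label": specific_per_label,
        "n_exposure_specific": n_specific,
        "fraction_exposure_specific": (
            n_specific / part.universe_size if part.universe_size else 0.0
        ),
        "n_shared_by_all": counts.get(all_labels, 0),
    }
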