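"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the library's vectorized code paths: plain
character scans, exhaustive window enumeration, and naive graph search.
"""
from itertools import combinations


def scan_cpg_positions(seq: str) -> list[int]:
    """Position-by-position scan for CG dinucleotides."""
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


def count_cpg_in(seq: str, start: int, end: int) -> int:
    """CpG sites with C in [start, end) by direct scan."""
    return sum(
        1
        for i in range(start, min(end, len(seq) - 1))
        if seq[i] == "C" and seq[i + 1] == "G"
    )


def window_densities(seq: str, window: int, step: int) -> list[float]:
    out = []
    pos = 0
    while pos + window <= len(seq):
        out.append(count_cpg_in(seq, pos, pos + window) * 100.0 / window)
        pos += step
    return out


def island_oracle(seq, min_length=200, gc_threshold=0.50, oe_threshold=0.60, window=200):
    """Exhaustive window enumeration + merge + re-validation."""

    def stats(s, e):
        sub = seq[s:e]
        n_c, n_g = sub.count("C"), sub.count("G")
        n_cpg = sub.count("CG")  # CG cannot overlap itself, count is exact
        gc = (n_c + n_g) / (e - s)
        oe = (n_cpg * (e - s) / (n_c * n_g)) if n_c * n_g else 0.0
        return gc, oe

    qualifying = []
    for s in range(0, len(seq) - window + 1):
        gc, oe = stats(s, s + window)
        if gc >= gc_threshold and oe >= oe_threshold:
            qualifying.append(s)
    merged = []
    for s in qualifying:
        if merged and s < merged[-1][1]:
            merged[-1] = (merged[-1][0], s + window)
        else:
            merged.append((s, s + window))
    result = []
    for s, e in merged:
        gc, oe = stats(s, e)
        if e - s >= min_length and gc >= gc_threshold and oe >= oe_threshold:
            result.append((s, e, gc, oe))
    return result


def cluster_runs(positions, lo, hi, min_sites=3, max_gap=30):
    """Enumerate maximal close-site runs inside [lo, hi) from a site list."""
    pos = [p for p in positions if lo <= p < hi]
    runs, current = [], []
    for p in pos:
        if current and p - current[-1] > max_gap:
            if len(current) >= min_sites:
                runs.append(list(current))
            current = []
        current.append(p)
    if len(current) >= min_sites:
        runs.append(current)
    return runs


def venn_components(labelled_intervals):
    """Connected components over all pairwise overlaps, O(n^2).

    ``labelled_intervals``: list of (label, chrom, start, end). Returns a
    mapping frozenset(labels) -> component count.
    """
    n = len(labelled_intervals)
    adj = {i: set() for i in range(n)}
    for i, j in combinations(range(n), 2):
        _, ci, si, ei = labelled_intervals[i]
        _, cj, sj, ej = labelled_intervals[j]
        if ci == cj and si < ej and sj < ei:
            adj[i].add(j)
            adj[j].add(i)
    seen, cells = set(), {}
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], []
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            comp.append(k)
            stack.extend(adj[k] - seen)
        key = frozenset(labelled_intervals[k][0] for k in comp)
        cells[key] = cells.get(key, 0) + 1
    return cells
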