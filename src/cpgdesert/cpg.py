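"""CpG detection and density profiling.

A CpG site is a cytosine immediately followed by a guanine on the forward
strand; the dinucleotide is strand-symmetric as a methylation substrate, so
each dinucleotide is counted once (never once per strand). Density is
expressed throughout as CpG per 100 bp, the scale on which CpG deserts
(<15 CpG/100 bp) and islands are defined, so the maximum possible value in
a 100 bp window is 50.

Island criteria default to the Gardiner-Garden & Frommer convention
(length >= 200 bp, GC >= 50%, observed/expected CpG >= 0.6, 200 bp scan
window); a stricter preset (>= 500 bp, GC >= 55%, obs/exp >= 0.65) is
provided. "Small CpG clusters" — short runs of nearby CpG sites inside
otherwise CpG-poor sequence — default to >= 3 sites with consecutive gaps
<= 30 bp; every parameter is exposed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, SequenceRecord

log = logging.getLogger(__name__)

#: strict island preset (promoter-grade stringency)
STRICT_ISLAND_PARAMS = dict(min_length=500, gc_threshold=0.55, oe_threshold=0.65)


@dataclass(frozen=True)
class CpGSiteList:
    """Sorted 0-based positions of the C of each forward-strand CpG."""

    chrom: str
    positions: np.ndarray  # int64, strictly increasing

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class DensityProfile:
    """Windowed CpG density track (CpG per 100 bp)."""

    window_size: int
    step: int
    window_starts: np.ndarray
    densities: np.ndarray


@dataclass(frozen=True)
class CpGIsland:
    interval: GenomicInterval
    gc_fraction: float
    obs_exp: float


@dataclass(frozen=True)
class CpGCluster:
    """Run of >= min_sites CpG sites with consecutive gaps <= max_gap.

    The interval spans the first C through the last G (last site + 2).
    """

    interval: GenomicInterval
    n_sites: int
    max_gap: int


def find_cpg_sites(rec: SequenceRecord) -> CpGSiteList:
    """All forward-strand CpG dinucleotide start positions in rec."""
    arr = np.frombuffer(rec.seq.encode("ascii"), dtype=np.uint8)
    if len(arr) < 2:
        return CpGSiteList(rec.id, np.empty(0, dtype=np.int64))
    mask = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    return CpGSiteList(rec.id, np.nonzero(mask)[0].astype(np.int64))


def count_sites_in(sites: CpGSiteList, iv: GenomicInterval) -> int:
    """Number of CpG sites whose C lies inside [iv.start, iv.end)."""
    lo, hi = np.searchsorted(sites.positions, [iv.start, iv.end])
    return int(hi - lo)


def interval_cpg_density(
    sites: CpGSiteList, iv: GenomicInterval, effective_length: int
) -> float:
    """Whole-interval CpG density in CpG per 100 bp.

    ``effective_length`` is the interval length minus masked (N) bases;
    a fully masked interval is an error.
    """
    if effective_length <= 0:
        raise ValueError(f"fully masked interval {iv.display()}: effective length 0")
    return count_sites_in(sites, iv) * 100.0 / effective_length


def sliding_density_profile(
    sites: CpGSiteList, seq_length: int, window: int = 100, step: int = 50
) -> DensityProfile:
    """Density per window fully contained in [0, seq_length).

    A trailing partial window is dropped; a sequence shorter than the
    window yields an empty profile with a warning.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    if seq_length < window:
        log.warning(
            "sequence length %d < window %d: empty density profile", seq_length, window
        )
        starts = np.empty(0, dtype=np.int64)
        return DensityProfile(window, step, starts, np.empty(0))
    starts = np.arange(0, seq_length - window + 1, step, dtype=np.int64)
    lo = np.searchsorted(sites.positions, starts)
    hi = np.searchsorted(sites.positions, starts + window)
    densities = (hi - lo) * 100.0 / window
    return DensityProfile(window, step, starts, densities)


def _base_cumsums(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Prefix counts of C, G and CpG dinucleotide starts."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    cpg = np.zeros(len(arr), dtype=bool)
    if len(arr) >= 2:
        cpg[:-1] = is_c[:-1] & is_g[1:]
    zero = np.zeros(1, dtype=np.int64)
    return (
        np.concatenate([zero, np.cumsum(is_c)]),
        np.concatenate([zero, np.cumsum(is_g)]),
        np.concatenate([zero, np.cumsum(cpg)]),
    )


def observed_expected_cpg(n_cpg: int, n_c: int, n_g: int, length: int) -> float:
    """(n_CpG * L) / (n_C * n_G); defined as 0 when n_C * n_G == 0."""
    denom = n_c * n_g
    if denom == 0:
        return 0.0
    return n_cpg * length / denom


def detect_islands(
    rec: SequenceRecord,
    min_length: int = 200,
    gc_threshold: float = 0.50,
    oe_threshold: float = 0.60,
    window: int = 200,
    step: int = 1,
) -> list[CpGIsland]:
    """CpG islands as maximal merged runs of qualifying scan windows.

    A window qualifies when its GC fraction and observed/expected CpG
    ratio meet the thresholds. Overlapping qualifying windows are merged
    and the merged extent is re-validated against all three criteria
    (including ``min_length``); extents failing re-validation are dropped.
    Returned islands are non-overlapping and sorted.
    """
    L = len(rec.seq)
    if L < window:
        return []
    cum_c, cum_g, cum_cpg = _base_cumsums(rec.seq)
    starts = np.arange(0, L - window + 1, step, dtype=np.int64)
    ends = starts + window
    n_c = cum_c[ends] - cum_c[starts]
    n_g = cum_g[ends] - cum_g[starts]
    # CpG dinucleotides wholly inside the window: C at p, G at p+1 <= end-1
    n_cpg = cum_cpg[ends - 1] - cum_cpg[starts]
    gc = (n_c + n_g) / window
    denom = (n_c * n_g).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(denom > 0, n_cpg * window / denom, 0.0)
    ok = (gc >= gc_threshold) & (oe >= oe_threshold)

    islands: list[CpGIsland] = []
    qual = starts[ok]
    if len(qual) == 0:
        return islands
    # merge overlapping qualifying windows into maximal extents
    run_start = int(qual[0])
    run_end = run_start + window
    extents: list[tuple[int, int]] = []
    for s in qual[1:]:
        s = int(s)
        if s < run_end:
            run_end = s + window
        else:
            extents.append((run_start, run_end))
            run_start, run_end = s, s + window
    extents.append((run_start, run_end))

    for s, e in extents:
        length = e - s
        nc = int(cum_c[e] - cum_c[s])
        ng = int(cum_g[e] - cum_g[s])
        ncpg = int(cum_cpg[e - 1] - cum_cpg[s])
        gc_frac = (nc + ng) / length
        oe_val = observed_expected_cpg(ncpg, nc, ng, length)
        if length >= min_length and gc_frac >= gc_threshold and oe_val >= oe_threshold:
            islands.append(
                CpGIsland(GenomicInterval(rec.id, s, e), gc_frac, oe_val)
            )
    return islands


def detect_clusters(
    sites: CpGSiteList,
    iv: GenomicInterval,
    min_sites: int = 3,
    max_gap: int = 30,
    exclude: list[CpGIsland] | None = None,
) -> list[CpGCluster]:
    """Maximal runs of nearby CpG sites inside iv.

    A run requires >= min_sites sites with every consecutive gap
    (difference of C positions) <= max_gap. Runs whose interval overlaps
    an island in ``exclude`` are dropped (a cluster is, by definition,
    CpG structure outside islands).
    """
    if min_sites < 2:
        raise ValueError("min_sites must be >= 2")
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    lo, hi = np.searchsorted(sites.positions, [iv.start, iv.end])
    pos = sites.positions[lo:hi]
    clusters: list[CpGCluster] = []
    if len(pos) == 0:
        return clusters
    gaps = np.diff(pos)
    breakpoints = np.nonzero(gaps > max_gap)[0]
    run_bounds = np.concatenate([[0], breakpoints + 1, [len(pos)]])
    for a, b in zip(run_bounds[:-1], run_bounds[1:]):
        run = pos[a:b]
        if len(run) < min_sites:
            continue
        civ = GenomicInterval(sites.chrom, int(run[0]), int(run[-1]) + 2)
        if exclude and any(
            civ.chrom == isl.interval.chrom
            and civ.start < isl.interval.end
            and isl.interval.start < civ.end
            for isl in exclude
        ):
            continue
        gap_max = int(np.max(np.diff(run))) if len(run) > 1 else 0
        clusters.append(CpGCluster(civ, int(len(run)), gap_max))
    return clusters


@dataclass(frozen=True)
class DensityHistogram:
    bin_width: float
    bin_lefts: np.ndarray = field(default_factory=lambda: np.empty(0))
    counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def total(self) -> int:
        return int(self.counts.sum())


def density_histogram(densities, bin_width: float = 1.0) -> DensityHistogram:
    """Counts per [k*bin_width, (k+1)*bin_width) bin; empty input -> empty."""
    d = np.asarray(list(densities), dtype=np.float64)
    if len(d) == 0:
        return DensityHistogram(bin_width)
    if np.any(d < 0):
        raise ValueError("densities must be >= 0")
    idx = np.floor(d / bin_width).astype(np.int64)
    counts = np.bincount(idx)
    lefts = np.arange(len(counts)) * bin_width
    return DensityHistogram(bin_width, lefts, counts)
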