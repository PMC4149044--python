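"""Synthetic genomes, tiling-array experiments and exposure DMR sets.

The generators emulate the data the analysis assumes, with planted ground
truth recorded exactly:

* ``simulate_genome`` — a CpG-depleted background sequence from a
  first-order (dinucleotide) Markov chain whose C->G transition is tuned
  to a genome-wide observed/expected CpG of ~0.2, with planted CpG
  islands (locally boosted C->G transition) and planted CpG desert loci
  (CpG-free low-GC background with an exact number of CpG sites written
  in, including at least one small cluster).
* ``simulate_probe_experiment`` — homoscedastic Normal log-intensity
  noise; exposure samples are shifted by delta*sigma on planted probe
  runs of width >= 3 (the adjacency rule's minimum).
* ``simulate_exposure_sets`` — labelled interval sets with a known Venn
  partition, built by disjoint-pair sharing of identical intervals.

Everything is deterministic under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .dmr import IntensityMatrix, ProbeDesign
from .intervals import GenomicInterval, SequenceRecord
from .overlap import NamedIntervalSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3

#: exposure lineages used as default set labels
EXPOSURE_LABELS = ("vinclozolin", "plastics", "pesticides", "hydrocarbons", "dioxin", "ddt")


# -- genome specification ------------------------------------------------

@dataclass(frozen=True)
class IslandSpec:
    """A planted CpG island: high GC, boosted C->G transition."""

    position: int
    length: int
    gc_fraction: float = 0.70
    cg_transition: float = 0.50  # P(G | C) inside the island


@dataclass(frozen=True)
class DesertLocusSpec:
    """A planted desert DMR locus: exact CpG count on a CpG-free background.

    ``density`` is the target whole-locus CpG density in CpG/100 bp;
    ``clusters`` lists (n_sites, gap_bp) small-cluster blocks, at least
    one of which is required by the desert definition.
    """

    position: int
    length: int
    density: float
    clusters: tuple[tuple[int, int], ...] = ((3, 12),)
    gc_fraction: float = 0.30

    def __post_init__(self) -> None:
        if not (500 <= self.length <= 2000):
            raise ValueError("desert locus length must be 500-2000 bp")


@dataclass(frozen=True)
class GenomeSpec:
    seed: int
    length: int
    chrom: str = "chrSim"
    gc_fraction: float = 0.42
    cpg_obs_exp: float = 0.20
    islands: tuple[IslandSpec, ...] = ()
    deserts: tuple[DesertLocusSpec, ...] = ()

    def __post_init__(self) -> None:
        feats = sorted(
            [(i.position, i.position + i.length, "island") for i in self.islands]
            + [(d.position, d.position + d.length, "desert") for d in self.deserts]
        )
        prev_end = 0
        for s, e, kind in feats:
            if s < prev_end:
                raise ValueError(f"planted features overlap near position {s}")
            if e > self.length:
                raise ValueError(f"planted {kind} at {s} extends past genome end")
            prev_end = e


@dataclass(frozen=True)
class DesertTruth:
    interval: GenomicInterval
    density: float
    clusters: tuple[GenomicInterval, ...]


@dataclass(frozen=True)
class GenomeTruth:
    islands: tuple[GenomicInterval, ...]
    deserts: tuple[DesertTruth, ...]

    def desert_intervals(self) -> list[GenomicInterval]:
        return [d.interval for d in self.deserts]


# -- Markov sequence machinery -------------------------------------------

def _transition_rows(gc: float, cg_transition: float) -> np.ndarray:
    """4x4 transition matrix with P(G|C) pinned and stationary preserved.

    Row C gets the prescribed C->G probability (the rest of the row
    proportional to the base composition); the shared row of the other
    states is solved from the stationarity equation so the chain's base
    composition equals the target exactly. Then the realized CpG obs/exp
    is cg_transition / pi_G by construction.
    """
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    row_c = pi * (1.0 - cg_transition) / (1.0 - pi[_G])
    row_c[_G] = cg_transition
    # stationarity: pi_j = pi_C * row_c[j] + (1 - pi_C) * q[j]
    q = (pi - pi[_C] * row_c) / (1.0 - pi[_C])
    if np.any(q < 0):
        raise ValueError("infeasible composition/transition combination")
    rows = np.tile(q, (4, 1))
    rows[_C] = row_c
    return rows


def _markov_sample(n: int, rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample an n-base chain as uint8 codes 0..3."""
    cum = np.cumsum(rows, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(n)
    out = np.empty(n, dtype=np.uint8)
    c0, c1, c2 = cum[:, 0], cum[:, 1], cum[:, 2]
    state = _A
    for i in range(n):
        x = u[i]
        if x < c0[state]:
            state = _A
        elif x < c1[state]:
            state = _C
        elif x < c2[state]:
            state = _G
        else:
            state = _T
        out[i] = state
    return out


def _background(n: int, gc: float, obs_exp: float, rng: np.random.Generator) -> np.ndarray:
    rows = _transition_rows(gc, cg_transition=obs_exp * gc / 2)  # oe = t / pi_G
    return _markov_sample(n, rows, rng)


def _island_segment(spec: IslandSpec, rng: np.random.Generator) -> np.ndarray:
    rows = _transition_rows(spec.gc_fraction, cg_transition=spec.cg_transition)
    return _markov_sample(spec.length, rows, rng)


def _cpg_free_segment(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    seg = _markov_sample(n, _transition_rows(gc, cg_transition=0.0), rng)
    # a trailing C could form a CpG with the next genome base
    if seg[-1] == _C:
        seg[-1] = _T
    return seg


def _plan_desert_sites(
    spec: DesertLocusSpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Site offsets (of the C) within the locus, plus cluster blocks.

    Returns strictly increasing offsets >= 0 and <= length-2, all >= 2
    apart, and (first, last) offset pairs for each planted cluster.
    """
    L = spec.length
    n_total = max(
        int(round(spec.density * L / 100.0)), sum(n for n, _ in spec.clusters)
    )
    margin = 20
    taken: list[tuple[int, int]] = []  # occupied [lo, hi) blocks incl. clearance
    cluster_blocks: list[tuple[int, int]] = []
    cluster_sites: list[int] = []
    for n_sites, gap in spec.clusters:
        span = (n_sites - 1) * gap + 2
        for _ in range(200):
            start = int(rng.integers(margin, L - margin - span))
            lo, hi = start - 40, start + span + 40
            if all(hi <= a or lo >= b for a, b in taken):
                taken.append((lo, hi))
                offs = [start + j * gap for j in range(n_sites)]
                cluster_sites.extend(offs)
                cluster_blocks.append((offs[0], offs[-1]))
                break
        else:
            raise ValueError("could not place cluster in desert locus")
    n_scatter = n_total - len(cluster_sites)
    scatter: list[int] = []
    if n_scatter > 0:
        # stratified spread keeps local density close to the target
        edges = np.linspace(margin, L - margin, n_scatter + 1)
        for k in range(n_scatter):
            lo, hi = edges[k], edges[k + 1]
            for _ in range(50):
                p = int(rng.integers(int(lo), max(int(hi), int(lo) + 1)))
                if p > L - 2:
                    p = L - 2
                if all(abs(p - q) >= 2 for q in cluster_sites + scatter):
                    scatter.append(p)
                    break
    sites = np.array(sorted(cluster_sites + scatter), dtype=np.int64)
    return sites, cluster_blocks


def simulate_genome(spec: GenomeSpec) -> tuple[SequenceRecord, GenomeTruth]:
    """Realize a genome with planted islands and desert DMR loci.

    Planted desert densities are exact up to rounding of the site count
    (well within +-1 CpG/100 bp of the target).
    """
    rng = np.random.default_rng(spec.seed)
    codes = _background(spec.length, spec.gc_fraction, spec.cpg_obs_exp, rng)

    island_truth: list[GenomicInterval] = []
    for isl in spec.islands:
        seg = _island_segment(isl, rng)
        codes[isl.position : isl.position + isl.length] = seg
        island_truth.append(
            GenomicInterval(spec.chrom, isl.position, isl.position + isl.length, "island")
        )

    desert_truth: list[DesertTruth] = []
    for des in spec.deserts:
        seg = _cpg_free_segment(des.length, des.gc_fraction, rng)
        sites, blocks = _plan_desert_sites(des, rng)
        seg[sites] = _C
        seg[sites + 1] = _G
        # guard against a C just before a planted G creating an extra CpG
        pre = sites[sites >= 1] - 1
        pre = pre[~np.isin(pre, sites)]
        fix = pre[seg[pre] == _C]
        seg[fix] = _T
        codes[des.position : des.position + des.length] = seg
        iv = GenomicInterval(spec.chrom, des.position, des.position + des.length, "desert")
        desert_truth.append(
            DesertTruth(
                interval=iv,
                density=len(sites) * 100.0 / des.length,
                clusters=tuple(
                    GenomicInterval(spec.chrom, des.position + a, des.position + b + 2)
                    for a, b in blocks
                ),
            )
        )

    seq = _BASES[codes].tobytes().decode("ascii")
    rec = SequenceRecord(spec.chrom, seq)
    return rec, GenomeTruth(tuple(island_truth), tuple(desert_truth))


def make_genome_spec(
    seed: int,
    length: int,
    n_deserts: int,
    n_islands: int,
    density_range: tuple[float, float] = (1.0, 8.0),
    desert_length_range: tuple[int, int] = (500, 2000),
    island_length_range: tuple[int, int] = (300, 800),
    grid: int | None = None,
    margin: int = 2000,
) -> GenomeSpec:
    """Randomly place non-overlapping planted features in a genome spec.

    Desert densities are drawn uniformly from ``density_range`` (default
    the 1-8 CpG/100 bp band where most transgenerational DMRs fall).
    ``grid``, if given, aligns desert starts to multiples of that many bp
    (convenient for tiling probes exactly inside each locus).
    """
    rng = np.random.default_rng(seed)
    placed: list[tuple[int, int]] = []

    def place(seg_len: int) -> int:
        for _ in range(1000):
            pos = int(rng.integers(margin, length - margin - seg_len))
            if grid:
                pos = (pos // grid) * grid
            lo, hi = pos - margin, pos + seg_len + margin
            if all(hi <= a or lo >= b for a, b in placed):
                placed.append((lo, hi))
                return pos
        raise ValueError("could not place feature; genome too crowded")

    deserts = []
    for _ in range(n_deserts):
        dlen = int(rng.integers(desert_length_range[0], desert_length_range[1] + 1))
        if grid:
            dlen = max(desert_length_range[0], (dlen // grid) * grid)
        dens = float(rng.uniform(*density_range))
        deserts.append(DesertLocusSpec(place(dlen), dlen, dens))
    islands = []
    for _ in range(n_islands):
        ilen = int(rng.integers(island_length_range[0], island_length_range[1] + 1))
        islands.append(IslandSpec(place(ilen), ilen))
    return GenomeSpec(
        seed=seed,
        length=length,
        deserts=tuple(sorted(deserts, key=lambda d: d.position)),
        islands=tuple(sorted(islands, key=lambda i: i.position)),
    )


# -- probe experiments ----------------------------------------------------

@dataclass(frozen=True)
class PlantedRun:
    """A planted methylation shift over ``width`` adjacent probes."""

    start_probe: int
    width: int
    delta: float  # shift in units of sigma
    direction: int = 1

    def __post_init__(self) -> None:
        if self.width < 3:
            raise ValueError(
                "planted run width must be >= 3 probes: a DMR requires a "
                "minimum of three adjacent significant probes"
            )
        if self.direction not in (-1, 1):
            raise ValueError("direction must be -1 or +1")


@dataclass(frozen=True)
class ExperimentSpec:
    seed: int
    n_probes: int
    probe_length: int = 50
    spacing: int = 100  # start-to-start
    chrom: str = "chrSim"
    n_control: int = 3
    n_exposure: int = 3
    sigma: float = 0.25
    planted: tuple[PlantedRun, ...] = ()

    def __post_init__(self) -> None:
        spans = sorted((r.start_probe, r.start_probe + r.width) for r in self.planted)
        prev = 0
        for s, e in spans:
            if s < prev:
                raise ValueError("planted probe runs overlap")
            if e > self.n_probes:
                raise ValueError("planted run extends past the probe design")
            prev = e


@dataclass(frozen=True)
class DMRTruth:
    interval: GenomicInterval
    start_probe: int
    width: int
    delta: float
    direction: int


def simulate_probe_experiment(
    spec: ExperimentSpec,
) -> tuple[ProbeDesign, IntensityMatrix, list[DMRTruth]]:
    """Tile probes and draw log-intensities with planted shifts.

    Control samples are i.i.d. Normal(0, sigma^2) per probe; exposure
    samples follow the same distribution shifted by direction*delta*sigma
    on planted probes.
    """
    rng = np.random.default_rng(spec.seed)
    probes = tuple(
        (
            f"p{i:06d}",
            GenomicInterval(
                spec.chrom, i * spec.spacing, i * spec.spacing + spec.probe_length
            ),
        )
        for i in range(spec.n_probes)
    )
    design = ProbeDesign(probes)
    control = rng.normal(0.0, spec.sigma, size=(spec.n_probes, spec.n_control))
    exposure = rng.normal(0.0, spec.sigma, size=(spec.n_probes, spec.n_exposure))
    truth: list[DMRTruth] = []
    for run in spec.planted:
        sl = slice(run.start_probe, run.start_probe + run.width)
        exposure[sl, :] += run.direction * run.delta * spec.sigma
        first = probes[run.start_probe][1]
        last = probes[run.start_probe + run.width - 1][1]
        truth.append(
            DMRTruth(
                interval=GenomicInterval(spec.chrom, first.start, last.end),
                start_probe=run.start_probe,
                width=run.width,
                delta=run.delta,
                direction=run.direction,
            )
        )
    mat = IntensityMatrix(tuple(p for p, _ in probes), control, exposure)
    return design, mat, truth


def plan_runs_for_deserts(
    desert_intervals: list[GenomicInterval],
    spacing: int = 100,
    width: int = 5,
    delta: float = 5.0,
    rng: np.random.Generator | None = None,
) -> tuple[PlantedRun, ...]:
    """Plant one width-probe shifted run inside each desert locus.

    The first probe of the run is the first probe starting at or after the
    locus start, so with grid-aligned loci the run lies wholly inside.
    Directions alternate hyper/hypo unless an rng is given to randomize.
    """
    runs = []
    for k, iv in enumerate(desert_intervals):
        start_probe = -(-iv.start // spacing)  # ceil division
        if rng is None:
            direction = 1 if k % 2 == 0 else -1
        else:
            direction = int(rng.choice([-1, 1]))
        runs.append(PlantedRun(start_probe, width, delta, direction))
    return tuple(runs)


# -- exposure sets ---------------------------------------------------------

def simulate_exposure_sets(
    seed: int,
    n_sets: int,
    set_sizes: list[int],
    shared_fraction: float,
    labels: tuple[str, ...] | None = None,
    interval_length: int = 1000,
    slot: int = 10_000,
    chrom: str = "chrSim",
) -> tuple[list[NamedIntervalSet], dict]:
    """Labelled DMR sets with an exactly known Venn partition.

    Sets are paired (0,1), (2,3), ...; each pair shares
    round(shared_fraction*min(pair sizes)) identical intervals, all other
    elements are set-specific and mutually disjoint. Returns the sets and
    the true partition cell counts keyed by frozenset of labels.
    """
    if not (0 <= shared_fraction < 1):
        raise ValueError("shared_fraction must be in [0, 1)")
    if len(set_sizes) != n_sets:
        raise ValueError("set_sizes must have n_sets entries")
    labels = labels or EXPOSURE_LABELS[:n_sets]
    rng = np.random.default_rng(seed)

    next_slot = 0

    def fresh_interval(name: str) -> GenomicInterval:
        nonlocal next_slot
        start = next_slot * slot + int(rng.integers(0, slot - interval_length))
        next_slot += 1
        return GenomicInterval(chrom, start, start + interval_length, name)

    members: dict[str, list[GenomicInterval]] = {lab: [] for lab in labels}
    truth_cells: dict[frozenset, int] = {}
    for a in range(0, n_sets - 1, 2):
        b = a + 1
        n_shared = int(round(shared_fraction * min(set_sizes[a], set_sizes[b])))
        for j in range(n_shared):
            iv = fresh_interval(f"shared_{labels[a]}_{labels[b]}_{j}")
            members[labels[a]].append(iv)
            members[labels[b]].append(iv)
        key = frozenset([labels[a], labels[b]])
        truth_cells[key] = n_shared
    pair_of: dict[int, int] = {}
    for a in range(0, n_sets - 1, 2):
        pair_of[a], pair_of[a + 1] = a + 1, a
    for i, lab in enumerate(labels):
        j = pair_of.get(i)
        pair_shared = (
            truth_cells.get(frozenset([lab, labels[j]]), 0) if j is not None else 0
        )
        n_unique = set_sizes[i] - pair_shared
        for j in range(n_unique):
            members[lab].append(fresh_interval(f"{lab}_{j}"))
        truth_cells[frozenset([lab])] = n_unique

    sets = [NamedIntervalSet(lab, tuple(members[lab])) for lab in labels]
    universe = sum(truth_cells.values())
    truth = {
        "cells": truth_cells,
        "universe_size": universe,
        "fraction_exposure_specific": (
            sum(v for k, v in truth_cells.items() if len(k) == 1) / universe
            if universe
            else 0.0
        ),
    }
    return sets, truth


def genome_manifest(spec: GenomeSpec) -> dict:
    return asdict(spec)


def experiment_manifest(spec: ExperimentSpec) -> dict:
    return asdict(spec)
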