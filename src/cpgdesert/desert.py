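"""CpG desert classification.

A CpG desert is a 500-2000 bp differentially methylated region with a
whole-interval CpG density strictly below 15 CpG/100 bp, containing at
least one small CpG cluster and overlapping no CpG island. Every criterion
is evaluated (no short-circuiting) so the verdict always carries a
complete list of failure reasons.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cpg
from .intervals import (
    GenomicInterval,
    SequenceRecord,
    effective_length,
    intervals_overlap,
    n_fraction,
)

#: an interval with more N than this fraction is considered masked and is
#: never classified as a desert
MASKED_N_FRACTION = 0.5


@dataclass(frozen=True)
class DesertParams:
    """Thresholds of the CpG desert definition.

    min/max_length bound the region size in bp; max_density is an
    exclusive bound in CpG/100 bp; require_cluster demands >= 1 small CpG
    cluster; forbid_island rejects regions overlapping a CpG island.
    Cluster and island detection parameters are carried along so one
    object fully specifies a classification.
    """

    min_length: int = 500
    max_length: int = 2000
    max_density: float = 15.0
    require_cluster: bool = True
    forbid_island: bool = True
    cluster_min_sites: int = 3
    cluster_max_gap: int = 30
    island_params: dict = field(
        default_factory=lambda: dict(
            min_length=200, gc_threshold=0.50, oe_threshold=0.60, window=200, step=1
        )
    )

    def __post_init__(self) -> None:
        if not (0 < self.min_length <= self.max_length):
            raise ValueError("require 0 < min_length <= max_length")
        if self.max_density <= 0:
            raise ValueError("max_density must be > 0")


@dataclass(frozen=True)
class DesertCall:
    interval: GenomicInterval
    density: float
    n_clusters: int
    n_islands_overlapping: int
    is_desert: bool
    reasons: tuple[str, ...]  # empty iff is_desert


def classify_interval(
    rec: SequenceRecord,
    iv: GenomicInterval,
    params: DesertParams | None = None,
    sites: cpg.CpGSiteList | None = None,
    islands: list[cpg.CpGIsland] | None = None,
) -> DesertCall:
    """Classify one interval against the CpG desert definition.

    ``sites`` and ``islands`` may be supplied (precomputed over the whole
    record) to avoid rescanning when classifying many intervals; they are
    otherwise computed here.
    """
    params = params or DesertParams()
    if sites is None:
        sites = cpg.find_cpg_sites(rec)
    if islands is None:
        islands = cpg.detect_islands(rec, **params.island_params)

    reasons: list[str] = []
    if n_fraction(rec, iv) > MASKED_N_FRACTION:
        reasons.append("masked")

    eff = effective_length(rec, iv)
    density = (
        cpg.interval_cpg_density(sites, iv, eff) if eff > 0 else math.nan
    )
    overlapping = [i for i in islands if intervals_overlap(i.interval, iv)]
    clusters = cpg.detect_clusters(
        sites,
        iv,
        min_sites=params.cluster_min_sites,
        max_gap=params.cluster_max_gap,
        exclude=overlapping if params.forbid_island else None,
    )

    length = iv.length()
    if not (params.min_length <= length <= params.max_length):
        reasons.append("length")
    if not (density < params.max_density):  # strict bound; NaN fails too
        reasons.append("density")
    if params.require_cluster and len(clusters) == 0:
        reasons.append("cluster")
    if params.forbid_island and len(overlapping) > 0:
        reasons.append("island")

    return DesertCall(
        interval=iv,
        density=density,
        n_clusters=len(clusters),
        n_islands_overlapping=len(overlapping),
        is_desert=not reasons,
        reasons=tuple(reasons),
    )


def classify_dmr_set(
    records: SequenceRecord | list[SequenceRecord],
    intervals: list[GenomicInterval],
    params: DesertParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Classify a set of intervals (typically called DMRs).

    Returns a per-interval table and a summary with the fraction of
    deserts, the fraction with density < 10 CpG/100 bp, density
    min/max/median, and a 1 CpG/100 bp density histogram.
    """
    params = params or DesertParams()
    if isinstance(records, SequenceRecord):
        records = [records]
    by_id = {r.id: r for r in records}
    unresolved = sorted({iv.chrom for iv in intervals if iv.chrom not in by_id})
    if unresolved:
        raise ValueError(f"intervals reference unknown sequences: {unresolved}")

    sites_cache = {rid: cpg.find_cpg_sites(r) for rid, r in by_id.items()}
    islands_cache = {
        rid: cpg.detect_islands(r, **params.island_params) for rid, r in by_id.items()
    }
    calls = [
        classify_interval(
            by_id[iv.chrom],
            iv,
            params,
            sites=sites_cache[iv.chrom],
            islands=islands_cache[iv.chrom],
        )
        for iv in intervals
    ]
    table = pd.DataFrame(
        {
            "chrom": [c.interval.chrom for c in calls],
            "start": [c.interval.start for c in calls],
            "end": [c.interval.end for c in calls],
            "name": [c.interval.name or "." for c in calls],
            "length_bp": [c.interval.length() for c in calls],
            "density_cpg_per_100bp": [c.density for c in calls],
            "n_clusters": [c.n_clusters for c in calls],
            "n_islands_overlapping": [c.n_islands_overlapping for c in calls],
            "is_desert": [c.is_desert for c in calls],
            "reasons": [",".join(c.reasons) for c in calls],
        }
    )
    dens = table["density_cpg_per_100bp"].to_numpy()
    finite = dens[np.isfinite(dens)]
    n = len(calls)
    summary = {
        "n_intervals": n,
        "n_desert": int(table["is_desert"].sum()),
        "fraction_desert": (float(table["is_desert"].mean()) if n else 0.0),
        "n_density_lt_10": int((finite < 10.0).sum()),
        "fraction_density_lt_10": (float((finite < 10.0).sum() / n) if n else 0.0),
        "density_min": float(finite.min()) if len(finite) else None,
        "density_max": float(finite.max()) if len(finite) else None,
        "density_median": float(np.median(finite)) if len(finite) else None,
        "histogram": _hist_dict(cpg.density_histogram(finite)),
    }
    return table, summary


def _hist_dict(h: cpg.DensityHistogram) -> dict:
    return {
        "bin_width": h.bin_width,
        "bin_lefts": [float(x) for x in h.bin_lefts],
        "counts": [int(c) for c in h.counts],
    }
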