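"""DMR calling from control-vs-exposure tiling-array log-intensities.

Per probe, the statistic is the median of all control x exposure pairwise
intensity differences (exposure minus control). Medians are standardized
against the experiment-wide mean and standard deviation of that statistic
and converted to two-sided normal p-values. A DMR is a maximal run of
design-adjacent probes, each significant at alpha (default 1e-5) with the
same direction of change, of at least ``min_adjacent`` (default 3) probes.
No multiple-testing correction enters the calling itself; a
Benjamini-Hochberg q-value column is emitted for context only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .intervals import GenomicInterval


@dataclass(frozen=True)
class ProbeDesign:
    """Ordered tiling-array probe layout.

    Probes are sorted by (chrom, start) and non-overlapping within a
    chromosome; adjacency is consecutive design order within a chromosome
    regardless of genomic gap.
    """

    probes: tuple[tuple[str, GenomicInterval], ...]

    def __post_init__(self) -> None:
        prev: GenomicInterval | None = None
        for _, iv in self.probes:
            if prev is not None and prev.chrom == iv.chrom:
                if iv.start < prev.end:
                    raise ValueError(
                        f"probes overlap or are unsorted: {prev.display()} then {iv.display()}"
                    )
            elif prev is not None and prev.chrom > iv.chrom:
                raise ValueError("probes not sorted by chromosome")
            prev = iv

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def spacing(self) -> float:
        """Median start-to-start gap between design-adjacent probes."""
        gaps = [
            b[1].start - a[1].start
            for a, b in zip(self.probes[:-1], self.probes[1:])
            if a[1].chrom == b[1].chrom
        ]
        return float(np.median(gaps)) if gaps else float("nan")


@dataclass(frozen=True)
class IntensityMatrix:
    """Probe x sample log-intensities, split by lineage group."""

    probe_ids: tuple[str, ...]
    control: np.ndarray  # (n_probes, n_control)
    exposure: np.ndarray  # (n_probes, n_exposure)

    def __post_init__(self) -> None:
        n = len(self.probe_ids)
        if self.control.ndim != 2 or self.exposure.ndim != 2:
            raise ValueError("intensity matrices must be 2-D")
        if self.control.shape[0] != n or self.exposure.shape[0] != n:
            raise ValueError("matrix rows must match probe_ids")
        if self.control.shape[1] < 1 or self.exposure.shape[1] < 1:
            raise ValueError("need >= 1 sample per group")


@dataclass(frozen=True)
class ProbeStat:
    probe_id: str
    m: float  # median intensity difference
    z: float
    p: float  # two-sided
    direction: int  # sign of m


@dataclass(frozen=True)
class DMRCall:
    interval: GenomicInterval
    probe_ids: tuple[str, ...]
    n_probes: int
    min_p: float
    mean_m: float
    direction: int
    size_bp: int


def probe_median_difference(
    mat: IntensityMatrix, aggregate: str = "pairwise_median"
) -> np.ndarray:
    """Per-probe median intensity difference (exposure minus control).

    ``pairwise_median`` (default): median over all n_c x n_e pairwise
    differences. ``group_median_difference``: difference of the group
    medians. Non-finite input is an error naming the probe and sample.
    """
    for name, arr in (("control", mat.control), ("exposure", mat.exposure)):
        bad = np.argwhere(~np.isfinite(arr))
        if len(bad):
            i, j = bad[0]
            raise ValueError(
                f"non-finite intensity for probe {mat.probe_ids[i]!r}, "
                f"{name} sample index {j}"
            )
    if aggregate == "pairwise_median":
        diffs = mat.exposure[:, :, None] - mat.control[:, None, :]
        return np.median(diffs.reshape(len(mat.probe_ids), -1), axis=1)
    if aggregate == "group_median_difference":
        return np.median(mat.exposure, axis=1) - np.median(mat.control, axis=1)
    raise ValueError(f"unknown aggregate {aggregate!r}")


def probe_pvalues(
    ms: np.ndarray,
    probe_ids: list[str] | None = None,
    chroms: list[str] | None = None,
) -> list[ProbeStat]:
    """Standardize per-probe medians and attach two-sided normal p-values.

    The scaling mean and standard deviation (ddof=1) are computed over all
    probes in the experiment; pass ``chroms`` to scale per chromosome
    instead. Requires >= 2 probes per scaling group and non-constant
    medians.
    """
    ms = np.asarray(ms, dtype=np.float64)
    if probe_ids is None:
        probe_ids = [f"probe_{i}" for i in range(len(ms))]
    z = np.empty_like(ms)
    groups = (
        {None: np.arange(len(ms))}
        if chroms is None
        else {c: np.nonzero(np.asarray(chroms) == c)[0] for c in dict.fromkeys(chroms)}
    )
    for key, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"need >= 2 probes to scale (group {key!r})")
        mu = ms[idx].mean()
        sd = ms[idx].std(ddof=1)
        if sd == 0:
            raise ValueError("degenerate experiment: constant differences")
        z[idx] = (ms[idx] - mu) / sd
    p = 2.0 * sstats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)
    return [
        ProbeStat(pid, float(m), float(zi), float(pi), int(np.sign(m)))
        for pid, m, zi, pi in zip(probe_ids, ms, z, p)
    ]


def call_dmrs(
    design: ProbeDesign,
    probe_stats: list[ProbeStat],
    alpha: float = 1e-5,
    min_adjacent: int = 3,
    same_direction: bool = True,
    max_gap_bp: int | None = None,
) -> list[DMRCall]:
    """Merge runs of adjacent significant probes into DMR calls.

    A run is maximal over design-adjacent probes on one chromosome, each
    with p < alpha and (if ``same_direction``) an identical sign of
    change; runs shorter than ``min_adjacent`` probes are discarded. The
    DMR interval spans the first probe start through the last probe end.
    ``max_gap_bp``, if set, additionally breaks runs across genomic gaps
    larger than that many bp between consecutive probes.
    """
    if len(probe_stats) != len(design):
        raise ValueError(
            f"{len(probe_stats)} probe stats for {len(design)} design probes"
        )
    calls: list[DMRCall] = []
    run: list[tuple[str, GenomicInterval, ProbeStat]] = []

    def flush() -> None:
        if len(run) >= min_adjacent:
            ivs = [iv for _, iv, _ in run]
            stats_ = [s for _, _, s in run]
            interval = GenomicInterval(ivs[0].chrom, ivs[0].start, ivs[-1].end)
            calls.append(
                DMRCall(
                    interval=interval,
                    probe_ids=tuple(pid for pid, _, _ in run),
                    n_probes=len(run),
                    min_p=min(s.p for s in stats_),
                    mean_m=float(np.mean([s.m for s in stats_])),
                    direction=stats_[0].direction,
                    size_bp=interval.length(),
                )
            )
        run.clear()

    for (pid, iv), st in zip(design.probes, probe_stats):
        significant = st.p < alpha
        if not significant:
            flush()
            continue
        if run:
            _, prev_iv, prev_st = run[-1]
            broken = prev_iv.chrom != iv.chrom
            if same_direction and prev_st.direction != st.direction:
                broken = True
            if max_gap_bp is not None and not broken:
                if iv.start - prev_iv.end > max_gap_bp:
                    broken = True
            if broken:
                flush()
        run.append((pid, iv, st))
    flush()
    return calls


def probe_stats_table(probe_stats: list[ProbeStat], fdr: bool = True) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "probe_id": [s.probe_id for s in probe_stats],
            "m": [s.m for s in probe_stats],
            "z": [s.z for s in probe_stats],
            "p": [s.p for s in probe_stats],
            "direction": [s.direction for s in probe_stats],
        }
    )
    if fdr and len(df):
        # context only; never used by call_dmrs
        df["q_bh"] = sstats.false_discovery_control(df["p"].to_numpy())
    return df


def dmr_report(calls: list[DMRCall]) -> tuple[pd.DataFrame, dict]:
    """Tabulate DMR calls; summary reports the mean size ('NA' if empty)."""
    table = pd.DataFrame(
        {
            "chrom": [c.interval.chrom for c in calls],
            "start": [c.interval.start for c in calls],
            "end": [c.interval.end for c in calls],
            "n_probes": [c.n_probes for c in calls],
            "min_p": [c.min_p for c in calls],
            "mean_m": [c.mean_m for c in calls],
            "direction": [c.direction for c in calls],
            "size_bp": [c.size_bp for c in calls],
        }
    )
    summary = {
        "n_dmrs": len(calls),
        "mean_size_bp": (float(table["size_bp"].mean()) if len(calls) else "NA"),
    }
    return table, summary
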