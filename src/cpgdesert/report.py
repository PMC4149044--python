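"""Text-track reports: per-DMR CpG maps and density histograms.

``render_dmr_map`` draws the figure-style view of one DMR: a box for the
region, one hatch mark per CpG site, underlines for small CpG clusters
and boxes for any overlapping island. The track embeds the exact site
positions in a machine-readable comment line so a rendered map can be
parsed back losslessly.
"""
from __future__ import annotations

from . import cpg
from .intervals import GenomicInterval, SequenceRecord, intervals_overlap


def render_dmr_map(
    rec: SequenceRecord,
    iv: GenomicInterval,
    sites: cpg.CpGSiteList | None = None,
    clusters: list[cpg.CpGCluster] | None = None,
    islands: list[cpg.CpGIsland] | None = None,
    width: int = 80,
) -> str:
    """Deterministic text track for one region (1-based display header)."""
    if sites is None:
        sites = cpg.find_cpg_sites(rec)
    if clusters is None:
        clusters = cpg.detect_clusters(sites, iv)
    if islands is None:
        islands = cpg.detect_islands(rec)
    lo, hi = iv.start, iv.end
    in_region = [int(p) for p in sites.positions if lo <= p < hi]

    def col(pos: int) -> int:
        c = int((pos - lo) * width / iv.length())
        return min(c, width - 1)

    hatch = [" "] * width
    for p in in_region:
        hatch[col(p)] = "#"
    clu_line = [" "] * width
    for cl in clusters:
        if not intervals_overlap(cl.interval, iv):
            continue
        for c in range(col(max(cl.interval.start, lo)), col(min(cl.interval.end, hi) - 1) + 1):
            clu_line[c] = "_"
    isl_line = [" "] * width
    overlapping_islands = [i for i in islands if intervals_overlap(i.interval, iv)]
    for isl in overlapping_islands:
        for c in range(col(max(isl.interval.start, lo)), col(min(isl.interval.end, hi) - 1) + 1):
            isl_line[c] = "="

    lines = [
        f"# region {iv.display()} ({iv.length()} bp)"
        + (f" {iv.name}" if iv.name else ""),
        f"# cpg_positions: {','.join(str(p) for p in in_region)}",
        "DMR  |" + "=" * width + "|",
        "CpG  |" + "".join(hatch) + "|",
        "CLU  |" + "".join(clu_line) + "|",
        "ISL  |"
        + ("".join(isl_line) if overlapping_islands else " (none)".ljust(width))
        + "|",
    ]
    return "\n".join(lines) + "\n"


def parse_dmr_map(text: str) -> list[int]:
    """Recover the CpG site positions embedded in a rendered map."""
    for line in text.splitlines():
        if line.startswith("# cpg_positions:"):
            payload = line.split(":", 1)[1].strip()
            return [int(x) for x in payload.split(",")] if payload else []
    raise ValueError("no cpg_positions line in track")


def format_histogram(hist: cpg.DensityHistogram, bar_width: int = 50) -> str:
    """Horizontal ASCII histogram of a density distribution."""
    if hist.total() == 0:
        return "(empty histogram)\n"
    peak = int(hist.counts.max())
    lines = []
    for left, count in zip(hist.bin_lefts, hist.counts):
        bar = "#" * int(round(count / peak * bar_width))
        lines.append(
            f"{left:6.1f}-{left + hist.bin_width:<6.1f} {int(count):6d} {bar}"
        )
    return "\n".join(lines) + "\n"
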