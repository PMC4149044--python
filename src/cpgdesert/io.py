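"""File I/O: FASTA, BED6, probe designs, intensity matrices, group maps.

All tabular formats are plain tab-delimited text. BED output is 0-based
half-open per the BED standard.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .intervals import GenomicInterval, SequenceRecord, normalize_sequence

log = logging.getLogger(__name__)


# -- FASTA --------------------------------------------------------------

def parse_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-record, line-wrapped) FASTA file.

    Sequences are uppercased and non-ACGTN symbols mapped to N with a
    logged warning. Raises on an empty file or duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(rec.id, normalize_sequence(str(rec.seq), record_id=rec.id))
        )
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# -- BED ----------------------------------------------------------------

def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED6: chrom, start, end, name, score, strand='.'."""
    rows = []
    for i, iv in enumerate(intervals):
        score = 0 if scores is None else scores[i]
        rows.append((iv.chrom, iv.start, iv.end, iv.name or ".", score, "."))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (3+ columns); the 4th column, if present, becomes name."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), name))
    return out


# -- probe designs and intensities --------------------------------------

def write_probe_design(probes: Iterable[tuple[str, GenomicInterval]], path: str | Path) -> None:
    rows = [(pid, iv.chrom, iv.start, iv.end) for pid, iv in probes]
    pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def read_probe_design(path: str | Path) -> list[tuple[str, GenomicInterval]]:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    return [
        (r.probe_id, GenomicInterval(r.chrom, int(r.start), int(r.end)))
        for r in df.itertuples()
    ]


def write_intensity_table(
    probe_ids: Sequence[str],
    samples: dict[str, np.ndarray],
    path: str | Path,
) -> None:
    """Columns: probe_id then one column of log-intensities per sample."""
    df = pd.DataFrame({"probe_id": list(probe_ids)})
    for name, col in samples.items():
        df[name] = col
    df.to_csv(path, sep="\t", index=False)


def read_intensity_table(path: str | Path) -> tuple[list[str], pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    probe_ids = df["probe_id"].tolist()
    return probe_ids, df.drop(columns=["probe_id"])


def write_group_map(groups: dict[str, str], path: str | Path) -> None:
    """sample -> 'control' | 'exposure', one pair per line."""
    with open(path, "w") as fh:
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def read_group_map(path: str | Path) -> dict[str, str]:
    groups: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, group = line.split("\t")
            if group not in ("control", "exposure"):
                raise ValueError(f"unknown group {group!r} for sample {sample!r}")
            groups[sample] = group
    return groups
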