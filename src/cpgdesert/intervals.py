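"""Sequence and interval primitives.

Coordinates are 0-based half-open throughout the library (BED convention);
human-readable reports render 1-based inclusive. Sequences are uppercase
strings over {A, C, G, T, N}; soft-masked (lowercase) input is treated as
its uppercase equivalent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_sequence(raw: str, *, record_id: str = "?") -> str:
    """Uppercase a raw sequence and map any symbol outside {A,C,G,T,N} to N.

    A warning is logged when symbols were replaced.
    """
    seq = raw.upper()
    if not set(seq) <= ALPHABET:
        n_bad = sum(1 for c in seq if c not in ALPHABET)
        log.warning(
            "sequence %r: %d non-ACGTN symbol(s) replaced with N", record_id, n_bad
        )
        seq = "".join(c if c in ALPHABET else "N" for c in seq)
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named genomic sequence (chromosome, contig or promoter region)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        if not set(self.seq) <= ALPHABET:
            raise ValueError(
                f"sequence {self.id!r} contains symbols outside ACGTN; "
                "use SequenceRecord.from_raw to normalize"
            )

    @classmethod
    def from_raw(cls, id: str, raw: str) -> "SequenceRecord":
        return cls(id=id, seq=normalize_sequence(raw, record_id=id))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located region, 0-based half-open: [start, end) on chrom."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def length(self) -> int:
        return self.end - self.start

    def display(self) -> str:
        """1-based inclusive rendering for human-readable reports."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff a and b share at least one base (half-open semantics)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def extract_subsequence(rec: SequenceRecord, iv: GenomicInterval) -> str:
    """Return the bases of rec covered by iv.

    Raises ValueError if iv names a different sequence or runs past its end.
    """
    if iv.chrom != rec.id:
        raise ValueError(f"interval chrom {iv.chrom!r} does not match record {rec.id!r}")
    if iv.end > len(rec.seq):
        raise ValueError(
            f"interval {iv.display()} out of bounds for sequence {rec.id!r} "
            f"of length {len(rec.seq)}"
        )
    return rec.seq[iv.start : iv.end]


def effective_length(rec: SequenceRecord, iv: GenomicInterval) -> int:
    """Interval length minus masked (N) bases."""
    sub = extract_subsequence(rec, iv)
    return len(sub) - sub.count("N")


def n_fraction(rec: SequenceRecord, iv: GenomicInterval) -> float:
    sub = extract_subsequence(rec, iv)
    return sub.count("N") / len(sub)
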