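"""Sequence and interval primitives for bisulfite-space genomics.

Everything downstream (probe design, coverage accounting, beta
aggregation) is built on three ideas defined here:

* 0-based half-open genomic intervals (BED convention) as the single
  internal coordinate system; 1-based formats are converted at I/O
  boundaries.
* In-silico bisulfite conversion: on a given strand every cytosine in
  CpH context (followed by A, C or T) deaminates and reads as thymine,
  while CpG cytosines may be protected by methylation.  The fully
  converted sequence (every CpH C -> T, CpG C retained) is the search
  space capture probes hybridise against.
* CpG enumeration, reported as the 0-based position of the C on the
  top strand, which is the coordinate per-CpG counts are keyed by.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

__all__ = [
    "GenomicInterval",
    "TargetRegion",
    "ConvertedSequence",
    "reverse_complement",
    "convert_cph_to_tph",
    "enumerate_cpgs",
    "pad_targets",
    "DEFAULT_PAD_BP",
]

DEFAULT_PAD_BP = 100

_DNA = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """End-to-end gap in bp; 0 if overlapping, None on different chroms."""
        if self.chrom != other.chrom:
            return None
        return max(0, other.start - self.end, self.start - other.end)


@dataclass(frozen=True)
class TargetRegion:
    """A target interval (typically a DMR call) plus its capture padding.

    The probes are designed against, and reads are collected over, the
    *padded footprint*; coverage and beta metrics are reported over the
    original interval.
    """

    interval: GenomicInterval
    name: str
    pad_bp: int = DEFAULT_PAD_BP

    def __post_init__(self) -> None:
        if self.pad_bp < 0:
            raise ValueError("pad_bp must be non-negative")

    def padded(self, chrom_length: int | None = None) -> GenomicInterval:
        start = max(0, self.interval.start - self.pad_bp)
        end = self.interval.end + self.pad_bp
        if chrom_length is not None:
            end = min(end, chrom_length)
        return replace(self.interval, start=start, end=end)


@dataclass(frozen=True)
class ConvertedSequence:
    """A fully CpH>TpH bisulfite-converted sequence.

    ``source_strand`` records which genomic strand was converted; a
    ``bottom`` sequence is reported in reverse-complement orientation
    (i.e. as the bottom strand reads 5'->3').
    """

    seq: str
    source_strand: str = "top"

    def __post_init__(self) -> None:
        if self.source_strand not in ("top", "bottom"):
            raise ValueError(f"invalid source_strand {self.source_strand!r}")

    def __len__(self) -> int:
        return len(self.seq)


def _convert_top(seq: str) -> str:
    out = list(seq)
    n = len(seq)
    for i, base in enumerate(seq):
        if base == "C" and not (i + 1 < n and seq[i + 1] == "G"):
            # CpH, CpN and terminal C all convert: context not provably CpG.
            out[i] = "T"
    return "".join(out)


def convert_cph_to_tph(seq: str, strand: str = "top") -> ConvertedSequence:
    """Fully convert a sequence in CpH>TpH space.

    Every cytosine not immediately followed by G becomes T; CpG
    cytosines are retained (methylation-protected positions remain
    informative).  For ``strand="bottom"`` the rule is applied to the
    reverse complement and the result reported in that orientation.

    Parameters
    ----------
    seq : DNA string over {A,C,G,T,N} (case-insensitive).
    strand : ``"top"`` or ``"bottom"``.
    """
    seq = _check_dna(seq)
    if strand == "top":
        return ConvertedSequence(_convert_top(seq), "top")
    if strand == "bottom":
        return ConvertedSequence(_convert_top(reverse_complement(seq)), "bottom")
    raise ValueError(f"strand must be 'top' or 'bottom', got {strand!r}")


def enumerate_cpgs(seq: str, offset: int = 0) -> list[int]:
    """0-based positions (plus *offset*) of the C of every CpG dinucleotide."""
    seq = _check_dna(seq)
    pos = []
    i = seq.find("CG")
    while i != -1:
        pos.append(i + offset)
        i = seq.find("CG", i + 1)
    return pos


def pad_targets(
    targets: Iterable[TargetRegion],
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Padded capture footprint of each target, clipped at chromosome ends.

    Overlapping padded footprints are *not* merged; region identity is
    preserved so per-target metrics stay attributable.
    """
    out = []
    for t in targets:
        clen = None
        if chrom_lengths is not None:
            clen = chrom_lengths.get(t.interval.chrom)
        out.append(t.padded(clen))
    return out


def unpad(interval: GenomicInterval, pad_bp: int) -> GenomicInterval:
    """Inverse of padding for interior intervals (left clip not recoverable)."""
    return replace(interval, start=interval.start + pad_bp, end=interval.end - pad_bp)
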