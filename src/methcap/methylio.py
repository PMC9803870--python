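"""Readers and writers for the formats a capture-methylation workflow touches.

Per-read methylation travels as the Bismark-style ``XM`` call string
(one character per aligned base: ``Z``/``z`` methylated/unmethylated
CpG, ``X``/``x`` CHG, ``H``/``h`` CHH, ``U``/``u`` unknown context,
``.`` non-cytosine).  Per-CpG methylation travels as Bismark-dialect
coverage files (chrom, start, end, %methylation, count_M, count_U;
1-based inclusive coordinates).  Internally everything is 0-based
half-open; conversion happens here and only here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcore import GenomicInterval, TargetRegion, DEFAULT_PAD_BP

__all__ = [
    "ReadMethylation",
    "CpGCount",
    "read_cpg_counts",
    "write_cpg_counts",
    "read_alignments",
    "write_alignments",
    "AlignmentReadStats",
    "read_bed",
    "write_bed",
    "read_targets",
    "read_fasta",
    "write_fasta",
]

CALL_CHARS = set("ZzXxHhUu.")

XM_TAG = "XM"


@dataclass(frozen=True)
class ReadMethylation:
    """One aligned read: its reference interval plus per-base calls."""

    interval: GenomicInterval
    call_string: str
    duplicate_flag: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.call_string) != len(self.interval):
            raise ValueError(
                "call string length must equal aligned length: "
                f"{len(self.call_string)} vs {len(self.interval)}"
            )
        bad = set(self.call_string) - CALL_CHARS
        if bad:
            raise ValueError(f"invalid methylation call characters: {sorted(bad)}")


@dataclass(frozen=True)
class CpGCount:
    """Methylated/unmethylated evidence at one CpG (0-based C position)."""

    position: GenomicInterval
    count_methylated: int
    count_unmethylated: int

    def __post_init__(self) -> None:
        if self.count_methylated < 0 or self.count_unmethylated < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.count_methylated + self.count_unmethylated

    @property
    def beta(self) -> float | None:
        """Methylated fraction; None when no evidence."""
        if self.total == 0:
            return None
        return self.count_methylated / self.total


def read_cpg_counts(path: str | Path) -> list[CpGCount]:
    """Parse a Bismark-dialect coverage file.

    Columns: chrom, start, end (1-based inclusive), %methylation,
    count_methylated, count_unmethylated.  The percentage column is
    ignored and beta recomputed from the counts; rows with zero total
    are retained (beta undefined).
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                count_m, count_u = int(fields[4]), int(fields[5])
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"{path}: malformed coverage row at line {lineno}: {line!r}"
                ) from exc
            if end < start:
                raise ValueError(
                    f"{path}: end < start at line {lineno}: {line!r}"
                )
            out.append(
                CpGCount(
                    GenomicInterval(chrom, start - 1, end),
                    count_m,
                    count_u,
                )
            )
    return out


def write_cpg_counts(counts: Iterable[CpGCount], path: str | Path) -> None:
    """Write counts back to the 1-based coverage dialect (lossless round trip)."""
    with open(path, "w") as fh:
        for c in counts:
            pct = 100.0 * c.beta if c.beta is not None else 0.0
            fh.write(
                f"{c.position.chrom}\t{c.position.start + 1}\t{c.position.end}\t"
                f"{pct:g}\t{c.count_methylated}\t{c.count_unmethylated}\n"
            )


@dataclass
class AlignmentReadStats:
    """Side-channel counters from an alignment pass."""

    yielded: int = 0
    duplicates_excluded: int = 0
    missing_call_string: int = 0
    not_primary: int = 0
    unmapped: int = 0


def read_alignments(
    path: str | Path,
    region: GenomicInterval | None = None,
    include_duplicates: bool = False,
    stats: AlignmentReadStats | None = None,
) -> Iterator[ReadMethylation]:
    """Yield primary alignments carrying XM-style call strings.

    Reads flagged as PCR/optical duplicates are excluded by default
    (matching a dedup-upstream pipeline); reads without a call-string
    tag are skipped and counted in *stats*.  Regional queries use the
    index when present, else fall back to a filtered linear scan (SAM
    without index).
    """
    stats = stats if stats is not None else AlignmentReadStats()
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as af:
        if region is not None:
            try:
                it = af.fetch(region.chrom, region.start, region.end)
            except ValueError:
                it = (
                    a
                    for a in af.fetch(until_eof=True)
                    if a.reference_name == region.chrom
                    and a.reference_start is not None
                    and a.reference_end is not None
                    and a.reference_start < region.end
                    and a.reference_end > region.start
                )
        else:
            it = af.fetch(until_eof=True)
        for aln in it:
            if aln.is_unmapped:
                stats.unmapped += 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                stats.not_primary += 1
                continue
            if aln.is_duplicate and not include_duplicates:
                stats.duplicates_excluded += 1
                continue
            if not aln.has_tag(XM_TAG):
                stats.missing_call_string += 1
                continue
            call = aln.get_tag(XM_TAG)
            interval = GenomicInterval(
                aln.reference_name,
                aln.reference_start,
                aln.reference_end,
                "-" if aln.is_reverse else "+",
            )
            if len(call) != len(interval):
                # Indel-containing alignments are out of scope for the
                # simulator-backed workflow; skip rather than mis-assign.
                stats.missing_call_string += 1
                continue
            stats.yielded += 1
            yield ReadMethylation(
                interval, call, bool(aln.is_duplicate), aln.query_name
            )


def write_alignments(
    reads: Iterable[tuple[ReadMethylation, str]],
    path: str | Path,
    chrom_lengths: Mapping[str, int],
) -> None:
    """Write (read, query sequence) pairs as coordinate-order SAM/BAM."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()],
    }
    mode = "wb" if str(path).endswith(".bam") else "w"
    tid = {c: i for i, c in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(str(path), mode, header=header) as af:
        for rm, seq in sorted(
            reads, key=lambda p: (tid[p[0].interval.chrom], p[0].interval.start)
        ):
            a = pysam.AlignedSegment(af.header)
            a.query_name = rm.name or "frag"
            a.query_sequence = seq
            a.reference_name = rm.interval.chrom
            a.reference_start = rm.interval.start
            a.mapping_quality = 60
            a.cigarstring = f"{len(rm.interval)}M"
            a.flag = (16 if rm.interval.strand == "-" else 0) | (
                1024 if rm.duplicate_flag else 0
            )
            a.set_tag(XM_TAG, rm.call_string)
            af.write(a)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3/BED6 reader (0-based half-open, as BED already is)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"{path}: malformed BED row at line {lineno}: {line!r}"
                ) from exc
            strand = f[5] if len(f) >= 6 and f[5] in "+-" else "."
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def read_bed_named(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """BED reader retaining the name column (col 4; positional fallback)."""
    out = []
    with open(path) as fh:
        idx = 0
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            strand = f[5] if len(f) >= 6 and f[5] in "+-" else "."
            name = f[3] if len(f) >= 4 and f[3] not in (".", "") else f"region_{idx}"
            idx += 1
            out.append((GenomicInterval(chrom, start, end, strand), name))
    return out


def write_bed(
    intervals: Iterable[GenomicInterval | tuple[GenomicInterval, str]],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        for item in intervals:
            if isinstance(item, tuple):
                iv, name = item
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{item.chrom}\t{item.start}\t{item.end}\n")


def read_targets(path: str | Path, pad_bp: int = DEFAULT_PAD_BP) -> list[TargetRegion]:
    """Read a target (DMR) panel from BED, attaching the capture pad."""
    return [
        TargetRegion(iv, name, pad_bp) for iv, name in read_bed_named(path)
    ]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Whole-genome FASTA into an in-memory chrom->sequence dict (uppercased)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    """Write sequences wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)
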