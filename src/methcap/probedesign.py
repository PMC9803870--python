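"""Hybridization probe design for bisulfite-converted target panels.

Two design strategies are implemented:

* **read tiling** — candidate probes are tiled across real (or
  simulated) bisulfite reads aligned over the padded targets, so each
  probe matches an empirically observed methylation/conversion state
  of the locus;
* **methylation-state simulation** — for each target the CpG
  methylation states are enumerated (exhaustively up to a cap, else
  sampled) and probes tiled across the resulting in-silico converted
  variants of both strands.

Candidates then pass through redundancy collapse (remove any probe
sharing a long, high-identity ungapped overlap with an already-kept
probe) and a specificity screen against the fully CpH>TpH converted
genome (both strands): a probe survives only if it hits its own locus
and has at most ``max_offtarget_hits`` additional hit loci.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqcore import (
    ConvertedSequence,
    GenomicInterval,
    TargetRegion,
    convert_cph_to_tph,
    enumerate_cpgs,
    reverse_complement,
)

__all__ = [
    "DesignParams",
    "ProbeCandidate",
    "ProbeSet",
    "tile_probes",
    "collapse_probes",
    "is_redundant",
    "simulate_methylation_states",
    "ConvertedGenomeIndex",
    "specificity_filter",
    "extract_target_reads",
    "design_probes",
]


@dataclass(frozen=True)
class DesignParams:
    """All tunables of the probe-design pipeline.

    Defaults follow the published workflow: 80 nt probes tiled three
    per read; collapse at >=60 nt overlap and >=95% identity (the
    stricter 78 nt / 97% pairing is the alternative preset); the
    specificity screen keeps probes with at most ``max_offtarget_hits``
    off-origin loci, a hit being a local converted-genome match of at
    least ``hit_min_length`` nt at ``hit_min_identity``.
    """

    probe_length: int = 80
    tiling_count: int = 3
    min_read_length: int | None = None  # None -> probe_length
    collapse_min_overlap: int = 60
    collapse_min_identity: float = 0.95
    state_cap: int = 16
    max_offtarget_hits: int = 4
    hit_min_length: int = 60
    hit_min_identity: float = 0.90
    seed_k: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.collapse_min_identity <= 1):
            raise ValueError("collapse_min_identity must be in (0, 1]")
        if self.collapse_min_overlap > self.probe_length:
            raise ValueError("collapse_min_overlap cannot exceed probe_length")
        if self.state_cap < 2:
            raise ValueError("state_cap must allow at least all-M and all-U")

    @property
    def effective_min_read_length(self) -> int:
        return (
            self.min_read_length
            if self.min_read_length is not None
            else self.probe_length
        )


@dataclass(frozen=True)
class ProbeCandidate:
    seq: str
    origin: GenomicInterval | None
    source: str  # {"read_tiling", "state_simulation"}
    id: str


@dataclass
class ProbeSet:
    probes: list[ProbeCandidate]
    params: DesignParams
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def log(self, stage: str, count: int) -> None:
        self.provenance.append((stage, count))

    def to_fasta(self, path) -> None:
        """Probe FASTA; header encodes origin locus, strand and strategy."""
        with open(path, "w") as fh:
            for p in self.probes:
                if p.origin is not None:
                    loc = f"{p.origin.chrom}:{p.origin.start}-{p.origin.end}/{p.origin.strand}"
                else:
                    loc = "unplaced"
                fh.write(f">{p.id}|{loc}|{p.source}\n{p.seq}\n")


def tile_probes(
    read_seq: str,
    params: DesignParams,
    origin: GenomicInterval | None = None,
    source: str = "read_tiling",
    id_prefix: str = "probe",
) -> list[ProbeCandidate]:
    """Tile fixed-length probes evenly across one read.

    A read of length L yields ``tiling_count`` probes at starts
    ``round(i * (L - P) / (n - 1))``, so the first probe starts at the
    read's 5' end and the last ends at its 3' end.  Reads shorter than
    the minimum length yield nothing; reads of exactly probe length
    yield a single probe.
    """
    L, P, n = len(read_seq), params.probe_length, params.tiling_count
    if L < params.effective_min_read_length or L < P:
        return []
    if L == P or n == 1:
        starts = [0]
    else:
        starts = sorted({int(i * (L - P) / (n - 1) + 0.5) for i in range(n)})
    out = []
    for j, s in enumerate(starts):
        probe_origin = None
        if origin is not None:
            probe_origin = GenomicInterval(
                origin.chrom, origin.start + s, origin.start + s + P, origin.strand
            )
        out.append(
            ProbeCandidate(
                read_seq[s : s + P], probe_origin, source, f"{id_prefix}.{j}"
            )
        )
    return out


def _overlap_identity(a: str, b: str, offset: int) -> tuple[int, float]:
    """Ungapped overlap length and identity of equal-length seqs at *offset*.

    *offset* is b's start relative to a's start; positive means b is
    shifted right of a.
    """
    P = len(a)
    ov = P - abs(offset)
    if ov <= 0:
        return 0, 0.0
    if offset >= 0:
        sa, sb = a[offset:], b[:ov]
    else:
        sa, sb = a[:ov], b[-offset:]
    matches = sum(x == y for x, y in zip(sa, sb))
    return ov, matches / ov


def is_redundant(a: ProbeCandidate, b: ProbeCandidate, params: DesignParams) -> bool:
    """Redundancy predicate: ungapped overlap >= threshold at >= identity.

    When both probes carry origin coordinates on the same chromosome
    the overlap offset is implied by those coordinates (probes derive
    from co-aligned reads); otherwise every offset with sufficient
    overlap is scanned and the best taken.
    """
    if len(a.seq) != len(b.seq):
        raise ValueError("mixed probe lengths in collapse")
    P = len(a.seq)
    if (
        a.origin is not None
        and b.origin is not None
        and a.origin.chrom == b.origin.chrom
    ):
        offsets: Iterable[int] = (b.origin.start - a.origin.start,)
    else:
        span = P - params.collapse_min_overlap
        offsets = range(-span, span + 1)
    for d in offsets:
        ov, ident = _overlap_identity(a.seq, b.seq, d)
        if ov >= params.collapse_min_overlap and ident >= params.collapse_min_identity:
            return True
    return False


def _sort_key(p: ProbeCandidate):
    if p.origin is not None:
        return (0, p.origin.chrom, p.origin.start, p.origin.end, p.seq)
    return (1, "", 0, 0, p.seq)


def collapse_probes(
    candidates: Sequence[ProbeCandidate], params: DesignParams
) -> list[ProbeCandidate]:
    """Greedy redundancy collapse in deterministic first-kept-wins order.

    Candidates are sorted by origin coordinate then sequence; each is
    kept iff it is not redundant with any already-kept probe.  The
    result is idempotent and every removed probe is redundant with at
    least one survivor.
    """
    lengths = {len(c.seq) for c in candidates}
    if len(lengths) > 1:
        raise ValueError(f"mixed probe lengths in collapse: {sorted(lengths)}")
    kept: list[ProbeCandidate] = []
    for cand in sorted(candidates, key=_sort_key):
        if not any(is_redundant(cand, k, params) for k in kept):
            kept.append(cand)
    return kept


def _variant_for_state(
    seq: str, cpgs: Sequence[int], meth: Sequence[bool], strand: str
) -> str:
    """Bisulfite image of *seq* under one CpG methylation assignment."""
    n = len(seq)
    meth_at = {p: m for p, m in zip(cpgs, meth)}
    if strand == "top":
        out = list(seq)
        for i, base in enumerate(seq):
            if base != "C":
                continue
            if i in meth_at:
                out[i] = "C" if meth_at[i] else "T"
            else:
                out[i] = "T"
        return "".join(out)
    rc = reverse_complement(seq)
    out = list(rc)
    for j, base in enumerate(rc):
        if base != "C":
            continue
        p = n - 2 - j  # genomic top-strand C of the same CpG
        if j + 1 < n and rc[j + 1] == "G" and p in meth_at:
            out[j] = "C" if meth_at[p] else "T"
        else:
            out[j] = "T"
    return "".join(out)


def simulate_methylation_states(
    target_seq: str,
    params: DesignParams,
    strands: Sequence[str] = ("top", "bottom"),
    rng: np.random.Generator | None = None,
) -> list[ConvertedSequence]:
    """Converted-sequence variants of a target under sampled CpG states.

    With k CpGs there are 2^k methylation states.  All are enumerated
    when ``2^k <= state_cap``; otherwise the all-methylated and
    all-unmethylated states are always included and ``state_cap - 2``
    further states are sampled without replacement (seeded).  Each
    requested strand contributes one variant per state; duplicates
    (states indistinguishable after conversion) are removed.
    """
    cpgs = enumerate_cpgs(target_seq)
    k = len(cpgs)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if k == 0 or (k <= 30 and 2**k <= params.state_cap):
        masks = list(range(2**k)) if k else [0]
    else:
        all_u, all_m = 0, (1 << k) - 1
        chosen = {all_u, all_m}
        while len(chosen) < params.state_cap:
            m = 0
            for bit in rng.random(k) < 0.5:  # bit-wise draw: k may exceed 62
                m = (m << 1) | int(bit)
            chosen.add(m)
        masks = sorted(chosen)
    variants: list[ConvertedSequence] = []
    seen: set[tuple[str, str]] = set()
    for strand in strands:
        for mask in masks:
            meth = [bool(mask >> i & 1) for i in range(k)]
            v = _variant_for_state(target_seq, cpgs, meth, strand)
            if (strand, v) not in seen:
                seen.add((strand, v))
                variants.append(ConvertedSequence(v, strand))
    return variants


class ConvertedGenomeIndex:
    """K-mer seeded search index over both fully converted genome strands.

    The bottom-strand converted sequence is stored in its native
    (reverse-complement) orientation; hit coordinates are mapped back
    to top-strand genomic positions before reporting.
    """

    def __init__(self, genome: Mapping[str, str], k: int = 12):
        if not genome:
            raise ValueError("empty genome index")
        self.k = k
        self.chrom_lengths = {c: len(s) for c, s in genome.items()}
        self.strands: dict[tuple[str, str], str] = {}
        for chrom, seq in genome.items():
            self.strands[(chrom, "top")] = convert_cph_to_tph(seq, "top").seq
            self.strands[(chrom, "bottom")] = convert_cph_to_tph(seq, "bottom").seq
        self._index: dict[str, list[tuple[str, str, int]]] = {}
        for (chrom, strand), seq in self.strands.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((chrom, strand, i))

    def find_hits(
        self, probe_seq: str, min_length: int, min_identity: float
    ) -> list[GenomicInterval]:
        """Distinct genomic hit loci of a probe (local ungapped matches).

        Each candidate diagonal found by seeding is extended ungapped
        over the full probe span; it qualifies if any sub-window of
        length >= *min_length* reaches *min_identity*.  Qualifying
        diagonals within a probe length of each other on the same
        chromosome are merged into one locus.
        """
        P = len(probe_seq)
        k = self.k
        diagonals: set[tuple[str, str, int]] = set()
        for i in range(P - k + 1):
            for chrom, strand, pos in self._index.get(probe_seq[i : i + k], ()):
                diagonals.add((chrom, strand, pos - i))
        raw_hits: list[tuple[str, int, int]] = []
        for chrom, strand, dstart in diagonals:
            seq = self.strands[(chrom, strand)]
            lo = max(0, dstart)
            hi = min(len(seq), dstart + P)
            if hi - lo < min_length:
                continue
            match = np.frombuffer(
                probe_seq[lo - dstart : hi - dstart].encode(), dtype=np.uint8
            ) == np.frombuffer(seq[lo:hi].encode(), dtype=np.uint8)
            if not self._has_window(match, min_length, min_identity):
                continue
            clen = self.chrom_lengths[chrom]
            if strand == "top":
                raw_hits.append((chrom, lo, hi))
            else:
                raw_hits.append((chrom, clen - hi, clen - lo))
        return self._cluster(raw_hits, P)

    @staticmethod
    def _has_window(match: np.ndarray, min_length: int, min_identity: float) -> bool:
        n = len(match)
        cum = np.concatenate([[0], np.cumsum(match)])
        for L in range(min_length, n + 1):
            win = cum[L:] - cum[:-L]
            if win.size and win.max() >= min_identity * L:
                return True
        return False

    @staticmethod
    def _cluster(hits: list[tuple[str, int, int]], span: int) -> list[GenomicInterval]:
        loci: list[GenomicInterval] = []
        for chrom, start, end in sorted(set(hits)):
            if (
                loci
                and loci[-1].chrom == chrom
                and start - loci[-1].end <= span
            ):
                loci[-1] = GenomicInterval(
                    chrom, loci[-1].start, max(loci[-1].end, end)
                )
            else:
                loci.append(GenomicInterval(chrom, start, end))
        return loci


def specificity_filter(
    candidates: Sequence[ProbeCandidate],
    index: ConvertedGenomeIndex,
    params: DesignParams,
    hit_log: dict[str, int] | None = None,
) -> list[ProbeCandidate]:
    """Keep probes that hit their own locus and few others.

    A probe is retained iff one hit locus overlaps (or lies within a
    probe length of) its origin interval and the number of remaining
    loci is at most ``max_offtarget_hits``.  Probes with no origin
    coordinates must simply have ``<= max_offtarget_hits + 1`` loci and
    at least one.
    """
    kept = []
    for p in candidates:
        hits = index.find_hits(p.seq, params.hit_min_length, params.hit_min_identity)
        if hit_log is not None:
            hit_log[p.id] = len(hits)
        if not hits:
            continue
        if p.origin is None:
            if len(hits) - 1 <= params.max_offtarget_hits:
                kept.append(p)
            continue
        pad = len(p.seq)
        origin_hit = any(
            h.chrom == p.origin.chrom
            and h.start < p.origin.end + pad
            and h.end > p.origin.start - pad
            for h in hits
        )
        if origin_hit and len(hits) - 1 <= params.max_offtarget_hits:
            kept.append(p)
    return kept


def extract_target_reads(
    alignments, targets: Sequence[TargetRegion]
) -> list[tuple[str, GenomicInterval]]:
    """Primary, non-duplicate reads overlapping any padded target.

    *alignments* is a pysam.AlignmentFile path or open handle.  Read
    sequences are reported in reference orientation (as stored in
    SAM).  A read overlapping several padded targets is returned once.
    """
    import pysam

    own = isinstance(alignments, (str,)) or hasattr(alignments, "__fspath__")
    af = (
        pysam.AlignmentFile(
            str(alignments), "rb" if str(alignments).endswith(".bam") else "r"
        )
        if own
        else alignments
    )
    seen: set[tuple[str, int, int]] = set()
    out: list[tuple[str, GenomicInterval]] = []
    try:
        footprints = [t.padded() for t in targets]
        try:
            iterators = [af.fetch(f.chrom, f.start, f.end) for f in footprints]
            aln_iter = itertools.chain.from_iterable(iterators)
            regional = True
        except ValueError:
            aln_iter = af.fetch(until_eof=True)
            regional = False
        for aln in aln_iter:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_duplicate:
                continue
            iv = GenomicInterval(
                aln.reference_name,
                aln.reference_start,
                aln.reference_end,
                "-" if aln.is_reverse else "+",
            )
            if not regional and not any(iv.overlaps(f) for f in footprints):
                continue
            key = (aln.query_name, aln.reference_start, aln.flag)
            if key in seen:
                continue
            seen.add(key)
            out.append((aln.query_sequence, iv))
    finally:
        if own:
            af.close()
    return out


def design_probes(
    targets: Sequence[TargetRegion],
    params: DesignParams,
    genome: Mapping[str, str],
    strategy: str = "read_tiling",
    alignments=None,
    run_specificity: bool = True,
) -> ProbeSet:
    """Full design pipeline: candidates -> collapse -> specificity screen."""
    probeset = ProbeSet([], params)
    candidates: list[ProbeCandidate] = []
    if strategy in ("read_tiling", "read-tiling"):
        if alignments is None:
            raise ValueError("read_tiling strategy requires alignments")
        reads = extract_target_reads(alignments, targets)
        probeset.log("reads_extracted", len(reads))
        for i, (seq, iv) in enumerate(reads):
            candidates.extend(
                tile_probes(seq, params, origin=iv, id_prefix=f"rt{i}")
            )
    elif strategy in ("state_simulation", "state-sim", "state_sim"):
        rng = np.random.default_rng(params.seed)
        step = max(1, int(params.probe_length / params.tiling_count + 0.5))
        for t in targets:
            fp = t.padded(len(genome[t.interval.chrom]))
            tseq = genome[fp.chrom][fp.start : fp.end]
            for vi, variant in enumerate(
                simulate_methylation_states(tseq, params, rng=rng)
            ):
                n = len(variant.seq)
                P = params.probe_length
                if n < P:
                    continue
                starts = list(range(0, n - P + 1, step))
                if starts[-1] != n - P:
                    starts.append(n - P)
                for s in starts:
                    if variant.source_strand == "top":
                        o = GenomicInterval(fp.chrom, fp.start + s, fp.start + s + P, "+")
                    else:
                        o = GenomicInterval(
                            fp.chrom, fp.start + n - s - P, fp.start + n - s, "-"
                        )
                    candidates.append(
                        ProbeCandidate(
                            variant.seq[s : s + P],
                            o,
                            "state_simulation",
                            f"ss.{t.name}.{vi}.{s}",
                        )
                    )
    else:
        raise ValueError(f"unknown design strategy {strategy!r}")
    probeset.log("candidates", len(candidates))
    collapsed = collapse_probes(candidates, params)
    probeset.log("after_collapse", len(collapsed))
    if run_specificity:
        index = ConvertedGenomeIndex(genome, k=params.seed_k)
        final = specificity_filter(collapsed, index, params)
        probeset.log("after_specificity", len(final))
    else:
        final = collapsed
    probeset.probes = final
    return probeset
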