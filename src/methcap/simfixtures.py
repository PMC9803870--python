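"""Synthetic cfDNA bisulfite data: toy genomes, target panels,
fragment simulation and methylation standards.

The simulator emulates the inputs of a targeted-methylation capture
experiment well enough to exercise every downstream statistic with a
known truth:

* a toy genome with CpG-rich island segments, an interspersed repeat
  family (identical copies, for specificity-screen tests) and a few
  functional feature annotations;
* cfDNA-like fragments (lengths ~Normal(160, sd), truncated) drawn
  mostly from the padded target footprints, each CpG methylated with
  its region's true beta, bisulfite-converted at a configurable
  efficiency, and emitted as aligned reads carrying XM-style call
  strings;
* methylation standards built the way physical controls are: a
  mixture of fully methylated and fully unmethylated *molecules* at a
  chosen fraction, so the pooled beta equals the fraction while the
  per-read alpha distribution stays bimodal at 0 and 1.

Everything is deterministic under the configured seed.  Fragments are
simulated from the top (original-top bisulfite) strand only; per-CpG
counts are keyed by the C coordinate, so region betas are unaffected.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methylio import ReadMethylation
from .seqcore import GenomicInterval, TargetRegion, DEFAULT_PAD_BP

__all__ = [
    "SimulationConfig",
    "ToyGenome",
    "make_toy_genome",
    "make_target_panel",
    "SimulatedReadSet",
    "simulate_fragments",
    "mix_standards",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Knobs of the fragment simulator.

    Defaults mirror the assay being emulated: ~160 bp sonicated
    cfDNA-like fragments and 99% bisulfite conversion efficiency.
    ``on_target_fraction`` (default 0.65) matches the mid-range
    on/near-target rate of a decent capture.  ``background_beta``
    (0.75) is a typical genome-wide methylation level for off-target
    molecules.  ``seq_error_rate`` perturbs non-cytosine bases only,
    so methylation truth stays exact unless errors are explicitly
    pointed at call positions upstream.
    """

    seed: int = 0
    n_fragments: int = 10_000
    fragment_mean: float = 160.0
    fragment_sd: float = 20.0
    conversion_efficiency: float = 0.99
    seq_error_rate: float = 0.0
    region_betas: dict[str, float] = field(default_factory=dict)
    background_beta: float = 0.75
    on_target_fraction: float = 0.65
    min_fragment: int = 50

    def __post_init__(self) -> None:
        for name, val in (
            ("conversion_efficiency", self.conversion_efficiency),
            ("seq_error_rate", self.seq_error_rate),
            ("on_target_fraction", self.on_target_fraction),
            ("background_beta", self.background_beta),
        ):
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if self.fragment_mean <= 0:
            raise ValueError("fragment_mean must be positive")
        for b in self.region_betas.values():
            if not (0.0 <= b <= 1.0):
                raise ValueError("region betas must be in [0, 1]")


@dataclass
class ToyGenome:
    """A small genome plus the annotation tracks built into it."""

    seqs: dict[str, str]
    islands: list[GenomicInterval]
    repeats: list[tuple[GenomicInterval, str]]
    functional: dict[str, list[GenomicInterval]]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}


def _random_seq(rng: np.random.Generator, n: int, cpg_suppressed: bool = True) -> str:
    """Background DNA; CpG dinucleotides thinned to mimic genomic depletion."""
    arr = _BASES[rng.integers(0, 4, size=n)]
    if cpg_suppressed:
        s = arr
        cg = np.flatnonzero((s[:-1] == ord("C")) & (s[1:] == ord("G")))
        # break ~80% of background CpGs
        drop = cg[rng.random(cg.size) < 0.8]
        s[drop] = ord("T")
    return arr.tobytes().decode()


def _island_seq(rng: np.random.Generator, n: int) -> str:
    """CpG-enriched segment (~1 CpG per 8 bp, GC-rich)."""
    parts: list[str] = []
    length = 0
    while length < n:
        if rng.random() < 0.25:
            parts.append("CG")
            length += 2
        else:
            b = "ACGT"[rng.integers(0, 4)]
            parts.append(b)
            length += 1
    return "".join(parts)[:n]


def make_toy_genome(
    seed: int,
    length: int = 50_000,
    n_islands: int = 5,
    n_repeat_copies: int = 0,
    chrom: str = "chr1",
    island_length: int = 500,
    repeat_length: int = 200,
    repeat_family: str = "ToyRep",
) -> ToyGenome:
    """Build a deterministic toy genome with islands, repeats and features.

    The repeat family is one unit copied verbatim ``n_repeat_copies``
    times at evenly spaced, non-overlapping positions — multi-mapping
    bait for the probe specificity screen.
    """
    if length < 10_000:
        raise ValueError("toy genome length must be >= 10 kb")
    rng = np.random.default_rng(seed)
    seq = list(_random_seq(rng, length))

    islands: list[GenomicInterval] = []
    slots = np.linspace(0.05, 0.9, max(n_islands, 1))
    for i in range(n_islands):
        start = int(slots[i] * length)
        isl = _island_seq(rng, island_length)
        seq[start : start + island_length] = isl
        islands.append(GenomicInterval(chrom, start, start + island_length))

    repeats: list[tuple[GenomicInterval, str]] = []
    if n_repeat_copies > 0:
        unit = _random_seq(rng, repeat_length, cpg_suppressed=False)
        gap = length // (n_repeat_copies + 1)
        for i in range(n_repeat_copies):
            start = (i + 1) * gap + 37  # offset away from island slots
            if any(start < iv.end and start + repeat_length > iv.start for iv in islands):
                start += island_length
            seq[start : start + repeat_length] = unit
            repeats.append(
                (GenomicInterval(chrom, start, start + repeat_length), repeat_family)
            )

    functional: dict[str, list[GenomicInterval]] = {
        "promoter": [],
        "enhancer": [],
        "exon": [],
        "intron": [],
    }
    labels = list(functional)
    n_feat = max(4, length // 5000)
    starts = rng.integers(0, length - 600, size=n_feat)
    for i, s in enumerate(sorted(starts.tolist())):
        functional[labels[i % len(labels)]].append(
            GenomicInterval(chrom, s, s + int(rng.integers(200, 600)))
        )

    return ToyGenome({chrom: "".join(seq)}, islands, repeats, functional)


def make_target_panel(
    genome: ToyGenome,
    n_targets: int,
    seed: int,
    target_length: int = 200,
    pad_bp: int = DEFAULT_PAD_BP,
    min_gap: int = 800,
) -> list[TargetRegion]:
    """Evenly spaced non-overlapping targets, biased to include islands.

    The first targets are placed on island segments (DMR panels are
    CpG-dense by construction); the remainder spread over background.
    """
    rng = np.random.default_rng(seed)
    chrom = next(iter(genome.seqs))
    length = genome.chrom_lengths[chrom]
    targets: list[TargetRegion] = []
    taken: list[tuple[int, int]] = []

    def free(s: int, e: int) -> bool:
        return all(e + min_gap <= a or b + min_gap <= s for a, b in taken)

    for iv in genome.islands:
        if len(targets) >= n_targets:
            break
        s = iv.start + max(0, (len(iv) - target_length) // 2)
        e = s + target_length
        if e < length and free(s, e):
            taken.append((s, e))
            targets.append(
                TargetRegion(GenomicInterval(chrom, s, e), f"t{len(targets):04d}", pad_bp)
            )
    guard = 0
    while len(targets) < n_targets and guard < 50_000:
        guard += 1
        s = int(rng.integers(pad_bp + 1, length - target_length - pad_bp - 1))
        e = s + target_length
        if free(s, e):
            taken.append((s, e))
            targets.append(
                TargetRegion(GenomicInterval(chrom, s, e), f"t{len(targets):04d}", pad_bp)
            )
    if len(targets) < n_targets:
        raise ValueError("could not place requested number of targets")
    return sorted(targets, key=lambda t: (t.interval.chrom, t.interval.start))


# ---------------------------------------------------------------------------
# fragment simulation

# top-strand cytosine context codes
_CTX_NONE, _CTX_CPG, _CTX_CHG, _CTX_CHH, _CTX_UNK = 0, 1, 2, 3, 4
_PROT = np.frombuffer(b".ZXHU", dtype=np.uint8)
_CONV = np.frombuffer(b".zxhu", dtype=np.uint8)


def _context_codes(seq: str) -> np.ndarray:
    """Per-base cytosine context on the top strand (vectorised)."""
    b = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = b.size
    ctx = np.zeros(n, dtype=np.uint8)
    is_c = b == ord("C")
    nxt = np.full(n, ord("N"), dtype=np.uint8)
    nxt[:-1] = b[1:]
    nxt2 = np.full(n, ord("N"), dtype=np.uint8)
    nxt2[:-2] = b[2:]
    h = (nxt == ord("A")) | (nxt == ord("C")) | (nxt == ord("T"))
    ctx[is_c & (nxt == ord("G"))] = _CTX_CPG
    ctx[is_c & h & (nxt2 == ord("G"))] = _CTX_CHG
    ctx[is_c & h & (nxt2 != ord("G")) & (nxt2 != ord("N"))] = _CTX_CHH
    ctx[is_c & ((nxt == ord("N")) | (h & (nxt2 == ord("N"))))] = _CTX_UNK
    return ctx


@dataclass
class SimulatedReadSet:
    """Aligned simulated reads plus the ground truth behind them."""

    reads: list[ReadMethylation]
    sequences: list[str]
    truth: pd.DataFrame
    config: SimulationConfig

    def write_sam(self, path, chrom_lengths: Mapping[str, int]) -> None:
        from .methylio import write_alignments

        write_alignments(zip(self.reads, self.sequences), path, chrom_lengths)


def simulate_fragments(
    genome: Mapping[str, str] | ToyGenome,
    targets: Sequence[TargetRegion],
    config: SimulationConfig,
    standard_frac: float | None = None,
) -> SimulatedReadSet:
    """Draw cfDNA-like fragments and emit aligned bisulfite reads.

    Each on-target fragment (probability ``on_target_fraction``)
    overlaps the padded footprint of a uniformly chosen target;
    off-target fragments land uniformly on the genome.  Methylation is
    a property of the locus: any fragment covering a padded footprint
    draws CpG states at that region's true beta, everything else at
    ``background_beta``.  Every CpG is an
    independent Bernoulli(beta) draw; an unmethylated cytosine escapes
    conversion (reads as methylated) with probability
    ``1 - conversion_efficiency``.  With ``standard_frac`` set, the
    per-fragment beta is instead 1.0 with that probability and 0.0
    otherwise (a molecule mixture, as physical standards are made).
    """
    seqs = genome.seqs if isinstance(genome, ToyGenome) else dict(genome)
    if config.on_target_fraction > 0 and not targets:
        raise ValueError("on_target_fraction > 0 requires at least one target")
    for t in targets:
        if standard_frac is None and t.name not in config.region_betas:
            raise ValueError(f"no true beta configured for region {t.name!r}")

    rng = np.random.default_rng(config.seed)
    chroms = list(seqs)
    base_arrays = {c: np.frombuffer(s.encode(), dtype=np.uint8).copy() for c, s in seqs.items()}
    ctx_arrays = {c: _context_codes(s) for c, s in seqs.items()}
    clens = {c: len(s) for c, s in seqs.items()}
    total_len = sum(clens.values())
    chrom_w = np.array([clens[c] for c in chroms], dtype=float) / total_len
    footprints = [t.padded(clens[t.interval.chrom]) for t in targets]

    n = config.n_fragments
    lengths = rng.normal(config.fragment_mean, config.fragment_sd, size=n)
    lengths = np.clip(
        np.rint(lengths), config.min_fragment, 2 * config.fragment_mean
    ).astype(np.int64)
    is_on = rng.random(n) < config.on_target_fraction
    tgt_idx = rng.integers(0, max(len(targets), 1), size=n)
    u_pos = rng.random(n)
    chrom_pick = rng.choice(len(chroms), size=n, p=chrom_w)
    if standard_frac is not None:
        frag_beta = (rng.random(n) < standard_frac).astype(float)
    else:
        frag_beta = np.full(n, config.background_beta)

    # methylation level is a property of the locus: any fragment covering a
    # padded footprint inherits that region's beta, wherever it was drawn from
    fp_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for t, fp in zip(targets, footprints):
        fp_by_chrom.setdefault(fp.chrom, []).append((fp.start, fp.end, t.name))
    for c in fp_by_chrom:
        fp_by_chrom[c].sort()

    def locus_region(chrom: str, start: int, end: int) -> str | None:
        fps = fp_by_chrom.get(chrom)
        if not fps:
            return None
        j = bisect.bisect_right(fps, (start, np.inf, "")) - 1
        for cand in (j, j + 1):
            if 0 <= cand < len(fps):
                s, e, name = fps[cand]
                if start < e and end > s:
                    return name
        return None

    conv = config.conversion_efficiency
    reads: list[ReadMethylation] = []
    out_seqs: list[str] = []
    rows = []
    for i in range(n):
        L = int(lengths[i])
        if is_on[i] and targets:
            fp = footprints[tgt_idx[i]]
            chrom = fp.chrom
            lo = max(0, fp.start - L + 1)
            hi = min(clens[chrom] - L, fp.end - 1)
            if hi < lo:
                lo = hi = max(0, min(fp.start, clens[chrom] - L))
            start = lo + int(u_pos[i] * (hi - lo + 1))
            region = targets[tgt_idx[i]].name
        else:
            chrom = chroms[chrom_pick[i]]
            start = int(u_pos[i] * (clens[chrom] - L))
            region = ""
        end = start + L
        if standard_frac is None:
            hit = locus_region(chrom, start, end)
            if hit is not None:
                region = hit
                frag_beta[i] = config.region_betas[hit]
            else:
                region = ""
        ctx = ctx_arrays[chrom][start:end].copy()
        if end >= clens[chrom]:
            ctx[-1] = _CTX_UNK if ctx[-1] else ctx[-1]
        bases = base_arrays[chrom][start:end].copy()
        cidx = np.flatnonzero(ctx > 0)
        call = np.full(L, ord("."), dtype=np.uint8)
        n_meth = n_cpg = 0
        if cidx.size:
            cc = ctx[cidx]
            is_cpg = cc == _CTX_CPG
            meth = np.zeros(cidx.size, dtype=bool)
            if is_cpg.any():
                meth[is_cpg] = rng.random(int(is_cpg.sum())) < frag_beta[i]
            escaped = np.zeros(cidx.size, dtype=bool)
            unmeth = ~meth
            if conv < 1.0 and unmeth.any():
                escaped[unmeth] = rng.random(int(unmeth.sum())) > conv
            protected = meth | escaped
            call[cidx] = np.where(protected, _PROT[cc], _CONV[cc])
            bases[cidx[~protected]] = ord("T")
            n_cpg = int(is_cpg.sum())
            n_meth = int((meth & is_cpg).sum())
        if config.seq_error_rate > 0:
            noncall = np.flatnonzero(ctx == 0)
            err = noncall[rng.random(noncall.size) < config.seq_error_rate]
            if err.size:
                bases[err] = _BASES[
                    (
                        np.searchsorted(_BASES, bases[err]) + rng.integers(1, 4, err.size)
                    )
                    % 4
                ]
        name = f"frag{i:07d}"
        reads.append(
            ReadMethylation(
                GenomicInterval(chrom, start, end, "+"),
                call.tobytes().decode(),
                False,
                name,
            )
        )
        out_seqs.append(bases.tobytes().decode())
        rows.append((name, chrom, start, end, region, n_cpg, n_meth, frag_beta[i]))

    truth = pd.DataFrame(
        rows,
        columns=[
            "fragment", "chrom", "start", "end", "region",
            "n_cpg", "n_methylated", "true_beta",
        ],
    )
    return SimulatedReadSet(reads, out_seqs, truth, config)


def mix_standards(
    frac_methylated: float,
    genome: Mapping[str, str] | ToyGenome,
    targets: Sequence[TargetRegion],
    config: SimulationConfig,
) -> SimulatedReadSet:
    """Simulate a methylation standard: molecules fully methylated with
    probability *frac_methylated*, else fully unmethylated.

    At perfect conversion the expected pooled beta equals the mixing
    fraction, while per-read alphas concentrate at 0 and 1.
    """
    if not (0.0 <= frac_methylated <= 1.0):
        raise ValueError("frac_methylated must be in [0, 1]")
    return simulate_fragments(genome, targets, config, standard_frac=frac_methylated)
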