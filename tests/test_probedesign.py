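"""Probe tiling, redundancy collapse, state enumeration and specificity."""

import numpy as np
import pytest

from methcap.methylio import write_alignments
from methcap.probedesign import (
    ConvertedGenomeIndex,
    DesignParams,
    ProbeCandidate,
    collapse_probes,
    design_probes,
    extract_target_reads,
    is_redundant,
    simulate_methylation_states,
    specificity_filter,
    tile_probes,
)
from methcap.methylio import ReadMethylation
from methcap.seqcore import GenomicInterval, TargetRegion, convert_cph_to_tph


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------------------
# tiling

def test_tiling_151nt_read_gives_three_80mers_spanning_the_read():
    read = _rand_seq(np.random.default_rng(0), 151)
    probes = tile_probes(read, DesignParams(), origin=GenomicInterval("chr1", 1000, 1151))
    assert len(probes) == 3
    assert all(len(p.seq) == 80 for p in probes)
    starts = [p.origin.start - 1000 for p in probes]
    assert starts == [0, 36, 71]
    assert probes[0].seq == read[:80]
    assert probes[-1].seq == read[71:151]


@pytest.mark.parametrize("length,expected", [(80, 1), (79, 0), (0, 0)])
def test_tiling_short_reads(length, expected):
    probes = tile_probes("A" * length, DesignParams())
    assert len(probes) == expected


def test_tiled_probes_never_extend_past_read_boundaries():
    rng = np.random.default_rng(1)
    params = DesignParams()
    for L in rng.integers(80, 400, size=30):
        read = _rand_seq(rng, int(L))
        for p in tile_probes(read, params, origin=GenomicInterval("c", 0, int(L))):
            assert 0 <= p.origin.start and p.origin.end <= L
            assert p.seq == read[p.origin.start : p.origin.end]


# ---------------------------------------------------------------------------
# collapse

def _probe(seq, start=None, chrom="chr1", pid="p"):
    origin = None if start is None else GenomicInterval(chrom, start, start + len(seq))
    return ProbeCandidate(seq, origin, "read_tiling", pid)


def test_collapse_identical_pair_leaves_one():
    rng = np.random.default_rng(2)
    s = _rand_seq(rng, 80)
    out = collapse_probes([_probe(s, 0, pid="a"), _probe(s, 0, pid="b")], DesignParams())
    assert len(out) == 1


def test_collapse_70nt_overlap_full_identity_is_redundant():
    rng = np.random.default_rng(3)
    src = _rand_seq(rng, 90)
    a, b = _probe(src[:80], 0, pid="a"), _probe(src[10:90], 10, pid="b")
    assert is_redundant(a, b, DesignParams())
    assert len(collapse_probes([a, b], DesignParams())) == 1


def test_collapse_50nt_overlap_below_threshold_keeps_both():
    rng = np.random.default_rng(4)
    src = _rand_seq(rng, 110)
    a, b = _probe(src[:80], 0, pid="a"), _probe(src[30:110], 30, pid="b")
    out = collapse_probes([a, b], DesignParams())
    assert len(out) == 2


def test_collapse_rejects_mixed_lengths():
    with pytest.raises(ValueError):
        collapse_probes([_probe("A" * 80, 0), _probe("A" * 60, 0)], DesignParams())


def _oracle_redundant(a, b, min_overlap, min_identity):
    """All-offset ungapped overlap scan, written independently."""
    P = len(a)
    for d in range(-(P - min_overlap), P - min_overlap + 1):
        if d >= 0:
            x, y = a[d:], b[: P - d]
        else:
            x, y = a[: P + d], b[-d:]
        ov = len(x)
        if ov < min_overlap:
            continue
        ident = sum(1 for u, v in zip(x, y) if u == v) / ov
        if ident >= min_identity:
            return True
    return False


def _random_candidate_pool(rng, n, with_origins=False):
    """Probes in redundant families: shifted/mutated copies of source reads."""
    pool = []
    i = 0
    while len(pool) < n:
        src = _rand_seq(rng, 120)
        base = int(rng.integers(0, 10_000))
        for _ in range(int(rng.integers(1, 5))):
            off = int(rng.integers(0, 41))
            seq = list(src[off : off + 80])
            for pos in rng.integers(0, 80, size=int(rng.integers(0, 5))):
                seq[pos] = "ACGT"[int(rng.integers(0, 4))]
            origin = base + off if with_origins else None
            pool.append(_probe("".join(seq), origin, pid=f"c{i}"))
            i += 1
            if len(pool) == n:
                break
    return pool


@pytest.mark.parametrize("with_origins", [False, True])
def test_collapse_agrees_with_brute_force_property(with_origins):
    """Greedy sweep output satisfies the survivor/removed property
    verified with an independently written all-pairs oracle."""
    rng = np.random.default_rng(5)
    params = DesignParams()
    pool = _random_candidate_pool(rng, 200, with_origins)
    kept = collapse_probes(pool, params)
    kept_ids = {p.id for p in kept}
    removed = [p for p in pool if p.id not in kept_ids]

    def oracle(a, b):
        if with_origins:
            d = b.origin.start - a.origin.start
            ov = 80 - abs(d)
            if ov < params.collapse_min_overlap:
                return False
            x, y = (a.seq[d:], b.seq[:ov]) if d >= 0 else (a.seq[:ov], b.seq[-d:])
            return sum(u == v for u, v in zip(x, y)) / ov >= params.collapse_min_identity
        return _oracle_redundant(
            a.seq, b.seq, params.collapse_min_overlap, params.collapse_min_identity
        )

    for i, a in enumerate(kept):
        for b in kept[i + 1 :]:
            assert not oracle(a, b), f"survivors {a.id},{b.id} are redundant"
    for r in removed:
        assert any(oracle(r, k) for k in kept), f"{r.id} removed without a survivor"


def test_collapse_is_idempotent_and_deterministic():
    rng = np.random.default_rng(6)
    pool = _random_candidate_pool(rng, 120, with_origins=True)
    params = DesignParams()
    once = collapse_probes(pool, params)
    assert collapse_probes(once, params) == once
    assert collapse_probes(list(reversed(pool)), params) == once


def test_stricter_collapse_preset_keeps_more():
    """The 78 nt / 97% pairing removes only near-duplicates."""
    rng = np.random.default_rng(7)
    pool = _random_candidate_pool(rng, 100, with_origins=True)
    loose = collapse_probes(pool, DesignParams(collapse_min_overlap=60, collapse_min_identity=0.95))
    strict = collapse_probes(pool, DesignParams(collapse_min_overlap=78, collapse_min_identity=0.97))
    assert len(strict) >= len(loose)


# ---------------------------------------------------------------------------
# methylation-state simulation

def test_state_simulation_exhaustive_for_two_cpgs():
    seq = "AACGTTACGTT"  # 2 CpGs
    variants = simulate_methylation_states(seq, DesignParams(state_cap=8), strands=("top",))
    assert len(variants) == 4
    assert len({v.seq for v in variants}) == 4
    seqs = {v.seq for v in variants}
    assert "AACGTTACGTT" in seqs  # all-methylated: both CpG C's retained
    assert "AATGTTATGTT" in seqs  # all-unmethylated: fully converted


def test_state_simulation_no_cpg_yields_single_converted_variant():
    variants = simulate_methylation_states("ACCTTT", DesignParams(), strands=("top",))
    assert [v.seq for v in variants] == [convert_cph_to_tph("ACCTTT").seq]


def test_state_simulation_cap_and_extremes():
    seq = "CG" * 10 + "A"  # 10 CpGs -> 1024 states
    params = DesignParams(state_cap=16, seed=9)
    variants = simulate_methylation_states(seq, params, strands=("top",))
    assert len(variants) == 16
    seqs = {v.seq for v in variants}
    assert "CG" * 10 + "A" in seqs           # all-methylated
    assert "TG" * 10 + "A" in seqs           # all-unmethylated
    # deterministic under the configured seed
    again = simulate_methylation_states(seq, params, strands=("top",))
    assert [v.seq for v in again] == [v.seq for v in variants]


def test_state_simulation_bottom_strand_tracks_same_cpgs():
    seq = "ACGT"
    top = {v.seq for v in simulate_methylation_states(seq, DesignParams(), strands=("top",))}
    bottom = {v.seq for v in simulate_methylation_states(seq, DesignParams(), strands=("bottom",))}
    assert top == {"ACGT", "ATGT"}
    # revcomp(ACGT) = ACGT; same single CpG, methylated or not
    assert bottom == {"ACGT", "ATGT"}


# ---------------------------------------------------------------------------
# specificity

def test_specificity_filter_keeps_unique_drops_repeats_and_aliens(toy_genome):
    genome = toy_genome.seqs
    chrom = next(iter(genome))
    params = DesignParams(max_offtarget_hits=4)
    index = ConvertedGenomeIndex(genome, k=params.seed_k)

    # unique locus: an island segment (CpG-rich, unlikely to repeat)
    isl = toy_genome.islands[0]
    uniq_seq = convert_cph_to_tph(genome[chrom][isl.start : isl.start + 80]).seq
    unique = ProbeCandidate(uniq_seq, GenomicInterval(chrom, isl.start, isl.start + 80), "read_tiling", "uniq")

    # repeat locus: copied 8 times -> more than max_offtarget_hits
    rep_iv, _ = toy_genome.repeats[0]
    rep_seq = convert_cph_to_tph(genome[chrom][rep_iv.start : rep_iv.start + 80]).seq
    repeat = ProbeCandidate(rep_seq, GenomicInterval(chrom, rep_iv.start, rep_iv.start + 80), "read_tiling", "rep")

    # scrambled: hits nowhere
    rng = np.random.default_rng(10)
    alien = ProbeCandidate(_rand_seq(rng, 80), GenomicInterval(chrom, 0, 80), "read_tiling", "alien")

    kept = specificity_filter([unique, repeat, alien], index, params)
    assert [p.id for p in kept] == ["uniq"]

    # brute-force hit count for the repeat probe: count occurrences of the
    # repeat unit prefix in the converted top strand
    conv_top = convert_cph_to_tph(genome[chrom]).seq
    occurrences = conv_top.count(rep_seq)
    assert occurrences >= 8
    hits = index.find_hits(rep_seq, params.hit_min_length, params.hit_min_identity)
    assert len(hits) >= occurrences


def test_specificity_filter_relaxed_cap_admits_moderate_repeats(toy_genome):
    rep_iv, _ = toy_genome.repeats[0]
    chrom = rep_iv.chrom
    genome = toy_genome.seqs
    rep_seq = convert_cph_to_tph(genome[chrom][rep_iv.start : rep_iv.start + 80]).seq
    probe = ProbeCandidate(rep_seq, GenomicInterval(chrom, rep_iv.start, rep_iv.start + 80), "read_tiling", "rep")
    index = ConvertedGenomeIndex(genome, k=12)
    relaxed = DesignParams(max_offtarget_hits=50)
    assert specificity_filter([probe], index, relaxed) == [probe]


def test_empty_genome_index_is_an_error():
    with pytest.raises(ValueError):
        ConvertedGenomeIndex({})


# ---------------------------------------------------------------------------
# read extraction + pipeline

def _write_toy_sam(path, chrom_lengths, records):
    reads = []
    for name, chrom, start, length, flag_dup, secondary in records:
        iv = GenomicInterval(chrom, start, start + length, "+")
        rm = ReadMethylation(iv, "." * length, flag_dup, name)
        reads.append((rm, "A" * length))
    write_alignments(reads, path, chrom_lengths)
    return path


def test_extract_target_reads_rules(tmp_path, toy_genome):
    chrom = next(iter(toy_genome.seqs))
    clens = toy_genome.chrom_lengths
    target = TargetRegion(GenomicInterval(chrom, 2000, 2200), "t0", pad_bp=100)
    sam = tmp_path / "reads.sam"
    _write_toy_sam(
        sam,
        clens,
        [
            ("inside", chrom, 2050, 100, False, False),
            ("flank_only", chrom, 1850, 100, False, False),  # overlaps pad only
            ("dup", chrom, 2050, 100, True, False),
            ("far", chrom, 9000, 100, False, False),
        ],
    )
    got = extract_target_reads(str(sam), [target])
    assert sorted(iv.start for _, iv in got) == [1850, 2050]


def test_design_pipeline_deterministic_fasta(tmp_path, toy_genome, panel, readset):
    sam = tmp_path / "sim.sam"
    readset.write_sam(sam, toy_genome.chrom_lengths)
    params = DesignParams(seed=21)
    outs = []
    for rep in range(2):
        ps = design_probes(
            panel, params, toy_genome.seqs, strategy="read_tiling", alignments=str(sam)
        )
        fa = tmp_path / f"probes{rep}.fa"
        ps.to_fasta(fa)
        outs.append(fa.read_bytes())
    assert outs[0] == outs[1]
    stages = dict(ps.provenance)
    assert stages["candidates"] >= stages["after_collapse"] >= stages["after_specificity"]
    assert stages["after_specificity"] > 0


def test_state_sim_design_produces_specific_probes(toy_genome, panel):
    params = DesignParams(seed=22, state_cap=4)
    ps = design_probes(panel[:3], params, toy_genome.seqs, strategy="state_simulation")
    assert ps.probes
    assert all(len(p.seq) == 80 for p in ps.probes)
    assert all(p.source == "state_simulation" for p in ps.probes)
    # emitted in converted space: no CpH cytosine in any probe
    for p in ps.probes:
        for i, b in enumerate(p.seq[:-1]):
            if b == "C":
                assert p.seq[i + 1] == "G"
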