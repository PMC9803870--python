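"""Capture-performance evaluation: the statistics a targeted-methylation
assay is judged by.

Coverage accounting (per-target mean depth, fraction of the panel at a
depth threshold), read classification into on/near/off target with a
flanking buffer, region-level beta aggregation from per-CpG counts,
per-read alpha values, standard-curve regression for methylation
controls, between-sample beta concordance, and coverage-vs-genomic-
context association tests (CpG island/shore/shelf/open sea, functional
features, repeat families).

Definitions
-----------
beta   methylated fraction at a CpG or region, ``M / (M + U)``.
alpha  mean methylation across the CpG calls of one read, so a region
       mixing fully methylated and fully unmethylated molecules shows
       a bimodal alpha histogram even at intermediate beta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .methylio import CpGCount, ReadMethylation
from .seqcore import GenomicInterval, TargetRegion

__all__ = [
    "CoverageSummary",
    "per_target_coverage",
    "ReadClassCounts",
    "classify_reads",
    "RegionBetaMatrix",
    "region_beta",
    "read_alpha",
    "AlphaDistribution",
    "alpha_distribution",
    "StandardCurveFit",
    "fit_standard_curve",
    "ConcordanceResult",
    "concordance",
    "ContextAnnotation",
    "annotate_context",
    "AssociationResults",
    "coverage_context_association",
    "count_cpg_calls",
]

DEFAULT_DEPTH_THRESHOLDS = (1, 10, 30, 100)
NEAR_TARGET_BUFFER_BP = 300


# ---------------------------------------------------------------------------
# coverage

@dataclass
class CoverageSummary:
    """Panel-level depth summary over the original target intervals."""

    per_target_mean: dict[str, float]
    median: float
    iqr: tuple[float, float]
    frac_ge: dict[int, float]
    frac_lt1: float


def _reads_by_chrom(
    reads: Iterable[ReadMethylation | GenomicInterval],
) -> dict[str, np.ndarray]:
    buckets: dict[str, list[tuple[int, int]]] = {}
    for r in reads:
        iv = r.interval if isinstance(r, ReadMethylation) else r
        buckets.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        c: np.asarray(v, dtype=np.int64).reshape(-1, 2) for c, v in buckets.items()
    }


def per_target_coverage(
    reads: Iterable[ReadMethylation | GenomicInterval],
    targets: Sequence[TargetRegion],
    thresholds: Sequence[int] = DEFAULT_DEPTH_THRESHOLDS,
) -> CoverageSummary:
    """Mean per-base depth per target plus panel summary statistics.

    Depth for a target is total aligned bases overlapping the original
    (unpadded) interval divided by its length.  Median and IQR are
    computed across targets.
    """
    if not targets:
        raise ValueError("per_target_coverage requires at least one target")
    by_chrom = _reads_by_chrom(reads)
    means: dict[str, float] = {}
    for t in targets:
        iv = t.interval
        arr = by_chrom.get(iv.chrom)
        if arr is None or arr.size == 0:
            means[t.name] = 0.0
            continue
        ov = np.minimum(arr[:, 1], iv.end) - np.maximum(arr[:, 0], iv.start)
        means[t.name] = float(np.clip(ov, 0, None).sum()) / len(iv)
    vals = np.array(list(means.values()))
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return CoverageSummary(
        per_target_mean=means,
        median=float(med),
        iqr=(float(q1), float(q3)),
        frac_ge={int(th): float(np.mean(vals >= th)) for th in thresholds},
        frac_lt1=float(np.mean(vals < 1)),
    )


# ---------------------------------------------------------------------------
# read classification

@dataclass
class ReadClassCounts:
    """On/near/off-target read tallies at a flanking buffer."""

    on: int
    near: int
    off: int
    buffer_bp: int = NEAR_TARGET_BUFFER_BP

    @property
    def total(self) -> int:
        return self.on + self.near + self.off

    @property
    def fractions(self) -> tuple[float, float, float]:
        n = self.total
        if n == 0:
            return (0.0, 0.0, 0.0)
        return (self.on / n, self.near / n, self.off / n)


def classify_reads(
    reads: Iterable[ReadMethylation | GenomicInterval],
    targets: Sequence[TargetRegion],
    buffer_bp: int = NEAR_TARGET_BUFFER_BP,
) -> ReadClassCounts:
    """Classify each read once against the original target intervals.

    on: overlaps a target by >=1 bp; near: no overlap but end-to-end
    gap to the nearest target <= buffer; off: everything else
    (including reads on chromosomes without targets).
    """
    tgt_by_chrom: dict[str, np.ndarray] = {}
    for t in targets:
        tgt_by_chrom.setdefault(t.interval.chrom, [])  # type: ignore[arg-type]
    tmp: dict[str, list[tuple[int, int]]] = {c: [] for c in tgt_by_chrom}
    for t in targets:
        tmp[t.interval.chrom].append((t.interval.start, t.interval.end))
    tgt_arrays = {
        c: np.asarray(v, dtype=np.int64).reshape(-1, 2) for c, v in tmp.items()
    }
    on = near = off = 0
    by_chrom = _reads_by_chrom(reads)
    for chrom, arr in by_chrom.items():
        tgts = tgt_arrays.get(chrom)
        if tgts is None:
            off += len(arr)
            continue
        S, E = tgts[:, 0], tgts[:, 1]
        for lo in range(0, len(arr), 8192):
            chunk = arr[lo : lo + 8192]
            rs = chunk[:, 0][:, None]
            re_ = chunk[:, 1][:, None]
            gap = np.maximum(S[None, :] - re_, rs - E[None, :])
            min_gap = gap.min(axis=1)
            on += int(np.sum(min_gap < 0))
            near += int(np.sum((min_gap >= 0) & (min_gap <= buffer_bp)))
            off += int(np.sum(min_gap > buffer_bp))
    return ReadClassCounts(on, near, off, buffer_bp)


# ---------------------------------------------------------------------------
# beta aggregation

class RegionBetaMatrix:
    """Regions x samples beta values with a companion coverage matrix.

    Region beta is count-weighted: summed methylated counts over summed
    total counts across the CpGs contained in the original target
    interval.  Beta is NaN wherever coverage is zero.
    """

    def __init__(self, beta: pd.DataFrame, coverage: pd.DataFrame):
        if not beta.index.equals(coverage.index) or not beta.columns.equals(
            coverage.columns
        ):
            raise ValueError("beta and coverage matrices must be aligned")
        self.beta = beta
        self.coverage = coverage

    @classmethod
    def from_samples(
        cls,
        sample_counts: Mapping[str, Iterable[CpGCount]],
        targets: Sequence[TargetRegion],
    ) -> "RegionBetaMatrix":
        betas = {}
        covs = {}
        for sample, counts in sample_counts.items():
            b, c = region_beta(counts, targets)
            betas[sample] = b
            covs[sample] = c
        return cls(pd.DataFrame(betas), pd.DataFrame(covs).fillna(0).astype(int))

    def to_tsv(self, beta_path, coverage_path=None) -> None:
        self.beta.to_csv(beta_path, sep="\t", index_label="region")
        if coverage_path is not None:
            self.coverage.to_csv(coverage_path, sep="\t", index_label="region")

    @classmethod
    def read_tsv(cls, beta_path, coverage_path) -> "RegionBetaMatrix":
        beta = pd.read_csv(beta_path, sep="\t", index_col="region", comment="#")
        cov = pd.read_csv(coverage_path, sep="\t", index_col="region", comment="#")
        return cls(beta, cov)


def region_beta(
    cpg_counts: Iterable[CpGCount], targets: Sequence[TargetRegion]
) -> tuple[pd.Series, pd.Series]:
    """Count-weighted beta and total coverage per target region.

    Only CpGs whose C position falls inside the original target
    interval contribute; beta = sum(M) / (sum(M) + sum(U)), NaN when
    the denominator is zero.
    """
    counts = list(cpg_counts)
    pos_by_chrom: dict[str, np.ndarray] = {}
    m_by_chrom: dict[str, np.ndarray] = {}
    u_by_chrom: dict[str, np.ndarray] = {}
    tmp: dict[str, list[tuple[int, int, int]]] = {}
    for c in counts:
        tmp.setdefault(c.position.chrom, []).append(
            (c.position.start, c.count_methylated, c.count_unmethylated)
        )
    for chrom, rows in tmp.items():
        arr = np.asarray(rows, dtype=np.int64)
        order = np.argsort(arr[:, 0])
        pos_by_chrom[chrom] = arr[order, 0]
        m_by_chrom[chrom] = arr[order, 1]
        u_by_chrom[chrom] = arr[order, 2]
    beta = {}
    cov = {}
    for t in targets:
        iv = t.interval
        pos = pos_by_chrom.get(iv.chrom)
        if pos is None:
            beta[t.name], cov[t.name] = np.nan, 0
            continue
        lo, hi = np.searchsorted(pos, [iv.start, iv.end])
        m = int(m_by_chrom[iv.chrom][lo:hi].sum())
        u = int(u_by_chrom[iv.chrom][lo:hi].sum())
        cov[t.name] = m + u
        beta[t.name] = m / (m + u) if m + u else np.nan
    return pd.Series(beta, name="beta"), pd.Series(cov, name="coverage")


def count_cpg_calls(reads: Iterable[ReadMethylation]) -> list[CpGCount]:
    """Pile per-read CpG calls (Z/z) into per-position counts.

    The position reported is the reference coordinate of the called
    cytosine, so top- and bottom-strand evidence at the same C lands
    on the same key only if calls were emitted on the C coordinate
    (the simulator and the usual extractor both do this).
    """
    acc: dict[tuple[str, int], list[int]] = {}
    Z, z = ord("Z"), ord("z")
    for r in reads:
        arr = np.frombuffer(r.call_string.encode(), dtype=np.uint8)
        start = r.interval.start
        chrom = r.interval.chrom
        for i in np.flatnonzero(arr == Z):
            key = (chrom, start + int(i))
            acc.setdefault(key, [0, 0])[0] += 1
        for i in np.flatnonzero(arr == z):
            key = (chrom, start + int(i))
            acc.setdefault(key, [0, 0])[1] += 1
    return [
        CpGCount(GenomicInterval(chrom, pos, pos + 1), m, u)
        for (chrom, pos), (m, u) in sorted(acc.items())
    ]


# ---------------------------------------------------------------------------
# alpha values

def read_alpha(read: ReadMethylation, min_cpg: int = 1) -> float | None:
    """Mean methylation across a read's CpG calls; None below *min_cpg* calls."""
    n_meth = read.call_string.count("Z")
    n_unmeth = read.call_string.count("z")
    n = n_meth + n_unmeth
    if n < max(min_cpg, 1):
        return None
    return n_meth / n


@dataclass
class AlphaDistribution:
    """Per-read alpha values plus a fixed-bin histogram on [0, 1]."""

    values: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.values.mean()) if self.values.size else math.nan


def alpha_distribution(
    reads: Iterable[ReadMethylation], min_cpg: int = 1, bins: int = 20
) -> AlphaDistribution:
    vals = np.array(
        [a for r in reads if (a := read_alpha(r, min_cpg)) is not None]
    )
    counts, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0))
    return AlphaDistribution(vals, edges, counts)


# ---------------------------------------------------------------------------
# standard curves and concordance

@dataclass
class StandardCurveFit:
    """OLS of observed mean beta (%) against expected methylation (%)."""

    expected: tuple[float, ...]
    observed: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float


def fit_standard_curve(
    expected_levels: Sequence[float], observed_betas: Sequence[float]
) -> StandardCurveFit:
    """Fit the methylation standard curve observed ~ expected (both in %).

    Replicate curves may be pooled by repeating levels in
    *expected_levels*.  Requires at least three distinct levels.
    """
    x = np.asarray(expected_levels, dtype=float)
    y = np.asarray(observed_betas, dtype=float)
    if x.shape != y.shape:
        raise ValueError("expected and observed must have equal length")
    if len(np.unique(x)) < 3:
        raise ValueError("need >=3 distinct expected levels")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in expected levels")
    res = sstats.linregress(x, y)
    return StandardCurveFit(
        tuple(x), tuple(y), float(res.slope), float(res.intercept),
        float(res.rvalue**2),
    )


@dataclass
class ConcordanceResult:
    r_squared: float | None
    slope: float | None
    n_regions: int
    degenerate: bool = False


def concordance(beta_a: pd.Series, beta_b: pd.Series) -> ConcordanceResult:
    """Squared Pearson correlation and OLS slope of shared region betas.

    Regions are paired by id; regions undefined (NaN) in either sample
    are dropped.  A constant vector yields a flagged degenerate result
    rather than a number.
    """
    df = pd.concat([beta_a.rename("a"), beta_b.rename("b")], axis=1, join="inner")
    df = df.dropna()
    n = len(df)
    if n < 3:
        raise ValueError(f"concordance needs >=3 shared regions, got {n}")
    if df["a"].nunique() == 1 or df["b"].nunique() == 1:
        return ConcordanceResult(None, None, n, degenerate=True)
    res = sstats.linregress(df["a"].to_numpy(), df["b"].to_numpy())
    return ConcordanceResult(float(res.rvalue**2), float(res.slope), n)


# ---------------------------------------------------------------------------
# genomic context

CPG_CONTEXTS = ("island", "shore", "shelf", "open_sea")
FUNCTIONAL_PRECEDENCE = ("promoter", "enhancer", "exon", "intron")
SHORE_BP = 2000
SHELF_BP = 4000


@dataclass
class ContextAnnotation:
    """One CpG-context label, one functional label and the overlapping
    repeat families per region; a layer is None when its track was
    not supplied."""

    cpg_context: dict[str, str] | None
    functional: dict[str, str] | None
    repeat_families: dict[str, frozenset[str]] | None


def _min_gap(iv: GenomicInterval, others: Sequence[GenomicInterval]) -> int | None:
    gaps = [g for o in others if (g := iv.gap_to(o)) is not None]
    return min(gaps) if gaps else None


def annotate_context(
    targets: Sequence[TargetRegion],
    islands: Sequence[GenomicInterval] | None = None,
    functional: Mapping[str, Sequence[GenomicInterval]] | None = None,
    repeats: Sequence[tuple[GenomicInterval, str]] | None = None,
    shore_bp: int = SHORE_BP,
    shelf_bp: int = SHELF_BP,
) -> ContextAnnotation:
    """Label each target by CpG context, functional feature and repeats.

    CpG context is distance-based: overlap an island -> island; within
    *shore_bp* -> shore; within *shelf_bp* -> shelf; else open sea.
    Functional labels resolve overlaps by fixed precedence
    promoter > enhancer > exon > intron, defaulting to intergenic.
    """
    cpg_ctx = None
    if islands is not None:
        cpg_ctx = {}
        for t in targets:
            gap = _min_gap(t.interval, islands)
            if gap is None:
                cpg_ctx[t.name] = "open_sea"
            elif gap == 0:
                cpg_ctx[t.name] = "island"
            elif gap <= shore_bp:
                cpg_ctx[t.name] = "shore"
            elif gap <= shelf_bp:
                cpg_ctx[t.name] = "shelf"
            else:
                cpg_ctx[t.name] = "open_sea"
    func = None
    if functional is not None:
        func = {}
        for t in targets:
            label = "intergenic"
            for feat in FUNCTIONAL_PRECEDENCE:
                if any(t.interval.overlaps(iv) for iv in functional.get(feat, ())):
                    label = feat
                    break
            func[t.name] = label
    rep = None
    if repeats is not None:
        rep = {
            t.name: frozenset(
                fam for iv, fam in repeats if t.interval.overlaps(iv)
            )
            for t in targets
        }
    return ContextAnnotation(cpg_ctx, func, rep)


@dataclass
class GroupTest:
    statistic: float
    p_value: float
    group_means: dict[str, float]


@dataclass
class AssociationResults:
    """Coverage-vs-context test battery.

    One-way fixed-effects ANOVA across CpG-context groups and across
    functional groups; per-repeat-family ANOVA of family-containing
    targets vs the rest; and a pooled two-sample t-test of repetitive
    vs non-repetitive targets.  Raw p-values, no multiplicity
    correction.
    """

    cpg_context_anova: GroupTest | None
    functional_anova: GroupTest | None
    repeat_family_anova: dict[str, GroupTest]
    repetitive_t_test: GroupTest | None


def _anova(groups: Mapping[str, Sequence[float]], what: str) -> GroupTest:
    usable = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValueError(
            f"degenerate grouping for {what}: need >=2 groups with >=2 targets, "
            f"got {sorted(groups)} with sizes {[len(v) for v in groups.values()]}"
        )
    f, p = sstats.f_oneway(*usable.values())
    return GroupTest(
        float(f), float(p), {k: float(v.mean()) for k, v in usable.items()}
    )


def _t_test(a: Sequence[float], b: Sequence[float], what: str) -> GroupTest:
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"degenerate grouping for {what}: both groups need >=2")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, p = sstats.ttest_ind(a, b)
    if np.isnan(t):  # identical constant groups: no evidence of difference
        t, p = 0.0, 1.0
    return GroupTest(float(t), float(p), {"group_a": float(a.mean()), "group_b": float(b.mean())})


def coverage_context_association(
    per_target_mean: Mapping[str, float], annotation: ContextAnnotation
) -> AssociationResults:
    """Test whether mean target coverage differs by genomic context."""
    names = list(per_target_mean)
    cov = {n: per_target_mean[n] for n in names}

    cpg_res = None
    if annotation.cpg_context is not None:
        groups: dict[str, list[float]] = {}
        for n in names:
            groups.setdefault(annotation.cpg_context[n], []).append(cov[n])
        cpg_res = _anova(groups, "cpg_context")
    func_res = None
    if annotation.functional is not None:
        groups = {}
        for n in names:
            groups.setdefault(annotation.functional[n], []).append(cov[n])
        func_res = _anova(groups, "functional")
    fam_res: dict[str, GroupTest] = {}
    rep_res = None
    if annotation.repeat_families is not None:
        families = sorted(
            {f for fams in annotation.repeat_families.values() for f in fams}
        )
        for fam in families:
            inside = [cov[n] for n in names if fam in annotation.repeat_families[n]]
            outside = [cov[n] for n in names if fam not in annotation.repeat_families[n]]
            fam_res[fam] = _anova(
                {"with_" + fam: inside, "without_" + fam: outside}, f"repeat {fam}"
            )
        rep = [cov[n] for n in names if annotation.repeat_families[n]]
        nonrep = [cov[n] for n in names if not annotation.repeat_families[n]]
        rep_res = _t_test(rep, nonrep, "repetitive vs non-repetitive")
    return AssociationResults(cpg_res, func_res, fam_res, rep_res)
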