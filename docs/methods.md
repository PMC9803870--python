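# Methods

## Coordinate and conversion conventions

All intervals are 0-based half-open (BED convention) internally;
1-based formats (the per-CpG coverage dialect) are converted at the
I/O boundary only. In-silico bisulfite conversion (`seqcore`) converts
every cytosine not immediately followed by guanine to thymine. Two
ambiguous cases are resolved deterministically and conservatively, the
way standard in-silico converters behave: a terminal cytosine (no next
base, context unknowable) converts, and `CN` converts because N is not
provably G. The bottom strand is converted as the reverse complement
and reported in that orientation. Conversion is idempotent and
preserves the CpG positions of the input — these are tested as
properties over random sequences.

## Probe design

**Tiling.** A read of length L yields `tiling_count` (default 3)
probes of `probe_length` (default 80) nt at starts
`round(i·(L−P)/(n−1))`, so the outermost probes pin the read ends and
a 151-nt read gives starts 0/36/71. Reads shorter than the probe give
nothing; an 80-nt read gives one probe.

**Redundancy collapse.** The redundancy predicate R(a, b) holds when
the two probes share an ungapped overlap of at least
`collapse_min_overlap` nt with identity at least
`collapse_min_identity` inside the overlap (defaults 60 nt / 0.95;
the strict preset is 78 nt / 0.97). When both probes carry origin
coordinates on the same chromosome, the overlap offset is the one
implied by those coordinates — probes derive from co-aligned reads, so
a gapped or multi-offset alignment adds complexity without
information; otherwise every offset with sufficient overlap is
scanned. Collapse is a greedy first-kept-wins sweep over candidates
sorted by origin coordinate then sequence. Which member of a redundant
pair survives is underdetermined in principle; the deterministic sort
makes the output reproducible and the sweep idempotent. Correctness is
checked against an all-pairs brute-force oracle: no two survivors are
mutually redundant, and every removed probe is redundant with a
survivor.

**State simulation.** With k CpGs in a target there are 2^k
methylation states. All are enumerated while `2^k ≤ state_cap`
(default 16); beyond that the all-methylated and all-unmethylated
states are always included and the remaining `state_cap − 2` states
are sampled uniformly without replacement under the configured seed —
uniform sampling is the least-informative choice when nothing is known
about the haplotype structure of the locus. Both strands are
converted per state and duplicate images removed.

**Specificity.** The screen searches the fully CpH>TpH-converted
genome, both strands, with an exact k-mer seed (k = 12) followed by
ungapped extension along the diagonal; a hit is any sub-window of at
least `hit_min_length` nt (default 60) at `hit_min_identity` (default
0.90) identity. Qualifying diagonals within one probe length on a
chromosome merge into a single hit locus. A probe is kept iff a locus
overlaps its origin and at most `max_offtarget_hits` (default 4) other
loci exist. The 60 nt / 0.90 / ≤4 triple is this package's definition
of a "relaxed" screen — commercial filtration criteria are
proprietary, so the level is exposed as three plain parameters rather
than imitated. Note a deliberate consequence: the converted reference
retains every CpG cytosine (the fully methylated image), so probes
tiled from heavily unmethylated, CpG-dense reads accumulate mismatches
at their CpG sites and can fail the origin-hit requirement; raising
`max_offtarget_hits` or lowering `hit_min_identity` relaxes this.

## Evaluation statistics

Per-target depth is total aligned bases overlapping the *original*
target interval divided by its length; reads are collected over the
padded footprints but metrics are reported on the unpadded interval,
and median/IQR are taken across targets. Read classification measures
the end-to-end gap to the nearest target: overlap ⇒ on; gap ≤ 300 bp
(the default buffer, matching a design padded beyond the targets) ⇒
near; strictly greater ⇒ off.

Region beta is count-weighted, β = ΣM/(ΣM+ΣU) over the CpGs inside
the target interval, equivalent to weighting CpGs by their read
evidence (and equal to the mean of per-CpG betas when coverage is
uniform, which is tested). A CpG-mean alternative would up-weight
poorly covered CpGs; count weighting matches how region summarization
utilities in the bisulfite ecosystem pool evidence.

The standard-curve fit is ordinary least squares of observed mean
beta (%) on expected methylation (%); R² is the squared Pearson
correlation, identical to OLS R² for a simple linear regression.
Concordance between two samples is the squared Pearson correlation
and OLS slope over regions with defined betas in both; a constant
vector returns a flagged degenerate result instead of a number.

CpG context is distance-based: overlap an island ⇒ island; within
2 kb ⇒ shore; 2–4 kb ⇒ shelf; else open sea (distances configurable).
Functional labels resolve multi-overlap by fixed precedence
promoter > enhancer > exon > intron, defaulting to intergenic — a
region gets exactly one label, and the precedence order is this
package's tie-break. Association tests are one-way fixed-effects
ANOVA on per-target mean coverage (per context grouping, and per
repeat family as containing-vs-not) plus a pooled two-sample t-test of
repetitive vs non-repetitive targets; p-values are raw, with no
multiplicity correction, since each grouping is a separate a-priori
question. Two identical groups report t = 0, p = 1 rather than the
undefined statistic of a zero-variance contrast.

## The simulator: what it emulates and what it does not

`simfixtures` generates (i) a toy genome — CpG-suppressed background
(~80 % of background CpG dinucleotides broken), CpG-enriched island
segments (~1 CpG per 5–8 bp), one repeat unit copied verbatim at
spaced positions, and scattered functional features; (ii) a target
panel biased to island segments, as DMR panels are CpG-dense; and
(iii) cfDNA-like fragments: lengths ~ Normal(160, 20) truncated to
[50, 320] bp (cfDNA peaks near the mononucleosome length), placed over
a padded target footprint with probability `on_target_fraction`
(default 0.65, a mid-range capture efficiency) and uniformly
otherwise.

Methylation is a property of the locus: any fragment covering a padded
footprint draws each CpG as an independent Bernoulli at that region's
true beta, all other fragments at `background_beta` (default 0.75, a
typical genome-wide level). An unmethylated cytosine escapes
conversion with probability `1 − conversion_efficiency` (default
0.99 efficiency) and then reads as methylated — so the expected
apparent beta is β + (1−β)(1−e), a property of the chemistry, not of
the estimator. Sequencing errors, when enabled, touch only
non-cytosine-call bases so methylation truth stays exact. Standards
are simulated the way physical controls are manufactured: each
*molecule* is fully methylated with probability f, else fully
unmethylated, which makes the pooled beta equal f while the per-read
alpha histogram is bimodal at 0 and 1.

Reads are emitted as already-aligned records (the placement is the
fragment's true origin) on the top bisulfite strand only, with
XM-style call strings; per-CpG counts are keyed by the C coordinate,
so single-strand simulation does not bias region betas. Everything is
deterministic under the configured seed.

Not emulated: nucleosome-informed fragmentation, sequencer error
profiles, hybridization thermodynamics and capture GC bias, PCR
duplicates, indels, and bottom-strand read pairs. Passing recovery
tests therefore demonstrates correctness of the statistics under
ideal alignment and calling, not robustness to those artifacts.

## Validation scales and numerical choices

The recovery tests run at desk scale: standard curves use six levels
× 50 000 fragments over a 200 kb genome with a 100-region panel;
region-beta recovery uses 100 regions with betas ~ U(0,1) at ≥ 50×
evidence, asserting every estimate within 3 binomial standard errors
√(β(1−β)/n) of truth; replicate concordance uses two independent
simulations of the same methylome (R² > 0.95). These recovery tests
fix conversion efficiency at 1.0 to isolate estimator behavior from
the chemistry bias described above, which is characterized separately
(residual apparent methylation ≈ 1 − e on unmethylated input).
Boundary behavior of read classification (gap 300 ⇒ near, 301 ⇒ off)
is asserted exactly against a brute-force per-read scan.

## Known limitations

* The specificity screen is seed-and-extend with an exact 12-mer seed;
  a hit diverging enough that no 12-mer survives is missed. At the
  default 0.90 identity over 60 nt this is unlikely but possible for
  adversarial inputs.
* Collapse compares probes at the coordinate-implied offset when
  origins are known; sequence-identical probes from different loci are
  only collapsed in the origin-free scan mode.
* Alignment records with indels are skipped by the call-string reader
  (the simulator never produces them).
* The CLI's context-association table is skipped with a warning when a
  grouping is degenerate (fewer than two groups with two targets).
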