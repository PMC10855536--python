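# Methods

This note documents the models, algorithms, defaults and design choices
behind `ervamp`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Problem setting

A degenerate primer pair amplifies a segment (e.g. of the ENV gene) from
many near-identical genomic ERV copies at once. Sequencing the amplicon
pool and assigning each read to its copy of origin yields per-copy
("per-locus") expression estimates. Each stage below exists because of the
near-identity of the copies: locus discovery must tolerate primer-site
mismatches, mapping must be strict enough that a read's 2–8% of
copy-discriminating positions actually discriminate, and reads equally
consistent with several copies must be handled by an explicit policy
rather than silently dropped or double-counted.

## Virtual PCR

A locus is any pair of primer-annealing sites facing each other with a
product length inside a window. Matching is IUPAC-aware (a primer base
matches a genome base iff the base is in the primer code's set) with
defaults:

| parameter | default | meaning |
|---|---|---|
| `max_mismatches_per_primer` | 2 | annealing tolerance per primer |
| `three_prime_protected` | 3 | 3′-terminal bases where no mismatch is tolerated (polymerase extension requires a paired 3′ end) |
| amplicon window | 100–2000 bp | plausible product sizes |

Coordinates are 0-based half-open internally and BED on disk. All
conformant pairs are reported, including overlapping or nested products;
no suppression heuristic is applied, because downstream counting treats
loci independently. The scan is vectorised (per-position bitmask
comparison) and is tested for exact agreement with a naive
every-position oracle and for reverse-complement symmetry.

## Read preparation

Reads may begin at either primer, so trimming checks both primers against
the 5′ end and both reverse complements against the 3′ end, taking the
best match within a mismatch budget (default 1). The length filter keeps
reads whose **post-trim** length is strictly greater than 135 bp: the
mapped portion is what the floor protects, and the strict inequality is
deliberate (135 is dropped, 136 kept).

## Alignment

Scoring is match +1, mismatch −10, gap −10 **per gap base** (linear; no
separate gap-open term — the single stated gap figure is read as a
per-base cost, and an affine scheme would be a configuration extension).
"No soft clipping" is operationalised as read-global alignment: every read
base is scored, while the reference end is free (glocal DP). A read is
called mapped when its best score reaches `read_len − 33`, i.e. at most
three penalized events; the threshold is configurable.

Two implementations share this definition:

- `align_read_glocal` — exact DP over the full reference; the row
  recurrence resolves reference-gap chains with a decayed running
  maximum, which is exact for linear gap costs. Memory is O(read × ref),
  so this is the small-reference/reference-truth path.
- `GenomeAligner` — seed-and-verify: exact k-mers (k = 13, 8 seeds spread
  along the read, both strands) propose diagonals; candidates are scored
  ungapped by vectorised mismatch counting, then by an exact single-gap
  split search (gap sizes 1..3; a 4-base gap can never reach the
  acceptance threshold). Candidates still below the threshold go through
  a windowed full DP (capped at the 6 most promising clusters). The fast
  path is therefore exact for every alignment with at most one gap event
  above threshold, and multi-gap reads are either recovered exactly by
  the fallback or rejected — never silently misassigned. Agreement with
  the exact DP is asserted in the test suite.

Multi-mappers: **all** positions achieving the best score are collected
and one is drawn uniformly at random. The draw is keyed by hashing
(seed, read id) rather than by a shared RNG stream, so the choice for a
read is reproducible and independent of input order. Accumulated mismatch
percentage across mapped reads is reported as a QC metric (not applied as
a filter); on defect-free synthetic data it stays below the simulated
substitution rate plus sampling noise.

## Quantification

A mapped read counts toward a locus when at least 90% of its aligned
reference span lies inside the locus interval; this threshold is a
package construction (amplicon reads ordinarily lie entirely inside a
locus, so the rule only adjudicates boundary-spanning or spurious
alignments). Reads overlapping no locus are tallied off-target,
preserving `mapped = on-target + off-target` per sample.

Relative frequency is `100 × count / denominator` with the denominator
either the on-target total (default; rows sum to exactly 100) or all
mapped reads. On data where ≥ 99% of mapped reads are on-target the two
are nearly identical, which is why both are supported and the choice is
recorded in the run manifest. A locus with fewer than `min_count` (1)
reads in **more than** 50% of samples (strict majority) is excluded
before testing.

## Group statistics

*Descriptive.* Fold change is the ratio of group **median** percentages,
case over control. Conventions: case median 0 gives `x = 0`; control
median 0 with a nonzero case median gives an infinite sentinel that is
excluded (and counted) in cohort summaries. The relative fold change
`rfc(x) = x − 1` for `x > 1`, `1/x − 1` for `0 < x < 1`, and `0` at
`x ∈ {0, 1}` is symmetric under inversion, so a doubling and a halving
are equidistant from "no change". Cohort summaries report both the signed
version (sign from the direction of `x`) and the absolute version,
because either aggregation of "median fold change over loci" is
defensible; the changed-only subset drops loci with `0.8 < x < 1.2`.

*Negative-binomial Wald test.* Raw counts are normalized by
median-of-ratios size factors (computed over loci nonzero in every
sample, normalized to geometric mean 1; total-count fallback if no such
locus exists). Per locus, the group means of normalized counts estimate
the NB means; the dispersion α (variance = μ + αμ²) is a pooled
within-group method-of-moments estimate floored at 1e−8 — deliberately
transparent, with **no** empirical-Bayes shrinkage and no outlier
refitting. The Wald statistic is the log2 ratio of group means (a +0.5
pseudocount on both means when either is zero) divided by its
delta-method standard error,

    Var(ln m_g) ≈ ξ_g/(n_g·m_g) + α/n_g,     ξ_g = mean(1/s_j in group g),

and is referred to a Student-t distribution with `n₁ + n₂ − 2` degrees of
freedom. The t reference (rather than a normal) accounts for the mean and
dispersion being estimated from very few samples: with a normal reference
the null rejection rate at α = 0.05 is ≈ 0.087 in simulation at n = 4 vs
4, while the t reference gives ≈ 0.040 and keeps the extreme tail honest
enough that BH at FDR 0.05 over 2000 null loci almost never rejects.
Calibration and power are asserted at pre-registered simulation settings:
null, 2000 loci × 4 vs 4, NB α = 0.05, means log-uniform on [5, 500],
depth factors U(0.7, 1.4); power, a 27-locus panel with a 4-fold effect
planted on a locus of baseline mean 100 normalized counts (observed power
≈ 0.96 at FDR < 0.05). Benjamini–Hochberg adjustment is the step-up
formula with monotonicity enforcement, tested against its brute-force
definition and statsmodels.

## qPCR arithmetic

Triplicate Cts are gated at sample SD (ddof = 1) strictly below 0.2;
"undetermined" replicates are dropped first. ΔCt subtracts the
**arithmetic mean** of the reference-gene Cts (equivalent to geometric-mean
normalization of quantities; with multiple reference genes the
average-Cts-first and per-gene-ΔΔCt-then-average conventions differ
slightly — the former is used and exposed). The calibrator is the mean
(default) or median ΔCt of the control group, selectable per analysis.
Amplification efficiency is assumed 100% (the 2^−ΔΔCt model); measured
efficiencies are carried as config metadata only. The RT+/RT− check
computes `2^(Ct_RT− − Ct_RT+)` and passes at ≥ 10-fold (an undetected RT−
reaction passes with an infinite ratio).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

- **Genome**: `n_loci` (27) copies of a 600 bp random consensus, each
  independently diverged by 2–8% substitutions, flanked by concretized
  primer sites carrying 0–2 planted mismatches outside the protected 3′
  positions; copies are placed on 5 chromosomes, on either strand, with
  at least 800 bp of random background between loci so that primer sites
  of adjacent copies cannot pair into chained products within the default
  2000 bp scan window.
- **Expression**: control-group proportions put 48% of reads on one
  dominant locus and 7.5% on a second, with the remaining mass log-spaced
  down to ~2×10⁻⁴ — one dominant copy plus a long tail of rare copies, so
  the low-count filter and rare-locus fold changes are exercised
  realistically. Case-group proportions multiply planted loci by their
  fold and renormalize (the realized ratio is therefore slightly below
  the nominal fold; ground truth records the realized proportions).
- **Samples**: 8 vs 8 groups by default; per-sample depth is lognormal
  around `reads_per_sample` with CV 0.3 (matching the roughly one-third
  relative spread of real per-sample yields). The working default depth
  is 6000 reads/sample; `PAPER_SCALE_READS` (70 694) is the study-scale
  preset.
- **Reads**: single-ended from either amplicon end, raw length uniform
  150–190 nt (so that post-trim lengths straddle the 135 bp floor),
  substitution rate 0.005/base, 1-base indels at 0.001/base with a 4×
  multiplier inside homopolymer runs, emulating semiconductor-sequencer
  error structure. Read ids encode sample, ordinal, source locus and
  primer end.

All randomness descends from a single seed through spawned
`SeedSequence` streams; identical configs are byte-identical across runs.

*What passing on this generator does not show*: real amplicon data add
PCR chimeras and duplicates, primer-efficiency differences between copies
(the generator's locus proportions absorb, rather than model, amplification
bias), quality-score structure, and reference-genome errors. Results on
the generator validate the pipeline's bookkeeping, calibration and
recovery properties, not the biology of any particular cohort.

## Numerical and engineering choices

- Alignment DP uses int32 scores; traceback prefers diagonal, then
  read-gap, then reference-gap moves, making reported
  mismatch/gap decompositions deterministic among equal-score paths.
- Degenerate placements consuming no reference base are discarded.
- BH-adjusted p-values are clamped to `p_adj ≥ p` to guard the documented
  invariant against 1-ulp rounding in `p·m/rank`.
- Zero denominators (a sample with no counted reads) yield flagged NaN
  frequencies, never a fabricated 0.
- Test problem sizes are scaled-down versions of the defaults (e.g.
  5000 reads × 8 samples for the end-to-end bookkeeping checks, 600
  reads × 6 samples for determinism), chosen to exercise every code path
  at interactive runtimes.

## Known limitations

- The NB test has no dispersion shrinkage, no Cook's-distance outlier
  handling and no covariates; it is calibrated for the two-group designs
  it targets, not a general DESeq2 replacement.
- The fast aligner's multi-gap fallback examines the 6 most promising
  candidate clusters; a read needing two or more gaps whose true locus is
  not among them is reported unmapped (never misassigned). At the default
  error rates this affects a negligible fraction of reads, without locus
  bias.
- Affine gap costs, quality-aware scoring and spliced alignment are out
  of scope; so are primer thermodynamics and assembly liftover.
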