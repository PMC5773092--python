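# Methods

This note records the statistical conventions, defaults, and design
choices behind `histosig`, and what the synthetic test bed does and does
not establish about real data.

## Input model

Expression values are assumed to be log2-scale, already normalized
(e.g. RMA for Affymetrix arrays) — the package never touches raw
intensities, and batch correction is out of scope (external tools exist
for both).  Gene identifiers are expected to be unique after loading;
duplicate rows (multiple probes per gene) are collapsed to the row with
the highest variance across samples, the standard microarray practice that
preserves dynamic range.  Per-gene **median centering** (row median
subtracted) is the only owned transformation; it is idempotent and is
applied upstream of heatmap-style clustering so distances reflect relative
expression.

## Permutation differential expression

The two-class statistic is the moderated relative difference
d_i = (x̄_a − x̄_b)/(s_i + s0) with the pooled standard error
s_i = √[(1/n_a + 1/n_b)(SS_a + SS_b)/(n_a + n_b − 2)].  The fudge factor
s0 stabilizes d for low-variance genes; it is chosen from the percentiles
0, 5, …, 100 of the s distribution as the candidate minimizing the
coefficient of variation of MADs of d computed in contiguous windows of
s (window count min(100, n_genes/10), floor 2 so small inputs remain
well-defined; with fewer than 20 genes the 5th percentile is used
directly).

Significance comes from permuting class labels: exhaustively when the
number of distinct assignments C(n, n_a) is within the permutation budget
(default 1000), otherwise by uniform seeded draws.  For a gene at
threshold t = |d|,

    q = π₀ · median over permutations of #{|d*| ≥ t} / #{observed |d| ≥ t}

capped at 1 and made monotone nonincreasing in t (each gene takes the
minimum raw q over itself and all less extreme genes).  π₀ is the fraction
of observed d inside the central 50% of the pooled permuted d
distribution, capped at 1.  Ties count as exceeding — conservative.  The
permuted null retains truly differential genes (the standard convention),
which makes the q-values conservative on strongly structured cohorts:
realized false discovery on the synthetic cohorts runs well below the
nominal level, at some cost in power.

## Signature derivation

A histology signature is the intersection over all contrasts
(target vs each other histology) of the genes at q ≤ 0.05 with d > 0
(up list) or d < 0 (down list).  Requiring consistency across contrasts
whose reference groups carry different genotype programs is what removes
genotype/batch genes: an offset shared by target and reference samples
cannot be significant in every comparison.  Empty lists are legitimate
outcomes.  The optional fold filter uses the worst case across contrasts —
an up gene's minimum fold change must clear the floor, a down gene's
maximum must stay under the ceiling — so a printed criterion like
"> 5-fold up" holds in every comparison.  "At least 2-fold down" means
fold change ≤ 0.5 on the linear scale; both thresholds are configurable.
Intermediate manual curation against an external validation set (dropping
genes that track poorly) is supported as an explicit gene-list subset
step, never guessed automatically.

## Gene set enrichment

Ranking uses the signal-to-noise metric (μ_a − μ_b)/(σ_a + σ_b) with each
group's sd floored at max(0.2·|μ|, 0.2); groups below 3 samples fall back
to difference of means with a warning.  Ties in the metric break
lexicographically by gene ID for cross-platform determinism.  The running
sum adds |metric|^p (default weight p = 1) normalized over the set at
hits and subtracts 1/(N − N_H) at misses; ES is the signed maximum
deviation and the leading edge is the set members at or before (after,
for negative ES) the extremum.  A set covering the whole list has an
undefined miss step; by convention it is 0, giving ES = 1 (flagged
degenerate).

Phenotype (label) permutation is the default; classes too small for a
meaningful label null (fewer than 7 per class *and* fewer than 50 distinct
splits) switch to random same-size gene sets with a warning — balanced
4v4 designs keep their exhaustive 70-split phenotype null.  NES divides ES
by the mean |permuted ES| of matching sign; the nominal p is the
same-signed permutation tail fraction (reported as 0.0 at the permutation
floor, with the count basis stored so < 1/B can be quoted); FDR q is the
sign-stratified ratio of permuted to observed NES tail fractions, capped
and monotonized; FWER uses the per-permutation extreme-NES distribution.

## Single-sample scoring and classification

ssGSEA ranks genes within each sample (descending, ties by gene ID),
assigns ranks N..1, and accumulates the difference between the
rank^α-weighted in-set ECDF and the uniform out-of-set ECDF over the whole
ranking (α = 0.25).  Scores are normalized by the global score range
(range normalization is rank-preserving within a sample, so it can never
change an argmax).  Classification restricts to the "up" gene lists,
assigns each tumor its argmax signature, breaks ties lexicographically
(recorded), and optionally flags calls whose margin over the runner-up is
below a floor (default 0 — off) without altering the stored argmax.  The
heatmap ordering groups samples by call and sorts by winning score
descending within groups.

## Clustering, homology, survival

Hierarchical clustering offers uncentered correlation (raw cross-product
cosine, the classic desktop tool's default), Pearson (both as 1 − r), and
Euclidean distances with average or complete linkage via SciPy.  Items are
sorted by ID before linkage so results are input-order invariant with
deterministic tie-breaking; trees export as Newick (branch length =
parent height − child height) and merge tables, and validation uses an
explicit k = 2 tree cut rather than visual inspection.

Homology mapping is table-driven (two-column mouse/human TSV, never a
bundled database).  Policy "expand" keeps all homologs of a many-homolog
gene; "drop" removes such genes.  The report lists unmapped and expanded
genes and per-set retention; an empty mapped set is an error, never
silent.

Survival scoring defaults to the mean of median-centered expression of a
signature's up genes (simple, monotone, reproducible; ssGSEA scores are a
drop-in alternative for sensitivity checks).  The median split is computed
over the analyzed population — the named stratum when stratified — with
ties assigned to "low" (strictly above defines "high"; recorded in output
metadata).  Groups are compared by the product-limit estimator, the
log-rank test (hypergeometric expectation/variance over event times), and
a univariate Cox hazard ratio for high vs low (HR > 1 = worse outcome in
the high group), falling back to the Mantel–Haenszel (O/E)/(O/E) ratio if
the fit fails; both estimates are stored.  Zero-event inputs return curves
with the comparison flagged undefined.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: baseline gene
means ~ Normal(8, 1) on the log2 scale, per-histology planted up/down
programs shifted by ±effect_log2, genotype/batch offsets applied to a
disjoint gene block in a random sample subset independent of histology,
i.i.d. Gaussian noise, and mixed-histology samples as convex combinations
of class mean profiles plus noise.  Defaults — 2000 genes, the six
mammary histologies at 12 samples each, 60 up / 30 down planted genes per
class at 2.0 log2 effect, one batch at 1.5 log2 offset over half the
samples, unit noise — are sized to a compact annotated tumor study and
keep full-suite runs fast.  Survival times are exponential with hazard
baseline_rate · exp(β · z) for the standardized score z, with independent
exponential censoring calibrated by bisection to a target censored
fraction.

What the generator does *not* emulate: probe-level effects, correlated
gene–gene noise, heavy-tailed intensities, non-additive batch structure,
or platform differences.  Passing tests therefore demonstrate the
statistical machinery (calibration, recovery, exclusion of orthogonal
offsets, estimator behavior) under the assumed model, not performance on
any particular public dataset.

## Test-bed operating characteristics worth knowing

Two composite behaviors are intrinsic to the conditions, not tunable
implementation details.  First, intersecting five contrasts at 10 samples
per class compounds per-contrast sensitivity (~0.93 at q ≤ 0.05 for a
2.0 log2 effect) down to roughly 0.8 joint recovery; an independent
Welch-t + Benjamini–Hochberg route does markedly worse under identical
conditions, so this is the power frontier of the design, improved only by
more samples per class.  Second, a Cox log-HR estimated from ~420 events
has a sampling sd near 0.12, so single-run hazard-ratio estimates around
a true 2.0 scatter roughly between 1.6 and 2.5.  The acceptance script
reports both quantities as measured.

## Numerical and degenerate-input conventions

All randomness flows through `numpy.random.default_rng` from explicit
seeds (the CLI derives per-stage seeds from one root seed via
`SeedSequence`, keeping stages individually rerunnable).  Within-group
sums of squares are floored at 0 against rounding; distance matrices are
symmetrized and floored at 0; a constant gene has d = 0 by convention
(0/denominator), and s + s0 = 0 with a nonzero numerator is an error
instructing a positive s0.  Exhaustive permutation modes are
seed-independent.  Parsers fail loudly with line/column locations; GMT
round trips preserve name, description, and gene order, dropping
within-set duplicate genes with a warning.

## Known limitations

Probe-level analyses, RMA/quantile normalization, multivariate Cox
adjustment, competing risks, and enrichment-map or heatmap rendering are
out of scope.  Signature derivation assumes every contrast shares the
same target-histology samples; paired or multi-class designs are not
supported.  Reproducing gene counts from any specific public cohort will
shift by a few genes under any reimplementation of the permutation
machinery, since the original tool's version and settings are not part of
this package's contract.
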