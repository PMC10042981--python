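# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## The data model

A study is three tables: a sample table (one row per injection: variety,
cultivation method, within-variety harvest week 1..W, calendar week,
replicate, batch, injection order, QC flag), a compound table (platform,
annotation, chemical class, identification level 1–4, flavour-relevance
flag), and a samples × compounds intensity matrix with explicit missing
values. The matrix carries a scale flag (`raw`, `log2`, `corrected`,
`pareto`) and each stage refuses input at the wrong scale — most historical
preprocessing bugs in this kind of pipeline are silent double transforms.

The modelling time axis is the within-variety harvest index (week 1 =
first sampled week of that variety's season); calendar week is kept as
metadata and used only by the per-time-point cultivation contrasts. This
matters because varieties start their 8-week windows months apart.

## QC-based correction

Pooled-QC aliquots are injected at the first and last slot of every batch
and evenly in between (placement within batches is an assumption; only the
count per batch is a known design quantity). Per compound and batch we fit
the least-squares line of QC log2 values on injection order and subtract it
from every sample in the batch, centred on the mean QC injection order so
the batch QC mean is preserved; each batch is then shifted so its QC mean
equals the grand QC mean (the mean over usable batch QC means). The drift
model is linear in injection order — the minimal invertible choice, and the
mechanism the generator injects; smoother QC-trend models would slot into
the same interface. Batches with fewer than 2 usable QC values for a
compound fall back to median alignment (logged); with none, that
batch × compound is left unchanged.

Two consequences worth knowing: the correction is exactly idempotent (after
it, the QC line has slope 0 and all batch QC means coincide), and it shifts
every sample of a batch by the same per-compound amount, so within-batch
biological contrasts are untouched and between-batch contrasts are moved
only through the QC estimates.

## Trend models and moderation

Per compound: `y = β_v + N_v(w)·(γ + δ_v) + ε`. `N_v` is the natural cubic
spline basis (3 df) on variety v's observed weeks — truncated-power
construction with natural boundary constraints, interior knots at evenly
spaced quantiles of the *distinct* observed weeks (replicate counts must
not move knots), boundary knots at the extremes — anchored by subtracting
the basis row at week 1. Anchoring makes `N_v(1) = 0`, so the fitted curve
at week 1 is exactly 0 with zero CI width, and the time coefficients are
directly log2 fold changes from harvest start. Interaction deviations are
coded sum-to-zero across varieties, making γ the across-variety mean trend;
"Time" then tests γ = 0 (3 df), "Interaction" tests all δ = 0 (3(V−1) df),
and "Variety" tests equality of the anchored intercepts (start-of-harvest
differences, V−1 df). An anchored basis and post-hoc subtraction of the
fitted week-1 value give identical curves under least squares (asserted in
the tests).

Fits use observed cells only. Compounds unobserved in an entire variety
get aliased columns dropped greedily in design order (intercepts and the
common trend survive; interaction columns go first), are flagged partial,
and are excluded from tests whose contrast touches a dropped column.
Compounds with fewer observations than their design's rank are flagged
unfitted and excluded from testing.

Moderation follows the standard empirical-Bayes variance scheme: with
`e_g = log s_g² − ψ(d_g/2) + log(d_g/2)`, a tricube local-linear smoother
(span 0.5, nearest-neighbour bandwidth) of `e_g` on the average abundance
`A_g` gives the mean–variance trend; the excess of `var(e − e₀)` over the
sampling term `mean ψ′(d_g/2)` is inverted through the trigamma function
(Newton iteration) to give the prior df `d₀`, with `d₀ = ∞` when there is
no excess spread (an effective cap of 1e7 is used in F/t dfs). Posterior
variances pool `s̃² = (d₀ s₀² + d s²)/(d₀ + d)`; moderated F for a contrast
matrix L is `(Lβ)'(L C L')⁻¹(Lβ)/q / s̃²` on `F(q, d₀+d)`. BH adjustment is
computed in-house (six lines) and cross-checked against statsmodels in the
tests. By default the pipeline moderates each platform (GC–MS, LC–MS)
against its own ensemble — the two instruments have different noise floors —
while the library-level model pools unless asked.

Pointwise 95% CIs for the weekly curves use `t(d₀+d)` quantiles with the
posterior variance. On simulated data at residual sd 0.3 the week-5
coverage is ~95–96%: slightly conservative, as expected when the prior df
are large and the truth is inside the model family.

## The synthetic-study generator

The generator is the package's substitute for the unavailable field data
and defines the conditions everything is tested under: 8 varieties in 10
variety × cultivation series (three full 8-week series suitable for trend
modelling, shorter 3–4-week series, plus heated-field and greenhouse series
starting ~9 calendar weeks early), 3 biological replicates per
variety × week, injection batches of 32 with 5 pooled QCs placed first,
last and evenly between, ~366 compounds (~29% volatile). Log2 signal =
compound baseline (N(14, 2.5²)) + variety offset + template curve(week) +
batch effect (N(0, 0.5²)) + linear drift (slope N(0, 0.02²) per batch) ×
injection order + N(0, 0.3²) residual. QC rows carry the pooled mean of
the biological signal per compound plus the same technical terms — exactly
what a pooled aliquot measures. Missingness is intensity-dependent
left-censoring: cells vanish with probability
`logistic(steepness·(threshold − log2 x))` (threshold 11.5, steepness 1.5),
QC rows exempt; this exercises the ≥90%-missing exclusion rules, unlike
MCAR missingness.

True trend curves come from a repertoire of eight named shapes — flat,
strong decrease, decrease with late-variety rebound, single-variety
increase, mid-season peak with late decline, single-variety strong
decrease, and two mild (±2 logFC) patterns plus a late increase — with 45%
of compounds flat by default and the rest spread evenly. Two deliberate
choices: (i) template curves are projected onto the anchored 3-df spline
span on the week grid, i.e. the truth lives in the model family, which is
what makes the noise-free-recovery check exact rather than approximate;
(ii) the per-variety patterns of the seven non-flat shapes were chosen so
their concatenated curves have pairwise positive correlation ≤ ~0.25 —
templates more strongly positively correlated than the eigengene merge
threshold (0.75) are indistinguishable to a signed network *by
construction*, so module-recovery checks would measure the repertoire, not
the method.

What the generator does not emulate: non-linear drift, missingness that is
not intensity-driven (e.g. sporadic injection failures), compound-dependent
batch interactions, heteroscedasticity across the season, and correlated
residuals between co-eluting compounds. Passing tests therefore demonstrate
correctness of the machinery under the stated noise model, not robustness
to every artefact of real MS data.

## Network clustering

Signed adjacency `((1+r)/2)^β` with Pearson correlation (the modelled
curves are smooth; a robust correlation would change little) and β = 12
fixed. TOM follows the standard formula; 1 − TOM feeds scipy's
average-linkage tree. The tree cut is not a line-for-line port of the
reference hybrid algorithm: branches are found by cutting at a
deepSplit-mapped fraction of each (sub)tree's height (0.60/0.75/0.85/0.92/
0.98 for deepSplit 0–4) recursively, honouring the minimum module size;
leftover objects are then assigned PAM-style to the nearest module by
average dissimilarity, but only when they are closer to it than to the
network at large — this keeps genuinely isolated objects (and undersized
blocks) unassigned. Afterwards members with kME < 0.5 are pruned, modules
whose eigengenes are closer than the merge cut 0.25 are merged (closest
pair first, eigengenes recomputed each round, fixed point or 20 iterations)
and modules falling under the minimum size dissolve. Final labels are
C1..Ck by decreasing size; every unassigned compound records why
(tree cut / kME pruned / module dissolved). All tie-breaks are by lowest
index, so clustering is deterministic without seeds. The acceptance surface
is template recovery (ARI), not bitwise equivalence with any particular
implementation.

Module eigengenes are the first right singular vector of the module's
row-standardized trend matrix, sign-aligned to the module mean profile;
kME is the Pearson correlation of a member's profile with its eigengene.

## Reports

Fold changes are observed group means relative to each series' first
sampled week (no model), with compounds ≥90% missing over biological cells
excluded and listed; the denominator of that rule (all biological cells) is
configurable. Display copies are truncated to ±6; analysis copies never
are. HCA uses 1 − Pearson over pairwise-complete columns (FC matrices have
gaps); compounds with under 3 complete pairs against the rest are dropped
with a warning. PCA Pareto-scales after imputing each compound's missing
cells with its minimum observed log2 value (left-censoring rationale; PCA
is the only consumer of imputed data) and projects QC samples with the
biological ones so technical spread is inspectable. The flavour panel
(17 sensory-relevant compounds, configurable) is reported independent of
significance, with 2-fold-band crossings and CI-excludes-zero flags. The
cultivation contrasts fit a one-way variety × cultivation model per
calendar week, re-estimating the variance prior on each subset.

## Problem sizes and numerics

Verification runs use a 3-variety × 8-week × 3-replicate design (72
biological samples): 500 compounds × 20 seeds for the null calibration,
1000 compounds for CI coverage, 7 × 30 compounds for module recovery —
sizes at which every Monte-Carlo interval in the checks is decisively
narrower than the tolerance it is compared against, while the whole
verification suite runs in seconds. Least squares uses explicit normal
equations per missingness pattern (patterns are shared across compounds,
so the complete-data case is solved once); the trigamma inversion is a
Newton iteration with the standard asymptotic endpoints; BH is the exact
step-up with a reverse cumulative minimum. TSV outputs use a fixed
round-trippable float format, which is what makes repeated runs
bit-identical.

## Known limitations

- The drift model is linear per batch; strongly curved drift would leave
  structure the correction cannot remove (it would, however, still be
  visible in the retained QC diagnostics).
- The "Time" test is the joint test of the mean trend γ under sum-to-zero
  coding; a compound whose varieties change in exactly opposite ways loads
  on Interaction, not Time. The union Time ∪ Interaction — the set taken
  forward to clustering — is insensitive to this convention.
- The tree cut is a behavioural, not bitwise, reimplementation of the
  field-standard dynamic cut; on dendrograms with weak or heavily chained
  structure its module boundaries may differ from other implementations.
- With very few compounds (< 30) the variance-trend smoother falls back to
  a constant prior; moderation is then equivalent to simple pooling.
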