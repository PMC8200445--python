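# Methods

This note records the statistical model behind each pipeline stage, the
defaults and their units, what the synthetic data does and does not
emulate, and the decisions taken where the design was genuinely open.

## Study design and data model

Each condition group (e.g. disuse, young RET, older RET) contributes
several independent studies.  A study is a log₂ expression matrix
(genes × samples) with a paired design: every subject has exactly one
"pre" and one "post" sample.  Within-person pairing is central — all
differential tests operate on per-subject (post − pre) differences, which
removes between-subject baseline variation.

Preprocessing assumes platform-specific background correction happened
upstream.  The package applies: between-array quantile normalization
(each column forced onto the across-column mean empirical distribution;
ties receive the mean of the reference values across the tie span — a
deterministic convention), probe→gene collapse by arithmetic mean over
probes sharing a gene ID (unmapped probes dropped and listed, never
silently kept), intersection of every study's gene list (all downstream
matrices align row-for-row), and removal of genes with zero variance in
any study (Pearson correlation is undefined for them).  A `--log2` flag
applies log₂(x+1) for inputs delivered on the raw intensity scale.

## Gene-level meta-analysis

Per study, the paired contrast reduces to a one-sample test on the
difference matrix D (genes × subjects).  Variance moderation follows the
hierarchical model s²_g ~ s₀²·F(d, d₀) with d = n−1: the first two moments
of log s²_g (digamma/trigamma identities) give method-of-moments
estimates of (d₀, s₀²); when the observed spread of log s²_g does not
exceed the sampling floor trigamma(d/2), d₀ = ∞.  If all variances are
literally identical the prior variance is that common value (the
log-scale bias correction would otherwise overshoot on a degenerate
input).  The moderated statistic uses the posterior variance
(d₀s₀² + d·s²_g)/(d₀ + d) with d₀ + d degrees of freedom; d₀ = 0 recovers
the classical t, d₀ = ∞ the normal test.  The fit is per study — platforms
differ in variance scale — and is cross-checked in the test suite against
an independent R implementation of the same empirical-Bayes scheme.

Per-study p-values are right-tailed, so a coherent down-shift yields p
near 1.  They are combined unweighted: Z = Σ Φ⁻¹(1−pᵢ)/√k (p clamped to
[1e−15, 1−1e−15] before the probit).  Purely right-tailed aggregation
cannot flag down-regulation, yet both directions are of interest; the
final meta significance is therefore **two-sided**, p = 2(1 − Φ(|Z|)),
with direction from sign(Z).  The right-tailed meta p is kept as a column
for rank-based consumers.  BH correction is applied across genes, and the
DE call requires all of: q ≤ `alpha_meta` (0.1), |meta mean log₂FC| >
`lfc_min` (0.1, log₂ units), and a common fold-change sign across every
study of the group.  The conjunction is deliberately strict: it selects
changes reproduced in every study rather than driven by one.

## Consensus networks

Signed adjacency Adj = (½(1+cor))^β maps correlation −1→0, 0→0.5^β, +1→1,
so anti-correlated genes are *not* connected.  β is chosen per study as
the lowest integer in 1..`beta_max` (20) whose scale-free topology fit
reaches `scale_free_r2_min` (0.8) with a negative log-log slope; the fit
bins whole-network connectivities into 10 equal-width bins and regresses
log₁₀(bin frequency) on log₁₀(mean connectivity).  If no β qualifies (the
synthetic background is not scale-free, and pure noise never is), the
argmax-fit β is used and flagged in the report — chosen β values are
always written out because they are data-dependent.

The topological overlap matrix,
TOM_ij = (ℓ_ij + A_ij)/(min(kᵢ,kⱼ) + 1 − A_ij) with ℓ_ij = Σ_u A_iu A_uj,
re-expresses connection strength through shared neighbourhoods and is
less noisy than raw adjacency.  Per-study TOMs are made comparable by
single-quantile scaling at `calibration_quantile` (0.95, off-diagonal):
every TOM is multiplied by (target q)/(own q) and clipped to [0,1].  The
target is the **median** of the per-study quantiles.  A fixed-study
reference was considered and rejected: scaling is only
reference-independent without clipping, and if the reference study
happens to carry a degenerate network (argmax-β fallback), every other
TOM is crushed toward zero before the minimum is taken, destroying the
consensus — the median target is insensitive to one outlier study.  The
consensus TOM is the element-wise minimum of the calibrated TOMs: an edge
is only as strong as its weakest study, which is what makes the modules
"consensus" structures.

Module detection clusters dis-cTOM = 1 − cTOM by average linkage, then
cuts the dendrogram in two deterministic stages: a static cut at 0.99 of
the top merge height, followed by recursive splitting of any branch whose
internal merge heights contain a gap ≥ 0.02 — provided cutting inside
that gap leaves at least two branches of `min_module_size` (50); without
that guard the largest gap typically sits among a module's lowest merges
and fragments it.  Accepted clusters below the minimum size dissolve into
the unassigned label "M0".  Because average linkage on a dissimilarity
with a noise floor lets unrelated genes accrete one-by-one onto genuine
branches below the static cut, each detected module is pruned once by
consensus membership: a gene stays only if its correlation with the
module eigengene reaches 0.5 in *every* study.  Pruning removes genes (to
M0) but never reassigns them between modules, so it is a reproducibility
filter, not an iterative partition optimizer.  On the standard benchmark
(5 modules × 80 genes, within-module correlation 0.6, 3 studies × 20
pairs) this recovers all five modules with adjusted Rand index ≈ 0.9,
while pure-noise inputs yield no modules.

Module eigengenes are the first right-singular vectors of the z-scored
module submatrix per study (unit norm, sign-aligned with the mean module
profile; variance explained recorded).  Modules merge greedily while the
*minimum* eigengene correlation across studies exceeds `merge_cor_min`
(0.75) — the minimum rule again enforces consensus — with eigengenes
recomputed after every merge until a fixed point; final labels are
M1..Mk by descending size.

## Module-level meta-analysis

Eigengene scores are standardized to unit variance within each study and
the per-subject (post − pre) differences tested with an ordinary paired
t (one series per module gives no ensemble to moderate over).  Stouffer
combination, two-sided conversion and BH across the network's modules
mirror the gene level.  The effect-size criterion needs a unit: an
eigengene has no log-fold-change scale, so the same 0.1 threshold is
applied to the meta mean shift in within-study SD units — a documented
convention, configurable through the same `lfc_min` knob.

## Cross-condition comparison

RRHO ranks each condition's genes by sign(meta log₂FC)·(−log₁₀ q)
(q floored at 1e−300; rank ties broken by gene ID).  The grid steps are
`rrho_step_fraction` (1%) of the list length; cell (i, j) scores the
hypergeometric upper-tail p of |top-i(A) ∩ top-j(B)| against the shared
universe.  Concordant quadrants pair tops with tops and bottoms with
bottoms; discordant quadrants pair the top of one list with the bottom of
the other.  Thresholds per side never cross the zero-score boundary, so
an "up" set can only contain genes actually scored upward.  The
maximizing cell per quadrant defines the optimal overlap set.  Gene
classes follow from the DE calls plus these sets: common (concordant or
discordant) requires DE in both conditions *and* membership of the
direction-matched optimal set; unique requires DE in exactly one
condition *and* absence from every optimal set; everything else is
"none".  The classes are mutually exclusive and exhaustive by
construction.

Module labels between two networks are aligned by one-sided Fisher exact
tests on all module pairs, BH across cells, then greedy assignment in
ascending p among significant cells (corrected p < 0.05), no label used
twice; unmatched source modules take fresh labels.  Greedy matching
follows the field's convention; the test suite checks it against an
exhaustive assignment oracle on small cases.

## Hubs and enrichment

kME is the correlation of a gene with its own module's study-specific
eigengene (intramodular by design), with an upper-tail correlation-test p
(signed networks make membership one-sided).  Consensus membership is the
Stouffer Z of these p-values across studies; within each module, genes
strictly above the linearly interpolated `hub_percentile` (0.85) quantile
are consensus hubs — ties at the threshold are excluded, making the rule
deterministic and leaving ~15% of module genes as hubs when values are
distinct.  Hub sets of matched modules are compared with a
hypergeometric overlap test on the shared analysis universe (the test is
a documented choice; several reasonable tests exist).  Finally hubs are
overlaid with RRHO classes: a hub is a candidate when its gene class
matches its module's differential-regulation scenario (e.g. a module up
in condition A only pairs with class unique-A-up).

Over-representation uses one-sided Fisher tests of a query list against
GMT terms intersected with the analysis universe — the post-intersection
gene set, not the genome, so untested genes cannot inflate enrichment —
with BH across terms and `ora_alpha` (0.05).

## Synthetic data

Per study, gene g of subject s at timepoint t is

x = μ_g + λ_g(f_{m(g),s} + shift_m·[t=post]) + effect_g·[t=post] + ε,

with μ_g ~ N(8, 1.5²) (log₂ scale), one latent factor per planted module
and subject shared between that subject's two samples (this is what makes
the design "within-person"), ε ~ N(0, σ_d²), and loadings chosen so the
expected within-module correlation matches the target (correlation-scale
loadings jittered ±0.1 around √target, so some genes are more central
than others — hub selection is tested against exactly this gradient).
Defaults mirror the emulated study conditions: 3 studies per group, 20
pairs each, 4000 genes, five 80-gene modules at correlation 0.6, noise SD
0.5, gene effects ±0.5 log₂ units, module shifts ±0.8 SD.  Effect classes
(shared / unique / inverted) are planted on disjoint background genes so
the RRHO quadrant truth is unambiguous.

What the generator does **not** emulate: probe-level structure, batch or
surrogate-variable effects, heavy-tailed noise, correlated effect sizes,
overlapping modules, or count-based (RNA-seq) sampling.  Passing tests
therefore demonstrate correctness of the machinery and calibration under
a faithful idealization of the design, not robustness to every artefact
of real array data.

## Problem sizes and numerical conventions

The test suite and the acceptance script run at the sizes above or
modest multiples (up to 4000 genes end-to-end), chosen as the package's
standard benchmark conditions.  Seeds fix all randomness; the
configuration and seed travel with every run in a JSON report.
Numerical edge cases are handled explicitly and logged: p-values clamped
at 1e−15 before the probit, q floored at 1e−300 before logs, degenerate
zero-variance rows excluded by name, all-equal connectivity defined as
scale-free fit 0, single-column quantile normalization a warning no-op.

## Known limitations

- The dendrogram cut is a deterministic approximation of adaptive
  tree-cut practice; very close or nested modules that require the
  PAM-like reassignment stage will not be separated.
- Stouffer combination is unweighted; studies with very different sample
  sizes contribute equally (a documented simplification).
- Discordant (inverted) regulation is the lowest-powered RRHO class at
  small problem sizes, as the analysis scripts report.
- BH corrections are applied within their natural families (genes within
  a group; modules within a network; cells within a match table; terms
  within a collection), never pooled across families.
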