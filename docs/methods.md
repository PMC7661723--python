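# Methods

## Model and procedure

The pipeline classifies transcription factors (TFs) for a cell-fate
conversion experiment with four sample roles: a target state (embryonic
stem cells, ESC), a start state (naive fibroblasts), a vector control
(GFP-transduced fibroblasts), and induced cells (OSKM-transduced
fibroblasts harvested at two time points, 48 h and 72 h). Counts are
normalized genome-wide with median-of-ratios size factors *before* any TF
subsetting, and Benjamini–Hochberg q-values are likewise computed per
contrast over all genes in the matrix and only then restricted to the TF
catalog; this matches the usual practice of running the DE analysis on
the full transcriptome and extracting the TF census afterwards.

### Differential expression

For a two-group contrast the engine computes per-gene group means of
normalized counts, a method-of-moments negative-binomial dispersion
(variance = μ + αμ², the two per-group estimates averaged and floored at
1e-8), and a Wald statistic on the log2 fold change with a delta-method
standard error. Two numerical choices matter at typical replicate counts
(n = 4):

* **Dispersion moderation.** The raw moment estimator at n = 4 is far too
  noisy to use per gene: genes with by-chance-low sample variance get
  drastically understated standard errors (anticonservative tails) and
  genes with by-chance-high variance lose power. The estimate is
  therefore shrunk toward the across-gene median dispersion with a prior
  weight of 6 degrees of freedom against the 6 residual degrees of
  freedom — the same motivation as the limma/edgeR variance shrinkage,
  while remaining far simpler than DESeq2's Cox–Reid/MAP machinery.
* **Reference distribution.** The Wald statistic is referred to a t
  distribution with residual + 9 degrees of freedom. The extra 9 df
  credit the moderated variance with the information carried by the
  shrinkage target, which is estimated from the whole gene ensemble and
  is therefore much more informative than its formal prior weight; the
  value was set by null-simulation calibration so the empirical type-I
  error sits at its nominal level across means (30–200) and dispersions
  (0.01–0.2). With a plain normal reference the same statistic rejects at
  roughly 0.09 at a nominal 0.05.

No fold-change shrinkage is applied, so the classifiers' 2-fold
thresholds act on plain ratios of normalized group means. When either
group mean is exactly zero, fold changes use a pseudocount of 0.5 on both
means; genes with zero counts in both groups get p = q = NA and are
routed to the activity-based categories only. Identical groups yield
log2fc = 0 and p = 1 exactly. Swapping the contrast's groups negates
log2fc and preserves p.

### State classification

Activity uses the fixed normalized-count threshold of 50: a gene is
active in a group only when *every* replicate exceeds 50, and inactive
only when every replicate is below 50. Both comparisons are strict, so a
replicate exactly at 50 satisfies neither; such genes can only fall into
enriched or marginal categories. Rules are applied first-match in the
order inactive_both → activatome → erasome → up-enriched → down-enriched
→ equal_active → marginal. Following the wording of the defining
criteria, the exclusive sets (activatome/erasome) require fold strictly
greater than 2 while the enriched sets require at least 2-fold; fidelity
to the stated rules was preferred over symmetry. `StateThresholds`
separates the activity and inactivity cutoffs (both default 50) so that
tightening the activity requirement alone drains the exclusive sets
monotonically.

### Response calling and irresponsiveness

Responses are conjunctions over the full reference × time grid: up means
fold ≥ 2 toward induction with q < 0.01 in every contrast (both
references, both time points), down is the mirror. Designs with a single
reference degrade to whatever grid is configured. The exogenous factor
symbols (POU5F1/OCT4, SOX2, KLF4, MYC) are flagged and never counted
among responsive TFs, since their signal is transgene expression.

A reprogramome member is irresponsive when, in every contrast, its fold
change is below 2 in either direction *and* no contrast reaches q < 0.01
(a significant 1.5-fold change disqualifies), *unless* its induced
expression has come within 2-fold of the target-state mean at any time
point (then it is excluded from the irresponsive list regardless of
significance — it effectively arrived). For up-reprogramome genes only,
a gene inactive in the start state that remains inactive after induction
(every induced replicate < 50) is irresponsive outright, even when its
fold change is large and significant. The "remains inactive" condition is
read as requiring prior inactivity: a fibroblast-active gene that gets
silenced by induction responded (downward) and is not captured by this
rule.

### Legitimacy

Verdicts come from a total table over (direction × relaxed enrichment):
up × target-higher and down × start-higher are legitimate; the opposite
pairings are wrong; equal or silent-in-both genes make any response
unwanted. Relaxed enrichment uses q < 0.05 at any fold, because the
strict reprogramome criteria are deliberately conservative and the
responsive sets are heavily biased toward the matching enrichment; the
strict calls remain the reprogramome definition (two-tier usage).

Legitimate responses are subclassified deterministically in
log2(normalized + 1) space: the induced samples' mean profile is compared
with the target and start group means per gene. Overshooting the target
mean by more than 2-fold in the direction of change is *over*; otherwise
moving strictly closer to the target than to the start (and in the
direction of the call) is *proper*; the remainder is *insufficient*.
This replaces a visual "clusters with the target cells" judgement with a
reproducible rule; `clustering_report` reproduces average-linkage
correlation-distance clustering for concordance checks. The 2-fold
overshoot margin is configurable; the class is named in the field without
a published threshold, so a round value matching the other fold
thresholds was chosen.

## Synthetic data

The generator emulates the study design: five groups (ESC, naive
fibroblast, GFP fibroblast, OSKM at 48 h and 72 h), four biological
replicates each, negative-binomial counts with dispersion 0.05 and
log-normal library-size factors (sd 0.15). Genes are planted in blocks
(state class × response class) with explicit means: the base active level
is 400 and the silent level 5 (well clear of the activity threshold 50),
and the default enriched fold is 8. Blocks exercising the insufficient
and over trajectories use wider state folds (e.g. 32-fold enrichment with
an induced endpoint a quarter of the way up) so that the planted
trajectory geometry is unambiguous — at an 8-fold state enrichment the
proper/insufficient boundary would sit exactly at the planted midpoint.
Induced means interpolate geometrically from the fibroblast level toward
each block's endpoint (fraction 0.8 at 48 h, 1.0 at 72 h), giving
realistic partial progress at the earlier time point while keeping the
planted response above the 2-fold calling threshold at both times. A
deliberately hostile marginal block sits at activity ≈ 50 and fold ≈ 2;
its recovery is reported, never asserted. The default universe is 504
genes (500 study genes + the four factor transgenes).

What the generator does *not* emulate: platform-specific biases
(Illumina vs DNB-seq), GC/length effects, correlated genes, outlier
replicates, or transgene-vs-endogenous read assignment. Passing recovery
tests therefore demonstrates that the classification rules are
implemented correctly and are recoverable under the stated generative
model, not that the thresholds are optimal for any particular real
dataset.

With ~56% of planted genes genuinely differential between the two states,
the balanced up/down design keeps the median-of-ratios assumption intact;
test fixtures that plant one-directional effects embed them in a
mostly-null background for the same reason.

## Problem sizes and determinism

Default analyses run on the 504-gene universe (20 samples); the null
calibration uses 4000 genes × 8 samples; the replicate-count sweep fits
the full pipeline at n = 2, 4, 6 with dispersion 0.15. All randomness
flows through a single integer seed into `numpy.random.default_rng`;
identical seeds reproduce byte-identical counts, tables, and summaries.

## Known limitations

* The DE engine is intentionally minimal: no multi-factor designs, no
  batch correction, no independent filtering beyond the all-zero rule,
  and no exact DESeq2 parity (a cross-check test confirms strong but not
  perfect agreement on significant calls).
* With many strong true effects, BH at q < 0.01 admits the expected small
  number of false discoveries among truly-null genes; a handful of planted
  equal-expression genes therefore land in `marginal` on any given seed.
  The relaxed q < 0.05 tier likewise lets an occasional null gene into an
  enrichment class.
* Family assignment falls back to a symbol-prefix heuristic when the
  catalog carries no annotation column; prefix tallies are an
  approximation to curated family membership.
* The two-dataset comparison rescues unique calls at p < 0.05 (not q),
  mirroring how that one analysis is conventionally reported; this is an
  intentional inconsistency with the q-based main criteria.
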