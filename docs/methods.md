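# Methods

This note documents the models, conventions, and numerical choices
behind `markcast`, and what its synthetic-data tests do and do not
establish.

## Coordinate and overlap conventions

All intervals are BED-style 0-based half-open `[start, end)`; no 1-based
conversion exists anywhere in the codebase, which removes the classic
off-by-one failure mode when mixing peak files and region files. Two
intervals overlap when they share at least `min_bp` bases (default 1 bp,
the bedtools-intersect convention); `[a,b)` and `[b,c)` never overlap.
Strand is ignored throughout — histone-mark peaks and enhancer assays
are strand-agnostic. Duplicate identical regions are retained on parsing
(peak callers can emit them; deduplication is the caller's decision),
and overlapping peaks within one dataset are not merged — presence/
absence featurization is unaffected by either choice. Overlap queries
binary-search sorted per-chromosome start arrays and vectorize the
candidate window; equivalence with the all-pairs oracle is property-
tested.

## Featurization

Features are strictly binary presence/absence of overlap, one column per
(context, mark) dataset. Coverage fractions and signal strengths are
deliberately out of scope: the question under study is what the mere
location of a mark in another context tells you, and binary features
keep the classifiers' inputs directly comparable across datasets with
different peak-calling depths.

## Matched background sampling

For each positive, `ratio` negatives (default 10) are drawn on the same
chromosome with exactly the same length by rejection sampling: a start is
drawn uniformly over all in-bounds placements and redrawn (up to
`max_tries`, default 1000) while the candidate overlaps any exclusion
region. Exclusions conventionally comprise all known-active regions
(positives plus every labeled enhancer of any tissue). Per-positive exact
length matching is strictly stronger than matching the length
*distribution* and is what randomBed-style tools achieve when given
per-record lengths. Negatives may overlap one another: preventing
self-overlap would bias placement of long regions on crowded
chromosomes. Negatives are drawn once per scenario (one draw shared by
all folds and classifiers within it), keeping within-scenario
comparisons paired; the draw seed is recorded in the report provenance.

## Classifiers and evaluation

Six algorithms run with fixed hyperparameters (any other value requires
an explicit override flag): random forest (10 trees, max depth 5, Gini),
linear SVM (ℓ2 penalty, C = 0.1), AdaBoost (50 depth-1 stumps, learning
rate 1 — stump depth is exposed as `base_max_depth` for users who want
deeper base learners), Gaussian naive Bayes, decision tree (depth 5,
Gini), and 3-nearest-neighbours. Gaussian — not Bernoulli — naive Bayes
is used on the binary features, mirroring common practice in the studies
this pipeline emulates, even though Bernoulli NB is the textbook match.
Scores are: per-tree-averaged class-1 probability (forest), signed
decision values (SVM, AdaBoost), posterior log-odds (NB), class-1
probability (tree), and the fraction of the 3 nearest neighbours labeled
1 (KNN; Euclidean distance on the binary features, distance ties broken
by training-row order via a stable argsort — library neighbour searches
do not guarantee this).

Cross-validation is stratified five-fold. Stratification is the
defensible default at 1:10 class imbalance, where unstratified folds can
lose every positive; if a class has fewer members than folds, the split
degrades to a plain shuffled partition. Per-fold ROC curves are computed
on held-out rows only; AUC is the Mann–Whitney rank statistic with
midrank tie correction, which equals the trapezoidal area under the
stepped curve (asserted in tests). The reported `mean_auc` is the
arithmetic mean of fold AUCs — never the area of an averaged curve. The
displayed curve is a vertical average (TPR at fixed FPR) over a
101-point grid with endpoints pinned to (0,0) and (1,1).

Feature importances are normalized Gini (mean decrease in impurity) from
a single full-data fit, not averaged over folds — one table per task is
the convention being reproduced; `cross_validate(compute_importances=…)`
exposes the choice. A caveat found while testing: at a fixed seed a
random forest's importances are not exactly invariant under feature
permutation, because per-tree feature subsampling consumes the RNG in
column order; the exact permutation-equivariance property holds for the
full-search decision tree and is asserted there.

## Enrichment statistics

Per dataset, a 2×2 table counts overlapped/non-overlapped positives and
negatives. The summary is the sample odds ratio `(a·d)/(b·c)` — reported
as `inf` when `b·c = 0` with `a·d > 0`, and 1 when both products vanish —
with a Haldane–Anscombe (+0.5) variant available for plotting finite
values. The two-sided Fisher p-value follows the small-p-values
convention: the sum of hypergeometric probabilities, over all tables with
the observed margins, no larger than the observed table's. Point
probabilities share the denominator `C(n, a+c)`, so the implementation
compares exact integer numerators (`math.comb`); tie classification is
therefore exact, with no floating-point or log-space ambiguity, and the
final division is the only inexact step. Tests verify agreement with an
independent Pascal-triangle enumeration on every table with total ≤ 60
(to 1e-10 relative) and cross-check scipy at its own 1e-7 tie-guard
tolerance. Benjamini–Hochberg adjustment across datasets is available
but off by default; raw p-values are the primary report.

## Synthetic studies

The generator emits a complete study — genome, labeled truth enhancers,
per-context peak sets, manifest — with the statistical structure that
makes cross-context transfer measurable:

- **Enhancers.** Target and other-tissue enhancers are placed uniformly
  and non-overlapping, lengths uniform in 500–3,500 bp, on a 4 × 10 Mb
  genome (300 target + 300 other across 3 tissues by default).
- **Developmental decay.** A lineage context at stage `s` covers each
  target enhancer with probability `p(d) = p_max · e^(−λd)`,
  `d = |s − target_stage|` (defaults `p_max = 0.9`, `λ = 0.35`, stages
  0–10 with target 5). Exponential decay is the simplest monotone model
  consistent with the proximity effect being emulated; no functional form
  is claimed for real data. Covering peaks have width uniform in
  500–2,000 bp and a uniform offset constrained to keep ≥ 1 bp overlap.
- **Independence.** Marks are drawn independently per (context, mark,
  enhancer). Real H3K4me1/H3K27ac are correlated within a context;
  independence is chosen so closed-form checks (per-context binomial
  frequencies) are available. A shared latent activity bit would add
  realism and is deliberately left out of this version.
- **Confounds.** A fraction `shared_frac = 0.2` of other-tissue
  enhancers is ubiquitously active: active in *every* context and
  therefore marked in each context with probability `p_max` —
  independent per context, not deterministically, since ChIP-seq misses
  active elements too. (Deterministic marking would give these elements
  *more* marks than any true target enhancer and make them trivially
  separable — inverting, rather than creating, the intended confound.)
  Non-target tissue contexts additionally mark their own tissue's
  enhancers at `p_max` and target enhancers at `p_max · shared_frac`.
  Each dataset receives Poisson(`p_bg` × genome Mb) uniformly placed
  spurious peaks (`p_bg = 5`/Mb); spurious peaks may hit enhancers by
  chance and are not rejected, since rejecting them would distort the
  null.
- **Cross-species.** Every lineage dataset gets a degraded copy:
  regions dropped independently with probability `unmappable_frac = 0.23`
  (the canonical unreliably-mapped fraction for human–mouse enhancer
  sets) and survivors shifted by `round(N(0, 300 bp))`, clipped to
  bounds at constant length. This emulates liftOver-style coordinate
  transfer without chain files.

Everything is deterministic given one seed (numpy `SeedSequence`
spawning, one child per dataset), and export → import round-trips
byte-identically.

**What a green test establishes.** The synthetic world validates the
*machinery*: that the pipeline recovers planted orderings (proximal
contexts more important and more enriched, lineage endpoints hardest to
impute, background easier than other-enhancer negatives for lineage
features) and that its statistics match exact oracles. It does not
establish real-data performance: synthetic marks are independent across
contexts given the enhancer, peak widths and placements are uniform
rather than signal-driven, and no sequence composition, mappability, or
assay-depth structure exists. One structural difference surfaced by the
generator itself: with *other-tissue* features, other-enhancer negatives
are easier than background (the negatives' own strong mark signature is
informative), whereas real studies find the reverse; conclusions about
that comparison should come from real data, and the package only asserts
the ordering for lineage features.

Observed marking frequencies under the full default configuration exceed
`p(d)` by ~1–2% (chance overlap with spurious peaks), so the closed-form
decay law is verified with confounds disabled and the monotone ordering
is verified under the full configuration.

## Experiment grid and reproducibility

`run_report` executes six scenarios (3 feature subsets × 2 negative
modes, random forest), the six-classifier sweep on identical folds
(certified by a fold-index digest), lineage enrichment against a matched
background draw, and mark leave-out (fresh matched negatives per held-out
dataset, positives = that dataset's peaks, features = all other lineage
datasets). Every component's seed derives from the master seed by stable
hashing (CRC-32) of the component's name, so adding or reordering
scenarios cannot shift any result; two runs with the same master seed
produce byte-identical JSON. Provenance (config, seeds, an SHA-256
digest of all study intervals) is embedded in the report.

## Degenerate inputs and edge rules

- Parsing rejects zero-length and negative intervals with the offending
  line number; `track`/`browser`/`#` lines are tolerated.
- Single-class labels raise an evaluation error before any training.
- A tree fit that never splits (all-constant features) yields uniform
  importances rather than a 0/0.
- Empty peak sets produce all-zero feature columns (retained) and
  `(OR, p) = (1, 1)` enrichment rows.
- Fisher tables with a zero margin have exactly one realizable table and
  return `p = 1`.
- Background sampling raises a named error when a negative cannot be
  placed (e.g. exclusions tile the chromosome) rather than looping
  forever.
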