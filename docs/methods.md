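# Methods

## Model and procedure

GSANOVA tests whether a predefined gene set is enriched for expression
changes across k ≥ 2 sample groups. The gene-level statistic is the
one-way ANOVA F,

f = [(n − k)/(k − 1)] · [Σᵢ nᵢ(x̄ᵢ − x̄)²] / [Σᵢ Σⱼ (xᵢⱼ − x̄ᵢ)²],

computed on log-scale expression estimates. Because F is one-sided by
construction (any departure of group means from the grand mean increases
it), all p-values are upper-tail. The set-level statistic is the mean F
over member genes present in the matrix, standardized by the mean and
sample standard deviation (ddof = 1) of the mean-F scores of
`n_random_sets` gene sets of identical size drawn uniformly without
replacement from the full gene universe — including unexpressed genes,
which carry f = 0, so sparse universes correctly deflate the null mean.
Inference permutes the full group-label vector uniformly (group sizes are
preserved automatically; no stratification): each permutation recomputes
every gene's F and re-standardizes every set with freshly drawn random
sets. The per-set nominal p and the pooled p against the global null
(permutation scores combined across sets) both use the add-one estimator
p = (1 + #{null ≥ obs})/(B + 1), which is a valid p-value and never zero.
q-values are computed from the *pooled* p-values — the global null is
what makes set-to-set comparisons commensurable — as π₀ · BH, with π₀
fixed at 1 by default or estimated by the cubic-smoother-on-a-λ-grid
procedure (`pi0_method="storey_smoother"`). Both p columns are reported.
Enrichment is called at q < `q_cutoff` (default 0.25).

A note on the between-group term: the method's printed source formula
contains a degenerate numerator (the deviation of the grand mean from
itself); this package implements the standard between-group sum of
squares Σᵢ nᵢ(x̄ᵢ − x̄)², which is the only reading consistent with
"ratio of between-group to within-group variation".

## Expression estimates

Counts are normalized by median-of-ratios size factors (the median over
genes, restricted to genes with positive counts in every sample, of the
count-to-geometric-mean ratio) and transformed as
log2(count/s_j + pseudocount), with pseudocount 1. This is a plain
variance-stabilizing log transform: the enrichment machinery only needs
an approximately homoscedastic expression estimate, and the transform
used is recorded in `ExpressionMatrix.transform_tag`. Shrinkage-based
regularized-log transforms from negative-binomial DE packages can be
substituted by constructing an `ExpressionMatrix` directly. Two practical
consequences of median-of-ratios normalization are worth knowing: scaling
one library rescales all factors by a common constant (the scaled sample
enters the geometric-mean reference), and a doubled library is removed
only up to a uniform additive offset on the log scale — between-sample
structure, which is all the F-statistic sees, is preserved exactly.

## Degenerate F cases

- Unexpressed genes (total count below `expressed_min_total`, default 1,
  i.e. all-zero) are assigned f = 0 before any set is scored.
- Zero within-group and zero between-group variation (a constant gene)
  gives f = 0.
- Zero within-group variation with a real between-group difference would
  give f = ∞; it is capped at `f_cap` = 1e12 so that set means and null
  standard deviations stay finite. Sums of squares below a relative
  threshold of 1e-12·(mean squared value + 1) are treated as rounding
  dust, not variation.
- Designs with n ≤ k have no within-group degrees of freedom and are
  rejected.

## Randomness, reproducibility, threading

All randomness flows from `GsanovaParams.rng_seed` through a
`SeedSequence` tree: one child stream per permutation plus one for the
observed-data standardization. Results are therefore bit-identical across
repeat runs *and* across `threads` settings (threads only distribute the
per-permutation streams). Random sets are redrawn inside every
permutation by default, keeping the null exchangeable with the observed
standardization; `reuse_random_sets=True` draws the index sets once and
reuses them across permutations for speed at the cost of slightly
dependent nulls. Without-replacement sampling uses duplicate-rejection on
integer draws (exact, fast when set size ≪ universe) and falls back to
partial shuffles when sizes approach the universe. When the universe
admits no more than `n_random_sets` distinct subsets of the requested
size, the implementation enumerates them all instead of sampling — exact
on toy problems and unreachable at realistic universe sizes (C(N, s) is
astronomical for N in the thousands).

## Sample QC

Outlier screening computes pairwise Euclidean distances between samples
on the transformed matrix, builds an average-linkage dendrogram (emitted
as Newick-like text for manual review), and flags any sample whose
nearest-neighbour distance exceeds `multiplier` (default 2) times the
median nearest-neighbour distance. The rule is a deliberate, reproducible
stand-in for the common practice of excluding outliers by visual
inspection of the dendrogram; the dendrogram is still reported so the
automatic call can be overridden. Average linkage is the conventional
default for sample QC and is recorded in the report.

## Downstream computations

Two-time-point log2 fold changes are classified by sign into quadrants
I (+,+ sustained up), II (−,+ transient down then up), III (−,− sustained
down) and IV (+,− transient up then down). Exact zeros are boundary cases
that realistic estimates never produce; they are reported as unclassified
rather than silently assigned. The classification uses whatever fold-
change estimates the caller supplies (shrunken or not) — estimation is
upstream. qPCR quantification is (1 + E/100)^(−Ct) with the primer
efficiency E in percent; an efficiency ≤ 1 triggers a units warning since
it is almost certainly a fraction. Target genes are normalized to a
reference gene by simple division.

## Synthetic data

The generator emulates the motivating study design: 3 groups
(vehicle, 30-minute and 90-minute treatment arms) × 4 replicates,
~12 000 genes, negative-binomial counts with a single common dispersion
(default 0.1, typical of bulk RNA-seq biological replicates), per-gene
base means log-uniform on [10, 1000], and per-sample size factors uniform
on [0.7, 1.4]. A `small-n` preset mirrors a post-QC unbalanced 2/4/3
design. Spiked gene sets shift their members' group means by
`spike_shift` log2 units (default +1.0, a two-fold change) in designated
groups — by default the last group only, mimicking a late response.
What the simulation does **not** emulate: per-gene dispersion trends,
gene–gene correlation beyond set-driven mean shifts, batch structure, and
annotation noise (partially overlapping or mislabeled sets). Passing
calibration and power tests on this generator therefore demonstrates
correctness of the inference machinery under the assumed sampling model,
not robustness to correlated real data, where permutation of whole
samples remains valid but random-set standardization can be conservative
or liberal depending on co-expression within sets.

## Problem sizes used in validation

The test suite and acceptance script validate at these scales, chosen to
exercise the study-like regime: oracle agreement on 100 random
10 × 10 three-group matrices; exhaustive enumeration on 4–10-gene
universes and the 90 distinct label assignments of a 6-sample, 3-group
toy; type-I calibration on 12 000 genes × 200 null sets with 500
permutations and 1000 random sets; power on 20 replicates of a 40-set
collection with 250 permutations and 500 random sets. Larger settings
change runtime, not conclusions: the estimators are unbiased at any B,
with Monte-Carlo error shrinking as 1/√B.

## Known limitations

- The log2(normalized + 1) transform under-stabilizes variance for very
  low counts compared to shrinkage transforms; with few replicates this
  inflates within-group variance estimates for weakly expressed genes
  (a conservative direction for F).
- Random-set standardization treats genes as exchangeable; strongly
  co-expressed sets violate this, and the pooled null inherits any such
  miscalibration.
- The permutation count bounds the smallest attainable nominal p at
  1/(B + 1); with B = 1000 and many sets, pooled p-values provide the
  finer resolution that q-values need.
- Set-size filters (`min_set_size`, `max_set_size`) default to off;
  singleton sets are legal but their "enrichment" is just a gene test.
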