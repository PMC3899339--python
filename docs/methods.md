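# Methods

## The transfer problem

Gene essentiality is assayed genome-wide in few microorganisms, under
particular growth conditions, with assay-dependent reliability. The
package treats annotation transfer as a supervised problem: features of
species *j*'s genes are scored by a classifier fitted on species *i*'s
labeled genes, and the quality of the transfer m_ij (AUC or PPV@k) is
studied as a function of properties of the (i, j) pair — label quality,
growth condition, divergence time, lifestyle — and of how training sets
are sized, pooled, and selected.

## Classifier

Naive Bayes with Gaussian class-conditionals for continuous features and
Laplace-smoothed multinomials (default α = 1) for categorical ones
(domain type, phyletic-age group). Scoring is done entirely in log
space; a posterior is always finite and in [0, 1] even for thousands of
extreme feature values.

Choices worth stating:

- **Normalization.** Raw feature units (expression platforms, network
  sizes, genome lengths) are incomparable across species, so the default
  recipe rank-transforms every continuous column *per species* to
  rank/(n+1) ∈ (0, 1) (average ranks for ties; a constant column maps to
  0.5). Z-scoring and no-op recipes are available; the recipe identifier
  travels with the fitted model. Count-valued features (NP, NS, NEH,
  NNH) are treated as continuous after rank normalization.
- **Missing data** are marginalized, not imputed: a missing feature
  contributes no factor at fit or score time. This preserves the naive
  factorization exactly and keeps a gene with no features at the prior.
- **Degeneracies.** Variances are floored at 1e-9 (on the normalized
  scale) to prevent spikes from near-constant features; a feature with
  no observed value in one class is flagged unusable and skipped; a
  categorical level unseen in training receives its smoothed
  pseudo-count mass α / (n_c + α(K+1)).
- **Integrated training sets** are plain concatenation of the member
  species' per-species-normalized labeled tables; pooling several
  datasets is provably identical to fitting one concatenated table.

## Features

The 15 features follow standard definitions; the implementation choices
that the definitions leave open are:

- **DoC** aggregates all of a gene's domain hits as Σ bit-score /
  Σ domain-length (all evidence, length-weighted); a best-hit-only
  reading would discard multi-domain evidence. **DoT** is the
  top-scoring hit's domain id, ties broken lexicographically.
- **CAI** is the geometric mean of relative adaptiveness over codons
  with synonymous choice (stops, ATG, TGG excluded). Weights come from a
  user-supplied reference gene set (default: all genes of the species);
  codons absent from the reference receive a 0.5 pseudo-count before
  normalization so weights stay in (0, 1].
- **Centralities** are computed with networkx on the simplified graph:
  DC = degree/(n−1); CCo = local clustering; CC = within-component
  closeness scaled by the reachable fraction (the standard
  disconnected-graph correction — PPI exports are rarely connected);
  BC normalized by (n−1)(n−2)/2. Isolated nodes score 0 on all four.
  The test suite cross-checks all four against igraph, an independent
  implementation.
- **Phyletic age** uses a generic ordered-clade interface (innermost →
  outermost, default five groups); the age is the outermost clade with a
  homolog regardless of gaps.
- **mEF** uses the sample (n−1) standard deviation over the mean and is
  missing for fewer than two observations or a non-positive mean.

## Synthetic corpus generator

The generator produces the statistical structure the analyses rest on,
not sequence-level realism.

**Tree.** A Yule (pure-birth) tree, branch lengths rescaled so the
root-to-tip depth equals `max_depth_my` (default 4000 My, a span that
accommodates a bacteria + fungi panel). Divergence time between two
species is the time since their MRCA; the matrix is ultrametric by
construction.

**Latent importance.** Each of the shared ortholog families carries a
latent importance z ~ N(0, 1) at the root that evolves by Brownian
motion; `drift_sigma` is the standard deviation of the root-to-tip
displacement in units of the trait's baseline scale (default 0.5). A
species' essentiality propensity is its tip value plus two terms:
+`condition_effect_size` on a designated "biosynthesis" gene subset when
the species lives on minimal medium (those genes are essential only
because the medium lacks their products), and ±`lifestyle_effect_size`
on a designated "energy" subset keyed to the oxygen tag (aerobe +,
anaerobe −, facultative 0). The per-species threshold is set at the
empirical quantile that realizes the target essential fraction π within
±2% (an unreachable π raises rather than silently clipping). Defaults:
π = 0.15, inside the observed 7–16% range for bacterial deletion
screens; `conditional_gene_fraction` = 0.15 of families in each
designated subset.

**Features.** Continuous features are class-conditional Gaussians with
unit noise: essential genes at +δ_f/2, non-essential at −δ_f/2, where
the separation vector δ (baseline `feature_separation` = 0.55 per
feature, 13 continuous + 2 categorical features by default) itself
drifts on the tree with relative rate `drift_sigma`. The baseline was
chosen so that within-species AUC lands in the mid-0.9s, matching what
genome-wide essentiality classifiers typically reach on real bacterial
data. Categorical features are per-species quantile binnings of noisy
copies of z into five levels, mirroring the five phyletic-age groups.

Condition and lifestyle tags additionally shift δ on small matched
feature blocks (±effect × `feature_separation` on a "biosynthesis" and
an "energy" block of features). This is deliberate: with purely
label-side condition effects and features drawn conditionally on each
species' own labels, two equidistant training species would be
statistically exchangeable and sharing a growth condition could not
improve transfer, contradicting the phenomenon the generator exists to
emulate. Tag-keyed feature-direction shifts are the minimal mechanism
that makes condition/lifestyle sharing matter, while the label-side
terms reproduce the higher essential fraction of minimal-medium species.

**Noise and missingness.** Labels flip independently with per-species
probability q ∈ [0, 0.5] (transposon-screen and inferred label sets are
emulated with q > 0; the species metadata's quality tier is derived from
q). A missing-completely-at-random mask (default 5%) is applied to the
feature table.

**Determinism.** One integer seed drives everything through a fixed
`numpy.random.SeedSequence` spawn order (tree, z root, z drift, δ drift,
subset choice, features, categorical noise, label flips, missingness);
identical configurations give bit-identical corpora, and corpora
round-trip byte-identically through the TSV writers.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: real feature marginals (counts, heavy
tails, feature correlations beyond the shared latent), non-random
missingness, ascertainment biases of PPI and expression data, and any
particular real species' parameter values. Conclusions supported by the
suite are about the pipeline's correctness and about the qualitative
mechanisms (distance decay, quality degradation, saturation,
integration), not about effect sizes in any real clade.

## Experiments

- **Incomplete training sets.** Per replicate, a class-stratified 20% of
  labeled genes is held out; training sets are nested prefixes of one
  random permutation of the remainder (lower variance across fractions
  than independent draws, and matching the idea of gradually growing one
  training set), sized as fractions of the *total* labeled genes. The
  default grid is 1%…10% in steps of 1%, then 15%…80%. Replicates are
  independently seeded; single-class draws are re-permuted with bounded
  retries.
- **HASTS/LASTS.** The top ⌈n·9/19⌉ single-species training sets by AUC
  form the high group — exactly 9 vs 10 for a 19-species pool,
  generalized proportionally to other pool sizes. The threshold reported
  is the midpoint between the boundary scores.
- **Random-integration null.** The threshold is the integrated AUC of
  the rule-selected k-set; the null draws k-subsets uniformly with
  replacement over the combination space (10,000 draws exceed the 3,876
  distinct 4-subsets of 19, so reuse is unavoidable); `exact` mode
  enumerates all subsets and is the oracle the sampled mode is tested
  against. The p-value uses strict exceedance (simulated AUC >
  threshold). Distinct combinations are fitted once and cached — valid
  because the classifier and metric are deterministic.
- **Rule-based selection** scores each candidate as an equally-weighted
  sum (weights configurable) of: quality tier (deletion 1.0 >
  transposon 0.5 > inferred 0.0), growth-condition match (0/1),
  phylogenetic proximity (1 − d/d_max over the candidate set), and
  lifestyle similarity (fraction of matching gram/oxygen/shape tags).
  The four criteria are applied qualitatively in the underlying
  analysis; the equal weighting is this package's concretization.

## Numerical conventions

- AUC is the rank-based Mann–Whitney statistic (tied pairs count ½);
  PPV@k (default k = 200) and TPR-at-prevalence break score ties by
  descending score then ascending gene id, so results are deterministic.
- Column dispersion uses linear-interpolation quantiles and the 1.5·IQR
  whisker rule; the diagonal (self-prediction) is excluded by default.
- The divergence correlation uses ordered pairs (i→j and j→i both
  enter), Pearson's R with a two-sided p; outliers are discarded when
  the standardized OLS residual exceeds 3 (configurable, or disabled) —
  a stand-in for the visual outlier pruning common in such regressions.
- Acceptance-scale problem sizes (12 species × 500 genes for the
  distance analysis; 300-gene species for integration suites; 100
  replicates for the saturation curve) were chosen as the smallest
  corpora at which the qualitative effects are stable across seeds.

## Known limitations

- The naive Bayes independence assumption is wrong for correlated
  centralities (DC/CC/BC); the pipeline inherits this, as any
  feature-based transfer study does.
- TPR differences driven by growth-condition sharing are only as strong
  as the tag-keyed feature-block shifts; the package makes no claim
  about their real-world magnitude.
- `rule_based_select` returns a ranking, not a guarantee: with equal
  weights the rule set is competitive but not always the optimum of the
  random-integration distribution.
- The PPV@k default (k = 200) assumes genomes of a few thousand genes;
  small synthetic corpora should pass a smaller k explicitly.
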