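# Methods

## Setting and data model

The package treats automated GO annotation as a bank of independent binary
classification problems, one per GO term.  The inputs are two long-format
annotation tables — (protein, IPR signature) and (protein, GO term) pairs —
turned into binary incidence matrices over a shared protein universe (the
union of both tables' proteins; a protein missing from the GO table is a
negative for every term, one missing from the IPR table has an all-zero
profile).  Row and column orderings are made deterministic (sorted ids, or a
caller-supplied universe) so that seeded downstream steps reproduce exactly.

Two pathologies motivate every stage: per GO term the positives are a small
minority, and most IPR columns are nearly all-zero.  A GO term is considered
trainable only if at least `min_positive` proteins carry it; the default 20
guarantees at least two positives per fold under stratified 10-fold CV.
GO-hierarchy structure is deliberately not used: terms are independent
labels here, and no annotation propagation along the ontology graph is
performed.

## Balancing

For each term, every positive protein is kept and an equal number of
negatives is drawn uniformly without replacement from
`numpy.random.default_rng(seed)`; the seed is recorded in the output for
provenance.  Uniformity is the natural default in the absence of any
covariate worth stratifying on.  Oversampling the positives is not offered:
duplicating or interpolating minority proteins adds no information here, and
the negative pool is always large in the intended regime.  When repeated
undersamples are wanted, `n_resamples` in the grid runner reports the mean
and standard deviation of the error across draws (default 1 draw).

## Feature selection

Crossing an IPR column with the term's labels gives a 2×2 contingency; the
four conditional probabilities P(GO state | IPR state) are obtained by
normalizing with the IPR-state totals (the number of proteins carrying,
respectively lacking, the signature).  The alternative normalization by GO
totals is exposed behind `condition_on="go"` for comparison, but the
IPR-conditioned reading is the default: it is the direction in which the
probabilities describe what a signature says about the term.  Zero
denominators yield probability 0, so the four-term score is totally
ordered: exactly 2 for any column observed in both states, below 2 for
degenerate columns.  Because the score alone cannot rank non-degenerate
columns, the operational selection criterion is co-occurrence: a column is
kept iff it is non-zero in the balanced set and fires on at least
`min_cooccur` positive proteins (default 1).  In a balanced per-term subset
the overwhelming majority of columns are all-zero — jointly absent with the
term — and are excluded by this rule; an optional `score_min` threshold
additionally removes degenerate columns.  An empty selection is flagged
rather than fatal; the grid runner then falls back to all non-zero columns.
No multiple-testing control is applied — selection here is a coverage
filter, not an inference procedure.

## Weighted IPR transform

Pairwise column correlations are the phi coefficients (Pearson on 0/1
columns), computed by centered dot products.  Zero-variance columns get
correlation 0 with every other column and 1 with themselves — they carry no
association and should contribute nothing to any weight.

Per protein, features are partitioned by value into the carried group and
the absent group.  Within a group g, feature i's raw weight is
Σ_{j∈g, j≠i} corr(i, j), and the group shares a fixed mass of 0.5 in
proportion to the weights: weightsum(i) = 0.5·weight(i)/Σ_{k∈g} weight(k).
Edge cases, each fixed by the worked example or by the conservation
requirement:

- **Singleton group** → 0.5 exactly (the ratio is taken as 1).
- **Negative group total** → the ratio is applied unchanged; individual
  entries may then fall outside [0, 1], and the group still sums to 0.5.
- **Zero group total with ≥ 2 members** (e.g. several zero-variance columns
  in one group) → equal shares 0.5/|g|, recorded in `degenerate_groups`;
  chosen so the per-group conservation invariant (weights sum to 0.5)
  holds unconditionally.

Correlations enter at full floating precision; 4-d.p. rounding is applied
only to displayed output.  The bundled example's published reference table
was itself produced with intermediate rounding that varies between rows
(deriving it from the 4-d.p. correlation table reproduces most rows;
one cell requires full precision), so automated comparisons against that
table use a tolerance of 2.5×10⁻⁴ rather than exact 4-d.p. equality, and
the derivation-level checks are made exact under the convention that
generates each cell.

The transform is row-local given the correlation matrix: new proteins can
be encoded with correlations fitted on training data.  It is *not*
invariant to enlarging the dataset (correlations are data-dependent); this
is a documented property, tested as such.

## Classifier grid and cross-validation

Twelve cells: three learners × {binary, weighted encoding} × {with,
without feature selection}.  The learners are scikit-learn's
AdaBoostClassifier over depth-1 decision stumps with 50 rounds (the
classical configuration), an RBF-kernel soft-margin SVM, and a
linear-kernel SVM — libsvm's solver being sequential minimal optimization,
the latter is the "SMO" cell; C = 1.0 for both, all overridable via
`learner_params`.  The two SVM cells are kept distinct because they can
rank differently per term; no claim is made that either kernel choice is
canonical.

Error rates come from stratified 10-fold cross-validation (stratification
keeps the folds of a balanced set balanced); the reported error is the mean
of per-fold misclassification rates, with pooled counting available via
`pooled=True`.  Feature selection and the correlation matrix of the
weighted transform are fitted on each fold's training portion only.  When
both options are on, selection runs first on the binary columns and the
transform is computed on the selected columns.  A deliberate
`leakage="full"` mode fits selection and correlations on the complete
dataset instead; it exists purely for sensitivity analysis, and the test
suite demonstrates its optimistic bias on a configuration where those
estimates are noisy (small folds, weak sparse signal, RBF cells) —
conditions chosen because leakage bias scales with the variance of what is
being leaked.

Per-term sub-seeds are derived as `crc32(term) XOR f(seed)` so that results
are deterministic, independent of the order terms are requested in, and
distinct across terms.  Per-term failures (no positives, fewer negatives
than positives, folds that cannot hold both classes) become skipped report
rows carrying the reason.

The `ProteinFunctionModel` / `GridResults` pair wraps this pipeline in a
model-object interface: the model holds the two matrices and the
trainability threshold, `fit()` returns results carrying the per-cell error
estimates, resampling spreads, a `summary()` table and a bar-chart `plot()`.

## Synthetic data generator

`SynthConfig` defaults — 2,000 proteins, 500 IPR columns, 5 GO terms,
background density 0.01, 10 informative columns per term, association
strength 0.8, positive fraction 0.05 — mirror the shape of a yeast-scale
SWISS-PROT extraction (thousands of proteins, a signature universe where
almost every column is nearly empty, ~5% positives per term) scaled down
roughly 2× for test speed.  Each term's positives are drawn exactly
(`round(positive_fraction·n)`), and its informative columns fire with
probability `assoc_strength` on positives and `background_density`
elsewhere.  The truth map makes recovery a first-class measurement.

What the generator does *not* emulate: phylogenetic co-occurrence structure
among domains (real IPR columns are correlated through shared ancestry),
hierarchically consistent GO labels, and annotation noise (wrong or missing
labels).  Tests passing on this generator therefore show that the pipeline
recovers planted marginal associations under realistic sparsity and skew —
not that real-data error rates will match.

## Verification strategy and problem sizes

The weighted transform is checked entrywise against an independent
brute-force oracle (explicit double loop, correlations recomputed from raw
columns) on 200 random matrices up to 20×15 at 1e-9, plus a derandomized
property-based test.  Grid calibration uses 50 seeds of a 100-protein,
25-column null dataset (permuted labels): every cell must average within
0.5 ± 0.05; a deterministic 4-column pattern that remains separable through
the weighted encoding must give error 0 in every cell.  Feature-selection
recovery uses 20 seeds of the generator defaults.  These sizes keep the
full suite to a few minutes while leaving the statistical assertions
comfortably powered.

## Known limitations

- Error rates on real SWISS-PROT-derived extractions depend on the curation
  snapshot and are not reproduced here; the behavioral tests on synthetic
  data are the acceptance surface.
- The per-term models are independent: no sharing of statistical strength
  across related GO terms, no DAG-consistent post-processing.
- The co-occurrence selection criterion is a coverage filter; with
  `min_cooccur=1` a single noisy co-occurrence admits a column (harmless in
  the balanced regime, but not a significance statement).
- Undersampling discards most negatives; with one draw (default) the error
  estimates carry sampling noise that `n_resamples > 1` quantifies but does
  not remove.
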