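# Methods notes

This note records the modeling choices, tunable parameters and known
limitations of the package.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Feature definitions and conventions

- **Content words.** Nouns, verbs, adjectives and adverbs (proper nouns
  count as nouns); function words never enter any feature.  Lemmas are
  case-folded but accent-preserving, because Spanish norms are
  accent-sensitive.  Tokenization splits on Unicode word boundaries and
  keeps hyphenated forms whole.
- **Distance metric.** Cosine distance (1 − cosine similarity) by
  default, configurable to Euclidean.  Cosine is the standard choice
  for word embeddings and makes semantic variability and property
  distance flow invariant under global orthogonal transforms and
  per-vector positive rescaling of the lexicon (rescaling exactly so
  for single-word properties; property *mean* vectors move slightly
  under rescaling).
- **Variance convention.** Sample variance (n − 1), configurable.
  Fewer than two distances yields an undefined (NaN) value, never 0:
  reporting zero variability for a two-word response would fabricate
  the most clinically loaded value from the least data.
- **Semantic-variability adjacency.** The concept's content tokens form
  one series across property boundaries in production order
  (`adjacency="concat"`, default); `"per_property"` restricts distance
  pairs to within-property neighbors and pools them before the
  variance.  The underlying elicitation produces short phrases in one
  continuous session, so the concatenated series is the default.
- **Relevance / distinctiveness.** Natural log by default (the base
  only rescales globally).  Production frequency x_ij pools all
  participants of the analysis set and counts repetitions
  (`count_unit="tokens"`); `"participants"` counts each participant at
  most once per (concept, property).  Property identity is the sorted
  lemma multiset of the property, the most conservative normalization
  that does not require external resources.  Participant-level values
  average k_ij and log(I/I_j) over the properties the participant
  actually listed, looked up in the pooled table.
- **Granularity.** Depth is the shortest parent-path edge count to the
  root `entity`; a polysemous word uses its minimum depth over senses
  (configurable to mean), the least specific defensible sense.  The
  scalar entering the feature matrix is the mean depth over the
  concept's nouns; the per-noun depth distribution is available from
  the taxonomy API for binned analyses.
- **Out-of-vocabulary policy.** Skip with warning, everywhere.  A
  concept whose tokens are all OOV yields an undefined cell; a
  participant cell is missing only if the feature is undefined for
  every concept.  No imputation happens during extraction; the
  classifier imputes training-fold medians at fit time.

## Statistics

- Outlier fencing retains x with Q1 − 3·IQR ≤ x ≤ Q3 + 3·IQR, quartiles
  by linear interpolation (type 7) on the pooled sample, single pass.
  Per-group fencing is available by configuration.
- The ANCOVA group test compares the covariate-only model with the
  covariate+group model by least squares (Type-II sum of squares for
  the single factor); partial eta squared is
  SS_group / (SS_group + SS_error).  With no covariate this is exactly
  the one-way ANOVA.  A covariate collinear with the group indicator to
  machine precision raises an error.
- Post hocs are Tukey–Kramer: studentized-range p-values with
  unequal-n standard errors; Cohen's d uses the pooled SD without
  small-sample correction.
- Clinical correlations choose Pearson only when both variables pass
  Shapiro–Wilk at alpha = 0.05, otherwise Spearman.  A covariate is
  partialled out by residualizing both variables (after rank transform
  for Spearman) with the classic n − 3 degrees-of-freedom adjustment.
- No multiple-comparison correction is applied across the ten features;
  raw p-values are reported and correction is left to configuration.

## Classification

- Stratified 5-fold partitions, re-randomized every iteration; the
  iteration AUC comes from the pooled out-of-fold probability scores
  (stable at n ≈ 46; per-fold AUCs at fold sizes of 9 are noisy).
- Min-max normalization, median imputation and (optional) inner 3-fold
  grid search are fitted on training folds only.  `paper_mode=True`
  instead fits the normalizer on the full sample, for comparison with
  analyses that normalize before partitioning.
- The boosted-tree model is scikit-learn's gradient boosting; the
  default configuration runs without a tuning grid (library defaults)
  and a small published grid (depth {2,3} × learning rate {0.1,0.3})
  exercises the tuning path.  Reported runs use 200 random partitions;
  the study-scale setting is 1000 and changes only the Monte-Carlo
  error of the AUC mean.

## The synthetic cohort: what it emulates, what it does not

The generator emulates the *data structure and effect structure* of a
three-group property-listing study: group sizes 20/16/26; 10 cue words
(the packaged Spanish stimuli, 1–3 syllables); valid properties per
concept drawn from a truncated negative binomial matched to group means
(SD) 6.30 (2.35) / 5.98 (2.82) / 8.31 (2.96); content words per concept
matched to 14.45 / 15.45 / 22.75 via the tokens-per-property rate; an
8% rate of tagged non-valid responses; education drawn per group
(means 9.95 / 14.0 / 13.0 years).

Effects are injected mechanistically:

- **Abstraction shifts.** The 240-word toy vocabulary is stratified
  high/low on concreteness and imageability (strata crossed and
  balanced within every vector cluster, so cluster occupancy is
  independent of norm content by construction).  Each participant
  samples high-stratum words with probability p = 0.5 + Δp, with
  between-participant SD 0.10.  Δp for a target Cohen's d starts from
  the stratum-mixture closed form and is corrected once against a pilot
  simulation, because patients' higher cluster-stay probability
  concentrates their token sample and inflates their feature SD in a
  way the closed form misses.
- **Semantic-variability shifts.** Tokens are drawn from 6 orthogonal
  vector clusters (dimension 16, within-cluster dispersion 0.3) via a
  Markov chain with stay probability p_stay (baseline 0.5, SD 0.08).
  The variance of the distance series is an inverted-U in p_stay with
  its peak near 0.5, so the generator operates on the decreasing branch
  [0.5, 0.95]: staying more compresses variability.  Only reductions
  are representable.  The p_stay for a target d is found by a pilot
  Monte Carlo (fixed internal seed): a monotone grid fit of the
  d-versus-p_stay curve per patient group — with that group's own token
  counts, since their sampling noise inflates the pooled SD — refined by
  one secant step.
- **Clinical scores.** MoCA and Hayling are linear functions of the
  participant's generative latents plus Gaussian noise, with target
  |r| = 0.45: higher concreteness latent → lower MoCA, higher stay
  latent (lower variability) → higher Hayling error score.  The target
  is chosen so that tandem correlations at n ≈ 46 are adequately
  powered; the observed study-scale coefficients (≈ −0.3) would leave
  single-cohort correlation tests underpowered and untestable.
  PDQ-39 scores are drawn for PD only and carry no feature link.

The calibration pilot is part of the stated world: its seed is fixed,
so every replicate of one spec shares the same dial settings, and the
calibration is cached per spec (vocabularies are exchangeable across
seeds; the residual vocabulary-specific error is of the order of the
pilot noise, about ±0.1 on d).

What the generator does **not** emulate: real Spanish phrase structure
(tokens are cluster-coded symbols), taxonomy semantics (random trees),
norm–frequency correlations, age effects, or any neuroimaging-derived
quantity.  A green test therefore establishes that the *pipeline
machinery* recovers what was injected — not that the features are valid
markers in human data.

### The exchangeable null

"Zero effect" alone does not make group labels exchangeable: patients
also produce fewer properties, and production volume feeds relevance/
distinctiveness and the sampling noise of every variance feature, so a
zero-shift cohort with study production parameters is still
classifiable above chance.  `CohortSpec.exchangeable_null` therefore
zeroes the shifts *and* equalizes production and education parameters
across groups; it is the correct null for type-I-error and
chance-level-AUC checks.

## Known limitations

- Only variability *reductions* can be injected (the branch constraint
  above); the observed disease direction is a reduction.
- The per-group calibration targets Cohen's d against the pilot control
  population; realized cohort-level d fluctuates with replicate
  sampling error (SE ≈ 0.3 per cohort at these group sizes).
- The omnibus ANCOVA at n = 62 has limited power for standardized
  shifts below ≈ 0.8 (noncentral-F power ≈ 0.7 at d = 0.78 with one
  shifted group of 20); detection-rate checks at those magnitudes sit
  near their pass boundary by construction.
- The dictionary demo tagger covers test vocabulary only; real
  transcripts should arrive pre-tagged or with a proper morphological
  tagger plugged in.
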