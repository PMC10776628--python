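# semnav

Lexico-semantic word-property markers from property-listing-task
transcripts, with a focus on cognitive profiling of Parkinson's disease
(PD) against behavioral-variant frontotemporal dementia (bvFTD) and
healthy controls (HC).

## The problem

In a property listing task a participant hears a cue concept ("sun")
and freely names its properties ("hot", "yellow", "it rises in the
morning").  Counting correct responses misses *how* a speaker navigates
semantic memory.  This package reduces coded transcripts to ten word
properties per participant and pushes them through the full analysis
chain used in neurodegeneration research:

**Property-specific features** (of the produced words themselves)

- *concreteness, imageability, familiarity, log frequency, phoneme
  length* — means of psycholinguistic norms (1–7 scales; log10
  occurrences per million; phoneme counts) over the lemmatized content
  words of each concept;
- *semantic variability* — with each content word mapped to an
  embedding vector w_t, the sample variance of the distance series
  d_t = dist(w_t, w_{t+1}); low variance means the speaker stays inside
  a semantic field;
- *granularity* — mean taxonomy depth of the produced nouns, i.e. the
  shortest parent-path edge count from the noun's node to the root
  `entity`; deeper = more specific.

**Concept-to-property features** (relating cue and responses)

- *property distance flow* — each property is the mean vector of its
  words; the feature is the variance of the distances between property
  vectors and the cue vector;
- *relevance and distinctiveness* — from the production-frequency table
  x_ij (property j listed for concept i), with I concepts and
  I_j = #{i : x_ij > 0}:

      k_ij = x_ij · log(I / I_j),     distinctiveness_j = log(I / I_j)

  so a property shared by every concept carries zero weight.

Downstream, features are compared between groups (3×IQR outlier fences,
one-way ANCOVA with years of education as covariate, Tukey–Kramer post
hocs, partial eta squared, Cohen's d), fed to subject-level
classification (min-max normalization and gradient-boosted trees inside
repeated stratified 5-fold cross-validation, AUC mean ± SD over random
partitions), and correlated with clinical scores (MoCA, Hayling) in
patient+control tandems, Pearson or Spearman as gated by Shapiro–Wilk.

A first-class synthetic-cohort generator (`semnav.synthetic`) emits all
input files — transcripts, norms, word2vec-text vectors, taxonomy,
clinical scores — for the study design (20 PD / 16 bvFTD / 26 HC, 10
Spanish cue words, overdispersed property counts) with *mechanistically*
injected group effects, so every stage is testable without external
data.

## Worked example

```bash
python examples/03_group_statistics.py
```

simulates the default cohort (seed 7), extracts the feature matrix and
prints the inferential table:

```
feature                       F        p  eta_p2   PD-HC d
concreteness               6.10   0.0039   0.174      1.11 *
imageability               8.01   0.0008   0.216      0.90 *
familiarity                1.40   0.2559   0.046     -0.21
log_frequency              0.56   0.5728   0.019      0.28
length                     0.71   0.4951   0.024     -0.52
semantic_variability       4.91   0.0107   0.145     -1.01 *
granularity                2.81   0.0685   0.088      0.74
property_distance_flow     2.54   0.0876   0.081     -0.67
relevance                 19.94   0.0000   0.407     -1.82 *
distinctiveness           20.88   0.0000   0.419     -2.03 *
```

The three features carrying injected shifts are flagged: PD
participants produce more concrete (d = +1.11) and imageable (+0.90)
words and show reduced semantic variability (−1.01).  Relevance and
distinctiveness also separate groups because patients produce fewer
properties, which feeds the production-frequency table — a real,
volume-driven group difference.  `examples/04_classification.py` on the
same cohort prints

```
PD-vs-HC: AUC 0.795 +- 0.043 (50 random partitions)
bvFTD-vs-HC: AUC 0.621 +- 0.069 (50 random partitions)
```

i.e. PD separates from controls well above chance while bvFTD barely
does — the qualitative pattern the feature set is designed to capture.
The other examples cover simulation (`01`), feature extraction (`02`),
clinical correlations (`05`) and the one-call pipeline (`06`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the stimulus-set statistics from the packaged 10 Spanish cue
words with the orthographic syllabifier (targets `t1`, `t2`: mean and
sample SD of the syllable counts) and then runs the entire pipeline —
simulation of the study design, ingest, feature extraction, group
statistics, three pairwise classifications at 200 cross-validation
repetitions, clinical correlations — printing a stage summary to
stderr and writing the target JSON to `--out`.

## Layout

```
src/semnav/
  ingest.py     transcript parsing, validity filter, content tokens
  tagging.py    pluggable lemmatizer/POS interface + demo dictionary
  lexicon.py    norms, word2vec-text vectors, taxonomy, syllabifier
  features.py   the ten features; relevance table; feature matrix
  synthetic.py  cohort generator with calibrated group effects
  stats.py      fencing, ANCOVA, Tukey-Kramer, gated correlations
  classify.py   repeated stratified CV gradient boosting
  pipeline.py   RunConfig + one-call orchestration
examples/       one narrative script per capability
docs/methods.md the model, parameter and calibration notes
```
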