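"""The ten word-property features, per concept and per participant.

Property-specific features (characteristics of produced words):

* concreteness, imageability, familiarity, log frequency, phoneme length
  — means of the psycholinguistic norms over the concept's in-vocabulary
  content lemmas;
* semantic variability — sample variance of the distances between
  embedding vectors of consecutive produced words; low values mean the
  speaker stays within a semantic field;
* granularity — mean taxonomy depth (edge count from the word's node to
  the root 'entity') of the concept's nouns; larger = more specific.

Concept-to-property features (relations between cue and responses):

* property distance flow — variance of the distances between each
  property's mean vector and the cue concept's vector;
* relevance — mean k_ij = x_ij * log(I / I_j) over the properties listed
  for the concept, where x_ij is the production frequency of property j
  for concept i, I the number of concepts and I_j the number of concepts
  sharing property j;
* distinctiveness — mean log(I / I_j); zero when every concept shares
  the property.

Per-participant values are the means across that participant's concepts,
skipping concepts where a feature is undefined.  All computations are
pure functions of their inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields as dc_fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from semnav.ingest import PropertyRecord
from semnav.lexicon import NORM_COLUMNS, NormsTable, Taxonomy, VectorLexicon

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = (
    "concreteness",
    "imageability",
    "familiarity",
    "log_frequency",
    "length",
    "semantic_variability",
    "granularity",
    "property_distance_flow",
    "relevance",
    "distinctiveness",
)


@dataclass(frozen=True)
class ConceptFeatures:
    """The ten features for one (participant, concept); NaN = undefined."""

    participant_id: str
    concept: str
    concreteness: float = math.nan
    imageability: float = math.nan
    familiarity: float = math.nan
    log_frequency: float = math.nan
    length: float = math.nan
    semantic_variability: float = math.nan
    granularity: float = math.nan
    property_distance_flow: float = math.nan
    relevance: float = math.nan
    distinctiveness: float = math.nan


@dataclass
class RelevanceTable:
    """Concept x property production-frequency counts and Eq-style weights.

    Attributes
    ----------
    x : DataFrame, concepts x property keys, production frequencies x_ij.
    n_concepts : int, the total number of concepts I.
    concept_count : Series per property, I_j = number of concepts with x_ij > 0.
    distinctiveness : Series per property, log(I / I_j).
    k : DataFrame, relevance k_ij = x_ij * log(I / I_j) (0 where x_ij = 0).
    """

    x: pd.DataFrame
    n_concepts: int
    concept_count: pd.Series
    distinctiveness: pd.Series
    k: pd.DataFrame
    log_base: float | None = None  # None = natural log


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cosine similarity; standard for word embeddings."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return math.nan
    return float(1.0 - np.dot(u, v) / (nu * nv))


def euclidean_distance(u: np.ndarray, v: np.ndarray) -> float:
    return float(np.linalg.norm(u - v))


_METRICS = {"cosine": cosine_distance, "euclidean": euclidean_distance}


def _metric(metric) -> callable:
    if callable(metric):
        return metric
    try:
        return _METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; use 'cosine' or 'euclidean'")


def _sample_variance(values: Sequence[float], ddof: int = 1) -> float:
    values = [v for v in values if not math.isnan(v)]
    if len(values) < ddof + 1:
        return math.nan
    return float(np.var(values, ddof=ddof))


def norm_feature_means(records: Sequence[PropertyRecord], norms: NormsTable) -> dict[str, float]:
    """Mean of each psycholinguistic norm over a concept's in-vocabulary lemmas.

    Lemmas are pooled across the concept's properties; a feature is NaN
    (undefined) when no lemma is in the norms table.
    """
    rows = []
    for rec in records:
        for tok in rec.tokens:
            hit = norms.lookup(tok.lemma)
            if hit is not None:
                rows.append(hit)
    if not rows:
        logger.warning("norm_feature_means: no in-vocabulary lemma; features undefined")
        return {col: math.nan for col in NORM_COLUMNS}
    stacked = pd.DataFrame(rows)
    return {col: float(stacked[col].mean()) for col in NORM_COLUMNS}


def semantic_variability(
    property_lemmas: Sequence[Sequence[str]],
    vectors: VectorLexicon,
    metric="cosine",
    adjacency: str = "concat",
    ddof: int = 1,
) -> float:
    """Variance of distances between consecutive produced-word vectors.

    Parameters
    ----------
    property_lemmas
        Lemma sequences, one per property, in production order.
    adjacency
        "concat" (default): the concept's tokens form one series across
        property boundaries; "per_property": distance pairs never cross
        a boundary but all pairs pool into one series before the
        variance.
    ddof
        Variance denominator is n - ddof (sample variance by default).

    Returns NaN when fewer than two distances are available (i.e. fewer
    than three usable tokens under "concat").
    """
    dist = _metric(metric)
    if adjacency not in ("concat", "per_property"):
        raise ValueError("adjacency must be 'concat' or 'per_property'")
    groups: list[list[np.ndarray]]
    if adjacency == "concat":
        flat = [v for prop in property_lemmas for v in map(vectors.lookup, prop) if v is not None]
        groups = [flat]
    else:
        groups = [
            [v for v in map(vectors.lookup, prop) if v is not None] for prop in property_lemmas
        ]
    distances = [dist(a, b) for g in groups for a, b in zip(g, g[1:])]
    return _sample_variance(distances, ddof=ddof)


def granularity_score(
    noun_lemmas: Sequence[str], taxonomy: Taxonomy, polysemy: str = "min"
) -> float:
    """Mean taxonomy depth over the nouns that map to a node; NaN if none do."""
    depths = [d for d in (taxonomy.word_depth(w, polysemy=polysemy) for w in noun_lemmas) if d is not None]
    if not depths:
        return math.nan
    return float(np.mean(depths))


def property_distance_flow(
    concept: str,
    property_lemmas: Sequence[Sequence[str]],
    vectors: VectorLexicon,
    metric="cosine",
    ddof: int = 1,
) -> float:
    """Variance of distances from each property's mean vector to the cue vector.

    Each property is represented by the mean of its in-vocabulary word
    vectors (properties with no usable word are dropped).  NaN when the
    concept word is out of vocabulary or fewer than two properties are
    usable.
    """
    dist = _metric(metric)
    cvec = vectors.lookup(concept)
    if cvec is None:
        logger.warning("property_distance_flow: concept %r out of vocabulary", concept)
        return math.nan
    distances = []
    for prop in property_lemmas:
        vecs = [v for v in map(vectors.lookup, prop) if v is not None]
        if not vecs:
            continue
        pvec = np.mean(vecs, axis=0)
        distances.append(dist(pvec, cvec))
    return _sample_variance(distances, ddof=ddof)


def relevance_distinctiveness(counts: pd.DataFrame, log_base: float | None = None) -> RelevanceTable:
    """Relevance/distinctiveness weights from a concept x property count table.

    ``counts`` has one row per concept, one column per property key and
    non-negative integer production frequencies x_ij.  With I concepts
    and I_j = #{i : x_ij > 0}:

        distinctiveness_j = log(I / I_j)
        k_ij              = x_ij * log(I / I_j)

    so k_ij = 0 exactly when x_ij = 0 or the property is shared by all
    concepts.  Natural log by default; never-listed properties (I_j = 0)
    are excluded.
    """
    if (counts.values < 0).any():
        raise ValueError("production frequencies must be non-negative")
    x = counts.astype(float)
    listed = (x > 0).sum(axis=0)
    never = listed[listed == 0].index
    if len(never):
        logger.warning("relevance_distinctiveness: dropping %d never-listed properties", len(never))
        x = x.drop(columns=never)
        listed = listed.drop(never)
    n_concepts = len(x.index)
    ratio = n_concepts / listed
    log = (lambda v: np.log(v) / np.log(log_base)) if log_base else np.log
    distinct = pd.Series(log(ratio.values), index=x.columns, name="distinctiveness")
    k = x.mul(distinct, axis=1)
    k[x == 0] = 0.0
    return RelevanceTable(
        x=x,
        n_concepts=n_concepts,
        concept_count=listed.rename("I_j"),
        distinctiveness=distinct,
        k=k,
        log_base=log_base,
    )


def aggregate_participant(concept_features: Sequence[ConceptFeatures]) -> dict[str, float]:
    """Average each feature across concepts, skipping undefined (NaN) ones.

    A cell stays NaN only when the feature was undefined for every
    concept.
    """
    if not concept_features:
        raise ValueError("aggregate_participant needs at least one scored concept")
    out: dict[str, float] = {}
    for col in FEATURE_COLUMNS:
        vals = [getattr(cf, col) for cf in concept_features]
        vals = [v for v in vals if not math.isnan(v)]
        out[col] = float(np.mean(vals)) if vals else math.nan
    return out


def property_key(lemmas: Sequence[str]) -> str:
    """Property identity for counting: the sorted lemma multiset."""
    return " ".join(sorted(lemmas))


def build_relevance_table(
    records: Sequence[PropertyRecord],
    log_base: float | None = None,
    count_unit: str = "tokens",
) -> RelevanceTable:
    """Pool production frequencies over the analysis set and weight them.

    ``count_unit="tokens"`` counts every listing including repetitions
    (default); ``"participants"`` counts each participant at most once
    per (concept, property).
    """
    if count_unit not in ("tokens", "participants"):
        raise ValueError("count_unit must be 'tokens' or 'participants'")
    rows = []
    for rec in records:
        if not rec.tokens:
            continue
        rows.append((rec.concept, property_key([t.lemma for t in rec.tokens]), rec.participant_id))
    if not rows:
        raise ValueError("no tokenized records to count")
    df = pd.DataFrame(rows, columns=["concept", "property", "participant"])
    if count_unit == "participants":
        df = df.drop_duplicates()
    counts = df.pivot_table(index="concept", columns="property", aggfunc="size", fill_value=0)
    return relevance_distinctiveness(counts, log_base=log_base)


def concept_feature_row(
    participant_id: str,
    concept: str,
    records: Sequence[PropertyRecord],
    norms: NormsTable,
    vectors: VectorLexicon,
    taxonomy: Taxonomy,
    relevance: RelevanceTable,
    metric="cosine",
    adjacency: str = "concat",
    polysemy: str = "min",
    ddof: int = 1,
) -> ConceptFeatures:
    """Score one participant-concept from its (filtered, tokenized) records."""
    ordered = sorted(records, key=lambda r: r.property_index)
    prop_lemmas = [[t.lemma for t in r.tokens] for r in ordered]
    nm = norm_feature_means(ordered, norms)
    nouns = [t.lemma for r in ordered for t in r.tokens if t.pos == "noun"]
    keys = [property_key(p) for p in prop_lemmas if p]
    k_vals = [
        float(relevance.k.at[concept, key])
        for key in keys
        if concept in relevance.k.index and key in relevance.k.columns
    ]
    d_vals = [
        float(relevance.distinctiveness.at[key])
        for key in keys
        if key in relevance.distinctiveness.index
    ]
    return ConceptFeatures(
        participant_id=participant_id,
        concept=concept,
        **nm,
        semantic_variability=semantic_variability(prop_lemmas, vectors, metric, adjacency, ddof),
        granularity=granularity_score(nouns, taxonomy, polysemy),
        property_distance_flow=property_distance_flow(concept, prop_lemmas, vectors, metric, ddof),
        relevance=float(np.mean(k_vals)) if k_vals else math.nan,
        distinctiveness=float(np.mean(d_vals)) if d_vals else math.nan,
    )


def build_feature_matrix(
    records: Sequence[PropertyRecord],
    norms: NormsTable,
    vectors: VectorLexicon,
    taxonomy: Taxonomy,
    participants: Optional[pd.DataFrame] = None,
    metric="cosine",
    adjacency: str = "concat",
    polysemy: str = "min",
    log_base: float | None = None,
    count_unit: str = "tokens",
    ddof: int = 1,
) -> tuple[pd.DataFrame, RelevanceTable, pd.DataFrame]:
    """The full feature-extraction stage: records -> participant matrix.

    Parameters
    ----------
    records
        Valid, tokenized PropertyRecords for the whole analysis set.
    participants
        Optional frame with participant_id, and e.g. education /
        clinical columns to merge onto the matrix.

    Returns
    -------
    (matrix, relevance_table, concept_frame)
        ``matrix`` has one row per participant: participant_id, group,
        any merged covariates, and the ten feature columns.
        ``concept_frame`` holds the per-(participant, concept) values
        for audit.
    """
    relevance = build_relevance_table(records, log_base=log_base, count_unit=count_unit)
    by_pc: dict[tuple[str, str, str], list[PropertyRecord]] = {}
    for rec in records:
        by_pc.setdefault((rec.participant_id, rec.group, rec.concept), []).append(rec)
    concept_rows = []
    for (pid, group, concept), recs in by_pc.items():
        cf = concept_feature_row(
            pid, concept, recs, norms, vectors, taxonomy, relevance,
            metric=metric, adjacency=adjacency, polysemy=polysemy, ddof=ddof,
        )
        row = {f.name: getattr(cf, f.name) for f in dc_fields(cf)}
        row["group"] = group
        concept_rows.append(row)
    concept_frame = pd.DataFrame(concept_rows)
    part_rows = []
    for (pid, group), sub in concept_frame.groupby(["participant_id", "group"], sort=True):
        cfs = [
            ConceptFeatures(**{k: r[k] for k in ("participant_id", "concept") + FEATURE_COLUMNS})
            for r in sub.to_dict("records")
        ]
        row = {"participant_id": pid, "group": group}
        row.update(aggregate_participant(cfs))
        part_rows.append(row)
    matrix = pd.DataFrame(part_rows)
    if participants is not None:
        extra = participants.drop(columns=[c for c in ("group",) if c in participants.columns])
        matrix = matrix.merge(extra, on="participant_id", how="left")
    ordered_cols = ["participant_id", "group"] + [
        c for c in matrix.columns if c not in ("participant_id", "group") and c not in FEATURE_COLUMNS
    ] + list(FEATURE_COLUMNS)
    return matrix[ordered_cols], relevance, concept_frame
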