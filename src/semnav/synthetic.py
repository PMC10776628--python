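"""Synthetic property-listing cohorts with parameterized group effects.

The generator emits every input the pipeline consumes — coded
transcripts, a norms table, a word-vector lexicon, taxonomy files and
clinical scores — for a three-group design (Parkinson's disease,
behavioral-variant frontotemporal dementia, healthy controls; default
sizes 20/16/26) with 10 cued concepts per participant and overdispersed
valid-property counts per concept (default group means 6.30/5.98/8.31).

Group effects are injected mechanistically, not painted onto feature
values:

* concreteness / imageability shifts — the toy vocabulary is stratified
  into high / low norm strata on each scale, and each participant draws
  tokens from the high stratum with a group-dependent probability.  The
  probability shift for a target standardized effect size is inverted
  analytically from the stratum-mixture model.
* semantic-variability shifts — tokens are drawn from vector clusters
  via a Markov chain that stays in the current cluster with probability
  p_stay; raising p_stay compresses the distance series and lowers its
  variance.  The p_stay value matching a target effect size is found by
  a small deterministic pilot simulation (the mapping has no closed
  form).

Clinical scores (MoCA, Hayling, PDQ-39) are linear-plus-noise functions
of the participant latents, signed to match the reported correlation
directions (higher concreteness -> lower MoCA; lower semantic
variability -> higher Hayling error scores).  Education is drawn per
group.  A seed fixes all randomness; the ground-truth record suffices to
re-derive every injected effect.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from semnav.features import semantic_variability
from semnav.ingest import ContentToken, PropertyRecord, write_records
from semnav.lexicon import NormsTable, Taxonomy, VectorLexicon, load_norms, load_taxonomy, load_vectors

#: The ten Spanish stimulus words (common natural entities and artifacts).
DEFAULT_STIMULI = (
    "árbol", "sol", "payaso", "puma", "avión", "pelo", "pato", "casa", "tiburón", "cama",
)

GROUPS = ("PD", "bvFTD", "HC")

INVALID_TAGS = ("examiner_directed", "personal_experience", "metacognitive")


@dataclass
class CohortSpec:
    """Stated world for a synthetic cohort.

    Effect shifts are signed standardized differences relative to HC
    (positive = patient group higher).  Defaults reproduce the study's
    design: PD responses more concrete (+0.78) and imageable (+0.74),
    semantic variability reduced in PD (-1.04) and bvFTD (-0.91).
    """

    group_sizes: dict = field(default_factory=lambda: {"PD": 20, "bvFTD": 16, "HC": 26})
    concepts: tuple = DEFAULT_STIMULI
    # valid properties per concept: mean (SD) per group
    props_mean: dict = field(default_factory=lambda: {"PD": 6.30, "bvFTD": 5.98, "HC": 8.31})
    props_sd: dict = field(default_factory=lambda: {"PD": 2.35, "bvFTD": 2.82, "HC": 2.96})
    # content words per concept, used to set tokens-per-property
    content_words_mean: dict = field(default_factory=lambda: {"PD": 14.45, "bvFTD": 15.45, "HC": 22.75})
    education_mean: dict = field(default_factory=lambda: {"PD": 9.95, "bvFTD": 14.0, "HC": 13.0})
    education_sd: dict = field(default_factory=lambda: {"PD": 5.10, "bvFTD": 5.28, "HC": 3.77})
    concreteness_shift: dict = field(default_factory=lambda: {"PD": 0.78, "bvFTD": 0.0})
    imageability_shift: dict = field(default_factory=lambda: {"PD": 0.74, "bvFTD": 0.0})
    semantic_variability_shift: dict = field(default_factory=lambda: {"PD": -1.04, "bvFTD": -0.91})
    # vocabulary / embedding space
    vocab_size: int = 240
    dim: int = 16
    n_clusters: int = 6
    within_dispersion: float = 0.30
    # stratum mixing
    p_high_base: float = 0.5
    sigma_p: float = 0.10
    # cluster-stay chain; the base sits at the top of the variance curve so
    # that raising p_stay monotonically compresses semantic variability
    p_stay_base: float = 0.5
    sigma_stay: float = 0.08
    invalid_fraction: float = 0.08
    # clinical models: target |r| and Table-style score moments
    clinical_r: float = 0.45
    moca_mean: dict = field(default_factory=lambda: {"PD": 20.05, "bvFTD": 22.07, "HC": 24.33})
    moca_sd: float = 4.0
    hayling_mean: dict = field(default_factory=lambda: {"PD": 14.90, "bvFTD": 15.79, "HC": 8.0})
    hayling_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 participants")
        for d in (self.concreteness_shift, self.imageability_shift, self.semantic_variability_shift):
            if not all(math.isfinite(v) for v in d.values()):
                raise ValueError("effect shifts must be finite")

    @classmethod
    def exchangeable_null(cls, seed: int = 0, **overrides) -> "CohortSpec":
        """A zero-effect world in which group labels are exchangeable.

        All feature shifts are zero AND the production parameters
        (properties per concept, content words, education) take the
        control-group values for every group.  Group differences in
        production volume are themselves real signal — the study found
        fewer valid properties in patients — so a null that keeps them
        is not a null for classification or type-I-error checks.
        """
        flat = {g: 0.0 for g in ("PD", "bvFTD")}
        base = cls(
            seed=seed,
            concreteness_shift=dict(flat),
            imageability_shift=dict(flat),
            semantic_variability_shift=dict(flat),
            props_mean={g: 8.31 for g in GROUPS},
            props_sd={g: 2.96 for g in GROUPS},
            content_words_mean={g: 22.75 for g in GROUPS},
            education_mean={g: 13.0 for g in GROUPS},
            education_sd={g: 3.77 for g in GROUPS},
            **overrides,
        )
        return base


@dataclass
class SyntheticDataset:
    """In-memory synthetic inputs plus (optionally) the files they were written to."""

    records: list
    norms: NormsTable
    vectors: VectorLexicon
    taxonomy: Taxonomy
    clinical: pd.DataFrame
    ground_truth: dict
    cluster_of: dict
    paths: dict = field(default_factory=dict)


def make_toy_lexicon(
    vocab_size: int,
    dim: int = 16,
    n_clusters: int = 6,
    within_dispersion: float = 0.3,
    seed: int = 0,
    words: Optional[Sequence[str]] = None,
) -> tuple[VectorLexicon, dict[str, int]]:
    """Unit-norm vectors around well-separated cluster centroids.

    Centroids are rows of a random orthogonal matrix (pairwise cosine
    distance 1); members are the centroid plus isotropic Gaussian noise
    of scale ``within_dispersion``, re-normalized.  Deterministic given
    the seed.
    """
    if n_clusters < 2 or dim < 2:
        raise ValueError("need n_clusters >= 2 and dim >= 2")
    if n_clusters > dim:
        raise ValueError("toy centroids are orthogonal; need n_clusters <= dim")
    if vocab_size < n_clusters:
        raise ValueError(f"vocab_size {vocab_size} smaller than n_clusters {n_clusters}")
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    centroids = q[:n_clusters]
    if words is None:
        words = [f"w{i:04d}" for i in range(vocab_size)]
    elif len(words) != vocab_size:
        raise ValueError("len(words) must equal vocab_size")
    vectors: dict[str, np.ndarray] = {}
    assignment: dict[str, int] = {}
    for i, word in enumerate(words):
        c = i % n_clusters  # round-robin keeps clusters balanced
        vec = centroids[c] + within_dispersion * rng.standard_normal(dim)
        norm = np.linalg.norm(vec)
        vectors[word] = vec / norm if norm > 0 else centroids[c]
        assignment[word] = c
    return VectorLexicon(vectors=vectors, dim=dim), assignment


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    draw = rng.normal(mean, sd, size=size)
    return np.clip(draw, lo, hi)


def _neg_binomial_props(rng, mean: float, sd: float) -> int:
    """Valid-property count: truncated negative binomial matched to mean/SD."""
    var = sd * sd
    if var > mean:
        r = mean * mean / (var - mean)
        p = r / (r + mean)
        n = rng.negative_binomial(r, p)
    else:
        n = rng.poisson(mean)
    return max(int(n), 1)


# --- vocabulary -----------------------------------------------------------

_POS_CHOICES = ("noun", "verb", "adjective", "adverb")
_POS_PROBS = (0.55, 0.20, 0.15, 0.10)


def _build_vocabulary(spec: CohortSpec, rng):
    """Toy words with POS, 2x2 norm strata and cluster-structured vectors."""
    words = [f"w{i:04d}" for i in range(spec.vocab_size)]
    lex_seed = int(rng.integers(0, 2**31 - 1))
    all_words = words + list(spec.concepts)
    vectors, cluster_of = make_toy_lexicon(
        len(all_words), spec.dim, spec.n_clusters, spec.within_dispersion,
        seed=lex_seed, words=all_words,
    )
    pos_of = {w: str(rng.choice(_POS_CHOICES, p=_POS_PROBS)) for w in words}
    for c in spec.concepts:
        pos_of[c] = "noun"
    # norm strata crossed and balanced *within* each vector cluster, so that
    # cluster occupancy (which group effects manipulate) is independent of
    # stratum content by construction
    hi_c: dict[str, bool] = {}
    hi_i: dict[str, bool] = {}
    for i, w in enumerate(words):
        quadrant = (i // spec.n_clusters) % 4
        hi_c[w] = quadrant < 2
        hi_i[w] = quadrant % 2 == 0
    rows = []
    for w in words:
        rows.append(
            {
                "word": w,
                "concreteness": rng.uniform(5, 7) if hi_c[w] else rng.uniform(1, 3),
                "imageability": rng.uniform(5, 7) if hi_i[w] else rng.uniform(1, 3),
                "familiarity": rng.uniform(3, 7),
                "log_frequency": rng.uniform(0, 2.5),
                "length": int(rng.integers(2, 9)),
            }
        )
    for c in spec.concepts:  # concrete stimuli rank high on all scales
        rows.append(
            {
                "word": c,
                "concreteness": rng.uniform(5.8, 6.6),
                "imageability": rng.uniform(6.0, 6.9),
                "familiarity": rng.uniform(6.0, 6.9),
                "log_frequency": rng.uniform(0.9, 2.1),
                "length": int(rng.integers(3, 8)),
            }
        )
    norms_df = pd.DataFrame(rows)
    norms = NormsTable(table=norms_df.set_index("word"))
    # taxonomy: random tree over noun words, rooted at 'entity'
    nouns = [w for w in words if pos_of[w] == "noun"]
    nodes = ["entity"]
    edges = []
    for i in range(60):
        parent = nodes[int(rng.integers(0, len(nodes)))]
        node = f"n{i:03d}"
        edges.append((node, parent))
        nodes.append(node)
    mapping = {}
    for w in nouns + list(spec.concepts):
        senses = rng.choice(nodes[1:], size=int(rng.integers(1, 3)), replace=False)
        mapping[w] = tuple(str(s) for s in senses)
    import networkx as nx

    graph = nx.DiGraph()
    graph.add_edges_from(edges)
    taxonomy = Taxonomy(graph=graph, mapping=mapping)
    strata = {
        "hi_c": hi_c,
        "hi_i": hi_i,
        "pos_of": pos_of,
        "words": words,
        "norms_df": norms_df,
        "edges": edges,
        "mapping": mapping,
    }
    return vectors, cluster_of, norms, taxonomy, strata


def _index_cells(words, cluster_of, hi_c, hi_i, pos_of):
    """(cluster, c-stratum, i-stratum) -> word list, plus fallbacks."""
    cells: dict[tuple, list] = {}
    by_cluster: dict[int, list] = {}
    for w in words:
        cells.setdefault((cluster_of[w], hi_c[w], hi_i[w]), []).append(w)
        by_cluster.setdefault(cluster_of[w], []).append(w)
    return cells, by_cluster


def _sample_token(rng, cluster, want_hi_c, want_hi_i, cells, by_cluster):
    cell = cells.get((cluster, want_hi_c, want_hi_i))
    if not cell:
        cell = by_cluster[cluster]
    return cell[int(rng.integers(0, len(cell)))]


# --- effect calibration ---------------------------------------------------


def _predicted_feature_sd(spec: CohortSpec, group: str) -> float:
    """Between-participant SD of a stratum-mixture norm mean (analytic)."""
    hi, lo = 6.0, 2.0  # stratum means on the 1-7 scale
    scale = hi - lo
    tokens = spec.content_words_mean[group] * len(spec.concepts)
    p = spec.p_high_base
    tok_var = p * (1 - p) * scale**2 + 1.0 / 3.0  # mixture + U(±1) rating spread
    return math.sqrt((scale * spec.sigma_p) ** 2 + tok_var / tokens)


def _delta_p_for_shift(spec: CohortSpec, group: str, d: float) -> float:
    """Stratum-probability shift realizing standardized effect d on a norm mean."""
    if d == 0:
        return 0.0
    sd_feat = _predicted_feature_sd(spec, "HC")
    delta = d * sd_feat / 4.0  # feature mean = lo + (hi-lo) * p, hi-lo = 4
    return delta


_CAL_CACHE: dict = {}


def _participant_property_lemmas(
    rng, spec: CohortSpec, group: str, p_stay: float, p_c: float, p_i: float,
    cells, by_cluster, cluster_list,
) -> list[list[list[str]]]:
    """Property lemma lists per concept for one participant.

    The single source of generated token structure: both the cohort
    simulator and the calibration pilot call this, so the pilot sees
    exactly the distribution the cohort realizes.
    """
    lam_tokens = max(spec.content_words_mean[group] / spec.props_mean[group] - 1.0, 0.05)
    concepts_out = []
    for _ in range(len(spec.concepts)):
        n_props = _neg_binomial_props(rng, spec.props_mean[group], spec.props_sd[group])
        cluster = cluster_list[int(rng.integers(0, len(cluster_list)))]
        props = []
        first_token = True
        for _ in range(n_props):
            n_tok = 1 + int(rng.poisson(lam_tokens))
            lemmas = []
            for _ in range(n_tok):
                if not first_token and rng.random() >= p_stay:
                    others = [c for c in cluster_list if c != cluster]
                    cluster = others[int(rng.integers(0, len(others)))]
                first_token = False
                lemmas.append(
                    _sample_token(rng, cluster, rng.random() < p_c, rng.random() < p_i,
                                  cells, by_cluster)
                )
            props.append(lemmas)
        concepts_out.append(props)
    return concepts_out


def _pilot_participant(rng, spec, group, p_stay, p_c, p_i,
                       vectors, cells, by_cluster, cluster_list, norm_map):
    """(semantic variability, concreteness, imageability) features for one
    pilot participant, computed exactly as the extraction stage would."""
    sv_vals, conc_vals, imag_vals = [], [], []
    concepts = _participant_property_lemmas(
        rng, spec, group, p_stay, p_c, p_i, cells, by_cluster, cluster_list,
    )
    for props in concepts:
        sv = semantic_variability(props, vectors)
        if not math.isnan(sv):
            sv_vals.append(sv)
        lemmas = [w for prop in props for w in prop]
        if lemmas:
            conc_vals.append(float(np.mean([norm_map[w][0] for w in lemmas])))
            imag_vals.append(float(np.mean([norm_map[w][1] for w in lemmas])))
    return (
        float(np.mean(sv_vals)) if sv_vals else math.nan,
        float(np.mean(conc_vals)) if conc_vals else math.nan,
        float(np.mean(imag_vals)) if imag_vals else math.nan,
    )


def _calibrate_effects(spec: CohortSpec, vectors, cells, by_cluster, norm_map) -> dict:
    """Invert the generator's dials to the target standardized shifts.

    A pilot Monte Carlo with a fixed seed (calibration is part of the
    stated world and shared by all replicates of one spec) simulates
    participants through the exact generation path and measures Cohen's
    d against a pilot control population that carries the full latent
    variation.

    * semantic variability: the expected-variance curve over the
      cluster-stay probability is inverted-U shaped with its peak near
      0.5, so the generator works on the decreasing branch
      [p_stay_base, 0.95]; a monotone grid fit is refined by one secant
      step.  Only non-positive shifts are representable.
    * concreteness / imageability: the analytic stratum-mixture guess
      for the high-stratum probability shift is corrected by pilot
      measurement (patients' higher cluster-stay concentrates their
      token sample and inflates their SD, which the closed form misses).
    """
    key = (
        spec.dim, spec.n_clusters, spec.within_dispersion, spec.p_stay_base,
        spec.sigma_stay, spec.p_high_base, spec.sigma_p, len(spec.concepts),
        tuple(round(spec.content_words_mean[g], 3) for g in sorted(spec.content_words_mean)),
        tuple(round(spec.props_mean[g], 3) for g in sorted(spec.props_mean)),
        tuple(sorted(spec.semantic_variability_shift.items())),
        tuple(sorted(spec.concreteness_shift.items())),
        tuple(sorted(spec.imageability_shift.items())),
    )
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]
    stay = {"HC": spec.p_stay_base}
    d_p_c = {g: _delta_p_for_shift(spec, g, d) for g, d in spec.concreteness_shift.items()}
    d_p_i = {g: _delta_p_for_shift(spec, g, d) for g, d in spec.imageability_shift.items()}
    no_sv = all(v == 0 for v in spec.semantic_variability_shift.values())
    no_norm = all(v == 0 for v in spec.concreteness_shift.values()) and all(
        v == 0 for v in spec.imageability_shift.values()
    )
    stay.update({g: spec.p_stay_base for g in spec.semantic_variability_shift})
    if no_sv and no_norm:
        out = {"stay": stay, "d_p_c": d_p_c, "d_p_i": d_p_i}
        _CAL_CACHE[key] = out
        return out

    rng = np.random.default_rng(987654321)  # fixed: calibration defines the stated world
    cluster_list = sorted(by_cluster)

    def draw(group, p_stay_center, dp_c=0.0, dp_i=0.0, n=96):
        rows = []
        for _ in range(n):
            p_stay = float(np.clip(rng.normal(p_stay_center, spec.sigma_stay), 0.02, 0.98))
            p_c = float(np.clip(rng.normal(spec.p_high_base + dp_c, spec.sigma_p), 0.02, 0.98))
            p_i = float(np.clip(rng.normal(spec.p_high_base + dp_i, spec.sigma_p), 0.02, 0.98))
            rows.append(_pilot_participant(rng, spec, group, p_stay, p_c, p_i,
                                           vectors, cells, by_cluster, cluster_list, norm_map))
        return np.asarray(rows)  # columns: sv, conc, imag

    hc = draw("HC", spec.p_stay_base, n=480)
    if not no_sv:
        grid = np.linspace(spec.p_stay_base + 0.05, 0.95, 6)
        for group, shift in spec.semantic_variability_shift.items():
            if shift == 0:
                continue
            d_curve = np.minimum.accumulate(
                [_cohens_d(draw(group, p, n=64)[:, 0], hc[:, 0]) for p in grid]
            )
            p1 = float(np.interp(shift, d_curve[::-1], grid[::-1]))
            p1 = float(np.clip(p1, spec.p_stay_base, 0.95))
            # one secant refinement against the local grid slope
            d1 = _cohens_d(draw(group, p1, n=320)[:, 0], hc[:, 0])
            slope = np.gradient(d_curve, grid)[int(np.argmin(np.abs(grid - p1)))]
            if slope < 0:
                p1 = float(np.clip(p1 + (shift - d1) / slope, spec.p_stay_base, 0.95))
            stay[group] = p1
    if not no_norm:
        for group in set(spec.concreteness_shift) | set(spec.imageability_shift):
            t_c = spec.concreteness_shift.get(group, 0.0)
            t_i = spec.imageability_shift.get(group, 0.0)
            if t_c == 0 and t_i == 0:
                continue
            # one pilot-corrected iteration of the analytic guess; a single
            # damped step avoids compounding pilot noise
            pilot = draw(group, stay.get(group, spec.p_stay_base),
                         d_p_c.get(group, 0.0), d_p_i.get(group, 0.0), n=320)
            if t_c != 0:
                d_hat = _cohens_d(pilot[:, 1], hc[:, 1])
                if abs(d_hat) > 0.05:
                    d_p_c[group] = float(np.clip(d_p_c[group] * t_c / d_hat, -0.4, 0.4))
            if t_i != 0:
                d_hat = _cohens_d(pilot[:, 2], hc[:, 2])
                if abs(d_hat) > 0.05:
                    d_p_i[group] = float(np.clip(d_p_i[group] * t_i / d_hat, -0.4, 0.4))
    out = {"stay": stay, "d_p_c": d_p_c, "d_p_i": d_p_i}
    _CAL_CACHE[key] = out
    return out


def _cohens_d(a, b) -> float:
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    na, nb = len(a), len(b)
    pooled = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    return float((np.mean(a) - np.mean(b)) / math.sqrt(pooled)) if pooled > 0 else 0.0


# --- cohort simulation ----------------------------------------------------


def simulate_cohort(spec: CohortSpec, outdir: Optional[str | Path] = None) -> SyntheticDataset:
    """Generate a full synthetic cohort under ``spec``.

    Returns in-memory records and resources; when ``outdir`` is given,
    also writes transcripts.csv, norms.csv, vectors.txt,
    taxonomy_edges.tsv, taxonomy_mapping.tsv, clinical.csv and
    ground_truth.json in the pipeline's input formats.
    """
    rng = np.random.default_rng(spec.seed)
    vectors, cluster_of, norms, taxonomy, strata = _build_vocabulary(spec, rng)
    words = strata["words"]
    pos_of, hi_c, hi_i = strata["pos_of"], strata["hi_c"], strata["hi_i"]
    cells, by_cluster = _index_cells(words, cluster_of, hi_c, hi_i, pos_of)
    for flag in (True, False):
        if not any((c, flag, s) in cells for c in by_cluster for s in (True, False)):
            raise ValueError("concreteness effect unreachable: a norm stratum is empty")
    cluster_list = sorted(by_cluster)
    norm_map = {
        row["word"]: (row["concreteness"], row["imageability"])
        for row in strata["norms_df"].to_dict("records")
    }
    calibration = _calibrate_effects(spec, vectors, cells, by_cluster, norm_map)
    stay_by_group = calibration["stay"]
    d_p_c = calibration["d_p_c"]
    d_p_i = calibration["d_p_i"]
    records: list[PropertyRecord] = []
    participants = []
    for group in GROUPS:
        n = spec.group_sizes[group]
        for k in range(n):
            pid = f"{group}{k:03d}"
            p_c = float(np.clip(rng.normal(spec.p_high_base + d_p_c.get(group, 0.0), spec.sigma_p), 0.02, 0.98))
            p_i = float(np.clip(rng.normal(spec.p_high_base + d_p_i.get(group, 0.0), spec.sigma_p), 0.02, 0.98))
            p_stay = float(np.clip(rng.normal(stay_by_group.get(group, spec.p_stay_base), spec.sigma_stay), 0.02, 0.98))
            education = float(np.clip(rng.normal(spec.education_mean[group], spec.education_sd[group]), 0, 25))
            participants.append(
                {"participant_id": pid, "group": group, "education": round(education, 1),
                 "p_high_c": p_c, "p_high_i": p_i, "p_stay": p_stay}
            )
            concepts_lemmas = _participant_property_lemmas(
                rng, spec, group, p_stay, p_c, p_i, cells, by_cluster, cluster_list,
            )
            for concept, props in zip(spec.concepts, concepts_lemmas):
                prop_index = 0
                for lemmas in props:
                    prop_index += 1
                    tokens = tuple(
                        ContentToken(surface=w, lemma=w, pos=str(pos_of[w])) for w in lemmas
                    )
                    records.append(
                        PropertyRecord(
                            participant_id=pid, group=group, concept=concept,
                            property_index=prop_index, text=" ".join(lemmas),
                            validity_tag="valid", tokens=tokens, pretagged=True,
                        )
                    )
                    if rng.random() < spec.invalid_fraction:
                        prop_index += 1
                        tag = INVALID_TAGS[int(rng.integers(0, len(INVALID_TAGS)))]
                        records.append(
                            PropertyRecord(
                                participant_id=pid, group=group, concept=concept,
                                property_index=prop_index,
                                text="comentario fuera de tarea",
                                validity_tag=tag, tokens=(), pretagged=True,
                            )
                        )
    part_df = pd.DataFrame(participants)
    clinical = _make_clinical(spec, part_df, rng)
    ground_truth = {
        "spec": _spec_to_json(spec),
        "stay_prob_by_group": stay_by_group,
        "delta_p_concreteness": d_p_c,
        "delta_p_imageability": d_p_i,
        "participants": part_df.to_dict("records"),
    }
    dataset = SyntheticDataset(
        records=records, norms=norms, vectors=vectors, taxonomy=taxonomy,
        clinical=clinical, ground_truth=ground_truth, cluster_of=cluster_of,
    )
    if outdir is not None:
        dataset.paths = _write_dataset(dataset, strata, Path(outdir))
    return dataset


def _make_clinical(spec: CohortSpec, part_df: pd.DataFrame, rng) -> pd.DataFrame:
    """MoCA/Hayling/PDQ-39 scores as latent-linked linear models plus noise."""
    r = spec.clinical_r
    noise = math.sqrt(1 - r * r)
    z_c = (part_df["p_high_c"] - part_df["p_high_c"].mean()) / part_df["p_high_c"].std(ddof=1)
    z_stay = (part_df["p_stay"] - part_df["p_stay"].mean()) / part_df["p_stay"].std(ddof=1)
    rows = []
    for idx, row in part_df.iterrows():
        g = row["group"]
        moca = spec.moca_mean[g] + spec.moca_sd * (-r * z_c[idx] + noise * rng.standard_normal())
        # higher Hayling = worse inhibition; staying in a cluster (low SV) raises it
        hayling = spec.hayling_mean[g] + spec.hayling_sd * (r * z_stay[idx] + noise * rng.standard_normal())
        rows.append(
            {
                "participant_id": row["participant_id"],
                "group": g,
                "education": row["education"],
                "moca": round(float(np.clip(moca, 0, 30)), 1),
                "hayling": round(float(max(hayling, 0.0)), 1),
                "pdq39_total": round(float(np.clip(rng.normal(72.19, 24.68), 0, 156)), 1)
                if g == "PD" else math.nan,
                "pdq39_mobility": round(float(np.clip(rng.normal(19.53, 9.72), 0, 40)), 1)
                if g == "PD" else math.nan,
            }
        )
    return pd.DataFrame(rows)


def _spec_to_json(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["concepts"] = list(d["concepts"])
    return d


def _write_dataset(dataset: SyntheticDataset, strata: dict, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcripts": outdir / "transcripts.csv",
        "norms": outdir / "norms.csv",
        "vectors": outdir / "vectors.txt",
        "taxonomy_edges": outdir / "taxonomy_edges.tsv",
        "taxonomy_mapping": outdir / "taxonomy_mapping.tsv",
        "clinical": outdir / "clinical.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_records(dataset.records, paths["transcripts"])
    strata["norms_df"].to_csv(paths["norms"], index=False, encoding="utf-8")
    with open(paths["vectors"], "w", encoding="utf-8") as fh:
        fh.write(f"{len(dataset.vectors.vectors)} {dataset.vectors.dim}\n")
        for word, vec in dataset.vectors.vectors.items():
            fh.write(word + " " + " ".join(f"{v:.8f}" for v in vec) + "\n")
    with open(paths["taxonomy_edges"], "w", encoding="utf-8") as fh:
        for child, parent in strata["edges"]:
            fh.write(f"{child}\t{parent}\n")
    with open(paths["taxonomy_mapping"], "w", encoding="utf-8") as fh:
        for word, nodes in strata["mapping"].items():
            for node in nodes:
                fh.write(f"{word}\t{node}\n")
    dataset.clinical.to_csv(paths["clinical"], index=False, encoding="utf-8")
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(dataset.ground_truth, fh, indent=2, ensure_ascii=False)
    return {k: str(v) for k, v in paths.items()}


def load_dataset(outdir: str | Path) -> dict:
    """Re-load a written synthetic bundle through the standard loaders."""
    outdir = Path(outdir)
    from semnav.ingest import parse_responses

    return {
        "records": parse_responses(outdir / "transcripts.csv"),
        "norms": load_norms(outdir / "norms.csv"),
        "vectors": load_vectors(outdir / "vectors.txt"),
        "taxonomy": load_taxonomy(outdir / "taxonomy_edges.tsv", outdir / "taxonomy_mapping.tsv"),
        "clinical": pd.read_csv(outdir / "clinical.csv"),
        "ground_truth": json.loads((outdir / "ground_truth.json").read_text(encoding="utf-8")),
    }
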