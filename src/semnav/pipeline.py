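"""End-to-end orchestration: raw inputs -> features -> stats -> classification.

`RunConfig` validates every option before any computation and is
serialized into the output directory, so each output bundle is fully
re-derivable from the config copy plus the inputs.  `run_pipeline`
executes ingest -> feature extraction -> group statistics -> pairwise
classification -> clinical correlations, logging stage counts
(records in, excluded by validity tag, outliers removed) that satisfy
conservation at every filter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from semnav.classify import crossval_classify
from semnav.features import FEATURE_COLUMNS, build_feature_matrix
from semnav.ingest import extract_content_tokens, filter_valid, parse_responses
from semnav.lexicon import load_norms, load_taxonomy, load_vectors
from semnav.stats import compare_groups, correlate_clinical

logger = logging.getLogger(__name__)

PAIRINGS = (("PD", "HC"), ("bvFTD", "HC"), ("PD", "bvFTD"))
TANDEMS = (("PD", "HC"), ("bvFTD", "HC"))


@dataclass
class RunConfig:
    """Validated options for one pipeline run; defaults mirror the study design."""

    transcripts: str = ""
    norms: str = ""
    vectors: str = ""
    taxonomy_edges: str = ""
    taxonomy_mapping: str = ""
    clinical: str = ""
    outdir: str = "semnav_out"
    # feature options
    metric: str = "cosine"
    adjacency: str = "concat"
    polysemy: str = "min"
    variance_ddof: int = 1
    log_base: Optional[float] = None
    count_unit: str = "tokens"
    # stats options
    fence_k: float = 3.0
    fence_scope: str = "pooled"
    alpha: float = 0.05
    covariate: str = "education"
    clinical_scores: tuple = ("moca", "hayling")
    # classifier options
    n_folds: int = 5
    n_iterations: int = 1000
    tuning_grid: Optional[dict] = None
    seed: int = 0
    paper_mode: bool = False

    def __post_init__(self) -> None:
        if self.metric not in ("cosine", "euclidean"):
            raise ValueError("metric must be cosine or euclidean")
        if self.adjacency not in ("concat", "per_property"):
            raise ValueError("adjacency must be concat or per_property")
        if self.fence_scope not in ("pooled", "per_group"):
            raise ValueError("fence_scope must be pooled or per_group")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_folds < 2 or self.n_iterations < 1:
            raise ValueError("n_folds >= 2 and n_iterations >= 1 required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["clinical_scores"] = list(d["clinical_scores"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True, allow_unicode=True)


def _stage(name: str, **info) -> None:
    for key, value in info.items():
        logger.info("stage=%s %s=%s", name, key, value)


def run_pipeline(config: RunConfig, tagger=None) -> dict:
    """Execute the full analysis and write the output bundle.

    Returns a dict with the feature matrix, per-feature group
    comparisons, classifier reports for the three pairings and the
    clinical correlation results.  Any stage failure raises with the
    stage name and offending input.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    try:
        records = parse_responses(config.transcripts)
    except Exception as exc:
        raise RuntimeError(f"stage ingest failed on {config.transcripts}: {exc}") from exc
    _stage("ingest", records_in=len(records))
    retained, excluded = filter_valid(records)
    _stage("filter", retained=len(retained), **{f"excluded_{k}": v for k, v in excluded.items()})
    if tagger is not None:
        retained = [extract_content_tokens(r, tagger) for r in retained]
    if not all(r.pretagged or r.tokens for r in retained):
        n_untagged = sum(1 for r in retained if not r.pretagged and not r.tokens)
        _stage("tokenize", untagged_records=n_untagged)

    norms = load_norms(config.norms)
    vectors = load_vectors(config.vectors)
    taxonomy = load_taxonomy(config.taxonomy_edges, config.taxonomy_mapping)
    clinical = pd.read_csv(config.clinical) if config.clinical else None
    _stage("lexicon", norms=len(norms), vectors=len(vectors), taxonomy_nodes=len(taxonomy.graph))

    try:
        matrix, relevance, concept_frame = build_feature_matrix(
            retained, norms, vectors, taxonomy,
            participants=clinical,
            metric=config.metric, adjacency=config.adjacency, polysemy=config.polysemy,
            log_base=config.log_base, count_unit=config.count_unit, ddof=config.variance_ddof,
        )
    except Exception as exc:
        raise RuntimeError(f"stage features failed: {exc}") from exc
    oov = float(matrix[list(FEATURE_COLUMNS)].isna().to_numpy().mean())
    _stage("features", participants=len(matrix), missing_cell_rate=round(oov, 4))
    matrix.to_csv(out / "feature_matrix.csv", index=False, encoding="utf-8")
    concept_frame.to_csv(out / "concept_features.csv", index=False, encoding="utf-8")
    rel_long = relevance.x.stack().rename("x_ij").reset_index()
    rel_long.columns = ["concept", "property_key", "x_ij"]
    rel_long["I_j"] = rel_long["property_key"].map(relevance.concept_count)
    rel_long["k_ij"] = [
        relevance.k.at[c, p] for c, p in zip(rel_long["concept"], rel_long["property_key"])
    ]
    rel_long[rel_long["x_ij"] > 0].to_csv(out / "relevance_table.csv", index=False, encoding="utf-8")

    comparisons = []
    for feat in FEATURE_COLUMNS:
        try:
            comparisons.append(
                compare_groups(
                    matrix, feat,
                    covariate_col=config.covariate if config.covariate in matrix.columns else None,
                    fence_k=config.fence_k, fence_scope=config.fence_scope,
                )
            )
        except Exception as exc:
            raise RuntimeError(f"stage stats failed on feature {feat}: {exc}") from exc
    _stage("stats", features_tested=len(comparisons),
           outliers_removed=sum(c.n_outliers_removed for c in comparisons))
    stats_rows = [
        {
            "feature": c.feature, "F": c.f_statistic, "p": c.p_value,
            "partial_eta_squared": c.partial_eta_squared,
            "n_outliers_removed": c.n_outliers_removed, "n_used": c.n_used,
            **{
                f"tukey_p_{a}_{b}": ph.p_value
                for ph in c.posthoc for a, b in [ph.pair]
            },
            **{
                f"cohens_d_{a}_{b}": ph.cohens_d
                for ph in c.posthoc for a, b in [ph.pair]
            },
        }
        for c in comparisons
    ]
    pd.DataFrame(stats_rows).to_csv(out / "group_comparisons.csv", index=False, encoding="utf-8")

    reports = {}
    for pair in PAIRINGS:
        try:
            rep = crossval_classify(
                matrix, pair, FEATURE_COLUMNS,
                n_folds=config.n_folds, n_iterations=config.n_iterations,
                tuning_grid=config.tuning_grid, seed=config.seed,
                paper_mode=config.paper_mode,
            )
        except Exception as exc:
            raise RuntimeError(f"stage classify failed on pair {pair}: {exc}") from exc
        reports[rep.pair] = rep
        rep.decision_scores.to_csv(out / f"decision_scores_{rep.pair}.csv", index=False, encoding="utf-8")
    _stage("classify", **{k: round(v.mean_auc, 4) for k, v in reports.items()})
    with open(out / "classifier_report.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                k: {"mean_auc": v.mean_auc, "sd_auc": v.sd_auc, "aucs": v.aucs,
                    "seed": v.seed, "n_folds": v.n_folds, "n_iterations": v.n_iterations}
                for k, v in reports.items()
            },
            fh, indent=2,
        )

    correlations = []
    if clinical is not None:
        significant = [c.feature for c in comparisons if c.p_value < config.alpha]
        for patient, control in TANDEMS:
            tandem = matrix[matrix["group"].isin((patient, control))]
            for feat in significant:
                for score in config.clinical_scores:
                    if score not in tandem.columns:
                        continue
                    sub = tandem[[feat, score]].dropna()
                    if len(sub) < 4 or sub[feat].nunique() < 2 or sub[score].nunique() < 2:
                        continue
                    correlations.append(
                        correlate_clinical(
                            sub[feat], sub[score],
                            tandem=f"{patient}-{control}", feature=feat, clinical=score,
                            alpha=config.alpha,
                        )
                    )
        _stage("correlate", n_correlations=len(correlations))
        pd.DataFrame([dataclasses.asdict(c) for c in correlations]).to_csv(
            out / "clinical_correlations.csv", index=False, encoding="utf-8"
        )

    return {
        "feature_matrix": matrix,
        "relevance": relevance,
        "concept_features": concept_frame,
        "comparisons": comparisons,
        "classifier_reports": reports,
        "correlations": correlations,
        "excluded_counts": excluded,
        "outdir": str(out),
    }
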