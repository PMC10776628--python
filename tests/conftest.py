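import numpy as np
import pandas as pd
import pytest

from semnav.features import build_feature_matrix
from semnav.ingest import filter_valid
from semnav.lexicon import NormsTable, VectorLexicon
from semnav.synthetic import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic cohort under the study's stated design."""
    return simulate_cohort(CohortSpec(seed=20260918))


@pytest.fixture(scope="session")
def default_matrix(default_dataset):
    ds = default_dataset
    retained, _ = filter_valid(ds.records)
    matrix, relevance, concept_frame = build_feature_matrix(
        retained, ds.norms, ds.vectors, ds.taxonomy, participants=ds.clinical
    )
    return matrix, relevance, concept_frame


def _replicate_matrices(spec_factory, n_replicates, seed0):
    out = []
    for i in range(n_replicates):
        ds = simulate_cohort(spec_factory(seed0 + i))
        retained, _ = filter_valid(ds.records)
        matrix, _, _ = build_feature_matrix(retained, ds.norms, ds.vectors, ds.taxonomy)
        matrix = matrix.merge(
            ds.clinical[["participant_id", "education"]], on="participant_id"
        )
        out.append(matrix)
    return out


@pytest.fixture(scope="session")
def null_replicates():
    """50 zero-effect (exchangeable) cohorts for null calibration checks."""
    return _replicate_matrices(lambda s: CohortSpec.exchangeable_null(seed=s), 50, 1000)


@pytest.fixture(scope="session")
def injected_replicates():
    """50 cohorts with the study-magnitude shifts (SV 1.04 in both patient groups)."""

    def factory(seed):
        return CohortSpec(
            seed=seed,
            semantic_variability_shift={"PD": -1.04, "bvFTD": -1.04},
        )

    return _replicate_matrices(factory, 50, 2000)


@pytest.fixture
def tiny_vectors():
    """Hand-set 2-D unit vectors for distance oracles."""
    return VectorLexicon(
        vectors={
            "ex": np.array([1.0, 0.0]),
            "ey": np.array([0.0, 1.0]),
            "exb": np.array([1.0, 0.0]),
            "diag": np.array([1.0, 1.0]) / np.sqrt(2),
        },
        dim=2,
    )


@pytest.fixture
def tiny_norms():
    df = pd.DataFrame(
        {
            "word": ["sol", "ala", "calor", "luz"],
            "concreteness": [6.1, 4.0, 3.0, 6.0],
            "imageability": [6.5, 5.0, 4.0, 6.0],
            "familiarity": [6.8, 6.0, 5.5, 6.2],
            "log_frequency": [1.7, 1.0, 1.2, 1.5],
            "length": [3, 3, 5, 3],
        }
    ).set_index("word")
    return NormsTable(table=df)


def write_transcript(path, rows, header=None, delim=","):
    header = header or [
        "participant_id", "group", "concept", "property_index", "text", "validity_tag",
    ]
    lines = [delim.join(header)]
    for row in rows:
        lines.append(delim.join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
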