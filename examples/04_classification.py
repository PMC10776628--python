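"""Subject-level discrimination by repeated cross-validated gradient boosting.

All ten features enter a stratified 5-fold cross-validation repeated
over random partitions; per iteration the pooled out-of-fold scores
yield one AUC.  Normalization and imputation are fitted on training
folds only.
"""

from semnav import CohortSpec, build_feature_matrix, crossval_classify, filter_valid, simulate_cohort
from semnav.features import FEATURE_COLUMNS

dataset = simulate_cohort(CohortSpec(seed=7))
valid, _ = filter_valid(dataset.records)
matrix, _, _ = build_feature_matrix(valid, dataset.norms, dataset.vectors, dataset.taxonomy)

for pair in (("PD", "HC"), ("bvFTD", "HC")):
    report = crossval_classify(
        matrix, pair, FEATURE_COLUMNS, n_iterations=50, seed=7,
    )
    print(f"{report.pair}: AUC {report.mean_auc:.3f} +- {report.sd_auc:.3f} "
          f"({report.n_iterations} random partitions)")
# PD separates from controls well above chance because three of its
# features carry injected shifts; bvFTD differs mainly in semantic
# variability and its lower production volume, so its AUC is lower.
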